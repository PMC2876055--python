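"""End-to-end orchestration: derivation, validation, reporting.

``derive`` runs the whole chain on in-memory objects:

    cell-line contrast (intensity filtration + SAM + 2-fold cutoff)
      -> cohort median normalization (+ optional probe collapapsing)
      -> uniform-gene elimination -> k-means (k=2) -> F/t selection
      -> per-gene AUC -> signature -> scoring -> KM / log-rank / Cox

``run_derivation`` / ``run_validation`` wrap it with file IO and write the
fixed output set (differential.tsv, partition.csv, selection.tsv,
signature.tsv, scores.csv, km_<class>.tsv, cox.tsv, report.txt).  Outputs
carry a config hash and seed, never timestamps, so identical runs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clinical import ClinicalTable
from .diffexpr import SAMDifferential, estimate_intensity_cutoff, filter_low_intensity
from .matrix import (
    ExpressionMatrix,
    ProbeAnnotation,
    cohort_median_normalize,
    collapse_probes_to_genes,
    read_expression_matrix,
)
from .signature import (
    MAPS_NEG,
    MAPS_POS,
    SignatureDeriver,
    SignatureSet,
    maps_score,
)
from .survival import CoxConvergenceError, cox_fit, km_fit, logrank_test, survival_at

logger = logging.getLogger(__name__)

FIVE_YEARS_MONTHS = 60.0


@dataclass
class PipelineConfig:
    """All paths, cutoffs and flags of a pipeline run."""

    # paths (optional: in-memory runs do not need them)
    cell_matrix: str | None = None
    cohort_matrix: str | None = None
    clinical: str | None = None
    annotation: str | None = None
    output_dir: str = "mapsig_run"
    # parameters
    fold_cutoff: float = 2.0
    alpha: float = 0.05
    auc_cutoff: float = 0.95
    k: int = 2
    spread_threshold: float = 0.5
    n_restarts: int = 50
    seed: int = 0
    condition: str = "muc1cd"
    control: str = "vector"
    # flags
    use_bh_correction: bool = False
    tie_method: str = "efron"
    cohort_is_probe_level: bool = False
    use_all_genes_for_clustering: bool = False

    def validate(self) -> None:
        if not (self.fold_cutoff > 1 and 0 < self.alpha < 1 and 0.5 < self.auc_cutoff < 1):
            raise ValueError("cutoff out of range")
        if self.k < 2:
            raise ValueError("k must be >= 2")

    _PATH_FIELDS = ("cell_matrix", "cohort_matrix", "clinical", "annotation",
                    "output_dir")

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded, so the same
        analysis on the same inputs hashes identically wherever it runs)."""
        params = {
            k: v for k, v in asdict(self).items() if k not in self._PATH_FIELDS
        }
        payload = repr(sorted(params.items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunReport:
    """Auditable per-stage summary of a derivation or validation run."""

    counts: dict = field(default_factory=dict)
    partition_sizes: tuple[int, int] | None = None
    five_year_survival: dict = field(default_factory=dict)
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    cox_table: pd.DataFrame | None = None
    n_genes_used: int | None = None
    config_hash: str = ""
    seed: int = 0
    notes: list[str] = field(default_factory=list)

    def check_monotone_counts(self) -> None:
        chain = [
            self.counts.get(k)
            for k in ("differential_genes", "cohort_genes", "post_elimination",
                      "post_t_test", "signature")
            if self.counts.get(k) is not None
        ]
        if any(a < b for a, b in zip(chain, chain[1:])):
            raise AssertionError(f"gene-count chain is not non-increasing: {chain}")

    def render(self) -> str:
        lines = [
            "mapsig run report",
            f"config_hash: {self.config_hash}",
            f"seed: {self.seed}",
            "",
            "gene counts:",
        ]
        for k, v in self.counts.items():
            lines.append(f"  {k}: {v}")
        if self.partition_sizes is not None:
            lines.append(
                f"partition sizes (expressor_candidate/other): "
                f"{self.partition_sizes[0]}/{self.partition_sizes[1]}"
            )
        if self.n_genes_used is not None:
            lines.append(f"signature genes used for scoring: {self.n_genes_used}")
        if self.five_year_survival:
            lines.append("5-year survival:")
            for cls_, s in sorted(self.five_year_survival.items()):
                lines.append(f"  {cls_}: {100 * s:.1f}%")
        if self.logrank_p is not None:
            lines.append(
                f"log-rank: chi2={self.logrank_chi2:.4f} p={self.logrank_p:.3e}"
            )
        if self.cox_table is not None and not self.cox_table.empty:
            lines.append("Cox proportional hazards:")
            lines.append(self.cox_table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        for n in self.notes:
            lines.append(f"note: {n}")
        return "\n".join(lines) + "\n"


@dataclass
class DerivationResult:
    signature: SignatureSet
    report: RunReport
    differential: pd.DataFrame | None = None
    partition: pd.Series | None = None
    selection: pd.DataFrame | None = None
    scores: pd.DataFrame | None = None
    km_fits: dict = field(default_factory=dict)
    cohort_normalized: ExpressionMatrix | None = None


# ---------------------------------------------------------------------------
# survival evaluation shared by derivation and validation
# ---------------------------------------------------------------------------

def _align_clinical(scores: pd.DataFrame, clinical: ClinicalTable) -> pd.DataFrame:
    merged = scores.merge(clinical.df, on="patient_id", how="inner")
    if merged.empty:
        raise ValueError("no overlap between scored patients and the clinical table")
    return merged


def evaluate_survival(
    scores: pd.DataFrame,
    clinical: ClinicalTable,
    report: RunReport,
    tie_method: str = "efron",
) -> dict:
    """KM per signature class, log-rank, and uni/multivariate Cox."""
    merged = _align_clinical(scores, clinical)
    t = merged["time_months"].to_numpy(float)
    e = merged["event"].to_numpy(int)
    cls = merged["maps_class"].to_numpy()

    km_fits = {}
    for label in (MAPS_NEG, MAPS_POS):
        mask = cls == label
        if mask.sum() == 0:
            report.notes.append(f"no patients in class {label}")
            continue
        fit = km_fit(t[mask], e[mask])
        km_fits[label] = fit
        report.five_year_survival[label] = survival_at(fit, FIVE_YEARS_MONTHS)
    if len(km_fits) == 2:
        lr = logrank_test(t, e, cls)
        report.logrank_chi2, report.logrank_p = lr.chi_square, lr.p_value

    sub = ClinicalTable(
        merged[
            ["patient_id", "time_months", "event", "t_stage", "n_stage", "grade"]
        ].copy()
    )
    covs = {
        "T stage (T1-2 vs T3-4)": sub.t_binary().to_numpy(),
        "N stage (N0 vs N1-2)": sub.n_binary().to_numpy(),
        "Grade (1 vs 2-3)": sub.grade_binary().to_numpy(),
        "MAPS (neg vs pos)": (cls == MAPS_POS).astype(float),
    }
    rows = []
    uni_p = {}
    for name, v in covs.items():
        try:
            f = cox_fit(t, e, v, names=[name], ties=tie_method)
            uni_p[name] = float(f.wald_p[0])
        except (ValueError, CoxConvergenceError) as exc:
            uni_p[name] = np.nan
            report.notes.append(f"univariate Cox failed for {name}: {exc}")
    try:
        x = np.column_stack(list(covs.values()))
        multi = cox_fit(t, e, x, names=list(covs), ties=tie_method)
        multi_p = dict(zip(covs, multi.wald_p))
        multi_hr = dict(zip(covs, multi.hazard_ratio))
    except (ValueError, CoxConvergenceError) as exc:
        multi_p = {name: np.nan for name in covs}
        multi_hr = {name: np.nan for name in covs}
        report.notes.append(f"multivariate Cox failed: {exc}")
    for name in covs:
        rows.append(
            (name, uni_p.get(name, np.nan), multi_p.get(name, np.nan),
             multi_hr.get(name, np.nan))
        )
    report.cox_table = pd.DataFrame(
        rows, columns=["variable", "p_univariate", "p_multivariate", "HR_multivariate"]
    )
    return km_fits


# ---------------------------------------------------------------------------
# derivation
# ---------------------------------------------------------------------------

def derive(
    cell_matrix: ExpressionMatrix,
    cell_condition_labels,
    cohort_matrix: ExpressionMatrix,
    clinical: ClinicalTable,
    annotation: ProbeAnnotation,
    config: PipelineConfig | None = None,
) -> DerivationResult:
    """Full in-memory derivation; see the module docstring for the chain."""
    cfg = config or PipelineConfig()
    cfg.validate()
    report = RunReport(config_hash=cfg.config_hash(), seed=cfg.seed)

    # --- stage 1: two-condition contrast --------------------------------
    if isinstance(cell_condition_labels, dict):
        lab = cell_condition_labels
    else:
        lab = dict(zip(cell_matrix.sample_ids, cell_condition_labels))
    pairs = []
    for cond in (cfg.condition, cfg.control):
        cols = [s for s in cell_matrix.sample_ids if lab[s] == cond]
        pairs += [(cols[i], cols[i + 1]) for i in range(0, len(cols) - 1, 2)]
    cutoff = estimate_intensity_cutoff(cell_matrix, pairs)
    filtered = filter_low_intensity(cell_matrix, cutoff)
    report.counts["probes_input"] = cell_matrix.shape[0]
    report.counts["probes_post_filtration"] = filtered.shape[0]

    sam = SAMDifferential(
        condition=cfg.condition,
        control=cfg.control,
        fold_cutoff=cfg.fold_cutoff,
    ).fit(filtered, lab)
    diff_genes = sam.select_genes(annotation)
    report.counts["differential_genes"] = len(diff_genes)
    result = DerivationResult(
        signature=SignatureSet([], {}, {}, {}), report=report,
        differential=sam.result_,
    )
    if not diff_genes:
        report.notes.append("no differential genes; derivation halted")
        return result

    # --- stage 2: cohort preparation ------------------------------------
    normalized = cohort_median_normalize(cohort_matrix)
    if cfg.cohort_is_probe_level:
        normalized = collapse_probes_to_genes(normalized, annotation)
    present = [g for g in diff_genes if g in normalized.data.index]
    if len(present) < len(diff_genes):
        report.notes.append(
            f"{len(diff_genes) - len(present)} differential genes absent from cohort"
        )
    if not present:
        report.notes.append("no differential gene measured in cohort; halted")
        return result
    candidate = normalized.subset_features(present)
    report.counts["cohort_genes"] = candidate.shape[0]
    result.cohort_normalized = normalized

    # --- stage 3: outcome-blind signature derivation --------------------
    deriver = SignatureDeriver(
        spread_threshold=cfg.spread_threshold,
        k=cfg.k,
        n_restarts=cfg.n_restarts,
        alpha=cfg.alpha,
        auc_cutoff=cfg.auc_cutoff,
        use_bh_correction=cfg.use_bh_correction,
        use_all_genes_for_clustering=cfg.use_all_genes_for_clustering,
        random_state=cfg.seed,
    ).fit(candidate)
    report.counts["post_elimination"] = deriver.counts_["post_elimination"]
    report.counts["post_t_test"] = deriver.counts_["post_t_test"]
    report.counts["signature"] = deriver.counts_["signature"]
    report.partition_sizes = deriver.partition_.sizes()
    result.partition = deriver.partition_.labels
    result.selection = deriver.records_
    result.signature = deriver.signature_
    report.check_monotone_counts()
    if len(deriver.signature_) == 0:
        report.notes.append("empty signature; run ends after reporting")
        return result

    # --- stage 4: scoring and survival ----------------------------------
    scores = maps_score(normalized, deriver.signature_)
    result.scores = scores
    report.n_genes_used = int(scores["n_genes_used"].iloc[0])
    result.km_fits = evaluate_survival(scores, clinical, report, cfg.tie_method)
    return result


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_signature(
    signature: SignatureSet,
    cohort_matrix: ExpressionMatrix,
    clinical: ClinicalTable,
    config: PipelineConfig | None = None,
) -> tuple[RunReport, pd.DataFrame, dict]:
    """Score an independent cohort with a fixed signature and test survival.

    The cohort is normalized within itself (its own per-gene medians); genes
    absent from the platform are skipped and the count reported.
    """
    cfg = config or PipelineConfig()
    report = RunReport(config_hash=cfg.config_hash(), seed=cfg.seed)
    if cohort_matrix.shape[1] < 2:
        raise ValueError("validation cohort needs >= 2 patients for normalization")
    normalized = cohort_median_normalize(cohort_matrix)
    if cfg.cohort_is_probe_level:
        raise ValueError("validation expects a gene-level matrix")
    scores = maps_score(normalized, signature)
    report.counts["signature"] = len(signature)
    report.n_genes_used = int(scores["n_genes_used"].iloc[0])
    if report.n_genes_used < len(signature):
        report.notes.append(
            f"{len(signature) - report.n_genes_used} signature genes absent "
            "from the validation platform"
        )
    km_fits = evaluate_survival(scores, clinical, report, cfg.tie_method)
    return report, scores, km_fits


# ---------------------------------------------------------------------------
# file-driven entry points
# ---------------------------------------------------------------------------

def _write_outputs(outdir: Path, cfg: PipelineConfig, result: DerivationResult) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# config {cfg.config_hash()} seed {cfg.seed}\n"
    if result.differential is not None:
        with open(outdir / "differential.tsv", "w") as fh:
            fh.write(header)
            result.differential.to_csv(fh, sep="\t", index=False, float_format="%.8g")
    if result.partition is not None:
        with open(outdir / "partition.csv", "w") as fh:
            fh.write(header)
            result.partition.rename_axis("patient_id").to_csv(fh)
    if result.selection is not None:
        with open(outdir / "selection.tsv", "w") as fh:
            fh.write(header)
            result.selection.to_csv(fh, sep="\t", index=False, float_format="%.8g")
    result.signature.metadata.setdefault("config", cfg.config_hash())
    result.signature.write(outdir / "signature.tsv")
    if result.scores is not None:
        with open(outdir / "scores.csv", "w") as fh:
            fh.write(header)
            result.scores.to_csv(fh, index=False, float_format="%.8g")
    for label, fit in result.km_fits.items():
        with open(outdir / f"km_{label}.tsv", "w") as fh:
            fh.write(header)
            fit.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.8g")
    if result.report.cox_table is not None:
        with open(outdir / "cox.tsv", "w") as fh:
            fh.write(header)
            result.report.cox_table.to_csv(fh, sep="\t", index=False, float_format="%.8g")
    (outdir / "report.txt").write_text(result.report.render())


def run_derivation(config: PipelineConfig) -> DerivationResult:
    """File-driven derivation: read inputs, run ``derive``, write outputs."""
    config.validate()
    for name in ("cell_matrix", "cohort_matrix", "clinical", "annotation"):
        if getattr(config, name) is None:
            raise ValueError(f"config path {name!r} is required for run_derivation")
    cell = read_expression_matrix(config.cell_matrix, scale="raw")
    cohort = read_expression_matrix(config.cohort_matrix, scale="raw")
    clinical = ClinicalTable.read(config.clinical)
    ann = ProbeAnnotation.read(config.annotation)
    labels = {
        s: (config.condition if s.rsplit("_", 1)[0] == config.condition else config.control)
        for s in cell.sample_ids
    }
    result = derive(cell, labels, cohort, clinical, ann, config)
    _write_outputs(Path(config.output_dir), config, result)
    return result


def run_validation(signature_path, config: PipelineConfig) -> RunReport:
    """File-driven validation of an existing signature on a new cohort."""
    config.validate()
    signature = SignatureSet.read(signature_path)
    if len(signature) == 0:
        raise ValueError("signature file contains no genes")
    cohort = read_expression_matrix(config.cohort_matrix, scale="raw")
    clinical = ClinicalTable.read(config.clinical)
    report, scores, km_fits = validate_signature(signature, cohort, clinical, config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# config {config.config_hash()} seed {config.seed}\n"
    with open(outdir / "scores.csv", "w") as fh:
        fh.write(header)
        scores.to_csv(fh, index=False, float_format="%.8g")
    for label, fit in km_fits.items():
        with open(outdir / f"km_{label}.tsv", "w") as fh:
            fh.write(header)
            fit.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.8g")
    (outdir / "report.txt").write_text(report.render())
    return report
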
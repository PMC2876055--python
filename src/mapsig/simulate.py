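"""Synthetic data generators with planted ground truth.

Two generators mirror the two kinds of input the analysis consumes:

``simulate_cell_line_arrays``
    duplicated two-condition microarrays (oncogene-transfected vs empty
    vector) with planted fold-changes and a low-intensity, poorly
    reproducible background probe population;

``simulate_cohort``
    a patient cohort in which a latent proliferation factor ``z`` drives a
    correlated gene module and, through a proportional-hazards model, the
    hazard of death, with administrative censoring and stage/node/grade
    covariates mildly correlated with ``z``.

Both return a :class:`GroundTruth`-style record sufficient to score any
downstream recovery without re-simulation.  All randomness flows through a
single seeded ``numpy`` generator; no time-based entropy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .clinical import ClinicalTable
from .matrix import RAW, ExpressionMatrix, ProbeAnnotation

#: the seven-gene proliferation signature, in descending published AUC order
MAPS_GENES = ("CDC20", "RRM2", "CCNB1", "MAD2L1", "PRC1", "CDC2", "CDKN3")


# ---------------------------------------------------------------------------
# cell-line arrays
# ---------------------------------------------------------------------------

@dataclass
class CellLineSimConfig:
    """Two-condition duplicated-array design with planted fold changes.

    ``n_probes`` well-measured probes (of which ``n_planted_up`` /
    ``n_planted_down`` differ by ``planted_fold`` between conditions) plus
    ``n_background_probes`` low-intensity probes whose replicate noise is
    large (``background_noise_sd``), emulating the sub-threshold population
    that intensity filtration is meant to remove.  Pooling of RNA from
    independent lines is emulated simply as small replicate noise.
    """

    n_probes: int = 1000
    n_planted_up: int = 50
    n_planted_down: int = 50
    planted_fold: float = 2.5
    n_background_probes: int = 300
    noise_sd: float = 0.2
    n_arrays_per_condition: int = 2
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.0
    background_log2_mean: float = 7.0
    background_log2_sd: float = 0.5
    background_noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_planted_up + self.n_planted_down > self.n_probes:
            raise ValueError("planted probe counts exceed n_probes")
        if self.planted_fold < 2.0:
            raise ValueError("planted_fold must be >= 2 (linear scale)")
        if self.noise_sd <= 0 or self.background_noise_sd <= 0:
            raise ValueError("noise standard deviations must be > 0")
        if self.n_arrays_per_condition < 2:
            raise ValueError("need >= 2 arrays per condition")


@dataclass
class CellLineTruth:
    up_probes: list[str]
    down_probes: list[str]
    null_probes: list[str]
    background_probes: list[str]
    planted_fold: float
    annotation: ProbeAnnotation

    def write(self, path) -> None:
        rows = (
            [(p, "up") for p in self.up_probes]
            + [(p, "down") for p in self.down_probes]
            + [(p, "null") for p in self.null_probes]
            + [(p, "background") for p in self.background_probes]
        )
        pd.DataFrame(rows, columns=["probe_id", "role"]).to_csv(path, index=False)


def simulate_cell_line_arrays(
    cfg: CellLineSimConfig,
) -> tuple[ExpressionMatrix, CellLineTruth]:
    """Draw raw intensities for condition and control arrays.

    Noise is lognormal on the raw scale (Gaussian in log2).  Planted probes
    differ by ``planted_fold`` in expectation; background probes sit at low
    intensity with inflated replicate noise so that they straddle any
    sensible filtration cutoff.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_rep = cfg.n_arrays_per_condition
    n_main = cfg.n_probes
    n_bg = cfg.n_background_probes

    probe_ids = [f"probe_{i:05d}" for i in range(n_main + n_bg)]
    up = probe_ids[: cfg.n_planted_up]
    down = probe_ids[cfg.n_planted_up : cfg.n_planted_up + cfg.n_planted_down]
    null = probe_ids[cfg.n_planted_up + cfg.n_planted_down : n_main]
    background = probe_ids[n_main:]

    base = np.empty(n_main + n_bg)
    base[:n_main] = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, n_main)
    base[n_main:] = rng.normal(
        cfg.background_log2_mean, cfg.background_log2_sd, n_bg
    )

    shift = np.zeros(n_main + n_bg)
    lf = np.log2(cfg.planted_fold)
    shift[: cfg.n_planted_up] = lf
    shift[cfg.n_planted_up : cfg.n_planted_up + cfg.n_planted_down] = -lf

    sd = np.full(n_main + n_bg, cfg.noise_sd)
    sd[n_main:] = cfg.background_noise_sd

    cols, mats = [], []
    for cond, offset in (("muc1cd", shift), ("vector", np.zeros_like(shift))):
        for r in range(n_rep):
            cols.append(f"{cond}_{r + 1}")
            log2 = base + offset + rng.normal(0.0, 1.0, base.shape) * sd
            mats.append(2.0 ** log2)
    data = pd.DataFrame(np.column_stack(mats), index=probe_ids, columns=cols)
    data.index.name = "feature_id"

    mapping = {}
    for i, p in enumerate(up):
        mapping[p] = MAPS_GENES[i] if i < len(MAPS_GENES) else f"UPG{i:03d}"
    for i, p in enumerate(down):
        mapping[p] = f"DNG{i:03d}"
    for i, p in enumerate(null):
        mapping[p] = f"NUL{i:04d}"
    # background probes are deliberately unannotated

    truth = CellLineTruth(
        up_probes=up,
        down_probes=down,
        null_probes=null,
        background_probes=background,
        planted_fold=cfg.planted_fold,
        annotation=ProbeAnnotation(mapping),
    )
    return ExpressionMatrix(data, RAW), truth


def cell_line_condition_labels(m: ExpressionMatrix) -> dict[str, str]:
    """Map each array name to its condition prefix (before the final '_')."""
    return {s: s.rsplit("_", 1)[0] for s in m.sample_ids}


# ---------------------------------------------------------------------------
# patient cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSimConfig:
    """Survival-linked cohort with a planted one-factor proliferation module.

    The latent factor z is a two-component Gaussian mixture (so that a
    2-cluster structure genuinely exists); module gene g of patient i has
    log2 intensity ``baseline_g + loading * z_i + N(0, noise_sd)``, giving a
    within-module correlation of loading^2 / (loading^2 + noise_sd^2).
    Survival times are exponential with hazard
    ``baseline_hazard * exp(beta_z z + beta_t T + beta_n N)`` (rates per
    month); censoring is administrative at a Uniform(0, h) horizon with h
    calibrated to the requested censoring fraction.
    """

    n_patients: int = 441
    n_genes: int = 254
    module_size: int = 7
    loading: float = 1.0
    noise_sd: float = 0.5
    background_sd: float = 0.8
    uniform_sd: float = 0.05
    latent_weights: tuple[float, float] = (0.5, 0.5)
    latent_means: tuple[float, float] = (-1.0, 1.0)
    latent_sds: tuple[float, float] = (0.5, 0.5)
    beta_z: float = float(np.log(2.0))
    beta_t: float = float(np.log(1.5))
    beta_n: float = float(np.log(2.0))
    baseline_hazard: float = 0.01
    censoring_rate: float = 0.3
    uniform_gene_fraction: float = 0.2
    covariate_odds_ratio: float = 1.5
    base_rate_t: float = 0.09
    base_rate_n: float = 0.32
    base_rate_grade: float = 0.86
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.module_size > self.n_genes:
            raise ValueError("module_size exceeds n_genes")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.noise_sd <= 0 or self.background_sd <= 0 or self.uniform_sd <= 0:
            raise ValueError("noise standard deviations must be > 0")
        if abs(sum(self.latent_weights) - 1.0) > 1e-9:
            raise ValueError("latent mixture weights must sum to 1")


@dataclass
class CohortTruth:
    z: np.ndarray
    true_class: np.ndarray  # 1 = high-z mixture component ("expressor")
    module_genes: list[str]
    directions: dict[str, str]
    uniform_genes: list[str]
    betas: dict[str, float]
    censoring_horizon: float

    def write(self, directory) -> None:
        directory = Path(directory)
        pd.DataFrame(
            {
                "patient_index": np.arange(len(self.z)),
                "z": self.z,
                "true_class": self.true_class,
            }
        ).to_csv(directory / "truth_patients.csv", index=False)
        rows = [(g, "module", self.directions[g]) for g in self.module_genes]
        rows += [(g, "uniform", "") for g in self.uniform_genes]
        pd.DataFrame(rows, columns=["gene", "role", "direction"]).to_csv(
            directory / "truth_genes.csv", index=False
        )


def _censoring_horizon(times: np.ndarray, target: float) -> float:
    """Horizon h such that C ~ U(0, h) censors about a `target` fraction.

    E[fraction censored | T] = mean(min(T_i, h) / h), monotone decreasing
    in h; solved by bisection on the realized event times.
    """
    if target <= 0:
        return np.inf

    def frac(h):
        return float(np.mean(np.minimum(times, h) / h))

    lo, hi = 1e-6, float(times.max()) * 2
    while frac(hi) > target:
        hi *= 2
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(
    cfg: CohortSimConfig,
    gene_names: list[str] | None = None,
    module_genes: list[str] | None = None,
    uniform_genes: list[str] | None = None,
) -> tuple[ExpressionMatrix, ClinicalTable, CohortTruth]:
    """Generate raw-scale cohort expression, clinical outcomes and truth.

    The optional ``gene_names`` / ``module_genes`` / ``uniform_genes``
    arguments let a caller impose an externally defined gene universe (used
    when composing with the cell-line simulation); by default the module
    carries the seven signature symbols and other genes get generic names.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients

    # latent factor z from the two-component mixture
    comp = rng.random(n) < cfg.latent_weights[1]
    z = np.where(
        comp,
        rng.normal(cfg.latent_means[1], cfg.latent_sds[1], n),
        rng.normal(cfg.latent_means[0], cfg.latent_sds[0], n),
    )
    hi = int(np.argmax(cfg.latent_means))
    true_class = (comp == bool(hi)).astype(int)

    # gene universe and roles
    n_uniform = int(round(cfg.uniform_gene_fraction * cfg.n_genes))
    if gene_names is None:
        module = [
            MAPS_GENES[i] if i < len(MAPS_GENES) else f"MOD{i:03d}"
            for i in range(cfg.module_size)
        ]
        uniform = [f"UNI{i:04d}" for i in range(n_uniform)]
        n_bg = cfg.n_genes - cfg.module_size - n_uniform
        backgr = [f"BKG{i:04d}" for i in range(n_bg)]
        gene_names = module + uniform + backgr
    else:
        gene_names = list(gene_names)
        if module_genes is None:
            module = gene_names[: cfg.module_size]
        else:
            module = list(module_genes)
        remaining = [g for g in gene_names if g not in set(module)]
        if uniform_genes is None:
            uniform = remaining[:n_uniform]
        else:
            uniform = list(uniform_genes)
    module_set, uniform_set = set(module), set(uniform)

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, len(gene_names))
    log2 = np.empty((len(gene_names), n))
    for gi, g in enumerate(gene_names):
        if g in module_set:
            log2[gi] = (
                baseline[gi] + cfg.loading * z + rng.normal(0, cfg.noise_sd, n)
            )
        elif g in uniform_set:
            log2[gi] = baseline[gi] + rng.normal(0, cfg.uniform_sd, n)
        else:
            log2[gi] = baseline[gi] + rng.normal(0, cfg.background_sd, n)

    patient_ids = [f"P{i:04d}" for i in range(n)]
    expr = ExpressionMatrix(
        pd.DataFrame(2.0 ** log2, index=gene_names, columns=patient_ids), RAW
    )

    # clinical covariates, mildly linked to z on the logit scale
    def binary(base_rate):
        logit = np.log(base_rate / (1 - base_rate)) + np.log(
            cfg.covariate_odds_ratio
        ) * z
        return (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

    t_hi, n_pos, g_hi = binary(cfg.base_rate_t), binary(cfg.base_rate_n), binary(
        cfg.base_rate_grade
    )
    t_stage = np.where(t_hi == 1, rng.choice(["T3", "T4"], n), rng.choice(["T1", "T2"], n))
    n_stage = np.where(n_pos == 1, rng.choice(["N1", "N2"], n), "N0")
    grade = np.where(g_hi == 1, rng.choice(["2", "3"], n), "1")

    # exponential survival under the proportional-hazards model
    rate = cfg.baseline_hazard * np.exp(
        cfg.beta_z * z + cfg.beta_t * t_hi + cfg.beta_n * n_pos
    )
    t_event = rng.exponential(1.0 / rate)
    horizon = _censoring_horizon(t_event, cfg.censoring_rate)
    if np.isinf(horizon):
        time, event = t_event, np.ones(n, dtype=int)
    else:
        c = rng.uniform(0, horizon, n)
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "patient_id": patient_ids,
                "time_months": time,
                "event": event,
                "t_stage": t_stage,
                "n_stage": n_stage,
                "grade": grade,
            }
        )
    )
    truth = CohortTruth(
        z=z,
        true_class=true_class,
        module_genes=list(module),
        directions={g: "up" for g in module},
        uniform_genes=list(uniform),
        betas={"z": cfg.beta_z, "t": cfg.beta_t, "n": cfg.beta_n},
        censoring_horizon=float(horizon) if np.isfinite(horizon) else float("inf"),
    )
    return expr, clinical, truth


# ---------------------------------------------------------------------------
# composed study
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    cell_matrix: ExpressionMatrix
    cell_truth: CellLineTruth
    cohort_matrix: ExpressionMatrix
    clinical: ClinicalTable
    cohort_truth: CohortTruth
    annotation: ProbeAnnotation


def simulate_study(
    cell_cfg: CellLineSimConfig | None = None,
    cohort_cfg: CohortSimConfig | None = None,
    seed: int | None = None,
) -> StudyData:
    """Generate a coherent cell-line + cohort pair for end-to-end runs.

    The cohort's gene universe is the set of annotated cell-line genes, so
    that whatever differential set the contrast stage produces can be looked
    up in the cohort; the planted proliferation module is the seven
    signature genes carried by the first planted-up probes, and the
    near-constant (uniform) genes are drawn from the remaining planted
    genes — emulating differential genes that turn out flat in patients.
    """
    cell_cfg = cell_cfg or CellLineSimConfig()
    cohort_cfg = cohort_cfg or CohortSimConfig()
    if seed is not None:
        cell_cfg.seed = seed
        cohort_cfg.seed = seed + 1

    cell_m, cell_truth = simulate_cell_line_arrays(cell_cfg)
    ann = cell_truth.annotation
    genes = sorted(set(ann.mapping.values()))
    module = [g for g in MAPS_GENES if g in genes][: cohort_cfg.module_size]
    planted = sorted(
        {ann.mapping[p] for p in cell_truth.up_probes + cell_truth.down_probes}
        - set(module)
    )
    n_uniform = int(round(cohort_cfg.uniform_gene_fraction * len(planted)))
    uniform = planted[:n_uniform]
    cohort_cfg.n_genes = len(genes)
    cohort_m, clinical, cohort_truth = simulate_cohort(
        cohort_cfg, gene_names=genes, module_genes=module, uniform_genes=uniform
    )
    return StudyData(cell_m, cell_truth, cohort_m, clinical, cohort_truth, ann)
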
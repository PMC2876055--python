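"""Cohort stage: from a differential gene set to a short prognostic signature.

The derivation is outcome-blind by construction — nothing in this module
accepts survival data.  Patients are partitioned by k-means (k=2) in the
space of the candidate genes; genes discriminating the two clusters are
found by a variance-test-guided t-test at alpha = 0.05 (no multiplicity
correction, matching common practice of the era; a Benjamini-Hochberg
option exists behind a flag); each surviving gene is scored as a
single-feature classifier of cluster membership by its empirical
(Mann-Whitney) AUC, and genes whose AUC exceeds a strict cutoff (default
0.95) form the signature.  A patient's signature score is the mean
normalized log2 expression over the signature genes (down-oriented genes
sign-flipped); score > 0 labels the patient an expressor (MAPS+).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.metrics import roc_auc_score

from .matrix import NORMALIZED, ExpressionMatrix

logger = logging.getLogger(__name__)

EXPRESSOR = "expressor_candidate"
OTHER = "other"
MAPS_POS = "MAPS_pos"
MAPS_NEG = "MAPS_neg"


# ---------------------------------------------------------------------------
# uniform-gene elimination
# ---------------------------------------------------------------------------

def remove_uniform_genes(
    m: ExpressionMatrix, spread_threshold: float = 0.5
) -> ExpressionMatrix:
    """Drop genes whose interquartile range across patients is below the
    threshold (log2 units); these carry no clustering information."""
    if m.scale != NORMALIZED:
        raise ValueError("uniform-gene elimination expects a normalized matrix")
    q75, q25 = np.percentile(m.values, [75, 25], axis=1)
    keep = (q75 - q25) >= spread_threshold
    if not keep.any():
        raise ValueError("every gene is uniform at this spread threshold")
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("remove_uniform_genes: eliminated %d / %d genes", n_removed, len(keep))
    return ExpressionMatrix(m.data.loc[keep], m.scale)


# ---------------------------------------------------------------------------
# patient partition
# ---------------------------------------------------------------------------

@dataclass
class PatientPartition:
    """k=2 patient clusters; the expressor candidate is the cluster with the
    higher mean expression across the candidate genes."""

    labels: pd.Series  # patient_id -> EXPRESSOR / OTHER
    k: int
    inertia: float
    n_restarts: int

    @property
    def expressor_ids(self) -> list[str]:
        return list(self.labels.index[self.labels == EXPRESSOR])

    @property
    def other_ids(self) -> list[str]:
        return list(self.labels.index[self.labels == OTHER])

    def sizes(self) -> tuple[int, int]:
        return len(self.expressor_ids), len(self.other_ids)


def kmeans_partition(
    m: ExpressionMatrix,
    genes: list[str] | None = None,
    k: int = 2,
    n_restarts: int = 50,
    seed: int = 0,
) -> PatientPartition:
    """Euclidean k-means over patients in gene space, best of ``n_restarts``.

    Cluster identity is anonymous in k-means, so the expressor-candidate
    label is assigned to the cluster with the higher grand mean over the
    clustering genes.
    """
    if genes is not None:
        m = m.subset_features(genes)
    x = m.values.T  # patients as samples
    if k > x.shape[0]:
        raise ValueError("k exceeds the number of patients")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(x)
    raw = km.labels_
    if len(np.unique(raw)) < k:
        raise ValueError("k-means produced an empty cluster")
    means = [x[raw == c].mean() for c in range(k)]
    expressor_cluster = int(np.argmax(means))
    labels = pd.Series(
        np.where(raw == expressor_cluster, EXPRESSOR, OTHER),
        index=m.sample_ids,
        name="cluster",
    )
    return PatientPartition(labels, k, float(km.inertia_), n_restarts)


# ---------------------------------------------------------------------------
# discriminant gene selection
# ---------------------------------------------------------------------------

def _variance_f_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided variance-ratio F test p-value."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    p = 2 * min(
        stats.f.cdf(f, len(a) - 1, len(b) - 1),
        stats.f.sf(f, len(a) - 1, len(b) - 1),
    )
    return float(min(p, 1.0))


def select_discriminant_genes(
    m: ExpressionMatrix,
    partition: PatientPartition,
    alpha: float = 0.05,
    use_bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-gene F-test-guided t-test between the two patient clusters.

    The variance-ratio F test (two-sided, alpha 0.05) decides whether the
    unequal-variance (Welch) or the pooled t statistic is used; genes with a
    two-sided t p-value below ``alpha`` are selected.  With
    ``use_bh_correction`` the t p-values are Benjamini-Hochberg adjusted
    before thresholding (off by default).
    Returns a DataFrame (gene, f_p, t_p, t_variant, selected).
    """
    if m.scale != NORMALIZED:
        raise ValueError("discriminant selection expects a normalized matrix")
    a_ids, b_ids = partition.expressor_ids, partition.other_ids
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("each cluster needs >= 2 patients")
    a = m.data[a_ids].to_numpy()
    b = m.data[b_ids].to_numpy()
    rows = []
    for gi, gene in enumerate(m.feature_ids):
        f_p = _variance_f_test(a[gi], b[gi])
        equal_var = f_p >= 0.05
        if np.allclose(a[gi], a[gi][0]) and np.allclose(b[gi], b[gi][0]) and np.isclose(
            a[gi][0], b[gi][0]
        ):
            t_p = 1.0  # identical constants in both clusters: t = 0
        else:
            t_p = float(stats.ttest_ind(a[gi], b[gi], equal_var=equal_var).pvalue)
        rows.append((gene, f_p, t_p, "pooled" if equal_var else "unequal_variance"))
    df = pd.DataFrame(rows, columns=["gene", "f_p", "t_p", "t_variant"])
    pvals = df["t_p"].to_numpy()
    if use_bh_correction:
        order = np.argsort(pvals)
        ranked = pvals[order] * len(pvals) / (np.arange(len(pvals)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(adj)
        out[order] = np.minimum(adj, 1.0)
        pvals = out
        df["t_p_adjusted"] = pvals
    df["selected"] = pvals < alpha
    return df


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def gene_auc(values: pd.Series | np.ndarray, partition: PatientPartition) -> float:
    """Oriented empirical AUC of one gene as a cluster classifier.

    AUC = P(value_expressor > value_other) + 1/2 P(tie) over all
    between-cluster patient pairs, with the expressor-candidate cluster as
    the positive class.  Values below 0.5 indicate a gene expressed lower
    in the expressor cluster.
    """
    pos, neg = partition.expressor_ids, partition.other_ids
    if not pos or not neg:
        raise ValueError("both clusters must be non-empty")
    if isinstance(values, pd.Series):
        v = values.loc[list(partition.labels.index)].to_numpy(float)
    else:
        v = np.asarray(values, float)
    y = (partition.labels == EXPRESSOR).to_numpy()
    return float(roc_auc_score(y, v))


# ---------------------------------------------------------------------------
# signature selection and scoring
# ---------------------------------------------------------------------------

@dataclass
class SignatureSet:
    """Ordered signature genes with per-gene AUC and orientation."""

    gene_symbols: list[str]
    auc: dict[str, float]
    direction: dict[str, str]  # "up" / "down" relative to the expressor cluster
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.gene_symbols)

    def write(self, path) -> None:
        meta = " ".join(f"{k}={v}" for k, v in sorted(self.metadata.items()))
        with open(path, "w") as fh:
            fh.write(f"# signature derivation: {meta}\n")
            fh.write("gene_symbol\tauc\tdirection\n")
            for g in self.gene_symbols:
                fh.write(f"{g}\t{self.auc[g]:.6f}\t{self.direction[g]}\n")

    @classmethod
    def read(cls, path) -> "SignatureSet":
        metadata: dict = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first.lstrip("#").strip().split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        metadata[k.replace("signature", "").strip(":")] = v
                header = fh.readline()
            else:
                header = first
            if not header.startswith("gene_symbol"):
                raise ValueError("malformed signature file")
            genes, auc, direction = [], {}, {}
            for line in fh:
                g, a, d = line.strip().split("\t")
                genes.append(g)
                auc[g] = float(a)
                direction[g] = d
        return cls(genes, auc, direction, metadata)


def select_signature(
    records: pd.DataFrame, auc_cutoff: float = 0.95
) -> SignatureSet:
    """Genes whose discrimination AUC strictly exceeds the cutoff.

    ``records`` must carry gene, auc (oriented) and direction columns for
    the t-test-selected genes.  A down-oriented gene discriminates with
    AUC' = 1 - auc; the folded value is stored.  Output is ordered by AUC
    descending, ties alphabetical.
    """
    rows = []
    for _, r in records.iterrows():
        folded = r["auc"] if r["direction"] == "up" else 1.0 - r["auc"]
        if folded > auc_cutoff:
            rows.append((r["gene"], folded, r["direction"]))
    rows.sort(key=lambda t: (-t[1], t[0]))
    if not rows:
        logger.warning("select_signature: no gene exceeded AUC %.3f", auc_cutoff)
    return SignatureSet(
        gene_symbols=[g for g, _, _ in rows],
        auc={g: a for g, a, _ in rows},
        direction={g: d for g, _, d in rows},
        metadata={"auc_cutoff": auc_cutoff},
    )


def maps_score(m: ExpressionMatrix, sig: SignatureSet) -> pd.DataFrame:
    """Relative expression score and expressor class per patient.

    score = mean over the available signature genes of the normalized log2
    value, with down-oriented genes sign-flipped.  Strictly positive scores
    give class MAPS_pos.  Returns (patient_id, score, maps_class,
    n_genes_used).
    """
    if m.scale != NORMALIZED:
        raise ValueError("scoring expects a normalized matrix")
    present = [g for g in sig.gene_symbols if g in m.data.index]
    if not present:
        raise ValueError("no signature gene present in the matrix")
    missing = set(sig.gene_symbols) - set(present)
    if missing:
        logger.info("maps_score: %d signature genes absent: %s", len(missing), sorted(missing))
    block = m.data.loc[present].copy()
    for g in present:
        if sig.direction[g] == "down":
            block.loc[g] = -block.loc[g]
    score = block.mean(axis=0)
    return pd.DataFrame(
        {
            "patient_id": m.sample_ids,
            "score": score.to_numpy(),
            "maps_class": np.where(score.to_numpy() > 0, MAPS_POS, MAPS_NEG),
            "n_genes_used": len(present),
        }
    )


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class SignatureDeriver(BaseEstimator):
    """Outcome-blind signature derivation as a fit-shaped estimator.

    fit(m) runs: uniform-gene elimination -> k-means patient partition ->
    F/t discriminant selection -> per-gene AUC -> strict-cutoff signature.

    Fitted attributes: ``partition_``, ``records_`` (selection table with
    AUCs), ``signature_`` and ``counts_`` (the gene-count reduction chain).
    """

    def __init__(
        self,
        spread_threshold: float = 0.5,
        k: int = 2,
        n_restarts: int = 50,
        alpha: float = 0.05,
        auc_cutoff: float = 0.95,
        use_bh_correction: bool = False,
        use_all_genes_for_clustering: bool = False,
        random_state: int = 0,
    ):
        self.spread_threshold = spread_threshold
        self.k = k
        self.n_restarts = n_restarts
        self.alpha = alpha
        self.auc_cutoff = auc_cutoff
        self.use_bh_correction = use_bh_correction
        self.use_all_genes_for_clustering = use_all_genes_for_clustering
        self.random_state = random_state

    def fit(self, m: ExpressionMatrix) -> "SignatureDeriver":
        n_input = m.shape[0]
        informative = remove_uniform_genes(m, self.spread_threshold)
        cluster_m = m if self.use_all_genes_for_clustering else informative
        self.partition_ = kmeans_partition(
            cluster_m,
            k=self.k,
            n_restarts=self.n_restarts,
            seed=self.random_state,
        )
        records = select_discriminant_genes(
            informative,
            self.partition_,
            alpha=self.alpha,
            use_bh_correction=self.use_bh_correction,
        )
        sel = records[records["selected"]].copy()
        aucs, directions = [], []
        order = list(self.partition_.labels.index)
        for gene in sel["gene"]:
            a = gene_auc(informative.data.loc[gene, order], self.partition_)
            aucs.append(a)
            directions.append("up" if a >= 0.5 else "down")
        sel["auc"] = aucs
        sel["direction"] = directions
        self.records_ = records.merge(
            sel[["gene", "auc", "direction"]], on="gene", how="left"
        )
        self.signature_ = select_signature(sel, self.auc_cutoff)
        self.signature_.metadata.update(
            {"alpha": self.alpha, "k": self.k, "auc_cutoff": self.auc_cutoff}
        )
        self.counts_ = {
            "input_genes": n_input,
            "post_elimination": informative.shape[0],
            "post_t_test": int(records["selected"].sum()),
            "signature": len(self.signature_),
        }
        return self

    def transform(self, m: ExpressionMatrix) -> pd.DataFrame:
        """Score a (normalized) cohort with the fitted signature."""
        return maps_score(m, self.signature_)
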
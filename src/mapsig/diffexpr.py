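"""Two-condition contrast: intensity filtration and SAM-style selection.

The stage reproduces the classic small-replicate microarray workflow:

1. estimate a signal-intensity cutoff by ROC analysis of probe
   reproducibility between duplicate arrays and drop probes that never
   clear it;
2. compute per-probe linear fold changes and moderated d-statistics
   d_i = (mean_1 - mean_2) / (s_i + s0);
3. estimate a false discovery ratio for a grid of delta band half-widths
   by exhaustively permuting the condition labels (with 2+2 arrays there
   are only 4!/2!2! = 6 distinct relabelings, so enumeration is exact);
4. call probes passing BOTH the two-sided 2.0-fold cutoff and the SAM band
   at the selected delta, and collapse them to unique gene symbols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .matrix import RAW, ExpressionMatrix, ProbeAnnotation

logger = logging.getLogger(__name__)


def _group_columns(
    m: ExpressionMatrix,
    labels: Mapping[str, str] | Sequence[str],
    condition: str,
    control: str,
) -> tuple[list[str], list[str]]:
    if isinstance(labels, Mapping):
        lab = [labels[s] for s in m.sample_ids]
    else:
        lab = list(labels)
        if len(lab) != len(m.sample_ids):
            raise ValueError("labels length must match the number of samples")
    cond = [s for s, l in zip(m.sample_ids, lab) if l == condition]
    ctrl = [s for s, l in zip(m.sample_ids, lab) if l == control]
    if not cond or not ctrl:
        raise ValueError(f"labels must contain both {condition!r} and {control!r}")
    return cond, ctrl


# ---------------------------------------------------------------------------
# intensity filtration
# ---------------------------------------------------------------------------

def estimate_intensity_cutoff(
    m: ExpressionMatrix,
    replicate_pairs: Sequence[tuple[str, str]],
    concordance_bound: float = 1.0,
    n_candidates: int = 50,
) -> float:
    """ROC-estimated signal-intensity cutoff.

    A probe is labelled *reproducible* when its between-replicate absolute
    log2 difference stays below ``concordance_bound`` in every replicate
    pair.  Candidate cutoffs are quantiles of the per-probe mean intensity;
    the returned cutoff maximizes Youden's J (sensitivity + specificity - 1)
    for "mean intensity >= cutoff" as a predictor of reproducibility.
    """
    if m.scale != RAW:
        raise ValueError("intensity cutoff estimation expects raw intensities")
    if len(replicate_pairs) == 0:
        raise ValueError("at least one replicate pair is required")
    v = m.data
    reproducible = np.ones(len(v), dtype=bool)
    for a, b in replicate_pairs:
        diff = np.abs(np.log2(v[a].to_numpy() / v[b].to_numpy()))
        reproducible &= diff < concordance_bound
    mean_int = v.mean(axis=1).to_numpy()
    candidates = np.unique(
        np.quantile(mean_int, np.linspace(0.0, 1.0, max(int(n_candidates), 1)))
    )
    if reproducible.all() or not reproducible.any():
        return float(candidates.min())
    best_c, best_j = float(candidates.min()), -np.inf
    for c in candidates:
        pred = mean_int >= c
        tpr = pred[reproducible].mean()
        fpr = pred[~reproducible].mean()
        j = tpr - fpr
        if j > best_j + 1e-15:
            best_c, best_j = float(c), j
    return best_c


def filter_low_intensity(m: ExpressionMatrix, cutoff: float) -> ExpressionMatrix:
    """Retain probes exceeding ``cutoff`` in at least one array."""
    if m.scale != RAW:
        raise ValueError("intensity filtration expects raw intensities")
    keep = (m.values > cutoff).any(axis=1)
    n_keep = int(keep.sum())
    if n_keep == 0:
        raise ValueError(f"cutoff {cutoff} removes every probe")
    logger.info(
        "filter_low_intensity: retained %d / %d probes (cutoff %.4g)",
        n_keep, len(keep), cutoff,
    )
    return ExpressionMatrix(m.data.loc[keep], m.scale)


# ---------------------------------------------------------------------------
# fold change and d-statistics
# ---------------------------------------------------------------------------

def fold_changes(
    m: ExpressionMatrix,
    labels: Mapping[str, str] | Sequence[str],
    condition: str,
    control: str,
) -> pd.Series:
    """Linear-scale fold change: mean(condition) / mean(control) per probe."""
    if m.scale != RAW:
        raise ValueError("fold changes are computed on raw linear intensities")
    cond, ctrl = _group_columns(m, labels, condition, control)
    ctrl_mean = m.data[ctrl].mean(axis=1)
    if (ctrl_mean <= 0).any():
        raise ValueError("control mean must be positive for every probe")
    return m.data[cond].mean(axis=1) / ctrl_mean


def _pooled_se(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    n1, n2 = x1.shape[1], x2.shape[1]
    ss = ((x1 - x1.mean(1, keepdims=True)) ** 2).sum(1) + (
        (x2 - x2.mean(1, keepdims=True)) ** 2
    ).sum(1)
    return np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))


def _resolve_s0(s: np.ndarray, s0_policy) -> float:
    if isinstance(s0_policy, (int, float)):
        s0 = float(s0_policy)
    elif s0_policy == "median":
        s0 = float(np.median(s))
    elif s0_policy == "zero":
        s0 = 0.0
    else:
        raise ValueError(f"unknown s0 policy {s0_policy!r}")
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    return s0


def sam_d_statistics(
    log2_values: np.ndarray,
    group1: Sequence[int],
    group2: Sequence[int],
    s0_policy="median",
) -> tuple[np.ndarray, float, np.ndarray]:
    """Moderated d-statistic per probe on log2 data.

    d_i = (mean(group1) - mean(group2)) / (s_i + s0) with s_i the pooled
    standard error of the mean difference.  Returns (d, s0, s).
    """
    g1, g2 = list(group1), list(group2)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each condition needs >= 2 arrays")
    x1, x2 = log2_values[:, g1], log2_values[:, g2]
    s = _pooled_se(x1, x2)
    s0 = _resolve_s0(s, s0_policy)
    return (x1.mean(1) - x2.mean(1)) / (s + s0), s0, s


def _enumerate_relabelings(n1: int, n2: int) -> list[tuple[list[int], list[int]]]:
    idx = list(range(n1 + n2))
    out = []
    for combo in combinations(idx, n1):
        g1 = list(combo)
        g2 = [i for i in idx if i not in combo]
        out.append((g1, g2))
    return out


@dataclass
class FdrTable:
    """Permutation FDR scan over the delta grid."""

    table: pd.DataFrame  # columns delta, called, expected_false, fdr, cut_up, cut_low
    chosen_delta: float
    fdr_at_delta: float
    pi0: float
    d_sorted: np.ndarray
    d_expected: np.ndarray


def sam_permutation_fdr(
    log2_values: np.ndarray,
    group1: Sequence[int],
    group2: Sequence[int],
    delta_grid: Sequence[float] | None = None,
    s0_policy="median",
) -> tuple[FdrTable, np.ndarray]:
    """Delta scan with exhaustively enumerated label permutations.

    Observed order statistics d_(i) are compared with their expectation
    dbar_(i), the rank-wise mean over all distinct relabelings of the arrays
    (identity included; with 2+2 arrays the 4!/2!2! = 6 relabelings are
    enumerated, never sampled).  For a band half-width delta the upper cut
    point is the smallest positive d_(i) with d_(i) - dbar_(i) >= delta and
    the lower cut the largest negative d_(i) with dbar_(i) - d_(i) >= delta;
    probes beyond a cut are called.  The expected number of false calls is
    the median over the relabelings of the count of permuted d beyond the
    same cuts, shrunk by the usual pi0 estimate from the inner quartiles of
    the permuted statistics; FDR = pi0 * expected / called.

    Delta selection: with so few distinct relabelings the median false-call
    count — and hence the FDR ratio — is a coarse step function that
    collapses to exactly zero over the entire extreme tail, so literally
    minimizing the ratio degenerates to calling only the handful of probes
    beyond the largest permuted statistic.  The scan therefore selects the
    delta maximizing the estimated number of TRUE discoveries,
    called - pi0 * expected_false (ties to the smaller delta), which is the
    stable formalization of "the best delta" in this small-permutation
    design: where signal exists it lands at the band that admits the signal
    while the expected false count is still small, and without signal it
    reports an FDR near 1.  Returns the scan plus per-probe calls at the
    chosen delta.
    """
    g1, g2 = list(group1), list(group2)
    n1, n2 = len(g1), len(g2)
    relabelings = _enumerate_relabelings(n1, n2)
    if len(relabelings) < 2:
        raise ValueError("need at least 2 distinct label permutations")
    cols = g1 + g2
    x = log2_values[:, cols]

    d_obs, s0, _ = sam_d_statistics(log2_values, g1, g2, s0_policy)
    d_sorted = np.sort(d_obs)

    perm_d = np.empty((len(relabelings), len(d_obs)))
    for b, (p1, p2) in enumerate(relabelings):
        perm_d[b], _, _ = sam_d_statistics(x, p1, p2, s0_policy=s0)
    d_expected = np.sort(perm_d, axis=1).mean(axis=0)

    q25, q75 = np.percentile(perm_d, [25, 75])
    pi0 = float(min(1.0, ((d_obs > q25) & (d_obs < q75)).sum() / (0.5 * len(d_obs))))

    diff = d_sorted - d_expected
    if delta_grid is None:
        top = float(np.abs(diff).max())
        delta_grid = np.linspace(0.0, top, 41)[1:] if top > 0 else np.array([1e-12])
    delta_grid = np.asarray(list(delta_grid), dtype=float)

    rows = []
    for delta in delta_grid:
        up_cross = np.where((diff >= delta) & (d_sorted > 0))[0]
        cut_up = d_sorted[up_cross[0]] if up_cross.size else np.inf
        low_cross = np.where((-diff >= delta) & (d_sorted < 0))[0]
        cut_low = d_sorted[low_cross[-1]] if low_cross.size else -np.inf
        called = int(((d_obs >= cut_up) | (d_obs <= cut_low)).sum())
        expected_false = float(
            np.median(((perm_d >= cut_up) | (perm_d <= cut_low)).sum(axis=1))
        )
        fdr = min(pi0 * expected_false / called, 1.0) if called > 0 else 0.0
        rows.append((delta, called, expected_false, fdr, cut_up, cut_low))
    table = pd.DataFrame(
        rows, columns=["delta", "called", "expected_false", "fdr", "cut_up", "cut_low"]
    )
    table["true_discoveries"] = table["called"] - pi0 * table["expected_false"]

    eligible = table[table["called"] >= 1]
    if eligible.empty:
        chosen_delta = float(table["delta"].iloc[0])
        fdr_at = 0.0
        significant = np.zeros(len(d_obs), dtype=bool)
    else:
        best = eligible.sort_values(
            ["true_discoveries", "delta"], ascending=[False, True]
        ).iloc[0]
        chosen_delta = float(best["delta"])
        fdr_at = float(best["fdr"])
        significant = (d_obs >= best["cut_up"]) | (d_obs <= best["cut_low"])
    return (
        FdrTable(table, chosen_delta, fdr_at, pi0, d_sorted, d_expected),
        significant,
    )


# ---------------------------------------------------------------------------
# gene selection
# ---------------------------------------------------------------------------

def select_differential_genes(
    fold: pd.Series,
    sam_significant: pd.Series,
    ann: ProbeAnnotation,
    fold_cutoff: float = 2.0,
) -> list[str]:
    """Probes passing both the two-sided fold cutoff and the SAM call,
    collapsed to unique gene symbols (sorted)."""
    if not fold.index.equals(sam_significant.index):
        raise ValueError("fold and SAM results must be aligned on probe ids")
    passes_fold = (fold >= fold_cutoff) | (fold <= 1.0 / fold_cutoff)
    probes = fold.index[passes_fold & sam_significant.astype(bool)]
    genes = sorted({ann.gene_for(p) for p in probes if ann.gene_for(p) is not None})
    if not genes:
        logger.warning("select_differential_genes: no gene passed both cutoffs")
    return genes


class SAMDifferential(BaseEstimator):
    """Two-condition differential contrast as a fit-shaped estimator.

    Parameters
    ----------
    condition, control:
        the two label values in ``condition_labels``; fold change and d are
        oriented condition-over-control.
    fold_cutoff:
        two-sided linear fold threshold (>= cutoff up, <= 1/cutoff down).
    s0_policy:
        "median" (fudge factor = median pooled SE), "zero", or a number.
    delta_grid:
        optional explicit grid of band half-widths.

    Fitted attributes
    -----------------
    result_ : DataFrame (probe_id, fold_change, d_stat, sam_called,
        significant); ``significant`` is the fold AND SAM conjunction.
    delta_, fdr_at_delta_, s0_, fdr_table_ : scan outcome.
    """

    def __init__(
        self,
        condition: str = "muc1cd",
        control: str = "vector",
        fold_cutoff: float = 2.0,
        s0_policy="median",
        delta_grid=None,
    ):
        self.condition = condition
        self.control = control
        self.fold_cutoff = fold_cutoff
        self.s0_policy = s0_policy
        self.delta_grid = delta_grid

    def fit(self, m: ExpressionMatrix, condition_labels) -> "SAMDifferential":
        cond, ctrl = _group_columns(m, condition_labels, self.condition, self.control)
        fold = fold_changes(m, condition_labels, self.condition, self.control)
        log2v = np.log2(m.values)
        g1 = [m.sample_ids.index(s) for s in cond]
        g2 = [m.sample_ids.index(s) for s in ctrl]
        d, s0, _ = sam_d_statistics(log2v, g1, g2, self.s0_policy)
        fdr_table, significant = sam_permutation_fdr(
            log2v, g1, g2, delta_grid=self.delta_grid, s0_policy=self.s0_policy
        )
        sam_called = pd.Series(significant, index=m.data.index)
        passes_fold = (fold >= self.fold_cutoff) | (fold <= 1.0 / self.fold_cutoff)
        self.result_ = pd.DataFrame(
            {
                "probe_id": m.feature_ids,
                "fold_change": fold.to_numpy(),
                "d_stat": d,
                "sam_called": sam_called.to_numpy(),
                "significant": (passes_fold & sam_called).to_numpy(),
            }
        )
        self.s0_ = s0
        self.fdr_table_ = fdr_table
        self.delta_ = fdr_table.chosen_delta
        self.fdr_at_delta_ = fdr_table.fdr_at_delta
        return self

    def select_genes(self, ann: ProbeAnnotation) -> list[str]:
        fold = pd.Series(
            self.result_["fold_change"].to_numpy(), index=self.result_["probe_id"]
        )
        called = pd.Series(
            self.result_["sam_called"].to_numpy(), index=self.result_["probe_id"]
        )
        return select_differential_genes(fold, called, ann, self.fold_cutoff)
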
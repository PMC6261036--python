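"""Rank statistics, Holm-Bonferroni correction, and the trial-label
permutation contrast of windowed ERP amplitudes.

The rank tests wrap the scipy implementations (exact null distributions
for small untied samples, normal approximation otherwise) and report the
normal-approximation z alongside the p-value, matching the convention of
reporting signed-rank results as z statistics.  The permutation test is a
Monte-Carlo contrast of condition means of the window/ROI-averaged
single-trial amplitude, with the add-one p-value convention
``p = (1 + #{|null| >= |observed|}) / (n_perm + 1)`` so p can never be 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

from .containers import EpochSet


@dataclass
class TestResult:
    """Outcome of a two-tailed rank test."""

    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str
    tails: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _signed_rank_z(d: np.ndarray) -> float:
    """Normal-approximation z for the signed-rank statistic (ties handled)."""
    n = len(d)
    ranks = sst.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 from the null variance
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((counts ** 3 - counts).sum()) / 48.0
    if var <= 0:
        return 0.0
    return float((w_plus - mu) / np.sqrt(var))


def wilcoxon_signed_rank(paired_a: Sequence[float], paired_b: Sequence[float]
                         ) -> TestResult:
    """Two-tailed Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped before ranking.  If every difference is
    zero the comparison is degenerate and ``p = 1`` is reported by
    convention.  For small samples without ties the p-value comes from the
    exact permutation distribution of sign assignments; otherwise from the
    normal approximation.  The reported statistic is always the
    normal-approximation z.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    nz = d[d != 0]
    if len(nz) == 0:
        return TestResult(0.0, 1.0, (len(a),), "wilcoxon-signed-rank(degenerate)")
    if len(nz) < 5:
        raise ValueError(
            f"only {len(nz)} non-zero differences; need >= 5 for a "
            "meaningful signed-rank test")
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "approx" if (has_ties or len(nz) > 25) else "exact"
    res = sst.wilcoxon(nz, zero_method="wilcox", alternative="two-sided",
                       method=method, correction=False)
    z = _signed_rank_z(nz)
    return TestResult(z, float(res.pvalue), (len(a),),
                      f"wilcoxon-signed-rank({method})")


def mann_whitney_u(sample_a: Sequence[float], sample_b: Sequence[float]
                   ) -> TestResult:
    """Two-tailed Mann-Whitney U test for independent samples."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = sst.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult(float(res.statistic), float(res.pvalue),
                      (len(a), len(b)), "mann-whitney-u")


@dataclass
class HolmResult:
    """Step-down Holm-Bonferroni decisions and adjusted p-values."""

    reject: np.ndarray
    adjusted_p: np.ndarray
    alpha: float


def holm_bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> HolmResult:
    """Holm's step-down procedure controlling family-wise error.

    p-values are sorted ascending and p(i) is compared with
    ``alpha / (m - i + 1)``, stopping at the first failure; adjusted
    p-values are monotone non-decreasing and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return HolmResult(reject, adj, alpha)


@dataclass
class PermutationResult:
    """Monte-Carlo permutation contrast of two condition means."""

    observed: float
    p_value: float
    n_permutations: int
    null_distribution_size: int
    n_per_condition: dict
    seed: int
    window_ms: tuple[float, float] | None = None
    roi: tuple[str, ...] | None = None


def window_roi_amplitudes(ep: EpochSet, window_ms: tuple[float, float],
                          roi: Sequence[str]) -> np.ndarray:
    """Per-trial mean amplitude over the ROI channels and time window."""
    t = ep.times_ms
    sel = (t >= window_ms[0]) & (t < window_ms[1])
    if not sel.any():
        raise ValueError(f"window {window_ms} contains no samples")
    idx = ep.roi_indices(roi)
    return ep.data[:, idx][:, :, sel].mean(axis=(1, 2))


def permutation_condition_test(
    ep: EpochSet,
    window_ms: tuple[float, float],
    roi: Sequence[str],
    *,
    conditions: tuple[str, str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Trial-label permutation test of a condition amplitude difference.

    The observed statistic is the difference of condition means of the
    window/ROI-averaged single-trial amplitude (first listed condition
    minus second).  The null distribution reassigns condition labels
    uniformly at random across trials ``n_perm`` times.
    """
    labels = ep.conditions.astype(str)
    valid = ep.valid
    present = sorted(np.unique(labels[valid]))
    if conditions is None:
        if len(present) != 2:
            raise ValueError(
                f"need exactly two conditions, found {present}; pass "
                "`conditions` explicitly")
        conditions = (present[1], present[0])  # e.g. ("NoGo", "Go")
    for c in conditions:
        if c not in present:
            raise ValueError(f"condition {c!r} has no valid trials")

    keep = valid & np.isin(labels, conditions)
    x = window_roi_amplitudes(ep, window_ms, roi)[keep]
    is_a = labels[keep] == conditions[0]
    n_a, n_b = int(is_a.sum()), int((~is_a).sum())
    observed = x[is_a].mean() - x[~is_a].mean()

    rng = np.random.default_rng(seed)
    # each row of `order` is a random relabelling: first n_a entries get label a
    order = np.argsort(rng.random((n_perm, len(x))), axis=1)
    perm_a = np.take(x, order[:, :n_a]).mean(axis=1)
    perm_b = np.take(x, order[:, n_a:]).mean(axis=1)
    null = perm_a - perm_b
    p = (1.0 + np.count_nonzero(np.abs(null) >= abs(observed))) / (n_perm + 1.0)
    return PermutationResult(float(observed), float(p), n_perm, len(null),
                             {conditions[0]: n_a, conditions[1]: n_b},
                             int(seed), tuple(window_ms), tuple(roi))
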
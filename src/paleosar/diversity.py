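"""Coverage-standardized richness (SQS) and face-value richness.

Shareholder Quorum Subsampling standardizes richness across samples of
unequal size by drawing every sample down (or extrapolating it up) to a
common *coverage* -- the fraction of the underlying species-abundance
distribution represented -- called the quorum.  Coverage is estimated from
singleton and doubleton counts with the Good--Turing correction of Chao &
Jost; rarefaction uses the exact hypergeometric expectation and
extrapolation the asymptotic ``f1/f2`` (Chao1) form, the standard
abundance-based machinery of the iNEXT lineage.

All estimators operate on an :class:`AbundanceVector` (species ->
occurrence-count map for one region).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = ["AbundanceVector", "RichnessEstimate", "coverage_of_sample",
           "rarefied_richness", "expected_coverage", "richness_at_quorum",
           "face_value_richness", "true_richness_at_coverage"]


class AbundanceVector:
    """Per-region species occurrence counts with cached summaries.

    Parameters
    ----------
    counts : mapping or array-like
        Either ``{species: count}`` or a plain sequence of positive counts.
    """

    def __init__(self, counts):
        if hasattr(counts, "items"):
            arr = np.asarray(list(counts.values()), dtype=float)
        else:
            arr = np.asarray(counts, dtype=float)
        arr = arr[arr > 0]
        if np.any(arr != np.floor(arr)):
            raise ValueError("abundances must be whole occurrence counts")
        self.counts = arr.astype(np.int64)
        self.n = int(self.counts.sum())
        self.s_obs = int(len(self.counts))
        self.f1 = int(np.sum(self.counts == 1))
        self.f2 = int(np.sum(self.counts == 2))

    def __repr__(self):
        return f"AbundanceVector(n={self.n}, S_obs={self.s_obs}, f1={self.f1}, f2={self.f2})"


@dataclass(frozen=True)
class RichnessEstimate:
    """Coverage-standardized richness at a fixed quorum."""

    value: float
    quorum: float
    mode: str                # 'interpolated' | 'extrapolated' | 'observed'
    usable: bool
    m: float                 # effective sample size at which coverage == quorum
    note: str = ""


def coverage_of_sample(ab: AbundanceVector) -> float:
    """Chao--Jost corrected Good's coverage of the full sample:
    ``1 - (f1/n) * [(n-1) f1 / ((n-1) f1 + 2 f2)]``."""
    if ab.n < 1:
        raise ValueError("coverage undefined for an empty sample")
    if ab.n == 1:
        return 0.0
    if ab.f1 == 0:
        return 1.0
    a = (ab.n - 1) * ab.f1 / ((ab.n - 1) * ab.f1 + 2.0 * ab.f2)
    return float(1.0 - (ab.f1 / ab.n) * a)


def _log_choose(a, b):
    return gammaln(a + 1.0) - gammaln(b + 1.0) - gammaln(a - b + 1.0)


def rarefied_richness(ab: AbundanceVector, m: int) -> float:
    """Expected species count in a subsample of ``m`` occurrences drawn
    without replacement (hypergeometric expectation), ``1 <= m <= n``."""
    if not 1 <= m <= ab.n:
        raise ValueError(f"m={m} outside [1, n={ab.n}]")
    x = ab.counts
    keep = (ab.n - x) >= m
    terms = np.zeros(len(x))
    if keep.any():
        terms[keep] = np.exp(_log_choose(ab.n - x[keep], m) - _log_choose(ab.n, m))
    return float(np.sum(1.0 - terms))


def _f0_hat(ab: AbundanceVector) -> float:
    # Chao1 unseen-species estimate, bias-corrected form when f2 == 0.
    n = ab.n
    if ab.f2 > 0:
        return (n - 1.0) / n * ab.f1 ** 2 / (2.0 * ab.f2)
    return (n - 1.0) / n * ab.f1 * (ab.f1 - 1.0) / 2.0


def _extrap_a(ab: AbundanceVector) -> float:
    # Geometric decay rate of undiscovered coverage beyond n.
    n = ab.n
    if ab.f2 > 0:
        return (n - 1.0) * ab.f1 / ((n - 1.0) * ab.f1 + 2.0 * ab.f2)
    if ab.f1 > 0:
        return (n - 1.0) * (ab.f1 - 1.0) / ((n - 1.0) * (ab.f1 - 1.0) + 2.0)
    return 1.0


def expected_coverage(ab: AbundanceVector, m: float) -> float:
    """Estimated expected coverage of a sample of size ``m`` drawn from the
    same assemblage (interpolated for ``m < n``, Chao--Jost corrected at
    ``m == n``, geometric extrapolation for ``m > n``)."""
    n = ab.n
    if m < 1:
        raise ValueError("m must be >= 1")
    if m >= n:
        if m == n:
            return coverage_of_sample(ab)
        a = _extrap_a(ab)
        return float(1.0 - (ab.f1 / n) * a ** (m - n + 1.0))
    m = int(m)
    x = ab.counts
    keep = (n - x) >= m
    acc = 0.0
    if keep.any():
        acc = np.sum((x[keep] / n)
                     * np.exp(_log_choose(n - x[keep], m) - _log_choose(n - 1.0, m)))
    return float(1.0 - acc)


def _extrapolated_richness(ab: AbundanceVector, m: float) -> float:
    f0 = _f0_hat(ab)
    if f0 <= 0 or ab.f1 == 0:
        return float(ab.s_obs)
    mstar = m - ab.n
    return float(ab.s_obs + f0 * (1.0 - (1.0 - ab.f1 / (ab.n * f0 + ab.f1)) ** mstar))


def richness_at_quorum(ab: AbundanceVector, quorum: float = 0.8, *,
                       min_n: int = 10, min_s_obs: int = 2,
                       max_extrapolation: float = 2.0) -> RichnessEstimate:
    """Species richness standardized to a fixed coverage (the quorum).

    Finds the effective sample size ``m`` at which expected coverage equals
    ``quorum`` (integer bracketing with linear interpolation below ``n``;
    analytic inversion of the geometric form above ``n``) and returns the
    expected species count at ``m``.

    Estimates are flagged unusable when the sample is too sparse
    (``n < min_n`` or ``S_obs < min_s_obs``) or when reaching the quorum
    would require extrapolating beyond ``max_extrapolation * n`` occurrences.
    """
    if not 0.0 < quorum < 1.0:
        raise ValueError("quorum must lie in (0, 1)")
    if ab.n < 1:
        raise ValueError("empty abundance vector")
    sparse = ab.n < min_n or ab.s_obs < min_s_obs
    c_full = coverage_of_sample(ab)

    if c_full >= quorum:                       # interpolation (or the sample itself)
        lo, hi = 1, ab.n
        if expected_coverage(ab, 1) >= quorum:
            return RichnessEstimate(value=1.0, quorum=quorum, mode="interpolated",
                                    usable=not sparse, m=1.0,
                                    note="quorum at or below single-draw coverage")
        while hi - lo > 1:                     # coverage is nondecreasing in m
            mid = (lo + hi) // 2
            if expected_coverage(ab, mid) < quorum:
                lo = mid
            else:
                hi = mid
        c_lo, c_hi = expected_coverage(ab, lo), expected_coverage(ab, hi)
        s_lo, s_hi = rarefied_richness(ab, lo), rarefied_richness(ab, hi)
        w = 0.0 if c_hi <= c_lo else (quorum - c_lo) / (c_hi - c_lo)
        w = min(max(w, 0.0), 1.0)
        return RichnessEstimate(value=s_lo + w * (s_hi - s_lo), quorum=quorum,
                                mode="interpolated", usable=not sparse,
                                m=lo + w * (hi - lo))

    # extrapolation: invert 1 - (f1/n) A^(m-n+1) = quorum
    a = _extrap_a(ab)
    note = "bias-corrected f0 (f2=0)" if ab.f2 == 0 else ""
    if not 0.0 < a < 1.0:
        return RichnessEstimate(value=float(ab.s_obs), quorum=quorum,
                                mode="extrapolated", usable=False, m=float(ab.n),
                                note=note + "; coverage cannot reach quorum")
    m = ab.n - 1.0 + np.log(ab.n * (1.0 - quorum) / ab.f1) / np.log(a)
    m = max(m, float(ab.n))
    value = _extrapolated_richness(ab, m)
    usable = (not sparse) and m <= max_extrapolation * ab.n
    return RichnessEstimate(value=value, quorum=quorum, mode="extrapolated",
                            usable=usable, m=float(m), note=note)


def face_value_richness(ab) -> int:
    """Observed (raw, uncorrected) species count."""
    if ab is None:
        return 0
    if not isinstance(ab, AbundanceVector):
        ab = AbundanceVector(ab)
    return ab.s_obs


def true_richness_at_coverage(rel_abundance, quorum: float = 0.8) -> float:
    """Coverage-standardized richness of a fully known community.

    For true relative abundances ``p_i`` the expected richness and coverage
    of an ``m``-individual sample are ``sum(1-(1-p_i)^m)`` and
    ``sum(p_i (1-(1-p_i)^m))``; this solves coverage == quorum for
    continuous ``m`` and returns the richness there.  Used to build truth
    baselines for synthetic communities.
    """
    p = np.asarray(rel_abundance, dtype=float)
    p = p[p > 0]
    p = p / p.sum()
    if len(p) == 1:
        return 1.0

    def cov(m):
        return float(np.sum(p * (1.0 - (1.0 - p) ** m)))

    lo, hi = 1.0, 2.0
    while cov(hi) < quorum and hi < 1e12:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if cov(mid) < quorum:
            lo = mid
        else:
            hi = mid
    m = 0.5 * (lo + hi)
    return float(np.sum(1.0 - (1.0 - p) ** m))
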
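"""Enrichment statistics on one ranked gene list.

Four ways to ask the same question — are a miRNA's putative targets shifted
toward the repressed end of a sample's fold-change ranking? —

* ``mrs_test``: modified rank sum.  Each gene's motif indicator is centered
  by its sequence-specific null probability p_g, so genes whose UTRs carry
  the motif merely because they are long or biased in composition do not
  inflate the statistic.
* ``bb_test``: Brownian bridge.  A cumulative walk of (indicator − p_g) over
  the full ordering; the maximal deviation of the tied-down walk is compared
  with the supremum distribution of a Brownian bridge (Kolmogorov series).
* ``hypergeom_landscape``: hypergeometric over/under-representation of
  motif-bearing genes in leading bins of the ranking, scanned over cutoffs
  (presence-based per gene; no composition correction — the p_g-aware
  methods handle composition).
* ``targetset_ranksum``: two-sided Mann–Whitney comparing curated target
  genes against the rest, for use with database-defined target sets instead
  of sequence motifs.

All tests are two-sided; the direction (+1 = enriched among repressed genes
= high miRNA activity) is reported separately.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

P_FLOOR = 1e-300


class NoContrastError(ValueError):
    """All indicators identical (or variance zero): the test is undefined."""


#: Continuity correction for discretely monitored extremes of a Brownian
#: process (Broadie–Glasserman–Kou): beta = -zeta(1/2)/sqrt(2*pi).  The max
#: over N discrete steps underestimates the continuous bridge supremum by
#: about beta*sqrt(dt); adding it back keeps the Kolmogorov-series p-values
#: calibrated at finite N.
BGK_BETA = 0.5826


@dataclass
class EnrichmentResult:
    """Outcome of one enrichment test.

    ``direction`` is +1 when the motif/targets are enriched among repressed
    genes (leading ranks), −1 otherwise; a zero statistic maps to +1 by
    convention.  The activity score is derivable as −log10(p) · direction.
    """

    p_value: float
    statistic: float
    direction: int
    method: str
    landscape: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")


def _as_arrays(indicators, null_probs):
    I = np.asarray(indicators, dtype=float)
    p = np.asarray(null_probs, dtype=float)
    if I.shape != p.shape:
        raise ValueError("indicators and null_probs must have the same shape")
    if not np.isin(I, (0.0, 1.0)).all():
        raise ValueError("indicators must be 0/1")
    if ((p < 0) | (p >= 1)).any():
        raise ValueError("null probabilities must lie in [0, 1)")
    if I.min() == I.max():
        raise NoContrastError("indicators are all identical: no contrast to test")
    return I, p


def mrs_test(midranks, indicators, null_probs) -> EnrichmentResult:
    """Modified rank-sum test on midranks (rank 1 = most repressed).

    With centered weights c_g = (N+1)/2 − r_g:
        T = Σ c_g (I_g − p_g),  Var = Σ c_g² p_g(1−p_g),  Z = T/√Var,
    two-sided normal p-value.  Positive Z means motif-bearing genes sit
    toward the repressed end beyond their null propensity.
    """
    I, p = _as_arrays(indicators, null_probs)
    r = np.asarray(midranks, dtype=float)
    n = len(r)
    c = (n + 1) / 2.0 - r
    T = float(np.sum(c * (I - p)))
    var = float(np.sum(c * c * p * (1.0 - p)))
    if var <= 0.0:
        raise NoContrastError("zero variance: all null probabilities degenerate")
    z = T / np.sqrt(var)
    pval = max(2.0 * stats.norm.sf(abs(z)), P_FLOOR)
    return EnrichmentResult(
        p_value=min(pval, 1.0),
        statistic=z,
        direction=1 if z >= 0 else -1,
        method="mrs",
    )


def kolmogorov_sup_pvalue(d: float) -> float:
    """P(sup |Brownian bridge| > d) via the alternating Kolmogorov series.

    2 Σ_{j>=1} (−1)^{j−1} exp(−2 j² d²), truncated when a term drops below
    1e−16; clamped into (0, 1].  p(0) = 1 and p is strictly decreasing.
    """
    if d < 0:
        raise ValueError("d must be non-negative")
    if d == 0.0:
        return 1.0
    total = 0.0
    for j in range(1, 1000):
        term = np.exp(-2.0 * j * j * d * d)
        if term < 1e-16:
            break
        total += term if j % 2 == 1 else -term
    return float(min(max(2.0 * total, P_FLOOR), 1.0))


def bb_test(indicators, null_probs) -> EnrichmentResult:
    """Brownian-bridge test over the stable full ordering (repressed first).

    Walk S_k = Σ_{j<=k}(I_j − p_j); bridge B_k = (S_k − (k/N)·S_N)/√V with
    V = Σ p_g(1−p_g); D = max_k |B_k| plus the discrete-monitoring
    continuity correction BGK_BETA/√N; p from the Kolmogorov sup series.
    Direction is the sign of the bridge at its first argmax.
    """
    I, p = _as_arrays(indicators, null_probs)
    n = len(I)
    if n < 10:
        warnings.warn("bb_test with N < 10: asymptotic approximation is poor", stacklevel=2)
    V = float(np.sum(p * (1.0 - p)))
    if V <= 0.0:
        raise NoContrastError("zero variance: all null probabilities degenerate")
    s = np.cumsum(I - p)
    k = np.arange(1, n + 1)
    bridge = (s - (k / n) * s[-1]) / np.sqrt(V)
    imax = int(np.argmax(np.abs(bridge)))
    d = abs(bridge[imax]) + BGK_BETA / np.sqrt(n)
    direction = 1 if bridge[imax] >= 0 else -1
    pval = kolmogorov_sup_pvalue(float(d))
    return EnrichmentResult(
        p_value=pval,
        statistic=float(d * direction),
        direction=direction,
        method="bb",
    )


def default_cutoff_grid(n: int, n_cutoffs: int = 20) -> np.ndarray:
    """Evenly spaced cutoffs in {1..N−1} (the full-list bin is uninformative)."""
    grid = np.unique(np.linspace(1, n - 1, num=min(n_cutoffs, n - 1)).round().astype(int))
    return grid[(grid >= 1) & (grid <= n - 1)]


def hypergeom_landscape(
    indicators,
    cutoff_grid: Optional[Sequence[int]] = None,
    bonferroni: bool = False,
) -> EnrichmentResult:
    """Hypergeometric landscape over leading-bin cutoffs of the ordering.

    For each cutoff n, k = motif genes among the leading n; the landscape
    records P(X >= k) and P(X <= k) for X ~ Hypergeom(N, K, n).  The overall
    p is the minimum over cutoffs and tails (optionally Bonferroni-corrected
    across cutoffs); direction +1 if the minimising tail is the
    over-representation tail.  Statistic = −log10(p) · direction.
    """
    I = np.asarray(indicators, dtype=float)
    if not np.isin(I, (0.0, 1.0)).all():
        raise ValueError("indicators must be 0/1")
    n_total = len(I)
    K = int(I.sum())
    if K == 0 or K == n_total:
        raise NoContrastError("motif present in all or no genes: no contrast")
    if cutoff_grid is None:
        grid = default_cutoff_grid(n_total)
    else:
        grid = np.asarray(cutoff_grid, dtype=int)
        if ((grid < 1) | (grid > n_total - 1)).any():
            raise ValueError("cutoffs must lie in {1..N-1}")
    k_at = np.cumsum(I)[grid - 1]
    p_over = stats.hypergeom.sf(k_at - 1, n_total, K, grid)
    p_under = stats.hypergeom.cdf(k_at, n_total, K, grid)
    i_over = int(np.argmin(p_over))
    i_under = int(np.argmin(p_under))
    if p_over[i_over] <= p_under[i_under]:
        p_min, direction = float(p_over[i_over]), 1
    else:
        p_min, direction = float(p_under[i_under]), -1
    if bonferroni:
        p_min = min(1.0, p_min * len(grid))
    p_min = min(max(p_min, P_FLOOR), 1.0)
    score = -np.log10(p_min) * direction
    return EnrichmentResult(
        p_value=p_min,
        statistic=float(score),
        direction=direction,
        method="hypergeom",
        landscape={"cutoffs": grid, "k": k_at, "p_over": p_over, "p_under": p_under},
    )


def targetset_ranksum(fold_change_values, is_target) -> EnrichmentResult:
    """Two-sided Mann–Whitney comparing curated targets against other genes.

    Normal approximation with tie correction (midranks); direction +1 when
    targets have the smaller mean rank, i.e. sit among repressed genes.
    """
    values = np.asarray(fold_change_values, dtype=float)
    mask = np.asarray(is_target, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError("is_target must align with fold_change_values")
    if not mask.any():
        raise NoContrastError("target set does not intersect the ranked genes")
    if mask.all():
        raise NoContrastError("target set equals the whole gene universe")
    res = stats.mannwhitneyu(
        values[mask], values[~mask], alternative="two-sided", method="asymptotic"
    )
    ranks = stats.rankdata(values, method="average")
    direction = 1 if ranks[mask].mean() < ranks[~mask].mean() else -1
    pval = min(max(float(res.pvalue), P_FLOOR), 1.0)
    return EnrichmentResult(
        p_value=pval,
        statistic=float(res.statistic) * direction,
        direction=direction,
        method="tarbase",
    )
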
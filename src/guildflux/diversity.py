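"""Shannon diversity and Mann-Whitney U comparison of sample groups.

The Shannon index is computed in natural-log units, H = -sum p_i ln p_i
with 0 ln 0 = 0.  The rank-sum test uses midranks for ties, an exact
null distribution by full enumeration of group assignments for small
samples, and a tie- and continuity-corrected normal approximation
otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata
from scipy.special import ndtr

__all__ = [
    "AbundanceProfile",
    "MannWhitneyResult",
    "DiversityReport",
    "shannon",
    "mann_whitney_u",
    "compare_system_diversity",
    "EXACT_ENUMERATION_MAX_N",
]

#: Largest pooled sample size for which the exact null is enumerated.
EXACT_ENUMERATION_MAX_N = 12


@dataclass(frozen=True)
class AbundanceProfile:
    """A composition over OTUs / MAGs / pathways.

    Accepts proportions or raw counts; counts are normalized internally.
    """

    labels: Tuple[str, ...]
    proportions: np.ndarray

    def __init__(self, labels: Sequence[str], values: Sequence[float]):
        labels = tuple(str(x) for x in labels)
        vals = np.asarray(values, dtype=float)
        if len(labels) != vals.size:
            raise ValueError("labels and values must have equal length")
        if vals.size == 0:
            raise ValueError("profile must have at least one category")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("abundances must be finite and >= 0")
        total = vals.sum()
        if total <= 0:
            raise ValueError("profile has zero total abundance")
        props = vals / total
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "proportions", props)

    @classmethod
    def from_counts(cls, labels: Sequence[str], counts: Sequence[float]) -> "AbundanceProfile":
        return cls(labels, counts)

    @property
    def n(self) -> int:
        """Number of categories."""
        return len(self.labels)


def shannon(profile: AbundanceProfile, base: Optional[float] = None) -> float:
    """Shannon index H = -sum p_i ln p_i (nats by default).

    ``base`` switches the logarithm base (e.g. 2 for bits); natural log is
    the default and the convention used throughout this package.
    """
    p = profile.proportions
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base is not None:
        h /= math.log(base)
    return h


@dataclass
class MannWhitneyResult:
    """U statistic (for the first sample) and two-sided p-value."""

    u: float
    p_value: float
    method: str
    degenerate: bool = False


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x via midranks: U_x = R_x - n_x(n_x+1)/2."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r_x = ranks[: len(x)].sum()
    return float(r_x - len(x) * (len(x) + 1) / 2.0)


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumerating every split of the pooled sample.

    p = P(|U - n_x n_y / 2| >= |U_obs - n_x n_y / 2|) under the null that
    all assignments of the pooled values to the two groups are equally
    likely (ties handled through midranks automatically, since U is
    computed from the values themselves).
    """
    pooled = np.concatenate([x, y])
    n = pooled.size
    nx = x.size
    mu = nx * y.size / 2.0
    dev_obs = abs(u_obs - mu)
    hits = 0
    total = 0
    idx = np.arange(n)
    for subset in combinations(idx, nx):
        mask = np.zeros(n, dtype=bool)
        mask[list(subset)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - mu) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> MannWhitneyResult:
    """Mann-Whitney U rank-sum test for two independent samples.

    Returns U for ``x`` and a two-sided p-value: exact (full enumeration)
    when n_x + n_y <= 12, otherwise a normal approximation with midrank tie
    correction and 0.5 continuity correction.  Identical constant samples
    give p = 1 with the ``degenerate`` flag set.
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is supported")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(u=u, p_value=1.0, method="degenerate", degenerate=True)

    n = x.size + y.size
    if n <= EXACT_ENUMERATION_MAX_N:
        p = _exact_two_sided_p(x, y, u)
        return MannWhitneyResult(u=u, p_value=p, method="exact")

    nx, ny = x.size, y.size
    mu = nx * ny / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return MannWhitneyResult(u=u, p_value=1.0, method="degenerate", degenerate=True)
    dev = abs(u - mu)
    z = max(dev - 0.5, 0.0) / math.sqrt(sigma2)
    p = float(min(1.0, 2.0 * (1.0 - ndtr(z))))
    return MannWhitneyResult(u=u, p_value=p, method="normal")


@dataclass
class DiversityReport:
    """Per-sample Shannon values and the between-group rank-sum comparison."""

    h_a: List[float]
    h_b: List[float]
    median_a: float
    median_b: float
    u: float
    p_value: float
    significant: bool
    alpha: float
    warnings: List[str] = field(default_factory=list)


def compare_system_diversity(
    profiles_a: Sequence[AbundanceProfile],
    profiles_b: Sequence[AbundanceProfile],
    alpha: float = 0.05,
) -> DiversityReport:
    """Compare Shannon diversity between two groups of samples.

    Computes per-sample H, group medians, and the two-sided Mann-Whitney
    test; flags significance at ``alpha``.
    """
    if not profiles_a or not profiles_b:
        raise ValueError("each group needs at least one profile")
    h_a = [shannon(p) for p in profiles_a]
    h_b = [shannon(p) for p in profiles_b]
    result = mann_whitney_u(h_a, h_b)
    notes = []
    if len(h_a) < 2 or len(h_b) < 2:
        notes.append("insufficient-n: fewer than 2 samples in a group")
    if result.degenerate:
        notes.append("degenerate-variance: all diversity values identical")
    return DiversityReport(
        h_a=h_a,
        h_b=h_b,
        median_a=float(np.median(h_a)),
        median_b=float(np.median(h_b)),
        u=result.u,
        p_value=result.p_value,
        significant=bool(result.p_value < alpha),
        alpha=alpha,
        warnings=notes,
    )
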
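"""Survey statistics over site-by-scaffold match outcomes.

The central container is :class:`MatchMatrix`: boolean fast-match outcomes
per (site, scaffold) cell, the seed-shuffled order in which scaffolds were
tested, and each site's first-encounter number — the number of scaffolds
examined until its first successful match.  Everything downstream (success
rates, overlap tests, encounter curves, power-law fits, subset resampling)
reads from this container.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Hashable, NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ParameterError

__all__ = [
    "MatchMatrix",
    "PowerLawFit",
    "enrichment_ratios",
    "success_rate_by",
    "overlap_test",
    "encounter_curve",
    "fit_power_law",
    "resample_subsets",
]

# Cell states in MatchMatrix tables.
MATCHED = 1
TESTED_NO_MATCH = 0
UNTESTED = -1


@dataclass
class MatchMatrix:
    """Site x scaffold match outcomes.

    ``fast[i, j]`` is 1 (matched), 0 (tested, no match) or -1 (untested);
    columns follow the order of ``scaffolds``.  ``order`` lists scaffold
    indices in the (seed-shuffled) order they were tested; ``encounter[i]``
    is the 1-based position in that order of site i's first success, or
    None if the site never matched.  ``confirmed`` optionally holds
    post-confirmation outcomes and may only switch cells from 1 to 0.
    """

    sites: list[str]
    scaffolds: list[str]
    fast: np.ndarray
    order: list[int] = field(default_factory=list)
    encounter: list[Optional[int]] = field(default_factory=list)
    confirmed: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.fast = np.asarray(self.fast, dtype=np.int8)
        if self.fast.shape != (len(self.sites), len(self.scaffolds)):
            raise ParameterError("fast table shape must be (n_sites, n_scaffolds)")
        if not self.order:
            self.order = list(range(len(self.scaffolds)))
        if not self.encounter:
            self.encounter = self._compute_encounters()
        self.validate()

    def _compute_encounters(self) -> list[Optional[int]]:
        enc: list[Optional[int]] = []
        for row in self.fast:
            first = None
            for pos, j in enumerate(self.order, start=1):
                if row[j] == MATCHED:
                    first = pos
                    break
            enc.append(first)
        return enc

    def validate(self) -> None:
        if self.confirmed is not None:
            conf = np.asarray(self.confirmed, dtype=np.int8)
            if conf.shape != self.fast.shape:
                raise ParameterError("confirmed table shape mismatch")
            bad = (conf == MATCHED) & (self.fast != MATCHED)
            if bad.any():
                raise ParameterError("confirmed match without a fast match")
        for i, enc in enumerate(self.encounter):
            if enc is not None:
                j = self.order[enc - 1]
                if self.fast[i, j] != MATCHED:
                    raise ParameterError(f"encounter for site {i} inconsistent")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_scaffolds(self) -> int:
        return len(self.scaffolds)

    def matched_any(self, confirmed: bool = False) -> np.ndarray:
        table = self.confirmed if confirmed and self.confirmed is not None else self.fast
        return (np.asarray(table) == MATCHED).any(axis=1)

    @property
    def fully_tested(self) -> bool:
        return not (self.fast == UNTESTED).any()


def enrichment_ratios(
    site_freqs: dict[str, float], background_freqs: dict[str, float]
) -> dict[str, float]:
    """Per-amino-acid ratio of site frequency to background frequency."""
    out = {}
    for aa, f in site_freqs.items():
        bg = background_freqs.get(aa)
        if bg is None or bg <= 0:
            raise ParameterError(f"background frequency for {aa!r} must be positive")
        out[aa] = f / bg
    return out


class GroupRate(NamedTuple):
    count: int
    matched: int
    rate: float


def success_rate_by(
    matrix: MatchMatrix,
    grouping: Callable[[str], Hashable],
    confirmed: bool = False,
) -> dict[Hashable, GroupRate]:
    """Match success rate per group of sites, keys in ascending order."""
    matched = matrix.matched_any(confirmed=confirmed)
    groups: dict[Hashable, list[int]] = {}
    for i, site in enumerate(matrix.sites):
        groups.setdefault(grouping(site), []).append(i)
    out = {}
    for key in sorted(groups):
        idx = groups[key]
        m = int(matched[idx].sum())
        out[key] = GroupRate(count=len(idx), matched=m, rate=m / len(idx))
    return out


class OverlapResult(NamedTuple):
    observed: int
    expected: float
    chi2: float
    p: float


def overlap_test(matrix_a: np.ndarray, matrix_b: np.ndarray) -> OverlapResult:
    """Test whether matching to two scaffold sets is independent.

    Under independence the expected number of sites matched to both sets is
    n_a * n_b / N.  The chi-squared statistic is computed on the 2x2 table
    {both, a-only, b-only, neither} with 1 degree of freedom and no
    continuity correction.
    """
    a = np.asarray(matrix_a, dtype=bool)
    b = np.asarray(matrix_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("inputs must be equal-length 1-d boolean vectors")
    n = a.size
    if n == 0:
        raise ParameterError("empty site universe")
    both = int((a & b).sum())
    n_a, n_b = int(a.sum()), int(b.sum())
    expected = n_a * n_b / n
    t11, t10 = both, n_a - both
    t01 = n_b - both
    t00 = n - n_a - n_b + both
    denom = n_a * (n - n_a) * n_b * (n - n_b)
    if denom == 0:
        # A degenerate margin leaves independence unconstrained.
        return OverlapResult(both, expected, 0.0, 1.0)
    chi2 = n * (t11 * t00 - t10 * t01) ** 2 / denom
    p = float(stats.chi2.sf(chi2, df=1))
    return OverlapResult(both, expected, float(chi2), p)


def encounter_curve(matrix: MatchMatrix, n: int) -> int:
    """Number of sites whose first-encounter number is <= n."""
    if not 1 <= n <= matrix.n_scaffolds:
        raise ParameterError(f"n must be in [1, {matrix.n_scaffolds}]")
    return sum(1 for e in matrix.encounter if e is not None and e <= n)


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log10(count) against log10(n)."""

    exponent: float
    intercept: float
    r_squared: float

    def extrapolate(self, n: float) -> float:
        return float(10.0 ** (self.intercept + self.exponent * np.log10(n)))


def fit_power_law(curve: Sequence[tuple[float, float]]) -> PowerLawFit:
    """Fit count = 10^intercept * n^exponent by least squares in log-log space."""
    pts = np.asarray(curve, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ParameterError("need at least 2 (n, count) pairs")
    if (pts <= 0).any():
        raise ParameterError("all n and counts must be positive")
    x, y = np.log10(pts[:, 0]), np.log10(pts[:, 1])
    if np.allclose(x, x[0]):
        raise ParameterError("all n values identical; slope undefined")
    res = stats.linregress(x, y)
    r2 = 1.0 if np.allclose(y, y[0]) else float(res.rvalue**2)
    return PowerLawFit(float(res.slope), float(res.intercept), r2)


class ResampleResult(NamedTuple):
    mean_matches: float
    max_matches: int
    counts: np.ndarray


def resample_subsets(
    matrix: MatchMatrix, subset_size: int, reps: int, seed: int
) -> ResampleResult:
    """Mean/max number of matched sites over random scaffold subsets.

    Each rep draws ``subset_size`` scaffolds without replacement and counts
    the sites matched to at least one of them.  Requires a fully tested
    matrix (no skipped cells).
    """
    if not matrix.fully_tested:
        raise ParameterError(
            "matrix has untested cells; rerun matching with stop_at_first=False"
        )
    if not 1 <= subset_size <= matrix.n_scaffolds:
        raise ParameterError("subset_size out of range")
    rng = np.random.default_rng(seed)
    hits = matrix.fast == MATCHED
    counts = np.empty(reps, dtype=int)
    for r in range(reps):
        cols = rng.choice(matrix.n_scaffolds, size=subset_size, replace=False)
        counts[r] = int(hits[:, cols].any(axis=1).sum())
    return ResampleResult(float(counts.mean()), int(counts.max()), counts)
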
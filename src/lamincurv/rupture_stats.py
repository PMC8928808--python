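"""Cohort-level nuclear-rupture statistics.

Covers the three population analyses built on top of the single-filament
model:

* counts of rupture sites (lamin-B-deficient blebs/scars) per migrated cell,
  with the independence prediction ``P(N >= k) = p1**k`` — a k-th rupture
  occurs with probability ``p1`` regardless of how many preceded it — and a
  goodness-of-fit test of that prediction;
* enrichment of rupture sites in curvature regimes relative to how often the
  regime occurs along nuclear perimeters;
* the hinge ("critical strain-rate") fit of tip dilution versus nuclear entry
  rate, ``phi = c * max(0, rate - rate_crit)``: lamin-B behaves elastically
  (``rate_crit ~ 0``, dilution proportional to rate) whereas lamin-A flows
  only above a critical extension rate.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .contour_geometry import CurvatureRegime, classify_regime
from .intensity_metrics import Channel

__all__ = [
    "Condition",
    "RuptureRecord",
    "SiteCountDistribution",
    "IndependenceTestResult",
    "RegimeEnrichment",
    "HingeFit",
    "count_distribution",
    "multisite_prediction",
    "independence_test",
    "holm_adjust",
    "regime_enrichment",
    "estimate_critical_rate",
]

Condition = Literal["untreated", "myosin_inhibited", "hypotonic"]


@dataclass(frozen=True)
class RuptureRecord:
    """One migrated or aspirated cell and its rupture-site tally.

    ``imposed_curvature`` is the pore/pipette curvature in 1/um, or ``None``
    for unconfined 2-D culture.  ``site_curvatures`` may be empty for pore
    cohorts where only counts were scored.
    """

    cell_id: str
    n_sites: int
    imposed_curvature: float | None = None
    site_curvatures: tuple[float, ...] = ()
    condition: Condition = "untreated"

    def __post_init__(self) -> None:
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        if self.site_curvatures and len(self.site_curvatures) != self.n_sites:
            raise ValueError(
                f"{len(self.site_curvatures)} site curvatures recorded for "
                f"n_sites={self.n_sites}"
            )


@dataclass(frozen=True)
class SiteCountDistribution:
    """Fractions of cells with 0, exactly 1, exactly 2, and 3+ rupture sites."""

    zero: float
    one: float
    two: float
    three_plus: float
    n_cells: int

    @property
    def ruptured(self) -> float:
        """Overall rupture fraction: cells with at least one site."""
        return self.one + self.two + self.three_plus


def count_distribution(records: Sequence[RuptureRecord]) -> SiteCountDistribution:
    """Fractions of cells by rupture-site count, pooling counts >= 3 as "3+"."""
    if not records:
        raise ValueError("empty cohort")
    n = len(records)
    counts = np.array([min(r.n_sites, 3) for r in records])
    frac = np.bincount(counts, minlength=4) / n
    return SiteCountDistribution(*(float(f) for f in frac), n_cells=n)


def multisite_prediction(p1: float, k: int) -> float:
    """Independence prediction ``p1**k`` for the fraction with >= k sites.

    Treating each rupture as an independent event with per-event probability
    ``p1`` (the measured single-site fraction), the predicted fraction of
    cells with at least ``k`` rupture sites is ``p1**k``; for the pooled top
    class ("3+") this is used directly, for interior classes the "exactly k"
    fraction is ``p1**k - p1**(k+1)``.
    """
    if not 0 <= p1 <= 1:
        raise ValueError(f"p1 must be in [0, 1], got {p1}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return p1**k


def _class_probs(p1: float) -> np.ndarray:
    """Class probabilities for {0, 1, 2, 3+} under P(N >= k) = p1**k."""
    return np.array([1 - p1, p1 - p1**2, p1**2 - p1**3, p1**3])


@functools.lru_cache(maxsize=64)
def _exact_multinomial_table(n: int, probs: tuple[float, ...]) -> tuple[np.ndarray, np.ndarray]:
    """All outcome log-pmfs of Multinomial(n, probs), plus sorted pmf cumsum.

    Outcomes are enumerated as compositions of ``n`` into ``len(probs)``
    parts; returns (sorted pmf ascending, cumulative sums) for p-value
    lookup.  Cached because null calibrations reuse one (n, probs) pair.
    """
    m = len(probs)
    # vectorised composition enumeration
    grids = np.meshgrid(*[np.arange(n + 1)] * (m - 1), indexing="ij")
    flat = np.stack([g.ravel() for g in grids], axis=1)
    rest = n - flat.sum(axis=1)
    ok = rest >= 0
    comps = np.column_stack([flat[ok], rest[ok]])
    logp = np.log(np.clip(np.asarray(probs), 1e-300, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        logpmf = (
            math.lgamma(n + 1)
            - np.sum([np.vectorize(math.lgamma)(comps[:, j] + 1) for j in range(m)], axis=0)
            + comps @ logp
        )
    # zero-probability classes force pmf 0 unless their count is 0
    zero_cls = np.asarray(probs) == 0
    if zero_cls.any():
        bad = (comps[:, zero_cls] > 0).any(axis=1)
        logpmf[bad] = -np.inf
    pmf = np.exp(logpmf)
    order = np.argsort(pmf, kind="stable")
    pmf_sorted = pmf[order]
    return pmf_sorted, np.cumsum(pmf_sorted)


def _exact_multinomial_pvalue(observed: np.ndarray, probs: np.ndarray) -> float:
    """Exact multinomial test: total probability of outcomes no more likely."""
    n = int(observed.sum())
    pmf_sorted, cumsum = _exact_multinomial_table(n, tuple(float(p) for p in probs))
    obs_pmf = float(stats.multinomial.pmf(observed, n, probs))
    if not np.isfinite(obs_pmf):
        obs_pmf = 0.0
    idx = np.searchsorted(pmf_sorted, obs_pmf * (1 + 1e-9), side="right")
    pval = float(cumsum[idx - 1]) if idx > 0 else 0.0
    return min(max(pval, 0.0), 1.0)


@dataclass(frozen=True)
class IndependenceTestResult:
    """Goodness-of-fit of observed site counts to the independence model."""

    statistic: float
    p_value: float
    observed: tuple[float, ...]
    expected: tuple[float, ...]
    class_labels: tuple[str, ...]
    method: Literal["exact_multinomial", "chi_square"]
    p_value_adjusted: float | None = None


def independence_test(
    records: Sequence[RuptureRecord], p1: float
) -> IndependenceTestResult:
    """Test observed site counts against ``P(N >= k) = p1**k``.

    ``p1`` is the per-event rupture probability (in practice the measured
    single-site fraction from an independent estimate).  Expected class
    counts for {0, 1, 2, 3+} follow the independence model; adjacent classes
    with expected counts below 5 are pooled from the tail.  Cohorts smaller
    than 200 cells get an exact multinomial test (summing the probability of
    all outcomes no more likely than the observed one); larger cohorts use a
    Pearson chi-square against the fixed expected counts.

    Note this formal test is an extension of the fit-based visual comparison
    the multisite analysis is usually judged by.
    """
    if len(records) < 20:
        raise ValueError(f"independence_test needs a cohort of >= 20 cells, got {len(records)}")
    if not 0 <= p1 <= 1:
        raise ValueError(f"p1 must be in [0, 1], got {p1}")

    dist = count_distribution(records)
    n = dist.n_cells
    observed = np.array([dist.zero, dist.one, dist.two, dist.three_plus]) * n
    probs = _class_probs(p1)
    labels = ["0", "1", "2", "3+"]

    # degenerate p1: conforming data has statistic 0, anything else is impossible
    if p1 in (0.0, 1.0):
        conforms = bool(np.all(observed[probs == 0] == 0))
        return IndependenceTestResult(
            0.0 if conforms else float("inf"),
            1.0 if conforms else 0.0,
            tuple(observed),
            tuple(probs * n),
            tuple(labels),
            "exact_multinomial",
        )

    # pool adjacent tail classes with expected counts < 5
    expected = probs * n
    while len(expected) > 2 and expected[-1] < 5:
        expected = np.concatenate([expected[:-2], [expected[-2] + expected[-1]]])
        observed = np.concatenate([observed[:-2], [observed[-2] + observed[-1]]])
        probs = np.concatenate([probs[:-2], [probs[-2] + probs[-1]]])
        labels = labels[:-2] + [labels[-2] + "+"]

    statistic = float(np.sum((observed - expected) ** 2 / expected))
    if n < 200:
        pval = _exact_multinomial_pvalue(observed.astype(int), probs)
        method: Literal["exact_multinomial", "chi_square"] = "exact_multinomial"
    else:
        pval = float(stats.chisquare(observed, expected).pvalue)
        method = "chi_square"
    return IndependenceTestResult(
        statistic, pval, tuple(observed), tuple(expected), tuple(labels), method
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment for tests run across several pore diameters."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


@dataclass(frozen=True)
class RegimeEnrichment:
    """Per-regime rupture enrichment over perimeter occupancy."""

    regime: CurvatureRegime
    enrichment: float  # NaN when the regime never occurs on the perimeter
    median_curvature: float
    rupture_fraction: float
    perimeter_fraction: float
    undefined: bool = False


def regime_enrichment(
    rupture_curvatures: Sequence[float],
    perimeter_curvatures: Sequence[float],
    thresholds: tuple[float, float],
) -> dict[CurvatureRegime, RegimeEnrichment]:
    """Rupture-site enrichment per curvature regime.

    ``enrichment(regime) = (fraction of rupture sites in regime) /
    (fraction of perimeter samples in regime)``, so a value of 1 means
    ruptures occur no more often than the regime itself occurs along nuclear
    perimeters.  Median curvature per regime is taken over the perimeter
    samples.  A regime absent from the perimeter has undefined enrichment
    and is flagged rather than raising.  Duplicating the perimeter list
    leaves every enrichment unchanged: density, not count, matters.
    """
    rupture = np.asarray(rupture_curvatures, dtype=float)
    perimeter = np.asarray(perimeter_curvatures, dtype=float)
    if perimeter.size == 0:
        raise ValueError("perimeter_curvatures must be non-empty")

    regimes = (CurvatureRegime.LOW, CurvatureRegime.MEDIUM, CurvatureRegime.HIGH)
    rup_lab = [classify_regime(k, thresholds) for k in rupture]
    per_lab = [classify_regime(k, thresholds) for k in perimeter]

    out: dict[CurvatureRegime, RegimeEnrichment] = {}
    for reg in regimes:
        per_sel = np.array([lab is reg for lab in per_lab])
        per_frac = float(per_sel.mean())
        rup_frac = (
            sum(lab is reg for lab in rup_lab) / len(rup_lab) if rup_lab else 0.0
        )
        in_reg = perimeter[per_sel]
        median = float(np.median(in_reg)) if in_reg.size else float("nan")
        if per_frac == 0:
            out[reg] = RegimeEnrichment(reg, float("nan"), median, rup_frac, per_frac, True)
        else:
            out[reg] = RegimeEnrichment(reg, rup_frac / per_frac, median, rup_frac, per_frac)
    return out


@dataclass(frozen=True)
class HingeFit:
    """Hinge ("critical-rate") fit ``phi = c * max(0, rate - critical_rate)``.

    Predicted dilution is exactly zero at rates up to ``critical_rate`` and
    grows linearly with slope ``slope_c`` above it.  For lamin-B the fitted
    critical rate is expected near zero (elastic, instantaneous dilution
    proportional to rate); for lamin-A it is positive.
    """

    slope_c: float
    critical_rate: float
    channel: Channel
    residual_norm: float
    n_points: int
    flags: tuple[str, ...] = field(default=())

    def predict(self, rate):
        rate = np.asarray(rate, dtype=float)
        out = self.slope_c * np.maximum(0.0, rate - self.critical_rate)
        return out if out.ndim else float(out)


def estimate_critical_rate(
    pairs: Sequence[tuple[float, float]],
    channel: Channel = Channel.LAMIN_A,
    n_grid: int = 201,
) -> HingeFit:
    """Fit the hinge law ``phi = c * max(0, rate - r_crit)`` to (rate, phi) pairs.

    The hinge objective is piecewise smooth in ``r_crit``, so the fit runs a
    deterministic coarse grid over the observed rate range (the slope has a
    closed form at fixed ``r_crit``), then refines the best knot by bounded
    scalar minimisation between its grid neighbours.  If no pair shows
    positive dilution the fit reports ``r_crit`` at the largest observed rate
    with a ``"no dilution detected"`` flag.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 4:
        raise ValueError("need >= 4 (rate, phi) pairs")
    rates, phis = arr.T
    if not np.all(np.isfinite(arr)):
        raise ValueError("pairs must be finite")

    phi_norm = float(np.sqrt(np.sum(phis**2)))

    if np.all(phis <= 0):
        return HingeFit(
            0.0, float(rates.max()), channel, 1.0 if phi_norm else 0.0, len(arr),
            ("no dilution detected",),
        )

    def sse(r_crit: float) -> tuple[float, float]:
        g = np.maximum(0.0, rates - r_crit)
        denom = float(np.sum(g**2))
        c = float(np.sum(g * phis)) / denom if denom > 0 else 0.0
        return float(np.sum((phis - c * g) ** 2)), c

    grid = np.linspace(0.0, float(rates.max()), n_grid)
    losses = np.array([sse(r)[0] for r in grid])
    i = int(np.argmin(losses))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda r: sse(r)[0], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        best_r = float(res.x) if res.fun <= losses[i] else float(grid[i])
    else:
        best_r = float(grid[i])
    loss, c = sse(best_r)
    # exact knots sit at data points; snap if a data rate does at least as well
    for r_cand in np.concatenate([[0.0], rates]):
        l_cand, _ = sse(float(r_cand))
        if l_cand < loss - 1e-15 or (l_cand <= loss + 1e-15 and r_cand < best_r):
            loss, c = l_cand, sse(float(r_cand))[1]
            best_r = float(r_cand)
    rel = math.sqrt(loss) / phi_norm if phi_norm > 0 else math.sqrt(loss)
    return HingeFit(c, max(best_r, 0.0), channel, rel, len(arr))
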
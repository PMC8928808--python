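"""Seeded generators emulating every input class of the analysis.

The generators reproduce the statistical structure the analysis assumes —
not micrographs.  They provide:

* parametric nuclear contours (circle, ellipse, spindle/capsule) with
  analytically known pole curvature;
* intensity line profiles in which lamin-B tracks filament attachment,
  ``1 - P_detached(kappa)``, lamin-A responds only above a critical strain
  rate, and DNA mirrors lamin-B with independent noise;
* migration cohorts through pores of set diameters, with rupture-site counts
  drawn from the independence model ``P(N >= k) = p**k`` where ``p`` follows
  the sigmoidal response of pore curvature;
* micropipette aspiration traces with elastic (lamin-B) versus hinge-law
  (lamin-A) tip dilution and slow convergence of lamin-A toward lamin-B at
  long times.

Everything is driven by a single :class:`GeneratorConfig`; a fixed config
(seed included) yields byte-identical outputs.  Noise is additive Gaussian on
intensities — profiles stand for background-subtracted averages over many
pixels, where Poisson statistics have already washed out.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .contour_geometry import Contour
from .filament_model import FilamentParams, SigmoidFit, detach_probability, sigmoid_response
from .intensity_metrics import Channel, IntensityProfile, dilution_phi
from .rupture_stats import Condition, RuptureRecord

__all__ = [
    "GeneratorConfig",
    "AspirationTrace",
    "make_contour",
    "render_profiles",
    "simulate_migration_cohort",
    "simulate_aspiration",
]

logger = logging.getLogger(__name__)

# sub-stream tags so each generator draws from an independent, named stream
_STREAM_PROFILES = 1
_STREAM_COHORT = 2
_STREAM_ASPIRATION = 3


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic-data generators.

    Defaults encode the study conditions the analyses target: pore diameters
    2.25-8 um (curvatures 0.25-0.89 1/um), 500 migrated cells per pore, a
    response sigmoid with midpoint at 0.5 1/um (eps/alpha = 4/8, matching a
    pipette curvature where rupture becomes frequent) and amplitude B = 34
    interpreted as a percentage, filament energies (E, a) equal to
    (eps, alpha) with the geometric bending constant 0.19 k_BT*um**2, and a
    lamin-A hinge with critical rate 0.2 um/s inside a 0.05-1 um/s
    aspiration-rate range.
    """

    seed: int = 0
    filament: FilamentParams = field(
        default_factory=lambda: FilamentParams(binding_energy_E=4.0, contact_coeff_a=8.0)
    )
    sigmoid: SigmoidFit = field(
        default_factory=lambda: SigmoidFit(amplitude_B=34.0, epsilon=4.0, alpha=8.0)
    )
    noise_sd: float = 0.05
    laminA_hinge: tuple[float, float] = (1.0, 0.2)  # (slope c per (um/s), critical rate um/s)
    laminB_slope: float = 1.0  # phi_B per (um/s): elastic, dilutes in proportion to rate
    pore_diameters: tuple[float, ...] = (2.25, 3.0, 4.0, 5.0, 6.0, 8.0)
    cells_per_pore: int = 500
    candidate_rate_range: tuple[float, float] = (0.05, 1.0)
    condition: Condition = "untreated"
    myosin_p_factor: float = 0.5  # approximation knob: ~2-fold rupture suppression
    hypotonic_rate_factor: float = 0.5
    relaxation_tau: float = 300.0  # s; lamin-A -> lamin-B convergence at long times
    measure_time: float = 60.0  # s; standard early dilution readout

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.cells_per_pore < 1:
            raise ValueError("cells_per_pore must be >= 1")
        if any(d <= 0 for d in self.pore_diameters):
            raise ValueError("pore diameters must be positive")
        lo, hi = self.candidate_rate_range
        if not 0 <= lo < hi:
            raise ValueError("candidate_rate_range must satisfy 0 <= min < max")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for a named sub-stream of this config's seed."""
        return np.random.default_rng([self.seed, stream])


@dataclass(frozen=True)
class AspirationTrace:
    """Time course of one nucleus pulled into a pipette at constant rate.

    ``projection_length_dL`` is the aspirated length ``rate * t`` (um,
    non-decreasing); tip and inside intensities are per-channel arrays over
    the same time base.  ``pressure_dP`` is carried as metadata only — the
    generators impose geometry and rate, never a pressure model.
    """

    time: np.ndarray
    projection_length_dL: np.ndarray
    tip_intensity: dict[Channel, np.ndarray]
    inside_intensity: dict[Channel, np.ndarray]
    rate: float
    pipette_curvature: float = 0.5
    pressure_dP: float = float("nan")

    def __post_init__(self) -> None:
        if np.any(np.diff(self.projection_length_dL) < -1e-12):
            raise ValueError("projection length must be non-decreasing")
        for ch, v in self.tip_intensity.items():
            if np.any(v < 0) or np.any(self.inside_intensity[ch] < 0):
                raise ValueError("intensities must be non-negative")

    def dilution_at(self, t: float, channel: Channel) -> float:
        """Tip dilution phi of a channel at the trace time nearest ``t``."""
        i = int(np.argmin(np.abs(self.time - t)))
        return dilution_phi(
            float(self.inside_intensity[channel][i]),
            float(self.tip_intensity[channel][i]),
            channel,
        ).phi


def make_contour(
    shape: Literal["circle", "ellipse", "spindle"],
    size_params: dict[str, float],
    n_points: int = 256,
) -> Contour:
    """Parametric closed nuclear contour with analytic curvature metadata.

    Shapes
    ------
    circle
        ``{"radius": r}``; curvature ``1/r`` everywhere.
    ellipse
        ``{"a": semi_major, "b": semi_minor}``; pole curvature ``a/b**2``,
        side curvature ``b/a**2``.  Points are equally spaced in the
        parametric angle, which samples poles more densely in arc length.
    spindle
        ``{"pole_radius": r, "length": L}``: a capsule — two semicircular
        pole caps of radius ``r`` joined tangentially by straight sides — so
        pole curvature is ``1/r`` and side curvature exactly 0.  This is the
        idealised stably-elongated ("spindle-shaped") nucleus.

    The returned contour's ``metadata`` holds ``pole_curvature``,
    ``side_curvature``, ``semi_length`` and ``axial_curvature`` (a callable
    mapping axial distance from the pole, um, to boundary curvature, 1/um).
    """
    if n_points < 32:
        raise ValueError(f"n_points must be >= 32, got {n_points}")

    if shape == "circle":
        r = float(size_params["radius"])
        if r <= 0:
            raise ValueError("radius must be positive")
        t = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
        pts = np.column_stack([r * np.cos(t), r * np.sin(t)])
        meta = {
            "shape": shape,
            "pole_curvature": 1 / r,
            "side_curvature": 1 / r,
            "semi_length": r,
            "axial_curvature": lambda d, r=r: np.full_like(np.asarray(d, float), 1 / r),
        }
        return Contour(pts, closed=True, metadata=meta)

    if shape == "ellipse":
        a, b = float(size_params["a"]), float(size_params["b"])
        if not (a >= b > 0):
            raise ValueError("ellipse needs a >= b > 0")
        t = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
        pts = np.column_stack([a * np.cos(t), b * np.sin(t)])

        def axial_curvature(d, a=a, b=b):
            d = np.clip(np.asarray(d, float), 0.0, 2 * a)
            ct = np.clip((a - d) / a, -1.0, 1.0)
            st2 = 1 - ct**2
            return a * b / (a**2 * st2 + b**2 * ct**2) ** 1.5

        meta = {
            "shape": shape,
            "pole_curvature": a / b**2,
            "side_curvature": b / a**2,
            "semi_length": a,
            "axial_curvature": axial_curvature,
        }
        return Contour(pts, closed=True, metadata=meta)

    if shape == "spindle":
        r, L = float(size_params["pole_radius"]), float(size_params["length"])
        if not (r > 0 and L > 2 * r):
            raise ValueError("spindle needs pole_radius > 0 and length > 2*pole_radius")
        half = L / 2 - r  # straight-side half-length
        # arc-length parametrisation: right cap, top side, left cap, bottom side
        per_len = 2 * np.pi * r + 4 * half
        s = np.linspace(0, per_len, n_points, endpoint=False)
        pts = np.empty((n_points, 2))
        cap = np.pi * r
        for i, si in enumerate(s):
            if si < cap:  # right cap, from (half, -r) sweeping CCW
                ang = -np.pi / 2 + si / r
                pts[i] = [half + r * np.cos(ang), r * np.sin(ang)]
            elif si < cap + 2 * half:  # top side, right to left
                pts[i] = [half - (si - cap), r]
            elif si < 2 * cap + 2 * half:  # left cap
                ang = np.pi / 2 + (si - cap - 2 * half) / r
                pts[i] = [-half + r * np.cos(ang), r * np.sin(ang)]
            else:  # bottom side, left to right
                pts[i] = [-half + (si - 2 * cap - 2 * half), -r]

        def axial_curvature(d, r=r):
            d = np.asarray(d, float)
            return np.where(d < r, 1 / r, 0.0)

        meta = {
            "shape": shape,
            "pole_curvature": 1 / r,
            "side_curvature": 0.0,
            "semi_length": L / 2,
            "axial_curvature": axial_curvature,
        }
        return Contour(pts, closed=True, metadata=meta)

    raise ValueError(f"unknown shape {shape!r}")


def _hinge_reduction(rate: float, config: GeneratorConfig) -> float:
    """Fractional lamin-A mobilisation: 0 below the critical rate, then linear."""
    c, r_crit = config.laminA_hinge
    return float(np.clip(c * max(0.0, rate - r_crit), 0.0, 1.0))


def render_profiles(
    contour: Contour,
    config: GeneratorConfig,
    strain_rate: float = 0.0,
    n_samples: int = 64,
    depth: float | None = None,
) -> dict[Channel, IntensityProfile]:
    """Per-channel intensity profiles along the major axis from a pole inward.

    Lamin-B intensity at axial distance ``d`` is ``1 - P_detached(kappa(d))``
    with ``kappa`` the contour's analytic boundary curvature; DNA mirrors
    lamin-B with independent noise; lamin-A is reduced by the detachment
    profile only to the extent the strain rate exceeds the hinge's critical
    rate, so below it the lamin-A profile stays flat while lamin-B dilutes.
    Additive Gaussian noise of sd ``config.noise_sd`` is applied per sample
    (seeded); values are clipped at 0.
    """
    kappa_of = contour.metadata.get("axial_curvature")
    if kappa_of is None:
        raise ValueError("contour lacks axial_curvature metadata; use make_contour")
    semi = contour.metadata.get("semi_length")
    depth = float(depth if depth is not None else semi)
    d = np.linspace(0.0, depth, n_samples)
    p_det = detach_probability(kappa_of(d), config.filament)

    rng = config.rng(_STREAM_PROFILES)
    g = _hinge_reduction(strain_rate, config)
    base = {
        Channel.LAMIN_B: 1.0 - p_det,
        Channel.LAMIN_A: 1.0 - g * p_det,
        Channel.DNA: 1.0 - p_det,
    }
    out = {}
    for ch in (Channel.LAMIN_A, Channel.LAMIN_B, Channel.DNA):
        noise = rng.normal(0.0, config.noise_sd, n_samples) if config.noise_sd else 0.0
        out[ch] = IntensityProfile(d, np.clip(base[ch] + noise, 0.0, None), ch)
    return out


def _rupture_probability(diameter: float, config: GeneratorConfig) -> float:
    """Per-event rupture probability for a pore, from the response sigmoid."""
    resp = sigmoid_response(2.0 / diameter, config.sigmoid)
    if config.sigmoid.amplitude_B > 1.0:
        # amplitude in percent; convert to probability
        logger.info("sigmoid amplitude %.3g > 1 treated as percent", config.sigmoid.amplitude_B)
        resp = resp / 100.0
    if config.condition == "myosin_inhibited":
        resp *= config.myosin_p_factor
    if not 0.0 <= resp <= 1.0:
        warnings.warn(f"rupture probability {resp:.3g} clipped to [0, 1]", stacklevel=2)
        resp = float(np.clip(resp, 0.0, 1.0))
    return float(resp)


def simulate_migration_cohort(config: GeneratorConfig) -> list[RuptureRecord]:
    """Cohort of cells migrated through each configured pore diameter.

    Each cell's rupture-site count follows the independence model: a k-th
    rupture occurs with probability ``p`` given k-1 occurred, i.e.
    ``P(N >= k) = p**k``, with counts capped at the "3+" class (recorded as
    3).  ``p`` is the sigmoidal response of pore curvature converted to a
    probability; myosin inhibition halves ``p`` (a documented approximation)
    and the hypotonic condition is tagged on the records for downstream
    rate modelling, leaving ``p`` untouched.
    """
    rng = config.rng(_STREAM_COHORT)
    records: list[RuptureRecord] = []
    for d_pore in config.pore_diameters:
        p = _rupture_probability(d_pore, config)
        kappa = 2.0 / d_pore
        draws = rng.random((config.cells_per_pore, 3))
        n_sites = (np.cumprod(draws < p, axis=1) > 0).sum(axis=1)
        for j, n in enumerate(n_sites):
            records.append(
                RuptureRecord(
                    cell_id=f"D{d_pore:g}_c{j:04d}",
                    n_sites=int(n),
                    imposed_curvature=kappa,
                    condition=config.condition,
                )
            )
    return records


def simulate_aspiration(
    config: GeneratorConfig,
    rates: Sequence[float],
    times: np.ndarray | None = None,
) -> list[AspirationTrace]:
    """Aspiration traces at the given entry rates into a 0.5 1/um pipette.

    Tip dilution of lamin-B is elastic: ``phi_B = laminB_slope * rate`` from
    the start of aspiration.  Lamin-A follows the hinge law at the standard
    readout time and then relaxes exponentially toward lamin-B's dilution
    (time constant ``relaxation_tau``), so at very long times the two
    converge regardless of rate; the relaxation clock starts at the readout
    time ``measure_time`` so the early readout reflects the hinge law
    exactly.  DNA tracks lamin-B.  The hypotonic condition scales rates by
    ``hypotonic_rate_factor``.
    """
    if times is None:
        times = np.linspace(0.0, 20 * 60.0, 81)
    times = np.asarray(times, dtype=float)
    rng = config.rng(_STREAM_ASPIRATION)
    traces = []
    for rate in rates:
        if rate < 0:
            raise ValueError("rates must be non-negative")
        eff_rate = rate * (
            config.hypotonic_rate_factor if config.condition == "hypotonic" else 1.0
        )
        phi_b = config.laminB_slope * eff_rate
        # unclipped hinge law: phi is a dilution, not a fraction
        phi_a0 = config.laminA_hinge[0] * max(0.0, eff_rate - config.laminA_hinge[1])
        relax = 1.0 - np.exp(-np.maximum(0.0, times - config.measure_time) / config.relaxation_tau)
        phi_a_t = phi_a0 + (phi_b - phi_a0) * relax
        phi_b_t = np.full_like(times, phi_b)
        if eff_rate == 0:
            phi_a_t = np.zeros_like(times)
            phi_b_t = np.zeros_like(times)
        inside = 1.0
        tip = {}
        ins = {}
        for ch, phi_t in (
            (Channel.LAMIN_A, phi_a_t),
            (Channel.LAMIN_B, phi_b_t),
            (Channel.DNA, phi_b_t),
        ):
            noise = rng.normal(0.0, config.noise_sd, len(times)) if config.noise_sd else 0.0
            tip[ch] = np.clip(inside / (1.0 + phi_t) + noise, 1e-9, None)
            ins[ch] = np.full_like(times, inside)
        traces.append(
            AspirationTrace(
                time=times,
                projection_length_dL=eff_rate * times,
                tip_intensity=tip,
                inside_intensity=ins,
                rate=float(rate),
            )
        )
    return traces
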
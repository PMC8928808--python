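"""Intensity-derived dilution statistics for nuclear poles and pipette tips.

Line-scan intensity profiles (lamin-A, lamin-B, DNA) originate at a nuclear
pole or aspirated tip and run inward along the major axis.  Profiles are
min-max normalized, averaged within 1 um of the pole, and combined into a
lamin-B-to-lamin-A ratio that is then paired with local curvature upstream.

For aspirated nuclei, dilution at the leading tip is summarised by
``phi = inside / tip - 1``: phi is 0 when the tip shows no lamin loss and
positive when the tip is depleted relative to the nuclear interior.  Both
intensities are assumed background-subtracted, with tip/inside regions sized
roughly as the pipette radius squared; at spindle poles the same measure is
computed from (center, pole) boxes of 2 x 2 um.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

__all__ = [
    "Channel",
    "Geometry",
    "IntensityProfile",
    "DilutionMeasure",
    "minmax_normalize",
    "pole_mean",
    "laminB_to_A_ratio",
    "dilution_phi",
    "relative_tip_intensity",
]


class Channel(str, Enum):
    LAMIN_A = "laminA"
    LAMIN_B = "laminB"
    DNA = "DNA"


class Geometry(str, Enum):
    PIPETTE_TIP = "pipette_tip"
    SPINDLE_POLE = "spindle_pole"


@dataclass(frozen=True)
class IntensityProfile:
    """Intensity sampled along a line scan from the pole/tip inward.

    ``distance`` is um from the origin (strictly increasing, >= 2 samples);
    ``value`` is intensity in arbitrary units, background-subtracted where
    the measurement protocol calls for it.  Raw line scans are averaged over
    a ~1.5 um-wide band at acquisition time, which this container only
    records conceptually — samples here are already 1-D.
    """

    distance: np.ndarray
    value: np.ndarray
    channel: Channel = Channel.LAMIN_B

    def __post_init__(self) -> None:
        d = np.asarray(self.distance, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if d.ndim != 1 or d.shape != v.shape or len(d) < 2:
            raise ValueError("distance and value must be matching 1-D arrays, >= 2 samples")
        if not (np.all(np.isfinite(d)) and np.all(np.isfinite(v))):
            raise ValueError("profile samples must be finite")
        if np.any(np.diff(d) <= 0):
            raise ValueError("distances must be strictly increasing")
        object.__setattr__(self, "distance", d)
        object.__setattr__(self, "value", v)


@dataclass(frozen=True)
class DilutionMeasure:
    """Local depletion ``phi = inside/tip - 1`` of one channel at one site."""

    phi: float
    tip_intensity: float
    inside_intensity: float
    channel: Channel
    geometry: Geometry = Geometry.PIPETTE_TIP

    def __post_init__(self) -> None:
        if self.phi < -1:
            raise ValueError("phi cannot be below -1 for non-negative intensities")


def minmax_normalize(profile: IntensityProfile) -> IntensityProfile:
    """Map profile values to ``(v - min) / (max - min)``, range [0, 1].

    Invariant under affine transforms ``v -> s*v + c`` (s > 0) of the raw
    intensities, so it removes exposure and offset differences between
    channels.  Constant profiles cannot be normalized and raise.
    """
    v = profile.value
    vmin, vmax = float(v.min()), float(v.max())
    if vmax <= vmin:
        raise ValueError("cannot min-max normalize a constant profile")
    return replace(profile, value=(v - vmin) / (vmax - vmin))


def pole_mean(profile: IntensityProfile, window: float = 1.0) -> float:
    """Mean intensity within ``window`` um of the profile origin.

    The mean is a trapezoidal average over distance rather than a raw sample
    mean, so non-uniformly sampled profiles are not biased toward densely
    sampled stretches.  If the window extends beyond the profile, the whole
    profile is averaged and a warning is emitted.
    """
    if not window > 0:
        raise ValueError(f"window must be positive, got {window}")
    d, v = profile.distance, profile.value
    limit = d[0] + window
    if limit >= d[-1]:
        if limit > d[-1]:
            warnings.warn(
                f"window {window} um exceeds profile extent {d[-1] - d[0]:.3g} um; "
                "averaging the whole profile",
                stacklevel=2,
            )
        sel = np.ones(len(d), dtype=bool)
    else:
        sel = d <= limit + 1e-12
    if not np.any(sel):
        raise ValueError("no profile samples within the pole window")
    dd, vv = d[sel], v[sel]
    if len(dd) == 1:
        return float(vv[0])
    return float(np.trapezoid(vv, dd) / (dd[-1] - dd[0]))


def laminB_to_A_ratio(
    profileB: IntensityProfile, profileA: IntensityProfile, window: float = 1.0
) -> float:
    """Ratio of mean lamin-B to mean lamin-A intensity near the pole.

    Both profiles should be min-max normalized and share an origin at the
    pole of interest; the ratio is paired with the local curvature upstream
    to build the ratio-vs-curvature response fitted by the detachment model.
    """
    mean_a = pole_mean(profileA, window)
    if mean_a == 0:
        raise ZeroDivisionError("lamin-A pole mean is zero; ratio undefined")
    return pole_mean(profileB, window) / mean_a


def dilution_phi(
    inside: float,
    tip: float,
    channel: Channel = Channel.LAMIN_B,
    geometry: Geometry = Geometry.PIPETTE_TIP,
) -> DilutionMeasure:
    """Dilution ``phi = inside/tip - 1`` of a channel at a tip or pole.

    ``phi = 0`` means the leading tip shows zero loss; ``phi > 0`` means the
    tip is diluted relative to the interior; negative phi indicates tip
    enrichment.  For spindle poles, pass the nuclear-center intensity as
    ``inside`` and the pole intensity as ``tip``.
    """
    if not tip > 0:
        raise ValueError(f"tip intensity must be positive, got {tip}")
    if inside < 0:
        raise ValueError(f"inside intensity must be non-negative, got {inside}")
    return DilutionMeasure(inside / tip - 1.0, tip, inside, channel, geometry)


def relative_tip_intensity(tip: float, inside: float) -> float:
    """Relative tip intensity ``tip / inside``; equals ``1 / (1 + phi)``."""
    if not inside > 0:
        raise ValueError(f"inside intensity must be positive, got {inside}")
    if tip < 0:
        raise ValueError(f"tip intensity must be non-negative, got {tip}")
    return tip / inside
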
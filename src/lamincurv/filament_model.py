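"""Two-state Boltzmann model of lamin-filament detachment from a curved membrane.

A single semi-flexible lamin-B filament of in-situ length ``L_fil`` and
persistence length ``l_p`` is either attached to the inner nuclear membrane or
detached from it.  Attachment to a membrane of Gaussian-curvature radius ``R``
costs a contact-area term ``a/R`` and a bending term ``k/(2 R**2)`` on top of
the (negative) binding energy ``-E``, so the Boltzmann probability of the
detached state rises sigmoidally with membrane curvature ``1/R``.

All energies are expressed in units of ``k_B*T``, so temperature never appears
explicitly: ``E`` is dimensionless, ``a`` carries units of k_BT*um and the
bending constant ``k`` units of k_BT*um**2.  Curvature arguments are ``1/R``
in 1/um, which keeps the flat-membrane limit representable as exactly zero.

The same logistic shape, ``y = B / (1 + exp(eps - alpha*x))``, is the response
curve fitted to rupture-frequency and lamin-ratio data; :func:`fit_sigmoid`
performs those fits with the amplitude ``B`` free and ``(eps, alpha)`` either
fixed from prior calibration or estimated jointly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit

__all__ = [
    "FilamentParams",
    "SigmoidFit",
    "bending_constant",
    "attached_energy",
    "detach_probability",
    "sigmoid_response",
    "fit_sigmoid",
]

# exponent clip before exponentiation; saturated probabilities are physical
_EXP_CLIP = 700.0


def bending_constant(lp: float, Lfil: float) -> float:
    """Filament bending constant ``k = l_p * L_fil`` in k_BT*um**2.

    The bending stiffness of a semi-flexible filament is ``l_p * k_B*T``;
    integrating the bending energy over the filament's in-situ length gives a
    curvature-squared energy coefficient of ``(l_p * k_B*T) * L_fil``.

    Parameters
    ----------
    lp : float
        Persistence length in um (> 0).
    Lfil : float
        In-situ filament length in um (> 0).
    """
    if not (lp > 0 and Lfil > 0):
        raise ValueError(f"lp and Lfil must be positive, got lp={lp}, Lfil={Lfil}")
    return lp * Lfil


@dataclass(frozen=True)
class FilamentParams:
    """Energies and geometry of the single-filament detachment model.

    Attributes
    ----------
    binding_energy_E : float
        Membrane binding energy in k_BT units (>= 0).
    contact_coeff_a : float
        Coefficient of the curvature-linear contact term, k_BT*um (>= 0);
        captures the curvature-induced change in filament/membrane contact
        area.
    bending_k : float
        Bending constant in k_BT*um**2 (>= 0).  When derived from geometry it
        equals ``persistence_length_lp * filament_length_Lfil``.
    persistence_length_lp : float
        Filament persistence length, um (> 0).  Median reported values for
        lamin filaments are ~0.5 um, with stiff filaments up to ~3 um.
    filament_length_Lfil : float
        In-situ filament length, um (> 0); ~0.38 um for lamin-B.
    """

    binding_energy_E: float
    contact_coeff_a: float
    bending_k: float | None = None
    persistence_length_lp: float = 0.5
    filament_length_Lfil: float = 0.38

    def __post_init__(self) -> None:
        if self.bending_k is None:
            object.__setattr__(
                self,
                "bending_k",
                bending_constant(self.persistence_length_lp, self.filament_length_Lfil),
            )
        for name in ("binding_energy_E", "contact_coeff_a", "bending_k"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if not (self.persistence_length_lp > 0 and self.filament_length_Lfil > 0):
            raise ValueError("persistence_length_lp and filament_length_Lfil must be > 0")

    def bending_consistent(self, rtol: float = 1e-9) -> bool:
        """True when ``bending_k`` equals ``l_p * L_fil`` to relative tolerance."""
        derived = bending_constant(self.persistence_length_lp, self.filament_length_Lfil)
        return math.isclose(self.bending_k, derived, rel_tol=rtol)


@dataclass(frozen=True)
class SigmoidFit:
    """Parameters of the logistic response ``y = B / (1 + exp(eps - alpha*x))``.

    ``amplitude_B`` carries the units of the fitted response (a percentage for
    rupture-frequency fits, dimensionless for intensity ratios); ``epsilon``
    is a binding energy in k_BT and ``alpha`` an interaction energy per unit
    curvature (k_BT*um).  ``mode`` records whether only B was fitted
    ("B_only") or all three parameters ("full"); ``residual_norm`` is the
    weighted residual norm relative to the weighted response norm, so it is
    dimensionless and invariant under rescaling of the response.
    """

    amplitude_B: float
    epsilon: float
    alpha: float
    mode: Literal["B_only", "full"] = "full"
    residual_norm: float = float("nan")
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_B < 0:
            raise ValueError(f"amplitude_B must be >= 0, got {self.amplitude_B}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, payload: str) -> "SigmoidFit":
        return cls(**json.loads(payload))


def attached_energy(inv_R, params: FilamentParams):
    """Energy of the attached state, ``-E + a/R + k/(2 R**2)``, in k_BT.

    ``inv_R`` is the curvature magnitude 1/R in 1/um (scalar or array).  The
    flat-membrane limit ``inv_R = 0`` returns ``-E``.  Sign classification of
    Gaussian curvature is the caller's responsibility (see
    :func:`lamincurv.contour_geometry.gaussian_sign`); negative values are
    rejected here.
    """
    inv_R = np.asarray(inv_R, dtype=float)
    if np.any(inv_R < 0):
        raise ValueError("inv_R must be a non-negative curvature magnitude")
    out = (
        -params.binding_energy_E
        + params.contact_coeff_a * inv_R
        + 0.5 * params.bending_k * inv_R**2
    )
    return out if out.ndim else float(out)


def detach_probability(inv_R, params: FilamentParams, include_bending: bool = True):
    """Boltzmann probability that the filament is detached at curvature 1/R.

    ``P = 1 / (1 + exp(E - a/R - k/(2 R**2)))`` with energies in k_BT.  The
    probability is monotone non-decreasing in curvature, tends to
    ``1/(1+exp(E))`` (≈ 0 for E >> 1) on flat membranes and saturates at 1 at
    high curvature.  ``include_bending=False`` drops the quadratic bending
    term, which has a negligible effect on fitted curves at physiological
    curvatures and is therefore frequently omitted in fits.
    """
    inv_R = np.asarray(inv_R, dtype=float)
    if np.any(inv_R < 0):
        raise ValueError("inv_R must be a non-negative curvature magnitude")
    exponent = params.binding_energy_E - params.contact_coeff_a * inv_R
    if include_bending:
        exponent = exponent - 0.5 * params.bending_k * inv_R**2
    exponent = np.clip(exponent, -_EXP_CLIP, _EXP_CLIP)
    out = expit(-exponent)
    return out if out.ndim else float(out)


def sigmoid_response(x, fit: SigmoidFit):
    """Evaluate the logistic response ``B / (1 + exp(eps - alpha*x))``.

    With ``B = 1``, ``eps = E`` and ``alpha = a`` this equals
    :func:`detach_probability` without the bending term.  The asymptote as
    ``x -> inf`` is ``B`` (for ``alpha > 0``); at ``x = eps/alpha`` the
    response is ``B/2``.
    """
    x = np.asarray(x, dtype=float)
    exponent = np.clip(fit.epsilon - fit.alpha * x, -_EXP_CLIP, _EXP_CLIP)
    out = fit.amplitude_B * expit(-exponent)
    return out if out.ndim else float(out)


def _parse_points(points) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Accept (x, y) or (x, y, n_trials) rows; return x, y, weights."""
    arr = np.atleast_2d(np.asarray(points, dtype=float))
    if arr.shape[1] == 2:
        x, y = arr.T
        w = np.ones_like(x)
    elif arr.shape[1] == 3:
        x, y, w = arr.T
        if np.any(w <= 0):
            raise ValueError("n_trials must be positive")
    else:
        raise ValueError("points must have columns (curvature, response[, n_trials])")
    if not np.all(np.isfinite(arr)):
        raise ValueError("points must be finite")
    return x, y, w


def fit_sigmoid(
    points: Sequence,
    mode: Literal["B_only", "full"] = "full",
    fixed_eps_alpha: tuple[float, float] | None = None,
    seed: int = 0,
    weighted: bool = True,
) -> SigmoidFit:
    """Least-squares fit of the logistic response to (curvature, response) data.

    Parameters
    ----------
    points
        Rows of ``(curvature, response)`` or ``(curvature, response,
        n_trials)``.  When trial counts are present and ``weighted`` is true,
        rows are weighted by ``n_trials`` (binomial weighting); both weighted
        and unweighted fits are exposed because figure-level fits in the
        source data do not state their weighting.
    mode
        ``"B_only"`` fits the amplitude with ``(eps, alpha)`` fixed to
        ``fixed_eps_alpha`` — the closed-form weighted ratio
        ``B = sum(w f y) / sum(w f**2)`` with ``f`` the unit logistic.
        ``"full"`` fits ``(B, eps, alpha)`` by nonlinear least squares with
        five deterministic multi-starts (alpha log-spaced over the data's
        curvature span); the best residual wins, ties broken by smallest
        alpha.
    fixed_eps_alpha
        Required in ``B_only`` mode.  There is deliberately no built-in
        default: the calibrated ``(eps, alpha)`` pair comes from prior work
        and must be supplied by the user.
    seed
        Reserved for reproducibility of the multi-start schedule; the default
        schedule is already deterministic.

    Notes
    -----
    The fit is scale-equivariant in the response: scaling all responses by s
    scales ``amplitude_B`` by s and leaves ``(eps, alpha, residual_norm)``
    unchanged.  All-zero responses yield ``B = 0`` with zero residual.
    """
    x, y, w = _parse_points(points)
    if not weighted:
        w = np.ones_like(w)
    n = len(x)

    y_norm = float(np.sqrt(np.sum(w * y**2)))

    def rel_residual(pred: np.ndarray) -> float:
        r = float(np.sqrt(np.sum(w * (y - pred) ** 2)))
        return r / y_norm if y_norm > 0 else r

    if mode == "B_only":
        if fixed_eps_alpha is None:
            raise ValueError("B_only mode requires fixed_eps_alpha=(eps, alpha)")
        if n < 1:
            raise ValueError("B_only mode needs at least 1 point")
        eps, alpha = map(float, fixed_eps_alpha)
        f = expit(np.clip(alpha * x - eps, -_EXP_CLIP, _EXP_CLIP))
        denom = float(np.sum(w * f**2))
        B = float(np.sum(w * f * y)) / denom if denom > 0 else 0.0
        B = max(B, 0.0)
        return SigmoidFit(B, eps, alpha, "B_only", rel_residual(B * f), n)

    if mode != "full":
        raise ValueError(f"unknown mode {mode!r}")
    if n < 3:
        raise ValueError("full mode needs at least 3 points")
    if y_norm == 0.0:
        eps0, alpha0 = fixed_eps_alpha if fixed_eps_alpha is not None else (0.0, 0.0)
        return SigmoidFit(0.0, eps0, alpha0, "full", 0.0, n)

    sw = np.sqrt(w)
    span = float(np.ptp(x))
    if span <= 0:
        raise ValueError("full mode needs at least two distinct curvature values")
    x_mid = float(np.median(x))

    def residuals(theta: np.ndarray) -> np.ndarray:
        B, eps, alpha = theta
        f = expit(np.clip(alpha * x - eps, -_EXP_CLIP, _EXP_CLIP))
        return sw * (B * f - y)

    best: tuple[float, np.ndarray] | None = None
    # log-spaced alpha starts spanning gentle to steep transitions over the data
    for alpha0 in np.geomspace(0.5 / span, 50.0 / span, 5):
        theta0 = np.array([max(float(np.max(y)), 1e-12), alpha0 * x_mid, alpha0])
        sol = optimize.least_squares(
            residuals,
            theta0,
            bounds=([0.0, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        key = (sol.cost, sol.x[2])  # tie-break by smallest alpha
        if best is None or key < (best[0], best[1][2]):
            best = (sol.cost, sol.x)
    assert best is not None
    B, eps, alpha = best[1]
    f = expit(np.clip(alpha * x - eps, -_EXP_CLIP, _EXP_CLIP))
    return SigmoidFit(float(B), float(eps), float(alpha), "full", rel_residual(B * f), n)
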
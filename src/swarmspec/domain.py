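"""Common expansion domain: exponential boundary fit and non-dimensionalization.

A swarm boundary expanding as ``b(t) = b0 * exp(t / tau)`` is fitted jointly
across replicates with one shared growth timescale ``tau`` and one intercept
``b0`` per replicate.  Per-replicate time shifts then superimpose all
boundaries, and sample coordinates are rescaled onto a single dimensionless
domain ``0 <= t~ <= T``, ``0 <= p~ <= exp(t~)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar


@dataclass(frozen=True)
class SampleAnnotation:
    """One space-time sampling location.

    Attributes
    ----------
    sample_id : str
    replicate_id : str
    time : float
        Sampling time in hours.
    position : float
        Radial position in mm from the inoculation point.
    boundary_radius : float
        Swarm boundary radius in mm at the sampling time.
    """

    sample_id: str
    replicate_id: str
    time: float
    position: float
    boundary_radius: float


@dataclass(frozen=True)
class BoundaryObservations:
    """Boundary radius measurements for one replicate.

    Parameters
    ----------
    replicate_id : str
        Replicate label.
    times : array of float
        Observation times in hours, strictly increasing.
    radii : array of float
        Boundary radii in mm, strictly positive.
    """

    replicate_id: str
    times: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.radii, dtype=float)
        if t.ndim != 1 or r.shape != t.shape:
            raise ValueError("times and radii must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("need at least 2 observations per replicate")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(r <= 0):
            raise ValueError("radii must be strictly positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "radii", r)


@dataclass
class DomainFit:
    """Joint exponential boundary fit across replicates.

    Attributes
    ----------
    tau : float
        Shared growth timescale (h).
    b0 : dict
        Per-replicate initial radius b0^(k) (mm).
    time_shifts : dict
        Per-replicate time shift t_s^(k) (h).
    b0_common : float
        Common length scale b0 = b0^(r) * exp(t_s^(r)/tau) (mm).
    T : float
        Maximum dimensionless time present in all replicates.
    reference : str
        Replicate with the largest b0 (defines the shift origin).
    residual : float
        Summed squared residual of the joint fit.
    """

    tau: float
    b0: dict[str, float]
    time_shifts: dict[str, float] = field(default_factory=dict)
    b0_common: float = float("nan")
    T: float = float("nan")
    reference: str = ""
    residual: float = float("nan")

    def boundary_radius(self, replicate_id: str, t: np.ndarray) -> np.ndarray:
        """Fitted boundary radius b0^(k) * exp(t/tau) in mm."""
        return self.b0[replicate_id] * np.exp(np.asarray(t, float) / self.tau)

    def to_json(self) -> str:
        return json.dumps(
            {
                "tau": self.tau,
                "b0": self.b0,
                "time_shifts": self.time_shifts,
                "b0_common": self.b0_common,
                "T": self.T,
                "reference": self.reference,
                "residual": self.residual,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DomainFit":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class ScaledCoordinate:
    """A sample location on the dimensionless domain."""

    t_tilde: float
    p_tilde: float
    in_domain: bool


def _profiled_loss(tau: float, observations: list[BoundaryObservations]) -> tuple[float, dict[str, float]]:
    """Loss at tau with each b0^(k) profiled out analytically.

    For fixed tau the model is linear in b0: the optimum is
    b0 = sum(b * e) / sum(e^2) with e = exp(t/tau).
    """
    loss = 0.0
    b0s: dict[str, float] = {}
    for obs in observations:
        e = np.exp(obs.times / tau)
        b0 = float(np.dot(obs.radii, e) / np.dot(e, e))
        b0s[obs.replicate_id] = b0
        resid = obs.radii - b0 * e
        loss += float(np.dot(resid, resid))
    return loss, b0s


def fit_boundary(observations: list[BoundaryObservations],
                 tau_bounds: tuple[float, float] = (0.05, 50.0)) -> DomainFit:
    """Fit one shared tau and per-replicate b0 by joint least squares.

    The fit minimizes the summed squared boundary residual over all
    replicates.  b0^(k) enters linearly given tau and is profiled out;
    the remaining 1-D problem in tau is solved by a coarse log-spaced
    grid scan refined with bounded scalar minimization — deterministic,
    no random initialization.
    """
    if not observations:
        raise ValueError("no boundary observations supplied")
    ids = [o.replicate_id for o in observations]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate replicate ids")

    grid = np.geomspace(tau_bounds[0], tau_bounds[1], 200)
    losses = np.array([_profiled_loss(t, observations)[0] for t in grid])
    i = int(np.argmin(losses))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(lambda t: _profiled_loss(t, observations)[0],
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    tau = float(res.x)
    loss, b0s = _profiled_loss(tau, observations)
    fit = DomainFit(tau=tau, b0=b0s, residual=loss)
    _attach_shifts(fit, observations)
    return fit


def _attach_shifts(fit: DomainFit, observations: list[BoundaryObservations]) -> None:
    fit.time_shifts = time_shifts(fit, {o.replicate_id: float(o.times[0]) for o in observations})
    # Common dimensionless horizon: latest time covered by every replicate.
    t_max = [
        (max(o.times) - fit.time_shifts[o.replicate_id]) / fit.tau for o in observations
    ]
    fit.T = float(min(t_max))


def time_shifts(fit: DomainFit, first_times: dict[str, float]) -> dict[str, float]:
    """Per-replicate time shifts that superimpose the fitted boundaries.

    The reference replicate ``r`` is the one with the largest b0 (ties
    broken by lowest replicate id); its shift is its own first sampling
    time.  Other shifts follow from
    ``t_s^(k) = tau * (log b0^(r) - log b0^(k)) + t_s^(r)``, after which
    every scaled boundary coincides with ``p~ = exp(t~)``.
    """
    items = sorted(fit.b0.items())
    ref = max(items, key=lambda kv: kv[1])[0]
    b0_max = fit.b0[ref]
    # ties -> lowest id among the maxima
    ref = min(k for k, v in items if v == b0_max)
    t_s_ref = first_times[ref]
    shifts = {
        k: fit.tau * (np.log(fit.b0[ref]) - np.log(fit.b0[k])) + t_s_ref
        for k in fit.b0
    }
    fit.reference = ref
    fit.b0_common = float(fit.b0[ref] * np.exp(t_s_ref / fit.tau))
    return shifts


def nondimensionalize(annotations, fit: DomainFit) -> list[ScaledCoordinate]:
    """Rescale sample annotations onto the common domain.

    ``t~ = (t - t_s^(k)) / tau`` and ``p~ = p / b0_common``.  A point is
    in-domain iff ``0 <= t~ <= T`` and ``0 <= p~ <= exp(t~)``, all four
    constraints boundary-inclusive.  Out-of-domain points are flagged,
    not dropped, so callers can report exclusions.
    """
    out = []
    for a in annotations:
        shift = fit.time_shifts[a.replicate_id]
        t_t = (a.time - shift) / fit.tau
        p_t = a.position / fit.b0_common
        inside = (0.0 <= t_t <= fit.T) and (0.0 <= p_t <= np.exp(t_t))
        out.append(ScaledCoordinate(float(t_t), float(p_t), bool(inside)))
    return out
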
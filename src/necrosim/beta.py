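"""Von Bertalanffy growth-exponent estimation from sparse volumetric follow-up.

The simplified Von Bertalanffy law

    dV/dt = alpha * V**beta

classifies longitudinal growth: ``beta < 1`` is sublinear (decelerating,
surface-limited growth gives 2/3), ``beta = 1`` is exponential and
``beta > 1`` is superlinear ("explosive") growth.  With three volumetric
observations (t0, V0), (t1, V1), (t2, V2) the two parameters are fully
determined: eliminating ``alpha`` from the integrated law yields the scalar
identity

    [1 - (V1/V0)**(1-beta)] / [1 - (V2/V0)**(1-beta)] = (t1-t0)/(t2-t0)

which is solved for ``beta`` by bracketed root finding.  The identity depends
only on volume ratios and time differences, so estimates are invariant under
volume rescaling and time shifts.

Clinical MRI follow-up provides irregularly spaced scans; the sampling
schemes here mimic that cadence, and noisy simulated lesions are summarised
by the median over repeated random observation triples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BetaEstimate",
    "SamplingScheme",
    "MedianBetaResult",
    "solve_beta",
    "sample_observation_times",
    "median_beta",
]

#: residual tolerance on the three-point identity for converged estimates
ROOT_TOL = 1e-8
#: |ln(V1/V0)/ln(V2/V0) - tau| below this means exactly exponential (beta = 1)
_EXP_TOL = 1e-10
#: initial root bracket; expanded geometrically when no sign change is found
_BRACKET = (-2.0, 5.0)
_MAX_EXPANSIONS = 4


@dataclass(frozen=True)
class BetaEstimate:
    """Result of inverting the three-point growth identity."""

    beta: float
    alpha: float
    triple: tuple[tuple[float, float], ...]
    converged: bool

    def residual(self) -> float:
        """Value of the three-point identity minus the time ratio at ``beta``."""
        (t0, v0), (t1, v1), (t2, v2) = self.triple
        tau = (t1 - t0) / (t2 - t0)
        return _identity_lhs(self.beta, v1 / v0, v2 / v0) - tau


@dataclass(frozen=True)
class SamplingScheme:
    """Random observation-time generator mimicking clinical follow-up.

    ``windowed`` draws t0 uniformly in ``t0_range`` (days) and each
    subsequent scan a uniform ``gap_range`` later, the cadence of routine
    post-treatment MRI surveillance from six months onward.  ``slotted``
    splits ``window`` into three equal slots and draws one uniform time in
    each, mimicking three-monthly imaging over a fixed horizon.
    """

    mode: Literal["windowed", "slotted"] = "windowed"
    n_repeats: int = 20
    window: tuple[float, float] = (0.0, 270.0)
    t0_range: tuple[float, float] = (180.0, 195.0)
    gap_range: tuple[float, float] = (80.0, 100.0)

    def __post_init__(self) -> None:
        if self.mode not in ("windowed", "slotted"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass(frozen=True)
class MedianBetaResult:
    """Median-of-repeats growth exponent for one simulated lesion."""

    beta_hat: float
    n_converged: int
    n_repeats: int
    reliable: bool
    estimates: tuple[BetaEstimate, ...] = field(repr=False, default=())


def _identity_lhs(beta: float, r1: float, r2: float) -> float:
    """LHS of the three-point identity, continuous through beta = 1.

    Written with ``expm1`` so the removable 0/0 singularity at beta = 1
    evaluates to its limit ln(r1)/ln(r2) to machine precision.
    """
    c = 1.0 - beta
    l1, l2 = np.log(r1), np.log(r2)
    if abs(c) < 1e-12 or abs(c * l2) < 1e-300:
        return l1 / l2
    return np.expm1(c * l1) / np.expm1(c * l2)


def solve_beta(triple: Sequence[tuple[float, float]]) -> BetaEstimate:
    """Invert three (time, volume) observations to (alpha, beta).

    Parameters
    ----------
    triple
        Three ``(t, V)`` pairs with strictly increasing times and positive
        volumes.

    Returns
    -------
    BetaEstimate
        ``converged`` is False when no root is bracketed (e.g. strongly
        non-monotone volumes); ``beta``/``alpha`` are NaN in that case.

    Notes
    -----
    Exactly exponential triples (the removable beta = 1 singularity of the
    identity) are detected first via |ln r1 / ln r2 - tau| < 1e-10 and
    returned as beta = 1 with alpha the exponential rate.
    """
    if len(triple) != 3:
        raise ValueError("exactly three (time, volume) points are required")
    (t0, v0), (t1, v1), (t2, v2) = [(float(t), float(v)) for t, v in triple]
    if not (t0 < t1 < t2):
        raise ValueError("observation times must be strictly increasing")
    if min(v0, v1, v2) <= 0:
        raise ValueError("volumes must be positive")
    if v0 == v1 == v2:
        raise ValueError("degenerate triple: all volumes equal")

    tau = (t1 - t0) / (t2 - t0)
    r1, r2 = v1 / v0, v2 / v0
    frozen = tuple(((t0, v0), (t1, v1), (t2, v2)))

    if r2 == 1.0:  # V2 back at V0: identity undefined, cannot bracket
        return BetaEstimate(np.nan, np.nan, frozen, False)

    # exponential special case: V grows (or shrinks) as a pure exponential
    if r1 > 0 and abs(np.log(r1) / np.log(r2) - tau) < _EXP_TOL:
        alpha = np.log(r1) / (t1 - t0)
        return BetaEstimate(1.0, alpha, frozen, True)

    def g(beta: float) -> float:
        return _identity_lhs(beta, r1, r2) - tau

    lo, hi = _BRACKET
    for _ in range(_MAX_EXPANSIONS + 1):
        try:
            glo, ghi = g(lo), g(hi)
        except (OverflowError, FloatingPointError):
            break
        if np.isfinite(glo) and np.isfinite(ghi) and glo * ghi <= 0:
            beta = brentq(g, lo, hi, xtol=1e-12, rtol=8.9e-16)
            alpha = _alpha_from_beta(beta, t0, v0, t1, v1)
            return BetaEstimate(float(beta), float(alpha), frozen, True)
        lo, hi = 2.0 * lo, 2.0 * hi
    return BetaEstimate(np.nan, np.nan, frozen, False)


def _alpha_from_beta(beta: float, t0: float, v0: float, t1: float, v1: float) -> float:
    """Growth coefficient alpha from the integrated law between two points."""
    if abs(1.0 - beta) < 1e-12:
        return np.log(v1 / v0) / (t1 - t0)
    c = 1.0 - beta
    return (v1**c - v0**c) / (c * (t1 - t0))


def sample_observation_times(
    scheme: SamplingScheme, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``scheme.n_repeats`` strictly increasing observation triples.

    Returns an array of shape ``(n_repeats, 3)`` in days.
    """
    n = scheme.n_repeats
    if scheme.mode == "windowed":
        t0 = rng.uniform(*scheme.t0_range, size=n)
        t1 = t0 + rng.uniform(*scheme.gap_range, size=n)
        t2 = t1 + rng.uniform(*scheme.gap_range, size=n)
        return np.column_stack([t0, t1, t2])
    lo, hi = scheme.window
    edges = np.linspace(lo, hi, 4)
    cols = [rng.uniform(edges[j], edges[j + 1], size=n) for j in range(3)]
    return np.column_stack(cols)


def median_beta(
    times: np.ndarray,
    volumes: np.ndarray,
    scheme: SamplingScheme,
    rng: np.random.Generator,
) -> MedianBetaResult:
    """Median growth exponent of a densely sampled volume curve.

    Draws ``scheme.n_repeats`` observation triples, reads volumes off the
    curve by linear interpolation in time, inverts each triple and returns
    the median of the converged estimates.  ``reliable`` is False when more
    than half the repeats fail to converge.
    """
    times = np.asarray(times, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if times.ndim != 1 or times.shape != volumes.shape:
        raise ValueError("times and volumes must be 1-D arrays of equal length")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    triples = sample_observation_times(scheme, rng)
    if triples[:, 0].min() < times[0] or triples[:, 2].max() > times[-1]:
        raise ValueError("trajectory does not cover the sampling window")

    estimates = []
    for t0, t1, t2 in triples:
        v = np.interp([t0, t1, t2], times, volumes)
        if np.any(v <= 0) or v[0] == v[1] == v[2]:
            estimates.append(
                BetaEstimate(np.nan, np.nan,
                             tuple(zip((t0, t1, t2), v)), False)
            )
            continue
        estimates.append(solve_beta(list(zip((t0, t1, t2), v))))

    betas = [e.beta for e in estimates if e.converged]
    n_conv = len(betas)
    beta_hat = float(np.median(betas)) if n_conv else np.nan
    return MedianBetaResult(
        beta_hat=beta_hat,
        n_converged=n_conv,
        n_repeats=scheme.n_repeats,
        reliable=n_conv * 2 > scheme.n_repeats,
        estimates=tuple(estimates),
    )
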
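"""Virtual-cohort generation and calibration for the voxel simulator.

Two cohorts of simulated brain metastases mirror the study design used to
test the growth exponent as a classifier:

* a **no-damage** cohort (``Sn = 1``): radiosurgery spares the surrounding
  brain, so any regrowth is tumor relapse (group R);
* a **damage** cohort (``0.1 <= Sn <= 0.7``): healthy tissue in the margin
  is lethally damaged, producing late inflammation.  Simulations with at
  most 10% maximal tumor survival (``Sf_hat <= 0.1``) regrow through
  inflammation alone (group I, the radiation-necrosis analogue); the rest
  combine relapse and inflammation (group R&I).

Each simulation draws its basal characteristic times uniformly from the
calibrated ranges, grows a lesion from 1000 cells to a diagnostic volume
(0.5-2 cm^3), applies radiosurgery, and follows the lesion for 420 days.
Mirroring the clinical inclusion criterion of an initial response,
simulations whose volume grows over the first four months after treatment
are rejected.  Included lesions get a growth exponent beta-hat: the median
over 20 random clinical-cadence observation triples.

``abc_calibrate`` implements the rejection flavour of approximate Bayesian
computation used to pin the basal rates: sample from the priors, simulate
the pre-treatment growth, and accept draws whose summary statistics
(time to diagnostic volume, early volume-doubling time) look like real
brain metastases, iterating with priors shrunk to the accepted hull until
the accepted fraction stabilises.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .beta import SamplingScheme, median_beta
from .dsbms import (
    BASAL_RATE_RANGES,
    DsbmsConfig,
    GrowthError,
    apply_srs,
    grow_to_diagnosis,
    simulate_post_srs,
)

__all__ = [
    "CohortSpec",
    "AbcConfig",
    "AbcResult",
    "build_cohort",
    "abc_calibrate",
    "simulate_lesion",
]

logger = logging.getLogger(__name__)

#: lower end of the log-uniform Sf_hat range for inflammation-targeted draws
_SF_LOG_FLOOR = 1e-3

PARAM_COLUMNS = [
    "tau_tp", "tau_td", "tau_tm", "tau_im", "tau_id", "tau_ia", "tau_ne",
]


@dataclass(frozen=True)
class CohortSpec:
    """Sampling rules of one cohort.

    ``group`` is ``"no_damage"`` (Sn = 1, Sf_hat uniform in (0, 1)) or
    ``"damage"`` (Sn uniform in [0.1, 0.7]; Sf_hat drawn log-uniformly in
    (1e-3, 0.1] for half the draws and uniformly in (0.1, 1) for the other
    half, so both the I and R&I sub-groups are populated).
    """

    group: str = "no_damage"
    target_volume_range: tuple[float, float] = (0.5, 2.0)
    horizon_days: float = 420.0
    rejection_window: tuple[float, float] = (14.0, 120.0)
    eps_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.group not in ("no_damage", "damage"):
            raise ValueError("group must be 'no_damage' or 'damage'")


def _sample_config(
    base: DsbmsConfig, spec: CohortSpec, rng: np.random.Generator, index: int
) -> DsbmsConfig:
    taus = {k: rng.uniform(*v) for k, v in BASAL_RATE_RANGES.items()}
    eps = rng.uniform(*spec.eps_range)
    if spec.group == "no_damage":
        Sn = 1.0
        Sf_hat = rng.uniform(0.0, 1.0)
    else:
        Sn = rng.uniform(0.1, 0.7)
        if index % 2 == 0:  # inflammation-targeted half
            Sf_hat = 10.0 ** rng.uniform(math.log10(_SF_LOG_FLOOR), -1.0)
        else:
            Sf_hat = rng.uniform(0.1, 1.0)
    return replace(base, Sn=Sn, Sf_hat=Sf_hat, eps=eps, **taus)


def simulate_lesion(
    config: DsbmsConfig,
    target_volume: float,
    rng: np.random.Generator,
    horizon_days: float = 420.0,
    rejection_window: tuple[float, float] | None = (14.0, 120.0),
    scheme: SamplingScheme | None = None,
    detection_floor_mm3: float = 50.0,
    max_growth_days: float = 2000.0,
):
    """Full life cycle of one virtual lesion: grow, irradiate, follow up.

    Returns ``(beta_result, trace, reject_reason)``; ``reject_reason`` is
    None for an included simulation.  When a rejection window ``(a, b)`` is
    given, the follow-up stops at day ``b`` if the volume then exceeds the
    volume at day ``a`` (no initial response: early regrowth).
    """
    scheme = scheme or SamplingScheme(mode="windowed", n_repeats=20)
    try:
        grid, _ = grow_to_diagnosis(
            config, target_volume, rng, max_days=max_growth_days
        )
    except GrowthError as exc:
        return None, None, f"growth_failure: {exc}"
    apply_srs(grid, config, rng)
    if rejection_window is not None and horizon_days > rejection_window[1]:
        a, b = rejection_window
        trace = simulate_post_srs(grid, config, b, rng)
        if trace.volume_at(b) > trace.volume_at(a):
            return None, trace, "early_growth"
        rest = simulate_post_srs(
            grid, config, horizon_days - b, rng, start_day=b
        )
        trace = _concat_traces(trace, rest)
    else:
        trace = simulate_post_srs(grid, config, horizon_days, rng)
    if np.all(trace.volume_mm3 <= 0):
        return None, trace, "no_measurable_lesion"
    # contrast-MRI cannot segment lesions below ~0.05 cm^3; measured
    # volumes are floored at the detection limit before fitting
    vol = np.maximum(trace.volume_mm3, detection_floor_mm3)
    result = median_beta(trace.days, vol, scheme, rng)
    # resolved lesions that re-expand late produce flat observation triples
    # the three-point identity cannot fit; the median is taken over the
    # converged repeats, and a lesion is dropped only when none converge
    if result.n_converged == 0:
        return result, trace, "beta_unsolvable"
    return result, trace, None


def _concat_traces(first, second):
    from .dsbms import LesionVolumeTrace

    return LesionVolumeTrace(
        days=np.concatenate([first.days, second.days[1:]]),
        volume_mm3=np.concatenate([first.volume_mm3, second.volume_mm3[1:]]),
        populations={
            k: np.concatenate([first.populations[k], second.populations[k][1:]])
            for k in first.populations
        },
        srs_day=0.0,
    )


def build_cohort(
    spec: CohortSpec,
    n_sims: int,
    seed: int,
    base_config: DsbmsConfig | None = None,
    scheme: SamplingScheme | None = None,
    max_attempts: int | None = None,
) -> pd.DataFrame:
    """Generate a cohort of ``n_sims`` included simulations.

    Rejection-sampled: attempts continue (up to ``max_attempts``, default
    ``6 * n_sims``) until ``n_sims`` simulations pass the inclusion rules.
    Every attempt is recorded — rejected ones carry ``included = False`` and
    a ``reject_reason``.  A cohort that falls short of ``n_sims`` is
    returned as-is with a warning, never padded.

    The returned frame has one row per attempt with the sampled parameters,
    the group label, ``beta_hat`` (included rows only) and inclusion status.
    """
    base = base_config or DsbmsConfig()
    max_attempts = max_attempts or 6 * n_sims
    ss = np.random.SeedSequence(seed)
    rows = []
    n_included = 0
    attempt = 0
    sampler = np.random.default_rng(ss.spawn(1)[0])
    while n_included < n_sims and attempt < max_attempts:
        rng = np.random.default_rng(ss.spawn(1)[0])
        config = _sample_config(base, spec, sampler, attempt)
        target = sampler.uniform(*spec.target_volume_range)
        result, _, reason = simulate_lesion(
            config,
            target,
            rng,
            horizon_days=spec.horizon_days,
            rejection_window=spec.rejection_window,
            scheme=scheme,
        )
        included = reason is None
        if included:
            n_included += 1
        label = (
            "R" if config.Sn == 1.0
            else ("I" if config.Sf_hat <= 0.1 else "R&I")
        )
        rows.append(
            {
                "sim_id": f"{spec.group}-{attempt:04d}",
                "group": label,
                "Sn": config.Sn,
                "Sf_hat": config.Sf_hat,
                "eps": config.eps,
                **{k: getattr(config, k) for k in PARAM_COLUMNS},
                "target_volume_cm3": target,
                "beta_hat": result.beta_hat if included else np.nan,
                "n_converged": result.n_converged if result else 0,
                "included": included,
                "reject_reason": reason or "",
            }
        )
        attempt += 1
    if n_included < n_sims:
        logger.warning(
            "cohort %s: only %d of %d requested simulations included after "
            "%d attempts", spec.group, n_included, n_sims, attempt,
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ABC rejection calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AbcConfig:
    """Priors, summary-statistic windows and stopping rule for ABC rejection.

    ``time_to_diagnosis_days`` and ``doubling_time_days`` are the acceptance
    windows on the two summaries; ``None`` disables a window (infinite
    tolerance).  Iteration stops when the accepted fraction changes by less
    than ``stability_tol`` (relative) between iterations.
    """

    priors: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(BASAL_RATE_RANGES)
    )
    n_per_iter: int = 30
    time_to_diagnosis_days: tuple[float, float] | None = (60.0, 700.0)
    doubling_time_days: tuple[float, float] | None = (8.0, 150.0)
    stability_tol: float = 0.05
    max_iters: int = 5
    target_volume_cm3: float = 0.5
    max_days: float = 900.0


@dataclass(frozen=True)
class AbcResult:
    """Accepted draws of the final iteration plus convergence diagnostics."""

    posterior: pd.DataFrame
    accepted_fractions: list[float]
    n_iterations: int
    converged: bool


def _growth_summaries(
    config: DsbmsConfig, target_cm3: float, max_days: float,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """(time to diagnostic volume, early volume-doubling time), in days."""
    try:
        _, trace = grow_to_diagnosis(
            config, target_cm3, rng, max_days=max_days
        )
    except GrowthError:
        return np.inf, np.inf
    t_diag = float(trace.days[-1])
    n_tum = trace.populations["n_tumor"].astype(float)
    window = (n_tum >= 1e4) & (n_tum <= 1e6)
    if window.sum() >= 2:
        t = trace.days[window]
        slope = np.polyfit(t, np.log(n_tum[window]), 1)[0]
        dbl = np.log(2.0) / slope if slope > 0 else np.inf
    else:
        dbl = np.inf
    return t_diag, dbl


def abc_calibrate(
    abc: AbcConfig,
    rng: np.random.Generator,
    base_config: DsbmsConfig | None = None,
) -> AbcResult:
    """Rejection-ABC calibration of the basal characteristic times.

    Each iteration samples ``n_per_iter`` parameter sets from the current
    priors, simulates pre-treatment growth, and accepts draws whose time to
    diagnosis and early doubling time fall inside the configured windows.
    Priors shrink to the hull of the accepted draws between iterations.
    Raises ``RuntimeError`` if no draw is ever accepted.
    """
    base = base_config or DsbmsConfig()
    priors = {k: tuple(v) for k, v in abc.priors.items()}
    for k in priors:
        lo, hi = BASAL_RATE_RANGES.get(k, priors[k])
        if priors[k][0] < lo or priors[k][1] > hi:
            raise ValueError(f"prior for {k} outside the allowed range")

    fractions: list[float] = []
    accepted_df = pd.DataFrame()
    converged = False
    for it in range(abc.max_iters):
        draws = {
            k: rng.uniform(lo, hi, size=abc.n_per_iter)
            for k, (lo, hi) in priors.items()
        }
        accepted = []
        for j in range(abc.n_per_iter):
            params = {k: draws[k][j] for k in draws}
            config = replace(base, **params)
            t_diag, dbl = _growth_summaries(
                config, abc.target_volume_cm3, abc.max_days, rng
            )
            ok = True
            if abc.time_to_diagnosis_days is not None:
                lo, hi = abc.time_to_diagnosis_days
                ok &= lo <= t_diag <= hi
            if abc.doubling_time_days is not None:
                lo, hi = abc.doubling_time_days
                ok &= lo <= dbl <= hi
            if ok:
                accepted.append(
                    {**params, "time_to_diagnosis": t_diag, "doubling_time": dbl}
                )
        frac = len(accepted) / abc.n_per_iter
        fractions.append(frac)
        if accepted:
            accepted_df = pd.DataFrame(accepted)
            for k in priors:
                priors[k] = (accepted_df[k].min(), accepted_df[k].max())
        if (
            len(fractions) >= 2
            and fractions[-2] > 0
            and abs(fractions[-1] - fractions[-2]) / fractions[-2]
            < abc.stability_tol
        ):
            converged = True
            break
    if accepted_df.empty:
        raise RuntimeError(
            f"ABC calibration failed: no acceptances in {abc.max_iters} "
            f"iterations (fractions {fractions})"
        )
    return AbcResult(
        posterior=accepted_df,
        accepted_fractions=fractions,
        n_iterations=len(fractions),
        converged=converged,
    )
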
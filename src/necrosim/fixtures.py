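"""Seeded synthetic fixtures for testing the estimators offline.

Three kinds of small inputs, all generated programmatically:

* ``volumes`` — lesion volume series following closed-form growth laws
  (power law / exponential solutions of dV/dt = alpha V^beta) with known
  exponents, for round-trip tests of the beta solver;
* ``compartmental`` — noisy volume series simulated from known ODE
  parameters, for parameter-recovery tests of the lesion fitter;
* ``dsbms`` — a small pre-grown voxel lesion snapshot for fast
  post-treatment tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import compartmental as comp
from .compartmental import (
    CompartmentParams,
    ConversionConstants,
    VolumeSeries,
    simulate,
)
from .dsbms import DsbmsConfig, VoxelGrid, desk_config, grow_to_diagnosis
from .io import write_volume_series

__all__ = [
    "closed_form_volumes",
    "make_volume_fixtures",
    "make_compartmental_fixtures",
    "make_dsbms_fixture",
    "generate_fixtures",
]


def closed_form_volumes(
    beta: float, alpha: float, V0: float, times: np.ndarray
) -> np.ndarray:
    """Exact solution of dV/dt = alpha V^beta from V(0) = V0.

    Exponential for beta = 1; otherwise
    ``V(t) = (V0^(1-beta) + (1-beta) alpha t)^(1/(1-beta))``.
    """
    times = np.asarray(times, dtype=float)
    if abs(beta - 1.0) < 1e-12:
        return V0 * np.exp(alpha * times)
    c = 1.0 - beta
    base = V0**c + c * alpha * times
    if np.any(base <= 0):
        raise ValueError("solution leaves the positive domain on this grid")
    return base ** (1.0 / c)


#: (label, beta, alpha, V0) of the bundled closed-form growth laws
VOLUME_FIXTURE_SPECS: tuple[tuple[str, float, float, float], ...] = (
    ("linear", 0.0, 0.01, 1.0),
    ("surface", 2.0 / 3.0, 0.02, 1.0),
    ("sqrt", 0.5, 0.02, 1.0),
    ("exponential", 1.0, 0.01, 1.0),
    ("super32", 1.5, 0.005, 1.0),
    ("quadratic", 2.0, 0.002, 1.0),
)


def make_volume_fixtures(
    seed: int, n_random: int = 4, horizon: float = 270.0
) -> tuple[list[VolumeSeries], dict[str, float]]:
    """Volume series with known growth exponents.

    The fixed specs cover the analytically interesting exponents; a few
    extra series draw beta uniformly from (0, 1.8).  Returns the series and
    a ``lesion_id -> true beta`` map.
    """
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, horizon, 28)
    series, truth = [], {}
    for label, beta, alpha, v0 in VOLUME_FIXTURE_SPECS:
        series.append(
            VolumeSeries(label, times, closed_form_volumes(beta, alpha, v0, times))
        )
        truth[label] = beta
    for i in range(n_random):
        beta = rng.uniform(0.0, 1.8)
        if beta > 1.05:
            # keep the finite-time blow-up of superlinear laws outside the
            # observation window: (beta-1) * alpha * horizon < 0.8
            alpha = rng.uniform(0.1, 0.8) * 0.8 / ((beta - 1.0) * horizon)
        else:
            alpha = rng.uniform(0.002, 0.02)
        label = f"random-{i}"
        series.append(
            VolumeSeries(label, times, closed_form_volumes(beta, alpha, 1.0, times))
        )
        truth[label] = beta
    return series, truth


@dataclass(frozen=True)
class CompartmentalFixture:
    series: VolumeSeries
    params: CompartmentParams
    noise_level: float


def make_compartmental_fixtures(
    seed: int,
    n_lesions: int = 3,
    noise_level: float = 0.01,
    n_points: int = 8,
    horizon: float = 270.0,
) -> list[CompartmentalFixture]:
    """Noisy volume series from known ODE parameters for recovery tests."""
    rng = np.random.default_rng(seed)
    conv = ConversionConstants()
    out = []
    for i in range(n_lesions):
        V0 = rng.uniform(0.5, 2.5)
        params = CompartmentParams(
            rho=rng.uniform(*comp.RHO_RANGE),
            lambda_N=rng.uniform(*comp.FITTED_PARAM_RANGES["lambda_N"]),
            gamma=rng.uniform(*comp.FITTED_PARAM_RANGES["gamma"]),
            theta=rng.uniform(*comp.FITTED_PARAM_RANGES["theta"]),
            k=comp.k_from_initial_volume(V0, conv),
            T0=conv.cells_from_cm3(V0),
        )
        traj = simulate(params, horizon, conv)
        times = np.linspace(0.0, horizon, n_points)
        vols = traj.volume_at(times) * (
            1.0 + noise_level * rng.standard_normal(n_points)
        )
        out.append(
            CompartmentalFixture(
                series=VolumeSeries(f"synthetic-{i}", times, np.abs(vols)),
                params=params,
                noise_level=noise_level,
            )
        )
    return out


def make_dsbms_fixture(
    seed: int, target_volume: float = 0.1, config: DsbmsConfig | None = None
) -> VoxelGrid:
    """A small pre-grown lesion (default 0.1 cm^3 at reduced K) for fast tests."""
    config = config or desk_config(L=40)
    rng = np.random.default_rng(seed)
    grid, _ = grow_to_diagnosis(config, target_volume, rng)
    return grid


def generate_fixtures(kind: str, seed: int, outdir: str | Path) -> list[Path]:
    """Write fixture files of the requested kind; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind == "volumes":
        series, truth = make_volume_fixtures(seed)
        p = outdir / "volumes.csv"
        write_volume_series(series, p)
        written.append(p)
        import json

        p2 = outdir / "volumes_truth.json"
        p2.write_text(json.dumps(truth, indent=2) + "\n")
        written.append(p2)
    elif kind == "compartmental":
        fixtures = make_compartmental_fixtures(seed)
        p = outdir / "compartmental.csv"
        write_volume_series([f.series for f in fixtures], p)
        written.append(p)
    elif kind == "dsbms":
        grid = make_dsbms_fixture(seed)
        p = outdir / "dsbms_lesion.npz"
        np.savez_compressed(p, **grid.populations(), K=grid.K)
        written.append(p)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written
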
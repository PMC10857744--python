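"""Discrete stochastic brain-metastasis simulator (DSBMS).

A mesoscale model of a brain metastasis and its response to stereotactic
radiosurgery (SRS).  Space is an ``L x L x L`` lattice of 1 mm voxels, each
holding integer counts of six cell populations — tumor ``n_t``, necrotic
``n_n``, healthy ``n_h``, radiation-damaged tumor ``n_d``, immune ``n_i``
and damaged healthy ``n_hd`` — bounded by a per-voxel carrying capacity
``K`` (2e5 cells; immune cells count with weight ``q`` = 3/2 because
activated immune cells are ~50% larger).

At every time step (4 h) each population in each voxel attempts its basic
processes — division, death, migration, damage-driven death, immune
activation, necrotic clearance — and the number of cells succeeding is a
binomial draw with probability equal to the process rate (time step over
the characteristic time tau) modulated by voxel occupancy.  Hyperbolic
tangent terms act as soft occupancy switches: tumor death turns on above
75% occupancy (hypoxia and vascular damage), healthy-cell displacement
above 45%.  Migrating cells redistribute over the 26-voxel Moore
neighbourhood with multinomial weights proportional to 1, 1/2 and 1/3 for
face, edge and vertex neighbours (renormalized at the lattice boundary).

SRS splits tumor cells into an undamaged surviving fraction (voxel-wise
``S_f``, largest in necrotic/hypoxic, radio-resistant voxels), an
immediately dying fraction ``eps`` and a lethally damaged remainder that
dies by mitotic catastrophe over the following weeks.  Healthy cells in a
1 mm margin around the tumor survive with probability ``Sn``; their
lethally damaged complement dies much later, when the slowly renewing
tissue reaches its k-th post-irradiation division (~390 days for k = 2),
seeding the late necrosis/inflammation wave characteristic of radiation
necrosis.

The lesion volume reported to the "MRI" is the number of voxels whose
(immune-weighted) occupancy exceeds 45% of carrying capacity, in mm^3 —
mimicking contrast enhancement where cell density is high.

Implementation notes: all dynamics are vectorized over a compacted index
of *active* voxels — those that can generate an event this step (tumor,
damaged or immune cells present, or healthy cells above the displacement
threshold).  Necrotic-only and background voxels are inert by construction
(necrotic cells are only cleared when immune cells share the voxel), so
skipping them is exact, and the cost per step scales with the number of
occupied voxels rather than the lattice size.  All draws in one step use
start-of-step counts (synchronous update); removals are clamped so counts
never go negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "DsbmsConfig",
    "desk_config",
    "VoxelGrid",
    "EventTotals",
    "LesionVolumeTrace",
    "GrowthError",
    "BASAL_RATE_RANGES",
    "moore_offsets",
    "moore_weights",
    "migrate_multinomial",
    "event_probabilities_pre_srs",
    "event_probabilities_post_srs",
    "step",
    "measure_volume",
    "grow_to_diagnosis",
    "apply_srs",
    "simulate_post_srs",
]

#: Characteristic-time sampling ranges (hours) for per-simulation basal rates.
BASAL_RATE_RANGES: dict[str, tuple[float, float]] = {
    "tau_tp": (450.0, 550.0),   # tumor division
    "tau_td": (1000.0, 1500.0),  # tumor death
    "tau_tm": (1000.0, 2000.0),  # tumor migration
    "tau_im": (150.0, 250.0),   # immune migration
    "tau_id": (1440.0, 1560.0),  # immune death
    "tau_ia": (12.0, 20.0),     # immune activation
    "tau_ne": (72.0, 96.0),     # necrotic clearance
}


class GrowthError(RuntimeError):
    """A lesion failed to reach its diagnostic volume within the allotted time."""


@dataclass(frozen=True)
class DsbmsConfig:
    """All parameters of the voxel simulator.

    Characteristic times tau are in hours; ``dt_hours`` is the step.
    ``Sf_hat`` is the maximum tumor survival fraction per voxel, ``eps`` the
    fraction of lethally damaged tumor cells dying immediately, ``Sn`` the
    healthy-cell survival fraction inside the 1 mm irradiation margin.
    ``sigma_hours`` sets the width of the delayed healthy-death step;
    ``healthy_frac`` is the background brain cell density as a fraction of K
    (below the 45% imaging threshold, so intact brain reads as zero lesion
    volume).  ``tau_hm`` (healthy displacement) defaults to ``tau_tm``.
    """

    L: int = 60
    K: int = 200_000
    dt_hours: float = 4.0
    tau_tp: float = 500.0
    tau_td: float = 1250.0
    tau_tm: float = 1500.0
    tau_hr: float = 4680.0
    tau_hm: float | None = None
    tau_im: float = 200.0
    tau_id: float = 1500.0
    tau_ia: float = 16.0
    tau_ne: float = 84.0
    k_mitosis: int = 2
    q: float = 1.5
    sigma_hours: float = 800.0
    Sf_hat: float = 0.2
    eps: float = 0.5
    Sn: float = 1.0
    healthy_frac: float = 0.35

    def __post_init__(self) -> None:
        taus = [self.tau_tp, self.tau_td, self.tau_tm, self.tau_hr,
                self.tau_im, self.tau_id, self.tau_ia, self.tau_ne,
                self.tau_hm if self.tau_hm is not None else self.tau_tm]
        if any(t <= 0 for t in taus):
            raise ValueError("all characteristic times must be positive")
        if not 0 < self.dt_hours < min(taus):
            raise ValueError("dt_hours must be positive and below every tau")
        for name in ("Sf_hat", "eps", "Sn"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.k_mitosis < 1:
            raise ValueError("k_mitosis must be >= 1")
        if self.q <= 0 or self.sigma_hours <= 0:
            raise ValueError("q and sigma_hours must be positive")
        if not 0.0 <= self.healthy_frac < 0.45:
            raise ValueError(
                "healthy_frac must be below the 0.45 imaging threshold"
            )
        if self.L < 9:
            raise ValueError("grid too small")

    @property
    def tau_hm_eff(self) -> float:
        return self.tau_hm if self.tau_hm is not None else self.tau_tm


def desk_config(**overrides) -> DsbmsConfig:
    """Reduced-resolution configuration for interactive ("desk") runs.

    The carrying capacity is lowered fortyfold (K = 5e3) and the lattice
    trimmed to L = 44.  Every event probability depends on occupancy
    *fractions* only, so the mean-field dynamics, lesion volumes (voxel
    counts) and time scales are unchanged; the differences are ~6x larger
    demographic noise and a much smaller per-step sampling cost.
    """
    defaults: dict = {"K": 5_000, "L": 44}
    defaults.update(overrides)
    return DsbmsConfig(**defaults)


# ---------------------------------------------------------------------------
# Moore neighbourhood
# ---------------------------------------------------------------------------

def _build_moore() -> tuple[np.ndarray, np.ndarray]:
    offs, wts = [], []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                offs.append((dx, dy, dz))
                order = abs(dx) + abs(dy) + abs(dz)
                wts.append({1: 1.0, 2: 0.5, 3: 1.0 / 3.0}[order])
    return np.array(offs, dtype=np.int64), np.array(wts)


_MOORE_OFFSETS, _MOORE_WEIGHTS = _build_moore()
_MOORE_P = _MOORE_WEIGHTS / _MOORE_WEIGHTS.sum()
_MOORE_CUMP = np.cumsum(_MOORE_P)


def moore_offsets() -> np.ndarray:
    """The 26 neighbour offsets, shape (26, 3)."""
    return _MOORE_OFFSETS.copy()


def moore_weights(normalized: bool = True) -> np.ndarray:
    """Migration weights per neighbour: 3/44 face, 3/88 edge, 1/44 vertex."""
    return (_MOORE_P if normalized else _MOORE_WEIGHTS).copy()


def migrate_multinomial(
    n_migrating: int,
    rng: np.random.Generator,
    in_grid: np.ndarray | None = None,
) -> np.ndarray:
    """Distribute migrating cells over the 26 Moore neighbours.

    ``in_grid`` is an optional boolean mask of admissible destinations (for
    lattice-boundary voxels); weights are renormalized over admissible
    neighbours, implementing a no-flux boundary.
    """
    if n_migrating < 0:
        raise ValueError("n_migrating must be non-negative")
    w = _MOORE_WEIGHTS.copy()
    if in_grid is not None:
        w = np.where(np.asarray(in_grid, dtype=bool), w, 0.0)
        if w.sum() == 0:
            raise ValueError("no admissible destination voxel")
    if n_migrating == 0:
        return np.zeros(26, dtype=np.int64)
    return rng.multinomial(n_migrating, w / w.sum())


# ---------------------------------------------------------------------------
# Grid state
# ---------------------------------------------------------------------------

_POPS = ("n_t", "n_n", "n_h", "n_d", "n_i", "n_hd")


@dataclass
class VoxelGrid:
    """Lattice state: six integer cell-count fields plus carrying capacity."""

    n_t: np.ndarray
    n_n: np.ndarray
    n_h: np.ndarray
    n_d: np.ndarray
    n_i: np.ndarray
    n_hd: np.ndarray
    K: int
    _active_mask: np.ndarray | None = field(default=None, repr=False)
    # subset of active voxels with non-idle dynamics, cached between the
    # stride boundaries of the idle-immune coarse-graining
    _core_mask: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def healthy(cls, L: int, K: int, healthy_frac: float = 0.35) -> "VoxelGrid":
        """Uniform healthy brain tissue at ``healthy_frac * K`` cells/voxel."""
        shape = (L, L, L)
        h = np.full(shape, int(round(healthy_frac * K)), dtype=np.int64)
        zeros = [np.zeros(shape, dtype=np.int64) for _ in range(5)]
        return cls(zeros[0], zeros[1], h, zeros[2], zeros[3], zeros[4], K)

    @classmethod
    def from_config(cls, config: DsbmsConfig) -> "VoxelGrid":
        return cls.healthy(config.L, config.K, config.healthy_frac)

    @property
    def L(self) -> int:
        return self.n_t.shape[0]

    def seed_tumor(
        self, n_cells: int = 1000, where: tuple[int, int, int] | None = None
    ) -> None:
        """Place the initial tumor cells (default: grid centre)."""
        if where is None:
            c = self.L // 2
            where = (c, c, c)
        self.n_t[where] += n_cells
        self.refresh_active()

    def populations(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in _POPS}

    def totals(self) -> dict[str, int]:
        return {name: int(getattr(self, name).sum()) for name in _POPS}

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(
            *(getattr(self, name).copy() for name in _POPS),
            K=self.K,
            _active_mask=(
                None if self._active_mask is None else self._active_mask.copy()
            ),
            _core_mask=(
                None if self._core_mask is None else self._core_mask.copy()
            ),
        )

    def validate(self) -> None:
        for name in _POPS:
            arr = getattr(self, name)
            if not np.issubdtype(arr.dtype, np.integer):
                raise ValueError(f"{name} must be an integer array")
            if (arr < 0).any():
                raise ValueError(f"negative counts in {name}")

    # -- active-voxel bookkeeping -------------------------------------------

    def refresh_active(self) -> None:
        """Rebuild the compacted index of voxels that can generate events.

        Active voxels hold tumor, damaged-tumor or immune cells, or healthy
        cells above the 45% displacement threshold.  Voxels containing only
        necrotic or damaged-healthy cells (plus sub-threshold healthy
        tissue) have no event with non-zero probability until immune cells
        migrate in or time-gated death fires — damaged-healthy voxels are
        therefore also kept active in the post-treatment phase via n_hd.
        """
        mask = (
            (self.n_t > 0)
            | (self.n_d > 0)
            | (self.n_i > 0)
            | (self.n_hd > 0)
            | (self.n_h > 0.45 * self.K)
        )
        self._active_mask = mask.reshape(-1)
        self._core_mask = None

    @property
    def active(self) -> np.ndarray:
        if self._active_mask is None:
            self.refresh_active()
        return np.flatnonzero(self._active_mask)

    def _add_active(self, new_idx: np.ndarray) -> None:
        if new_idx.size:
            self._active_mask[new_idx] = True
            if self._core_mask is not None:
                self._core_mask[new_idx] = True


# ---------------------------------------------------------------------------
# Event probabilities (public, array-friendly)
# ---------------------------------------------------------------------------

def _clip01(p: np.ndarray) -> np.ndarray:
    return np.clip(p, 0.0, 1.0)


def event_probabilities_pre_srs(
    n_t: np.ndarray, n_n: np.ndarray, n_h: np.ndarray, config: DsbmsConfig
) -> dict[str, np.ndarray]:
    """Per-voxel probabilities of the basic growth-phase events.

    Occupancy is ``n_t + n_n + n_h``.  Division is space-limited, migration
    crowding-driven, tumor death (hypoxia) switches on above 75% occupancy
    and healthy displacement above 45%; the tanh switches are negative
    below their thresholds and clamp to probability 0.
    """
    occ = (np.asarray(n_t) + np.asarray(n_n) + np.asarray(n_h)) / config.K
    dt = config.dt_hours
    return {
        "P_tp": _clip01(dt / config.tau_tp * (1.0 - occ)),
        "P_tm": _clip01(dt / config.tau_tm * occ),
        "P_td": _clip01(dt / config.tau_td * np.tanh(10.0 * (occ - 0.75))),
        "P_hm": _clip01(dt / config.tau_hm_eff * np.tanh(10.0 * (occ - 0.45))),
    }


def event_probabilities_post_srs(
    n_t: np.ndarray,
    n_n: np.ndarray,
    n_h: np.ndarray,
    n_d: np.ndarray,
    n_i: np.ndarray,
    n_hd: np.ndarray,
    t_since_srs: float,
    config: DsbmsConfig,
) -> dict[str, np.ndarray]:
    """Per-voxel probabilities of the post-treatment events.

    ``t_since_srs`` is in hours.  ``P_ia`` (immune activation) and ``P_ne``
    (necrotic clearance) involve the necrotic/immune ratio and require at
    least one cell of each in the voxel — the caller must respect that
    precondition.
    """
    if t_since_srs < 0:
        raise ValueError("t_since_srs must be non-negative")
    n_n = np.asarray(n_n)
    n_i = np.asarray(n_i)
    if np.any((n_n < 1) | (n_i < 1)):
        raise ValueError(
            "P_ia/P_ne require n_n >= 1 and n_i >= 1 in every evaluated voxel"
        )
    dt = config.dt_hours
    K = config.K
    occ5 = (np.asarray(n_t) + n_n + np.asarray(n_h) + np.asarray(n_d)
            + np.asarray(n_hd)).astype(float)
    occw = occ5 + config.q * n_i
    p_hd = 0.5 * np.tanh(
        (t_since_srs - config.k_mitosis * config.tau_hr)
        / (2.0 * config.sigma_hours)
    ) + 0.5
    return {
        "P_dd": _clip01(
            np.full_like(occw, dt / (config.k_mitosis * config.tau_tp))
        ),
        "P_hd": _clip01(np.full_like(occw, p_hd)),
        "P_ia": _clip01(dt / config.tau_ia * (n_n / n_i) * (1.0 - occw / K)),
        "P_ne": _clip01(dt / config.tau_ne * (n_i / n_n) * (1.0 - occ5 / K)),
        "P_id": _clip01(np.full_like(occw, dt / config.tau_id)),
        "P_im": _clip01(dt / config.tau_im * (occw / K)),
    }


# ---------------------------------------------------------------------------
# Stepping
# ---------------------------------------------------------------------------

@dataclass
class EventTotals:
    """Grid-wide event counts of one step, for the cell-mass ledger.

    The somatic pool ``n_t + n_d + n_n + n_h + n_hd`` changes only through
    ``births - necrotic_cleared``; the immune pool changes only through
    ``immune_activated - immune_deaths``.
    """

    births: int = 0
    tumor_deaths: int = 0
    damaged_deaths: int = 0
    healthy_damaged_deaths: int = 0
    necrotic_cleared: int = 0
    immune_activated: int = 0
    immune_deaths: int = 0


def _scatter_moore(
    flat: np.ndarray,
    src: np.ndarray,
    counts: np.ndarray,
    rng: np.random.Generator,
    L: int,
    full_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Scatter per-voxel migrant counts over Moore neighbours, in place.

    ``src`` are flat grid indices, ``counts`` the migrants per source.
    Boundary sources use per-voxel renormalized weights (no-flux).  When
    ``full_mask`` is given (flat boolean, True where the weighted occupancy
    has reached the carrying capacity), arrivals into full voxels are
    refused and stay in their source voxel.  Returns the flat indices of
    destinations that received at least one cell.
    """

    def _blocked(dest: np.ndarray) -> np.ndarray:
        if full_mask is None:
            return np.zeros(dest.shape, dtype=bool)
        return full_mask[dest]

    m = counts > 0
    if not m.any():
        return np.empty(0, dtype=np.int64)
    src = src[m]
    cnt = counts[m].astype(np.int64)
    syz = L * L
    x = src // syz
    rem = src - x * syz
    y = rem // L
    z = rem - y * L
    inner = (
        (x > 0) & (x < L - 1) & (y > 0) & (y < L - 1) & (z > 0) & (z < L - 1)
    )
    touched = []
    if not inner.all():
        # rare: sources on the lattice boundary get renormalized weights
        for s, c, xs, ys, zs in zip(
            src[~inner], cnt[~inner], x[~inner], y[~inner], z[~inner]
        ):
            nx = xs + _MOORE_OFFSETS[:, 0]
            ny = ys + _MOORE_OFFSETS[:, 1]
            nz = zs + _MOORE_OFFSETS[:, 2]
            ok = (
                (nx >= 0) & (nx < L) & (ny >= 0) & (ny < L)
                & (nz >= 0) & (nz < L)
            )
            dist = migrate_multinomial(int(c), rng, in_grid=ok)
            didx = (nx * syz + ny * L + nz)[ok]
            vals = dist[ok]
            blk = _blocked(didx)
            flat[s] += int(vals[blk].sum())
            np.add.at(flat, didx[~blk], vals[~blk])
            touched.append(didx[~blk][vals[~blk] > 0])
        src, cnt = src[inner], cnt[inner]
    if src.size:
        offs = (
            _MOORE_OFFSETS[:, 0] * syz
            + _MOORE_OFFSETS[:, 1] * L
            + _MOORE_OFFSETS[:, 2]
        )
        # hybrid multinomial: sparse sources (few migrants) draw one
        # categorical direction per cell; dense sources use the batched
        # multinomial.  Both are exact samples of Mult(cnt, P_Moore).
        small = cnt <= 8
        if small.any():
            cells = np.repeat(src[small], cnt[small])
            dirs = np.searchsorted(_MOORE_CUMP, rng.random(cells.size))
            dest = cells + offs[dirs]
            blk = _blocked(dest)
            if blk.any():
                np.add.at(flat, cells[blk], 1)  # refused: stay at source
                dest = dest[~blk]
            if dest.size < 4096:
                np.add.at(flat, dest, 1)
            else:
                flat += np.bincount(dest, minlength=flat.size).astype(np.int64)
            touched.append(dest)
        big = ~small
        if big.any():
            bsrc = src[big]
            dest_counts = rng.multinomial(cnt[big], _MOORE_P)  # (M, 26)
            dest_all = bsrc[:, None] + offs[None, :]
            if full_mask is not None:
                blk = full_mask[dest_all]
                refused = (dest_counts * blk).sum(axis=1)
                flat[bsrc] += refused  # refused arrivals stay at source
                ok = ~blk & (dest_counts > 0)
            else:
                ok = dest_counts > 0
            d = dest_all[ok]
            v = dest_counts[ok]
            if d.size:
                if d.size < 2048:
                    np.add.at(flat, d, v)
                else:
                    add = np.bincount(d, weights=v, minlength=flat.size)
                    flat += add.astype(np.int64)
                touched.append(d)
    return np.concatenate(touched) if touched else np.empty(0, dtype=np.int64)


def step(
    grid: VoxelGrid,
    config: DsbmsConfig,
    rng: np.random.Generator,
    phase: str = "pre",
    t_since_srs: float = 0.0,
    micro_stride: int = 1,
    stride_phase: int = 0,
) -> EventTotals:
    """Advance the grid by one time step in place; returns the event ledger.

    ``phase`` is ``"pre"`` (growth rules only) or ``"post"`` (growth rules
    for undamaged cells plus the damage/immune/necrosis dynamics);
    ``t_since_srs`` is hours since irradiation and gates the delayed death
    of damaged healthy tissue.  All event counts are binomial draws from
    the start-of-step populations (synchronous update); removals are
    clamped so no count goes negative.

    ``micro_stride`` > 1 coarse-grains *micro* voxels — voxels holding
    non-background cells below 2.5% of capacity and no displacement
    dynamics (stray migrating cells, dispersed immune, sub-resolution
    colonies).  They are updated only every ``stride``-th step
    (when ``stride_phase == 0``) with compounded per-event probabilities
    ``1 - (1 - p)^stride``, preserving per-cell event statistics while
    skipping the large diffuse halo on intermediate steps.
    """
    if phase not in ("pre", "post"):
        raise ValueError("phase must be 'pre' or 'post'")
    post = phase == "post"
    dt = config.dt_hours
    K = float(config.K)
    L = grid.L
    totals = EventTotals()

    use_core = (
        micro_stride > 1
        and stride_phase != 0
        and grid._core_mask is not None
    )
    a = np.flatnonzero(grid._core_mask) if use_core else grid.active
    if a.size == 0:
        return totals  # background tissue only: self-balanced
    tf = grid.n_t.reshape(-1)
    nf = grid.n_n.reshape(-1)
    hf = grid.n_h.reshape(-1)
    df = grid.n_d.reshape(-1)
    if_ = grid.n_i.reshape(-1)
    hdf = grid.n_hd.reshape(-1)

    # start-of-step snapshots on the active set
    t_a = tf[a]
    n_a = nf[a]
    h_a = hf[a]
    occ3 = (t_a + n_a + h_a).astype(float)
    if post:
        d_a = df[a]
        i_a = if_[a]
        hd_a = hdf[a]
        occ5 = occ3 + d_a + hd_a
        occw = occ5 + config.q * i_a
    occ_growth = occ3  # growth rules count tumor/necrotic/healthy occupancy

    svec = None  # per-voxel probability-compounding exponent (micro voxels)
    if micro_stride > 1 and not use_core:
        lim = max(64.0, 0.025 * K)  # sparse: below 2.5% of capacity
        if post:
            cells = t_a + n_a + d_a + i_a + hd_a
            # immune-only voxels have just constant-hazard death and slow
            # migration, which compound exactly at any population size
            pure_immune = (
                (i_a > 0) & (t_a == 0) & (n_a == 0) & (d_a == 0) & (hd_a == 0)
            )
            micro = (cells <= lim) | pure_immune
        else:
            micro = (t_a + n_a) <= lim
        micro &= occ_growth <= 0.45 * K
        svec = np.where(micro, micro_stride, 1)
        core = np.zeros(tf.size, dtype=bool)
        core[a[~micro]] = True
        grid._core_mask = core

    def eff(p, sub):
        """Probability compounded over the voxel's update stride."""
        if svec is None:
            return p
        return 1.0 - (1.0 - p) ** svec[sub]

    # ---- draws (all from start-of-step counts) ----------------------------
    ts = np.flatnonzero(t_a)
    births = deaths = migs = None
    if ts.size:
        ntv = t_a[ts]
        ov = occ_growth[ts] / K
        births = rng.binomial(
            ntv, eff(_clip01(dt / config.tau_tp * (1.0 - ov)), ts)
        )
        deaths = rng.binomial(
            ntv, eff(_clip01(dt / config.tau_td * np.tanh(10.0 * (ov - 0.75))), ts)
        )
        migs = rng.binomial(ntv, eff(_clip01(dt / config.tau_tm * ov), ts))
        migs = np.minimum(migs, ntv - deaths)

    hs = np.flatnonzero((occ_growth > 0.45 * K) & (h_a > 0))
    hmig = None
    if hs.size:
        p_hm = _clip01(
            dt / config.tau_hm_eff * np.tanh(10.0 * (occ_growth[hs] / K - 0.45))
        )
        hmig = rng.binomial(h_a[hs], p_hm)  # displacing voxels are never micro

    if post:
        ds = np.flatnonzero(d_a)
        dd = (
            rng.binomial(
                d_a[ds], eff(dt / (config.k_mitosis * config.tau_tp), ds)
            )
            if ds.size else None
        )

        hds = np.flatnonzero(hd_a)
        hdd = None
        if hds.size:
            p_hd = 0.5 * np.tanh(
                (t_since_srs - config.k_mitosis * config.tau_hr)
                / (2.0 * config.sigma_hours)
            ) + 0.5
            hdd = rng.binomial(hd_a[hds], eff(min(max(p_hd, 0.0), 1.0), hds))

        both = np.flatnonzero((n_a >= 1) & (i_a >= 1))
        act = clr = None
        if both.size:
            nnv = n_a[both].astype(float)
            niv = i_a[both].astype(float)
            act = rng.binomial(
                i_a[both],
                eff(_clip01(
                    dt / config.tau_ia * (nnv / niv) * (1.0 - occw[both] / K)
                ), both),
            )
            clr = rng.binomial(
                n_a[both],
                eff(_clip01(
                    dt / config.tau_ne * (niv / nnv) * (1.0 - occ5[both] / K)
                ), both),
            )

        # immune death and migration are the slowest immune processes
        # (tau >= 150 h); with coarse-graining on they are drawn every
        # second step with exactly compounded probabilities
        immune_now = micro_stride <= 1 or stride_phase % 2 == 0
        is_ = (
            np.flatnonzero(i_a) if immune_now else np.empty(0, dtype=np.int64)
        )
        idd = imig = None
        if is_.size:
            nv = i_a[is_]
            p_id = min(dt / config.tau_id, 1.0)
            p_im = _clip01(dt / config.tau_im * (occw[is_] / K))
            if micro_stride > 1:
                f = 2.0 if svec is None else np.maximum(svec[is_], 2)
                p_id = 1.0 - (1.0 - p_id) ** f
                p_im = 1.0 - (1.0 - p_im) ** f
            idd = rng.binomial(nv, p_id)
            imig = rng.binomial(nv, p_im)
            imig = np.minimum(imig, nv - idd)

    # ---- apply ------------------------------------------------------------
    # arrivals into voxels already at weighted capacity are refused; micro
    # voxels are never near capacity, so the active snapshot covers every
    # candidate
    sel = a[(occw if post else occ_growth) >= K]
    if sel.size:
        occ_check = np.zeros(tf.size, dtype=bool)
        occ_check[sel] = True
    else:
        occ_check = None
    new_active = []
    if ts.size:
        tf[a[ts]] += births - deaths - migs
        nf[a[ts]] += deaths
        totals.births = int(births.sum())
        totals.tumor_deaths = int(deaths.sum())
        new_active.append(_scatter_moore(tf, a[ts], migs, rng, L, occ_check))

    if hs.size:
        hf[a[hs]] -= hmig
        new_active.append(_scatter_moore(hf, a[hs], hmig, rng, L, occ_check))

    if post:
        if ds.size:
            df[a[ds]] -= dd
            nf[a[ds]] += dd
            totals.damaged_deaths = int(dd.sum())
        if hds.size:
            hdf[a[hds]] -= hdd
            nf[a[hds]] += hdd
            totals.healthy_damaged_deaths = int(hdd.sum())
        if both.size:
            nf[a[both]] -= clr  # clr <= start n_n, and n_n only gained since
            if_[a[both]] += act
            totals.necrotic_cleared = int(clr.sum())
            totals.immune_activated = int(act.sum())
        if is_.size:
            if_[a[is_]] -= idd + imig
            totals.immune_deaths = int(idd.sum())
            new_active.append(
                _scatter_moore(if_, a[is_], imig, rng, L, occ_check)
            )

    if new_active:
        fresh = np.concatenate(new_active)
        grid._add_active(fresh)
    return totals


def measure_volume(grid: VoxelGrid, config: DsbmsConfig) -> float:
    """Lesion volume in mm^3: voxels whose weighted occupancy exceeds 0.45 K.

    All six populations count, immune cells with weight ``q``; the
    threshold is strict ("more than 45%"), so background tissue at 35%
    reads as zero.
    """
    occw = (
        grid.n_t + grid.n_n + grid.n_h + grid.n_d + grid.n_hd
        + config.q * grid.n_i
    )
    return float(np.count_nonzero(occw > 0.45 * grid.K))


@dataclass
class LesionVolumeTrace:
    """Daily lesion volume plus grid-total populations along a simulation."""

    days: np.ndarray
    volume_mm3: np.ndarray
    populations: dict[str, np.ndarray]
    srs_day: float | None = None

    def volume_at(self, day: np.ndarray | float) -> np.ndarray:
        return np.interp(day, self.days, self.volume_mm3)

    def to_frame(self):
        import pandas as pd

        cols = {"day": self.days, "volume_mm3": self.volume_mm3}
        cols.update(self.populations)
        return pd.DataFrame(cols)


def grow_to_diagnosis(
    config: DsbmsConfig,
    target_volume: float,
    rng: np.random.Generator,
    n_seed_cells: int | None = None,
    max_days: float = 2000.0,
    measure_every: int = 5,
    micro_stride: int = 6,
) -> tuple[VoxelGrid, LesionVolumeTrace]:
    """Grow a metastasis from ``n_seed_cells`` to a diagnostic volume.

    ``target_volume`` is in cm^3 (clinically 0.5-2).  Seeds the grid
    centre, runs the growth-phase dynamics until the measured volume
    reaches the target, and returns the grid plus the volume trace.
    ``n_seed_cells`` defaults to 0.5% of the carrying capacity (1000 cells
    at the reference K of 2e5), so reduced-resolution runs seed the same
    occupancy fraction.  Raises ``GrowthError`` if the target is not
    reached within ``max_days``.
    """
    if target_volume <= 0:
        raise ValueError("target_volume must be positive")
    if n_seed_cells is None:
        n_seed_cells = max(1, int(round(0.005 * config.K)))
    target_mm3 = target_volume * 1000.0
    grid = VoxelGrid.from_config(config)
    grid.seed_tumor(n_seed_cells)
    steps_per_day = 24.0 / config.dt_hours
    max_steps = int(np.ceil(max_days * steps_per_day))

    days, vols, ntums = [0.0], [measure_volume(grid, config)], [int(grid.n_t.sum())]
    for i in range(1, max_steps + 1):
        step(
            grid, config, rng, phase="pre",
            micro_stride=micro_stride, stride_phase=i % micro_stride,
        )
        if i % 64 == 0:
            grid.refresh_active()
        if i % measure_every == 0 or i == max_steps:
            v = measure_volume(grid, config)
            days.append(i / steps_per_day)
            vols.append(v)
            ntums.append(int(grid.n_t.sum()))
            if v >= target_mm3:
                trace = LesionVolumeTrace(
                    days=np.asarray(days),
                    volume_mm3=np.asarray(vols, dtype=float),
                    populations={"n_tumor": np.asarray(ntums)},
                )
                return grid, trace
    raise GrowthError(
        f"lesion did not reach {target_volume} cm^3 within {max_days} days"
    )


def apply_srs(
    grid: VoxelGrid, config: DsbmsConfig, rng: np.random.Generator
) -> EventTotals:
    """Apply a single radiosurgery dose to a grown lesion, in place.

    Voxel-wise tumor survival is
    ``S_f = clip(Sf_hat * tanh(10 (n_n - 0.45 K) / K), 0, 1)`` — largest
    where necrosis marks hypoxic, radio-resistant tissue and zero in
    well-oxygenated voxels.  Non-survivors split ``eps : 1 - eps`` into
    immediate necrosis and the damaged compartment.  The irradiation field
    is the tumor-occupied region dilated by one voxel (the 1 mm clinical
    margin); healthy cells there survive with probability ``Sn``, the
    complement becoming damaged healthy cells.  Immune cells are seeded at
    10% of the (pre-damage) healthy count in the shell surrounding the
    tumor.
    """
    K = float(grid.K)
    tumor_mask = grid.n_t > 0
    field_mask = ndimage.binary_dilation(
        tumor_mask, structure=np.ones((3, 3, 3), dtype=bool)
    )
    shell_mask = field_mask & ~tumor_mask

    # tumor response
    tv = grid.n_t[tumor_mask]
    sf = np.clip(
        config.Sf_hat * np.tanh(10.0 * (grid.n_n[tumor_mask] - 0.45 * K) / K),
        0.0, 1.0,
    )
    survivors = rng.binomial(tv, sf)
    damaged = tv - survivors
    dead_now = rng.binomial(damaged, config.eps)
    grid.n_t[tumor_mask] = survivors
    grid.n_n[tumor_mask] += dead_now
    grid.n_d[tumor_mask] += damaged - dead_now

    # immune seeding from pre-damage healthy counts in the surrounding shell
    seeded = (0.1 * grid.n_h[shell_mask]).astype(np.int64)
    grid.n_i[shell_mask] += seeded

    # healthy-tissue damage inside the irradiation field
    h_field = grid.n_h[field_mask]
    h_surv = rng.binomial(h_field, config.Sn)
    grid.n_h[field_mask] = h_surv
    grid.n_hd[field_mask] += h_field - h_surv

    grid.refresh_active()
    return EventTotals(
        tumor_deaths=int(dead_now.sum()),
        immune_activated=int(seeded.sum()),
    )


def simulate_post_srs(
    grid: VoxelGrid,
    config: DsbmsConfig,
    horizon: float,
    rng: np.random.Generator,
    start_day: float = 0.0,
    micro_stride: int = 6,
) -> LesionVolumeTrace:
    """Run post-treatment dynamics for ``horizon`` days, recording daily.

    ``start_day`` is the time already elapsed since SRS (used when resuming
    a simulation); trace days are absolute days since SRS, starting with
    the current state.  Requires ``apply_srs`` to have been applied.
    ``micro_stride`` coarse-grains sparse stray-cell voxels (see ``step``);
    1 disables it.
    """
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    steps_per_day = 24.0 / config.dt_hours
    if abs(steps_per_day - round(steps_per_day)) > 1e-9:
        raise ValueError("dt_hours must divide 24 for daily recording")
    steps_per_day = int(round(steps_per_day))
    n_days = int(round(horizon))

    pops: dict[str, list[int]] = {
        "n_tumor": [], "n_damaged": [], "n_necrotic": [],
        "n_immune": [], "n_healthy_damaged": [],
    }
    days: list[float] = []
    vols: list[float] = []

    def record(day: float) -> None:
        days.append(day)
        vols.append(measure_volume(grid, config))
        pops["n_tumor"].append(int(grid.n_t.sum()))
        pops["n_damaged"].append(int(grid.n_d.sum()))
        pops["n_necrotic"].append(int(grid.n_n.sum()))
        pops["n_immune"].append(int(grid.n_i.sum()))
        pops["n_healthy_damaged"].append(int(grid.n_hd.sum()))

    record(start_day)
    istep = 0
    record_every = 2  # days; the estimator interpolates linearly anyway
    for d in range(1, n_days + 1):
        for _ in range(steps_per_day):
            t_hours = (start_day * steps_per_day + istep) * config.dt_hours
            istep += 1
            step(
                grid, config, rng, phase="post", t_since_srs=t_hours,
                micro_stride=micro_stride,
                stride_phase=istep % micro_stride,
            )
            if istep % 64 == 0:
                grid.refresh_active()
        if d % record_every == 0 or d == n_days:
            record(start_day + d)

    return LesionVolumeTrace(
        days=np.asarray(days, dtype=float),
        volume_mm3=np.asarray(vols, dtype=float),
        populations={k: np.asarray(v) for k, v in pops.items()},
        srs_day=0.0,
    )
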
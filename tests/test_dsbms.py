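"""Voxel simulator: probabilities, migration, stepping, radiosurgery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from necrosim import dsbms as D
from necrosim.dsbms import (
    DsbmsConfig,
    VoxelGrid,
    apply_srs,
    event_probabilities_post_srs,
    event_probabilities_pre_srs,
    grow_to_diagnosis,
    measure_volume,
    migrate_multinomial,
    moore_weights,
    simulate_post_srs,
    step,
)


class TestMooreNeighbourhood:
    def test_weights_are_normalized_distance_kernel(self):
        w = moore_weights()
        assert w.sum() == pytest.approx(1.0)
        # 6 face, 12 edge, 8 vertex neighbours with 1 : 1/2 : 1/3 weights
        assert np.sum(np.isclose(w, 3 / 44)) == 6
        assert np.sum(np.isclose(w, 3 / 88)) == 12
        assert np.sum(np.isclose(w, 1 / 44)) == 8

    def test_multinomial_conserves_cells(self, rng):
        out = migrate_multinomial(1000, rng)
        assert out.shape == (26,)
        assert out.sum() == 1000
        assert migrate_multinomial(0, rng).sum() == 0

    def test_boundary_renormalization(self, rng):
        in_grid = np.zeros(26, dtype=bool)
        in_grid[:7] = True  # corner-like voxel: 7 admissible neighbours
        out = migrate_multinomial(500, rng, in_grid=in_grid)
        assert out.sum() == 500
        assert np.all(out[7:] == 0)

    def test_no_destination_rejected(self, rng):
        with pytest.raises(ValueError):
            migrate_multinomial(5, rng, in_grid=np.zeros(26, dtype=bool))


class TestEventProbabilities:
    def test_growth_phase_reference_values(self, small_config):
        cfg = DsbmsConfig(L=12, K=200_000, tau_tp=500.0, tau_td=1250.0)
        p = event_probabilities_pre_srs(0, 0, 0, cfg)
        assert p["P_tp"] == pytest.approx(4.0 / 500.0)
        assert p["P_td"] == 0.0 and p["P_tm"] == 0.0 and p["P_hm"] == 0.0
        # death switch: zero at 75% occupancy, tanh(2.5) factor at full
        p75 = event_probabilities_pre_srs(int(0.75 * cfg.K), 0, 0, cfg)
        assert p75["P_td"] == pytest.approx(0.0, abs=1e-12)
        pfull = event_probabilities_pre_srs(cfg.K, 0, 0, cfg)
        assert pfull["P_td"] == pytest.approx(
            4.0 / 1250.0 * np.tanh(2.5)
        )
        assert pfull["P_tp"] == 0.0

    def test_post_phase_reference_values(self, small_config):
        cfg = DsbmsConfig(L=12, K=200_000, tau_tp=500.0, k_mitosis=2)
        p = event_probabilities_post_srs(
            10, 5, 100, 3, 4, 2, t_since_srs=0.0, config=cfg
        )
        assert p["P_dd"] == pytest.approx(4.0 / (2 * 500.0))
        # damaged-healthy death sits at 1/2 exactly at k * tau_hr
        p_mid = event_probabilities_post_srs(
            10, 5, 100, 3, 4, 2,
            t_since_srs=cfg.k_mitosis * cfg.tau_hr, config=cfg,
        )
        assert p_mid["P_hd"] == pytest.approx(0.5)

    def test_activation_clamps_at_one(self, small_config):
        cfg = small_config
        # necrotic >> immune at low occupancy: the ratio term exceeds 1
        p = event_probabilities_post_srs(
            0, 50_000, 1000, 0, 1, 0, t_since_srs=0.0, config=cfg
        )
        assert p["P_ia"] == 1.0

    def test_ratio_preconditions_enforced(self, small_config):
        with pytest.raises(ValueError):
            event_probabilities_post_srs(
                0, 0, 0, 0, 1, 0, t_since_srs=0.0, config=small_config
            )

    @given(
        n_t=st.integers(0, 250_000),
        n_n=st.integers(1, 250_000),
        n_h=st.integers(0, 250_000),
        n_d=st.integers(0, 250_000),
        n_i=st.integers(1, 250_000),
        n_hd=st.integers(0, 250_000),
        t=st.floats(0.0, 20_000.0),
    )
    @settings(max_examples=80, deadline=None)
    def test_all_probabilities_clamped_to_unit_interval(
        self, n_t, n_n, n_h, n_d, n_i, n_hd, t
    ):
        """Even over-capacity voxel states yield probabilities in [0, 1]."""
        cfg = DsbmsConfig(L=12)
        pre = event_probabilities_pre_srs(n_t, n_n, n_h, cfg)
        post = event_probabilities_post_srs(
            n_t, n_n, n_h, n_d, n_i, n_hd, t_since_srs=t, config=cfg
        )
        for name, p in {**pre, **post}.items():
            assert 0.0 <= float(p) <= 1.0, name


def _random_grid(rng, L=10, K=200_000):
    grid = VoxelGrid.healthy(L, K, 0.35)
    n = 30
    idx = tuple(rng.integers(2, L - 2, size=(3, n)))
    grid.n_t[idx] += rng.integers(0, 50_000, n)
    grid.n_n[idx] += rng.integers(1, 30_000, n)
    grid.n_d[idx] += rng.integers(0, 20_000, n)
    grid.n_i[idx] += rng.integers(1, 10_000, n)
    grid.n_hd[idx] += rng.integers(0, 20_000, n)
    grid.refresh_active()
    return grid


class TestStep:
    def test_untouched_background_is_stationary(self, small_config, rng):
        grid = VoxelGrid.from_config(small_config)
        grid.refresh_active()
        before = grid.n_h.copy()
        step(grid, small_config, rng, phase="pre")
        np.testing.assert_array_equal(grid.n_h, before)

    def test_cell_ledger_conservation(self, rng):
        """Somatic mass changes only by births - clearances; immune by
        activation - death."""
        cfg = DsbmsConfig(L=10)
        for trial in range(5):
            grid = _random_grid(rng)
            somatic0 = sum(
                int(getattr(grid, k).sum())
                for k in ("n_t", "n_n", "n_h", "n_d", "n_hd")
            )
            immune0 = int(grid.n_i.sum())
            totals = step(grid, cfg, rng, phase="post", t_since_srs=9360.0)
            grid.validate()
            somatic1 = sum(
                int(getattr(grid, k).sum())
                for k in ("n_t", "n_n", "n_h", "n_d", "n_hd")
            )
            immune1 = int(grid.n_i.sum())
            assert somatic1 - somatic0 == totals.births - totals.necrotic_cleared
            assert immune1 - immune0 == (
                totals.immune_activated - totals.immune_deaths
            )

    def test_bit_reproducibility_under_seed(self):
        cfg = DsbmsConfig(L=10)
        grids = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            grid = _random_grid(np.random.default_rng(1))
            for i in range(20):
                step(grid, cfg, rng, phase="post", t_since_srs=i * 4.0)
            grids.append(grid)
        for name in ("n_t", "n_n", "n_h", "n_d", "n_i", "n_hd"):
            np.testing.assert_array_equal(
                getattr(grids[0], name), getattr(grids[1], name)
            )

    def test_mean_field_agreement_single_voxel(self):
        """E[n_t] over replicates matches the deterministic recursion.

        At low occupancy only division and migration act; migrants leave
        the observed voxel, so E[n] follows n <- n (1 + P_tp - P_tm).
        """
        cfg = DsbmsConfig(L=9, healthy_frac=0.35)
        n0, n_steps, n_rep = 1000, 50, 300
        c = 9 // 2
        finals = np.empty(n_rep)
        rng = np.random.default_rng(2024)
        for r in range(n_rep):
            grid = VoxelGrid.from_config(cfg)
            grid.seed_tumor(n0)
            for _ in range(n_steps):
                step(grid, cfg, rng, phase="pre")
            finals[r] = grid.n_t[c, c, c]
        # deterministic mean-field recursion with the same occupancy
        n = float(n0)
        h = int(round(0.35 * cfg.K))
        for _ in range(n_steps):
            occ = (n + h) / cfg.K
            p_tp = cfg.dt_hours / cfg.tau_tp * (1 - occ)
            p_tm = cfg.dt_hours / cfg.tau_tm * occ
            n *= 1.0 + p_tp - p_tm
        se = finals.std(ddof=1) / np.sqrt(n_rep)
        assert abs(finals.mean() - n) < 3 * se + 1e-9

    def test_migration_conserves_mass_and_stays_in_grid(self, rng):
        cfg = DsbmsConfig(L=9, tau_tm=40.0, dt_hours=4.0)  # fast migration
        grid = VoxelGrid.healthy(9, cfg.K, 0.35)
        grid.n_t[1, 1, 1] = 50_000  # near the boundary on purpose
        grid.refresh_active()
        total0 = grid.n_t.sum()
        for _ in range(30):
            step(grid, cfg, rng, phase="pre")
            grid.refresh_active()
        grid.validate()
        assert grid.n_t.sum() + grid.n_n.sum() >= total0  # births only add


class TestMeasureVolume:
    def test_thresholds(self, small_config):
        grid = VoxelGrid.healthy(12, small_config.K, 0.0)
        assert measure_volume(grid, small_config) == 0.0
        grid.n_t[5, 5, 5] = int(0.46 * small_config.K)
        assert measure_volume(grid, small_config) == 1.0
        grid.n_t[5, 5, 5] = int(0.45 * small_config.K)  # strict threshold
        assert measure_volume(grid, small_config) == 0.0

    def test_immune_weighted_occupancy(self, small_config):
        grid = VoxelGrid.healthy(12, small_config.K, 0.0)
        # 0.31 K immune cells weigh q = 1.5: effective 0.465 K > threshold
        grid.n_i[3, 3, 3] = int(0.31 * small_config.K)
        assert measure_volume(grid, small_config) == 1.0


class TestRadiosurgery:
    def test_sf_zero_leaves_no_viable_tumor(self, tiny_lesion, rng):
        grid, config = tiny_lesion
        grid = grid.copy()
        from dataclasses import replace

        apply_srs(grid, replace(config, Sf_hat=0.0, eps=0.3), rng)
        grid.validate()
        assert grid.n_t.sum() == 0
        assert grid.n_d.sum() > 0  # lethally damaged remainder

    def test_sn_one_spares_healthy(self, tiny_lesion, rng):
        grid, config = tiny_lesion
        grid = grid.copy()
        from dataclasses import replace

        apply_srs(grid, replace(config, Sn=1.0), rng)
        assert grid.n_hd.sum() == 0

    def test_immune_seeded_in_shell(self, tiny_lesion, rng):
        grid, config = tiny_lesion
        work = grid.copy()
        apply_srs(work, config, rng)
        assert work.n_i.sum() > 0
        # immune cells appear only where there was no tumor (the margin)
        assert np.all(work.n_i[grid.n_t > 0] == 0)

    def test_oxygenation_dependence(self, rng):
        """Tumor survives only in necrotic (hypoxic) voxels."""
        cfg = DsbmsConfig(L=12, Sf_hat=1.0, eps=0.0)
        grid = VoxelGrid.healthy(12, cfg.K, 0.0)
        grid.n_t[4, 4, 4] = 10_000  # oxygenated: no necrosis
        grid.n_t[7, 7, 7] = 10_000
        grid.n_n[7, 7, 7] = int(0.9 * cfg.K)  # deeply hypoxic
        grid.refresh_active()
        apply_srs(grid, cfg, rng)
        assert grid.n_t[4, 4, 4] == 0
        assert grid.n_t[7, 7, 7] > 8000  # tanh(4.5) ~ 1: nearly all survive


class TestLifeCycle:
    def test_grow_reaches_target(self, tiny_lesion):
        grid, config = tiny_lesion
        assert measure_volume(grid, config) >= 20.0  # 0.02 cm^3 target

    def test_growth_failure_raises(self, rng):
        cfg = D.desk_config(L=24)
        with pytest.raises(D.GrowthError):
            grow_to_diagnosis(cfg, 0.05, rng, max_days=5.0)

    def test_post_srs_zero_horizon_single_record(self, tiny_lesion, rng):
        grid, config = tiny_lesion
        work = grid.copy()
        apply_srs(work, config, rng)
        trace = simulate_post_srs(work, config, 0.0, rng)
        assert len(trace.days) == 1

    def test_post_srs_trace_schema(self, tiny_lesion, rng):
        grid, config = tiny_lesion
        work = grid.copy()
        apply_srs(work, config, rng)
        trace = simulate_post_srs(work, config, 6.0, rng)
        df = trace.to_frame()
        assert {"day", "volume_mm3", "n_tumor", "n_immune"} <= set(df.columns)
        assert np.all(np.diff(trace.days) > 0)
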
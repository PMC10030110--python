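"""Blind/directed stepping schemes and the foot-placement index."""

import numpy as np
import pytest

import terrarun as tr
from terrarun.footsteps import (
    DirectedWalkConfig,
    PatchStatTable,
    blind_sample,
    compare_schemes,
    directed_walk,
    foot_placement_index,
)
from terrarun.terrain import CellGrid, TerrainField, patch_stats


def checkerboard_field(block=10, ny=400, nx=121, res=0.005, high=0.01):
    iy, ix = np.indices((ny, nx))
    h = ((iy // block + ix // block) % 2) * high
    return TerrainField(h.astype(float), res)


class TestBlindSample:
    def test_constant_field_zero_iqr(self, flat_field):
        s = blind_sample(flat_field, 500, seed=0)
        assert np.all(s.h_iqr == 0.0)

    def test_determinism(self, uneven1_small, uneven1_table):
        a = blind_sample(uneven1_small, 200, seed=9, table=uneven1_table)
        b = blind_sample(uneven1_small, 200, seed=9, table=uneven1_table)
        assert a.equals(b)

    def test_checkerboard_distribution_matches_enumeration(self):
        """Empirical h_IQR distribution of 1e5 uniform patches matches the
        exhaustive enumeration over all patch positions (KS < 0.02)."""
        field = checkerboard_field()
        table = PatchStatTable(field)
        sample = blind_sample(field, 100_000, seed=4, table=table).h_iqr.to_numpy()
        population = table.iqr.ravel()
        values = np.unique(population)
        pop_cdf = np.searchsorted(np.sort(population), values,
                                  side="right") / population.size
        emp_cdf = np.searchsorted(np.sort(sample), values,
                                  side="right") / sample.size
        assert np.abs(pop_cdf - emp_cdf).max() < 0.02

    def test_region_smaller_than_patch_rejected(self):
        tiny = TerrainField(np.zeros((5, 5)), 0.005)
        with pytest.raises(tr.DomainError):
            blind_sample(tiny, 10, seed=0)


class TestDirectedWalk:
    def test_flat_noise_free_walk_is_degenerate(self, flat_field):
        cfg = DirectedWalkConfig(n_steps=60, noise=False, seed=0)
        seq = directed_walk(flat_field, cfg)
        lengths, widths = seq.realized_steps()
        # every step is exactly the open-loop stride: the search grid is
        # uniformly level so the tie-break keeps the target itself
        assert np.allclose(lengths, cfg.step_length, atol=1e-12)
        assert np.std(lengths) == pytest.approx(0.0, abs=1e-12)
        # widths alternate at the configured offset (snapped to the grid)
        assert np.allclose(widths, widths[0], atol=1e-12)
        assert widths[0] == pytest.approx(cfg.step_width,
                                          abs=flat_field.dx)
        assert np.all(seq.h_iqr == 0.0)

    def test_stripe_of_level_ground_always_chosen(self):
        """With a zero-IQR longitudinal stripe reachable at every step,
        every minimisation pick lands on the stripe."""
        rng = np.random.default_rng(0)
        h = rng.normal(0.0, 0.01, (800, 121))
        h[:, 30:91] = 0.0               # level stripe, x in [0.15, 0.45]
        field = TerrainField(h, 0.005)
        cfg = DirectedWalkConfig(n_steps=120, noise=False, seed=1)
        seq = directed_walk(field, cfg)
        assert np.all(seq.chosen_iqr == 0.0)
        assert np.all(np.abs(seq.positions[:, 0] - 0.3) < 0.15)

    def test_choice_matches_exhaustive_candidate_oracle(self, uneven2_small):
        """The walk's pick equals a brute-force patch_stats evaluation of
        all (2n+1)^2 candidates with the lexicographic tie-break."""
        table = PatchStatTable(uneven2_small)
        cfg = DirectedWalkConfig(n_steps=6, noise=False, seed=3)
        seq = directed_walk(uneven2_small, cfg, table=table)
        xmin, ymin, xmax, ymax = table.valid_bounds
        x, y = 0.5 * (xmin + xmax), ymin + 0.05 * (ymax - ymin)
        j = 0
        off_x = np.linspace(-cfg.step_width_sd, cfg.step_width_sd, 21)
        off_y = np.linspace(-cfg.step_length_sd, cfg.step_length_sd, 21)
        for i in range(cfg.n_steps):
            sgn_w = 1.0 if i % 2 == 0 else -1.0
            travel = 1.0 if j % 2 == 0 else -1.0
            xt, yt = x + sgn_w * cfg.step_width, y + travel * cfg.step_length
            if yt > ymax or yt < ymin:
                j ^= 1
                travel = -travel
                x, xt = 0.5 * (xmin + xmax), 0.5 * (xmin + xmax) + sgn_w * cfg.step_width
                yt = y + travel * cfg.step_length
            best = None
            for oy in off_y:
                for ox in off_x:
                    iy, ix = table.indices(xt + ox, yt + oy)
                    cx, cy = table.centers(iy, ix)
                    ps = patch_stats(uneven2_small, (float(cx), float(cy)))
                    d2 = (cx - xt) ** 2 + (cy - yt) ** 2
                    key = (ps.h_iqr, d2, cy, cx)
                    if best is None or key < best[0]:
                        best = (key, (float(cx), float(cy)))
            assert np.allclose(seq.positions[i], best[1], atol=1e-12)
            x, y = seq.positions[i]

    def test_minimisation_never_worse_than_open_loop_target(
            self, uneven1_small, uneven1_table):
        cfg = DirectedWalkConfig(n_steps=400, seed=5)
        seq = directed_walk(uneven1_small, cfg, table=uneven1_table)
        assert np.all(seq.chosen_iqr <= seq.target_iqr + 1e-15)

    def test_noise_is_mean_zero_and_bounded(self):
        rng = np.random.default_rng(0)
        sigma = 0.05
        eta = rng.vonmises(0.0, 1.0, 200_000) * sigma / (2 * np.pi)
        assert np.abs(eta).max() <= sigma / 2 + 1e-12
        assert abs(eta.mean()) < 3 * eta.std() / np.sqrt(eta.size)

    def test_mean_step_statistics_match_configuration(
            self, uneven1_small, uneven1_table):
        cfg = DirectedWalkConfig(n_steps=20_000, seed=6)
        seq = directed_walk(uneven1_small, cfg, table=uneven1_table)
        s = seq.summary()
        assert abs(s["mean_step_length"] - cfg.step_length) \
            < 0.01 * cfg.step_length
        # the rectified width statistic folds the lateral spread around
        # the open-loop offset, so the match is looser than for length
        assert abs(s["mean_step_width"] - cfg.step_width) \
            < 0.05 * cfg.step_width

    def test_directed_dominates_blind(self, uneven1_small, uneven1_table):
        """Monte-Carlo stochastic dominance: the directed scheme lands on
        more level patches than uniform sampling."""
        cfg = DirectedWalkConfig(n_steps=10_000, seed=7)
        seq = directed_walk(uneven1_small, cfg, table=uneven1_table)
        blind = blind_sample(uneven1_small, 10_000, seed=8,
                             table=uneven1_table)
        assert seq.h_iqr.mean() < blind.h_iqr.mean()


class TestFootPlacementIndex:
    def toy_grid(self):
        return CellGrid(origin=(0.0, 0.0), cell_length=0.19, cell_width=0.095,
                        n_rows=3, n_cols=2, foot_length=0.19)

    def place(self, grid, counts):
        pts = []
        for i in range(counts.shape[0]):
            for j in range(counts.shape[1]):
                c = (grid.origin[0] + (j + 0.5) * grid.cell_width,
                     grid.origin[1] + (i + 0.5) * grid.cell_length)
                pts += [c] * counts[i, j]
        return np.array(pts)

    def test_three_row_hand_computed_table(self):
        grid = self.toy_grid()
        counts = np.array([[2, 0], [1, 1], [0, 3]])
        pim = foot_placement_index(grid, self.place(grid, counts),
                                   2 * grid.cell_length)
        # windows: rows {0,1} S=4, rows {1,2} S=5; normalisers 4, 4.5, 5
        expect = np.array([[0.5, 0.0],
                           [1 / 4.5, 1 / 4.5],
                           [0.0, 0.6]])
        assert np.allclose(pim.index, expect)
        assert pim.counts.sum() == counts.sum()

    def test_periodic_stepping_binary_index(self, flat_field):
        grid = tr.build_cell_grid(flat_field, 0.19)
        w = 6
        rows = np.arange(1, grid.n_rows - w, w)
        pts = np.array([[0.28, (r + 0.5) * grid.cell_length] for r in rows])
        pts = np.tile(pts, (15, 1))
        pim = foot_placement_index(grid, pts, w * grid.cell_length)
        vals = pim.index[np.isfinite(pim.index)]
        assert set(np.round(vals, 9)) <= {0.0, 1.0}

    def test_uniform_stepping_reciprocal_of_box(self, flat_field):
        rng = np.random.default_rng(11)
        grid = tr.build_cell_grid(flat_field, 0.19)
        n = 150_000
        pts = np.column_stack([
            rng.uniform(0, flat_field.track_width, n),
            rng.uniform(0, flat_field.track_length, n)])
        sl = 1.12
        pim = foot_placement_index(grid, pts, sl)
        w = pim.window_rows
        expect = 1.0 / (w * grid.n_cols)
        inner = pim.index[w:-w]
        assert np.nanmean(inner) == pytest.approx(expect, rel=0.02)

    def test_counts_partition_footsteps(self, flat_field):
        rng = np.random.default_rng(2)
        grid = tr.build_cell_grid(flat_field, 0.19)
        pts = np.column_stack([rng.uniform(0, 0.5, 1000),
                               rng.uniform(0, 9.0, 1000)])
        pim = foot_placement_index(grid, pts, 1.12)
        assert pim.counts.sum() == 1000

    def test_duplication_invariance(self):
        grid = self.toy_grid()
        counts = np.array([[2, 0], [1, 1], [0, 3]])
        one = foot_placement_index(grid, self.place(grid, counts),
                                   2 * grid.cell_length)
        two = foot_placement_index(grid, self.place(grid, 2 * counts),
                                   2 * grid.cell_length)
        assert np.allclose(one.index, two.index, equal_nan=True)

    def test_step_shorter_than_cell_rejected(self):
        with pytest.raises(tr.ConfigurationError):
            foot_placement_index(self.toy_grid(), np.zeros((1, 2)), 0.05)


class TestCompareSchemes:
    def test_observed_blind_self_comparison(self, uneven1_small,
                                            uneven1_table):
        blind = blind_sample(uneven1_small, 4000, seed=3, table=uneven1_table)
        observed = tr.StepSequence(
            positions=blind[["x", "y"]].to_numpy(),
            directions=np.ones(len(blind), dtype=int),
            h_iqr=blind.h_iqr.to_numpy(),
            h_median=blind.h_median.to_numpy())
        cfg = DirectedWalkConfig(n_steps=4000, seed=4)
        summary, hist = compare_schemes(uneven1_small, observed, cfg,
                                        n_blind=4000, seed=5,
                                        table=uneven1_table)
        a = summary.loc["blind", "mean_h_iqr"]
        b = summary.loc["observed", "mean_h_iqr"]
        assert abs(a - b) < 4 * blind.h_iqr.std() / np.sqrt(len(blind))
        assert summary.loc["directed", "mean_h_iqr"] <= a

    def test_flat_field_degenerate(self, flat_field):
        observed = tr.StepSequence(
            positions=np.array([[0.3, 2.0], [0.3, 3.0]]),
            directions=np.array([1, 1]),
            h_iqr=np.zeros(2), h_median=np.zeros(2))
        cfg = DirectedWalkConfig(n_steps=500, seed=1)
        summary, _ = compare_schemes(flat_field, observed, cfg, n_blind=500,
                                     seed=2)
        assert np.allclose(summary["mean_h_iqr"].to_numpy(), 0.0)
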
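"""Counting-frame geometry, location selection, and unbiased sampling."""

import numpy as np
import pytest
from scipy import stats

from boutonsort.errors import ConfigurationError, DataIntegrityError, GeometryError
from boutonsort.stereology import (
    FrameGeometry,
    GridSpec,
    build_array,
    run_uts,
    select_locations,
    test_inclusion as frame_decision,
)
from boutonsort.synthetic import StackSpec, generate_bouton_population, generate_stack


class TestGridArithmetic:
    def test_published_design_yields_1350_locations(self):
        grid = GridSpec()  # 6 grids of 15 x 15
        assert grid.total_locations == 1350

    def test_small_grid(self):
        assert GridSpec(grids_per_array=1, cells_per_side=2).total_locations == 4

    def test_inter_grid_distance(self):
        grid = GridSpec(grid_z_spacing=33, section_thickness_nm=75.0)
        assert grid.inter_grid_distance_um == pytest.approx(2.475)

    def test_build_array_counts_and_shared_boundaries(self):
        grid = GridSpec(grids_per_array=2, cells_per_side=3, frame_side_um=0.25)
        locs, frames = build_array(grid, (200, 200, 40), voxel_xy_nm=5.0)
        assert len(locs) == 18
        assert [l.location_id for l in locs] == list(range(1, 19))
        # adjacent frames share boundary lines: x0 spacing equals width
        f1, f2 = frames[1], frames[2]
        assert f2.x0 - f1.x0 == f1.width == 50

    def test_stack_too_small_reports_minimum(self):
        grid = GridSpec(grids_per_array=1, cells_per_side=10, frame_side_um=0.25)
        with pytest.raises(GeometryError, match="at least"):
            build_array(grid, (100, 100, 10), voxel_xy_nm=5.0)


class TestSelection:
    def test_half_of_1350_is_675(self):
        grid = GridSpec()
        locs = [
            type("L", (), {"location_id": i})() for i in range(1, grid.total_locations + 1)
        ]
        assert len(select_locations(locs, 0.5, seed=0)) == 675

    def test_full_fraction_selects_all(self):
        locs = [type("L", (), {"location_id": i})() for i in range(1, 11)]
        assert select_locations(locs, 1.0, seed=0) == list(range(1, 11))

    def test_same_seed_same_subset(self):
        locs = [type("L", (), {"location_id": i})() for i in range(1, 101)]
        assert select_locations(locs, 0.3, seed=5) == select_locations(
            locs, 0.3, seed=5
        )

    def test_fraction_out_of_range(self):
        locs = [type("L", (), {"location_id": 1})()]
        with pytest.raises(ConfigurationError):
            select_locations(locs, 0.0, seed=0)


class TestInclusionRule:
    FRAME = FrameGeometry(x0=10, y0=10, width=10, z=0)

    def test_blob_inside_included(self):
        assert frame_decision([(15, 15)], self.FRAME) == "included"

    def test_blob_crossing_left_exclusion_line(self):
        assert frame_decision([(9, 15), (10, 15)], self.FRAME) == "excluded"

    def test_blob_crossing_bottom_exclusion_line(self):
        assert frame_decision([(15, 9), (15, 10)], self.FRAME) == "excluded"

    def test_blob_touching_top_inclusion_edge(self):
        assert frame_decision([(15, 19), (15, 20)], self.FRAME) == "included"

    def test_blob_touching_right_inclusion_edge(self):
        assert frame_decision([(19, 15), (20, 15)], self.FRAME) == "included"

    def test_blob_far_away_outside(self):
        assert frame_decision([(50, 50)], self.FRAME) == "outside"

    def test_empty_footprint_rejected(self):
        with pytest.raises(DataIntegrityError):
            frame_decision(np.empty((0, 2)), self.FRAME)

    def test_exhaustive_tiling_counts_each_blob_once(self):
        """Over a full tiling of the plane by frames, every blob is included
        by exactly one frame (brute-force enumeration)."""
        rng = np.random.default_rng(1)
        w = 10
        for _ in range(200):
            x, y = (int(v) for v in rng.integers(20, 80, 2))
            pts = {(x, y)}
            for _ in range(int(rng.integers(1, 15))):
                x += int(rng.integers(-1, 2))
                y += int(rng.integers(-1, 2))
                pts.add((x, y))
            fp = np.array(sorted(pts))
            hits = sum(
                frame_decision(fp, FrameGeometry(x0=gx, y0=gy, width=w, z=0))
                == "included"
                for gx in range(0, 100, w)
                for gy in range(0, 100, w)
            )
            assert hits == 1


class TestRunUTS:
    def _setup(self, seed, density=25.0, n_pop=2000):
        pop = generate_bouton_population(
            self.dnm_spec, n_pop, seed=seed
        )
        spec = StackSpec(
            shape=(400, 400, 100), synapse_density_per_um3=density, seed=seed
        )
        labels, syn = generate_stack(spec, pop)
        grid = GridSpec(
            grids_per_array=3, cells_per_side=10, frame_side_um=0.2, grid_z_spacing=33
        )
        return pop, labels, syn, grid

    @pytest.fixture(autouse=True)
    def _specs(self, dnm_spec):
        self.dnm_spec = dnm_spec

    def test_empty_stack_all_locations_empty(self, lm_spec):
        pop = generate_bouton_population(lm_spec, 10, seed=0)
        labels = np.zeros((40, 120, 120), dtype=np.uint16)
        import pandas as pd

        grid = GridSpec(grids_per_array=1, cells_per_side=2, frame_side_um=0.25)
        sampled, tally, _ = run_uts(
            labels, pd.DataFrame(columns=["synapse_id", "bouton_id"]), pop, grid,
            fraction=1.0, seed=0,
        )
        assert sampled.empty
        assert tally["empty"] == 4
        assert tally["synapse_sampled"] == 0

    def test_planted_synapse_is_sampled(self, lm_spec):
        pop = generate_bouton_population(lm_spec, 3, seed=0)
        labels = np.zeros((40, 120, 120), dtype=np.uint16)
        labels[0, 20:23, 20:23] = 1  # inside frame (row 0, col 0) well off edges
        import pandas as pd

        syn = pd.DataFrame(
            {"synapse_id": [1], "bouton_id": [pop["bouton_id"].iloc[1]]}
        )
        grid = GridSpec(grids_per_array=1, cells_per_side=2, frame_side_um=0.25)
        sampled, tally, _ = run_uts(labels, syn, pop, grid, fraction=1.0, seed=0)
        assert len(sampled) == 1
        assert sampled["bouton_id"].iloc[0] == pop["bouton_id"].iloc[1]
        assert tally["synapse_sampled"] == 1

    def test_missing_bouton_link_raises(self, lm_spec):
        pop = generate_bouton_population(lm_spec, 3, seed=0)
        labels = np.zeros((40, 120, 120), dtype=np.uint16)
        labels[0, 20:23, 20:23] = 1
        import pandas as pd

        syn = pd.DataFrame({"synapse_id": [2], "bouton_id": [0]})  # id mismatch
        grid = GridSpec(grids_per_array=1, cells_per_side=2, frame_side_um=0.25)
        with pytest.raises(DataIntegrityError):
            run_uts(labels, syn, pop, grid, fraction=1.0, seed=0)

    def test_sampled_volumes_match_population_distribution(self):
        """Unbiasedness: KS test does not distinguish sampled volumes from
        the generating population (p > 0.01) in >= 9/10 fixed seeds."""
        passes = 0
        for seed in range(10):
            pop, labels, syn, grid = self._setup(seed)
            sampled, _, _ = run_uts(labels, syn, pop, grid, fraction=1.0, seed=seed)
            p = stats.ks_2samp(sampled["volume_um3"], pop["volume_um3"]).pvalue
            passes += p > 0.01
        assert passes >= 9

    def test_two_placements_statistically_indistinguishable(self):
        """Two independent grid placements on one stack give samples a
        Mann-Whitney test cannot tell apart in >= 90% of 20 seed pairs."""
        passes = 0
        for seed in range(20):
            pop = generate_bouton_population(self.dnm_spec, 2000, seed=seed)
            spec = StackSpec(
                shape=(400, 400, 120), synapse_density_per_um3=25.0, seed=seed
            )
            labels, syn = generate_stack(spec, pop)
            g1 = GridSpec(
                grids_per_array=2, cells_per_side=10, frame_side_um=0.2,
                grid_z_spacing=33, reference_sections=(0, 33),
            )
            g2 = GridSpec(
                grids_per_array=2, cells_per_side=10, frame_side_um=0.2,
                grid_z_spacing=33, reference_sections=(60, 93),
            )
            s1, _, _ = run_uts(labels, syn, pop, g1, fraction=1.0, seed=seed)
            s2, _, _ = run_uts(labels, syn, pop, g2, fraction=1.0, seed=seed)
            p = stats.mannwhitneyu(
                s1["volume_um3"], s2["volume_um3"], alternative="two-sided"
            ).pvalue
            passes += p > 0.05
        assert passes >= 18

    def test_soma_locations_tallied_not_sampled(self, lm_spec):
        pop = generate_bouton_population(lm_spec, 3, seed=0)
        labels = np.zeros((40, 120, 120), dtype=np.uint16)
        soma = np.zeros_like(labels, dtype=bool)
        soma[0, :60, :60] = True  # covers frame (0, 0) entirely
        import pandas as pd

        grid = GridSpec(grids_per_array=1, cells_per_side=2, frame_side_um=0.25)
        _, tally, _ = run_uts(
            labels, pd.DataFrame(columns=["synapse_id", "bouton_id"]), pop, grid,
            fraction=1.0, seed=0, soma_mask=soma,
        )
        assert tally["soma"] == 1
        assert tally["empty"] == 3
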
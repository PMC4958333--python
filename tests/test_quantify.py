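"""Clone calling and whole-mount quantification statistics."""

import math

import numpy as np
import pandas as pd
import pytest

import dermaclone as dc
from dermaclone.quantify import CloneCaller
from _oracles import max_merge_partition


def _cells(coords, ids=None, layer="papillary"):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return pd.DataFrame(
        {
            "cell_id": ids if ids is not None else np.arange(n),
            "x_um": coords[:, 0],
            "y_um": coords[:, 1],
            "z_um": coords[:, 2] if coords.shape[1] == 3 else 0.0,
            "layer": layer,
        }
    )


def _partition_of(table):
    groups = {}
    for cell_id, call in table.assignments.items():
        groups.setdefault(call, []).append(cell_id)
    return tuple(sorted(tuple(sorted(g)) for g in groups.values()))


class TestCloneCalling:
    def test_single_cell_single_clone(self):
        table = dc.call_clones(_cells([[0, 0]]))
        assert table.n_clones == 1
        assert table.clone_sizes().iloc[0] == 1

    @pytest.mark.parametrize("gap, n_expected", [(100.0, 1), (300.0, 2)])
    def test_two_cells_cutoff_definition(self, gap, n_expected):
        table = dc.call_clones(_cells([[0, 0], [gap, 0]]))
        assert table.n_clones == n_expected

    def test_radius_mode_doubles_effective_cutoff(self):
        cells = _cells([[0, 0], [400, 0]])
        diam = dc.call_clones(cells, dc.CloneCallingParams(cutoff_mode="diameter"))
        rad = dc.call_clones(cells, dc.CloneCallingParams(cutoff_mode="radius"))
        assert diam.n_clones == 2
        assert rad.n_clones == 1

    def test_empty_input_gives_empty_table(self):
        table = dc.call_clones(_cells(np.empty((0, 2))))
        assert table.n_clones == 0

    def test_nan_coordinate_is_a_data_error(self):
        cells = _cells([[0, 0], [np.nan, 0]])
        with pytest.raises(ValueError, match="finite"):
            dc.call_clones(cells)

    def test_matches_exhaustive_max_merge_oracle(self):
        """Identical partition to brute-force maximal merging on 500 random <=8-point sets."""
        rng = np.random.default_rng(42)
        for _ in range(500):
            n = int(rng.integers(1, 9))
            coords = rng.uniform(0, 600, (n, 2))
            caller = CloneCaller().fit(coords)
            got = tuple(
                sorted(
                    tuple(sorted(map(int, np.flatnonzero(caller.labels_ == lab))))
                    for lab in np.unique(caller.labels_)
                )
            )
            assert got == max_merge_partition(coords, 260.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 700, (12, 2))
        cells = _cells(coords)
        base = _partition_of(dc.call_clones(cells))
        for s in range(5):
            shuffled = cells.sample(frac=1.0, random_state=s).reset_index(drop=True)
            assert _partition_of(dc.call_clones(shuffled)) == base

    def test_projection_xy_ignores_depth(self):
        cells = _cells([[0, 0, 0], [50, 0, 1000]])
        assert dc.call_clones(cells, dc.CloneCallingParams(projection="xy")).n_clones == 1
        assert dc.call_clones(cells, dc.CloneCallingParams(projection="xyz")).n_clones == 2

    def test_clone_call_ids_are_smallest_member_cell_id(self):
        cells = _cells([[0, 0], [10, 0], [900, 0]], ids=[5, 9, 2])
        table = dc.call_clones(cells)
        assert set(table.assignments.unique()) == {5, 2}

    def test_within_clone_distances_respect_cutoff(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 1200, (40, 2))
        table = dc.call_clones(_cells(coords))
        for _, grp in table.members.groupby("clone_call"):
            pts = grp[["x_um", "y_um"]].to_numpy()
            if len(pts) > 1:
                d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
                assert d.max() <= 260.0 + 1e-9


class TestCloneSizes:
    def test_single_clone_all_papillary(self):
        cells = _cells([[0, 0]] * 4, ids=range(4), layer="papillary")
        summary = dc.clone_sizes_by_compartment(dc.call_clones(cells))
        assert summary.loc["papillary", "mean_cells_per_clone"] == 4
        assert summary.loc["reticular", "mean_cells_per_clone"] == 0
        assert summary.loc["total", "mean_cells_per_clone"] == 4

    def test_two_clones_mean_and_sd(self):
        coords = [[0, 0]] * 2 + [[5000, 0]] * 6
        cells = _cells(coords, ids=range(8))
        summary = dc.clone_sizes_by_compartment(dc.call_clones(cells))
        assert summary.loc["total", "mean_cells_per_clone"] == pytest.approx(4.0)
        assert summary.loc["total", "sd_cells_per_clone"] == pytest.approx(math.sqrt(8), abs=1e-6)

    def test_unknown_layer_label_is_a_data_error(self):
        cells = _cells([[0, 0]], layer="epidermis")
        with pytest.raises(ValueError, match="unknown layer"):
            dc.clone_sizes_by_compartment(dc.call_clones(cells))

    def test_compartment_means_match_groupby_oracle(self):
        """Simulated neonatal tissue: summary equals a direct pandas tabulation."""
        cfg = dc.preset_e12_to_p2(seed=4)
        snap = dc.run(cfg, [2.0])[0]
        lab = snap.labelled[["cell_id", "x_um", "y_um", "z_um", "layer"]]
        table = dc.call_clones(lab)
        summary = dc.clone_sizes_by_compartment(table)
        merged = lab.merge(table.assignments.rename("call"), left_on="cell_id", right_index=True)
        oracle = (
            merged.pivot_table(index="call", columns="layer", values="cell_id", aggfunc="count")
            .reindex(columns=["papillary", "reticular", "DWAT"], fill_value=0)
            .fillna(0)
        )
        for comp in ["papillary", "reticular", "DWAT"]:
            assert summary.loc[comp, "mean_cells_per_clone"] == pytest.approx(
                oracle[comp].mean()
            )


class TestDensity:
    def test_empty_region_zero_density(self):
        cells = _cells(np.empty((0, 2)))
        out = dc.density_per_layer(cells, [(0, 0, 100, 100)])
        assert out.loc["total", "rho_per_mm2"] == 0.0

    def test_arithmetic_example(self):
        # 50 cells in a 0.025 mm2 region -> 2000 per mm2
        coords = np.column_stack([np.linspace(1, 149, 50), np.full(50, 80.0)])
        cells = _cells(coords)
        out = dc.density_per_layer(cells, [(0, 0, 150.0, 500.0 / 3)])
        assert out.loc["total", "rho_per_mm2"] == pytest.approx(2000.0)

    def test_zero_regions_is_a_data_error(self):
        with pytest.raises(ValueError):
            dc.density_per_layer(_cells([[0, 0]]), [])

    def test_poisson_intensity_recovery_within_3_sigma(self):
        lam = 800.0
        rng = np.random.default_rng(0)
        estimates = []
        for s in range(40):
            n = rng.poisson(lam)  # 1 mm x 1 mm domain
            coords = rng.uniform(0, 1000, (n, 2))
            cells = _cells(coords)
            regions = [
                (i * 250.0, j * 250.0, (i + 1) * 250.0, (j + 1) * 250.0)
                for i in range(4)
                for j in range(4)
            ]
            estimates.append(dc.density_per_layer(cells, regions).loc["total", "rho_per_mm2"])
        se = math.sqrt(lam / 40)  # 40 independent 1 mm2 tilings
        assert abs(np.mean(estimates) - lam) < 3 * se

    def test_total_equals_sum_of_layers(self):
        rng = np.random.default_rng(5)
        frames = []
        for k, layer in enumerate(["papillary", "reticular", "DWAT"]):
            n = 50 + 20 * k
            df = _cells(rng.uniform(0, 500, (n, 2)), ids=range(1000 * k, 1000 * k + n), layer=layer)
            frames.append(df)
        cells = pd.concat(frames, ignore_index=True)
        out = dc.density_per_layer(cells, [(0, 0, 500, 500)])
        layer_sum = out.drop(index="total")["rho_per_mm2"].sum()
        assert out.loc["total", "rho_per_mm2"] == pytest.approx(layer_sum)


class TestFractionsAndIntensities:
    def test_fraction_positive_examples(self):
        cells = pd.DataFrame({"ki67": [False] * 100})
        assert dc.fraction_positive(cells, "ki67") == 0.0
        cells = pd.DataFrame({"ki67": [True] * 17 + [False] * 83})
        assert dc.fraction_positive(cells, "ki67") == pytest.approx(17.0)

    def test_fraction_positive_zero_cells_is_nan(self):
        assert math.isnan(dc.fraction_positive(pd.DataFrame({"ki67": []}), "ki67"))

    def test_fraction_positive_requires_defined_marker(self):
        cells = pd.DataFrame({"ki67": [True, None]})
        with pytest.raises(ValueError, match="undefined"):
            dc.fraction_positive(cells, "ki67")

    def test_fraction_positive_binomial_recovery(self):
        p = 0.17
        rng = np.random.default_rng(1)
        n = 5000
        cells = pd.DataFrame({"topgfp": rng.random(n) < p})
        est = dc.fraction_positive(cells, "topgfp")
        se = 100 * math.sqrt(p * (1 - p) / n)
        assert abs(est - 100 * p) < 3 * se

    def test_percentages_lie_in_unit_interval(self):
        rng = np.random.default_rng(2)
        for s in range(20):
            cells = pd.DataFrame({"m": rng.random(50) < rng.random()})
            assert 0.0 <= dc.fraction_positive(cells, "m") <= 100.0

    def test_normalized_intensity_modes(self):
        assert dc.normalized_mean_intensity([100, 100], [100, 100]) == pytest.approx(1.0)
        assert dc.normalized_mean_intensity([300], [100]) == pytest.approx(3.0)
        assert dc.normalized_mean_intensity([300], [100], mode="subtract") == pytest.approx(200.0)

    def test_normalized_intensity_scale_invariance(self):
        sig = np.array([120.0, 180.0, 90.0])
        bg = np.array([30.0, 50.0])
        base = dc.normalized_mean_intensity(sig, bg)
        assert dc.normalized_mean_intensity(7 * sig, 7 * bg) == pytest.approx(base)

    def test_normalized_intensity_rejects_nonpositive_background(self):
        with pytest.raises(ValueError):
            dc.normalized_mean_intensity([1.0], [0.0, 0.0])


class TestWoundSections:
    def test_constant_counts(self):
        records = pd.DataFrame(
            {"wound_id": [0] * 8, "section_id": range(8), "n_new_hfs": [5] * 8}
        )
        summary = dc.mean_hfs_per_section(records)
        assert summary.group_mean == pytest.approx(5.0)
        assert summary.per_wound.loc[0, "sd_hfs"] == pytest.approx(0.0)

    def test_all_zero_counts(self):
        records = pd.DataFrame(
            {"wound_id": [0] * 8, "section_id": range(8), "n_new_hfs": [0] * 8}
        )
        assert dc.mean_hfs_per_section(records).group_mean == 0.0

    def test_warns_below_protocol_minimum(self):
        records = pd.DataFrame({"wound_id": [0] * 3, "section_id": range(3), "n_new_hfs": [1, 2, 3]})
        with pytest.warns(UserWarning, match="fewer than 8"):
            dc.mean_hfs_per_section(records)

    def test_poisson_mean_recovery(self):
        records, truth = dc.synthetic.gen_wound_sections(
            n_wounds=10, sections_per_wound=8, mean_hfs=5.0, seed=0
        )
        summary = dc.mean_hfs_per_section(records)
        se = math.sqrt(5.0 / 80)
        assert abs(summary.group_mean - truth["mean_hfs"]) < 3 * se


def test_apparent_clone_size_shrinks_with_expansion():
    """Pure expansion: mean cells per called clone is non-increasing in the factor."""
    import dataclasses

    means = []
    for factor in (1.0, 2.0, 4.0):
        per_seed = []
        for s in range(20):
            cfg = dc.SimConfig(
                lx_um=1000.0,
                ly_um=1000.0,
                layer_bounds_um=(("papillary", 0.0, 100.0),),
                start_age_days=0.0,
                end_age_days=4.0,
                initial_density_per_mm2=(("papillary", 400.0),),
                division_rate=0.0,
                death_rate=0.0,
                expansion=dc.ExpansionSchedule.linear(0.0, 4.0, (factor, factor, 1.0)),
                label_age_days=0.0,
                labels_per_region=2.0,
                region_pitch_um=250.0,
                seed=s,
            )
            snap = dc.run(cfg, [4.0])[0]
            lab = snap.labelled[["cell_id", "x_um", "y_um", "layer"]]
            if len(lab) < 2:
                continue
            table = dc.call_clones(lab)
            per_seed.append(len(lab) / table.n_clones)
        means.append(np.mean(per_seed))
    assert means[0] >= means[1] >= means[2]
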
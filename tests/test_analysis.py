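"""Regional analysis: grid geometry, sampling oracle, table arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from condylefe.analysis import (RegionalStressTable, compare_variants,
                                convergence_check, make_sampling_grid,
                                regional_summary, sample_field,
                                sensitivity_compare)
from condylefe.meshing import build_voxel_mesh, label_regions
from condylefe.volume import VoxelVolume


def slab_mesh(n=20, m=9, k=8, spacing=1.0):
    """Rectangular slab with trivial region metadata for grid geometry
    tests: slice plane through the middle."""
    mask = VoxelVolume(np.ones((n, m, k), bool), (spacing,) * 3,
                       np.zeros(3), "mask")
    mesh = build_voxel_mesh(mask, 1)
    label_regions(mesh, None, articular_z_fraction=0.0,
                  x_mid=spacing * n / 2, sr_half_width=spacing * n / 8,
                  psg_outer=spacing * n / 4, ridge_plane_y=spacing * m / 2,
                  slice_offset=0.0)
    return mesh


def table(values: dict, **meta) -> RegionalStressTable:
    df = pd.DataFrame(
        {r: {"average": v, "peak": v, "n": 1} for r, v in values.items()}
    ).T[["average", "peak", "n"]]
    df.index.name = "region"
    return RegionalStressTable(table=df, metadata=meta)


class TestSamplingGrid:
    def test_rectangular_slice_closed_form_spacings(self):
        mesh = slab_mesh()
        grid = make_sampling_grid(mesh, "slice", (8, 20),
                                  slice_name="dorsal")
        pts = grid.points.reshape(8, 20, 3)
        # centroid extents: x in [0.5, 19.5], z in [0.5, 7.5] (w=19, h=7)
        dx = np.diff(pts[0, :, 0])
        dz = np.diff(pts[:, 0, 2])
        assert np.allclose(dx, 19.0 / 19)
        assert np.allclose(dz, 7.0 / 7)
        assert grid.n_projected == 0

    def test_affine_scaling_equivariance(self):
        a = make_sampling_grid(slab_mesh(spacing=1.0), "slice", (8, 20),
                               slice_name="dorsal")
        b = make_sampling_grid(slab_mesh(spacing=2.0), "slice", (8, 20),
                               slice_name="dorsal")
        assert np.allclose(b.points, 2.0 * a.points)

    def test_count_audit_on_phantom_slice(self, healthy_model):
        mesh = healthy_model[0]
        grid = make_sampling_grid(mesh, "slice", slice_name="dorsal")
        assert grid.n_points == 160
        assert all(lab is not None for lab in grid.labels)
        assert grid.n_projected <= 0.15 * 160

    def test_surface_grid_labels_and_count(self, healthy_model):
        mesh = healthy_model[0]
        grid = make_sampling_grid(mesh, "surface")
        assert grid.n_points == 160
        from condylefe.meshing import REGION_LABELS
        assert set(np.unique(grid.labels)) <= set(REGION_LABELS)

    def test_grid_reproducibility(self, healthy_model):
        mesh = healthy_model[0]
        a = make_sampling_grid(mesh, "slice", slice_name="palmar")
        b = make_sampling_grid(mesh, "slice", slice_name="palmar")
        assert np.array_equal(a.points, b.points)
        assert np.array_equal(a.labels, b.labels)

    def test_degenerate_layout_rejected(self, healthy_model):
        with pytest.raises(ValueError):
            make_sampling_grid(healthy_model[0], "slice", (0, 20),
                               slice_name="dorsal")


class TestSampleField:
    def test_constant_field(self):
        mesh = slab_mesh()
        grid = make_sampling_grid(mesh, "slice", slice_name="dorsal")
        vals = sample_field(grid, np.full(mesh.n_elements, 7.25), mesh)
        assert np.all(vals == 7.25)

    def test_linear_in_x_field_matches_point_location_oracle(self):
        mesh = slab_mesh()
        ec = mesh.element_centroids()
        field = 3.0 * ec[:, 0] + 1.0
        grid = make_sampling_grid(mesh, "slice", (8, 20),
                                  slice_name="dorsal")
        vals = sample_field(grid, field, mesh)
        # brute-force point location over all elements
        en = mesh.nodes[mesh.elements]
        lo, hi = en.min(axis=1), en.max(axis=1)
        for p, v in zip(grid.points, vals):
            inside = np.all((lo <= p) & (p < hi), axis=1)
            e = int(np.flatnonzero(inside)[0])
            assert v == field[e]

    def test_sampling_is_deterministic(self):
        mesh = slab_mesh()
        rng = np.random.default_rng(0)
        field = rng.random(mesh.n_elements)
        grid = make_sampling_grid(mesh, "slice", slice_name="dorsal")
        a = sample_field(grid, field, mesh)
        b = sample_field(grid, field, mesh)
        assert np.array_equal(a, b)


class TestRegionalSummary:
    def test_constant_samples(self):
        mesh = slab_mesh()
        grid = make_sampling_grid(mesh, "slice", slice_name="dorsal")
        t = regional_summary(np.full(160, 7.0), grid)
        assert np.all(t.table["average"] == 7.0)
        assert np.all(t.table["peak"] == 7.0)
        assert t.table["n"].sum() == 160

    def test_two_point_region_arithmetic(self):
        mesh = slab_mesh()
        grid = make_sampling_grid(mesh, "slice", slice_name="dorsal")
        samples = np.zeros(160)
        grid.labels = np.where(np.arange(160) < 2, "SR", "other")
        samples[:2] = [5.0, 9.0]
        t = regional_summary(samples, grid)
        assert t.region("SR")["average"] == pytest.approx(7.0)
        assert t.region("SR")["peak"] == pytest.approx(9.0)
        assert t.region("SR")["n"] == 2

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(a=st.lists(st.floats(0, 100), min_size=1, max_size=10),
           b=st.lists(st.floats(0, 100), min_size=1, max_size=10))
    def test_pooled_mean_is_weighted_mean(self, a, b):
        na, nb = len(a), len(b)
        pooled = np.mean(a + b)
        weighted = (na * np.mean(a) + nb * np.mean(b)) / (na + nb)
        assert pooled == pytest.approx(weighted, abs=1e-9)


class TestConvergenceCheck:
    def test_identical_tables_converged(self):
        t = table({"SR": 10.0, "DMC": 12.0})
        rep = convergence_check([t, t, t])
        assert np.all(rep["diff_MPa"] == 0)
        assert rep["converged"].all()

    def test_within_criterion(self):
        rep = convergence_check([table({"SR": 12.85}),
                                 table({"SR": 12.80})])
        row = rep.iloc[0]
        assert row["diff_MPa"] == pytest.approx(0.05)
        assert row["rel_diff"] == pytest.approx(0.05 / 12.80, rel=1e-9)
        assert row["rel_diff"] == pytest.approx(0.0039, abs=1e-4)
        assert row["converged"]

    def test_outside_criterion(self):
        rep = convergence_check([table({"SR": 13.6}), table({"SR": 12.8})])
        row = rep.iloc[0]
        assert row["rel_diff"] == pytest.approx(0.0625, rel=1e-9)
        assert not row["converged"]

    def test_region_mismatch_rejected(self):
        with pytest.raises(ValueError):
            convergence_check([table({"SR": 1.0}), table({"DMC": 1.0})])


class TestSensitivityCompare:
    def test_identity(self):
        t = table({"SR": 10.0, "DMC": 12.0})
        rep = sensitivity_compare(t, t)
        assert np.allclose(rep["per_region"]["ratio"], 1.0)

    def test_ratio_arithmetic(self):
        rep = sensitivity_compare(table({"DMC": 12.80}),
                                  table({"DMC": 12.94}))
        r = rep["per_region"].loc["DMC"]
        assert r["ratio"] == pytest.approx(1.0109, abs=1e-4)
        assert r["percent_change"] == pytest.approx(1.09, abs=0.01)

    def test_monotone_increase_gives_ratios_above_one(self):
        base = table({"SR": 5.0, "DMC": 7.0, "DLC": 9.0})
        up = table({"SR": 5.5, "DMC": 7.1, "DLC": 9.9})
        rep = sensitivity_compare(base, up)
        assert (rep["per_region"]["ratio"] >= 1.0).all()

    def test_point_change_fractions(self):
        base = table({"SR": 1.0})
        bs = np.array([1.0, 2.0, 3.0, 4.0])
        ss = np.array([1.0, 2.0, 3.3, 4.0])
        rep = sensitivity_compare(base, base, bs, ss)
        assert rep["points"]["n_changed"] == 1
        assert rep["points"]["fraction_changed"] == pytest.approx(0.25)
        assert rep["points"]["max_percent_increase"] == pytest.approx(10.0)


class TestCompareVariants:
    def test_equal_tables_give_zero(self):
        t = table({"SR": 10.0})
        d = compare_variants(t, t)
        assert np.all(d["diff_MPa"] == 0)
        assert np.all(d["percent"] == 0)

    def test_printed_pair_arithmetic(self):
        d = compare_variants(table({"DMC": 12.8}), table({"DMC": 14.1}))
        assert d.loc["DMC", "diff_MPa"] == pytest.approx(1.3)
        assert d.loc["DMC", "percent"] == pytest.approx(10.2, abs=0.05)

    def test_antisymmetry(self):
        a = table({"SR": 10.0, "DMC": 12.0})
        b = table({"SR": 11.5, "DMC": 9.0})
        ab = compare_variants(a, b)
        ba = compare_variants(b, a)
        assert np.allclose(ab["diff_MPa"], -ba["diff_MPa"])

    def test_incompatible_load_cases_rejected(self):
        a = table({"SR": 1.0}, load_case="impact")
        b = table({"SR": 1.0}, load_case="static")
        with pytest.raises(ValueError, match="incompatible"):
            compare_variants(a, b)
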
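import numpy as np
import pytest

from polarfields.hortonhoyt import HortonHoytModel
from polarfields.rois import (
    WedgeSpec,
    assemble_wedge,
    behavior_matched_areas,
    behavior_matched_wedges,
    eccentricity_band_areas,
    subject_area_table,
)
from polarfields.sectors import angular_edges_for_width, build_fine_grid
from polarfields.surface import vertex_areas


@pytest.fixture(scope="module")
def grids15(isotropic_cortex):
    edges = angular_edges_for_width(15, phase_deg=7.5)
    return {
        h: build_fine_grid(isotropic_cortex.bundles[h],
                           isotropic_cortex.sectors[h], edges)
        for h in isotropic_cortex.bundles
    }


@pytest.fixture(scope="module")
def fine_isotropic():
    """Finer isotropic cortex: band quantization well below band steps."""
    from polarfields.synth import CortexGenParams, generate_cortex

    cortex = generate_cortex(CortexGenParams(
        h=0.0, v=0.0, mesh_step=0.4, angle_noise_sd=0.0, ecc_noise_sd=0.0,
        ipsi_spill_prob=0.0, seed=1))
    edges = angular_edges_for_width(10)
    grids = {h: build_fine_grid(cortex.bundles[h], cortex.sectors[h], edges)
             for h in cortex.bundles}
    return cortex, grids


@pytest.fixture(scope="module")
def iso_grids(isotropic_cortex):
    edges = angular_edges_for_width(10)
    return {
        h: build_fine_grid(isotropic_cortex.bundles[h],
                           isotropic_cortex.sectors[h], edges)
        for h in isotropic_cortex.bundles
    }


def wedge_area(cortex, grids, spec):
    return sum(
        vertex_areas(cortex.bundles[h])[assemble_wedge(g, spec).vertex_ids].sum()
        for h, g in grids.items()
    )


class TestAssembleWedge:
    def test_full_halfwidth_covers_v1_band(self, clean_cortex, clean_grids):
        grid = clean_grids["left"]
        full = assemble_wedge(grid, WedgeSpec("HM", 90.0))
        v1_band = grid.select(("V1",), 0, 180, 1, 6)
        np.testing.assert_array_equal(np.sort(full.vertex_ids), v1_band)

    def test_incremental_disjoint_and_union_to_cumulative(self, clean_grids):
        grid = clean_grids["left"]
        incs = [assemble_wedge(grid, WedgeSpec("HM", w, "incremental"))
                for w in (10.0, 20.0, 30.0, 40.0, 50.0)]
        all_ids = np.concatenate([r.vertex_ids for r in incs])
        assert len(all_ids) == len(np.unique(all_ids))  # pairwise disjoint
        cum = assemble_wedge(grid, WedgeSpec("HM", 50.0))
        np.testing.assert_array_equal(np.sort(all_ids), cum.vertex_ids)

    def test_cumulative_area_strictly_increases(self, clean_cortex, clean_grids):
        areas = [wedge_area(clean_cortex, clean_grids, WedgeSpec("HM", w))
                 for w in (10.0, 20.0, 30.0, 40.0, 50.0)]
        assert (np.diff(areas) > 0).all()

    def test_straddling_vma_rois_include_v2(self, clean_cortex, clean_grids):
        both = wedge_area(clean_cortex, clean_grids,
                          WedgeSpec("UVM", 10.0, areas="V1+V2"))
        v1 = wedge_area(clean_cortex, clean_grids,
                        WedgeSpec("UVM", 10.0, areas="V1-only"))
        assert both == pytest.approx(2 * v1, rel=0.1)  # mirrored V2 strip

    def test_wedge_area_matches_generator_closed_form(self, clean_cortex,
                                                      clean_grids):
        """Quantization at this coarse fixture resolution (~3k vertices,
        ±10 deg spans ~5 mesh columns) bounds the error near 15%; the
        fine-resolution check lives in the acceptance suite."""
        gt = clean_cortex.ground_truth
        for w, tol in ((10.0, 0.15), (30.0, 0.05)):
            meas = wedge_area(clean_cortex, clean_grids, WedgeSpec("HM", w))
            true = 2 * gt.wedge_area(90 - w, 90 + w, 1, 6)  # both hemispheres
            assert meas == pytest.approx(true, rel=tol)

    def test_off_lattice_width_rejected(self, clean_grids):
        with pytest.raises(ValueError, match="multiple"):
            assemble_wedge(clean_grids["left"], WedgeSpec("HM", 12.0))


class TestAreaTable:
    def test_long_format_and_monotone_in_width(self, clean_cortex, clean_grids):
        tab = subject_area_table("s0", clean_cortex.bundles, clean_grids,
                                 half_widths=(10, 20, 30))
        assert set(tab.meridian) == {"HM", "UVM", "LVM", "VM"}
        assert (tab.area_mm2 >= 0).all()
        cum = tab[tab["mode"] == "cumulative"]
        for m, grp in cum.groupby("meridian"):
            assert grp.sort_values("half_width_deg").area_mm2.is_monotonic_increasing

    def test_incremental_sums_to_cumulative(self, clean_cortex, clean_grids):
        tab = subject_area_table("s0", clean_cortex.bundles, clean_grids,
                                 half_widths=(10, 20, 30))
        for m in ("HM", "VM"):
            inc = tab[(tab.meridian == m) & (tab["mode"] == "incremental")]
            cum = tab[(tab.meridian == m) & (tab["mode"] == "cumulative")
                      & (tab.half_width_deg == 30.0)]
            assert inc.area_mm2.sum() == pytest.approx(cum.area_mm2.iloc[0])


class TestBehaviorMatchedWedges:
    def test_24_wedges_partition_the_annulus(self, isotropic_cortex, grids15):
        wedges = behavior_matched_wedges(grids15)
        assert len(wedges) == 24
        for h in ("left", "right"):
            ids = np.concatenate([
                parts[h].vertex_ids for parts in wedges.values() if h in parts
            ])
            assert len(ids) == len(np.unique(ids))
            annulus = grids15[h].select(("V1",), 0, 180, 4, 5)
            np.testing.assert_array_equal(np.sort(ids), annulus)

    def test_mirror_wedges_equal_on_symmetric_cortex(self, isotropic_cortex,
                                                     grids15):
        va = {h: vertex_areas(b) for h, b in isotropic_cortex.bundles.items()}
        wedges = behavior_matched_wedges(grids15)
        for c in (15.0, 45.0, 105.0):
            a = sum(va[h][r.vertex_ids].sum() for h, r in wedges[c].items())
            b = sum(va[h][r.vertex_ids].sum()
                    for h, r in wedges[360.0 - c].items())
            assert a == pytest.approx(b, rel=1e-9)

    def test_mirror_folding_normalization(self, isotropic_cortex, grids15):
        """Mirror pairs averaged; HM summed over 90+270; VM single wedges."""
        va = {h: vertex_areas(b) for h, b in isotropic_cortex.bundles.items()}
        wedges = behavior_matched_wedges(grids15)
        raw = {c: sum(va[h][r.vertex_ids].sum() for h, r in parts.items())
               for c, parts in wedges.items()}
        folded = behavior_matched_areas(isotropic_cortex.bundles, grids15)
        got = dict(zip(folded.center_deg, folded.area_mm2))
        assert got[15.0] == pytest.approx((raw[15.0] + raw[345.0]) / 2)
        assert got[90.0] == pytest.approx(raw[90.0] + raw[270.0])
        assert got[0.0] == pytest.approx(raw[0.0])
        assert got[180.0] == pytest.approx(raw[180.0])

    def test_incompatible_grid_rejected(self, iso_grids):
        with pytest.raises(ValueError, match="edge"):
            behavior_matched_wedges(iso_grids)  # 10-deg grid lacks 7.5 edges


class TestEccentricityBands:
    def test_bands_partition_wedge(self, isotropic_cortex, iso_grids):
        bt = eccentricity_band_areas("s0", isotropic_cortex.bundles, iso_grids,
                                     half_width=10.0, areas="V1-only")
        hm = bt[bt.meridian == "HM"]
        full = wedge_area(isotropic_cortex, iso_grids,
                          WedgeSpec("HM", 10.0, ecc_range=(1.0, 6.0)))
        assert hm.area_mm2.sum() == pytest.approx(full, rel=1e-12)


    def test_band_areas_decrease_with_eccentricity(self, fine_isotropic):
        cortex, grids = fine_isotropic
        bt = eccentricity_band_areas("s0", cortex.bundles, grids,
                                     half_width=10.0, areas="V1-only")
        hm = bt[bt.meridian == "HM"].sort_values("ecc_lo")
        assert (np.diff(hm.area_mm2) < 0).all()

    def test_band_areas_near_magnification_integral(self, fine_isotropic):
        """Whole-vertex binning quantization keeps 1-degree bands within
        ~12% of the closed-form integral at working resolution; the error
        shrinks with mesh refinement (see convergence test)."""
        cortex, grids = fine_isotropic
        model = HortonHoytModel()
        bt = eccentricity_band_areas("s0", cortex.bundles, grids,
                                     half_width=10.0, areas="V1-only")
        hm = bt[bt.meridian == "HM"]
        for _, row in hm.iterrows():
            pred = model.predicted_area(row.ecc_lo, row.ecc_hi, 40)
            assert row.area_mm2 == pytest.approx(pred, rel=0.12)
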
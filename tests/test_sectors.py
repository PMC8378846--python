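import numpy as np
import pytest

from polarfields.sectors import (
    CoarseSector,
    angular_edges_for_width,
    fit_monotone_map,
    relative_distance,
    resample_sector,
    split_by_coordinate,
)
from polarfields.surface import CorticalSurfaceBundle, VertexRegion, vertex_areas

from conftest import strip_mesh


def pava(y):
    """Pooled-adjacent-violators oracle (increasing, unweighted)."""
    y = list(map(float, y))
    level = [[v] for v in y]
    i = 0
    while i < len(level) - 1:
        if np.mean(level[i]) > np.mean(level[i + 1]):
            level[i] += level.pop(i + 1)
            i = max(i - 1, 0)
        else:
            i += 1
    out = []
    for block in level:
        out += [np.mean(block)] * len(block)
    return np.array(out)


def strip_sector(n_quads=30, angle_lo=0.0, angle_hi=90.0):
    """A rectangular strip posing as one coarse sector: boundaries at the two
    ends, true angle affine in x."""
    coords, faces = strip_mesh(n_quads)
    n = len(coords)
    nb = n_quads + 1
    x = coords[:, 0]
    angle = angle_lo + (angle_hi - angle_lo) * x / n_quads
    bundle = CorticalSurfaceBundle(
        faces=faces,
        coords={"white": coords, "midgray": coords, "pial": coords},
        polar_angle=angle,
        eccentricity=np.full(n, 1.5),
        area_label=np.full(n, "V1", dtype=object),
        hemisphere="left",
    )
    sector = CoarseSector(
        vertices=VertexRegion(np.arange(n)),
        visual_area="V1",
        angular_band=(angle_lo, angle_hi),
        ecc_band=(1.0, 2.0),
        boundary_a=VertexRegion(np.array([0, nb])),
        boundary_b=VertexRegion(np.array([n_quads, n - 1])),
        boundary_e1=VertexRegion(np.arange(nb)),          # bottom row
        boundary_e2=VertexRegion(np.arange(nb, n)),       # top row
        name="strip",
    )
    return bundle, sector, angle


class TestRelativeDistance:
    def test_endpoints_and_range(self):
        bundle, sector, _ = strip_sector()
        rf = relative_distance(bundle, sector, "tangential")
        ids = sector.vertices.vertex_ids
        on_a = np.isin(ids, sector.boundary_a.vertex_ids)
        on_b = np.isin(ids, sector.boundary_b.vertex_ids)
        np.testing.assert_allclose(rf.r[on_a], -1.0)
        np.testing.assert_allclose(rf.r[on_b], 1.0)
        assert (np.abs(rf.r) <= 1.0).all()

    def test_equidistant_vertex_is_zero(self):
        bundle, sector, _ = strip_sector(n_quads=30)
        rf = relative_distance(bundle, sector, "tangential")
        mid = np.isclose(bundle.layer_coords()[:, 0], 15.0)
        np.testing.assert_allclose(rf.r[mid[sector.vertices.vertex_ids]], 0.0,
                                   atol=1e-12)

    def test_monotone_along_parallel_boundary_strip(self):
        bundle, sector, _ = strip_sector(n_quads=40)
        rf = relative_distance(bundle, sector, "tangential")
        x = bundle.layer_coords()[sector.vertices.vertex_ids, 0]
        order = np.argsort(x)
        assert (np.diff(rf.r[order]) >= -1e-12).all()

    def test_intersecting_boundaries_rejected(self):
        bundle, sector, _ = strip_sector()
        sector.boundary_b = sector.boundary_a
        with pytest.raises(ValueError, match="strip"):
            relative_distance(bundle, sector, "tangential")


class TestMonotoneFit:
    def test_exact_on_affine_relation(self):
        bundle, sector, angle = strip_sector()
        rf = relative_distance(bundle, sector, "tangential")
        m = fit_monotone_map(rf.r, angle)
        np.testing.assert_allclose(m.predict(rf.r), angle, atol=1e-6)

    def test_matches_pava_oracle_and_beats_noise(self, rng):
        """Isotonic fit equals pooled-adjacent-violators; RMSE <= noise SD."""
        r = np.sort(rng.uniform(-1, 1, 400))
        true = 45.0 * (r + 1)
        noisy = true + rng.normal(0, 5.0, r.size)
        m = fit_monotone_map(r, noisy)
        oracle = pava(noisy)
        # agreement up to the epsilon de-tie ramp that keeps the map strict
        np.testing.assert_allclose(m.predict(r), oracle, atol=1e-3)
        rmse = np.sqrt(np.mean((m.predict(r) - true) ** 2))
        assert rmse <= 5.0

    def test_orientation_symmetry(self, rng):
        r = np.sort(rng.uniform(-1, 1, 100))
        y = 10 + 80 * (1 - r) / 2 + rng.normal(0, 2, r.size)  # decreasing
        m_dec = fit_monotone_map(r, y)
        m_inc = fit_monotone_map(-r, y)
        np.testing.assert_allclose(m_dec.predict(r), m_inc.predict(-r), atol=1e-3)
        assert not m_dec.increasing and m_inc.increasing

    def test_inverse_round_trip(self, rng):
        r = np.sort(rng.uniform(-1, 1, 200))
        m = fit_monotone_map(r, 90 * (r + 1) / 2)
        vals = np.array([10.0, 45.0, 80.0])
        np.testing.assert_allclose(m.predict(m.inverse(vals)), vals, atol=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_monotone_map(np.linspace(-1, 1, 5), np.arange(5.0))
        with pytest.raises(ValueError, match="degenerate"):
            fit_monotone_map(np.linspace(-1, 1, 20), np.full(20, 7.0))


class TestSplitSector:
    def test_bins_partition_sector(self):
        bundle, sector, angle = strip_sector(n_quads=45)
        rf = relative_distance(bundle, sector, "tangential")
        m = fit_monotone_map(rf.r, angle)
        bins = split_by_coordinate(sector, rf.r, m,
                                   np.arange(0.0, 90.1, 10.0))
        assert len(bins) == 9
        all_ids = np.concatenate(list(bins.values()))
        assert len(all_ids) == len(sector.vertices)
        assert len(np.unique(all_ids)) == len(all_ids)

    def test_recovered_boundaries_near_true_iso_angle_lines(self):
        bundle, sector, angle = strip_sector(n_quads=90)
        grid = resample_sector(bundle, sector,
                               angular_edges_for_width(10),
                               ecc_edges=(1.0, 2.0))
        # true iso-angle lines sit at x = 10, 20, ... deg * (90 quads / 90 deg)
        x = bundle.layer_coords()[:, 0]
        for (_, (lo, hi), _), ids in grid.items():
            if len(ids) == 0:
                continue
            assert x[ids].min() >= lo - 1.0 - 1e-9  # one edge length
            assert x[ids].max() <= hi + 1.0 + 1e-9

    def test_fine_areas_sum_to_sector_area(self, noisy_cortex):
        """Partition conservation holds per sector even with measurement noise."""
        bundle = noisy_cortex.bundles["left"]
        va = vertex_areas(bundle)
        for sector in noisy_cortex.sectors["left"][:4]:
            grid = resample_sector(bundle, sector, angular_edges_for_width(10))
            total = sum(va[ids].sum() for ids in grid.values())
            expected = va[sector.vertices.vertex_ids].sum()
            np.testing.assert_allclose(total, expected, rtol=1e-9)

    def test_incompatible_edges_rejected(self):
        bundle, sector, angle = strip_sector()
        rf = relative_distance(bundle, sector, "tangential")
        m = fit_monotone_map(rf.r, angle)
        with pytest.raises(ValueError, match="align"):
            resample_sector(bundle, sector, angular_edges=(0.0, 12.0, 24.0),
                            ecc_edges=(1.0, 2.0))


def test_angular_edges_for_width():
    assert angular_edges_for_width(10) == tuple(float(x) for x in range(0, 190, 10))
    e15 = angular_edges_for_width(15, phase_deg=7.5)
    assert 90.0 in e15 and 7.5 in e15 and 172.5 in e15 and 0.0 in e15
    with pytest.raises(ValueError):
        angular_edges_for_width(0)
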
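"""Exact zonal statistics vs hand arithmetic, shapely, and the subcell oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon, box

from portmort.exposure import (
    ExposureGrid,
    assign_exposure,
    clip_to_rect,
    rasterized_mean_oracle,
    rect_clip_area,
    shoelace_area,
    tract_mean,
)


def make_grid(values, origin=(0.0, 0.0), cell=1000.0, pollutant="pm25"):
    return ExposureGrid(pollutant=pollutant, origin=origin, cell_size=cell,
                        values=np.asarray(values, dtype=float))


def tract_frame(polys):
    return pd.DataFrame({
        "tract_id": [f"T{i}" for i in range(len(polys))],
        "geometry": polys,
        "ses_category": "medium",
    })


TWO_CELL_GRID = make_grid([[10.0, 20.0]])
#: rectangle covering 25% of the 10-cell and 75% of the 20-cell -> 17.5
TWO_CELL_TRACT = box(750.0, 0.0, 1750.0, 1000.0)


def random_convex_polygon(rng, extent=3000.0, n_pts=8):
    from scipy.spatial import ConvexHull

    pts = rng.uniform(200.0, extent - 200.0, size=(n_pts, 2))
    h = ConvexHull(pts)
    return Polygon(pts[h.vertices])


class TestClippingPrimitives:
    def test_shoelace_unit_square(self):
        assert shoelace_area([(0, 0), (1, 0), (1, 1), (0, 1)]) == 1.0

    def test_clip_triangle_to_rect_matches_shapely(self, rng):
        for _ in range(50):
            tri = Polygon(rng.uniform(-2, 3, size=(3, 2)))
            if tri.area < 1e-6:
                continue
            ours = rect_clip_area(list(tri.exterior.coords)[:-1], 0, 0, 1, 1)
            ref = tri.intersection(box(0, 0, 1, 1)).area
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_clip_fully_inside_returns_polygon(self):
        v = clip_to_rect([(0.2, 0.2), (0.8, 0.2), (0.5, 0.9)], 0, 0, 1, 1)
        # base 0.6, height 0.7 -> area 0.21
        assert abs(shoelace_area(v)) == pytest.approx(0.21)

    def test_clip_disjoint_returns_empty(self):
        assert rect_clip_area([(2, 2), (3, 2), (3, 3)], 0, 0, 1, 1) == 0.0


class TestAssignExposure:
    def test_constant_field_returns_constant(self):
        grid = make_grid(np.full((3, 3), 18.4), cell=500.0)
        polys = [box(100, 100, 600, 400), Polygon([(200, 200), (1300, 250),
                                                   (800, 1200)])]
        out = assign_exposure(grid, tract_frame(polys))
        assert np.allclose(out["mean"], 18.4)
        assert np.allclose(out["coverage_fraction"], 1.0)

    def test_two_cell_worked_example(self):
        out = assign_exposure(TWO_CELL_GRID, tract_frame([TWO_CELL_TRACT]))
        assert out["mean"].iloc[0] == pytest.approx(17.5, abs=1e-12)

    def test_tract_equal_to_one_cell_is_identity(self):
        grid = make_grid([[10.0, 20.0], [30.0, 40.0]])
        out = assign_exposure(grid, tract_frame([box(1000, 1000, 2000, 2000)]))
        assert out["mean"].iloc[0] == 40.0

    def test_boundary_touching_cell_contributes_nothing(self):
        grid = make_grid([[10.0, 20.0]])
        # tract exactly on the first cell; shares an edge with the second
        out = assign_exposure(grid, tract_frame([box(0, 0, 1000, 1000)]))
        assert out["mean"].iloc[0] == 10.0

    def test_linearity_in_the_grid(self, rng):
        vals1 = rng.uniform(5, 30, size=(4, 4))
        vals2 = rng.uniform(5, 30, size=(4, 4))
        a, b = 0.7, 2.3
        tracts = tract_frame([Polygon([(300, 200), (3100, 600), (2000, 3500)])])
        m1 = assign_exposure(make_grid(vals1), tracts)["mean"].iloc[0]
        m2 = assign_exposure(make_grid(vals2), tracts)["mean"].iloc[0]
        m12 = assign_exposure(make_grid(a * vals1 + b * vals2),
                              tracts)["mean"].iloc[0]
        assert m12 == pytest.approx(a * m1 + b * m2, abs=1e-10)

    def test_translation_equivariance(self, rng):
        vals = rng.uniform(5, 30, size=(4, 4))
        poly = Polygon([(300, 200), (3100, 600), (2000, 3500)])
        dx, dy = 12345.0, -777.0
        m0 = assign_exposure(make_grid(vals), tract_frame([poly]))["mean"].iloc[0]
        shifted = Polygon([(x + dx, y + dy) for x, y in poly.exterior.coords])
        m1 = assign_exposure(make_grid(vals, origin=(dx, dy)),
                             tract_frame([shifted]))["mean"].iloc[0]
        assert m1 == pytest.approx(m0, abs=1e-10)

    def test_mean_bounded_by_cell_values(self, rng):
        for _ in range(20):
            vals = rng.uniform(0, 50, size=(4, 4))
            poly = random_convex_polygon(rng, extent=4000.0)
            grid = make_grid(vals)
            mean, _ = tract_mean(grid, poly)
            assert vals.min() - 1e-9 <= mean <= vals.max() + 1e-9

    def test_nodata_excluded_and_renormalized(self):
        vals = np.array([[10.0, np.nan]])
        grid = make_grid(vals)
        tracts = tract_frame([box(500, 0, 1500, 1000)])
        with pytest.warns(UserWarning, match="coverage"):
            out = assign_exposure(grid, tracts)
        assert out["mean"].iloc[0] == 10.0
        assert out["coverage_fraction"].iloc[0] == pytest.approx(0.5)

    def test_zero_overlap_fails_naming_tract(self):
        grid = make_grid([[10.0]])
        tracts = tract_frame([box(5000, 5000, 6000, 6000)])
        with pytest.raises(ValueError, match="T0"):
            assign_exposure(grid, tracts)

    def test_invalid_polygons_rejected(self):
        bowtie = Polygon([(0, 0), (1000, 1000), (1000, 0), (0, 1000)])
        with pytest.raises(ValueError, match="self-intersecting"):
            tract_mean(make_grid([[1.0]]), bowtie)
        holed = Polygon(box(0, 0, 1000, 1000).exterior.coords,
                        [box(400, 400, 600, 600).exterior.coords])
        with pytest.raises(ValueError, match="holes"):
            tract_mean(make_grid([[1.0]]), holed)


class TestRasterizationOracle:
    def test_constant_grid_any_subdivisions(self):
        grid = make_grid(np.full((2, 2), 7.25))
        poly = Polygon([(300, 200), (1500, 600), (900, 1700)])
        for s in (1, 4, 16):
            assert rasterized_mean_oracle(grid, poly, s) == 7.25

    def test_converges_on_worked_example(self):
        approx = rasterized_mean_oracle(TWO_CELL_GRID, TWO_CELL_TRACT, 64)
        assert abs(approx - 17.5) / 17.5 < 0.005

    def test_agrees_with_exact_on_random_tracts(self, rng):
        """50 seeded convex tracts: |oracle - exact| <= 1% of exact."""
        for _ in range(50):
            vals = rng.uniform(5.0, 40.0, size=(4, 4))
            grid = make_grid(vals)
            poly = random_convex_polygon(rng, extent=4000.0)
            exact, _ = tract_mean(grid, poly)
            approx = rasterized_mean_oracle(grid, poly, 32)
            assert abs(approx - exact) <= 0.01 * exact


@settings(max_examples=50, deadline=None, derandomize=True)
@given(x0=st.floats(0, 1500), y0=st.floats(0, 1500),
       w=st.floats(100, 2000), h=st.floats(100, 2000))
def test_rect_tract_mean_matches_direct_area_weights(x0, y0, w, h):
    """Axis-aligned tracts: clipped weights equal analytic overlap areas."""
    vals = np.arange(16, dtype=float).reshape(4, 4) + 1.0
    grid = make_grid(vals)
    poly = box(x0, y0, x0 + w, y0 + h)
    mean, cov = tract_mean(grid, poly)
    num = den = 0.0
    for r in range(4):
        for c in range(4):
            ox = max(x0, c * 1000.0)
            oy = max(y0, r * 1000.0)
            ex = min(x0 + w, (c + 1) * 1000.0)
            ey = min(y0 + h, (r + 1) * 1000.0)
            a = max(0.0, ex - ox) * max(0.0, ey - oy)
            num += vals[r, c] * a
            den += a
    assert mean == pytest.approx(num / den, abs=1e-10)
    assert cov == pytest.approx(den / (w * h), abs=1e-9)
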
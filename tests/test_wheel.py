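import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domwheel import wheel

AXES = tuple(
    wheel.AxisSpec(metric=m, vmin=0.0, vmax=1.0, angle_deg=a)
    for m, a in zip(wheel.DEFAULT_AXIS_METRICS, wheel.default_angles(4))
)


def make_wheel(values, key="w"):
    return wheel.Wheel(key=key, values=tuple(values), axes=AXES)


unit4 = st.tuples(*[st.floats(0.0, 1.0) for _ in range(4)])


class TestFitAxes:
    def test_min_max_bounds(self):
        table = pd.DataFrame({m: [2.0, 4.0, 6.0] for m in wheel.DEFAULT_AXIS_METRICS})
        axes = wheel.fit_axes(table)
        assert axes[0].vmin == 2.0 and axes[0].vmax == 6.0
        assert [a.angle_deg for a in axes] == [135.0, 45.0, -45.0, -135.0]

    def test_constant_column_error(self):
        table = pd.DataFrame({m: [3.0, 3.0, 3.0] for m in wheel.DEFAULT_AXIS_METRICS})
        with pytest.raises(ValueError, match="suva"):
            wheel.fit_axes(table)

    def test_missing_metric_error(self):
        table = pd.DataFrame({"suva": [1.0, 2.0], "s275_295": [0.01, 0.02],
                              "hsf": [20.0, 60.0]})
        with pytest.raises(ValueError, match="doc_don"):
            wheel.fit_axes(table, metrics=("suva", "s275_295", "doc_don"))


class TestNormalize:
    def _sample(self, x):
        return dict(zip(wheel.DEFAULT_AXIS_METRICS, x))

    def test_endpoints_and_midpoint(self):
        table = pd.DataFrame({m: [2.0, 6.0] for m in wheel.DEFAULT_AXIS_METRICS})
        axes = wheel.fit_axes(table)
        assert wheel.normalize(self._sample([2.0] * 4), axes).values == (0.0,) * 4
        assert wheel.normalize(self._sample([6.0] * 4), axes).values == (1.0,) * 4
        assert wheel.normalize(self._sample([4.0] * 4), axes).values == (0.5,) * 4

    def test_out_of_range_clipped(self):
        table = pd.DataFrame({m: [2.0, 6.0] for m in wheel.DEFAULT_AXIS_METRICS})
        axes = wheel.fit_axes(table)
        w = wheel.normalize(self._sample([1.0, 7.0, 4.0, 4.0]), axes)
        assert w.values[0] == 0.0 and w.values[1] == 1.0

    def test_missing_metric_no_wheel(self):
        w = wheel.normalize({"suva": 0.5}, AXES, key="x")
        assert w is None

    @given(x=unit4, y=unit4)
    @settings(max_examples=50, deadline=None)
    def test_monotone(self, x, y):
        lo = self._sample(np.minimum(x, y))
        hi = self._sample(np.maximum(x, y))
        wlo = wheel.normalize(lo, AXES)
        whi = wheel.normalize(hi, AXES)
        assert all(a <= b for a, b in zip(wlo.values, whi.values))


class TestPolygonGeometry:
    def test_all_ones_square_on_axes(self):
        pts = wheel.polygon(make_wheel([1, 1, 1, 1]), radius=1.0)
        r22 = np.sqrt(2) / 2
        np.testing.assert_allclose(
            pts, [[-r22, r22], [r22, r22], [r22, -r22], [-r22, -r22]], atol=1e-12
        )

    def test_all_zeros_degenerate(self):
        np.testing.assert_allclose(wheel.polygon(make_wheel([0, 0, 0, 0])), 0.0)

    def test_hand_computed_vertices(self):
        # v = (1, 0.5, 0.25, 0.75) at 135, 45, -45, -135 degrees
        pts = wheel.polygon(make_wheel([1.0, 0.5, 0.25, 0.75]), radius=1.0)
        expected = [
            [-0.70710678, 0.70710678],
            [0.35355339, 0.35355339],
            [0.17677670, -0.17677670],
            [-0.53033009, -0.53033009],
        ]
        np.testing.assert_allclose(pts, expected, atol=1e-8)

    def test_area_all_ones(self):
        assert wheel.area(make_wheel([1, 1, 1, 1])) == pytest.approx(2.0)

    def test_area_all_zeros(self):
        assert wheel.area(make_wheel([0, 0, 0, 0])) == 0.0

    def test_shoelace_equals_quarter_product_sum(self):
        # oracle: (1/2) sum v_i v_{i+1} for orthogonal axes
        rng = np.random.default_rng(17)
        for _ in range(1000):
            v = rng.uniform(0.0, 1.0, 4)
            expected = 0.5 * (v * np.roll(v, -1)).sum()
            assert wheel.area(make_wheel(v)) == pytest.approx(expected, abs=1e-12)

    @given(v=unit4, i=st.integers(0, 3), bump=st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_area_monotone_in_each_axis(self, v, i, bump):
        v2 = list(v)
        v2[i] = min(1.0, v2[i] + bump)
        assert wheel.area(make_wheel(v2)) >= wheel.area(make_wheel(v)) - 1e-12

    def test_normalization_affine_invariance(self):
        # rescaling a metric column in both sample and reference dataset
        # leaves the wheel, and hence its area, unchanged
        rng = np.random.default_rng(3)
        table = pd.DataFrame(
            {m: rng.uniform(1.0, 9.0, 20) for m in wheel.DEFAULT_AXIS_METRICS}
        )
        axes = wheel.fit_axes(table)
        sample = table.iloc[4]
        w = wheel.normalize(sample, axes)
        scaled = table.assign(hsf=2.5 * table["hsf"] + 11.0)
        axes2 = wheel.fit_axes(scaled)
        w2 = wheel.normalize(scaled.iloc[4], axes2)
        np.testing.assert_allclose(w.values, w2.values, atol=1e-12)
        assert wheel.area(w) == pytest.approx(wheel.area(w2), abs=1e-12)


class TestDistance:
    def test_extremes(self):
        assert wheel.distance(make_wheel([0] * 4), make_wheel([1] * 4)) == \
            pytest.approx(2.0)

    def test_identity_and_symmetry(self):
        a, b = make_wheel([0.2, 0.4, 0.6, 0.8]), make_wheel([0.5, 0.1, 0.9, 0.3])
        assert wheel.distance(a, a) == 0.0
        assert wheel.distance(a, b) == wheel.distance(b, a)

    def test_mismatched_axes_error(self):
        other = tuple(
            wheel.AxisSpec(metric=m, vmin=0.0, vmax=1.0, angle_deg=a)
            for m, a in zip(("suva", "sr", "hsf", "doc_don"),
                            wheel.default_angles(4))
        )
        b = wheel.Wheel(key="b", values=(0.1,) * 4, axes=other)
        with pytest.raises(ValueError, match="mismatch"):
            wheel.distance(make_wheel([0.1] * 4), b)

    @given(a=unit4, b=unit4, c=unit4)
    @settings(max_examples=100, deadline=None)
    def test_triangle_inequality(self, a, b, c):
        wa, wb, wc = map(make_wheel, (a, b, c))
        assert wheel.distance(wa, wc) <= (
            wheel.distance(wa, wb) + wheel.distance(wb, wc) + 1e-12
        )


class TestClassify:
    def test_exact_template_match(self):
        templates = wheel.default_templates(AXES)
        name, dist = wheel.classify(templates["groundwater"], templates)
        assert name == "groundwater" and dist == 0.0

    def test_midpoint_tie_broken_by_order(self):
        templates = wheel.default_templates(AXES)
        mid = make_wheel(
            0.5 * (np.array(templates["groundwater"].values)
                   + np.array(templates["photolyzed"].values))
        )
        name, _ = wheel.classify(mid, templates, cutoff=10.0)
        assert name == "groundwater"  # first in insertion order

    def test_beyond_cutoff_intermediate(self):
        templates = wheel.default_templates(AXES)
        name, dist = wheel.classify(make_wheel([0.5] * 4), templates, cutoff=0.1)
        assert name == "intermediate" and dist > 0.1

    def test_caption_variant_lowers_doc_don(self):
        default = wheel.default_templates(AXES)["groundwater"]
        variant = wheel.default_templates(
            AXES, groundwater_caption_variant=True
        )["groundwater"]
        i = wheel.DEFAULT_AXIS_METRICS.index("doc_don")
        assert default.values[i] == 0.85 and variant.values[i] == 0.15

    def test_recovers_cluster_labels(self, metrics, labels):
        # two-cluster synthetic study: >= 95% of generating labels recovered
        axes = wheel.fit_axes(metrics)
        wheels = wheel.wheels_from_table(metrics, axes)
        templates = wheel.default_templates(axes)
        want = {"groundwater_like": "groundwater", "photolyzed_like": "photolyzed"}
        hits = sum(
            wheel.classify(w, templates)[0] == want[labels[k]]
            for k, w in wheels.items()
        )
        assert hits / len(wheels) >= 0.95


class TestDegradationShift:
    def test_photolysis_directions(self):
        shifts = wheel.degradation_shift(make_wheel([0.5] * 4), "photolysis")
        assert shifts == {"suva": -1, "s275_295": +1, "hsf": -1, "doc_don": -1}
        assert sum(v > 0 for v in shifts.values()) == 1

    def test_microbial_directions(self):
        shifts = wheel.degradation_shift(make_wheel([0.5] * 4), "microbial")
        assert shifts == {"suva": +1, "s275_295": 0, "hsf": 0, "doc_don": -1}
        assert {m for m, v in shifts.items() if v == 0} == {"s275_295", "hsf"}

    def test_unknown_process_error(self):
        with pytest.raises(ValueError, match="thermal"):
            wheel.degradation_shift(make_wheel([0.5] * 4), "thermal")


class TestKAxesGeneralization:
    def test_three_axis_wheel(self):
        axes = tuple(
            wheel.AxisSpec(metric=m, vmin=0.0, vmax=1.0, angle_deg=a)
            for m, a in zip(("suva", "s275_295", "hsf"), wheel.default_angles(3))
        )
        w = wheel.Wheel(key="k3", values=(1.0, 1.0, 1.0), axes=axes)
        # equilateral triangle inscribed in the unit circle
        assert wheel.area(w) == pytest.approx(3 * np.sqrt(3) / 4, rel=1e-9)

    def test_fewer_than_three_axes_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            wheel.default_angles(2)
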
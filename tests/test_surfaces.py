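"""Resistance transformations, categorical assignments, composites."""

import numpy as np
import pytest

from landgen import (CategoricalAssignment, RasterSurface, TransformSpec,
                     apply_categorical, apply_transform, combine,
                     percent_contribution, rescale)
from landgen.surfaces import FAMILIES


@pytest.fixture
def ramp():
    """Values spanning [0, 10] exactly, already rescaled."""
    return RasterSurface(np.linspace(0, 10, 121).reshape(11, 11))


class TestRescale:
    def test_fixed_points_unchanged(self):
        s = RasterSurface(np.array([[0.0, 5.0], [10.0, 0.0]]))
        assert np.allclose(rescale(s).values, s.values)

    def test_two_point_map(self):
        s = RasterSurface(np.array([[100.0, 300.0]]))
        assert np.allclose(rescale(s).values, [[0.0, 10.0]])

    @pytest.mark.parametrize("trial", range(5))
    def test_output_range_exact(self, trial):
        rng = np.random.default_rng(trial)
        s = RasterSurface(rng.normal(size=(6, 6)) * 100)
        out = rescale(s).values
        assert np.nanmin(out) == pytest.approx(0.0, abs=1e-12)
        assert np.nanmax(out) == pytest.approx(10.0, abs=1e-12)

    def test_missing_preserved(self):
        v = np.array([[1.0, np.nan], [3.0, 5.0]])
        out = rescale(RasterSurface(v))
        assert np.isnan(out.values[0, 1])

    def test_constant_surface_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rescale(RasterSurface(np.full((3, 3), 2.0)))


class TestTransform:
    @pytest.mark.parametrize("family", [f for f in FAMILIES if f != "Distance"])
    def test_output_range_is_one_to_maximum(self, ramp, family):
        spec = TransformSpec(family, shape=2.5, maximum=350.0)
        out = apply_transform(ramp, spec).values
        assert np.nanmin(out) == pytest.approx(1.0)
        assert np.nanmax(out) == pytest.approx(350.0)

    def test_ricker_peak_at_shape(self, ramp):
        shape = 4.0
        out = apply_transform(ramp, TransformSpec("Ricker", shape, 100.0))
        x = ramp.values.ravel()
        peak_x = x[np.argmax(out.values.ravel())]
        assert peak_x == pytest.approx(shape, abs=0.1)

    def test_inverse_ricker_high_at_extremes(self, ramp):
        """The humped curve reflected: resistance highest in flat (low x) and
        rugged (high x) terrain, lowest near the former peak."""
        out = apply_transform(ramp, TransformSpec("Inverse Ricker", 2.606, 3490.174))
        v = out.values.ravel()
        x = ramp.values.ravel()
        near_peak = v[np.argmin(np.abs(x - 2.606))]
        assert v[np.argmin(x)] > near_peak
        assert v[np.argmax(x)] > near_peak
        assert np.argmin(v) == np.argmin(np.abs(x - 2.606))

    def test_monomolecular_monotone(self, ramp):
        out = apply_transform(ramp, TransformSpec("Monomolecular", 3.0, 50.0))
        assert np.all(np.diff(out.values.ravel()) >= 0)

    def test_reverse_reverse_is_identity(self, ramp):
        plain = apply_transform(ramp, TransformSpec("Monomolecular", 3.0, 50.0))
        flipped_input = ramp.copy(values=10.0 - ramp.values)
        rev = apply_transform(flipped_input,
                              TransformSpec("Reverse Monomolecular", 3.0, 50.0))
        assert np.allclose(plain.values, rev.values)

    def test_inverse_inverse_is_identity(self, ramp):
        spec = TransformSpec("Monomolecular", 3.0, 50.0)
        g = apply_transform(ramp, spec).values
        gi = apply_transform(ramp, TransformSpec("Inverse Monomolecular", 3.0, 50.0)).values
        # reflecting the reflected curve restores the original ordering
        gii = np.nanmax(gi) - gi + np.nanmin(gi)
        assert np.allclose(np.argsort(gii.ravel()), np.argsort(g.ravel()))

    def test_distance_family_is_flat(self, ramp):
        out = apply_transform(ramp, TransformSpec("Distance"))
        assert np.allclose(out.values, 1.0)

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            TransformSpec("Ricker", shape=-1.0, maximum=10.0)

    def test_spec_json_round_trip(self):
        spec = TransformSpec("Inverse Ricker", 2.606, 3490.174)
        assert TransformSpec.from_json(spec.to_json()) == spec


class TestCategorical:
    def test_matrix_vs_forest_ordering(self):
        surf = RasterSurface(np.array([[1.0, 2.0], [2.0, 1.0]]))
        a = CategoricalAssignment({1.0: 12.740, 2.0: 1.0})
        out = apply_categorical(surf, a)
        assert out.values[0, 0] == pytest.approx(12.740)   # matrix
        assert out.values[0, 1] == pytest.approx(1.0)      # forest
        assert out.values[0, 0] > out.values[0, 1]

    def test_all_ones_gives_uniform_surface(self):
        surf = RasterSurface(np.array([[1.0, 2.0, 3.0]]))
        out = apply_categorical(surf, CategoricalAssignment({1.0: 1.0, 2.0: 1.0, 3.0: 1.0}))
        assert np.allclose(out.values, 1.0)

    def test_lookup_bijection_on_labels(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(1, 4, size=(6, 6)).astype(float)
        surf = RasterSurface(labels)
        table = {1.0: 1.0, 2.0: 7.5, 3.0: 250.0}
        out = apply_categorical(surf, CategoricalAssignment(table))
        for lab, res in table.items():
            assert np.all(out.values[labels == lab] == res)

    def test_uncovered_label_rejected(self):
        surf = RasterSurface(np.array([[1.0, 9.0]]))
        with pytest.raises(ValueError, match="9"):
            apply_categorical(surf, CategoricalAssignment({1.0: 1.0}))

    def test_reference_class_required(self):
        with pytest.raises(ValueError, match="reference"):
            CategoricalAssignment({1.0: 2.0, 2.0: 3.0})


class TestCombine:
    def test_single_surface_unchanged(self, ramp):
        r = apply_transform(ramp, TransformSpec("Monomolecular", 3.0, 50.0))
        assert np.allclose(combine([r]).values, r.values)

    def test_two_uniform_ones_stay_one(self):
        u = RasterSurface(np.ones((4, 4)))
        assert np.allclose(combine([u, u]).values, 1.0)

    def test_flat_component_leaves_ordering_unchanged(self, ramp):
        active = apply_transform(ramp, TransformSpec("Inverse Ricker", 2.6, 500.0))
        flat = apply_transform(ramp, TransformSpec("Distance"))
        comp = combine([active, flat])
        assert np.array_equal(np.argsort(comp.values.ravel()),
                              np.argsort(active.values.ravel()))
        pct = percent_contribution([active, flat])
        assert pct[0] > 95.0

    def test_minimum_reanchored_to_one(self, ramp):
        a = apply_transform(ramp, TransformSpec("Monomolecular", 3.0, 50.0))
        b = apply_transform(ramp, TransformSpec("Ricker", 4.0, 20.0))
        assert np.nanmin(combine([a, b]).values) == pytest.approx(1.0)
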
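import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import argrelmax

from nucarray.arraystats import (ArrayStats, TemplateSpec, nrl_regularity,
                                 periodic_template, quartile_split,
                                 select_arrays, smooth)

COARSE = TemplateSpec(grid=tuple(range(140, 201, 5)))


def brute_force_scores(profile, spec, presmoothed=True):
    """Independent oracle: exhaustive (L, phase) loop with np.corrcoef."""
    x = np.asarray(profile, float)
    if not presmoothed:
        x = smooth(x, spec.smooth_window)
    scores = []
    for L in spec.grid:
        best = -np.inf
        for phase in range(0, int(L), spec.phase_step):
            t = periodic_template(L, len(x), spec.sigma, phase)
            if t.std() == 0:
                continue
            best = max(best, np.corrcoef(x, t)[0, 1])
        scores.append(best)
    return np.asarray(scores)


class TestSmooth:
    def test_constant_unchanged(self):
        x = np.full(300, 4.2)
        np.testing.assert_allclose(smooth(x, 75), x)

    def test_impulse_plateau(self):
        x = np.zeros(401)
        x[200] = 1.0
        y = smooth(x, 75)
        np.testing.assert_allclose(y[200 - 37:200 + 38], 1 / 75)
        assert y[200 - 38] == 0 and y[200 + 38] == 0

    def test_ramp_unchanged(self):
        x = np.arange(200, dtype=float)
        np.testing.assert_allclose(smooth(x, 75), x)  # symmetric shrink

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth(np.zeros(10), 4)


class TestPeriodicTemplate:
    def test_peak_count_and_positions(self):
        t = periodic_template(165, 1000, sigma=25, phase=0)
        peaks = argrelmax(t)[0]
        # interior peaks at 165k; the x=0 peak is a boundary maximum
        assert t[0] > t[1]
        np.testing.assert_array_equal(peaks, [165 * k for k in range(1, 7)])

    def test_phase_shifts_peaks(self):
        b = periodic_template(165, 1000, 25, 50)
        np.testing.assert_array_equal(argrelmax(b)[0],
                                      [50 + 165 * k for k in range(6)])

    def test_small_sigma_near_zero_between_peaks(self):
        t = periodic_template(165, 1000, sigma=5, phase=0)
        assert t[82] < 1e-10


class TestNrlRegularity:
    def test_comb_roundtrip_exact(self):
        prof = periodic_template(165, 1000, sigma=COARSE.sigma, phase=40)
        st_ = nrl_regularity(prof, COARSE, presmoothed=True)
        assert st_.nrl == 165
        assert st_.regularity >= 0.99

    @pytest.mark.parametrize("true_nrl", [150, 165, 185])
    def test_comb_roundtrip_across_grid(self, true_nrl):
        spec = TemplateSpec()
        prof = periodic_template(true_nrl, 1000, sigma=spec.sigma, phase=10)
        st_ = nrl_regularity(prof, spec, presmoothed=True)
        assert st_.nrl == true_nrl
        assert st_.regularity > 0.999

    def test_flat_profile_flagged(self):
        st_ = nrl_regularity(np.full(1000, 2.0), COARSE)
        assert st_.regularity == 0.0 and not st_.valid

    def test_noise_profiles_low_regularity(self):
        rng = np.random.default_rng(0)
        regs = [nrl_regularity(rng.random(1000), COARSE).regularity
                for _ in range(100)]
        assert np.median(regs) < 0.5

    def test_scale_offset_invariance(self):
        rng = np.random.default_rng(1)
        prof = rng.random(1000) + periodic_template(160, 1000, 25, 5)
        a = nrl_regularity(prof, COARSE)
        b = nrl_regularity(3.7 * prof + 11.0, COARSE)
        assert a.nrl == b.nrl
        assert abs(a.regularity - b.regularity) < 1e-9

    def test_too_short_profile_errors(self):
        with pytest.raises(ValueError, match="length"):
            nrl_regularity(np.zeros(100), COARSE)

    def test_matches_brute_force_oracle(self):
        """Vectorised scorer equals an exhaustive (L, phase) loop."""
        rng = np.random.default_rng(2)
        spec = TemplateSpec(grid=tuple(range(150, 181, 5)), region=(0, 600))
        for _ in range(3):
            prof = rng.random(600) + 0.5 * periodic_template(
                int(rng.integers(150, 181)), 600, 25, int(rng.integers(0, 50)))
            sm = smooth(prof, spec.smooth_window)
            expected = brute_force_scores(sm, spec, presmoothed=True)
            got = nrl_regularity(prof, spec)
            assert got.nrl == spec.grid[int(np.argmax(expected))]
            np.testing.assert_allclose(got.regularity, expected.max(),
                                       rtol=1e-9)


class TestSelectArrays:
    def mk(self, gid, nrl, reg):
        return ArrayStats(gid, nrl, reg)

    def test_regularity_strictly_above(self):
        stats = [self.mk("a", 165, 0.5), self.mk("b", 165, 0.501)]
        assert [s.gene_id for s in select_arrays(stats)] == ["b"]

    def test_nrl_bounds_inclusive(self):
        stats = [self.mk("a", 150, 0.9), self.mk("b", 200, 0.9),
                 self.mk("c", 149, 0.9), self.mk("d", 201, 0.9)]
        assert [s.gene_id for s in select_arrays(stats)] == ["a", "b"]

    def test_invalid_nrl_excluded(self):
        assert select_arrays([self.mk("a", np.nan, 0.0)]) == []

    def test_empty(self):
        assert select_arrays([]) == []


class TestQuartileSplit:
    def test_eight_distinct(self):
        vals = {f"g{i}": float(i) for i in range(8)}
        labels = quartile_split(vals)
        assert [labels[f"g{i}"] for i in range(8)] == \
            ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]

    def test_ten_values_sizes(self):
        labels = quartile_split({f"g{i:02d}": float(i) for i in range(10)})
        from collections import Counter
        sizes = Counter(labels.values())
        assert [sizes[f"Q{q}"] for q in (1, 2, 3, 4)] == [3, 3, 2, 2]

    def test_all_equal_uses_gene_id_order(self):
        labels = quartile_split({g: 1.0 for g in "abcdefgh"})
        assert labels["a"] == "Q1" and labels["h"] == "Q4"

    def test_too_few_errors(self):
        with pytest.raises(ValueError):
            quartile_split({"a": 1, "b": 2, "c": 3})


@settings(deadline=None, derandomize=True, max_examples=20)
@given(st.integers(4, 40))
def test_quartile_sizes_differ_by_at_most_one(n):
    labels = quartile_split({f"g{i:03d}": float(i % 7) for i in range(n)})
    from collections import Counter
    sizes = sorted(Counter(labels.values()).values())
    assert sizes[-1] - sizes[0] <= 1
    assert sum(sizes) == n
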
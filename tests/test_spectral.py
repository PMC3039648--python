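"""Spectral-synthesis generator: symmetry, spectrum, and parameter recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neutralscapes.spectral import (
    amplitude,
    composite_hurst,
    estimate_hurst,
    folded_frequency,
    generate_independent,
    generate_symmetric,
    inverse_transform,
    spectral_field,
    symmetric_index,
)
from neutralscapes.types import GridShape, HurstSpec, Landscape, SpectralField


class TestSymmetricIndex:
    @pytest.mark.parametrize(
        "k, expected",
        [((0, 0), (0, 0)), ((1, 3), (7, 5)), ((4, 4), (4, 4)), ((7, 1), (1, 7))],
    )
    def test_reflection_rule(self, k, expected):
        assert symmetric_index(k, GridShape(8, 2)) == expected

    @given(
        st.integers(1, 4).flatmap(
            lambda p: st.tuples(
                st.just(2**p),
                st.lists(st.integers(0, 2**p - 1), min_size=1, max_size=3),
            )
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_involution(self, case):
        n, k = case
        shape = GridShape(n, len(k))
        k = tuple(k)
        assert symmetric_index(symmetric_index(k, shape), shape) == k

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            symmetric_index((8, 0), GridShape(8, 2))


class TestFoldedFrequency:
    @pytest.mark.parametrize(
        "k, ndim, expected",
        [((5,), 1, (-3,)), ((4,), 1, (4,)), ((0, 3), 2, (0, 3)), ((7, 6), 2, (-1, -2))],
    )
    def test_folding(self, k, ndim, expected):
        assert folded_frequency(k, GridShape(8, ndim)) == expected

    @given(st.lists(st.integers(0, 15), min_size=1, max_size=3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_folded_magnitude_bounded(self, k):
        shape = GridShape(16, len(k))
        f = folded_frequency(tuple(k), shape)
        assert all(abs(fd) <= 8 for fd in f)
        # k and k* share one radius, the point of folding
        fsym = folded_frequency(symmetric_index(tuple(k), shape), shape)
        assert sum(x * x for x in f) == sum(x * x for x in fsym)


class TestAmplitude:
    def test_unit_radius_returns_draw(self):
        assert amplitude((1, 0), 0.3, 2, 1.0) == 1.0

    def test_power_law_decay(self):
        # 4^(-(2*0.5 + 2)/2) = 4^-1.5 = 0.125
        assert amplitude((4, 0), 0.5, 2, 1.0) == pytest.approx(0.125, abs=1e-15)

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            amplitude((0, 0), 0.5, 2, 1.0)

    def test_expected_squared_amplitude_matches_spectral_density(self, rng):
        # Monte Carlo check of the fBm spectral condition: over many draws
        # the mean squared amplitude at radius r equals r^-(2H+D).
        h, ndim, f = 0.3, 2, (3, 4)  # r = 5
        g = rng.standard_normal(100_000)
        amps = np.array([amplitude(f, h, ndim, gi) for gi in g[:100]])
        # vectorised equivalent for the full sample
        r = 5.0
        amps_full = g * r ** (-(2 * h + ndim) / 2)
        assert np.allclose(amps, amps_full[:100])
        ratio = np.mean(amps_full**2) / r ** (-(2 * h + ndim))
        assert ratio == pytest.approx(1.0, abs=0.02)


class TestCompositeHurst:
    def test_equal_exponents_collapse(self):
        spec = HurstSpec((0.4, 0.4, 0.4))
        assert composite_hurst((1, 2, 3), spec) == pytest.approx(0.4)

    @pytest.mark.parametrize(
        "f, expected", [((1, 0), 0.1), ((0, 2), 0.9), ((2, 2), 0.5), ((1, 3), 0.7)]
    )
    def test_frequency_weighted_average(self, f, expected):
        spec = HurstSpec((0.1, 0.9))
        assert composite_hurst(f, spec) == pytest.approx(expected)

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValueError):
            composite_hurst((0, 0), HurstSpec((0.1, 0.9)))

    @given(
        st.tuples(st.integers(-8, 8), st.integers(-8, 8)).filter(lambda f: any(f)),
        st.floats(0.01, 0.99),
        st.floats(0.01, 0.99),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_result_within_exponent_range(self, f, h1, h2):
        out = composite_hurst(f, HurstSpec((h1, h2)))
        assert min(h1, h2) - 1e-12 <= out <= max(h1, h2) + 1e-12


class TestConjugateSymmetry:
    def test_symmetric_field_is_exactly_conjugate_symmetric(self):
        shape = GridShape(16, 2)
        coeff = spectral_field(shape, 0.5, seed=11, symmetric=True).coefficients
        for k0 in range(16):
            for k1 in range(16):
                ks = symmetric_index((k0, k1), shape)
                assert coeff[k0, k1] == np.conj(coeff[ks])

    def test_self_symmetric_coefficients_are_real_and_dc_is_zero(self):
        coeff = spectral_field(GridShape(8, 2), 0.2, seed=5, symmetric=True).coefficients
        for k0 in (0, 4):
            for k1 in (0, 4):
                assert coeff[k0, k1].imag == 0.0
        assert coeff[0, 0] == 0.0

    def test_independent_field_violates_symmetry(self):
        shape = GridShape(16, 2)
        coeff = spectral_field(shape, 0.5, seed=11, symmetric=False).coefficients
        viol = sum(
            coeff[k0, k1] != np.conj(coeff[symmetric_index((k0, k1), shape)])
            for k0 in range(16)
            for k1 in range(16)
        )
        assert viol > 200  # nearly every non-self-symmetric coefficient


class TestGenerators:
    def test_deterministic_under_fixed_seed(self):
        shape = GridShape(32, 2)
        for gen in (generate_independent, generate_symmetric):
            a = gen(shape, 0.1, seed=42)
            b = gen(shape, 0.1, seed=42)
            assert np.array_equal(a.values, b.values)
            c = gen(shape, 0.1, seed=43)
            assert not np.array_equal(a.values, c.values)

    def test_symmetric_output_is_real_and_mean_zero(self):
        land = generate_symmetric(GridShape(32, 2), 0.5, seed=7)
        ratio = land.meta["imag_rms"] / land.meta["real_rms"]
        assert ratio <= 1e-9
        assert abs(land.values.mean()) <= 1e-10 * land.values.std()

    def test_independent_output_discards_real_signal(self):
        land = generate_independent(GridShape(32, 2), 0.5, seed=7)
        ratio = land.meta["imag_rms"] / land.meta["real_rms"]
        assert ratio > 1e-6

    def test_invalid_hurst_rejected(self):
        with pytest.raises(ValueError):
            generate_symmetric(GridShape(16, 2), 1.2, seed=0)
        with pytest.raises(ValueError):
            generate_symmetric(GridShape(16, 2), 0.0, seed=0)

    def test_non_power_of_two_rejected(self):
        with pytest.raises(ValueError):
            GridShape(12, 2)

    def test_one_dimensional_and_three_dimensional_shapes_supported(self):
        for ndim in (1, 3):
            land = generate_symmetric(GridShape(16, ndim), 0.5, seed=3)
            assert land.extent == (16,) * ndim
            assert land.meta["imag_rms"] <= 1e-9 * land.meta["real_rms"]

    def test_periodicity_no_seam_at_the_wrap_boundary(self):
        # a smooth (H=0.9) field must tile seamlessly: the wrap-around row
        # difference is no rougher than interior row differences
        for seed in range(5):
            x = generate_symmetric(GridShape(64, 2), 0.9, seed=seed).values
            steps = x - np.roll(x, 1, axis=0)  # row 0 holds the seam step
            seam = np.sqrt(np.mean(steps[0] ** 2))
            interior = np.sqrt(np.mean(steps[1:] ** 2, axis=1))
            assert seam <= 3.0 * interior.max()


class TestInverseTransform:
    def test_zero_field_gives_zero_landscape(self):
        land = inverse_transform(SpectralField(np.zeros((8, 8), dtype=complex)))
        assert np.all(land.values == 0.0)

    def test_linearity_under_scaling(self):
        rng = np.random.default_rng(0)
        coeff = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        a = inverse_transform(SpectralField(coeff)).values
        b = inverse_transform(SpectralField(3.0 * coeff)).values
        assert np.allclose(b, 3.0 * a, rtol=1e-12)

    def test_single_conjugate_pair_yields_pure_cosine(self):
        # 1-D, n=8: unit coefficients at k=1 and k=7 invert to
        # (1/8)(e^{iwt} + e^{-iwt}) = 0.25 cos(2 pi t / 8)
        coeff = np.zeros(8, dtype=complex)
        coeff[1] = 1.0
        coeff[7] = 1.0
        land = inverse_transform(SpectralField(coeff))
        t = np.arange(8)
        assert np.allclose(land.values, 0.25 * np.cos(2 * np.pi * t / 8), atol=1e-15)
        assert land.meta["imag_max"] <= 1e-15


class TestHurstRecovery:
    @pytest.mark.parametrize("h", [0.1, 0.5, 0.9])
    def test_spectral_slope_recovers_generating_exponent(self, h):
        ests = [
            estimate_hurst(generate_symmetric(GridShape(128, 2), h, seed=s))
            for s in range(20)
        ]
        assert abs(np.mean(ests) - h) <= 0.1

    def test_white_noise_is_flagged_out_of_model(self, rng):
        land = Landscape(rng.standard_normal((64, 64)))
        with pytest.warns(UserWarning, match="outside"):
            h = estimate_hurst(land)
        assert not (0.0 < h < 1.0)
        assert h == pytest.approx(-1.0, abs=0.3)  # flat spectrum: H = -D/2

    def test_constant_landscape_rejected(self):
        with pytest.raises(ValueError):
            estimate_hurst(Landscape(np.ones((16, 16))))


class TestAnisotropicHurst:
    def test_temporal_hurst_controls_slice_to_slice_similarity(self):
        # 3-D fields smooth in space; consecutive slices along the last axis
        # resemble each other far more when that axis has H=0.9 than H=0.1
        def mean_corr(h_t: float) -> float:
            cors = []
            for seed in range(5):
                land = generate_symmetric(
                    GridShape(32, 3), HurstSpec((0.9, 0.9, h_t)), seed=seed
                )
                x = land.values
                for t in range(0, 31, 8):
                    a, b = x[:, :, t].ravel(), x[:, :, t + 1].ravel()
                    cors.append(np.corrcoef(a, b)[0, 1])
            return float(np.mean(cors))

        assert mean_corr(0.9) > mean_corr(0.1)
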
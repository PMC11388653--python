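import numpy as np
import pytest

from mgx.dimred import (
    dfa,
    hilbert_analytic,
    lslr_fit,
    reduce_dimensions,
    window_partition,
)
from mgx.errors import (
    ConfigError,
    DegenerateFluctuationError,
    InputError,
    SingularDesignError,
)
from mgx.io_formats import ExpressionMatrix
from mgx.synthetic import SimulationSpec, generate_expression


def _brute_force_hilbert(x):
    """O(N^2) oracle: explicit DFT, -i sgn(f) multiplier, explicit inverse DFT."""
    n = len(x)
    k = np.arange(n)
    W = np.exp(-2j * np.pi * np.outer(k, k) / n)
    spec = W @ x
    mult = np.zeros(n, dtype=complex)
    mult[1:(n + 1) // 2] = -1j
    mult[n // 2 + 1:] = 1j
    return (np.conj(W) @ (mult * spec)).real / n


class TestHilbert:
    def test_zero_signal_maps_to_zero(self):
        tr, env = hilbert_analytic(np.zeros(16))
        assert not tr.any() and not env.any()

    def test_cosine_transforms_to_sine_with_unit_envelope(self):
        n = 1024
        t = np.arange(n)
        g = np.cos(2 * np.pi * 8 * t / n)
        tr, env = hilbert_analytic(g)
        assert np.abs(tr - np.sin(2 * np.pi * 8 * t / n)).max() < 1e-6
        assert np.abs(env - 1).max() < 1e-6

    def test_matches_brute_force_dft_oracle(self, rng):
        x = rng.standard_normal(64)
        tr, _ = hilbert_analytic(x)
        np.testing.assert_allclose(tr, _brute_force_hilbert(x), atol=1e-8)

    def test_double_transform_negates_zero_mean_signal(self, rng):
        # odd length: no Nyquist bin, so only the DC component is annihilated
        x = rng.standard_normal(255)
        x -= x.mean()
        tr, _ = hilbert_analytic(x)
        tr2, _ = hilbert_analytic(tr)
        assert np.abs(tr2 + x)[5:-5].max() < 1e-6

    def test_envelope_dominates_signal_pointwise(self, rng):
        x = rng.standard_normal(128)
        _, env = hilbert_analytic(x)
        assert np.all(env >= np.abs(x) - 1e-9)

    @pytest.mark.parametrize("bad", [np.zeros(3), np.array([1.0, np.nan, 2.0, 3.0])])
    def test_invalid_input_rejected(self, bad):
        with pytest.raises(InputError):
            hilbert_analytic(bad)


class TestDfa:
    SCALES = [8, 12, 16, 24, 32, 48, 64, 96, 128, 192, 256, 384, 512]

    def test_white_noise_alpha_near_half(self):
        alphas = [dfa(np.random.default_rng(s).standard_normal(4096), self.SCALES).alpha
                  for s in range(5)]
        assert 0.45 < np.mean(alphas) < 0.55

    def test_brownian_alpha_near_three_halves(self):
        alphas = [dfa(np.cumsum(np.random.default_rng(s).standard_normal(4096)),
                      self.SCALES).alpha for s in range(5)]
        assert 1.4 < np.mean(alphas) < 1.6

    def test_vanishing_residuals_are_degenerate(self):
        # a constant series integrates to the zero profile: every linear
        # detrend is exact and no fluctuation remains
        with pytest.raises(DegenerateFluctuationError):
            dfa(np.full(1024, 3.0), [8, 16, 32], detrend_order=1)

    def test_linear_trend_gives_steep_exponent(self):
        # a linear series integrates to a quadratic profile whose curvature
        # survives linear detrending: alpha near the trend-dominated ~2
        prof = dfa(np.arange(1024, dtype=float), [8, 16, 32, 64, 128], detrend_order=1)
        assert prof.alpha > 1.8

    def test_alpha_invariant_to_affine_rescaling(self, rng):
        x = rng.standard_normal(2048)
        a = dfa(x, self.SCALES[:8]).alpha
        b = dfa(7.3 * x + 125.0, self.SCALES[:8]).alpha
        assert abs(a - b) < 1e-6

    def test_profile_fields_consistent(self, rng):
        x = rng.standard_normal(1024)
        prof = dfa(x, [8, 16, 32, 64])
        np.testing.assert_allclose(prof.integrated, np.cumsum(x - x.mean()))
        assert np.all(prof.fluctuation >= 0)
        assert np.all(np.diff(prof.scales) > 0)
        assert np.isfinite(prof.alpha)

    def test_scale_larger_than_series_rejected(self):
        with pytest.raises(InputError):
            dfa(np.random.default_rng(0).standard_normal(64), [8, 128])


class TestLslr:
    def test_exact_line_recovered_with_zero_sse(self):
        x = np.arange(10, dtype=float)
        fit = lslr_fit(x, 2 * x + 1)
        np.testing.assert_allclose(fit.coefficients, [1.0, 2.0], atol=1e-10)
        assert fit.sse < 1e-10

    def test_constant_response_gives_flat_fit(self):
        fit = lslr_fit(np.arange(8, dtype=float), np.full(8, 3.25))
        np.testing.assert_allclose(fit.coefficients, [3.25, 0.0], atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        fit = lslr_fit(X, y)
        A = np.hstack([np.ones((20, 1)), X])
        beta = np.linalg.inv(A.T @ A) @ A.T @ y  # independent explicit oracle
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-8)
        assert fit.sse == pytest.approx(np.sum((y - A @ beta) ** 2), abs=1e-8)

    def test_residuals_sum_to_zero_with_intercept(self, rng):
        fit = lslr_fit(rng.standard_normal((15, 2)), rng.standard_normal(15))
        assert abs(fit.residuals.sum()) < 1e-8

    def test_sse_never_exceeds_zero_model(self, rng):
        X = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        assert lslr_fit(X, y).sse <= float(y @ y) + 1e-12

    def test_rank_deficiency_names_offending_columns(self, rng):
        X = rng.standard_normal((12, 2))
        X = np.column_stack([X, X[:, 0] * 2.0])  # column 2 duplicates column 0
        with pytest.raises(SingularDesignError) as exc:
            lslr_fit(X, rng.standard_normal(12))
        assert len(exc.value.columns) == 1


class TestReduceDimensions:
    def test_lh2_shape_partitions_into_width_ten_windows(self):
        wmap = window_partition(12533, 1253)
        widths = [b - a for a, b in wmap]
        assert len(wmap) == 1253
        assert widths[:-1] == [10] * 1252 and widths[-1] == 13
        # exact, ordered, half-open cover
        assert wmap[0][0] == 0 and wmap[-1][1] == 12533
        assert all(wmap[i][1] == wmap[i + 1][0] for i in range(1252))

    def test_every_method_emits_target_dim_features(self, small_matrix):
        for method in ("HT", "DFA", "LSLR"):
            r = reduce_dimensions(small_matrix, method, target_dim=100)
            assert r.values.shape == (80, 100)
            assert r.window_map[-1][1] == small_matrix.n_genes

    def test_constant_vector_under_ht_yields_constant_envelope(self):
        m = ExpressionMatrix(values=np.full((40, 5), 3.0),
                             gene_ids=[f"g{i}" for i in range(40)],
                             sample_ids=[f"s{i}" for i in range(5)],
                             labels=["Adeno"] * 3 + ["Meso"] * 2)
        r = reduce_dimensions(m, "HT", target_dim=4)
        np.testing.assert_allclose(r.values, 3.0, atol=1e-9)

    def test_output_independent_of_sample_order(self, small_matrix):
        r = reduce_dimensions(small_matrix, "DFA", target_dim=50)
        perm = np.random.default_rng(0).permutation(small_matrix.n_samples)
        shuffled = ExpressionMatrix(
            values=small_matrix.values[:, perm],
            gene_ids=small_matrix.gene_ids,
            sample_ids=[small_matrix.sample_ids[i] for i in perm],
            labels=[small_matrix.labels[i] for i in perm],
        )
        r2 = reduce_dimensions(shuffled, "DFA", target_dim=50)
        np.testing.assert_allclose(r2.values, r.values[perm], atol=1e-12)

    def test_planted_windows_separate_classes_more_than_background(self):
        """Windows overlapping planted blocks carry larger between-class
        feature shifts than background windows, across seeds and methods."""
        for method in ("HT", "DFA", "LSLR"):
            wins = 0
            for seed in range(10):
                spec = SimulationSpec(n_genes=1000, n_adeno=30, n_meso=10,
                                      n_informative_blocks=5, block_width=50,
                                      effect_size=2.0, seed=seed)
                m = generate_expression(spec)
                r = reduce_dimensions(m, method, target_dim=100)
                labels = np.asarray(r.labels)
                gap = np.abs(r.values[labels == "Adeno"].mean(axis=0)
                             - r.values[labels == "Meso"].mean(axis=0))
                planted = np.zeros(100, dtype=bool)
                for a, b in m.metadata["informative_blocks"]:
                    for j, (wa, wb) in enumerate(r.window_map):
                        if wa < b and a < wb:
                            planted[j] = True
                wins += gap[planted].mean() > gap[~planted].mean()
            assert wins >= 8, f"{method}: planted windows won only {wins}/10 seeds"

    def test_unknown_method_rejected(self, small_matrix):
        with pytest.raises(ConfigError):
            reduce_dimensions(small_matrix, "PCA")
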
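import numpy as np
import pandas as pd
import pytest

from gsemkit.ldsc import (LDScoreTable, ReferencePanel, SVMatrices, build_S_V,
                          estimate_gcov, estimate_h2, ld_scores,
                          read_reference_panel, read_sv, smooth_to_psd,
                          to_correlation, unvech, vech, vech_indices,
                          write_sv)
from gsemkit.simulate import (make_architecture, make_ld_scores,
                              simulate_sumstats_direct)
from gsemkit.sumstats import harmonize


def _panel_from_dosages(dosages):
    m = dosages.shape[0]
    variants = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(m)],
        "chrom": "1", "pos": np.arange(1, m + 1),
        "allele_effect": "A", "allele_other": "G",
    })
    return ReferencePanel(variants, dosages)


class TestVech:
    def test_order_is_column_major_lower(self):
        # frozen convention: (0,0),(1,0),(2,0),(1,1),(2,1),(2,2)
        assert vech_indices(3) == [(0, 0), (1, 0), (2, 0), (1, 1), (2, 1), (2, 2)]

    def test_roundtrip(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((5, 5))
        a = a + a.T
        np.testing.assert_array_equal(unvech(vech(a)), a)

    def test_bad_length(self):
        with pytest.raises(ValueError):
            unvech(np.zeros(5))


class TestLdScores:
    def test_independent_variants_score_near_one(self):
        rng = np.random.default_rng(0)
        panel = _panel_from_dosages(
            rng.binomial(2, 0.5, size=(30, 5000)).astype(float))
        scores = ld_scores(panel, window=29).ldscore
        # bias-corrected cross terms vanish in expectation; self term = 1
        assert np.all(np.abs(scores - 1) < 0.15)

    def test_duplicated_variant_scores_two(self):
        rng = np.random.default_rng(1)
        row = rng.binomial(2, 0.5, size=5000).astype(float)
        other = rng.binomial(2, 0.5, size=5000).astype(float)
        panel = _panel_from_dosages(np.vstack([row, row, other]))
        scores = ld_scores(panel, window=2).ldscore
        assert scores[0] == pytest.approx(2.0, abs=0.1)
        assert scores[1] == pytest.approx(2.0, abs=0.1)

    def test_matches_bruteforce_exactly(self):
        # 50 correlated variants: compare windowed sum against an all-pairs
        # double loop (window covers the whole panel)
        rng = np.random.default_rng(2)
        latent = rng.standard_normal((5, 200))
        dos = np.zeros((50, 200))
        for j in range(50):
            mix = 0.7 * latent[j % 5] + 0.3 * rng.standard_normal(200)
            dos[j] = np.digitize(mix, [-0.5, 0.5])
        panel = _panel_from_dosages(dos)
        got = ld_scores(panel, window=49).ldscore
        n = 200
        xs = (dos - dos.mean(1, keepdims=True)) / dos.std(1, keepdims=True)
        expected = np.zeros(50)
        for j in range(50):
            for k in range(50):
                if j == k:
                    expected[j] += 1.0
                    continue
                r2 = (np.dot(xs[j], xs[k]) / n) ** 2
                expected[j] += r2 - (1 - r2) / (n - 2)
        np.testing.assert_allclose(got, np.maximum(expected, 0), atol=1e-12)

    def test_monomorphic_warns_and_scores(self):
        rng = np.random.default_rng(3)
        dos = rng.binomial(2, 0.5, (5, 100)).astype(float)
        dos[2] = 2.0
        panel = _panel_from_dosages(dos)
        with pytest.warns(UserWarning, match="monomorphic"):
            scores = ld_scores(panel, window=4).ldscore
        assert np.isfinite(scores).all()

    def test_too_few_samples(self):
        panel = _panel_from_dosages(np.ones((3, 2)))
        with pytest.raises(ValueError, match="3 samples"):
            ld_scores(panel)

    def test_reference_panel_roundtrip(self, tmp_path):
        rng = np.random.default_rng(4)
        panel = _panel_from_dosages(rng.binomial(2, 0.4, (10, 20)).astype(float))
        panel.write(tmp_path / "ref")
        back = read_reference_panel(tmp_path / "ref")
        np.testing.assert_array_equal(back.dosages, panel.dosages)
        assert back.variants["variant_id"].tolist() == \
            panel.variants["variant_id"].tolist()


class TestEstimateH2:
    def test_hand_ols_oracle(self):
        # 3 points, l=(1,2,3), z^2=(1.1,1.2,1.3), N=1000, M=3, unit weights:
        # OLS slope on x=N*l/M is 0.1*M/N = 3e-4
        ld = LDScoreTable(np.array(["a", "b", "c"]), np.array([1.0, 2.0, 3.0]), 3)
        z = np.sqrt([1.1, 1.2, 1.3])
        est = estimate_h2(z, 1000.0, ld, n_blocks=3, unit_weights=True)
        assert est.estimate == pytest.approx(3.0e-4, rel=1e-10)
        assert est.intercept == pytest.approx(1.0, rel=1e-9)

    def test_null_simulation(self):
        rng = np.random.default_rng(10)
        m = 5000
        ld = make_ld_scores(m, seed=10)
        z = rng.standard_normal(m)  # h2 = 0, intercept 1
        est = estimate_h2(z, 50_000.0, ld, n_blocks=200)
        assert abs(est.estimate) < 2 * est.se_jackknife
        assert abs(est.intercept - 1) < 3 * est.intercept_se

    def test_h2_halves_when_n_doubles_at_fixed_z(self):
        # E[z^2] unchanged while N doubles <=> true per-SNP effects halved;
        # the estimator must attribute half the h2
        ld = make_ld_scores(3000, seed=11)
        arch = make_architecture("small", M=3000, N=40_000, seed=12)
        panel = harmonize(simulate_sumstats_direct(arch, ld))
        z, n = panel.z[:, 0], panel.n[:, 0]
        e1 = estimate_h2(z, n, ld, n_blocks=100)
        e2 = estimate_h2(z, 2 * n, ld, n_blocks=100)
        assert e2.estimate == pytest.approx(e1.estimate / 2, rel=1e-6)

    def test_recovery(self):
        ld = make_ld_scores(5000, seed=13)
        arch = make_architecture("small", M=5000, N=50_000, seed=13)
        panel = harmonize(simulate_sumstats_direct(arch, ld))
        est = estimate_h2(panel.z[:, 0], panel.n[:, 0], ld, n_blocks=200)
        assert abs(est.estimate - arch.h2[0]) < 3 * est.se_jackknife

    def test_errors(self):
        ld = make_ld_scores(100, seed=1)
        with pytest.raises(ValueError, match="blocks"):
            estimate_h2(np.zeros(100), 100.0, ld, n_blocks=101)
        z = np.zeros(100)
        z[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            estimate_h2(z, 100.0, ld, n_blocks=10)
        with pytest.raises(ValueError, match="aligned"):
            estimate_h2(np.zeros(50), 100.0, ld, n_blocks=10)


class TestEstimateGcov:
    def test_self_covariance_equals_h2(self, small_panel, small_ld):
        z, n = small_panel.z[:, 0], small_panel.n[:, 0]
        # exact identity under shared (unit) weights
        h2u = estimate_h2(z, n, small_ld, n_blocks=50, unit_weights=True)
        gu = estimate_gcov(z, z, n, n, small_ld, n_blocks=50,
                           unit_weights=True)
        assert gu.estimate == pytest.approx(h2u.estimate, rel=1e-12)
        # near-identity under the default two-pass weights (which differ
        # between the variance and covariance estimators)
        h2 = estimate_h2(z, n, small_ld, n_blocks=50)
        g = estimate_gcov(z, z, n, n, small_ld, n_blocks=50)
        assert g.estimate == pytest.approx(h2.estimate, rel=0.02)

    def test_null_gcov_within_2se(self):
        ld = make_ld_scores(4000, seed=20)
        arch = make_architecture("null", M=4000, N=30_000, seed=20)
        panel = harmonize(simulate_sumstats_direct(arch, ld))
        g = estimate_gcov(panel.z[:, 0], panel.z[:, 1], panel.n[:, 0],
                          panel.n[:, 1], ld, n_blocks=200)
        assert abs(g.estimate) < 2.5 * g.se_jackknife

    def test_rg_recovery(self):
        ld = make_ld_scores(8000, seed=21)
        arch = make_architecture("small", M=8000, N=50_000, seed=21)
        panel = harmonize(simulate_sumstats_direct(arch, ld))
        g = estimate_gcov(panel.z[:, 0], panel.z[:, 1], panel.n[:, 0],
                          panel.n[:, 1], ld, n_blocks=200)
        ha = estimate_h2(panel.z[:, 0], panel.n[:, 0], ld, n_blocks=200)
        hb = estimate_h2(panel.z[:, 1], panel.n[:, 1], ld, n_blocks=200)
        rg = g.estimate / np.sqrt(ha.estimate * hb.estimate)
        true_rg = arch.sigma_g_std[0, 1]
        assert abs(rg - true_rg) < 0.1


class TestBuildSV:
    def test_duplicate_trait_correlation_one(self, small_ld):
        arch = make_architecture("small", M=2000, N=50_000, seed=30)
        tabs = simulate_sumstats_direct(arch, small_ld)[:1]
        dup = tabs[0].df.copy()
        from gsemkit.sumstats import SumstatsTable
        panel = harmonize([tabs[0], SumstatsTable("copy", dup)])
        svu = build_S_V(panel, small_ld, n_blocks=50, unit_weights=True)
        assert to_correlation(svu).S[0, 1] == pytest.approx(1.0, abs=1e-12)
        sv = build_S_V(panel, small_ld, n_blocks=50)
        assert to_correlation(sv).S[0, 1] == pytest.approx(1.0, abs=0.01)

    def test_recovery_within_3se(self, small_panel, small_ld, small_arch):
        sv = build_S_V(small_panel, small_ld, n_blocks=100)
        se = np.sqrt(np.diag(sv.V))
        err = np.abs(vech(sv.S) - vech(small_arch.sigma_g))
        assert np.all(err <= 3.3 * se)

    def test_v_diagonal_matches_pairwise_se(self, small_panel, small_ld):
        sv = build_S_V(small_panel, small_ld, n_blocks=100)
        se = np.sqrt(np.diag(sv.V))
        pairs = vech_indices(small_panel.n_traits)
        for p, (i, j) in enumerate(pairs):
            if i == j:
                est = estimate_h2(small_panel.z[:, i], small_panel.n[:, i],
                                  small_ld, n_blocks=100)
            else:
                est = estimate_gcov(small_panel.z[:, i], small_panel.z[:, j],
                                    small_panel.n[:, i], small_panel.n[:, j],
                                    small_ld, n_blocks=100)
            assert abs(est.se_jackknife - se[p]) < 1e-10
            assert abs(est.estimate - sv.S[i, j]) < 1e-10

    def test_trait_reorder_consistency(self, small_panel, small_ld):
        sv = build_S_V(small_panel, small_ld, n_blocks=100)
        perm = [2, 0, 3, 1]
        sub = type(small_panel)(
            traits=[small_panel.traits[i] for i in perm],
            variants=small_panel.variants,
            z=small_panel.z[:, perm], n=small_panel.n[:, perm],
            freq=small_panel.freq[:, perm],
        )
        sv2 = build_S_V(sub, small_ld, n_blocks=100)
        np.testing.assert_allclose(sv2.S,
                                   sv.S[np.ix_(perm, perm)], atol=1e-10)
        np.testing.assert_allclose(sv2.V, sv.reorder(sv2.traits).V, atol=1e-10)

    def test_needs_two_traits(self, small_panel, small_ld):
        one = small_panel.subset(np.ones(small_panel.n_variants, bool))
        one.traits = one.traits[:1]
        one.z = one.z[:, :1]
        one.n = one.n[:, :1]
        one.freq = one.freq[:, :1]
        with pytest.raises(ValueError, match="2 traits"):
            build_S_V(one, small_ld)


class TestToCorrelation:
    def test_hand_arithmetic(self):
        s = np.array([[0.25, 0.1], [0.1, 0.16]])
        v = np.eye(3) * 1e-4
        std = to_correlation(SVMatrices(["a", "b"], s, v))
        assert std.S[0, 1] == pytest.approx(0.5)

    def test_diagonal_exactly_one(self, small_sv):
        std = to_correlation(small_sv)
        np.testing.assert_array_equal(np.diag(std.S), 1.0)

    def test_idempotent(self, small_sv):
        s1 = to_correlation(small_sv)
        s2 = to_correlation(s1)
        np.testing.assert_allclose(s1.S, s2.S, atol=1e-12)

    def test_entries_in_unit_interval_after_smoothing(self, small_sv):
        std = to_correlation(small_sv.smooth())
        sm = smooth_to_psd(std.S)
        assert np.all(np.abs(sm) <= 1 + 1e-8)

    def test_nonpositive_h2_errors(self):
        s = np.array([[0.0, 0.1], [0.1, 0.16]])
        with pytest.raises(ValueError, match="smooth"):
            to_correlation(SVMatrices(["a", "b"], s, np.eye(3)))

    def test_delta_method_matches_bruteforce_jackknife(self, small_panel,
                                                       small_ld):
        # independent oracle: standardize every delete-block S directly and
        # jackknife those; delta-method V must agree to first order
        from gsemkit.ldsc import _jackknife_wls, _provisional_h2, _h2_weights, \
            _gcov_weights
        sv = build_S_V(small_panel, small_ld, n_blocks=100)
        std = to_correlation(sv)
        se_delta = np.sqrt(np.diag(std.V))
        # brute force via pseudo-replicates of the full pipeline
        k = small_panel.n_traits
        pairs = vech_indices(k)
        m = small_panel.n_variants
        y = np.empty((m, len(pairs)))
        x = np.empty((m, len(pairs)))
        w = np.empty((m, len(pairs)))
        h2p = [_provisional_h2(small_panel.z[:, t], small_panel.n[:, t],
                               small_ld) for t in range(k)]
        for idx, (i, j) in enumerate(pairs):
            zi, zj = small_panel.z[:, i], small_panel.z[:, j]
            ni, nj = small_panel.n[:, i], small_panel.n[:, j]
            y[:, idx] = zi * zj
            x[:, idx] = np.sqrt(ni * nj) * small_ld.ldscore / small_ld.M
            if i == j:
                w[:, idx] = _h2_weights(ni, small_ld, h2p[i])
            else:
                xc = x[:, idx] - x[:, idx].mean()
                rho = float((xc * (y[:, idx] - y[:, idx].mean())).sum()
                            / (xc ** 2).sum())
                rho = min(max(rho, -1.0), 1.0)
                w[:, idx] = _gcov_weights(ni, nj, small_ld, h2p[i], h2p[j],
                                          rho, 0.0)
        _, delete, _, _ = _jackknife_wls(y, x, w, 100, True)
        slopes = delete[:, 1, :]  # (B, P)
        pos = {pair: q for q, pair in enumerate(pairs)}
        rg_del = np.empty_like(slopes)
        for q, (i, j) in enumerate(pairs):
            rg_del[:, q] = slopes[:, q] / np.sqrt(
                slopes[:, pos[(i, i)]] * slopes[:, pos[(j, j)]])
        b = 100
        center = rg_del - rg_del.mean(0)
        se_bf = np.sqrt((b - 1) / b * (center ** 2).sum(0))
        offdiag = [q for q, (i, j) in enumerate(pairs) if i != j]
        np.testing.assert_allclose(se_delta[offdiag], se_bf[offdiag], rtol=0.1)


class TestSmoothToPsd:
    def test_psd_fixed_point(self):
        a = np.array([[2.0, 0.5], [0.5, 1.0]])
        np.testing.assert_array_equal(smooth_to_psd(a), a)

    def test_eigen_oracle(self):
        a = np.array([[1.0, 1.2], [1.2, 1.0]])
        vals = np.linalg.eigvalsh(a)
        assert vals.min() == pytest.approx(-0.2)
        out = smooth_to_psd(a)
        assert np.linalg.eigvalsh(out).min() >= 0
        np.testing.assert_allclose(out, out.T)
        # positive eigenvector direction untouched
        assert np.linalg.eigvalsh(out).max() == pytest.approx(2.2)

    def test_min_eigenvalue_at_least_floor(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.standard_normal((6, 6))
            a = (a + a.T) / 2
            out = smooth_to_psd(a)
            floor = 1e-8 * max(np.linalg.eigvalsh(a).max(), 1e-8)
            assert np.linalg.eigvalsh(out).min() >= floor - 1e-12

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            smooth_to_psd(np.array([[1.0, 2.0], [0.0, 1.0]]))


def test_sv_serialization_roundtrip(tmp_path, small_sv):
    write_sv(small_sv, tmp_path / "sv")
    back = read_sv(tmp_path / "sv")
    assert back.traits == small_sv.traits
    np.testing.assert_allclose(back.S, small_sv.S, atol=1e-12)
    np.testing.assert_allclose(back.V, small_sv.V, atol=1e-12)


def test_ldscore_table_io(tmp_path):
    t = make_ld_scores(50, seed=9)
    t.write(tmp_path / "l.tsv")
    back = LDScoreTable.read(tmp_path / "l.tsv")
    assert back.M == t.M
    np.testing.assert_allclose(back.ldscore, t.ldscore)
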
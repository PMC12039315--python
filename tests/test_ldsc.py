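import numpy as np
import pytest
from scipy import stats

from genosem import (FactorArchitecture, GeneticCovariance, LDSCOptions,
                     build_S_V, ldsc_bivariate, ldsc_univariate, make_ld_panel,
                     simulate_zscores, standardize, unvech, vech, vech_indices)
from genosem.ldsc import _pair_regression
from genosem.simulate import SumStatsSet
from conftest import SYNTH_OPTS


def _ss(panel, Z, N):
    k = Z.shape[1]
    return SumStatsSet(panel, [f"t{i}" for i in range(k)], Z,
                       np.asarray(N), panel.a1, panel.a2)


# ---------------------------------------------------------------------------
# vech bookkeeping


def test_vech_round_trip_and_ordering():
    assert vech_indices(3) == [(0, 0), (1, 0), (2, 0), (1, 1), (2, 1), (2, 2)]
    rng = np.random.default_rng(0)
    A = rng.normal(size=(5, 5))
    A = A + A.T
    assert np.allclose(unvech(vech(A)), A)


# ---------------------------------------------------------------------------
# univariate / bivariate regressions


def test_constant_unit_chisq_gives_zero_h2(small_panel):
    z = np.ones(small_panel.n_snps)
    reg = ldsc_univariate(z, 10_000, small_panel)
    assert reg.slope == pytest.approx(0.0, abs=1e-12)
    assert reg.intercept == pytest.approx(1.0, abs=1e-12)


def test_four_snp_toy_matches_closed_form_wls():
    panel = make_ld_panel(4, 2, 1.0, seed=0)
    panel.ld_score[:] = [1.0, 2.0, 5.0, 10.0]
    z = np.array([0.5, -1.0, 2.0, 1.5])
    N = 1000
    reg = _pair_regression(z, z, N, N, panel, 0.0, 0.0,
                           LDSCOptions(weights="unit", max_chisq=None))
    x = N * panel.ld_score / panel.M
    X = np.column_stack([np.ones(4), x])
    beta = np.linalg.lstsq(X, z * z, rcond=None)[0]
    assert reg.intercept == pytest.approx(beta[0], rel=1e-10)
    assert reg.slope == pytest.approx(beta[1], rel=1e-10)


def test_self_covariance_equals_heritability(small_panel, k2_arch):
    ss = simulate_zscores(small_panel, k2_arch, seed=1)
    z = ss.Z[:, 0]
    uni = ldsc_univariate(z, 50_000, small_panel)
    biv = ldsc_bivariate(z, z, 50_000, 50_000, small_panel)
    assert biv.slope == pytest.approx(uni.slope, rel=1e-12)
    assert biv.intercept == pytest.approx(uni.intercept, rel=1e-12)
    assert np.allclose(biv.slope_delete, uni.slope_delete)


def test_independent_traits_have_null_covariance(small_panel):
    arch = FactorArchitecture(
        ["x", "y"], np.zeros((2, 1)), np.eye(1), np.eye(2),
        h2=np.array([0.3, 0.3]), N=np.full(2, 50_000),
    )
    ss = simulate_zscores(small_panel, arch, seed=21)
    reg = ldsc_bivariate(ss.Z[:, 0], ss.Z[:, 1], 50_000, 50_000, small_panel,
                         SYNTH_OPTS)
    assert abs(reg.slope) < 3 * reg.slope_se


def test_overlap_intercept_and_covariance_recovered(k2_arch):
    panel = make_ld_panel(20_000, 200, 50.0, seed=13)
    ss = simulate_zscores(panel, k2_arch, seed=14)
    reg = ldsc_bivariate(ss.Z[:, 0], ss.Z[:, 1], 50_000, 50_000, panel,
                         SYNTH_OPTS)
    assert abs(reg.slope - 0.2) < 3 * reg.slope_se
    assert abs(reg.intercept - 0.5) < 3 * reg.intercept_se


def test_too_few_snps_and_constant_ld_rejected():
    panel = make_ld_panel(20, 15, 5.0, seed=0)
    z = np.random.default_rng(0).normal(size=20)
    with pytest.raises(ValueError, match="jackknife blocks"):
        ldsc_univariate(z, 1000, panel)
    flat = make_ld_panel(100, 5, 1.0, seed=0)
    with pytest.raises(ValueError, match="unidentified"):
        ldsc_univariate(np.ones(100), 1000, flat)


# ---------------------------------------------------------------------------
# S / V assembly


def test_duplicated_traits_give_equal_S_and_V_entries(small_panel):
    arch = FactorArchitecture(
        ["x", "xcopy"], np.zeros((2, 1)), np.eye(1), np.ones((2, 2)),
        h2=np.array([0.3, 0.3]), N=np.full(2, 40_000),
        N_overlap=np.full((2, 2), 40_000.0), pheno_corr=np.ones((2, 2)),
    )
    ss = simulate_zscores(small_panel, arch, seed=3)
    gc = build_S_V(ss, small_panel, SYNTH_OPTS)
    assert np.allclose(gc.S, gc.S[0, 0])
    # vech order (0,0), (1,0), (1,1): all three slopes identical regressions
    assert gc.V[0, 0] == pytest.approx(gc.V[1, 1], rel=1e-10)
    assert gc.V[0, 0] == pytest.approx(gc.V[2, 2], rel=1e-10)


def test_jackknife_matches_brute_force_refit():
    """V must equal a from-scratch leave-one-block-out refit of every
    regression (200 SNPs, 3 traits, 4 blocks, unit weights)."""
    panel = make_ld_panel(200, 4, 10.0, seed=17)
    lam = np.array([[0.8], [0.6], [0.5]])
    arch = FactorArchitecture(
        ["a", "b", "c"], lam, np.eye(1),
        np.diag(1 - (lam ** 2).ravel()),
        h2=np.full(3, 0.4), N=np.full(3, 20_000),
    )
    ss = simulate_zscores(panel, arch, seed=18)
    gc = build_S_V(ss, panel, SYNTH_OPTS)

    idx = vech_indices(3)
    nb = panel.n_blocks
    deletes = np.zeros((nb, len(idx)))
    x_base = panel.ld_score / panel.M
    for b in range(nb):
        keep = panel.block_id != b
        for c, (i, j) in enumerate(idx):
            x = np.sqrt(float(ss.N[i]) * ss.N[j]) * x_base[keep]
            y = ss.Z[keep, i] * ss.Z[keep, j]
            X = np.column_stack([np.ones(keep.sum()), x])
            deletes[b, c] = np.linalg.lstsq(X, y, rcond=None)[0][1]
    centered = deletes - deletes.mean(axis=0)
    V_brute = (nb - 1) / nb * centered.T @ centered
    assert np.allclose(gc.V, V_brute, atol=1e-10)


def test_jackknife_V_is_psd(preset_sim_gc):
    eig = np.linalg.eigvalsh((preset_sim_gc.V + preset_sim_gc.V.T) / 2)
    assert eig.min() > -1e-10


def test_permutation_equivariance(small_panel):
    arch = FactorArchitecture(
        ["a", "b", "c"], np.array([[0.8], [0.6], [0.5]]), np.eye(1),
        np.diag([0.36, 0.64, 0.75]), h2=np.full(3, 0.4),
        N=np.full(3, 20_000),
    )
    ss = simulate_zscores(small_panel, arch, seed=5)
    gc = build_S_V(ss, small_panel, SYNTH_OPTS)
    order = [2, 0, 1]
    perm = gc.permute(order)
    ss_perm = SumStatsSet(small_panel, [ss.trait_names[o] for o in order],
                          ss.Z[:, order], ss.N[order], ss.a1, ss.a2)
    direct = build_S_V(ss_perm, small_panel, SYNTH_OPTS)
    assert direct.trait_names == perm.trait_names
    assert np.allclose(direct.S, perm.S, atol=1e-12)
    assert np.allclose(direct.V, perm.V, atol=1e-12)
    # round trip back
    inv = [order.index(i) for i in range(3)]
    back = perm.permute(inv)
    assert np.allclose(back.S, gc.S) and np.allclose(back.V, gc.V)


# ---------------------------------------------------------------------------
# standardization


def test_standardize_hand_example():
    S = np.array([[0.4, 0.1], [0.1, 0.1]])
    gc = GeneticCovariance(["a", "b"], S, 0.01 * np.eye(3), np.eye(2),
                           "covariance", 4)
    std = standardize(gc)
    assert std.S[0, 1] == pytest.approx(0.5)
    assert np.allclose(np.diag(std.S), 1.0)
    assert np.allclose(std.V[0, :], 0.0) and np.allclose(std.V[2, :], 0.0)


def test_delta_method_matches_numerical_jacobian():
    rng = np.random.default_rng(8)
    k = 3
    A = rng.normal(size=(k, k))
    S = A @ A.T + k * np.eye(k)
    c = k * (k + 1) // 2
    B = rng.normal(size=(c, c))
    V = 1e-4 * (B @ B.T)
    gc = GeneticCovariance(["a", "b", "c"], S, V, np.eye(k), "covariance", 10)
    std = standardize(gc)

    def corr_map(s_vec):
        M = unvech(s_vec)
        d = np.sqrt(np.diag(M))
        return vech(M / np.outer(d, d))

    s0 = vech(S)
    J = np.zeros((c, c))
    for t in range(c):
        h = 1e-7 * max(1.0, abs(s0[t]))
        up, dn = s0.copy(), s0.copy()
        up[t] += h; dn[t] -= h
        J[:, t] = (corr_map(up) - corr_map(dn)) / (2 * h)
    V_num = J @ V @ J.T
    off = [i for i, (a, b) in enumerate(vech_indices(k)) if a != b]
    assert np.allclose(std.V[np.ix_(off, off)], V_num[np.ix_(off, off)],
                       rtol=1e-8, atol=1e-14)


def test_standardize_refuses_nonpositive_heritability():
    S = np.array([[-0.01, 0.0], [0.0, 0.1]])
    gc = GeneticCovariance(["bad", "ok"], S, np.eye(3), np.eye(2),
                           "covariance", 4)
    with pytest.raises(ValueError, match="bad"):
        standardize(gc)


def test_null_zscores_standard_normal():
    """With h2 = 0 and no overlap, off-diagonal S/SE should be N(0,1)."""
    arch = FactorArchitecture(
        ["x", "y"], np.zeros((2, 1)), np.eye(1), np.eye(2),
        h2=np.zeros(2), N=np.full(2, 30_000),
    )
    panel = make_ld_panel(2000, 50, 20.0, seed=2)
    zstats = []
    for rep in range(80):
        ss = simulate_zscores(panel, arch, seed=400 + rep)
        gc = build_S_V(ss, panel, SYNTH_OPTS)
        se = np.sqrt(gc.V[1, 1])
        zstats.append(gc.S[0, 1] / se)
    _, p = stats.kstest(zstats, "norm")
    assert p > 0.01


def test_serialization_round_trip(tmp_path, preset_sim_gc):
    path = tmp_path / "SV.json"
    preset_sim_gc.to_json(str(path))
    back = GeneticCovariance.from_json(str(path))
    assert back.trait_names == preset_sim_gc.trait_names
    assert np.allclose(back.S, preset_sim_gc.S)
    assert np.allclose(back.V, preset_sim_gc.V)
    assert back.metric == "correlation"
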
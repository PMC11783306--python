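import warnings as _warnings

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from permlmm import (
    ModelPair,
    build_projector,
    compile_null,
    decorrelate,
    derive_threshold,
    draw_permutation,
    fit_null,
    permute_once,
    prepare_gwas,
)
from permlmm.errors import PermLMMError
from permlmm.lmm_core import DecorrelatedProblem
from permlmm.model_spec import DesignMatrix
from permlmm.variance_components import VarianceComponents

from conftest import make_aligned


def _vc(sg, se):
    return VarianceComponents(sg, se, sg / (sg + se), 0.0, 0, True)


def _problem(rng, n, q0, sg=0.5, se=0.5):
    A = rng.standard_normal((n, n))
    K = A @ A.T / n
    cols = [np.ones(n)] + [rng.standard_normal(n) for _ in range(q0 - 1)]
    X0 = DesignMatrix(np.column_stack(cols), [f"c{i}" for i in range(q0)])
    y = rng.standard_normal(n)
    dp = decorrelate(y, X0, K, _vc(sg, se))
    return dp, fit_null(dp)


def test_projector_spectrum_intercept_only():
    rng = np.random.default_rng(0)
    dp, nf = _problem(rng, 5, 1)
    rp = build_projector(dp, nf)
    assert rp.U1.shape == (5, 4)
    np.testing.assert_allclose(rp.U1.T @ rp.U1, np.eye(4), atol=1e-8)


def test_projector_rank_matches_svd_oracle():
    rng = np.random.default_rng(1)
    dp, nf = _problem(rng, 30, 4)
    rp = build_projector(dp, nf)
    V = np.eye(30) - dp.X0mm @ np.linalg.solve(dp.X0mm.T @ dp.X0mm, dp.X0mm.T)
    rank = int(np.sum(np.linalg.svd(V, compute_uv=False) > 1e-8))
    assert rank == 26 == rp.dim
    # V U1 = U1: U1 spans the unit-eigenvalue space
    np.testing.assert_allclose(V @ rp.U1, rp.U1, atol=1e-8)


def test_empty_null_design_gives_identity_projector():
    rng = np.random.default_rng(2)
    n = 8
    dp = decorrelate(
        rng.standard_normal(n), DesignMatrix(np.empty((n, 0)), []), np.eye(n), _vc(0.2, 0.8)
    )
    nf = fit_null(dp)
    rp = build_projector(dp, nf)
    assert rp.dim == n
    perm = np.arange(n)[::-1]
    np.testing.assert_allclose(
        permute_once(rp, nf, perm), (rp.U1 @ (rp.U1.T @ dp.ymm)[perm]), atol=1e-10
    )


def test_identity_permutation_recovers_phenotype():
    rng = np.random.default_rng(3)
    dp, nf = _problem(rng, 20, 3)
    rp = build_projector(dp, nf)
    np.testing.assert_allclose(permute_once(rp, nf, np.arange(rp.dim)), dp.ymm, atol=1e-8)


def test_permutation_preserves_norm_and_null_fit():
    rng = np.random.default_rng(4)
    dp, nf = _problem(rng, 20, 3)
    rp = build_projector(dp, nf)
    for _ in range(10):
        perm = rng.permutation(rp.dim)
        y_pi = permute_once(rp, nf, perm)
        # ||zeta_pi|| == ||zeta|| exactly => residual norm preserved
        assert np.linalg.norm(y_pi - nf.fitted0) == pytest.approx(
            np.linalg.norm(nf.emm), abs=1e-8
        )
        # regressing y_pi on X0mm returns the original fitted values
        beta = np.linalg.lstsq(dp.X0mm, y_pi, rcond=None)[0]
        np.testing.assert_allclose(dp.X0mm @ beta, nf.fitted0, atol=1e-8)


def test_permuted_residual_covariance_matches_exact_expectation():
    """Monte-Carlo mean of e_pi e_pi^T matches the exact expectation over
    uniform permutations: (c1 - c2) V + c2 u u^T with c1 = ||zeta||^2/d,
    c2 = ((1^T zeta)^2 - ||zeta||^2)/(d(d-1)) and u = U1 1 — i.e. ~ V up to
    a rank-one correction from the nonzero permutation-invariant mean."""
    rng = np.random.default_rng(5)
    n, q0 = 20, 2
    dp, nf = _problem(rng, n, q0)
    rp = build_projector(dp, nf)
    acc = np.zeros((n, n))
    n_perm = 2000
    for _ in range(n_perm):
        e_pi = permute_once(rp, nf, rng.permutation(rp.dim)) - nf.fitted0
        acc += np.outer(e_pi, e_pi)
    acc /= n_perm
    d = rp.dim
    zeta = rp.U1.T @ nf.emm
    c1 = (zeta @ zeta) / d
    c2 = ((zeta.sum()) ** 2 - zeta @ zeta) / (d * (d - 1))
    u = rp.U1 @ np.ones(d)
    V = rp.U1 @ rp.U1.T
    expected = (c1 - c2) * V + c2 * np.outer(u, u)
    assert np.linalg.norm(acc - expected) / np.linalg.norm(expected) < 0.1
    # and the dominant term is the projector itself
    assert np.linalg.norm(expected - c1 * V) < 0.5 * np.linalg.norm(expected)


def test_invalid_permutation_rejected():
    rng = np.random.default_rng(6)
    dp, nf = _problem(rng, 10, 1)
    rp = build_projector(dp, nf)
    with pytest.raises(PermLMMError):
        permute_once(rp, nf, np.zeros(rp.dim, dtype=int))


def test_draw_permutation_deterministic_and_replicate_independent():
    a = draw_permutation(7, 3, 50)
    b = draw_permutation(7, 3, 50)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, draw_permutation(7, 4, 50))
    assert not np.array_equal(a, draw_permutation(8, 3, 50))


@pytest.fixture(scope="module")
def prepared():
    data, _ = make_aligned(n=80, n_chromosomes=2, variants_per_chrom=30, seed=21,
                           h2_target=0.4)
    return prepare_gwas(data, ModelPair("y ~ x", "y ~ 1"))


def test_null_scan_deterministic(prepared):
    m1 = prepared.engine.null_scan(5, 123)
    m2 = prepared.engine.null_scan(5, 123)
    assert m1 == m2  # bitwise


def test_single_variant_identity_permutation_composition():
    """With one variant and the identity permutation, the permuted minimum
    equals the unpermuted p-value."""
    data, _ = make_aligned(n=40, n_chromosomes=1, variants_per_chrom=1, seed=22,
                           structure="none")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prep = prepare_gwas(data, ModelPair("y ~ x", "y ~ 1"), allow_non_loco=True)
    unit = prep.engine.units["1"]
    y_pi = permute_once(unit.projector, unit.nf, np.arange(unit.projector.dim))
    e_pi = y_pi - unit.nf.fitted0
    min_p = unit.scanner.min_p(y_pi, float(e_pi @ e_pi))
    raw = prep.scan_genome()[0].p_value
    assert min_p == pytest.approx(raw, rel=1e-8)


def test_permuted_scan_pvalues_near_uniform():
    """Within one permutation replicate the per-variant p-values are ~U(0,1)."""
    data, _ = make_aligned(n=100, n_chromosomes=4, variants_per_chrom=50, seed=23,
                           h2_target=0.5, background_loci=2000)
    engine = prepare_gwas(data, ModelPair("y ~ x", "y ~ 1")).engine
    perm = draw_permutation(99, 1, 100 - 1)
    ps = []
    for unit in engine.units.values():
        y_pi = permute_once(unit.projector, unit.nf, perm)
        e_pi = y_pi - unit.nf.fitted0
        for r in unit.scanner.scan(ymm=y_pi, rss0=float(e_pi @ e_pi)):
            if not r.degenerate:
                ps.append(r.p_value)
    ks = scipy.stats.kstest(ps, "uniform").statistic
    assert ks < 0.1


def test_threshold_order_statistic():
    min_p = np.linspace(0.001, 0.100, 100)
    assert derive_threshold(min_p, 0.05) == pytest.approx(0.005)
    with pytest.warns(UserWarning, match="smallest"):
        t = derive_threshold(np.linspace(0.01, 0.1, 10), 0.05)
    assert t == pytest.approx(0.01)


@given(
    st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=300),
    st.floats(0.01, 0.5),
)
@settings(deadline=None, max_examples=50, derandomize=True)
def test_threshold_is_the_prescribed_order_statistic(min_p, alpha):
    srt = sorted(min_p)
    k = int(np.floor(alpha * (len(min_p) + 1)))
    expected = srt[k - 1] if k >= 1 else srt[0]
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        assert derive_threshold(np.array(min_p), alpha) == pytest.approx(expected)


@given(st.permutations(list(range(12))))
@settings(deadline=None, max_examples=40, derandomize=True)
def test_any_permutation_preserves_residual_norm(perm):
    rng = np.random.default_rng(44)
    dp, nf = _problem(rng, 15, 3)
    rp = build_projector(dp, nf)
    y_pi = permute_once(rp, nf, np.array(perm))
    zeta = rp.U1.T @ nf.emm
    assert np.linalg.norm(rp.U1.T @ (y_pi - nf.fitted0)) == pytest.approx(
        np.linalg.norm(zeta), abs=1e-10
    )


def test_threshold_monotone_in_alpha():
    rng = np.random.default_rng(9)
    min_p = rng.uniform(size=199)
    ts = [derive_threshold(min_p, a) for a in (0.01, 0.05, 0.10, 0.2)]
    assert all(a <= b for a, b in zip(ts, ts[1:]))


def test_engine_run_warns_on_few_permutations(prepared):
    with pytest.warns(UserWarning, match="fewer than"):
        null = prepared.engine.run(10, 0.05, 1)
    assert null.threshold == null.min_p.min()
    assert ((null.min_p > 0) & (null.min_p <= 1)).all()
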
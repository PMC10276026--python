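"""REML core: likelihood conventions, optimization, solutions and criteria."""
import numpy as np
import pandas as pd
import pytest

from gblupad import (
    GBLUPModel,
    SimulationConfig,
    additive_kernel,
    aic,
    allele_frequency,
    bic,
    build_design,
    build_W,
    fit_dominance_pair,
    dominance_kernel,
    identity_kernel,
    lrt_dominance,
    restricted_loglik,
    simulate_dataset,
)
from gblupad.reml import _LOG2PI

from conftest import spawn_seeds


@pytest.fixture(scope="module")
def ad_design():
    cfg = SimulationConfig(
        n_individuals=10, n_markers=40, seed=3, year_effects={2018: 0.0, 2019: 0.5}
    )
    ds = simulate_dataset(cfg)
    G = additive_kernel(ds.genotypes)
    D = dominance_kernel(ds.genotypes)
    return ds, build_design(ds.phenotypes, [G, D]), G, D


def _dense_reml_loglik(design, comps):
    """Independent dense evaluation of the restricted log-likelihood."""
    y, X, Z = design.y, design.X, design.Z()
    n, p = len(y), X.shape[1]
    V = comps[-1] * np.eye(n)
    for s2, K in zip(comps[:-1], design.kernels):
        V += s2 * Z @ K.values @ Z.T
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    return -0.5 * (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtViX)[1]
        + y @ P @ y
        + (n - p) * _LOG2PI
    )


def test_design_incidence_structure(ad_design):
    ds, design, *_ = ad_design
    assert design.X.shape == (design.n_records, 2)
    assert design.X.sum() == design.n_records  # one-hot rows
    assert design.rank_X == 2
    # each record points at its own individual
    Z = design.Z()
    np.testing.assert_array_equal(Z.sum(axis=1), 1.0)


def test_design_rejects_unknown_individuals(small_dataset, small_kernels):
    bad = small_dataset.phenotypes.copy()
    bad.loc[0, "genotype_id"] = "STRANGER"
    with pytest.raises(KeyError, match="absent from kernel"):
        build_design(bad, [small_kernels[0]])


@pytest.mark.parametrize("comps", [(0.3, 0.2, 0.5), (1.0, 0.01, 0.2), (0.05, 0.9, 1.5)])
def test_loglik_matches_dense_oracle(ad_design, comps):
    _, design, *_ = ad_design
    assert restricted_loglik(design, comps) == pytest.approx(
        _dense_reml_loglik(design, np.asarray(comps)), abs=1e-8
    )


def test_loglik_closed_form_random_intercept():
    # one identity term, one record per individual, single year:
    # V = (s_a + s_e) I, so the REML likelihood has a hand closed form
    n = 15
    rng = np.random.default_rng(7)
    ids = [f"G{i}" for i in range(n)]
    ph = pd.DataFrame(
        {"genotype_id": ids, "year": 2018, "trait": "t", "value": rng.normal(size=n)}
    )
    design = build_design(ph, [identity_kernel(ids)])
    s_a, s_e = 0.4, 0.6
    s = s_a + s_e
    y = ph["value"].to_numpy()
    ss = ((y - y.mean()) ** 2).sum()
    closed = -0.5 * ((n - 1) * np.log(s) + np.log(n) + ss / s + (n - 1) * _LOG2PI)
    assert restricted_loglik(design, [s_a, s_e]) == pytest.approx(closed, abs=1e-10)


def test_loglik_unit_change_identity(ad_design):
    # scaling y by c (and variances by c^2) shifts the loglik by -(n-p) log c
    ds, design, G, D = ad_design
    comps = np.array([0.3, 0.2, 0.5])
    c = 3.7
    scaled = ds.phenotypes.assign(value=ds.phenotypes["value"] * c)
    design_c = build_design(scaled, [G, D])
    ll = restricted_loglik(design, comps)
    ll_c = restricted_loglik(design_c, comps * c**2)
    n_eff = design.n_records - design.rank_X
    assert ll_c == pytest.approx(ll - n_eff * np.log(c), abs=1e-8)


def test_identity_fit_matches_statsmodels_mixedlm(small_dataset):
    import statsmodels.formula.api as smf

    ph = small_dataset.phenotypes
    I = identity_kernel(small_dataset.genotypes.individual_ids)
    res = GBLUPModel.blup(ph, small_dataset.genotypes.individual_ids).fit()
    sm_res = smf.mixedlm("value ~ C(year) - 1", ph, groups=ph["genotype_id"]).fit(
        reml=True
    )
    assert res.components["identity"] == pytest.approx(
        float(sm_res.cov_re.iloc[0, 0]), rel=1e-3
    )
    assert res.components["residual"] == pytest.approx(float(sm_res.scale), rel=1e-3)


def test_gblup_equals_rrblup_with_matched_penalty():
    # GEBVs from the G-kernel equal ridge marker predictions W alpha-hat
    cfg = SimulationConfig(
        n_individuals=30, n_markers=50, seed=11, year_effects={2018: 0.0}
    )
    ds = simulate_dataset(cfg)
    freqs = allele_frequency(ds.genotypes)
    W = build_W(ds.genotypes, freqs)
    G = additive_kernel(ds.genotypes, freqs)
    res = GBLUPModel.additive(ds.phenotypes, G).fit()
    s_a, s_e = res.components["additive"], res.components["residual"]
    lam = s_e / (s_a / float((2 * freqs * (1 - freqs)).sum()))
    y = (
        ds.phenotypes.set_index("genotype_id")
        .loc[ds.genotypes.individual_ids, "value"]
        .to_numpy()
    )
    X = np.ones((30, 1))
    m = W.shape[1]
    A = np.block(
        [[X.T @ X, X.T @ W], [W.T @ X, W.T @ W + lam * np.eye(m)]]
    )
    sol = np.linalg.solve(A, np.concatenate([X.T @ y, W.T @ y]))
    np.testing.assert_allclose(
        W @ sol[1:], res.genetic_values.to_numpy(), atol=1e-6
    )


def test_solutions_satisfy_henderson_mme(ad_design):
    # V-based BLUPs must solve the K^-1-form mixed-model equations; the
    # kernels get a small common ridge so that K^-1 exists on both sides
    from gblupad import RelationshipMatrix

    ds, _, G0, D0 = ad_design
    n = G0.n_individuals
    G = RelationshipMatrix(G0.individual_ids, G0.values + 1e-4 * np.eye(n), "additive")
    D = RelationshipMatrix(D0.individual_ids, D0.values + 1e-4 * np.eye(n), "dominance")
    comps = np.array([0.35, 0.25, 0.5])
    model = GBLUPModel.additive_dominance(ds.phenotypes, G, D)
    design = model.design
    res = model.fit(fixed_components=comps)
    X, Z, y = design.X, design.Z(), design.y
    Gi = np.linalg.inv(G.values)
    Di = np.linalg.inv(D.values)
    lam1, lam2 = comps[2] / comps[0], comps[2] / comps[1]
    C = np.block(
        [
            [X.T @ X, X.T @ Z, X.T @ Z],
            [Z.T @ X, Z.T @ Z + lam1 * Gi, Z.T @ Z],
            [Z.T @ X, Z.T @ Z, Z.T @ Z + lam2 * Di],
        ]
    )
    rhs = np.concatenate([X.T @ y, Z.T @ y, Z.T @ y])
    sol = np.concatenate(
        [
            res.fe_params.to_numpy(),
            res.random_effects["additive"].to_numpy(),
            res.random_effects["dominance"].to_numpy(),
        ]
    )
    resid = C @ sol - rhs
    assert np.linalg.norm(resid) < 1e-8 * np.linalg.norm(rhs)
    # and the PEV of g+d matches the joint inverse-coefficient-matrix blocks
    Ci = np.linalg.inv(C)
    p = X.shape[1]
    B = Ci[p:, p:]
    pev_sum = comps[2] * (
        np.diag(B[:n, :n]) + np.diag(B[n:, n:]) + 2 * np.diag(B[:n, n:])
    )
    np.testing.assert_allclose(res.pev_genetic.to_numpy(), pev_sum, atol=1e-8)


def test_fit_is_a_local_maximum(small_dataset, small_kernels):
    G, D, _ = small_kernels
    res = GBLUPModel.additive_dominance(small_dataset.phenotypes, G, D).fit()
    assert res.converged
    comps = res.components.to_numpy()
    for k in range(comps.size):
        for eps in (0.99, 1.01):
            pert = comps.copy()
            pert[k] *= eps
            assert res.model.loglike(pert) <= res.loglik + 1e-6


def test_pev_within_bounds(small_dataset, small_kernels):
    G, D, _ = small_kernels
    res = GBLUPModel.additive_dominance(small_dataset.phenotypes, G, D).fit()
    for name, K in zip(("additive", "dominance"), (G, D)):
        s2 = res.components[name]
        upper = s2 * np.diag(K.values)
        pev = res.pev[name].to_numpy()
        assert (pev >= 0).all()
        assert (pev <= upper + 1e-8).all()


def test_boundary_recovery_when_dominance_absent():
    # data simulated without dominance: the AD fit should park sigma2_d at
    # (or near) zero in at least 80% of replicates
    hits = 0
    for seed in spawn_seeds(99, 30):
        cfg = SimulationConfig(
            n_individuals=200, n_markers=500, sigma2_a=0.4, sigma2_d=0.0,
            sigma2_e=0.4, seed=seed,
        )
        ds = simulate_dataset(cfg)
        G = additive_kernel(ds.genotypes)
        D = dominance_kernel(ds.genotypes)
        res = GBLUPModel.additive_dominance(ds.phenotypes, G, D).fit()
        hits += res.components["dominance"] < 0.05 * res.components.sum()
    assert hits >= 24


def test_constant_phenotypes_error(small_kernels):
    ph = pd.DataFrame(
        {
            "genotype_id": small_kernels[0].individual_ids[:10],
            "year": 2018,
            "trait": "t",
            "value": 1.0,
        }
    )
    with pytest.raises(ValueError, match="variance is zero"):
        GBLUPModel.additive(ph, small_kernels[0]).fit()


@pytest.mark.parametrize(
    "loglik, k, expected",
    [(-345.05, 4, 698.1), (-257.97, 3, 521.93), (-100.0, 0, 200.0)],
)
def test_aic_convention(loglik, k, expected):
    # k counts fixed-effect (year) parameters only
    assert aic(loglik, k) == pytest.approx(expected, abs=0.011)


def test_bic_convention():
    assert bic(-10.0, 2, 100) == pytest.approx(20.0 + 2 * np.log(100))


def test_lrt_boundary_convention(small_dataset, small_kernels):
    from scipy import stats

    G, D, _ = small_kernels
    res_a, res_ad = fit_dominance_pair(small_dataset.phenotypes, G, D)
    stat, p = lrt_dominance(res_a, res_ad)
    assert stat >= 0
    expected = 0.5 if stat == 0 else 0.5 * stats.chi2.sf(stat, 1)
    assert p == pytest.approx(expected)
    # the half-mixture at the classical 3.84 cutoff gives ~0.025
    assert 0.5 * stats.chi2.sf(3.84, 1) == pytest.approx(0.025, abs=5e-4)
    # equal likelihoods: statistic clipped to zero, p = 0.5 exactly
    stat0 = max(0.0, 2.0 * (res_a.loglik - res_a.loglik))
    assert stat0 == 0.0


def test_lrt_rejects_non_nested(small_dataset, small_kernels):
    G, D, I = small_kernels
    res_blup = GBLUPModel(small_dataset.phenotypes, [I]).fit()
    res_a = GBLUPModel.additive(small_dataset.phenotypes, G).fit()
    with pytest.raises(ValueError, match="not nested"):
        lrt_dominance(res_blup, res_a)


def test_summary_is_printable(small_dataset, small_kernels):
    res = GBLUPModel.additive(small_dataset.phenotypes, small_kernels[0]).fit()
    text = res.summary()
    assert "GBLUP-A" in text and "logLik" in text and "sigma2[additive]" in text
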
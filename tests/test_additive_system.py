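import math

import numpy as np
import pytest

from treeallom import (
    AgeGroup,
    Component,
    MODELS,
    SystemSpec,
    ValidationError,
    fit_log_ols,
    fit_sur,
    predict_components,
    predict_total,
    residual_cross_correlation,
)
from treeallom.candidate_models import design_row
from treeallom.synthetic_data import SyntheticConfig, default_config, simulate_dataset
from treeallom.tree_data import BIOMASS_COMPONENTS, TreeRecord

from conftest import make_record

YOUNG_SYSTEM = SystemSpec(
    group=AgeGroup.YOUNG,
    specs={
        Component.TRUNK: MODELS["M2"],
        Component.BRANCH: MODELS["M3"],
        Component.LEAF: MODELS["M3"],
        Component.ROOT: MODELS["M5"],
    },
)


def _young_records(n, seed, rho=0.5, sigma=0.15):
    cfg = default_config(
        seed=seed, sigma=sigma, rho=rho,
        n_per_group={AgeGroup.YOUNG: n, AgeGroup.MIDDLE: 2, AgeGroup.MATURE: 2},
    )
    return [r for r in simulate_dataset(cfg) if r.group is AgeGroup.YOUNG], cfg


def _ols_params(records, system):
    return {
        c: fit_log_ols(system.specs[c], records, c).params
        for c in BIOMASS_COMPONENTS
    }


def brute_force_iterated_gls(records, system, tol=1e-8, max_iter=100):
    """Independent oracle: dense 4n x K stacked system, explicit Kronecker
    weight matrix, solved with one dense lstsq per iteration."""
    Xs, ys = [], []
    for c in BIOMASS_COMPONENTS:
        spec = system.specs[c]
        Xs.append(np.array([design_row(spec, r.D, r.H, r.CR) for r in records]))
        ys.append(np.array([math.log(r.biomass(c)) for r in records]))
    n = len(records)
    ks = [X.shape[1] for X in Xs]
    K = sum(ks)
    bigX = np.zeros((4 * n, K))
    off = 0
    for i, X in enumerate(Xs):
        bigX[i * n:(i + 1) * n, off:off + ks[i]] = X
        off += ks[i]
    bigy = np.concatenate(ys)
    beta = np.linalg.lstsq(bigX, bigy, rcond=None)[0]  # OLS start (block-diag)
    for _ in range(max_iter):
        resid = (bigy - bigX @ beta).reshape(4, n)
        sigma = resid @ resid.T / n
        W = np.kron(np.linalg.inv(sigma), np.eye(n))
        L = np.linalg.cholesky(W)
        new = np.linalg.lstsq(L.T @ bigX, L.T @ bigy, rcond=None)[0]
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    out, off = {}, 0
    for c, k in zip(BIOMASS_COMPONENTS, ks):
        out[c] = beta[off:off + k]
        off += k
    return out


class TestEquivalences:
    def test_kruskal_identical_regressors(self):
        # every equation on the same design -> SUR coincides with OLS
        recs, _ = _young_records(40, seed=1)
        system = SystemSpec(group=AgeGroup.YOUNG,
                            specs={c: MODELS["M2"] for c in BIOMASS_COMPONENTS})
        sur = fit_sur(recs, system)
        ols = _ols_params(recs, system)
        assert sur.converged
        for c in BIOMASS_COMPONENTS:
            np.testing.assert_allclose(sur.params[c], ols[c], atol=1e-8)

    def test_diagonal_sigma_equals_ols(self):
        recs, _ = _young_records(40, seed=2)
        sur = fit_sur(recs, YOUNG_SYSTEM, diagonal_sigma=True)
        ols = _ols_params(recs, YOUNG_SYSTEM)
        for c in BIOMASS_COMPONENTS:
            np.testing.assert_allclose(sur.params[c], ols[c], atol=1e-8)

    @pytest.mark.parametrize("n,seed", [(30, 3), (50, 4)])
    def test_matches_dense_stacked_oracle(self, n, seed):
        recs, _ = _young_records(n, seed=seed, rho=0.7)
        sur = fit_sur(recs, YOUNG_SYSTEM)
        oracle = brute_force_iterated_gls(recs, YOUNG_SYSTEM)
        for c in BIOMASS_COMPONENTS:
            np.testing.assert_allclose(sur.params[c], oracle[c], atol=1e-8)

    def test_equation_order_invariance(self):
        recs, _ = _young_records(35, seed=5)
        shuffled = SystemSpec(
            group=AgeGroup.YOUNG,
            specs={c: YOUNG_SYSTEM.specs[c]
                   for c in reversed(BIOMASS_COMPONENTS)},
        )
        a = fit_sur(recs, YOUNG_SYSTEM)
        b = fit_sur(recs, shuffled)
        for c in BIOMASS_COMPONENTS:
            np.testing.assert_allclose(a.params[c], b.params[c], atol=1e-10)


class TestEstimation:
    def test_parameter_recovery_within_3_se(self):
        # simulated from the published young-group coefficients with
        # sigma = 0.15 and cross-correlation 0.5 at n = 300
        recs, cfg = _young_records(300, seed=42)
        sur = fit_sur(recs, YOUNG_SYSTEM)
        assert sur.converged
        for c in BIOMASS_COMPONENTS:
            truth = cfg.groups[AgeGroup.YOUNG].beta(c)
            se = sur.bse[c]
            assert np.all(np.abs(sur.params[c] - truth) < 3 * se), c

    def test_sigma_consistent_with_per_equation_mse(self):
        recs, _ = _young_records(100, seed=6)
        sur = fit_sur(recs, YOUNG_SYSTEM)
        n = sur.n
        for i, c in enumerate(BIOMASS_COMPONENTS):
            k = YOUNG_SYSTEM.specs[c].k
            # diag(Sigma-hat) uses divisor n; sigma2 uses n - k
            assert sur.sigma_hat[i, i] * n / (n - k) == pytest.approx(
                sur.sigma2[c], rel=1e-10
            )
            assert sur.cf[c] == pytest.approx(math.exp(sur.sigma2[c] / 2))

    def test_sur_more_efficient_than_ols(self):
        # cross-correlation 0.8 and differing regressor sets: over replicates
        # the sampling SD of every SUR coefficient is at most the OLS SD
        n_rep, n = 200, 40
        truth = default_config().groups[AgeGroup.YOUNG]
        sur_est = {c: [] for c in BIOMASS_COMPONENTS}
        ols_est = {c: [] for c in BIOMASS_COMPONENTS}
        for rep in range(n_rep):
            recs, _ = _young_records(n, seed=10_000 + rep, rho=0.8)
            sur = fit_sur(recs, YOUNG_SYSTEM)
            ols = _ols_params(recs, YOUNG_SYSTEM)
            for c in BIOMASS_COMPONENTS:
                sur_est[c].append(sur.params[c])
                ols_est[c].append(ols[c])
        for c in BIOMASS_COMPONENTS:
            sd_sur = np.std(np.array(sur_est[c]), axis=0)
            sd_ols = np.std(np.array(ols_est[c]), axis=0)
            assert np.all(sd_sur <= sd_ols), (c, sd_sur / sd_ols)

    def test_nonconvergence_warns_and_flags(self):
        recs, _ = _young_records(50, seed=8)
        with pytest.warns(UserWarning, match="did not converge"):
            sur = fit_sur(recs, YOUNG_SYSTEM, max_iter=1, tol=1e-14)
        assert not sur.converged and sur.iterations == 1

    def test_singular_sigma_rejected_and_ridge_recovers(self):
        recs, _ = _young_records(30, seed=9)
        # make the branch equation a clone of the trunk equation
        clones = [
            TreeRecord(r.tree_id, r.D, r.H, r.CR, r.w_trunk, r.w_trunk,
                       r.w_leaf, r.w_root, group=r.group)
            for r in recs
        ]
        system = SystemSpec(
            group=AgeGroup.YOUNG,
            specs={**YOUNG_SYSTEM.specs, Component.BRANCH: MODELS["M2"],
                   Component.TRUNK: MODELS["M2"]},
        )
        with pytest.raises(ValidationError, match="ridge"):
            fit_sur(clones, system)
        sur = fit_sur(clones, system, ridge=1e-8)
        assert sur.n == 30

    def test_too_few_records_rejected(self):
        recs, _ = _young_records(3, seed=10)
        with pytest.raises(ValidationError, match="need n >"):
            fit_sur(recs, YOUNG_SYSTEM)

    def test_total_as_equation_mode_close_to_default(self):
        recs, _ = _young_records(200, seed=11)
        base = fit_sur(recs, YOUNG_SYSTEM)
        with_total = fit_sur(recs, YOUNG_SYSTEM, total_as_equation=True,
                             max_iter=200)
        for c in BIOMASS_COMPONENTS:
            np.testing.assert_allclose(with_total.params[c], base.params[c],
                                       rtol=0.15, atol=0.15)


class TestPrediction:
    def test_additivity_identity(self, default_records):
        recs, _ = _young_records(1000, seed=12)
        sur = fit_sur([r for r in default_records if r.group is AgeGroup.YOUNG],
                      YOUNG_SYSTEM)
        for r in recs:
            comps = predict_components(sur, r)
            assert abs(predict_total(sur, r) - sum(comps.values())) < 1e-12
            assert all(v > 0 for v in comps.values())

    def test_noise_free_truth_reproduced(self):
        cfg = default_config(seed=13)
        quiet = SyntheticConfig(groups=cfg.groups, sigma_log=np.zeros((4, 4)),
                                seed=13)
        recs = [r for r in simulate_dataset(quiet) if r.group is AgeGroup.YOUNG]
        sur = fit_sur(recs, YOUNG_SYSTEM)
        for r in recs:
            assert predict_total(sur, r) == pytest.approx(r.total, rel=1e-8)
            for c, v in predict_components(sur, r).items():
                assert v == pytest.approx(r.biomass(c), rel=1e-8)

    def test_published_middle_trunk_prediction(self):
        # closed-form check of one component prediction at the middle-group
        # mean tree using the published jointly estimated coefficients
        rec = make_record(D=12.747, H=14.016, CR=3.834)
        expected = math.exp(-2.822 + 1.218 * math.log(12.747)
                            + 1.375 * math.log(14.016))
        cfg = default_config(seed=14)
        quiet = SyntheticConfig(groups=cfg.groups, sigma_log=np.zeros((4, 4)),
                                seed=14)
        recs = [r for r in simulate_dataset(quiet) if r.group is AgeGroup.MIDDLE]
        system = SystemSpec(
            group=AgeGroup.MIDDLE,
            specs={Component.TRUNK: MODELS["M2"], Component.BRANCH: MODELS["M1"],
                   Component.LEAF: MODELS["M1"], Component.ROOT: MODELS["M4"]},
        )
        sur = fit_sur(recs, system)
        comps = predict_components(sur, rec)
        assert comps[Component.TRUNK] == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(49.821410750002435, rel=1e-12)


class TestCrossCorrelation:
    def test_unit_diagonal(self):
        recs, _ = _young_records(60, seed=15)
        corr = residual_cross_correlation(fit_sur(recs, YOUNG_SYSTEM))
        np.testing.assert_allclose(np.diag(corr), 1.0)

    @pytest.mark.parametrize("rho", [0.0, 0.9])
    def test_recovers_generated_correlation(self, rho):
        recs, _ = _young_records(5000, seed=16, rho=rho)
        corr = residual_cross_correlation(fit_sur(recs, YOUNG_SYSTEM))
        se = (1 - rho**2) / math.sqrt(len(recs)) + 0.01
        off = corr[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off - rho) < 3 * se)
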
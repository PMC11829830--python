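"""Evidential losses against independent oracles.

The NIG NLL is checked against numerical quadrature of the
Gaussian × Inverse-Gamma marginal (the Gaussian convolution over the mean
is carried out analytically, leaving a 1-D integral over the variance) and
against scipy's Student-t density; the DER-M loss against hand-evaluated
closed forms and finite-difference gradients.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats
from scipy.special import psi

from pesuq.autodiff import Tensor, value_of
from pesuq.evidential import (
    NIGLossConfig,
    NIGParams,
    NIWOutput,
    build_scale_matrix,
    derl_total_loss,
    derm_loss,
    ders_total_loss,
    fit_nig_regressor,
    lipschitz_bound,
    lipschitz_reg,
    map_nu,
    nig_evidence_reg,
    nig_nll,
    nig_uncertainty,
    niw_uncertainty,
)

ENERGY_ONLY = NIGLossConfig(w_f=0.0, w_q=0.0, w_d=0.0)


def _quadrature_nll(y, gamma, nu, alpha, beta):
    """Independent oracle: -ln ∫ N(y|γ, σ²(1+1/ν)) InvGamma(σ²|α,β) dσ²."""

    def integrand(s2):
        return stats.norm.pdf(
            y, gamma, np.sqrt(s2 * (1 + 1 / nu))
        ) * stats.invgamma.pdf(s2, alpha, scale=beta)

    val, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    return -np.log(val)


class TestNigNll:
    @pytest.mark.parametrize("nu", [0.5, 1.0, 3.0])
    @pytest.mark.parametrize("alpha", [1.2, 2.0, 6.0])
    @pytest.mark.parametrize("beta", [0.5, 2.0])
    def test_matches_quadrature_oracle(self, nu, alpha, beta):
        for y in (-1.5, 0.0, 2.0):
            params = NIGParams(0.3, nu, alpha, beta).validate()
            assert np.isclose(
                nig_nll(params, y),
                _quadrature_nll(y, 0.3, nu, alpha, beta),
                atol=1e-6,
            )

    def test_even_in_residual(self):
        params = NIGParams(1.0, 1.0, 1.5, 1.0)
        for d in (0.3, 1.7, 4.0):
            assert np.isclose(
                nig_nll(params, 1.0 + d), nig_nll(params, 1.0 - d)
            )

    def test_strictly_increasing_in_residual(self):
        params = NIGParams(0.0, 1.0, 1.5, 1.0)
        vals = [nig_nll(params, r) for r in (0.0, 0.5, 1.0, 2.0, 5.0)]
        assert np.all(np.diff(vals) > 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            NIGParams(0.0, -1.0, 2.0, 1.0).validate()
        with pytest.raises(ValueError):
            NIGParams(0.0, 1.0, 0.9, 1.0).validate()


class TestEvidenceReg:
    def test_zero_residual_gives_zero(self):
        assert nig_evidence_reg(NIGParams(1.0, 1.0, 1.0 + 1e-9, 1.0), 1.0) == 0

    def test_forced_arithmetic(self):
        # |r| (2 nu + alpha) with r=2, nu=1, alpha=1 -> 6
        p = NIGParams(0.0, 1.0, 1.0, 1.0)
        assert np.isclose(nig_evidence_reg(p, 2.0), 6.0)

    def test_monotone_in_evidence(self):
        lo = nig_evidence_reg(NIGParams(0.0, 1.0, 2.0, 1.0), 1.0)
        hi = nig_evidence_reg(NIGParams(0.0, 2.0, 2.0, 1.0), 1.0)
        assert hi > lo

    def test_mse_form_option(self):
        p = NIGParams(0.0, 1.0, 2.0, 1.0)
        assert np.isclose(nig_evidence_reg(p, 3.0, reg_form="mse"), 9.0)


class TestTotalLosses:
    def _batch(self, rng, n=4):
        params = NIGParams(
            gamma=rng.normal(size=n),
            nu=rng.uniform(0.5, 2, n),
            alpha=rng.uniform(1.2, 3, n),
            beta=rng.uniform(0.5, 2, n),
        )
        pred = {
            "params": params,
            "forces": rng.normal(size=(n, 6)),
            "charge": rng.normal(size=n),
            "dipole": rng.normal(size=(n, 3)),
        }
        ref = {
            "energy": rng.normal(size=n),
            "forces": rng.normal(size=(n, 6)),
            "charge": rng.normal(size=n),
            "dipole": rng.normal(size=(n, 3)),
        }
        return pred, ref

    def test_reduces_to_mean_nll_with_zero_weights(self, rng):
        pred, ref = self._batch(rng)
        cfg = NIGLossConfig(lam=0.0, w_f=0.0, w_q=0.0, w_d=0.0)
        total = ders_total_loss(pred, ref, cfg)
        expected = np.mean(nig_nll(pred["params"], ref["energy"]))
        assert np.isclose(total, expected)

    def test_property_terms_vanish_for_perfect_predictions(self, rng):
        pred, ref = self._batch(rng)
        ref["forces"] = pred["forces"].copy()
        ref["charge"] = np.asarray(pred["charge"]).copy()
        ref["dipole"] = pred["dipole"].copy()
        cfg_off = NIGLossConfig(w_f=0.0, w_q=0.0, w_d=0.0)
        cfg_on = NIGLossConfig()
        assert np.isclose(
            ders_total_loss(pred, ref, cfg_on),
            ders_total_loss(pred, ref, cfg_off),
        )

    def test_matches_term_by_term_oracle(self, rng):
        pred, ref = self._batch(rng, n=2)
        cfg = NIGLossConfig()
        p = pred["params"]
        expected = 0.0
        for b in range(2):
            pb = NIGParams(p.gamma[b], p.nu[b], p.alpha[b], p.beta[b])
            expected += nig_nll(pb, ref["energy"][b]) / 2
            expected += (
                cfg.lam
                * (
                    nig_evidence_reg(pb, ref["energy"][b])
                    - cfg.epsilon
                )
                / 2
            )
        expected += cfg.w_f * np.abs(pred["forces"] - ref["forces"]).mean()
        expected += cfg.w_q * np.abs(
            np.asarray(pred["charge"]) - ref["charge"]
        ).mean()
        expected += cfg.w_d * np.abs(pred["dipole"] - ref["dipole"]).mean()
        assert np.isclose(ders_total_loss(pred, ref, cfg), expected)

    def test_missing_label_names_the_term(self, rng):
        pred, ref = self._batch(rng)
        del pred["forces"]
        with pytest.raises(ValueError, match="force"):
            ders_total_loss(pred, ref, NIGLossConfig())


class TestLipschitz:
    def test_zero_residual_gives_zero(self):
        p = NIGParams(0.0, 1.0, 2.0, 1.0)
        assert lipschitz_reg(0.0, 0.0, p) == 0.0

    def test_quadratic_branch_below_bound(self):
        p = NIGParams(0.0, 1.0, 2.0, 4.0)
        u = lipschitz_bound(p)
        d = 0.5 * np.sqrt(u)
        assert np.isclose(lipschitz_reg(d, 0.0, p), d**2)

    def test_linear_branch_arithmetic(self):
        # pick params with U = 4: U_nu = beta(nu+1)/(alpha nu)
        # with nu=1, alpha=1+e: U_nu = 2 beta / (1+e); choose beta so U=4
        p = NIGParams(0.0, 1.0, 1.0 + 1e-12, 2.0)
        u = lipschitz_bound(p)
        assert u <= 4.0 + 1e-9
        # direct check of the printed branch form with dE=3
        d = 3.0
        if d**2 >= u:
            expected = 2 * np.sqrt(u) * d - u
            assert np.isclose(lipschitz_reg(d, 0.0, p), expected)

    def test_branches_agree_at_crossover(self):
        p = NIGParams(0.0, 1.0, 2.0, 3.0)
        u = lipschitz_bound(p)
        d = np.sqrt(u)
        quad = d**2
        lin = 2 * np.sqrt(u) * d - u
        assert np.isclose(quad, lin)
        assert np.isclose(lipschitz_reg(d * (1 - 1e-9), 0.0, p), u, rtol=1e-6)

    def test_u_alpha_digamma_value(self):
        # U_alpha(beta=1, nu=1, alpha=1) = 4 [exp(psi(3/2) - psi(1)) - 1]
        p = NIGParams(0.0, 1.0, 1.0, 1.0)
        nu, alpha, beta = 1.0, 1.0, 1.0
        u_alpha = (
            2 * beta * (1 + nu) / nu
            * (np.exp(psi(alpha + 0.5) - psi(alpha)) - 1)
        )
        assert np.isclose(u_alpha, 4 * (np.exp(psi(1.5) - psi(1.0)) - 1))

    def test_derl_equals_ders_plus_quadratic_inside_bound(self, rng):
        n = 3
        params = NIGParams(
            gamma=np.zeros(n),
            nu=np.ones(n),
            alpha=np.full(n, 2.0),
            beta=np.full(n, 10.0),  # large beta -> large bound
        )
        pred = {"params": params}
        resid = np.array([0.1, -0.2, 0.15])
        ref = {"energy": resid}
        cfg = NIGLossConfig(w_f=0.0, w_q=0.0, w_d=0.0)
        assert (resid**2 < lipschitz_bound(params)).all()
        assert np.isclose(
            derl_total_loss(pred, ref, cfg),
            ders_total_loss(pred, ref, cfg) + np.mean(resid**2),
        )


class TestScaleMatrixAndNu:
    def test_softplus_zero_diagonal(self):
        l00, l10, l11 = build_scale_matrix((0.0, 0.0), 0.0)
        assert np.isclose(l00, np.log(2) + 1e-6)
        assert np.isclose(l11, np.log(2) + 1e-6)
        assert np.isclose(l10, 1e-6)

    def test_large_negative_floors_at_epsilon(self):
        l00, _, l11 = build_scale_matrix((-60.0, -60.0), 0.0)
        assert np.isclose(l00, 1e-6) and np.isclose(l11, 1e-6)

    def test_determinant_always_positive(self, rng):
        for _ in range(50):
            raw = rng.normal(0, 5, 3)
            l00, l10, l11 = build_scale_matrix((raw[0], raw[1]), raw[2])
            assert l00 * l11 > 0

    def test_nu_mapping_fixed_points(self):
        assert np.isclose(map_nu(0.0), 8.0)
        assert np.isclose(map_nu(1e6), 13.0)
        assert np.isclose(map_nu(-1e6), 3.0)

    def test_nu_mapping_bounds_and_monotonicity(self):
        x = np.linspace(-1e6, 1e6, 100_001)
        nu = map_nu(x)
        assert nu.max() <= 13.0 and nu.min() >= 3.0
        xs = np.linspace(-5, 5, 200)
        assert np.all(np.diff(map_nu(xs)) > 0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(x=st.floats(-1e300, 1e300, allow_nan=False))
    def test_nu_mapping_bounds_hypothesis(self, x):
        assert 3.0 <= map_nu(x) <= 13.0


class TestDermLoss:
    def test_identity_scale_zero_residual(self):
        out = NIWOutput(mu0=0.0, mu1=0.0, l00=1.0, l10=0.0, l11=1.0, nu=3.0)
        val = derm_loss(out, 0.0, 0.0, ENERGY_ONLY)
        # log((3+1)/(3-1)) - 3*0 + 2*log(det I) = log 2
        assert np.isclose(val, np.log(2.0))

    def test_raw_construction_term_by_term(self):
        out = NIWOutput.from_raw(
            mu0=0.0, mu1=0.0, ell_raw=(0.0, 0.0), l21=-1e-6, nu_raw=-1e9
        )
        # nu -> 3; L diag = ln2 + 1e-6, off-diagonal exactly 0
        d = np.log(2) + 1e-6
        expected = (
            np.log(4.0 / 2.0)
            - 3.0 * 2 * np.log(d)
            + 2.0 * np.log(d**4)
        )
        val = derm_loss(out, 0.0, 0.0, ENERGY_ONLY)
        assert np.isclose(val, expected, rtol=1e-9)

    def test_gradient_matches_finite_differences(self, rng):
        cfg = ENERGY_ONLY

        def loss_from_raw(raw):
            out = NIWOutput.from_raw(
                raw[0], raw[1], (raw[2], raw[3]), raw[4], raw[5]
            )
            return derm_loss(out, 1.1, -0.4, cfg)

        for _ in range(5):
            raw0 = rng.normal(0, 1, 6)
            ts = [Tensor(np.array(v)) for v in raw0]
            out = NIWOutput.from_raw(ts[0], ts[1], (ts[2], ts[3]), ts[4], ts[5])
            loss = derm_loss(out, 1.1, -0.4, cfg)
            loss.backward()
            grad = np.array([float(t.grad) for t in ts])
            num = np.zeros(6)
            h = 1e-6
            for k in range(6):
                rp = raw0.copy()
                rp[k] += h
                rm = raw0.copy()
                rm[k] -= h
                num[k] = (loss_from_raw(rp) - loss_from_raw(rm)) / (2 * h)
            denom = max(np.abs(num).max(), 1e-10)
            assert np.abs(grad - num).max() / denom < 1e-5


class TestUncertainties:
    def test_niw_forced_arithmetic(self):
        out = NIWOutput(mu0=0.0, mu1=0.0, l00=1.0, l10=0.0, l11=1.0, nu=4.0)
        d = niw_uncertainty(out)
        assert np.allclose(d.aleatoric, 4.0 * np.eye(2))
        assert np.allclose(d.epistemic, np.eye(2))

    def test_niw_limit_at_nu_13(self):
        out = NIWOutput(mu0=0.0, mu1=0.0, l00=2.0, l10=0.5, l11=1.0, nu=13.0)
        d = niw_uncertainty(out)
        ell = out.scale_matrix()
        assert np.allclose(d.aleatoric, 13.0 / 10.0 * ell @ ell.T)

    def test_niw_epistemic_dominated_by_aleatoric(self, rng):
        for _ in range(20):
            out = NIWOutput.from_raw(
                0.0, 0.0, tuple(rng.normal(0, 2, 2)), rng.normal(),
                rng.normal(),
            )
            d = niw_uncertainty(out)
            diff = np.asarray(d.aleatoric) - np.asarray(d.epistemic)
            assert np.all(np.linalg.eigvalsh(diff) >= -1e-12)

    def test_niw_domain_error(self):
        out = NIWOutput(mu0=0.0, mu1=0.0, l00=1.0, l10=0.0, l11=1.0, nu=2.5)
        with pytest.raises(ValueError):
            niw_uncertainty(out)

    def test_nig_forced_arithmetic_and_identity(self, rng):
        d = nig_uncertainty(NIGParams(0.0, 1.0, 2.0, 1.0))
        assert d.aleatoric == 1.0 and d.epistemic == 1.0
        for _ in range(20):
            p = NIGParams(
                0.0,
                rng.uniform(0.1, 5),
                rng.uniform(1.1, 5),
                rng.uniform(0.1, 5),
            )
            u = nig_uncertainty(p)
            assert np.isclose(u.epistemic * p.nu, u.aleatoric)

    def test_nig_domain_error(self):
        with pytest.raises(ValueError):
            nig_uncertainty(NIGParams(0.0, 1.0, 0.5, 1.0))


class TestGradientsThroughLosses:
    def test_nig_loss_gradients_match_finite_differences(self, rng):
        cfg = NIGLossConfig(w_f=0.0, w_q=0.0, w_d=0.0)

        def loss_of(raw):
            import pesuq.autodiff as ad

            params = NIGParams(
                gamma=raw[0],
                nu=ad.softplus(raw[1]) + 1e-6,
                alpha=1.0 + 1e-6 + ad.softplus(raw[2]),
                beta=ad.softplus(raw[3]) + 1e-6,
            )
            return ders_total_loss(
                {"params": params}, {"energy": np.array(0.7)}, cfg
            )

        for _ in range(20):
            raw0 = rng.normal(0, 1.5, 4)
            ts = [Tensor(np.array(v)) for v in raw0]
            loss = loss_of(ts)
            loss.backward()
            grad = np.array([float(t.grad) for t in ts])
            num = np.zeros(4)
            h = 1e-6
            for k in range(4):
                rp = raw0.copy()
                rp[k] += h
                rm = raw0.copy()
                rm[k] -= h
                num[k] = (
                    value_of(loss_of(rp)) - value_of(loss_of(rm))
                ) / (2 * h)
            denom = max(np.abs(num).max(), 1e-8)
            assert np.abs(grad - num).max() / denom < 1e-5


class TestNigRegressorMarginal:
    def test_marginal_variance_tracks_noise_without_regularizer(self):
        """With λ=0 the fitted Student-t marginal variance matches the
        injected homoskedastic noise; the decomposition into aleatoric and
        epistemic parts is not identified (see the NIG non-identifiability
        notes in docs/methods.md)."""
        sigma = 0.5
        rng = np.random.default_rng(42)
        x = rng.uniform(-3, 3, 2000)
        y = np.sin(x) + sigma * rng.normal(size=2000)
        cfg = NIGLossConfig(lam=0.0, w_f=0.0, w_q=0.0, w_d=0.0)
        predict = fit_nig_regressor(
            x, y, hidden=32, epochs=600, seed=0, config=cfg
        )
        p = predict(np.linspace(-2.5, 2.5, 200))
        scale2 = np.median(p.beta * (1 + p.nu) / (p.nu * p.alpha))
        assert abs(scale2 - sigma**2) / sigma**2 < 0.25
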
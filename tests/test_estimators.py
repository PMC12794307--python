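"""Log-linear and nonlinear effective-MR-radius estimators."""

import numpy as np
import pytest

from axonradius.estimators import (
    diffusivity_sweep,
    loglinear_radius_multi,
    loglinear_radius_sm,
    loglinear_radius_sv,
    nonlinear_radius,
)
from axonradius.rish import RishFeatures, fit_sh_ls, fit_sh_ml, rish_features, ShellData
from axonradius.signal_models import (
    ModelRegimeError,
    TissueParams,
    gradient_for_bvalue,
    sm_forward,
    sv_forward,
)
from axonradius.synth import add_rician_noise

D0 = 2.5


def forward_features(params, grads, model="neumann", scale=1.0):
    out = []
    for g in grads:
        out.append(RishFeatures(b=g.bvalue,
                                sm=scale * sm_forward(g, params, model),
                                sv=scale * sv_forward(g, params, model)))
    return out


class TestRoundTrip:
    @pytest.mark.parametrize("r_true", [0.5, 1.0, 2.0, 3.0, 4.0, 5.0])
    @pytest.mark.parametrize("dpar", [1.5, 2.0, 2.5])
    def test_sm_and_sv_exact_inverse(self, shell_pair, r_true, dpar):
        params = TissueParams(f=0.6, Dpar=dpar, p2=0.7, D0=D0, r=r_true)
        f1, f2 = forward_features(params, shell_pair)
        est = loglinear_radius_sm(f1, f2, shell_pair, D0)
        assert abs(est.r4_sm - r_true ** 4) <= 1e-9
        est = loglinear_radius_sv(f1, f2, shell_pair, D0, dpar)
        assert abs(est.r4_sv - r_true ** 4) <= 1e-9

    def test_stick_recovers_zero(self, shell_pair):
        params = TissueParams(f=0.6, Dpar=2.2, p2=0.7, D0=D0, r=0.0)
        f1, f2 = forward_features(params, shell_pair)
        est = loglinear_radius_sm(f1, f2, shell_pair, D0)
        assert abs(est.r4_sm) <= 1e-9
        assert est.r_sm == 0.0

    def test_scale_invariance(self, shell_pair, tissue):
        f1, f2 = forward_features(tissue, shell_pair)
        g1, g2 = forward_features(tissue, shell_pair, scale=17.3)
        a = loglinear_radius_sm(f1, f2, shell_pair, D0).r_sm
        b = loglinear_radius_sm(g1, g2, shell_pair, D0).r_sm
        assert a == pytest.approx(b, rel=1e-12)

    def test_sv_independent_of_p2_and_f(self, shell_pair):
        results = set()
        for f, p2 in [(0.2, 0.3), (0.9, 0.95)]:
            params = TissueParams(f=f, Dpar=2.2, p2=p2, D0=D0, r=3.0)
            f1, f2 = forward_features(params, shell_pair)
            est = loglinear_radius_sv(f1, f2, shell_pair, D0, 2.2)
            results.add(round(est.r_sv, 10))
        assert len(results) == 1

    def test_sm_independent_of_dpar_sv_continuous_in_dpar(self, shell_pair,
                                                          tissue):
        f1, f2 = forward_features(tissue, shell_pair)
        sm_vals = {loglinear_radius_sm(f1, f2, shell_pair, D0).r_sm}
        assert len(sm_vals) == 1  # SM path never sees Dpar
        dpars = np.linspace(1.6, 2.4, 9)
        rs = [loglinear_radius_sv(f1, f2, shell_pair, D0, d).r_sv
              for d in dpars]
        diffs = np.diff(rs)
        assert np.all(np.abs(diffs) < 0.2)  # no jumps
        assert np.all(diffs < 0)  # higher assumed Dpar -> smaller SV radius


class TestDegenerateInputs:
    def test_equal_kappa_is_degenerate(self, grad_b6, tissue):
        f1, f2 = forward_features(tissue, (grad_b6, grad_b6))
        with pytest.raises(ValueError):
            loglinear_radius_sm(f1, f2, (grad_b6, grad_b6), D0)

    def test_nonpositive_sm_flagged_nan(self, shell_pair, tissue):
        f1, f2 = forward_features(tissue, shell_pair)
        f1.sm = 0.0
        est = loglinear_radius_sm(f1, f2, shell_pair, D0)
        assert np.isnan(est.r4_sm)
        assert est.flags["invalid_input"]

    def test_sv_regime_error(self, tissue):
        g1 = gradient_for_bvalue(0.6, 15.0, 30.0)
        g2 = gradient_for_bvalue(30.0, 15.0, 30.0)
        f2 = RishFeatures(b=30.0, sm=0.1, sv=0.01)
        f1 = RishFeatures(b=0.6, sm=0.5, sv=0.05)
        with pytest.raises(ModelRegimeError):
            loglinear_radius_sv(f1, f2, (g1, g2), D0, 2.2)

    def test_negative_r4_clipped_with_flag(self, shell_pair, tissue):
        f1, f2 = forward_features(tissue, shell_pair)
        f1.sm, f2.sm = f2.sm, f1.sm  # inverted decay -> negative r^4
        est = loglinear_radius_sm(f1, f2, shell_pair, D0)
        assert est.r4_sm < 0
        assert est.r_sm == 0.0
        assert est.flags["negative_r4"]


class TestMultiShell:
    def test_three_shell_regression_matches_truth(self, tissue):
        grads = [gradient_for_bvalue(b, 15.0, 30.0) for b in (6.0, 15.0, 30.0)]
        feats = forward_features(tissue, grads)
        est = loglinear_radius_multi(feats, grads, D0, order="sm")
        assert est.r_sm == pytest.approx(tissue.r, abs=1e-9)
        est = loglinear_radius_multi(feats, grads, D0, order="sv",
                                     Dpar=tissue.Dpar)
        assert est.r_sv == pytest.approx(tissue.r, abs=1e-9)

    def test_two_shell_reduces_to_closed_form(self, shell_pair, tissue):
        feats = forward_features(tissue, shell_pair)
        multi = loglinear_radius_multi(feats, list(shell_pair), D0, order="sm")
        closed = loglinear_radius_sm(feats[0], feats[1], shell_pair, D0)
        assert multi.r_sm == pytest.approx(closed.r_sm, abs=1e-12)


class TestNonlinear:
    @pytest.mark.parametrize("order", ["sm", "sv"])
    def test_same_model_matches_loglinear(self, shell_pair, tissue, order):
        feats = forward_features(tissue, shell_pair)
        nl = nonlinear_radius(feats, list(shell_pair), D0, Dpar=tissue.Dpar,
                              model="neumann", order=order)
        r_nl = nl.r_sm if order == "sm" else nl.r_sv
        assert r_nl == pytest.approx(tissue.r, abs=1e-6)

    def test_vangelderen_self_recovery(self, shell_pair, tissue):
        feats = forward_features(tissue, shell_pair, model="vangelderen")
        nl = nonlinear_radius(feats, list(shell_pair), D0, Dpar=tissue.Dpar,
                              model="vangelderen", order="sm")
        assert nl.r_sm == pytest.approx(tissue.r, abs=1e-6)

    def test_neumann_inversion_of_vangelderen_data(self, shell_pair):
        # quantifies the long-pulse approximation error inside the regime
        params = TissueParams(f=0.6, Dpar=2.2, p2=0.7, D0=D0, r=3.0)
        feats = forward_features(params, shell_pair, model="vangelderen")
        nl = nonlinear_radius(feats, list(shell_pair), D0, model="neumann",
                              order="sm")
        assert nl.r_sm == pytest.approx(3.0, rel=0.05)


class TestNoisyRecovery:
    def test_median_sm_radius_within_5pct(self, shell_pair, protocol):
        # per-direction signal SNR 50, Rician noise, Rician-ML RISH fit
        from axonradius.mcsim import dispersed_cylinder_signal

        g6, g30 = shell_pair
        params = TissueParams(f=0.6, Dpar=2.2, p2=0.7, D0=D0, r=3.0)
        dirs6 = protocol.shells[3].directions
        dirs30 = protocol.shells[4].directions
        clean6 = dispersed_cylinder_signal(3.0, params, [g6], dirs6)[0]
        clean30 = dispersed_cylinder_signal(3.0, params, [g30], dirs30)[0]
        sig6, sig30 = clean6.mean() / 50.0, clean30.mean() / 50.0
        rng = np.random.default_rng(42)
        rs = []
        for _ in range(400):
            s6 = add_rician_noise(clean6, sig6, rng)
            s30 = add_rician_noise(clean30, sig30, rng)
            f1 = rish_features(fit_sh_ml(ShellData(
                b=6.0, grad=g6, directions=dirs6, signals=s6, sigma=sig6), 6),
                1.0, b=6.0)
            f2 = rish_features(fit_sh_ml(ShellData(
                b=30.0, grad=g30, directions=dirs30, signals=s30,
                sigma=sig30), 6), 1.0, b=30.0)
            rs.append(loglinear_radius_sm(f1, f2, shell_pair, D0).r_sm)
        assert np.median(rs) == pytest.approx(3.0, rel=0.05)


class TestDiffusivitySweep:
    def _pairs(self, params, shell_pair):
        f1, f2 = forward_features(params, shell_pair)
        return np.array([[f1.sm, f2.sm]]), np.array([[f1.sv, f2.sv]])

    def test_self_consistent_cell_is_zero(self, shell_pair, tissue):
        sm, sv = self._pairs(tissue, shell_pair)
        surf = diffusivity_sweep(sm, sv, shell_pair, [tissue.D0],
                                 [tissue.Dpar])
        assert surf[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_dpar(self, shell_pair, tissue):
        sm, sv = self._pairs(tissue, shell_pair)
        dpars = np.linspace(1.6, 2.5, 8)
        surf = diffusivity_sweep(sm, sv, shell_pair, [2.5], dpars)
        assert np.all(np.diff(surf[0]) > 0)  # SV radius falls as Dpar rises

    def test_d0_changes_difference_less_than_dpar(self, shell_pair, tissue):
        sm, sv = self._pairs(tissue, shell_pair)
        d0s = np.linspace(2.0, 3.0, 5)
        dpars = np.linspace(1.7, 2.5, 5)
        surf = diffusivity_sweep(sm, sv, shell_pair, d0s, dpars)
        spread_d0 = np.ptp(surf, axis=0).max()
        spread_dpar = np.ptp(surf, axis=1).min()
        assert spread_d0 < spread_dpar

    def test_empty_input_rejected(self, shell_pair):
        with pytest.raises(ValueError):
            diffusivity_sweep(np.empty((0, 2)), np.empty((0, 2)), shell_pair,
                              [2.5], [2.2])
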
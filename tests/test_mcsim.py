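"""Monte Carlo walker physics, PGSE synthesis, and substrate geometry."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from axonradius.mcsim import (
    WalkerEnsemble,
    cylinder_substrate,
    discrete_bvalue,
    dispersed_cylinder_signal,
    glia_substrate,
    pgse_signal,
    seed_walkers,
    simulate_pgse,
    sphere_substrate,
    substrate_from_swc,
    walk,
    watson_concentration,
)
from axonradius.signal_models import (
    PulsedGradient,
    TissueParams,
    compute_bvalue,
    gradient_for_bvalue,
    sm_forward,
    vangelderen_perp,
)

D0 = 2.5
STEP = 0.4
DT = STEP ** 2 / (6 * D0)


class TestSeeding:
    def test_uniform_ball_radial_moment(self):
        sub = sphere_substrate(5.0)
        ens = seed_walkers(sub, 20_000, seed=1)
        rad = np.linalg.norm(ens.positions, axis=1)
        se = rad.std() / np.sqrt(ens.n_walkers)
        assert abs(rad.mean() - 3.75) < 3 * se

    def test_containment_and_determinism(self):
        sub = glia_substrate(seed=3)
        a = seed_walkers(sub, 500, seed=9)
        b = seed_walkers(sub, 500, seed=9)
        assert np.array_equal(a.positions, b.positions)
        assert sub.contains(a.positions, tol=0.0).all()

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            seed_walkers(sphere_substrate(5.0), 0, seed=0)


class TestWalk:
    def test_einstein_relation_free_diffusion(self):
        ens = WalkerEnsemble(4000, STEP, np.zeros((4000, 3)), seed=2)
        traj = walk(ens, None, D0, duration=10.0)
        n_steps = traj.shape[0] - 1
        disp2 = np.sum((traj[-1].astype(float) - traj[0]) ** 2, axis=1)
        se = disp2.std() / np.sqrt(ens.n_walkers)
        assert abs(disp2.mean() - 6 * D0 * n_steps * DT) < 3 * se

    def test_zero_duration_is_identity(self):
        sub = sphere_substrate(4.0)
        ens = seed_walkers(sub, 100, seed=0)
        traj = walk(ens, sub, D0, duration=0.0)
        assert traj.shape[0] == 1
        assert np.allclose(traj[0], ens.positions)

    def test_cylinder_axial_free_transverse_saturates(self):
        sub = cylinder_substrate(3.0)
        ens = seed_walkers(sub, 3000, seed=4)
        traj = walk(ens, sub, D0, duration=30.0)
        d = traj[-1].astype(float) - traj[0]
        axial_var = d[:, 2].var()
        # axial variance grows like free diffusion: 2*D0*t
        n_steps = traj.shape[0] - 1
        expect = 2 * D0 * n_steps * DT
        assert axial_var == pytest.approx(expect, rel=0.15)
        # transverse displacement variance saturates near r^2/2 per axis
        trans_var = d[:, 0].var()
        assert trans_var == pytest.approx(3.0 ** 2 / 2, rel=0.15)

    def test_containment_at_every_step(self):
        sub = glia_substrate(seed=5)
        ens = seed_walkers(sub, 200, seed=6)
        traj = walk(ens, sub, D0, duration=2.0)
        pts = traj.reshape(-1, 3).astype(float)
        assert sub.contains(pts, tol=1e-4).all()

    def test_seed_reproducibility(self):
        sub = sphere_substrate(5.0)
        ens = seed_walkers(sub, 300, seed=11)
        t1 = walk(ens, sub, D0, duration=1.0)
        t2 = walk(ens, sub, D0, duration=1.0)
        assert np.array_equal(t1, t2)

    def test_wrong_dt_rejected(self):
        ens = WalkerEnsemble(10, STEP, np.zeros((10, 3)), seed=0)
        with pytest.raises(ValueError):
            walk(ens, None, D0, duration=1.0, dt=2 * DT)


class TestPgseSignal:
    def test_zero_gradient_gives_unity(self):
        ens = WalkerEnsemble(500, STEP, np.zeros((500, 3)), seed=3)
        traj = walk(ens, None, D0, duration=45.0)
        sig = pgse_signal(traj, [PulsedGradient(0.0, 15.0, 30.0,
                                                direction=(1, 0, 0))], DT)
        assert sig[0] == 1.0

    def test_free_diffusion_matches_closed_form(self):
        grad = gradient_for_bvalue(1.0, 15.0, 30.0, direction=(1.0, 0.0, 0.0))
        sig, se = simulate_pgse(None, [grad], 10_000, D0, seed=5,
                                return_se=True)
        expected = np.exp(-discrete_bvalue(grad, DT) * D0)
        assert abs(sig[0] - expected) < 3 * se[0]

    def test_perpendicular_cylinder_matches_vangelderen(self):
        grad30 = gradient_for_bvalue(30.0, 15.0, 30.0)
        grad = PulsedGradient(grad30.g, 15.0, 30.0, direction=(1.0, 0.0, 0.0))
        sig, se = simulate_pgse(cylinder_substrate(3.0), [grad], 8000, D0,
                                seed=6, return_se=True)
        gpd = vangelderen_perp(3.0, grad30, D0)
        assert abs(sig[0] - gpd) < 3 * se[0]

    def test_rotational_consistency(self):
        # rotating substrate and gradients together leaves the signal alone
        rot = Rotation.from_rotvec([0.3, 0.8, -0.5]).as_matrix()
        g = gradient_for_bvalue(6.0, 15.0, 30.0).g
        sub = cylinder_substrate(3.0)
        grad = PulsedGradient(g, 15.0, 30.0, direction=(1.0, 0.0, 0.0))
        grad_rot = PulsedGradient(g, 15.0, 30.0,
                                  direction=tuple(rot @ [1.0, 0.0, 0.0]))
        s1, e1 = simulate_pgse(sub, [grad], 4000, D0, seed=7, return_se=True)
        s2, e2 = simulate_pgse(sub.rotated(rot), [grad_rot], 4000, D0, seed=8,
                               return_se=True)
        assert abs(s1[0] - s2[0]) < 3 * np.hypot(e1[0], e2[0])

    def test_sphere_substrate_has_no_sv(self):
        from axonradius.rish import fit_sh_ls, rish_features
        from axonradius.synth import uniform_directions

        dirs = uniform_directions(60, seed=1)
        g30 = gradient_for_bvalue(30.0, 15.0, 30.0)
        grads = [PulsedGradient(g30.g, 15.0, 30.0, direction=tuple(d))
                 for d in dirs]
        sig, se = simulate_pgse(sphere_substrate(5.0), grads, 4000, D0,
                                seed=9, return_se=True)
        feats = rish_features(fit_sh_ls(dirs, sig, 6), 1.0)
        noise_floor = np.mean(se)
        assert feats.sv < 3 * noise_floor


class TestDispersedCylinders:
    def test_isotropic_odf_gives_isotropic_signal(self, grad_b30, tissue):
        from axonradius.synth import uniform_directions

        params = TissueParams(f=1.0, Dpar=2.5, p2=0.0, D0=D0, r=2.0)
        dirs = uniform_directions(40, seed=2)
        sig = dispersed_cylinder_signal(2.0, params, [grad_b30], dirs)[0]
        assert sig.std() / sig.mean() < 1e-3

    def test_full_coherence_is_single_kernel(self, grad_b30):
        from axonradius.signal_models import axon_kernel
        from axonradius.synth import uniform_directions

        params = TissueParams(f=1.0, Dpar=2.5, p2=1.0, D0=D0, r=2.0)
        dirs = uniform_directions(20, seed=3)
        sig = dispersed_cylinder_signal(2.0, params, [grad_b30], dirs)[0]
        expected = axon_kernel(grad_b30, dirs[:, 2], params)
        assert np.allclose(sig, expected, rtol=1e-10)

    def test_spherical_mean_matches_forward_model(self, grad_b30):
        from axonradius.synth import uniform_directions

        params = TissueParams(f=1.0, Dpar=2.5, p2=0.7, D0=D0, r=3.0)
        dirs = uniform_directions(240, seed=4)
        sig = dispersed_cylinder_signal(3.0, params, [grad_b30], dirs)[0]
        assert sig.mean() == pytest.approx(sm_forward(grad_b30, params),
                                           rel=0.02)

    def test_unattainable_p2_rejected(self, grad_b30, tissue):
        bad = dict(f=1.0, Dpar=2.5, D0=D0, r=2.0)
        with pytest.raises(ValueError):
            watson_concentration(-0.1)

    def test_watson_concentration_roundtrip(self):
        from axonradius.mcsim import _watson_p2

        for p2 in (0.1, 0.5, 0.7, 0.9):
            k = watson_concentration(p2)
            assert _watson_p2(k) == pytest.approx(p2, abs=1e-8)


class TestSwcReader:
    SWC = """# toy cell
1 1 0 0 0 4.0 -1
2 3 6 0 0 1.2 1
3 3 12 0 0 1.0 2
4 3 0 7 0 1.5 1
"""

    def test_parses_soma_and_segments(self):
        sub = substrate_from_swc(self.SWC)
        assert sub.spheres.shape == (1, 4)
        assert sub.spheres[0, 3] == 4.0
        assert sub.cylinders.shape == (3, 8)
        # first segment runs from the soma center along +x with radius 1.2
        np.testing.assert_allclose(sub.cylinders[0, 3:6], [1, 0, 0])
        assert sub.cylinders[0, 6] == 1.2
        assert sub.cylinders[0, 7] == 6.0

    def test_walkable(self):
        sub = substrate_from_swc(self.SWC)
        ens = seed_walkers(sub, 100, seed=0)
        traj = walk(ens, sub, D0, duration=1.0)
        assert sub.contains(traj[-1].astype(float), tol=1e-4).all()
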
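"""Likelihood evaluation, priors and pose search."""

import numpy as np
import pytest

from pseudotomo.fourier import freq_grid_2d, shell_index
from pseudotomo.geometry import (
    FourierReference,
    ProjectionMapping,
    TiltAlignment,
    matrix_to_euler,
    sample_reference,
)
from pseudotomo.likelihood import (
    OrientationPrior,
    PoseHypothesis,
    grid_search_pose,
    local_refine_pose,
    nll_2d,
    nll_pseudo,
    pose_prior_nll,
    wrap_angle,
)
from pseudotomo.pseudosubtomo import CropEntry, Particle2DCrops, construct_pseudosubtomogram
from pseudotomo.workflow import (
    build_all_pseudosubtomograms,
    extract_particle_crops,
    flat_sigma2,
)
from tests.conftest import state_from_truth


def _synthetic_crops(ref, align, R, n=32, px=4.0, ctf_value=0.8, noise=0.0, seed=0):
    """Crops manufactured exactly as CTF x reference slice (+ noise)."""
    rng = np.random.default_rng(seed)
    hx, hy = freq_grid_2d(n)
    j2 = np.stack([hx.ravel(), hy.ravel()], axis=1)
    entries = []
    for f in range(align.n_tilts):
        A = (align.matrices[f] @ R.T)[:2, :]
        sl = ref.sample(j2 @ A).reshape(n, n)
        X = ctf_value * sl
        if noise > 0:
            X = X + np.fft.fft2(rng.normal(0, noise, (n, n)))
        entries.append(CropEntry(fourier=X, ctf=np.full((n, n), ctf_value)))
    return Particle2DCrops(entries=entries, box=n, pixel_size=px)


@pytest.fixture(scope="module")
def three_tilt_align():
    return TiltAlignment.from_scheme([-20.0, 0.0, 20.0], np.arange(3))


class TestNll2d:
    def test_perfect_data_scores_zero(self, ref32, three_tilt_align):
        R = np.eye(3)
        crops = _synthetic_crops(ref32, three_tilt_align, R)
        s2 = np.full(17, 1.0)
        assert nll_2d(crops, ref32, R, three_tilt_align, s2) == pytest.approx(0.0, abs=1e-12)

    def test_noise_raises_nll_by_chi2_mean(self, ref32, three_tilt_align):
        # complex chi^2: each in-radius pixel contributes ~ n^2 sigma_px^2 / sigma2
        R = np.eye(3)
        noise = 0.7
        n = 32
        crops = _synthetic_crops(ref32, three_tilt_align, R, noise=noise, seed=4)
        s2 = np.full(17, n**2 * noise**2)
        val = nll_2d(crops, ref32, R, three_tilt_align, s2, premultiplied=False)
        # count in-radius pixels
        hx, hy = freq_grid_2d(n)
        j2 = np.stack([hx.ravel(), hy.ravel()], axis=1)
        lim = n / 2 - 1
        n_pix = 0
        for f in range(3):
            k3 = j2 @ three_tilt_align.matrices[f][:2, :]
            n_pix += int(np.sum(np.all(np.abs(k3) <= lim, axis=1)
                                & (np.linalg.norm(k3, axis=1) <= lim)))
        assert val == pytest.approx(n_pix, rel=3 / np.sqrt(n_pix) * 3)

    def test_doubling_noise_power_halves_value(self, ref32, three_tilt_align):
        R = np.eye(3)
        crops = _synthetic_crops(ref32, three_tilt_align, R, noise=0.5, seed=5)
        s2 = np.full(17, 2.0)
        v1 = nll_2d(crops, ref32, R, three_tilt_align, s2)
        v2 = nll_2d(crops, ref32, R, three_tilt_align, 2 * s2)
        assert v2 == pytest.approx(v1 / 2, rel=1e-12)

    def test_zero_noise_power_in_populated_shell_raises(self, ref32, three_tilt_align):
        crops = _synthetic_crops(ref32, three_tilt_align, np.eye(3))
        s2 = np.full(17, 1.0)
        s2[3] = 0.0
        with pytest.raises(ValueError, match="noise power"):
            nll_2d(crops, ref32, np.eye(3), three_tilt_align, s2)


class TestNllPseudo:
    def test_matching_model_scores_zero(self, ref32):
        # D manufactured exactly as W * V(R k) on the k_z = 0 plane
        n = 32
        align = TiltAlignment.from_scheme([0.0], [0])
        R = np.eye(3)
        crops = _synthetic_crops(ref32, align, R, ctf_value=0.9)
        P = construct_pseudosubtomogram(
            crops, [ProjectionMapping(A=np.eye(3)[:2, :], t=np.zeros(2))]
        )
        val = nll_pseudo(P, ref32, R, np.full(17, 1.0))
        assert val == pytest.approx(0.0, abs=1e-10)

    def test_single_tilt_on_grid_equals_2d(self, ref32, sim_five_tilts):
        # exact-mapping regime: one zero-degree tilt, identity construction
        from pseudotomo.simulate import SimulationConfig, simulate_tilt_series

        stack, truth = sim_five_tilts
        state = state_from_truth(stack, truth, 32)
        crops = extract_particle_crops(state, 0)
        # keep only the untilted image (angle 0 is first in the scheme)
        f0 = int(np.argmin(np.abs(truth.align.tilt_angles)))
        only = Particle2DCrops(entries=[crops.entries[f0]], box=32, pixel_size=4.0)
        align0 = TiltAlignment.from_scheme([0.0], [0])
        P = construct_pseudosubtomogram(
            only, [ProjectionMapping(A=np.eye(3)[:2, :], t=np.zeros(2))]
        )
        R = truth.poses[0].rotation
        s2 = flat_sigma2(32, 1.0)
        a = nll_pseudo(P, ref32, R, s2)
        b = nll_2d(only, ref32, R, align0, s2)
        assert a == pytest.approx(b, rel=1e-6)

    def test_multi_tilt_approximation_quality(self, phantom32, ref32):
        # with each likelihood using its own residual-estimated noise
        # spectrum, the 3D approximation tracks the 2D sum to a few percent
        from pseudotomo.reconstruct import ParticleRecord, update_sigma
        from pseudotomo.simulate import SimulationConfig, simulate_tilt_series

        cfg = SimulationConfig(
            box=32, n_particles=6, field_size=200, noise_sigma=2.0,
            max_tilt=40, tilt_step=20, apply_damage=True, seed=3,
        )
        stack, truth = simulate_tilt_series(phantom32, cfg)
        state = state_from_truth(stack, truth, 32)
        pseudos = build_all_pseudosubtomograms(state)
        recs = [
            ParticleRecord(pseudo=pseudos[p], pose=state.poses[p]) for p in range(6)
        ]
        s3 = update_sigma(recs, ref32)
        # 2D-side per-shell noise estimate from the same residuals
        n = 32
        hx, hy = freq_grid_2d(n)
        sh2 = shell_index(hx, hy).ravel()
        j2 = np.stack([hx.ravel(), hy.ravel()], axis=1)
        num = np.zeros(17)
        den = np.zeros(17)
        allcrops = []
        for p in range(6):
            crops = extract_particle_crops(state, p)
            allcrops.append(crops)
            R = truth.poses[p].rotation
            for f in range(stack.n_tilts):
                e = crops.entries[f]
                k3 = j2 @ truth.align.matrices[f][:2, :]
                lim = n / 2 - 1
                ok = np.all(np.abs(k3) <= lim, axis=1) & (
                    np.linalg.norm(k3, axis=1) <= lim
                )
                pred = sample_reference(ref32, k3[ok] @ R.T)
                c = e.ctf.ravel()[ok]
                resid = np.abs(c * e.fourier.ravel()[ok] - c * c * pred) ** 2
                np.add.at(num, sh2[ok], resid)
                np.add.at(den, sh2[ok], 1.0)
        s2d = num / (2 * np.maximum(den, 1))
        rels = []
        for p in range(6):
            R = truth.poses[p].rotation
            v3 = nll_pseudo(pseudos[p], ref32, R, s3)
            v2 = nll_2d(allcrops[p], ref32, R, truth.align, s2d)
            rels.append(abs(v3 - v2) / v2)
        assert np.median(rels) < 0.05


class TestPrior:
    def test_centre_scores_zero(self):
        prior = OrientationPrior(
            centre=PoseHypothesis(np.array([10.0, 20.0, 30.0])),
            sigma_euler=np.array([5.0, 5.0, 5.0]),
            sigma_shift=np.array([2.0, 2.0, 2.0]),
        )
        assert pose_prior_nll(prior.centre, prior) == 0.0

    def test_uniform_prior_scores_zero_everywhere(self):
        prior = OrientationPrior(centre=PoseHypothesis(np.zeros(3)))
        pose = PoseHypothesis(np.array([123.0, 45.0, -60.0]), np.array([9.0, 9.0, 9.0]))
        assert pose_prior_nll(pose, prior) == 0.0

    def test_angular_wrapping(self):
        assert wrap_angle(359.0 - 1.0) == pytest.approx(-2.0)
        prior = OrientationPrior(
            centre=PoseHypothesis(np.array([1.0, 0.0, 0.0])),
            sigma_euler=np.array([2.0, np.inf, np.inf]),
        )
        val = pose_prior_nll(PoseHypothesis(np.array([359.0, 0.0, 0.0])), prior)
        assert val == pytest.approx(0.5 * (2.0 / 2.0) ** 2)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            OrientationPrior(
                centre=PoseHypothesis(np.zeros(3)), sigma_euler=np.array([0.0, 1.0, 1.0])
            )


class TestGridSearch:
    @pytest.fixture(scope="class")
    def noiseless_setup(self, ref32):
        align = TiltAlignment.from_scheme(
            np.arange(-60, 61, 10, dtype=float), np.arange(13)
        )
        from pseudotomo.geometry import euler_to_matrix

        true_euler = np.array([20.0, 40.0, -10.0])
        R = euler_to_matrix(*true_euler)
        crops = _synthetic_crops(ref32, align, R, ctf_value=0.9)
        mappings = [
            ProjectionMapping(A=align.matrices[f][:2, :], t=np.zeros(2))
            for f in range(align.n_tilts)
        ]
        P = construct_pseudosubtomogram(crops, mappings)
        return P, true_euler

    def test_noiseless_truth_on_grid_is_map(self, ref32, noiseless_setup):
        P, true_euler = noiseless_setup
        prior = OrientationPrior(
            centre=PoseHypothesis(true_euler + np.array([10.0, -10.0, 10.0])),
            sigma_euler=np.full(3, 10.0),
        )
        res = grid_search_pose(P, ref32, np.full(17, 1.0), prior, angular_step=10.0)
        np.testing.assert_allclose(res.map_pose.euler, true_euler, atol=1e-9)
        assert res.weights.max() > 0.99

    def test_weights_normalised_and_shift_invariant(self, ref32, noiseless_setup):
        P, true_euler = noiseless_setup
        prior = OrientationPrior(
            centre=PoseHypothesis(true_euler), sigma_euler=np.full(3, 15.0)
        )
        res = grid_search_pose(P, ref32, np.full(17, 1.0), prior, angular_step=15.0)
        assert res.weights.sum() == pytest.approx(1.0)
        # adding a constant to all nll leaves the weights unchanged
        flat = res.nll + 123.4
        w = np.exp(-(flat - flat.min()))
        np.testing.assert_allclose(w / w.sum(), res.weights, rtol=1e-9)

    def test_tie_break_to_lowest_linear_index(self):
        # a flat landscape: all poses score identically -> index (0, 0)
        n = 16
        P = construct_pseudosubtomogram(
            Particle2DCrops(
                entries=[CropEntry(fourier=np.zeros((n, n), dtype=complex),
                                   ctf=np.ones((n, n)))],
                box=n, pixel_size=4.0,
            ),
            [ProjectionMapping(A=np.eye(3)[:2, :], t=np.zeros(2))],
        )
        zero_ref = FourierReference.from_map(np.zeros((n, n, n)))
        prior = OrientationPrior(centre=PoseHypothesis(np.zeros(3)),
                                 sigma_euler=np.full(3, np.inf))
        res = grid_search_pose(P, zero_ref, np.full(9, 1.0), prior, angular_step=90.0)
        assert res.map_index == (0, 0)

    def test_empty_grid_rejected(self, ref32, noiseless_setup):
        P, true_euler = noiseless_setup
        prior = OrientationPrior(centre=PoseHypothesis(true_euler))
        with pytest.raises(ValueError):
            grid_search_pose(P, ref32, np.full(17, 1.0), prior, angular_step=-1.0)


class TestLocalRefine:
    """Convergence is checked against the objective's own optimum: the
    approximate 3D likelihood's minimum can sit a degree or so from the
    generative pose even without noise (anisotropic insertion smearing),
    so proximity to truth is asserted only at the grid-search level."""

    @pytest.fixture(scope="class")
    def refine_setup(self, ref32):
        from pseudotomo.geometry import euler_to_matrix

        align = TiltAlignment.from_scheme(
            np.arange(-60, 61, 15, dtype=float), np.arange(9)
        )
        true_euler = np.array([5.0, 30.0, -12.0])
        R = euler_to_matrix(*true_euler)
        crops = _synthetic_crops(ref32, align, R, ctf_value=0.9)
        mappings = [ProjectionMapping(A=align.matrices[f][:2, :], t=np.zeros(2))
                    for f in range(align.n_tilts)]
        P = construct_pseudosubtomogram(crops, mappings)
        s2 = np.full(17, 1.0)
        opt = local_refine_pose(
            P, ref32, s2, PoseHypothesis(true_euler), maxiter=2000
        )
        return P, s2, true_euler, opt

    def test_restarting_at_the_optimum_stays_there(self, ref32, refine_setup):
        P, s2, _, opt = refine_setup
        again = local_refine_pose(P, ref32, s2, opt)
        assert np.all(np.abs(wrap_angle(again.euler - opt.euler)) < 0.3)
        assert np.all(np.abs(again.shift - opt.shift) < 0.3)

    def test_perturbation_recovered_to_the_optimum(self, ref32, refine_setup):
        from pseudotomo.likelihood import PseudoEvaluator

        P, s2, true_euler, opt = refine_setup
        start = PoseHypothesis(true_euler + np.array([4.0, -4.0, 4.0]))
        out = local_refine_pose(P, ref32, s2, start, maxiter=2000)
        ev = PseudoEvaluator(P, ref32, s2)
        # contract: never worse than the start
        assert ev.nll(out.rotation, out.shift) <= ev.nll(start.rotation, start.shift)
        # and close to the independently converged optimum in nll terms
        assert ev.nll(out.rotation, out.shift) <= 1.05 * ev.nll(opt.rotation, opt.shift)
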
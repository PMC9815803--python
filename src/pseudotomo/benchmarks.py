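"""Simulation studies validating each stage of the pipeline.

Each function generates synthetic data with known ground truth, runs the
estimation machinery, and returns the measured figures of merit.  They
are used by the test-suite and by ``scripts/acceptance.py``; all
randomness is controlled by the ``seed`` argument.

Problem sizes default to desk-scale settings (boxes of 32-48 voxels, at
most a few hundred particles) chosen so the whole battery runs on one
CPU core in minutes; the figures they produce are properties of the
method, not of these sizes, and are insensitive to modest changes in
them.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .ctf import zernike_basis
from .fourier import freq_grid_2d, shell_index
from .geometry import (
    FourierReference,
    ProjectionMapping,
    TiltAlignment,
    matrix_to_euler,
    project_map_slice,
    sample_reference,
    tilt_matrix,
)
from .likelihood import (
    OrientationPrior,
    PoseHypothesis,
    grid_search_pose,
    local_refine_pose,
    nll_2d,
    nll_pseudo,
)
from .pseudosubtomo import Particle2DCrops, construct_pseudosubtomogram, extract_crop
from .reconstruct import (
    ParticleRecord,
    ReconstructionState,
    backproject_accumulate,
    compute_fsc,
    em_update_map,
    update_sigma,
)
from .simulate import (
    SimulationConfig,
    make_phantom,
    noise_sigma_for_snr,
    simulate_tilt_series,
)
from .tiltrefine import (
    condense_tilt_image,
    estimate_aberrations,
    precompute_position_likelihood,
    refine_defocus,
    refine_particle_motion,
    refine_rigid_tilt_alignment,
)
from .workflow import (
    ProjectState,
    build_all_pseudosubtomograms,
    build_pseudosubtomogram_oriented,
    extract_particle_crops,
    flat_sigma2,
    make_tilt_views,
    particle_ctf_grid,
    projected_position_px,
    refine_cycle,
)

__all__ = [
    "likelihood_equivalence",
    "multiplicity_conservation",
    "reconstruction_fidelity",
    "pose_recovery",
    "sigma_recovery",
    "defocus_recovery",
    "rigid_alignment_recovery",
    "motion_recovery",
    "aberration_recovery",
    "workflow_cycle",
]


def _state(stack, truth, box, apply_damage=True):
    return ProjectState(
        stack=stack,
        align=truth.align,
        positions=np.array([p.position for p in truth.poses]),
        poses=[PoseHypothesis(np.array(matrix_to_euler(p.rotation))) for p in truth.poses],
        ctf=list(truth.ctf),
        box=box,
        apply_damage=apply_damage,
    )


def likelihood_equivalence(seed: int = 0, box: int = 32, n_particles: int = 12) -> dict:
    """2D-vs-3D likelihood agreement.

    Exact regime: a single untilted, on-grid construction must match the
    per-pixel 2D sum to floating-point precision.  General regime: five
    tilts at SNR ~1, each likelihood evaluated with its own
    residual-estimated noise spectrum (the sigma^2 of its model).
    """
    phantom = make_phantom(box, seed=seed, pixel_size=4.0)
    ref = FourierReference.from_map(phantom.data)
    base = SimulationConfig(
        box=box, n_particles=n_particles, field_size=240, max_tilt=40,
        tilt_step=20, apply_damage=True, seed=seed,
    )
    sigma = noise_sigma_for_snr(phantom, base, snr=1.0)
    cfg = replace(base, noise_sigma=sigma)
    stack, truth = simulate_tilt_series(phantom, cfg)
    state = _state(stack, truth, box)
    pseudos = build_all_pseudosubtomograms(state)

    # exact regime: the zero-degree tilt alone
    f0 = int(np.argmin(np.abs(truth.align.tilt_angles)))
    crops0 = extract_particle_crops(state, 0)
    only = Particle2DCrops(entries=[crops0.entries[f0]], box=box, pixel_size=4.0)
    P0 = construct_pseudosubtomogram(
        only, [ProjectionMapping(A=np.eye(3)[:2, :], t=np.zeros(2))]
    )
    align0 = TiltAlignment.from_scheme([0.0], [0])
    R0 = truth.poses[0].rotation
    s2flat = flat_sigma2(box, max(sigma, 1e-6))
    a = nll_pseudo(P0, ref, R0, s2flat)
    b = nll_2d(only, ref, R0, align0, s2flat)
    exact_rel = abs(a - b) / b

    # general regime with model-consistent noise spectra
    recs = [ParticleRecord(pseudo=pseudos[p], pose=state.poses[p])
            for p in range(n_particles)]
    s3 = update_sigma(recs, ref)
    hx, hy = freq_grid_2d(box)
    sh2 = shell_index(hx, hy).ravel()
    j2 = np.stack([hx.ravel(), hy.ravel()], axis=1)
    ns = box // 2 + 1
    num = np.zeros(ns)
    den = np.zeros(ns)
    allcrops = []
    lim = box / 2 - 1
    for p in range(n_particles):
        crops = extract_particle_crops(state, p)
        allcrops.append(crops)
        R = truth.poses[p].rotation
        for f in range(stack.n_tilts):
            e = crops.entries[f]
            k3 = j2 @ truth.align.matrices[f][:2, :]
            ok = np.all(np.abs(k3) <= lim, axis=1) & (np.linalg.norm(k3, axis=1) <= lim)
            pred = sample_reference(ref, k3[ok] @ R.T)
            c = e.ctf.ravel()[ok]
            resid = np.abs(c * e.fourier.ravel()[ok] - c * c * pred) ** 2
            np.add.at(num, sh2[ok], resid)
            np.add.at(den, sh2[ok], 1.0)
    s2d = num / (2 * np.maximum(den, 1))
    rels = []
    for p in range(n_particles):
        R = truth.poses[p].rotation
        v3 = nll_pseudo(pseudos[p], ref, R, s3)
        v2 = nll_2d(allcrops[p], ref, R, truth.align, s2d)
        rels.append(abs(v3 - v2) / v2)
    return {
        "exact_rel": float(exact_rel),
        "general_median_rel": float(np.median(rels)),
        "snr": float(truth.snr),
    }


def multiplicity_conservation(seed: int = 0, box: int = 32) -> dict:
    """Sum of M versus the number of inserted in-radius pixels, exactly,
    for several tilt schemes including an irregular one."""
    rng = np.random.default_rng(seed)
    hx, hy = freq_grid_2d(box)
    worst = 0.0
    total = 0
    schemes = [
        np.arange(-60.0, 61.0, 3.0),
        np.arange(-45.0, 46.0, 15.0),
        rng.uniform(-80, 80, 11),  # arbitrary scheme
    ]
    from .pseudosubtomo import CropEntry

    for angles in schemes:
        entries = []
        for _ in angles:
            plane = rng.normal(size=(box, box)) + 1j * rng.normal(size=(box, box))
            entries.append(CropEntry(fourier=plane, ctf=np.ones((box, box))))
        crops = Particle2DCrops(entries=entries, box=box, pixel_size=4.0)
        mappings = [ProjectionMapping(A=tilt_matrix(a)[:2, :], t=np.zeros(2))
                    for a in angles]
        P = construct_pseudosubtomogram(crops, mappings)
        worst = max(worst, abs(float(P.M.sum()) - P.n_inserted))
        total += P.n_inserted
    return {"max_abs_error": worst, "n_inserted": total}


def reconstruction_fidelity(
    seed: int = 0,
    box: int = 48,
    n_particles: int = 200,
    n_tomograms: int = 8,
) -> dict:
    """Noiseless end-to-end reconstruction versus the phantom.

    Particles with uniform random orientations are drawn from several
    simulated tomograms spanning a realistic defocus ladder (1.2-4.5 um)
    so CTF zeros do not coincide; the map comes from the refined-frame,
    oversampled reconstruction path.
    """
    phantom = make_phantom(box, seed=seed, pixel_size=4.0)
    defoci = np.linspace(12000.0, 45000.0, n_tomograms)
    per_tomo = n_particles // n_tomograms
    N = 2 * box
    states = [ReconstructionState.empty(N), ReconstructionState.empty(N)]
    from .workflow import _refine_shells, _fourier_crop

    s2f = _refine_shells(np.ones(box // 2 + 1), box, 2)
    idx = 0
    for t, dz in enumerate(defoci):
        cfg = SimulationConfig(
            box=box, n_particles=per_tomo, field_size=720, noise_sigma=0.0,
            defocus=float(dz), max_tilt=60, tilt_step=3, apply_damage=False,
            render_oversample=4, seed=seed * 1009 + t,
        )
        stack, truth = simulate_tilt_series(phantom, cfg)
        st = _state(stack, truth, box, apply_damage=False)
        for p in range(st.n_particles):
            P = build_pseudosubtomogram_oriented(st, p, st.poses[p].rotation, oversample=2)
            backproject_accumulate(states[idx % 2], P, np.eye(3), s2f)
            idx += 1
    full = states[0].merged(states[1])
    V = _fourier_crop(em_update_map(full, None), box, 2)
    from .fourier import ft3

    fsc = compute_fsc(V, ft3(phantom.data))
    k08 = int(np.floor(0.8 * box / 2))
    return {
        "min_fsc_to_0.8_nyquist": float(np.min(fsc[1 : k08 + 1])),
        "n_particles": idx,
    }


def pose_recovery(
    seed: int = 0,
    box: int = 32,
    n_particles: int = 100,
    angular_step: float = 10.0,
    start_sigma_deg: float = 8.0,
    start_sigma_px: float = 1.0,
    prior_sigma_deg: float = 15.0,
    kmax: float | None = 13.0,
) -> dict:
    """Grid search plus local refinement against perturbed starts at
    SNR 0.5 under the full dose-symmetric scheme."""
    phantom = make_phantom(box, seed=seed, pixel_size=4.0)
    ref = FourierReference.from_map(phantom.data)
    base = SimulationConfig(
        box=box, n_particles=n_particles, field_size=900, max_tilt=60,
        tilt_step=3, apply_damage=True, seed=seed,
    )
    sigma = noise_sigma_for_snr(phantom, replace(base, n_particles=8, field_size=260), 0.5)
    cfg = replace(base, noise_sigma=sigma)
    stack, truth = simulate_tilt_series(phantom, cfg)
    state = _state(stack, truth, box)
    pseudos = build_all_pseudosubtomograms(state)
    s2 = flat_sigma2(box, sigma)
    rng = np.random.default_rng(seed + 1)
    ang_errors, trans_errors = [], []
    for p in range(n_particles):
        true_euler = np.array(matrix_to_euler(truth.poses[p].rotation))
        start = PoseHypothesis(
            true_euler + rng.normal(0, start_sigma_deg, 3),
            rng.normal(0, start_sigma_px * 4.0, 3),
        )
        prior = OrientationPrior(
            centre=start,
            sigma_euler=np.full(3, prior_sigma_deg),
            sigma_shift=np.full(3, 8.0),
        )
        res = grid_search_pose(pseudos[p], ref, s2, prior, angular_step, kmax=kmax)
        pose = local_refine_pose(pseudos[p], ref, s2, res.map_pose, prior=prior, kmax=kmax)
        Rt = truth.poses[p].rotation
        Re = pose.rotation
        ang = np.degrees(np.arccos(np.clip((np.trace(Rt @ Re.T) - 1) / 2, -1, 1)))
        ang_errors.append(ang)
        trans_errors.append(np.linalg.norm(pose.shift) / 4.0)  # px; truth offset is 0
    return {
        "median_angular_error_deg": float(np.median(ang_errors)),
        "median_translation_error_px": float(np.median(trans_errors)),
        "snr": float(truth.snr),
        "n_particles": n_particles,
    }


def sigma_recovery(seed: int = 0, box: int = 32, n_particles: int = 100) -> dict:
    """Noise-power estimation on a pure-noise, untilted data set with
    |CTF| = 1 (the regime where the generative per-shell value is the
    analytic s^2/2 of the estimator's data model)."""
    noise = 3.0
    cfg = SimulationConfig(
        box=box, n_particles=n_particles, field_size=720, noise_sigma=noise,
        max_tilt=0.0, apply_damage=False, defocus=0.0, cs_mm=0.0,
        amplitude_contrast=1.0, defocus_jitter=0.0, seed=seed,
    )
    phantom = make_phantom(box, seed=seed, pixel_size=4.0)
    stack, truth = simulate_tilt_series(phantom, cfg)
    rng = np.random.default_rng(seed + 7)
    stack.images[:] = rng.normal(0.0, noise, stack.images.shape)
    state = _state(stack, truth, box, apply_damage=False)
    pseudos = build_all_pseudosubtomograms(state)
    recs = [ParticleRecord(pseudo=pseudos[p], pose=state.poses[p])
            for p in range(n_particles)]
    zero_ref = FourierReference.from_map(np.zeros((box, box, box)))
    sig = update_sigma(recs, zero_ref)
    expected = box**2 * noise**2 / 2.0
    k08 = int(np.floor(0.8 * box / 2))
    ratios = sig[1 : k08 + 1] / expected
    return {
        "max_rel_deviation": float(np.nanmax(np.abs(ratios - 1.0))),
        "n_particles": n_particles,
    }


def _defocus_error_for_subset(state, ref, s2, f, subset, inject=800.0):
    sub = ProjectState(
        stack=state.stack, align=state.align,
        positions=state.positions[subset],
        poses=[state.poses[i] for i in subset],
        ctf=list(state.ctf), box=state.box, apply_damage=state.apply_damage,
    )
    sub.ctf[f] = replace(
        sub.ctf[f],
        defocus_u=sub.ctf[f].defocus_u + inject,
        defocus_v=sub.ctf[f].defocus_v + inject,
    )
    views, kappa = make_tilt_views(sub, ref, f)
    pair = condense_tilt_image(views, s2, sub.ctf[f].amplitude_contrast, sub.pixel_size)
    dz, ok = refine_defocus(pair, sub.ctf[f].wavelength, 3000.0, 100.0, kappa=kappa)
    return abs(dz + inject), ok


def defocus_recovery(
    seed: int = 0, box: int = 64, n_particles: int = 100, n_seeds: int = 5
) -> dict:
    """Recovery of an injected +800 A defocus offset on one tilt at
    SNR 0.5 (box 64), and the shrinkage of the error with particle count
    (10 vs all)."""
    phantom = make_phantom(box, seed=seed, pixel_size=4.0)
    ref = FourierReference.from_map(phantom.data)
    errs_full, errs_small = [], []
    f = 1
    for s in range(n_seeds):
        base = SimulationConfig(
            box=box, n_particles=n_particles, field_size=1700, max_tilt=60,
            tilt_step=3, apply_damage=True, seed=seed * 131 + s,
        )
        sigma = noise_sigma_for_snr(
            phantom, replace(base, n_particles=8, field_size=620), 0.5
        )
        cfg = replace(base, noise_sigma=sigma)
        stack, truth = simulate_tilt_series(phantom, cfg)
        state = _state(stack, truth, box)
        s2 = flat_sigma2(box, sigma)
        e_full, _ = _defocus_error_for_subset(state, ref, s2, f, np.arange(n_particles))
        e_small, _ = _defocus_error_for_subset(state, ref, s2, f, np.arange(10))
        errs_full.append(e_full)
        errs_small.append(e_small)
    return {
        "median_error_A": float(np.median(errs_full)),
        "median_error_10_particles_A": float(np.median(errs_small)),
        "n_particles": n_particles,
    }


def rigid_alignment_recovery(
    seed: int = 0, box: int = 32, n_particles: int = 60
) -> dict:
    """Recovery of an injected 1.5 px shift and 0.5 deg in-plane rotation
    on a single tilt image at SNR ~0.5."""
    phantom = make_phantom(box, seed=seed, pixel_size=4.0)
    ref = FourierReference.from_map(phantom.data)
    F = 21
    f_inj = 2
    inj_shift_px = np.array([1.5, 0.0])
    inj_rot = 0.5
    tilt_shifts = np.zeros((F, 2))
    tilt_shifts[f_inj] = inj_shift_px * 4.0
    tilt_inplane = np.zeros(F)
    tilt_inplane[f_inj] = inj_rot
    base = SimulationConfig(
        box=box, n_particles=n_particles, field_size=600, max_tilt=60, tilt_step=6,
        apply_damage=True, seed=seed, tilt_shifts=tilt_shifts, tilt_inplane=tilt_inplane,
    )
    sigma = noise_sigma_for_snr(phantom, replace(base, n_particles=8, field_size=260), 0.5)
    cfg = replace(base, noise_sigma=sigma)
    stack, truth = simulate_tilt_series(phantom, cfg)
    state = _state(stack, truth, box)
    angles = cfg.tilt_angles()
    state.align = TiltAlignment(
        np.stack([tilt_matrix(a) for a in angles]), np.zeros((F, 2)),
        angles, np.arange(F), truth.align.dose,
    )
    s2 = flat_sigma2(box, sigma)
    centre = stack.images.shape[-1] / 2.0
    liks, pos = [], []
    for p in range(n_particles):
        pos2d = projected_position_px(state, p, f_inj)
        X, vis = extract_crop(stack.images[f_inj], (pos2d[0], pos2d[1]), box)
        if not vis:
            continue
        ctf, oddph = particle_ctf_grid(state, p, f_inj)
        A = (state.align.matrices[f_inj] @ state.poses[p].rotation.T)[:2, :]
        pred = project_map_slice(ref, ProjectionMapping(A=A, t=np.zeros(2)), 4.0)
        liks.append(precompute_position_likelihood(X, pred * ctf * oddph, s2, 6))
        pos.append(pos2d)
    rot, shift, ok = refine_rigid_tilt_alignment(liks, np.asarray(pos),
                                                 np.array([centre, centre]))
    return {
        "shift_error_px": float(np.max(np.abs(shift - inj_shift_px))),
        "rotation_error_deg": float(abs(rot - inj_rot)),
        "n_particles": len(liks),
    }


def motion_recovery(seed: int = 0, box: int = 32, n_particles: int = 12) -> dict:
    """Common 3 px linear drift at high SNR, plus the two limits of the
    spatial-coherence prior (stiff -> rigid-shift solution, loose ->
    independent per-particle fits)."""
    phantom = make_phantom(box, seed=seed, pixel_size=4.0)
    ref = FourierReference.from_map(phantom.data)
    F = 11
    drift = np.zeros((F, 3))
    for i in range(F):
        t = i / (F - 1)
        drift[i] = [12.0 * t, -6.0 * t, 4.0 * t]
    cfg = SimulationConfig(
        box=box, n_particles=n_particles, field_size=420, noise_sigma=0.1,
        max_tilt=60, tilt_step=12, apply_damage=False, seed=seed, motion=drift,
    )
    stack, truth = simulate_tilt_series(phantom, cfg)
    state = _state(stack, truth, box, apply_damage=False)
    s2 = flat_sigma2(box, 0.1)
    liks = [[None] * F for _ in range(n_particles)]
    for p in range(n_particles):
        for f in range(F):
            pos2d = projected_position_px(state, p, f)
            X, _ = extract_crop(stack.images[f], (pos2d[0], pos2d[1]), box)
            ctf, oddph = particle_ctf_grid(state, p, f)
            A = (state.align.matrices[f] @ state.poses[p].rotation.T)[:2, :]
            pred = project_map_slice(ref, ProjectionMapping(A=A, t=np.zeros(2)), 4.0)
            liks[p][f] = precompute_position_likelihood(X, pred * ctf * oddph, s2, 8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = refine_particle_motion(
            liks, state.align.matrices, state.positions,
            state.align.acquisition_order, 4.0,
            sigma_displacement=3.0, correlation_length=1e6, maxiter=3000,
        )
        # stiff limit versus the rigid translation solution on the last tilt
        stiff = model  # correlation length is already effectively infinite
        f = F - 1
        centre = stack.images.shape[-1] / 2.0
        rot, shift, _ = refine_rigid_tilt_alignment(
            [liks[p][f] for p in range(n_particles)],
            np.array([projected_position_px(state, p, f) for p in range(n_particles)]),
            np.array([centre, centre]),
        )
        common_px = (state.align.matrices[f] @ stiff.offsets[:, f, :].mean(axis=0))[:2] / 4.0
        stiff_vs_rigid = float(np.max(np.abs(common_px - shift)))
        # loose limit versus an independent single-particle fit
        loose = refine_particle_motion(
            liks, state.align.matrices, state.positions,
            state.align.acquisition_order, 4.0,
            sigma_displacement=3.0, correlation_length=1e-3, maxiter=3000,
        )
        single = refine_particle_motion(
            [liks[3]], state.align.matrices, state.positions[3:4],
            state.align.acquisition_order, 4.0,
            sigma_displacement=3.0, correlation_length=1e-3, maxiter=3000,
        )
    mean_traj = model.offsets.mean(axis=0)
    drift_err_px = float(np.max(np.abs(mean_traj[:, :2] - drift[:, :2])) / 4.0)
    loose_vs_indep = float(np.max(np.abs(loose.offsets[3] - single.offsets[0])))
    return {
        "drift_error_px": drift_err_px,
        "stiff_limit_vs_rigid_px": stiff_vs_rigid,
        "loose_limit_vs_independent_A": loose_vs_indep,
        "n_particles": n_particles,
    }


def aberration_recovery(seed: int = 0, box: int = 32, n_particles: int = 200) -> dict:
    """Injected trefoil of 0.5 rad at Nyquist on noiseless data, pooled
    over the whole data set."""
    phantom = make_phantom(box, seed=seed, pixel_size=4.0)
    ref = FourierReference.from_map(phantom.data)
    basis = zernike_basis(3, 0.5 / 4.0, parity="odd")
    true = np.zeros(basis.n_terms)
    i_tref = basis.nm_pairs.index((3, 3))
    true[i_tref] = 0.5
    cfg = SimulationConfig(
        box=box, n_particles=n_particles, field_size=1600, noise_sigma=0.0,
        max_tilt=60, tilt_step=20, apply_damage=False, seed=seed,
        zernike_odd=(true, basis.nm_pairs),
    )
    stack, truth = simulate_tilt_series(phantom, cfg)
    state = _state(stack, truth, box, apply_damage=False)
    state.ctf = [replace(c, zernike_odd=np.zeros(0), zernike_odd_nm=()) for c in state.ctf]
    s2 = flat_sigma2(box, 1.0)
    pairs = []
    for f in range(stack.n_tilts):
        views, _ = make_tilt_views(state, ref, f)
        pairs.append(condense_tilt_image(views, s2, state.ctf[f].amplitude_contrast, 4.0))
    coeffs = estimate_aberrations(pairs, basis, parity="odd")
    return {
        "trefoil_rel_error": float(abs(coeffs[i_tref] - 0.5) / 0.5),
        "max_other_coeff": float(np.max(np.abs(np.delete(coeffs, i_tref)))),
        "n_particles": n_particles,
    }


def workflow_cycle(seed: int = 0, box: int = 32, n_particles: int = 20, n_seeds: int = 3) -> dict:
    """One full improve->realign cycle starting from perturbed CTFs,
    tilt alignments and poses; reports the change in half-set resolution
    (negative = improvement), median over seeds."""
    phantom = make_phantom(box, seed=seed, pixel_size=4.0)
    ref = FourierReference.from_map(phantom.data)
    deltas = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed * 613 + s)
        F = 21
        tilt_shifts = rng.normal(0, 4.0, (F, 2))
        cfg = SimulationConfig(
            box=box, n_particles=n_particles, field_size=420, noise_sigma=1.0,
            max_tilt=60, tilt_step=6, apply_damage=True, seed=seed * 613 + s,
            tilt_shifts=tilt_shifts,
        )
        stack, truth = simulate_tilt_series(phantom, cfg)
        angles = cfg.tilt_angles()
        state = ProjectState(
            stack=stack,
            align=TiltAlignment(
                np.stack([tilt_matrix(a) for a in angles]), np.zeros((F, 2)),
                angles, np.arange(F), truth.align.dose,
            ),
            positions=np.array([p.position for p in truth.poses]),
            poses=[
                PoseHypothesis(np.array(matrix_to_euler(p.rotation)) + rng.normal(0, 4, 3))
                for p in truth.poses
            ],
            ctf=[
                replace(c, defocus_u=c.defocus_u + rng.normal(0, 500),
                        defocus_v=c.defocus_v + rng.normal(0, 500))
                for c in truth.ctf
            ],
            box=box,
        )
        s2 = flat_sigma2(box, 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = refine_cycle(state, ref, s2, angular_step=5.0, prior_sigma_euler=6.0)
        deltas.append(rep.resolution_after - rep.resolution_before)
    return {
        "median_resolution_change_A": float(np.median(deltas)),
        "n_seeds": n_seeds,
    }
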
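"""Pipeline glue: from tilt-series images and metadata to crops,
pseudo-subtomograms, condensed images and full improve->realign cycles.

The functions here orchestrate the lower-level modules and define the
bookkeeping shared by the CLI, the test-suite and the reproduction
script: how particle positions project into tilt images, how per-particle
CTFs are assembled from per-tilt optics, and the order of a refinement
cycle (CTF refinement, then geometry, then new pseudo-subtomograms, then
pose realignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ctf import CtfParams, defocus_at_particle, dose_damage_weight, evaluate_ctf, odd_phase_factor
from .fourier import freq_grid_2d
from .geometry import ProjectionMapping, TiltAlignment, project_map_slice
from .geometry import euler_to_matrix
from .likelihood import OrientationPrior, PoseHypothesis, grid_search_pose, local_refine_pose
from .pseudosubtomo import CropEntry, Particle2DCrops, construct_pseudosubtomogram, extract_crop
from .reconstruct import (
    ReconstructionState,
    backproject_accumulate,
    compute_fsc,
    em_update_map,
    resolution_at,
    shell_power,
)
from .simulate import TiltImageStack
from .tiltrefine import (
    TiltView,
    condense_tilt_image,
    precompute_position_likelihood,
    refine_defocus,
    refine_particle_motion,
    refine_rigid_tilt_alignment,
)

__all__ = [
    "ProjectState",
    "projected_position_px",
    "particle_ctf_grid",
    "extract_particle_crops",
    "build_pseudosubtomogram",
    "build_all_pseudosubtomograms",
    "make_tilt_views",
    "align_particles",
    "reconstruct_halves",
    "reconstruct_refined_frames",
    "refine_cycle",
]


@dataclass
class ProjectState:
    """Everything the iterative workflow updates in place."""

    stack: TiltImageStack
    align: TiltAlignment
    positions: np.ndarray  # (P, 3) A relative to the field centre
    poses: list  # PoseHypothesis per particle (attitude + residual 3D shift)
    ctf: list  # per-tilt base CtfParams
    box: int
    motion: np.ndarray | None = None  # (P, F, 3) A
    sigma2: np.ndarray | None = None  # per-3D-shell noise power
    apply_damage: bool = True  # model the dose damage envelope in CTFs

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    @property
    def pixel_size(self) -> float:
        return self.stack.pixel_size


def projected_position_px(
    state: ProjectState, p: int, f: int
) -> np.ndarray:
    """Projected 2D position (px) of particle p in tilt f, motion included."""
    pos = state.positions[p].copy()
    if state.motion is not None:
        pos = pos + state.motion[p, f]
    q = state.align.matrices[f] @ pos
    centre = state.stack.images.shape[-1] / 2.0
    return (q[:2] + state.align.shifts[f]) / state.pixel_size + centre


def particle_ctf_grid(
    state: ProjectState, p: int, f: int, with_damage: bool | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(real CTF array, complex odd-phase factor) of particle p in tilt f
    on the crop frequency grid."""
    n = state.box
    px = state.pixel_size
    hx, hy = freq_grid_2d(n)
    jx, jy = hx / (n * px), hy / (n * px)
    base = state.ctf[f]
    dz = defocus_at_particle(0.0, state.positions[p], state.align.matrices[f])
    params = replace(base, defocus_u=base.defocus_u + dz, defocus_v=base.defocus_v + dz)
    if state.apply_damage if with_damage is None else with_damage:
        dose = state.stack.dose[f]
        params = replace(params, scale=lambda k, dose=dose: dose_damage_weight(k, dose))
    return evaluate_ctf(params, jx, jy), odd_phase_factor(params, jx, jy)


def extract_particle_crops(state: ProjectState, p: int) -> Particle2DCrops:
    """All tilt crops of one particle, CTFs attached (not premultiplied)."""
    n = state.box
    entries = []
    for f in range(state.align.n_tilts):
        pos2d = projected_position_px(state, p, f)
        F, visible = extract_crop(state.stack.images[f], (pos2d[0], pos2d[1]), n)
        ctf, _ = particle_ctf_grid(state, p, f)
        entries.append(CropEntry(fourier=F, ctf=ctf, visible=visible))
    return Particle2DCrops(entries=entries, box=n, pixel_size=state.pixel_size)


def build_pseudosubtomogram(state: ProjectState, p: int):
    """Tomogram-frame (D, W, M) triplet of particle p."""
    crops = extract_particle_crops(state, p)
    mappings = [
        ProjectionMapping(A=state.align.matrices[f][:2, :], t=np.zeros(2))
        for f in range(state.align.n_tilts)
    ]
    return construct_pseudosubtomogram(crops, mappings)


def build_all_pseudosubtomograms(state: ProjectState) -> list:
    return [build_pseudosubtomogram(state, p) for p in range(state.n_particles)]


def make_tilt_views(
    state: ProjectState, Vhat: np.ndarray, f: int
) -> tuple[list[TiltView], np.ndarray]:
    """Per-particle (X, chi, prediction) triples of one tilt image for
    condensed scoring, plus the common damage envelope kappa(k)."""
    from .ctf import ctf_phase

    n = state.box
    px = state.pixel_size
    hx, hy = freq_grid_2d(n)
    jx, jy = hx / (n * px), hy / (n * px)
    views = []
    for p in range(state.n_particles):
        pos2d = projected_position_px(state, p, f)
        X, visible = extract_crop(state.stack.images[f], (pos2d[0], pos2d[1]), n)
        if not visible:
            continue
        base = state.ctf[f]
        dz = defocus_at_particle(0.0, state.positions[p], state.align.matrices[f])
        params = replace(base, defocus_u=base.defocus_u + dz, defocus_v=base.defocus_v + dz)
        chi = ctf_phase(params, jx, jy)
        pose = state.poses[p]
        A = (state.align.matrices[f] @ pose.rotation.T)[:2, :]
        pred = project_map_slice(Vhat, ProjectionMapping(A=A, t=np.zeros(2)), px)
        pred = pred * odd_phase_factor(params, jx, jy)
        if np.any(pose.shift != 0):
            k3 = np.stack([hx.ravel(), hy.ravel()], axis=1) @ state.align.matrices[f][:2, :]
            arg = (k3 @ pose.shift).reshape(n, n) / (n * px)
            pred = pred * np.exp(-2j * np.pi * arg)
        views.append(TiltView(X=X, chi=chi, pred=pred))
    k = np.sqrt(jx**2 + jy**2)
    if state.apply_damage:
        kappa = dose_damage_weight(k, state.stack.dose[f])
    else:
        kappa = np.ones_like(k)
    return views, kappa


def sigma2_flat(state: ProjectState, value: float) -> np.ndarray:
    return np.full(state.box // 2 + 1, value)


def align_particles(
    state: ProjectState,
    pseudos: list,
    Vhat: np.ndarray,
    sigma2: np.ndarray,
    priors: list | None = None,
    angular_step: float = 10.0,
    trans_range: float = 0.0,
    trans_step: float = 1.0,
    kmax: float | None = None,
    local: bool = True,
) -> list:
    """Grid search plus local polish for every particle; returns new poses."""
    out = []
    for p, P in enumerate(pseudos):
        prior = priors[p] if priors is not None else OrientationPrior(centre=state.poses[p])
        res = grid_search_pose(
            P, Vhat, sigma2, prior, angular_step, trans_range, trans_step, kmax=kmax
        )
        pose = res.map_pose
        if local:
            pose = local_refine_pose(P, Vhat, sigma2, pose, prior=prior, kmax=kmax)
        out.append(pose)
    return out


def build_pseudosubtomogram_oriented(
    state: ProjectState, p: int, rotation: np.ndarray, oversample: int = 1
):
    """(D, W, M) of particle p constructed in a rotated frame (e.g. the
    particle's current refined orientation).  With the frame equal to the
    refined pose, map accumulation needs no second interpolation."""
    crops = extract_particle_crops(state, p)
    R = np.asarray(rotation, dtype=float)
    mappings = [
        ProjectionMapping(A=(state.align.matrices[f] @ R.T)[:2, :], t=np.zeros(2))
        for f in range(state.align.n_tilts)
    ]
    return construct_pseudosubtomogram(crops, mappings, frame=R, oversample=oversample)


def _coarse_from_reference(V):
    """Plain working-box Fourier cube from either array or reference."""
    import numpy as _np

    from .geometry import FourierReference
    if isinstance(V, _np.ndarray):
        return V
    from .fourier import ft3, ift3

    m = ift3(V.F) * V.oversample**3
    N = V.F.shape[0]
    c, h = N // 2, V.box // 2
    return ft3(m[c - h : c + h, c - h : c + h, c - h : c + h])


def _refine_shells(arr: np.ndarray | None, box: int, oversample: int):
    if arr is None or oversample == 1:
        return arr
    fine = np.arange(oversample * box // 2 + 1)
    idx = np.minimum(np.rint(fine / oversample).astype(int), len(arr) - 1)
    return np.asarray(arr, dtype=float)[idx]


def _fourier_crop(Vfine: np.ndarray, box: int, oversample: int) -> np.ndarray:
    """Real-space central crop of an oversampled Fourier cube back to the
    working box (values scaled so amplitudes match the coarse grid)."""
    if oversample == 1:
        return Vfine
    from .fourier import ft3, ift3

    m = ift3(Vfine) * oversample**3
    N = Vfine.shape[0]
    c = N // 2
    h = box // 2
    return ft3(m[c - h : c + h, c - h : c + h, c - h : c + h])


def reconstruct_refined_frames(
    state: ProjectState,
    sigma2: np.ndarray,
    tau2: np.ndarray | None = None,
    oversample: int = 2,
):
    """Reference-frame reconstruction: each particle's tilt pixels are
    inserted directly at their rotated 3D frequencies (single trilinear
    interpolation, on a grid refined by ``oversample``), then combined
    with the Wiener-style update and cropped back to the working box.
    Returns (full map, (half1, half2))."""
    box = state.box
    N = box * oversample
    states = [ReconstructionState.empty(N), ReconstructionState.empty(N)]
    s2 = _refine_shells(sigma2, box, oversample)
    t2 = _refine_shells(tau2, box, oversample)
    for p in range(state.n_particles):
        pose = state.poses[p]
        P = build_pseudosubtomogram_oriented(state, p, pose.rotation, oversample=oversample)
        backproject_accumulate(states[p % 2], P, np.eye(3), s2, pose.shift)
    halves = [_fourier_crop(em_update_map(s, t2), box, oversample) for s in states]
    full = states[0].merged(states[1])
    V = _fourier_crop(em_update_map(full, t2), box, oversample)
    return V, tuple(halves)


def reconstruct_halves(
    pseudos: list, poses: list, sigma2: np.ndarray, tau2: np.ndarray | None
):
    """Deterministic even/odd half-set reconstruction; returns
    (full map, (half1, half2), full state)."""
    box = pseudos[0].box
    states = [ReconstructionState.empty(box), ReconstructionState.empty(box)]
    for i, (P, pose) in enumerate(zip(pseudos, poses)):
        backproject_accumulate(states[i % 2], P, pose.rotation, sigma2, pose.shift)
    halves = [em_update_map(s, tau2) for s in states]
    full = states[0].merged(states[1])
    return em_update_map(full, tau2), tuple(halves), full


@dataclass
class CycleReport:
    resolution_before: float
    resolution_after: float
    defocus_offsets: np.ndarray
    rigid_rotations: np.ndarray
    rigid_shifts_px: np.ndarray
    nll_before: float = float("nan")
    nll_after: float = float("nan")


def refine_cycle(
    state: ProjectState,
    Vhat: np.ndarray,
    sigma2: np.ndarray,
    angular_step: float = 5.0,
    prior_sigma_euler: float = 8.0,
    kmax: float | None = None,
    refine_ctf: bool = True,
    refine_geometry: bool = True,
    motion: bool = False,
    defocus_range: float = 3000.0,
    defocus_step: float = 100.0,
    likelihood_extent: int = 6,
) -> CycleReport:
    """One full improve->realign cycle, mutating ``state`` in place.

    Order: CTF refinement (per-tilt defocus), geometrical refinement
    (rigid tilt alignment, optionally per-particle motion), fresh
    pseudo-subtomograms, pose realignment, half-set reconstruction.
    """
    F = state.align.n_tilts
    pseudos = build_all_pseudosubtomograms(state)
    tau2 = shell_power(_coarse_from_reference(Vhat)) / 2.0
    _, halves0, _ = reconstruct_halves(pseudos, state.poses, sigma2, tau2)
    res_before = resolution_at(
        compute_fsc(halves0[0], halves0[1]), state.box, state.pixel_size
    )

    d_offsets = np.zeros(F)
    if refine_ctf:
        for f in range(F):
            views, kappa = make_tilt_views(state, Vhat, f)
            if not views:
                continue
            pair = condense_tilt_image(
                views, sigma2, state.ctf[f].amplitude_contrast, state.pixel_size
            )
            dz, ok = refine_defocus(
                pair, state.ctf[f].wavelength, defocus_range, defocus_step, kappa=kappa
            )
            if ok:
                d_offsets[f] = dz
                state.ctf[f] = replace(
                    state.ctf[f],
                    defocus_u=state.ctf[f].defocus_u + dz,
                    defocus_v=state.ctf[f].defocus_v + dz,
                )

    rig_rot = np.zeros(F)
    rig_shift = np.zeros((F, 2))
    if refine_geometry:
        centre = state.stack.images.shape[-1] / 2.0
        all_liks: list[list] = [[] for _ in range(state.n_particles)]
        for f in range(F):
            liks = []
            pos2d_list = []
            for p in range(state.n_particles):
                pos2d = projected_position_px(state, p, f)
                X, visible = extract_crop(state.stack.images[f], (pos2d[0], pos2d[1]), state.box)
                ctf, oddph = particle_ctf_grid(state, p, f)
                pose = state.poses[p]
                A = (state.align.matrices[f] @ pose.rotation.T)[:2, :]
                pred = project_map_slice(Vhat, ProjectionMapping(A=A, t=np.zeros(2)), state.pixel_size)
                C = pred * ctf * oddph
                lik = precompute_position_likelihood(X, C, sigma2, extent=likelihood_extent)
                liks.append(lik)
                pos2d_list.append(pos2d)
                all_liks[p].append(lik)
            rot, shift, ok = refine_rigid_tilt_alignment(
                liks, np.asarray(pos2d_list), np.array([centre, centre])
            )
            if ok:
                rig_rot[f] = rot
                rig_shift[f] = shift
                state.align.matrices[f] = euler_to_matrix(0.0, 0.0, rot) @ state.align.matrices[f]
                state.align.shifts[f] = state.align.shifts[f] + shift * state.pixel_size
        if motion:
            model = refine_particle_motion(
                all_liks,
                state.align.matrices,
                state.positions,
                state.align.acquisition_order,
                state.pixel_size,
            )
            state.motion = model.offsets if state.motion is None else state.motion + model.offsets

    pseudos = build_all_pseudosubtomograms(state)
    priors = [
        OrientationPrior(
            centre=pose, sigma_euler=np.full(3, prior_sigma_euler)
        )
        for pose in state.poses
    ]
    state.poses = align_particles(
        state, pseudos, Vhat, sigma2, priors=priors, angular_step=angular_step, kmax=kmax
    )
    _, halves1, _ = reconstruct_halves(pseudos, state.poses, sigma2, tau2)
    res_after = resolution_at(
        compute_fsc(halves1[0], halves1[1]), state.box, state.pixel_size
    )
    return CycleReport(
        resolution_before=res_before,
        resolution_after=res_after,
        defocus_offsets=d_offsets,
        rigid_rotations=rig_rot,
        rigid_shifts_px=rig_shift,
    )


def flat_sigma2(box: int, noise_sigma: float) -> np.ndarray:
    """Per-shell Fourier noise power of white real-space noise of standard
    deviation ``noise_sigma`` on a box^2 crop (unnormalised FFT):
    E|N(j)|^2 = box^2 sigma^2, flat across shells."""
    val = (box**2) * noise_sigma**2 if noise_sigma > 0 else 1.0
    return np.full(box // 2 + 1, val)


def load_project_state(project_dir, box: int | None = None) -> ProjectState:
    """Build a working :class:`ProjectState` from an exported project
    directory (tilt series + STAR metadata); the exported particle table
    provides the starting alignments."""
    from .geometry import tilt_matrix
    from .simulate import load_fixture

    stack, doc, _phantom = load_fixture(project_dir)
    optics = doc["optics"]
    tilts = doc["tilts"]
    box = int(optics["ptBoxSize"]) if box is None else box
    px = float(optics["ptPixelSize"])
    nyq = 0.5 / px
    angles = tilts["ptTiltAngle"].to_numpy(dtype=float)
    inplane = tilts["ptInPlaneRotation"].to_numpy(dtype=float)
    mats = np.stack([tilt_matrix(a, r) for a, r in zip(angles, inplane)])
    align = TiltAlignment(
        matrices=mats,
        shifts=np.stack(
            [tilts["ptShiftX"].to_numpy(float), tilts["ptShiftY"].to_numpy(float)], axis=1
        ),
        tilt_angles=angles,
        acquisition_order=tilts["ptAcquisitionOrder"].to_numpy(int),
        dose=tilts["ptDose"].to_numpy(float),
    )
    ctf = [
        CtfParams(
            voltage_kv=float(optics["ptVoltage"]),
            cs_mm=float(optics["ptSphericalAberration"]),
            amplitude_contrast=float(optics["ptAmplitudeContrast"]),
            defocus_u=float(d),
            defocus_v=float(d),
            nyquist=nyq,
        )
        for d in tilts["ptDefocus"].to_numpy(float)
    ]
    particles = doc["truth_particles"]
    positions = particles[["ptCoordX", "ptCoordY", "ptCoordZ"]].to_numpy(float)
    poses = [
        PoseHypothesis(
            euler=np.array([row["ptAngleRot"], row["ptAngleTilt"], row["ptAnglePsi"]])
        )
        for _, row in particles.iterrows()
    ]
    noise_sigma = float(optics.get("ptNoiseSigma", 0.0))
    return ProjectState(
        stack=stack,
        align=align,
        positions=positions,
        poses=poses,
        ctf=ctf,
        box=box,
        sigma2=flat_sigma2(box, noise_sigma),
    )
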
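"""Synthetic tilt-series generator with full ground truth.

Emulates the forward model of tomographic data acquisition: an
asymmetric Gaussian-blob phantom is projected into each tilt image
through the composed particle/stage geometry, premultiplied by the
per-particle CTF (astigmatic defocus from the particle's depth along the
beam, optional Zernike aberrations), damped by a dose-dependent damage
envelope, and buried in white Gaussian real-space noise.  Every
parameter the estimation modules recover (poses, tilt alignment, defoci,
aberrations, damage, motion, noise power) is recorded as ground truth.

Noise is white in real space so the per-shell noise power is flat,
keeping noise-recovery tests analytic.  Particles are placed in a slab
with a minimum-distance constraint; by default spacing is generous
enough that crops contain a single particle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import star as star_io
from .ctf import CtfParams, defocus_at_particle, dose_damage_weight, evaluate_ctf, odd_phase_factor
from .fourier import freq_grid_2d, ft3, ift2
from .geometry import FourierReference, ParticlePose, TiltAlignment, matrix_to_euler, tilt_matrix
from .mrc import VolumeGrid, read_mrc, write_mrc

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "TiltImageStack",
    "dose_symmetric_scheme",
    "make_phantom",
    "simulate_tilt_series",
    "export_fixture",
    "load_fixture",
]


def dose_symmetric_scheme(max_tilt: float = 60.0, step: float = 3.0) -> np.ndarray:
    """Stage angles in acquisition order: 0, +s, -s, +2s, -2s, ..."""
    angles = [0.0]
    a = step
    while a <= max_tilt + 1e-9:
        angles.extend([a, -a])
        a += step
    return np.asarray(angles)


@dataclass
class TiltImageStack:
    """A tilt series: one 2D image per tilt, in acquisition order, with
    accumulated dose (e/A^2) non-decreasing along that order."""

    images: np.ndarray  # (F, ny, nx)
    pixel_size: float
    acquisition_order: np.ndarray
    dose: np.ndarray

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        order = np.argsort(np.asarray(self.acquisition_order))
        d = np.asarray(self.dose, dtype=float)[order]
        if np.any(np.diff(d) < -1e-9):
            raise ValueError("accumulated dose must be non-decreasing in acquisition order")

    @property
    def n_tilts(self) -> int:
        return len(self.images)


@dataclass
class SimulationConfig:
    """All knobs of the generator; the same seed reproduces every draw."""

    box: int = 48
    pixel_size: float = 4.0
    max_tilt: float = 60.0
    tilt_step: float = 3.0
    dose_per_tilt: float = 3.0
    voltage_kv: float = 300.0
    cs_mm: float = 2.7
    amplitude_contrast: float = 0.07
    defocus: float = 30000.0
    defocus_offsets: np.ndarray | None = None  # (F,) per-tilt offsets, A; None = drawn
    defocus_jitter: float = 1500.0  # sigma of drawn per-tilt defocus variation, A
    astigmatism: tuple = (0.0, 0.0)  # (defocus_u - defocus_v, azimuth deg)
    zernike_even: tuple = ()  # (coeffs, nm_pairs)
    zernike_odd: tuple = ()
    apply_damage: bool = True
    noise_sigma: float = 0.0  # real-space sigma per pixel
    n_particles: int = 50
    field_size: int = 320
    slab_half: float = 120.0  # A
    min_distance: float | None = None  # A; default 1.2 * box * pixel
    tilt_shifts: np.ndarray | None = None  # (F, 2) injected rigid shifts, A
    tilt_inplane: np.ndarray | None = None  # (F,) injected in-plane rotations, deg
    motion: np.ndarray | None = None  # (n_particles, F, 3) A, or (F, 3) common drift
    render_oversample: int = 2  # grid refinement of the rendering transform
    seed: int = 0

    def tilt_angles(self) -> np.ndarray:
        return dose_symmetric_scheme(self.max_tilt, self.tilt_step)


@dataclass
class GroundTruth:
    """Everything needed to regenerate the simulated images exactly."""

    phantom: VolumeGrid
    phantom_hat: np.ndarray
    reference: FourierReference
    poses: list
    align: TiltAlignment
    ctf: list  # base CtfParams per tilt (particle depth not applied)
    motion: np.ndarray  # (n_particles, F, 3) A
    noise_sigma: float
    snr: float
    config: SimulationConfig = None


def make_phantom(box: int, seed: int = 0, pixel_size: float = 4.0, n_blobs: int = 20) -> VolumeGrid:
    """Deterministic asymmetric arrangement of Gaussian blobs.

    Blob centres fill an off-centre cloud so the phantom has no rotational
    self-similarity.  The support stays within radius ~0.28 box (particle
    boxed at roughly twice its diameter, the usual boxing margin): a
    compact support keeps the Fourier transform smooth on the voxel
    scale, which interpolation-based projection and insertion rely on.
    """
    if box < 16:
        raise ValueError("box must be >= 16")
    rng = np.random.default_rng(seed)
    n_blobs = max(int(n_blobs), 12)
    c = box // 2
    zz, yy, xx = np.meshgrid(*([np.arange(box) - c] * 3), indexing="ij")
    vol = np.zeros((box, box, box))
    max_r = 0.19 * box
    for _ in range(n_blobs):
        centre = rng.uniform(-max_r, max_r, size=3)
        width = rng.uniform(0.025, 0.05) * box
        amp = rng.uniform(0.5, 1.5)
        r2 = (xx - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (zz - centre[2]) ** 2
        vol += amp * np.exp(-r2 / (2.0 * width**2))
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    r_support = 0.28 * box
    edge = 0.05 * box
    mask = np.clip((r_support - r) / edge, 0.0, 1.0)
    mask = 0.5 - 0.5 * np.cos(np.pi * mask)
    return VolumeGrid(data=vol * mask, pixel_size=pixel_size)


def _place_particles(rng, config: SimulationConfig) -> np.ndarray:
    """Slab placement (A, relative to the field centre) with a minimum
    pairwise distance enforced on the *projected* positions over the whole
    tilt range (so crops stay isolated in every tilt image); raises if the
    field cannot hold the request."""
    px = config.pixel_size
    margin = 0.75 * config.box * px
    half_field = config.field_size * px / 2.0
    lo, hi = -half_field + margin, half_field - margin
    min_d = config.min_distance or 1.2 * config.box * px
    thetas = np.deg2rad(np.arange(-config.max_tilt, config.max_tilt + 1e-9, 15.0))
    cos_t, sin_t = np.cos(thetas), np.sin(thetas)

    def separated(a, b):
        dx = (a[0] - b[0]) * cos_t - (a[2] - b[2]) * sin_t
        dy = a[1] - b[1]
        return np.all(np.hypot(dx, dy) >= min_d)

    positions = []
    attempts = 0
    while len(positions) < config.n_particles:
        attempts += 1
        if attempts > 5000 * config.n_particles:
            raise RuntimeError(
                "could not place particles with the requested spacing; "
                "reduce n_particles or min_distance"
            )
        cand = np.array(
            [rng.uniform(lo, hi), rng.uniform(lo, hi), rng.uniform(-config.slab_half, config.slab_half)]
        )
        if all(separated(cand, p) for p in positions):
            positions.append(cand)
    return np.asarray(positions)


def _random_rotations(rng, n: int) -> list[np.ndarray]:
    """Uniform random rotation matrices (quaternion method)."""
    out = []
    for _ in range(n):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        out.append(
            np.array(
                [
                    [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
                    [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
                    [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
                ]
            )
        )
    return out


def base_ctf_params(config: SimulationConfig, f: int) -> CtfParams:
    """Ground-truth optics of tilt f (defocus offsets, astigmatism,
    Zernike injections; damage handled separately per particle)."""
    d = config.defocus
    if config.defocus_offsets is not None:
        d = d + float(config.defocus_offsets[f])
    astig_amp, astig_az = config.astigmatism
    nyq = 0.5 / config.pixel_size
    kwargs = {}
    if config.zernike_even:
        kwargs["zernike_even"] = np.asarray(config.zernike_even[0], dtype=float)
        kwargs["zernike_even_nm"] = tuple(config.zernike_even[1])
    if config.zernike_odd:
        kwargs["zernike_odd"] = np.asarray(config.zernike_odd[0], dtype=float)
        kwargs["zernike_odd_nm"] = tuple(config.zernike_odd[1])
    return CtfParams(
        voltage_kv=config.voltage_kv,
        cs_mm=config.cs_mm,
        amplitude_contrast=config.amplitude_contrast,
        defocus_u=d + astig_amp / 2.0,
        defocus_v=d - astig_amp / 2.0,
        astigmatism_deg=astig_az,
        nyquist=nyq,
        **kwargs,
    )


def particle_ctf(
    config_or_truth, f: int, position: np.ndarray, base: CtfParams, dose: float
) -> CtfParams:
    """Per-particle CTF at tilt f: depth-corrected defocus plus the dose
    damage envelope as the kappa factor."""
    cfg = config_or_truth
    A_f = tilt_matrix(cfg.tilt_angles()[f], 0.0 if cfg.tilt_inplane is None else float(cfg.tilt_inplane[f]))
    dz = defocus_at_particle(0.0, position, A_f)
    params = replace(
        base,
        defocus_u=base.defocus_u + dz,
        defocus_v=base.defocus_v + dz,
    )
    if cfg.apply_damage:
        params.scale = lambda k, dose=dose: dose_damage_weight(k, dose)
    return params


def simulate_tilt_series(
    phantom: VolumeGrid, config: SimulationConfig
) -> tuple[TiltImageStack, GroundTruth]:
    """Render the full tilt series and its ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.box
    px = config.pixel_size
    angles = config.tilt_angles()
    F = len(angles)
    if config.defocus_offsets is None and config.defocus_jitter > 0:
        config = replace(config, defocus_offsets=rng.normal(0.0, config.defocus_jitter, F))
    inplane = np.zeros(F) if config.tilt_inplane is None else np.asarray(config.tilt_inplane, float)
    shifts = np.zeros((F, 2)) if config.tilt_shifts is None else np.asarray(config.tilt_shifts, float)
    mats = np.stack([tilt_matrix(a, r) for a, r in zip(angles, inplane)])
    order = np.arange(F)
    dose = (order + 1.0) * config.dose_per_tilt
    align = TiltAlignment(mats, shifts, angles, order, dose)

    positions = _place_particles(rng, config)
    rotations = _random_rotations(rng, config.n_particles)
    motion = np.zeros((config.n_particles, F, 3))
    if config.motion is not None:
        m = np.asarray(config.motion, dtype=float)
        motion = np.broadcast_to(m, (config.n_particles, F, 3)).copy() if m.ndim == 2 else m.copy()
    poses = [
        ParticlePose(rotation=R, position=p, offsets=motion[i])
        for i, (R, p) in enumerate(zip(rotations, positions))
    ]

    phantom_hat = ft3(phantom.data)
    # render through the padded, gridding-corrected reference so the data
    # approximate continuous-transform slices, not grid artefacts
    reference = FourierReference.from_map(phantom.data, oversample=config.render_oversample)
    hx, hy = freq_grid_2d(n)
    jx = hx / (n * px)
    jy = hy / (n * px)
    field = config.field_size
    centre_px = field / 2.0
    half = n // 2
    images = np.zeros((F, field, field))
    signal_power = 0.0
    signal_pixels = 0
    for f in range(F):
        base = base_ctf_params(config, f)
        for i, pose in enumerate(poses):
            A = (mats[f] @ pose.rotation.T)[:2, :]
            pts = np.stack([hx.ravel(), hy.ravel()], axis=1) @ A
            slice_f = reference.sample(pts).reshape(n, n)
            params = particle_ctf(config, f, positions[i] + motion[i, f], base, dose[f])
            ctf = evaluate_ctf(params, jx, jy) * odd_phase_factor(params, jx, jy)
            crop_hat = slice_f * ctf
            # projected position in the image (px)
            q = mats[f] @ (positions[i] + motion[i, f])
            pos2d = (q[:2] + shifts[f]) / px + centre_px
            ix, iy = int(round(pos2d[0])), int(round(pos2d[1]))
            dx, dy = pos2d[0] - ix, pos2d[1] - iy
            if dx != 0.0 or dy != 0.0:
                crop_hat = crop_hat * np.exp(-2j * np.pi * (hx * dx + hy * dy) / n)
            crop = ift2(crop_hat)
            x0, y0 = ix - half, iy - half
            sx0, sy0 = max(x0, 0), max(y0, 0)
            sx1, sy1 = min(x0 + n, field), min(y0 + n, field)
            if sx0 >= sx1 or sy0 >= sy1:
                continue
            images[f, sy0:sy1, sx0:sx1] += crop[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0]
            signal_power += float(np.sum(crop**2))
            signal_pixels += crop.size
    if config.noise_sigma > 0:
        images += rng.normal(0.0, config.noise_sigma, size=images.shape)
    snr = (
        signal_power / signal_pixels / config.noise_sigma**2
        if config.noise_sigma > 0 and signal_pixels
        else float("inf")
    )
    stack = TiltImageStack(images=images, pixel_size=px, acquisition_order=order, dose=dose)
    truth = GroundTruth(
        phantom=phantom,
        phantom_hat=phantom_hat,
        reference=reference,
        poses=poses,
        align=align,
        ctf=[base_ctf_params(config, f) for f in range(F)],
        motion=motion,
        noise_sigma=config.noise_sigma,
        snr=snr,
        config=config,
    )
    return stack, truth


def export_fixture(stack: TiltImageStack, truth: GroundTruth, outdir) -> dict:
    """Write the simulated project (MRC stacks + STAR metadata).

    The ground truth goes into clearly named ``truth_*`` blocks of the
    sidecar STAR file.  Returns the written paths.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tilt_series": outdir / "tilt_series.mrcs",
        "phantom": outdir / "phantom.mrc",
        "metadata": outdir / "project.star",
    }
    write_mrc(
        VolumeGrid(data=stack.images, pixel_size=stack.pixel_size), paths["tilt_series"]
    )
    write_mrc(truth.phantom, paths["phantom"])
    cfg = truth.config
    import pandas as pd

    doc = star_io.StarDocument()
    doc["optics"] = {
        "ptVoltage": cfg.voltage_kv,
        "ptSphericalAberration": cfg.cs_mm,
        "ptAmplitudeContrast": cfg.amplitude_contrast,
        "ptPixelSize": cfg.pixel_size,
        "ptBoxSize": cfg.box,
        "ptFieldSize": cfg.field_size,
        "ptNoiseSigma": truth.noise_sigma,
        "ptSeed": cfg.seed,
        "ptSnr": truth.snr if np.isfinite(truth.snr) else -1.0,
    }
    A = truth.align
    doc["tilts"] = pd.DataFrame(
        {
            "ptTiltAngle": A.tilt_angles,
            "ptAcquisitionOrder": A.acquisition_order,
            "ptDose": A.dose,
            "ptShiftX": A.shifts[:, 0],
            "ptShiftY": A.shifts[:, 1],
            "ptInPlaneRotation": np.zeros(A.n_tilts)
            if cfg.tilt_inplane is None
            else np.asarray(cfg.tilt_inplane, float),
            "ptDefocus": [p.defocus_u / 2 + p.defocus_v / 2 for p in truth.ctf],
        }
    )
    rows = []
    for i, pose in enumerate(truth.poses):
        rot, tilt, psi = matrix_to_euler(pose.rotation)
        rows.append(
            {
                "ptIndex": i,
                "ptCoordX": pose.position[0],
                "ptCoordY": pose.position[1],
                "ptCoordZ": pose.position[2],
                "ptAngleRot": rot,
                "ptAngleTilt": tilt,
                "ptAnglePsi": psi,
            }
        )
    doc["truth_particles"] = pd.DataFrame(rows)
    mrows = []
    for i in range(truth.motion.shape[0]):
        for f in range(truth.motion.shape[1]):
            if np.any(truth.motion[i, f] != 0):
                mrows.append(
                    {
                        "ptIndex": i,
                        "ptTilt": f,
                        "ptDx": truth.motion[i, f, 0],
                        "ptDy": truth.motion[i, f, 1],
                        "ptDz": truth.motion[i, f, 2],
                    }
                )
    if mrows:
        doc["truth_motion"] = pd.DataFrame(mrows)
    star_io.write_star(doc, paths["metadata"])
    return paths


def load_fixture(outdir) -> tuple[TiltImageStack, star_io.StarDocument, VolumeGrid]:
    """Read back an exported project directory."""
    from pathlib import Path

    outdir = Path(outdir)
    doc = star_io.read_star(outdir / "project.star")
    vol = read_mrc(outdir / "tilt_series.mrcs")
    tilts = doc["tilts"]
    stack = TiltImageStack(
        images=vol.data,
        pixel_size=vol.pixel_size,
        acquisition_order=tilts["ptAcquisitionOrder"].to_numpy(),
        dose=tilts["ptDose"].to_numpy(),
    )
    phantom = read_mrc(outdir / "phantom.mrc")
    return stack, doc, phantom


def noise_sigma_for_snr(phantom: VolumeGrid, config: SimulationConfig, snr: float) -> float:
    """Real-space noise sigma giving the requested crop-average SNR.

    Renders the series once without noise to measure the mean signal
    power per pixel, then returns sqrt(power / snr).
    """
    probe = replace(config, noise_sigma=1.0)
    _, truth = simulate_tilt_series(phantom, probe)
    power = truth.snr * 1.0**2  # snr = power / sigma^2 at sigma = 1
    return float(np.sqrt(power / snr))
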
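"""Likelihood evaluation and pose search.

The central quantity is the pseudo-subtomogram negative log-likelihood

    nll(R, T) = sum_k |D_k - e^{-2 pi i k.T} W_k V(R k)|^2 / (M_k sigma_k^2)

over voxels with multiplicity above a small threshold, which approximates
the per-pixel 2D tilt-series likelihood.  The exact 2D counterpart is
implemented as :func:`nll_2d` and serves both as the oracle for the
approximation and as the target of tilt-series refinement.  When the 2D
residual is formed on CTF-premultiplied data (``premultiplied=True``) the
two agree exactly in the trivial-interpolation regime (single tilt,
on-grid mapping); the plain residual ``X - CTF.V`` differs by the CTF
premultiplication, as inherent to the pseudo-subtomogram approximation.

Pose search is an exhaustive grid under Gaussian orientation/translation
priors (uniform Euler grids within +-3 sigma), with translations scored
through 3D phase ramps, followed by a derivative-free local polish.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .fourier import freq_grid_2d, freq_grid_3d
from .geometry import TiltAlignment, euler_to_matrix, sample_reference
from .pseudosubtomo import Particle2DCrops, PseudoSubtomogram

__all__ = [
    "PoseHypothesis",
    "OrientationPrior",
    "PseudoEvaluator",
    "nll_pseudo",
    "nll_2d",
    "pose_prior_nll",
    "grid_search_pose",
    "local_refine_pose",
    "GridSearchResult",
]

M_THRESHOLD_DEFAULT = 0.5


@dataclass
class PoseHypothesis:
    """A candidate particle alignment: ZYZ Euler angles (deg) and a 3D
    translation offset (A) in the construction frame."""

    euler: np.ndarray
    shift: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.euler = np.asarray(self.euler, dtype=float)
        self.shift = np.asarray(self.shift, dtype=float)

    @property
    def rotation(self) -> np.ndarray:
        return euler_to_matrix(*self.euler)


@dataclass
class OrientationPrior:
    """Gaussian priors on the three Euler angles (deg; inf = uniform) and
    the Cartesian translations (A), centred on a reference pose."""

    centre: PoseHypothesis
    sigma_euler: np.ndarray = field(default_factory=lambda: np.full(3, np.inf))
    sigma_shift: np.ndarray = field(default_factory=lambda: np.full(3, np.inf))

    def __post_init__(self):
        self.sigma_euler = np.asarray(self.sigma_euler, dtype=float)
        self.sigma_shift = np.asarray(self.sigma_shift, dtype=float)
        if np.any(self.sigma_euler <= 0) or np.any(self.sigma_shift <= 0):
            raise ValueError("prior sigmas must be positive (inf = uniform)")


def wrap_angle(delta):
    """Wrap angular differences (deg) into (-180, 180]."""
    return -((-np.asarray(delta, dtype=float) + 180.0) % 360.0 - 180.0)


def pose_prior_nll(pose: PoseHypothesis, prior: OrientationPrior) -> float:
    """0.5 * sum((delta/sigma)^2) over angles (wrapped) and shifts."""
    d_ang = wrap_angle(pose.euler - prior.centre.euler)
    d_shift = pose.shift - prior.centre.shift
    out = 0.0
    for d, s in zip(d_ang, prior.sigma_euler):
        if np.isfinite(s):
            out += 0.5 * (d / s) ** 2
    for d, s in zip(d_shift, prior.sigma_shift):
        if np.isfinite(s):
            out += 0.5 * (d / s) ** 2
    return float(out)


class PseudoEvaluator:
    """Caches the masked voxel set of one pseudo-subtomogram so that many
    pose hypotheses can be scored cheaply.

    Voxels with multiplicity below ``m_threshold`` (default 0.5, i.e.
    carrying less than half an observation) are excluded: such sliver
    voxels at the edges of inserted slices hold only partial trilinear
    weights whose main mass went to neighbouring voxels, and the
    diagonal noise model (variance M sigma^2) is most biased there.
    Remaining voxels are weighted by 1 / (M_k sigma^2(shell)).
    """

    def __init__(
        self,
        P: PseudoSubtomogram,
        Vhat: np.ndarray,
        sigma2: np.ndarray,
        m_threshold: float = M_THRESHOLD_DEFAULT,
        kmax: float | None = None,
    ):
        n = P.box
        self.n = n
        self.pixel_size = P.pixel_size
        self.Vhat = Vhat
        hx, hy, hz = freq_grid_3d(n)
        r = np.sqrt(hx**2 + hy**2 + hz**2)
        lim = n / 2 - 1 if kmax is None else min(kmax, n / 2 - 1)
        mask = (P.M > m_threshold) & (r <= lim)
        shells = np.rint(r[mask]).astype(np.intp)
        sigma2 = np.asarray(sigma2, dtype=float)
        if np.any(sigma2[np.unique(shells)] <= 0):
            raise ValueError("non-positive noise power in a populated shell")
        self.kvec = np.stack([hx[mask], hy[mask], hz[mask]], axis=1)
        self.D = P.D[mask]
        self.W = P.W[mask]
        self.inv_var = 1.0 / (P.M[mask] * sigma2[shells])

    def _predict(self, R: np.ndarray) -> np.ndarray:
        pts = self.kvec @ np.asarray(R, dtype=float).T  # rows R k
        return self.W * sample_reference(self.Vhat, pts)

    def _shift_phase(self, shift: np.ndarray) -> np.ndarray:
        arg = self.kvec @ (np.asarray(shift, dtype=float) / (self.n * self.pixel_size))
        return np.exp(-2j * np.pi * arg)

    def nll(self, R: np.ndarray, shift: np.ndarray | None = None) -> float:
        pred = self._predict(R)
        if shift is not None and np.any(np.asarray(shift) != 0):
            pred = pred * self._shift_phase(shift)
        resid = self.D - pred
        return float(np.sum((resid.real**2 + resid.imag**2) * self.inv_var))

    def shift_phase_matrix(self, shifts: np.ndarray) -> np.ndarray:
        """(n_voxels, n_shifts) matrix of translation phase ramps; compute
        once per particle when scanning many rotations."""
        shifts = np.atleast_2d(np.asarray(shifts, dtype=float))
        scale = 1.0 / (self.n * self.pixel_size)
        return np.exp(-2j * np.pi * (self.kvec @ shifts.T) * scale)

    def nll_translations(
        self, R: np.ndarray, shifts: np.ndarray, phases: np.ndarray | None = None
    ) -> np.ndarray:
        """nll for one rotation and many 3D shifts (A), via phase ramps."""
        pred = self._predict(R)
        const = float(
            np.sum((np.abs(self.D) ** 2 + np.abs(pred) ** 2) * self.inv_var)
        )
        cross = np.conj(self.D) * pred * self.inv_var
        if phases is None:
            phases = self.shift_phase_matrix(shifts)
        return const - 2.0 * np.real(cross @ phases)


def nll_pseudo(
    P: PseudoSubtomogram,
    Vhat: np.ndarray,
    rotation: np.ndarray,
    sigma2: np.ndarray,
    shift: np.ndarray | None = None,
    m_threshold: float = M_THRESHOLD_DEFAULT,
    kmax: float | None = None,
) -> float:
    """One-off evaluation of the pseudo-subtomogram likelihood."""
    ev = PseudoEvaluator(P, Vhat, sigma2, m_threshold=m_threshold, kmax=kmax)
    return ev.nll(rotation, shift)


def nll_2d(
    crops: Particle2DCrops,
    Vhat: np.ndarray,
    rotation: np.ndarray,
    align: TiltAlignment,
    sigma2: np.ndarray,
    shift: np.ndarray | None = None,
    premultiplied: bool = True,
    kmax: float | None = None,
) -> float:
    """Exact 2D tilt-series likelihood (the reference the 3D form
    approximates).

    Sums |X - CTF.V|^2/sigma^2 over the in-radius pixels of all visible
    tilts; with ``premultiplied=True`` the residual is CTF.X - CTF^2.V,
    the exact counterpart of the pseudo-subtomogram target.  ``shift`` is
    a 3D offset in the tomogram frame, applied per tilt through its
    projected phase ramp.
    """
    n = crops.box
    hx, hy = freq_grid_2d(n)
    j2 = np.stack([hx.ravel(), hy.ravel()], axis=1)
    lim = n / 2 - 1 if kmax is None else min(kmax, n / 2 - 1)
    R = np.asarray(rotation, dtype=float)
    total = 0.0
    shells_all = np.rint(np.sqrt(hx**2 + hy**2)).astype(np.intp).ravel()
    sigma2 = np.asarray(sigma2, dtype=float)
    for f, entry in enumerate(crops.entries):
        if not entry.visible:
            continue
        Af = align.matrices[f]
        k3 = j2 @ Af[:2, :]  # insertion frequency A_f^T [j; 0]
        ok = np.all(np.abs(k3) <= lim, axis=1) & (
            np.linalg.norm(k3, axis=1) <= lim
        )
        if not np.any(ok):
            continue
        shells = shells_all[ok]
        if np.any(sigma2[np.unique(shells)] <= 0):
            raise ValueError("non-positive noise power in a populated shell")
        pts = k3[ok] @ R.T
        slice_vals = sample_reference(Vhat, pts)
        if shift is not None and np.any(np.asarray(shift) != 0):
            arg = k3[ok] @ (np.asarray(shift, dtype=float) / (n * crops.pixel_size))
            slice_vals = slice_vals * np.exp(-2j * np.pi * arg)
        X = entry.fourier.ravel()[ok]
        c = entry.ctf.ravel()[ok]
        if premultiplied:
            resid = c * X - c * c * slice_vals
        else:
            resid = X - c * slice_vals
        total += float(np.sum((resid.real**2 + resid.imag**2) / sigma2[shells]))
    return total


@dataclass
class GridSearchResult:
    """All evaluated hypotheses with their marginal weights."""

    eulers: np.ndarray  # (n_rot, 3)
    shifts: np.ndarray  # (n_trans, 3)
    nll: np.ndarray  # (n_rot, n_trans), includes the prior term
    weights: np.ndarray  # same shape, softmax of -nll
    map_pose: PoseHypothesis = None
    map_index: tuple = ()


def _angle_grid(centre: float, sigma: float, step: float, full_range: float) -> np.ndarray:
    if not np.isfinite(sigma):
        return centre + np.arange(0.0, full_range, step)
    half = min(3.0 * sigma, full_range / 2.0)
    k = int(np.floor(half / step))
    return centre + step * np.arange(-k, k + 1)


def grid_search_pose(
    P: PseudoSubtomogram,
    Vhat: np.ndarray,
    sigma2: np.ndarray,
    prior: OrientationPrior,
    angular_step: float,
    trans_range: float = 0.0,
    trans_step: float = 1.0,
    m_threshold: float = M_THRESHOLD_DEFAULT,
    kmax: float | None = None,
) -> GridSearchResult:
    """Exhaustive pose search on a uniform Euler/translation grid.

    The grid spans +-3 sigma around the prior centre for each finite prior
    width and the full range otherwise.  Marginal weights are the
    softmax of -nll (log-sum-exp stabilised); ties break to the lowest
    linear index (rotations outer, translations inner).
    """
    if angular_step <= 0 or trans_step <= 0:
        raise ValueError("grid steps must be positive")
    ev = PseudoEvaluator(P, Vhat, sigma2, m_threshold=m_threshold, kmax=kmax)
    c = prior.centre
    rot_g = _angle_grid(c.euler[0], prior.sigma_euler[0], angular_step, 360.0)
    tilt_g = _angle_grid(c.euler[1], prior.sigma_euler[1], angular_step, 180.0)
    psi_g = _angle_grid(c.euler[2], prior.sigma_euler[2], angular_step, 360.0)
    eulers = np.array([(r, t, p) for r in rot_g for t in tilt_g for p in psi_g])
    if trans_range > 0:
        ax = np.arange(-trans_range, trans_range + 1e-9, trans_step)
        shifts = c.shift + np.array([(x, y, z) for z in ax for y in ax for x in ax])
    else:
        shifts = c.shift[None, :]
    if eulers.size == 0 or shifts.size == 0:
        raise ValueError("empty search grid")
    phases = ev.shift_phase_matrix(shifts)
    prior_shift = np.array(
        [pose_prior_nll(PoseHypothesis(c.euler, s), prior) for s in shifts]
    )
    prior_rot = np.array(
        [pose_prior_nll(PoseHypothesis(e, c.shift), prior) for e in eulers]
    )
    nll = np.empty((len(eulers), len(shifts)))
    for i, e in enumerate(eulers):
        R = euler_to_matrix(*e)
        nll[i] = ev.nll_translations(R, shifts, phases) + prior_shift + prior_rot[i]
    flat = nll.ravel()
    lse = flat.min()
    w = np.exp(-(flat - lse))
    weights = (w / w.sum()).reshape(nll.shape)
    best = int(np.argmin(flat))
    bi, bj = divmod(best, len(shifts))
    map_pose = PoseHypothesis(eulers[bi].copy(), shifts[bj].copy())
    return GridSearchResult(
        eulers=eulers,
        shifts=shifts,
        nll=nll,
        weights=weights,
        map_pose=map_pose,
        map_index=(bi, bj),
    )


def local_refine_pose(
    P: PseudoSubtomogram,
    Vhat: np.ndarray,
    sigma2: np.ndarray,
    start: PoseHypothesis,
    prior: OrientationPrior | None = None,
    m_threshold: float = M_THRESHOLD_DEFAULT,
    kmax: float | None = None,
    maxiter: int = 400,
) -> PoseHypothesis:
    """Continuous derivative-free polish of a pose (Nelder-Mead on the six
    pose parameters).  Never returns a pose worse than the start."""
    ev = PseudoEvaluator(P, Vhat, sigma2, m_threshold=m_threshold, kmax=kmax)

    def objective(x):
        pose = PoseHypothesis(x[:3], x[3:])
        val = ev.nll(pose.rotation, pose.shift)
        if prior is not None:
            val += pose_prior_nll(pose, prior)
        return val

    x0 = np.concatenate([start.euler, start.shift])
    f0 = objective(x0)
    # explicit initial simplex: degrees and Angstrom live on different
    # scales, and the solver's default 5% perturbation is useless at 0
    steps = np.array([2.0, 2.0, 2.0, 2.0, 2.0, 2.0])
    simplex = np.vstack([x0] + [x0 + steps[i] * np.eye(6)[i] for i in range(6)])
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "maxiter": maxiter,
            "xatol": 1e-3,
            "fatol": 1e-10 * max(abs(f0), 1.0),
            "initial_simplex": simplex,
        },
    )
    if res.fun <= f0:
        return PoseHypothesis(res.x[:3].copy(), res.x[3:].copy())
    return start
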
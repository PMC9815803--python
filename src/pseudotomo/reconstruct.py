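"""Regularised expectation-maximisation reconstruction.

The map update is the Wiener-like ratio

    V_k = [sum_p D_p(R_p^T k) / sigma_k^2] / [sum_p W_p(R_p^T k) / sigma_k^2 + 1/tau_k^2]

with per-shell noise power sigma_k^2 estimated from the residuals

    sigma_k^2 = sum_p sum_{k in S_k} |D_k - W_k V(R_p k)|^2 / (2 sum_p sum M_k)

and per-shell signal power tau_k^2 from the shell power of V corrected by
the average CTF^2 (the W/M ratio), because the data were premultiplied:

    tau_k^2 = <|V_k|^2>_shell / 2 * (sum W / sum M).

Shells are hollow spheres of one-voxel thickness indexed by rounded |k|.
Half-set (gold-standard) splitting is deterministic by particle parity;
resolution is read from the FSC at the 0.143 threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fourier import freq_grid_3d, ift3, shell_sum, trilinear_sample, trilinear_sample_multi
from .geometry import FourierReference, sample_reference
from .likelihood import (
    M_THRESHOLD_DEFAULT,
    OrientationPrior,
    PoseHypothesis,
    PseudoEvaluator,
    grid_search_pose,
    local_refine_pose,
)
from .pseudosubtomo import PseudoSubtomogram

__all__ = [
    "ReconstructionState",
    "ParticleRecord",
    "backproject_accumulate",
    "em_update_map",
    "update_sigma",
    "update_tau",
    "compute_fsc",
    "resolution_at",
    "run_em",
    "EmResult",
]


@dataclass
class ParticleRecord:
    """A particle entering reconstruction: its pseudo-subtomogram, current
    pose and (optionally) the orientation prior guiding its search."""

    pseudo: PseudoSubtomogram
    pose: PoseHypothesis
    prior: OrientationPrior | None = None


@dataclass
class ReconstructionState:
    """Accumulators of the map update (numerator, denominator,
    multiplicity) plus raw per-shell CTF^2 and multiplicity sums."""

    num: np.ndarray
    den: np.ndarray
    mult: np.ndarray
    shell_W: np.ndarray
    shell_M: np.ndarray
    n_particles: int = 0

    @classmethod
    def empty(cls, box: int) -> "ReconstructionState":
        ns = box // 2 + 1
        return cls(
            num=np.zeros((box, box, box), dtype=complex),
            den=np.zeros((box, box, box)),
            mult=np.zeros((box, box, box)),
            shell_W=np.zeros(ns),
            shell_M=np.zeros(ns),
        )

    def merged(self, other: "ReconstructionState") -> "ReconstructionState":
        return ReconstructionState(
            num=self.num + other.num,
            den=self.den + other.den,
            mult=self.mult + other.mult,
            shell_W=self.shell_W + other.shell_W,
            shell_M=self.shell_M + other.shell_M,
            n_particles=self.n_particles + other.n_particles,
        )


def _grid_cache(n: int):
    hx, hy, hz = freq_grid_3d(n)
    r = np.sqrt(hx**2 + hy**2 + hz**2)
    mask = r <= n / 2 - 1
    kvec = np.stack([hx[mask], hy[mask], hz[mask]], axis=1)
    shells = np.rint(r[mask]).astype(np.intp)
    return mask, kvec, shells


def backproject_accumulate(
    state: ReconstructionState,
    P: PseudoSubtomogram,
    rotation: np.ndarray,
    sigma2: np.ndarray,
    shift: np.ndarray | None = None,
) -> ReconstructionState:
    """Add one particle: rotate its triplet by R^T (trilinear gather) and
    accumulate with 1/sigma^2 shell weighting.  A pose shift is removed
    from D by its phase ramp before insertion."""
    n = P.box
    mask, kvec, shells = _grid_cache(n)
    R = np.asarray(rotation, dtype=float)
    pts = kvec @ R  # rows are R^T k
    D = P.D
    if shift is not None and np.any(np.asarray(shift) != 0):
        # remove the residual translation so the particle is centred
        hx, hy, hz = freq_grid_3d(n)
        arg = (hx * shift[0] + hy * shift[1] + hz * shift[2]) / (n * P.pixel_size)
        D = D * np.exp(+2j * np.pi * arg)
    d, w, m = trilinear_sample_multi([D, P.W, P.M], pts)
    inv_s2 = 1.0 / np.asarray(sigma2, dtype=float)[shells]
    state.num[mask] += d * inv_s2
    state.den[mask] += w * inv_s2
    state.mult[mask] += m
    ns = len(state.shell_W)
    state.shell_W += shell_sum(P.W[mask], shells, ns).real
    state.shell_M += shell_sum(P.M[mask], shells, ns).real
    state.n_particles += 1
    return state


def em_update_map(state: ReconstructionState, tau2: np.ndarray | None) -> np.ndarray:
    """Element-wise Wiener-style update V = num / (den + 1/tau^2).

    ``tau2=None`` (or inf entries) drops the regulariser; voxels whose
    denominator vanishes are set to 0.
    """
    n = state.num.shape[0]
    hx, hy, hz = freq_grid_3d(n)
    shells = np.rint(np.sqrt(hx**2 + hy**2 + hz**2)).astype(np.intp)
    shells = np.clip(shells, 0, n // 2)
    if tau2 is None:
        inv_tau = np.zeros(n // 2 + 1)
    else:
        t = np.asarray(tau2, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_tau = np.where(np.isfinite(t) & (t > 0), 1.0 / t, 0.0)
        # undefined or zero signal on a shell: infinitely strong prior
        inv_tau = np.where(np.isnan(t) | (t == 0), np.inf, inv_tau)
    denom = state.den + inv_tau[shells]
    with np.errstate(divide="ignore", invalid="ignore"):
        V = np.where(denom > 0, state.num / np.where(denom > 0, denom, 1.0), 0.0)
    V = np.where(np.isfinite(denom), V, 0.0)
    return V


def update_sigma(
    particles: list[ParticleRecord],
    Vhat: np.ndarray,
    sigma2_prev: np.ndarray | None = None,
) -> np.ndarray:
    """Per-shell noise power from the premultiplied residuals.

    Empty shells carry the previous estimate forward (NaN if none)."""
    n = particles[0].pseudo.box
    ns = n // 2 + 1
    num = np.zeros(ns)
    den = np.zeros(ns)
    for rec in particles:
        P = rec.pseudo
        hx, hy, hz = freq_grid_3d(n)
        r = np.sqrt(hx**2 + hy**2 + hz**2)
        mask = (P.M > 1e-9) & (r <= n / 2 - 1)
        kvec = np.stack([hx[mask], hy[mask], hz[mask]], axis=1)
        shells = np.rint(r[mask]).astype(np.intp)
        R = rec.pose.rotation
        pred = P.W[mask] * sample_reference(Vhat, kvec @ R.T)
        D = P.D[mask]
        if np.any(rec.pose.shift != 0):
            arg = kvec @ (rec.pose.shift / (n * P.pixel_size))
            pred = pred * np.exp(-2j * np.pi * arg)
        resid = np.abs(D - pred) ** 2
        num += shell_sum(resid, shells, ns).real
        den += shell_sum(P.M[mask], shells, ns).real
    out = np.full(ns, np.nan)
    ok = den > 0
    out[ok] = num[ok] / (2.0 * den[ok])
    if sigma2_prev is not None:
        out[~ok] = np.asarray(sigma2_prev, dtype=float)[~ok]
    return out


def update_tau(Vhat: np.ndarray, shell_W: np.ndarray, shell_M: np.ndarray) -> np.ndarray:
    """Per-shell signal power of the current map, CTF^2-corrected.

    Shells with no observations (sum M = 0) are NaN (undefined)."""
    n = Vhat.shape[0]
    ns = n // 2 + 1
    hx, hy, hz = freq_grid_3d(n)
    shells = np.rint(np.sqrt(hx**2 + hy**2 + hz**2)).astype(np.intp)
    keep = shells < ns
    power = shell_sum(np.abs(Vhat[keep]) ** 2, shells[keep], ns).real
    count = shell_sum(np.ones(np.count_nonzero(keep)), shells[keep], ns).real
    mean_power = np.where(count > 0, power / np.maximum(count, 1), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(shell_M > 0, shell_W / np.maximum(shell_M, 1e-300), np.nan)
    return mean_power / 2.0 * ratio


def shell_power(Vhat: np.ndarray) -> np.ndarray:
    """Mean |V|^2 per radial shell (helper for initial tau^2)."""
    n = Vhat.shape[0]
    ns = n // 2 + 1
    hx, hy, hz = freq_grid_3d(n)
    shells = np.rint(np.sqrt(hx**2 + hy**2 + hz**2)).astype(np.intp)
    keep = shells < ns
    power = shell_sum(np.abs(Vhat[keep]) ** 2, shells[keep], ns).real
    count = shell_sum(np.ones(np.count_nonzero(keep)), shells[keep], ns).real
    return np.where(count > 0, power / np.maximum(count, 1), 0.0)


def compute_fsc(V1: np.ndarray, V2: np.ndarray) -> np.ndarray:
    """Fourier shell correlation between two maps of equal box size.

    Zero-power shells give FSC = 0."""
    if V1.shape != V2.shape:
        raise ValueError("maps must have equal shapes")
    n = V1.shape[0]
    ns = n // 2 + 1
    hx, hy, hz = freq_grid_3d(n)
    shells = np.rint(np.sqrt(hx**2 + hy**2 + hz**2)).astype(np.intp)
    keep = shells < ns
    s = shells[keep]
    cross = shell_sum(V1[keep] * np.conj(V2[keep]), s, ns).real
    p1 = shell_sum(np.abs(V1[keep]) ** 2, s, ns).real
    p2 = shell_sum(np.abs(V2[keep]) ** 2, s, ns).real
    with np.errstate(divide="ignore", invalid="ignore"):
        fsc = np.where((p1 > 0) & (p2 > 0), cross / np.sqrt(np.maximum(p1 * p2, 1e-300)), 0.0)
    return fsc


def resolution_at(
    fsc: np.ndarray, box: int, pixel_size: float, threshold: float = 0.143
) -> float:
    """Resolution (A) at the first crossing of ``threshold``, linearly
    interpolated between shells; Nyquist (2 * pixel) if never crossed."""
    fsc = np.asarray(fsc, dtype=float)
    for k in range(1, len(fsc)):
        if fsc[k] < threshold:
            f0, f1 = fsc[k - 1], fsc[k]
            frac = (f0 - threshold) / (f0 - f1) if f0 != f1 else 0.0
            k_cross = (k - 1) + frac
            if k_cross <= 0:
                return float("inf")
            return box * pixel_size / k_cross
    return 2.0 * pixel_size


@dataclass
class EmResult:
    Vhat: np.ndarray
    half_maps: tuple
    sigma2: np.ndarray
    tau2: np.ndarray
    fsc: np.ndarray
    resolution: float
    resolution_history: list = field(default_factory=list)
    nll_history: list = field(default_factory=list)
    converged: bool = False


def run_em(
    particles: list[ParticleRecord],
    V0hat: np.ndarray,
    n_iter: int,
    sigma2: np.ndarray | None = None,
    tau2: np.ndarray | None = None,
    search: bool = False,
    angular_step: float = 10.0,
    trans_range: float = 0.0,
    trans_step: float = 1.0,
    local_refine: bool = True,
    m_threshold: float = M_THRESHOLD_DEFAULT,
    kmax: float | None = None,
) -> EmResult:
    """Alternate pose (re-)alignment, half-set backprojection, map update
    and noise/signal re-estimation.

    Initial tau^2 comes from the shell power of the starting reference and
    initial sigma^2 from the residuals at the starting poses.  Stops when
    the half-set resolution changes by less than one shell for two
    consecutive iterations, or warns and stops early if the summed nll
    increases for two consecutive iterations.
    """
    if not particles:
        raise ValueError("no particles")
    box = particles[0].pseudo.box
    px = particles[0].pseudo.pixel_size

    def _as_ref(V):
        """Predictions always go through a padded, gridding-corrected
        reference; maps stay plain Fourier cubes."""
        if isinstance(V, FourierReference):
            return V
        return FourierReference.from_map(ift3(V))

    def _coarse_cube(V):
        if isinstance(V, np.ndarray):
            return V
        from .fourier import ft3

        m = ift3(V.F) * V.oversample**3
        N = V.F.shape[0]
        c, h = N // 2, V.box // 2
        return ft3(m[c - h : c + h, c - h : c + h, c - h : c + h])

    Vhat = _coarse_cube(V0hat)
    Vref = _as_ref(V0hat)
    if sigma2 is None:
        sigma2 = update_sigma(particles, Vref)
        sigma2 = np.where(np.isnan(sigma2) | (sigma2 <= 0), np.nanmax(sigma2), sigma2)
    if tau2 is None:
        tau2 = shell_power(Vhat) / 2.0
    res_hist: list[float] = []
    nll_hist: list[float] = []
    half_maps = (Vhat, Vhat)
    fsc = np.ones(box // 2 + 1)
    converged = False
    for it in range(n_iter):
        if search:
            for rec in particles:
                prior = rec.prior or OrientationPrior(centre=rec.pose)
                result = grid_search_pose(
                    rec.pseudo, Vref, sigma2, prior, angular_step,
                    trans_range, trans_step, m_threshold=m_threshold, kmax=kmax,
                )
                rec.pose = result.map_pose
                if local_refine:
                    rec.pose = local_refine_pose(
                        rec.pseudo, Vref, sigma2, rec.pose, prior=prior,
                        m_threshold=m_threshold, kmax=kmax,
                    )
        states = [ReconstructionState.empty(box), ReconstructionState.empty(box)]
        for i, rec in enumerate(particles):
            backproject_accumulate(
                states[i % 2], rec.pseudo, rec.pose.rotation, sigma2, rec.pose.shift
            )
        halves = [em_update_map(s, tau2) for s in states]
        full_state = states[0].merged(states[1])
        Vhat = em_update_map(full_state, tau2)
        Vref = _as_ref(Vhat)
        sigma2_new = update_sigma(particles, Vref, sigma2_prev=sigma2)
        sigma2 = np.where(np.isnan(sigma2_new) | (sigma2_new <= 0), sigma2, sigma2_new)
        tau2 = update_tau(Vhat, full_state.shell_W, full_state.shell_M)
        fsc = compute_fsc(halves[0], halves[1])
        res = resolution_at(fsc, box, px)
        res_hist.append(res)
        half_maps = (halves[0], halves[1])
        total_nll = 0.0
        for rec in particles:
            ev = PseudoEvaluator(rec.pseudo, Vref, sigma2, m_threshold, kmax)
            total_nll += ev.nll(rec.pose.rotation, rec.pose.shift)
        nll_hist.append(total_nll)
        if len(nll_hist) >= 3 and nll_hist[-1] > nll_hist[-2] > nll_hist[-3]:
            warnings.warn("EM objective increased for two iterations; stopping")
            break
        if len(res_hist) >= 3:
            k_now = box * px / res_hist[-1]
            k_prev = box * px / res_hist[-2]
            k_prev2 = box * px / res_hist[-3]
            if abs(k_now - k_prev) < 1.0 and abs(k_prev - k_prev2) < 1.0:
                converged = True
                break
    return EmResult(
        Vhat=Vhat,
        half_maps=half_maps,
        sigma2=sigma2,
        tau2=tau2,
        fsc=fsc,
        resolution=res_hist[-1] if res_hist else float("nan"),
        resolution_history=res_hist,
        nll_history=nll_hist,
        converged=converged,
    )
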
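"""Tilt-series refinement against the current average.

Optical refinement (defocus, astigmatism, even/odd Zernike aberrations,
damage scale factors) and geometrical refinement (rigid per-tilt
alignment, spatially coherent per-particle 3D motion), all minimising the
2D per-pixel negative log-likelihood

    nll = sum_{p,j} |X_pj - kappa(k) CTF_p(j) g_pj|^2 / sigma_j^2 ,

where g is the CTF-free complex prediction (reference slice, odd-phase
factor, position ramps).

Condensed scoring.  Writing CTF(chi) = Re(c e^{i chi}) with
c = -w + i sqrt(1 - w^2), the information of all particles in one tilt
image condenses into per-frequency accumulator images

    Q = c   sum_p e^{i chi_p}  Re(conj(X) g) / sigma^2      (data cross)
    P = c^2 sum_p e^{2i chi_p} |g|^2 / sigma^2              (power, rotating)
    S = |c|^2 sum_p |g|^2 / sigma^2                         (power, static)
    O =     sum_p CTF_p conj(X) g / sigma^2                 (odd-side cross)

after which any phase perturbation delta(j) shared by those particles
(a defocus offset, an astigmatism change, even Zernike terms) scores
*exactly* as

    nll(delta) = const - 2 Re(kappa e^{i delta} Q)
               + kappa^2 [ Re(e^{2 i delta} P) + S ] / 2 ,

and an odd (antisymmetric) phase psi(j) on the prediction scores as
const' - 2 Re(kappa e^{i psi} O).  One pass over the particles therefore
suffices for defocus scans, astigmatism fits, aberration fits and damage
scale factors alike.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RectBivariateSpline
from scipy.optimize import minimize

from .ctf import CtfParams, ZernikeBasis, ctf_phase
from .fourier import freq_grid_2d, shell_index, shell_sum

__all__ = [
    "TiltView",
    "CondensedImagePair",
    "MotionModel",
    "condense_tilt_image",
    "score_even_phase",
    "score_odd_phase",
    "refine_defocus",
    "refine_astigmatism",
    "estimate_aberrations",
    "estimate_scale_factors",
    "precompute_position_likelihood",
    "PositionLikelihood",
    "refine_rigid_tilt_alignment",
    "refine_particle_motion",
]


@dataclass
class TiltView:
    """One particle's view in one tilt image: the observed Fourier crop,
    the even CTF phase chi (with the particle's depth defocus), and the
    CTF-free complex prediction g."""

    X: np.ndarray
    chi: np.ndarray
    pred: np.ndarray


@dataclass
class CondensedImagePair:
    """Per-frequency accumulators condensing all particles of one tilt
    image (see module docstring); ``const`` is sum |X|^2/sigma^2."""

    Q: np.ndarray
    P: np.ndarray
    S: np.ndarray
    O: np.ndarray
    const: float
    w: float  # amplitude contrast used for c
    pixel_size: float
    n_particles: int = 0

    def __add__(self, other: "CondensedImagePair") -> "CondensedImagePair":
        return CondensedImagePair(
            Q=self.Q + other.Q,
            P=self.P + other.P,
            S=self.S + other.S,
            O=self.O + other.O,
            const=self.const + other.const,
            w=self.w,
            pixel_size=self.pixel_size,
            n_particles=self.n_particles + other.n_particles,
        )


def condense_tilt_image(
    views: list[TiltView], sigma2: np.ndarray, amplitude_contrast: float, pixel_size: float
) -> CondensedImagePair:
    """Accumulate the condensed images over the particles of one tilt."""
    if not views:
        raise ValueError("no particles in this tilt image")
    n = views[0].X.shape[0]
    hx, hy = freq_grid_2d(n)
    shells = shell_index(hx, hy)
    s2 = np.asarray(sigma2, dtype=float)[np.clip(shells, 0, len(sigma2) - 1)]
    w = amplitude_contrast
    c = -w + 1j * np.sqrt(1.0 - w * w)
    Q = np.zeros((n, n), dtype=complex)
    P = np.zeros((n, n), dtype=complex)
    S = np.zeros((n, n))
    O = np.zeros((n, n), dtype=complex)
    const = 0.0
    for v in views:
        eich = np.exp(1j * v.chi)
        r = np.real(np.conj(v.X) * v.pred) / s2
        u = np.abs(v.pred) ** 2 / s2
        Q += c * eich * r
        P += (c * eich) ** 2 * u
        S += np.abs(c) ** 2 * u
        ctf = np.real(c * eich)
        O += ctf * np.conj(v.X) * v.pred / s2
        const += float(np.sum(np.abs(v.X) ** 2 / s2))
    return CondensedImagePair(
        Q=Q, P=P, S=S, O=O, const=const, w=w, pixel_size=pixel_size, n_particles=len(views)
    )


def score_even_phase(
    pair: CondensedImagePair, delta: np.ndarray | float = 0.0, kappa: np.ndarray | float = 1.0
) -> float:
    """Exact nll for a common even phase perturbation delta(j), optionally
    scaled by a per-frequency kappa."""
    e1 = np.exp(1j * np.asarray(delta)) if np.any(np.asarray(delta) != 0) else 1.0
    cross = np.real(kappa * e1 * pair.Q)
    power = 0.5 * np.asarray(kappa) ** 2 * (np.real(e1 * e1 * pair.P) + pair.S)
    return float(pair.const - 2.0 * np.sum(cross) + np.sum(power))


def score_odd_phase(
    pair: CondensedImagePair, psi: np.ndarray, kappa: np.ndarray | float = 1.0
) -> float:
    """Exact nll for a common antisymmetric phase psi(j) on the prediction."""
    cross = np.real(kappa * np.exp(1j * psi) * pair.O)
    power = 0.5 * np.asarray(kappa) ** 2 * (np.real(pair.P) + pair.S)
    return float(pair.const - 2.0 * np.sum(cross) + np.sum(power))


def _freq_grids(n: int, pixel_size: float):
    hx, hy = freq_grid_2d(n)
    return hx / (n * pixel_size), hy / (n * pixel_size)


def refine_defocus(
    pair: CondensedImagePair,
    wavelength: float,
    search_range: float = 3000.0,
    search_step: float = 100.0,
    kappa: np.ndarray | float = 1.0,
) -> tuple[float, bool]:
    """Common defocus offset of one tilt image by scanning the condensed
    score and parabola-fitting the minimum.

    Returns (delta_defocus in A, refined).  A minimum at the scan boundary
    is flagged (refined=False) and 0 is returned unrefined.
    """
    n = pair.Q.shape[0]
    jx, jy = _freq_grids(n, pair.pixel_size)
    k2 = jx**2 + jy**2
    offsets = np.arange(-search_range, search_range + search_step / 2, search_step)
    scores = np.array(
        [score_even_phase(pair, np.pi * wavelength * dz * k2, kappa) for dz in offsets]
    )
    i = int(np.argmin(scores))
    if i == 0 or i == len(offsets) - 1:
        return 0.0, False
    # parabola through the three bracketing points
    y0, y1, y2 = scores[i - 1], scores[i], scores[i + 1]
    denom = y0 - 2 * y1 + y2
    frac = 0.5 * (y0 - y2) / denom if denom > 0 else 0.0
    return float(offsets[i] + frac * search_step), True


def refine_astigmatism(
    pair: CondensedImagePair,
    params: CtfParams,
    kappa: np.ndarray | float = 1.0,
) -> CtfParams:
    """3-parameter (defocus_u, defocus_v, azimuth) local optimisation of
    the condensed score; azimuth reported in [0, 180)."""
    n = pair.Q.shape[0]
    jx, jy = _freq_grids(n, pair.pixel_size)
    chi0 = ctf_phase(params, jx, jy)

    def objective(x):
        du, dv, az = x
        trial = CtfParams(
            voltage_kv=params.voltage_kv,
            cs_mm=params.cs_mm,
            amplitude_contrast=params.amplitude_contrast,
            defocus_u=du,
            defocus_v=dv,
            astigmatism_deg=az,
            phase_shift=params.phase_shift,
            nyquist=params.nyquist,
        )
        return score_even_phase(pair, ctf_phase(trial, jx, jy) - chi0, kappa)

    x0 = np.array([params.defocus_u, params.defocus_v, params.astigmatism_deg])
    # explicit simplex: defoci (A) and azimuth (deg) differ by orders of
    # magnitude, so the default relative perturbation never explores azimuth
    steps = np.array([400.0, -400.0, 45.0])
    simplex = np.vstack([x0] + [x0 + steps[i] * np.eye(3)[i] for i in range(3)])
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": 1.0,
            "fatol": 1e-9 * max(abs(pair.const), 1.0),
            "maxiter": 800,
            "initial_simplex": simplex,
        },
    )
    x = res.x if res.fun <= objective(x0) else x0
    du, dv, az = float(x[0]), float(x[1]), float(x[2]) % 180.0
    if dv > du:  # canonical: u >= v, azimuth rotated by 90
        du, dv, az = dv, du, (az + 90.0) % 180.0
    out = CtfParams(
        voltage_kv=params.voltage_kv,
        cs_mm=params.cs_mm,
        amplitude_contrast=params.amplitude_contrast,
        defocus_u=du,
        defocus_v=dv,
        astigmatism_deg=az,
        phase_shift=params.phase_shift,
        zernike_even=params.zernike_even,
        zernike_even_nm=params.zernike_even_nm,
        zernike_odd=params.zernike_odd,
        zernike_odd_nm=params.zernike_odd_nm,
        scale=params.scale,
        nyquist=params.nyquist,
    )
    return out


def estimate_aberrations(
    pairs: list[CondensedImagePair],
    basis: ZernikeBasis,
    parity: str = "odd",
    kappa: np.ndarray | float = 1.0,
) -> np.ndarray:
    """Zernike aberration coefficients fitted globally over the pooled
    condensed images of the whole data set.

    Even coefficients perturb the CTF phase chi; odd coefficients rotate
    the prediction phase.  A basis the pooled data cannot constrain
    raises an error naming the unconstrained terms.
    """
    if not pairs:
        raise ValueError("no condensed images")
    pooled = pairs[0]
    for p in pairs[1:]:
        pooled = pooled + p
    n = pooled.Q.shape[0]
    jx, jy = _freq_grids(n, pooled.pixel_size)
    Z = basis.evaluate(jx, jy)  # (n_terms, n, n)
    weight = np.abs(pooled.O) if parity == "odd" else np.abs(pooled.Q)
    for t, (nn, mm) in enumerate(basis.nm_pairs):
        if float(np.sum(weight * Z[t] ** 2)) <= 0:
            raise ValueError(f"Zernike term (n={nn}, m={mm}) is unconstrained by the data")

    if parity == "odd":
        def objective(coeffs):
            psi = np.tensordot(coeffs, Z, axes=1)
            return score_odd_phase(pooled, psi, kappa)
    else:
        def objective(coeffs):
            delta = np.tensordot(coeffs, Z, axes=1)
            return score_even_phase(pooled, delta, kappa)

    x0 = np.zeros(basis.n_terms)
    res = minimize(objective, x0, method="Powell", options={"xtol": 1e-4, "maxiter": 4000})
    return res.x if res.fun <= objective(x0) else x0


def estimate_scale_factors(
    pairs: list[CondensedImagePair],
    per_shell: bool = False,
):
    """Per-tilt damage envelope kappa_f(k) = s_f exp(-B_f k^2 / 4).

    The free per-shell optimum kappa(k) = sum Re(Q) / sum power is fitted
    with the (s, B) parameterisation, weighted by the per-shell power
    (well-constrained shells dominate).  s is clipped to [0, 1.5]; a
    negative fit is clipped and flagged.  Returns (s, B, flags), or the
    raw per-shell kappa arrays when ``per_shell`` is requested (useful
    for diagnostics; noisier, kept behind this flag).
    """
    from scipy.optimize import curve_fit

    if per_shell:
        out = []
        for pair in pairs:
            n = pair.Q.shape[0]
            hx, hy = freq_grid_2d(n)
            shells = shell_index(hx, hy)
            ns = n // 2 + 1
            cross = shell_sum(np.real(pair.Q), shells, ns)
            power = shell_sum(0.5 * (np.real(pair.P) + pair.S), shells, ns)
            with np.errstate(divide="ignore", invalid="ignore"):
                out.append(np.where(power > 0, cross / np.maximum(power, 1e-300), np.nan))
        return out

    s_out, b_out, flags = [], [], []
    for pair in pairs:
        n = pair.Q.shape[0]
        hx, hy = freq_grid_2d(n)
        shells = shell_index(hx, hy)
        ns = n // 2 + 1
        cross = shell_sum(np.real(pair.Q), shells, ns)
        power = shell_sum(0.5 * (np.real(pair.P) + pair.S), shells, ns)
        ok = power > 1e-12 * power.max()
        k_shell = np.arange(ns) / (n * pair.pixel_size)
        kappa_free = np.zeros(ns)
        kappa_free[ok] = cross[ok] / power[ok]
        flag = bool(np.any(kappa_free[ok] < 0))
        kk = k_shell[ok][1:]
        yy = np.clip(kappa_free[ok][1:], 0.0, None)
        ww = power[ok][1:]
        try:
            popt, _ = curve_fit(
                lambda k, s, B: s * np.exp(-B * k**2 / 4.0),
                kk,
                yy,
                p0=[max(yy.max(), 1e-3), 0.0],
                sigma=1.0 / np.sqrt(np.maximum(ww, 1e-12)),
                maxfev=10000,
            )
            s_f, b_f = float(popt[0]), float(popt[1])
        except RuntimeError:
            s_f, b_f = float(np.mean(yy)), 0.0
            flag = True
        if s_f < 0:
            s_f, flag = 0.0, True
        s_out.append(min(s_f, 1.5))
        b_out.append(b_f)
        flags.append(flag)
    return np.asarray(s_out), np.asarray(b_out), np.asarray(flags)


@dataclass
class PositionLikelihood:
    """2D nll of one particle's in-image displacement, FFT-precomputed on
    the integer grid and spline-interpolated for sub-pixel queries."""

    spline: RectBivariateSpline
    extent: int

    def value(self, dx: float, dy: float) -> float:
        return float(self.spline.ev(dy, dx))

    def grad(self, dx: float, dy: float) -> np.ndarray:
        return np.array(
            [float(self.spline.ev(dy, dx, dy=1)), float(self.spline.ev(dy, dx, dx=1))]
        )

    def values(self, d: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(d)
        return self.spline.ev(d[:, 1], d[:, 0])

    def grads(self, d: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(d)
        gx = self.spline.ev(d[:, 1], d[:, 0], dy=1)
        gy = self.spline.ev(d[:, 1], d[:, 0], dx=1)
        return np.stack([gx, gy], axis=1)


def precompute_position_likelihood(
    X: np.ndarray,
    prediction_with_ctf: np.ndarray,
    sigma2: np.ndarray,
    extent: int = 8,
) -> PositionLikelihood:
    """nll of Eq-style per-pixel residuals as a function of a 2D in-image
    displacement of the particle, for all integer displacements at once
    (one FFT), windowed to +-extent pixels.

    The value at (0, 0) equals the direct residual sum at the unshifted
    pose.
    """
    if extent < 1:
        raise ValueError("extent must be >= 1")
    n = X.shape[0]
    hx, hy = freq_grid_2d(n)
    shells = shell_index(hx, hy)
    s2 = np.asarray(sigma2, dtype=float)[np.clip(shells, 0, len(sigma2) - 1)]
    C = prediction_with_ctf
    G = np.conj(X) * C / s2
    cc = np.real(np.fft.fft2(G))  # cc[d] = sum_h G_h e^{-2 pi i h.d / n}
    const = float(np.sum((np.abs(X) ** 2 + np.abs(C) ** 2) / s2))
    nll_map = const - 2.0 * np.fft.fftshift(cc)
    c0 = n // 2
    window = nll_map[c0 - extent : c0 + extent + 1, c0 - extent : c0 + extent + 1]
    ax = np.arange(-extent, extent + 1, dtype=float)
    spline = RectBivariateSpline(ax, ax, window, kx=3, ky=3)
    return PositionLikelihood(spline=spline, extent=extent)


def refine_rigid_tilt_alignment(
    likelihoods: list[PositionLikelihood],
    positions_px: np.ndarray,
    image_centre_px: np.ndarray,
    min_particles: int = 3,
) -> tuple[float, np.ndarray, bool]:
    """Rigid in-plane rotation (deg) and 2D shift (px) of one tilt image,
    minimising the summed per-particle position likelihoods.

    Returns (rotation_deg, shift_px, refined).  With fewer than
    ``min_particles`` particles the tilt is skipped with a warning.
    """
    if len(likelihoods) < min_particles:
        warnings.warn("too few particles to refine this tilt; skipping")
        return 0.0, np.zeros(2), False
    rel = np.asarray(positions_px, dtype=float) - np.asarray(image_centre_px, dtype=float)

    def displacement(x):
        phi = np.deg2rad(x[0])
        c, s = np.cos(phi), np.sin(phi)
        Rm = np.array([[c, -s], [s, c]])
        return rel @ Rm.T + x[1:] - rel

    def objective(x):
        d = displacement(x)
        return float(sum(l.value(dx, dy) for l, (dx, dy) in zip(likelihoods, d)))

    x0 = np.zeros(3)
    f0 = objective(x0)
    res = minimize(
        objective, x0, method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-10 * max(abs(f0), 1.0), "maxiter": 800},
    )
    if res.fun <= f0:
        return float(res.x[0]), res.x[1:].copy(), True
    return 0.0, np.zeros(2), True


@dataclass
class MotionModel:
    """Per-particle, per-tilt 3D displacements (A) plus the hyperparameters
    of the spatial-coherence prior."""

    offsets: np.ndarray  # (P, F, 3)
    sigma_displacement: float  # A per tilt-to-tilt increment
    correlation_length: float  # A
    converged: bool = True


def _motion_prior_cholesky(positions: np.ndarray, sigma_d: float, corr_len: float):
    """Inverse-covariance factor of the spatial prior: K_ij = sigma_d^2
    exp(-|x_i - x_j| / L) over particle positions, regularised for
    numerical rank."""
    pos = np.asarray(positions, dtype=float)
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    K = sigma_d**2 * np.exp(-dist / corr_len)
    K += np.eye(len(pos)) * (1e-8 * sigma_d**2 + 1e-12)
    return np.linalg.inv(K)


def refine_particle_motion(
    likelihoods: list[list[PositionLikelihood]],
    align_matrices: np.ndarray,
    positions: np.ndarray,
    acquisition_order: np.ndarray,
    pixel_size: float,
    sigma_displacement: float = 1.0,
    correlation_length: float = 500.0,
    maxiter: int = 2000,
) -> MotionModel:
    """Spatially coherent per-particle 3D motion through the tilt series.

    ``likelihoods[p][f]`` scores particle p's 2D displacement in tilt f.
    The trajectory increments between consecutive tilts *in acquisition
    order* are penalised with a Gaussian-process prior over particle
    positions (exponential kernel, independent per increment and axis),
    so nearby particles move together.  The first acquired tilt anchors
    the trajectories (zero offset there).  Quasi-Newton (L-BFGS)
    optimisation with an analytic gradient.
    """
    P = len(likelihoods)
    F = len(align_matrices)
    order = np.argsort(np.asarray(acquisition_order))  # tilt indices in time order
    Kinv = _motion_prior_cholesky(positions, sigma_displacement, correlation_length)
    A2 = np.asarray(align_matrices)[:, :2, :]  # (F, 2, 3)

    free = order[1:]  # offsets at the first acquired tilt are fixed to zero
    nf = len(free)

    def unpack(x):
        T = np.zeros((P, F, 3))
        T[:, free, :] = x.reshape(P, nf, 3)
        return T

    def objective_grad(x):
        T = unpack(x)
        val = 0.0
        grad = np.zeros((P, F, 3))
        for f in range(F):
            d_px = (T[:, f, :] @ A2[f].T) / pixel_size  # (P, 2)
            for p in range(P):
                val += likelihoods[p][f].value(d_px[p, 0], d_px[p, 1])
                g2 = likelihoods[p][f].grad(d_px[p, 0], d_px[p, 1])  # d nll / d d_px
                grad[p, f, :] += (g2 @ A2[f]) / pixel_size
        # prior over increments in acquisition order
        for a, b in zip(order[:-1], order[1:]):
            delta = T[:, b, :] - T[:, a, :]  # (P, 3)
            kd = Kinv @ delta
            val += 0.5 * float(np.sum(delta * kd))
            grad[:, b, :] += kd
            grad[:, a, :] -= kd
        return val, grad[:, free, :].ravel()

    x0 = np.zeros(P * nf * 3)
    res = minimize(
        objective_grad, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-6},
    )
    if not res.success and res.nit >= maxiter:
        warnings.warn("motion refinement did not converge; returning best iterate")
    x_best = res.x if res.fun <= objective_grad(x0)[0] else x0
    return MotionModel(
        offsets=unpack(x_best),
        sigma_displacement=sigma_displacement,
        correlation_length=correlation_length,
        converged=bool(res.success),
    )
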
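"""Contrast transfer function model.

Per-tilt, per-particle CTFs with astigmatic defocus, phase shift, even
(symmetric) Zernike aberrations inside the phase function, odd
(antisymmetric) Zernike aberrations as a unit-modulus phase factor on the
complex prediction, and frequency-dependent damage scale factors
``kappa_f(k)``.

Sign convention: positive defocus is underfocus and the CTF is negative
at low frequency (``CTF(0) = -w``), matching the dominant single-particle
convention so imported STAR defoci keep their meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np

__all__ = [
    "CtfParams",
    "ZernikeBasis",
    "electron_wavelength",
    "ctf_phase",
    "evaluate_ctf",
    "odd_phase_factor",
    "defocus_at_particle",
    "zernike_basis",
    "zernike_nm",
    "dose_damage_weight",
]


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstrom for voltage in kV."""
    if voltage_kv <= 0:
        raise ValueError("voltage must be positive")
    v = voltage_kv * 1e3
    return 12.2639 / np.sqrt(v + 0.97845e-6 * v**2)


@dataclass
class CtfParams:
    """Optical parameters of one particle in one tilt image.

    Defoci in A (positive = underfocus); astigmatism azimuth in degrees;
    phase shift in radians; Zernike coefficients in radians, paired with
    the (n, m) index lists of the basis used; ``scale`` is the damage /
    amplitude factor kappa in [0, ~1] -- either a callable of |k| (1/A) or
    a constant.
    """

    voltage_kv: float = 300.0
    cs_mm: float = 2.7
    amplitude_contrast: float = 0.07
    defocus_u: float = 30000.0
    defocus_v: float = 30000.0
    astigmatism_deg: float = 0.0
    phase_shift: float = 0.0
    zernike_even: np.ndarray = field(default_factory=lambda: np.zeros(0))
    zernike_even_nm: tuple = ()
    zernike_odd: np.ndarray = field(default_factory=lambda: np.zeros(0))
    zernike_odd_nm: tuple = ()
    scale: object = 1.0
    nyquist: float | None = None  # 1/A; unit-disk scaling for Zernike terms

    def __post_init__(self):
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError("amplitude contrast must be in [0, 1]")
        self.zernike_even = np.atleast_1d(np.asarray(self.zernike_even, dtype=float))
        self.zernike_odd = np.atleast_1d(np.asarray(self.zernike_odd, dtype=float))

    @property
    def wavelength(self) -> float:
        return electron_wavelength(self.voltage_kv)

    def kappa(self, k: np.ndarray) -> np.ndarray:
        if callable(self.scale):
            return np.asarray(self.scale(k), dtype=float)
        return np.full_like(np.asarray(k, dtype=float), float(self.scale))


def _astig_defocus(params: CtfParams, jx, jy):
    """Defocus along the azimuth of each frequency (the astigmatism ellipse)."""
    du, dv = params.defocus_u, params.defocus_v
    if du == dv:
        return np.full_like(np.asarray(jx, dtype=float), du)
    az = np.deg2rad(params.astigmatism_deg)
    alpha = np.arctan2(jy, jx)
    return 0.5 * (du + dv + (du - dv) * np.cos(2.0 * (alpha - az)))


def ctf_phase(params: CtfParams, jx: np.ndarray, jy: np.ndarray) -> np.ndarray:
    """Phase function chi(j) in radians at 2D frequencies (jx, jy) in 1/A.

    chi = pi lambda dz(alpha) |j|^2 - (pi/2) Cs lambda^3 |j|^4
          + phase_shift + sum of even Zernike terms.
    """
    jx = np.asarray(jx, dtype=float)
    jy = np.asarray(jy, dtype=float)
    k2 = jx**2 + jy**2
    lam = params.wavelength
    cs = params.cs_mm * 1e7  # mm -> A
    dz = _astig_defocus(params, jx, jy)
    chi = np.pi * lam * dz * k2 - 0.5 * np.pi * cs * lam**3 * k2**2 + params.phase_shift
    if params.zernike_even.size and params.zernike_even_nm:
        chi = chi + _zernike_sum(
            params.zernike_even, params.zernike_even_nm, jx, jy, params.nyquist
        )
    return chi


def _zernike_sum(coeffs, nm_pairs, jx, jy, nyquist):
    if nyquist is None:
        raise ValueError("CtfParams.nyquist must be set to use Zernike terms")
    rho = np.sqrt(jx**2 + jy**2) / nyquist
    theta = np.arctan2(jy, jx)
    out = np.zeros_like(rho)
    for c, (n, m) in zip(coeffs, nm_pairs):
        if c != 0.0:
            out = out + c * zernike_nm(n, m, rho, theta)
    return out


def evaluate_ctf(params: CtfParams, jx: np.ndarray, jy: np.ndarray) -> np.ndarray:
    """Real CTF on a 2D frequency grid (1/A), including damage scaling.

    ``CTF(j) = -[sqrt(1-w^2) sin chi + w cos chi] * kappa(|j|)``.
    Odd Zernike terms do not enter here; they multiply the complex
    prediction as ``exp(i psi_odd(j))`` (see :func:`odd_phase_factor`).
    """
    chi = ctf_phase(params, jx, jy)
    w = params.amplitude_contrast
    base = -(np.sqrt(1.0 - w**2) * np.sin(chi) + w * np.cos(chi))
    k = np.sqrt(np.asarray(jx, dtype=float) ** 2 + np.asarray(jy, dtype=float) ** 2)
    return base * params.kappa(k)


def odd_phase_factor(params: CtfParams, jx: np.ndarray, jy: np.ndarray) -> np.ndarray:
    """Unit-modulus factor exp(i psi(j)) from antisymmetric aberrations."""
    if not (params.zernike_odd.size and params.zernike_odd_nm):
        return np.ones_like(np.asarray(jx, dtype=float), dtype=complex)
    psi = _zernike_sum(params.zernike_odd, params.zernike_odd_nm, jx, jy, params.nyquist)
    return np.exp(1j * psi)


def defocus_at_particle(
    base_defocus: float,
    position: np.ndarray,
    tilt_rotation: np.ndarray,
    handedness: int = 1,
) -> float:
    """Particle defocus from the tilt-image base defocus and the particle
    depth along the beam.

    ``position`` is the 3D tomogram-frame position (A, relative to the
    tilt axis plane); ``tilt_rotation`` is A_f.  With the default
    handedness (+1), particles higher along +z (closer to the beam source)
    are less underfocused: defocus = base - handedness * (A_f pos)_z.
    """
    z = float((np.asarray(tilt_rotation) @ np.asarray(position, dtype=float))[2])
    return float(base_defocus) - handedness * z


def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    m = abs(m)
    out = np.zeros_like(rho)
    for s in range((n - m) // 2 + 1):
        c = (
            (-1) ** s
            * math.factorial(n - s)
            / (
                math.factorial(s)
                * math.factorial((n + m) // 2 - s)
                * math.factorial((n - m) // 2 - s)
            )
        )
        out = out + c * rho ** (n - 2 * s)
    return out


def zernike_nm(n: int, m: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Zernike polynomial Z_n^m (unnormalised: Z_0^0 = 1, Z_2^0 = 2 rho^2 - 1)."""
    if (n - abs(m)) % 2 or abs(m) > n:
        raise ValueError(f"invalid Zernike indices ({n}, {m})")
    R = _radial_poly(n, m, np.asarray(rho, dtype=float))
    if m >= 0:
        return R * np.cos(m * np.asarray(theta, dtype=float))
    return R * np.sin(-m * np.asarray(theta, dtype=float))


@dataclass
class ZernikeBasis:
    """Zernike polynomials up to a maximum order, of one parity, evaluated
    on frequencies scaled so the unit disk touches Nyquist."""

    nm_pairs: list
    nyquist: float

    @property
    def n_terms(self) -> int:
        return len(self.nm_pairs)

    def evaluate(self, jx: np.ndarray, jy: np.ndarray) -> np.ndarray:
        """Stack of basis images, shape (n_terms, ...)."""
        rho = np.sqrt(np.asarray(jx, float) ** 2 + np.asarray(jy, float) ** 2) / self.nyquist
        theta = np.arctan2(jy, jx)
        return np.stack([zernike_nm(n, m, rho, theta) for n, m in self.nm_pairs])


def zernike_basis(max_order: int, nyquist: float, parity: str = "even") -> ZernikeBasis:
    """All (n, m) pairs with n <= max_order of the requested parity.

    'even' (n even) are the symmetric aberrations that add to the CTF
    phase; 'odd' (n odd) are antisymmetric and phase-shift the prediction.
    """
    if max_order < 0:
        raise ValueError("order must be >= 0")
    want = 0 if parity == "even" else 1
    pairs = [
        (n, m)
        for n in range(max_order + 1)
        if n % 2 == want
        for m in range(-n, n + 1, 2)
    ]
    return ZernikeBasis(nm_pairs=pairs, nyquist=nyquist)


def dose_damage_weight(k: np.ndarray, dose: float) -> np.ndarray:
    """Parametric radiation-damage envelope in [0, 1].

    Uses the empirical critical-exposure curve 0.245 k^-1.665 + 2.81
    (k in 1/A, dose in e/A^2); a fitted per-tilt kappa overrides this
    fallback wherever one is available.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    k = np.asarray(k, dtype=float)
    with np.errstate(divide="ignore"):
        crit = 0.245 * np.where(k > 0, k, np.inf) ** (-1.665) + 2.81
    return np.exp(-dose / (2.0 * crit))
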
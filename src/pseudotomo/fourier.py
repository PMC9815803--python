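"""Shared Fourier-space conventions.

All real-space arrays in this package hold the object centred at index
``n // 2`` on every axis (even box sizes only).  Discrete Fourier
transforms are taken through :func:`ft2` / :func:`ft3`, which apply
``ifftshift`` first so that the transform corresponds to an object centred
at the coordinate origin.  Fourier arrays are kept in standard numpy FFT
order (frequency 0 at index 0, negative frequencies wrapped); indices are
integer frequencies h with physical frequency h / (n * pixel_size) in 1/A.

Fourier arrays are stored as full complex planes/cubes.  Because real
input images contribute both j and -j, Hermitian symmetry is maintained
automatically and every physical frequency is counted twice in all sums
-- consistently so in both the 2D and the 3D likelihood, which leaves
every ratio and every argmin unchanged.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ft2",
    "ift2",
    "ft3",
    "ift3",
    "freq_grid_2d",
    "freq_grid_3d",
    "shell_index",
    "shell_sum",
    "trilinear_sample",
    "trilinear_insert",
    "phase_ramp_2d",
]


def ft2(img: np.ndarray) -> np.ndarray:
    """2D FFT of an image whose object is centred at ``n // 2``."""
    return np.fft.fft2(np.fft.ifftshift(img))


def ift2(F: np.ndarray) -> np.ndarray:
    """Inverse of :func:`ft2`; returns the real part."""
    return np.fft.fftshift(np.fft.ifft2(F)).real


def ft3(vol: np.ndarray) -> np.ndarray:
    return np.fft.fftn(np.fft.ifftshift(vol))


def ift3(F: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifftn(F)).real


def freq_grid_2d(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer frequency grids (hx, hy) for an (n, n) array indexed [y, x]."""
    h = np.fft.fftfreq(n, d=1.0 / n)
    hy, hx = np.meshgrid(h, h, indexing="ij")
    return hx, hy


def freq_grid_3d(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integer frequency grids (hx, hy, hz) for an (n, n, n) array indexed [z, y, x]."""
    h = np.fft.fftfreq(n, d=1.0 / n)
    hz, hy, hx = np.meshgrid(h, h, h, indexing="ij")
    return hx, hy, hz


def shell_index(*freqs: np.ndarray) -> np.ndarray:
    """Radial shell index: rounded |h| (shell thickness one frequency unit)."""
    r = np.sqrt(sum(np.asarray(f, dtype=float) ** 2 for f in freqs))
    return np.rint(r).astype(np.intp)


def shell_sum(values: np.ndarray, shells: np.ndarray, n_shells: int) -> np.ndarray:
    """Sum ``values`` per radial shell; shells >= n_shells are dropped."""
    v = np.asarray(values).ravel()
    s = np.asarray(shells).ravel()
    keep = s < n_shells
    if np.iscomplexobj(v):
        re = np.bincount(s[keep], weights=v.real[keep], minlength=n_shells)
        im = np.bincount(s[keep], weights=v.imag[keep], minlength=n_shells)
        return re + 1j * im
    return np.bincount(s[keep], weights=v[keep], minlength=n_shells)


def _corner_indices(pts: np.ndarray, n: int):
    """Floor corners and fractional offsets for trilinear interpolation."""
    f = np.floor(pts)
    d = pts - f
    f = f.astype(np.intp)
    return f, d


def trilinear_sample(F: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Trilinearly interpolate Fourier cube ``F`` (fft order, [z, y, x]) at
    continuous integer-frequency points ``pts`` of shape (m, 3) as (hx, hy, hz).

    Points with any |component| > n/2 - 1 lie outside the stored radius and
    return 0.
    """
    n = F.shape[0]
    pts = np.asarray(pts, dtype=float)
    out = np.zeros(pts.shape[0], dtype=F.dtype if np.iscomplexobj(F) else float)
    lim = n / 2 - 1
    ok = np.all(np.abs(pts) <= lim, axis=1)
    if not np.any(ok):
        return out
    p = pts[ok]
    f, d = _corner_indices(p, n)
    acc = np.zeros(p.shape[0], dtype=out.dtype)
    for cx in (0, 1):
        wx = d[:, 0] if cx else 1.0 - d[:, 0]
        ix = (f[:, 0] + cx) % n
        for cy in (0, 1):
            wy = d[:, 1] if cy else 1.0 - d[:, 1]
            iy = (f[:, 1] + cy) % n
            for cz in (0, 1):
                wz = d[:, 2] if cz else 1.0 - d[:, 2]
                iz = (f[:, 2] + cz) % n
                acc += (wx * wy * wz) * F[iz, iy, ix]
    out[ok] = acc
    return out


def trilinear_sample_multi(arrays: list, pts: np.ndarray) -> list:
    """Interpolate several same-shaped cubes at the same points, sharing
    the corner/weight computation.  Out-of-radius points give 0."""
    n = arrays[0].shape[0]
    pts = np.asarray(pts, dtype=float)
    outs = [
        np.zeros(pts.shape[0], dtype=a.dtype if np.iscomplexobj(a) else float)
        for a in arrays
    ]
    lim = n / 2 - 1
    ok = np.all(np.abs(pts) <= lim, axis=1)
    if not np.any(ok):
        return outs
    p = pts[ok]
    f, d = _corner_indices(p, n)
    accs = [np.zeros(p.shape[0], dtype=o.dtype) for o in outs]
    for cx in (0, 1):
        wx = d[:, 0] if cx else 1.0 - d[:, 0]
        ix = (f[:, 0] + cx) % n
        for cy in (0, 1):
            wy = d[:, 1] if cy else 1.0 - d[:, 1]
            iy = (f[:, 1] + cy) % n
            for cz in (0, 1):
                wz = d[:, 2] if cz else 1.0 - d[:, 2]
                iz = (f[:, 2] + cz) % n
                w = wx * wy * wz
                for a, acc in zip(arrays, accs):
                    acc += w * a[iz, iy, ix]
    for o, acc in zip(outs, accs):
        o[ok] = acc
    return outs


def trilinear_insert(
    pts: np.ndarray,
    values: np.ndarray,
    ctf: np.ndarray,
    D: np.ndarray,
    W: np.ndarray,
    M: np.ndarray,
) -> tuple[int, int]:
    """Forward-map 2D Fourier pixels into 3D arrays (scatter with trilinear
    weights over the 8 neighbouring voxels).

    Per in-radius pixel: ``ctf * value`` accumulates into D, ``ctf**2`` into
    W and exactly 1 (the partition of unity of the 8 weights) into M.
    Returns (n_inserted, n_skipped).
    """
    n = D.shape[0]
    pts = np.asarray(pts, dtype=float)
    lim = n / 2 - 1
    ok = np.all(np.abs(pts) <= lim, axis=1)
    p = pts[ok]
    v = np.asarray(values)[ok]
    c = np.asarray(ctf, dtype=float)[ok]
    f, d = _corner_indices(p, n)
    for cx in (0, 1):
        wx = d[:, 0] if cx else 1.0 - d[:, 0]
        ix = (f[:, 0] + cx) % n
        for cy in (0, 1):
            wy = d[:, 1] if cy else 1.0 - d[:, 1]
            iy = (f[:, 1] + cy) % n
            for cz in (0, 1):
                wz = d[:, 2] if cz else 1.0 - d[:, 2]
                iz = (f[:, 2] + cz) % n
                w = wx * wy * wz
                np.add.at(D, (iz, iy, ix), w * c * v)
                np.add.at(W, (iz, iy, ix), w * c * c)
                np.add.at(M, (iz, iy, ix), w)
    return int(np.count_nonzero(ok)), int(np.count_nonzero(~ok))


def phase_ramp_2d(n: int, shift_px: tuple[float, float]) -> np.ndarray:
    """Fourier-space phase ramp for a real-space shift by ``shift_px`` pixels.

    ``ft2(shift(img, +d)) == ft2(img) * phase_ramp_2d(n, d)``.
    """
    hx, hy = freq_grid_2d(n)
    dx, dy = shift_px
    return np.exp(-2j * np.pi * (hx * dx + hy * dy) / n)
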
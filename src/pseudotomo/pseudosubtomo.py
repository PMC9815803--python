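"""Pseudo-subtomogram construction.

A pseudo-subtomogram is the per-particle triplet of 3D Fourier arrays

* ``D`` -- sum of CTF-premultiplied 2D Fourier pixels forward-mapped into
  3D (the data term),
* ``W`` -- the matching sum of squared CTF values,
* ``M`` -- the multiplicity: how often each voxel was observed (each 2D
  pixel deposits exactly 1, split over its 8 trilinear neighbours).

Construction inserts each in-radius 2D Fourier pixel of every visible
tilt at the 3D frequency ``A_pf^T j``.  Crops are premultiplied with the
CTF at insertion time (not stored premultiplied), so refined CTFs can be
re-applied without re-extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fourier import freq_grid_2d, ft2, phase_ramp_2d, trilinear_insert
from .geometry import ProjectionMapping

__all__ = [
    "CropEntry",
    "Particle2DCrops",
    "PseudoSubtomogram",
    "extract_crop",
    "forward_insert",
    "construct_pseudosubtomogram",
    "save_pseudo_set",
    "load_pseudo_set",
]


@dataclass
class CropEntry:
    """One tilt's contribution: the centred complex Fourier crop, its CTF
    array on the same grid, and a visibility flag."""

    fourier: np.ndarray
    ctf: np.ndarray
    visible: bool = True


@dataclass
class Particle2DCrops:
    """Per-tilt 2D Fourier crops of one particle (all the same box)."""

    entries: list
    box: int
    pixel_size: float

    def __post_init__(self):
        for e in self.entries:
            if e.fourier.shape != (self.box, self.box):
                raise ValueError("all crops must share the box size")


@dataclass
class PseudoSubtomogram:
    """The (D, W, M) triplet plus grid metadata.

    ``frame`` is the rotation of the construction frame relative to the
    tomogram (identity by default; pre-oriented construction stores the
    chosen rotation here so priors can be expressed in a meaningful
    frame).
    """

    D: np.ndarray
    W: np.ndarray
    M: np.ndarray
    box: int
    pixel_size: float
    frame: np.ndarray = field(default_factory=lambda: np.eye(3))
    n_inserted: int = 0
    n_skipped: int = 0
    oversample: int = 1  # grid refinement factor relative to the crop box

    def __add__(self, other: "PseudoSubtomogram") -> "PseudoSubtomogram":
        if self.box != other.box:
            raise ValueError("box mismatch")
        return PseudoSubtomogram(
            D=self.D + other.D,
            W=self.W + other.W,
            M=self.M + other.M,
            box=self.box,
            pixel_size=self.pixel_size,
            frame=self.frame,
            n_inserted=self.n_inserted + other.n_inserted,
            n_skipped=self.n_skipped + other.n_skipped,
        )


def extract_crop(
    image: np.ndarray, centre_px: tuple[float, float], box: int
) -> tuple[np.ndarray, bool]:
    """Extract a Fourier crop centred on a (possibly sub-pixel) position.

    The real-space box is taken around the nearest pixel; the residual
    sub-pixel offset is carried as a phase ramp so the particle sits
    exactly at the crop centre ``box // 2``.  Returns (complex Fourier
    crop, visible).  A centre outside the image is flagged invisible.
    Regions extending past the edge are zero-padded.
    """
    if box % 2:
        raise ValueError("box size must be even")
    ny, nx = image.shape
    cx, cy = float(centre_px[0]), float(centre_px[1])
    if not (0 <= cx < nx and 0 <= cy < ny):
        return np.zeros((box, box), dtype=complex), False
    ix, iy = int(round(cx)), int(round(cy))
    dx, dy = cx - ix, cy - iy
    half = box // 2
    crop = np.zeros((box, box), dtype=float)
    x0, x1 = ix - half, ix + half
    y0, y1 = iy - half, iy + half
    sx0, sy0 = max(x0, 0), max(y0, 0)
    sx1, sy1 = min(x1, nx), min(y1, ny)
    if sx0 >= sx1 or sy0 >= sy1:
        return np.zeros((box, box), dtype=complex), False
    crop[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = image[sy0:sy1, sx0:sx1]
    F = ft2(crop)
    if dx != 0.0 or dy != 0.0:
        # shift content by -d so the particle lands exactly on the centre pixel
        F = F * phase_ramp_2d(box, (-dx, -dy))
    return F, True


def forward_insert(
    points: np.ndarray,
    values: np.ndarray,
    ctf: np.ndarray,
    D: np.ndarray,
    W: np.ndarray,
    M: np.ndarray,
) -> tuple[int, int]:
    """Insert 2D Fourier pixels at continuous 3D integer-frequency points.

    Thin wrapper over :func:`pseudotomo.fourier.trilinear_insert`; kept as
    the public seam so the insertion rule (8-neighbour trilinear scatter,
    partition of unity into M) is documented and testable in one place.
    """
    return trilinear_insert(points, values, ctf, D, W, M)


def construct_pseudosubtomogram(
    crops: Particle2DCrops,
    mappings: list[ProjectionMapping],
    frame: np.ndarray | None = None,
    oversample: int = 1,
) -> PseudoSubtomogram:
    """Sum all visible tilts into a fresh (D, W, M) triplet.

    Each mapping's 2D shift is removed from the crop by the conjugate
    phase ramp before insertion, so the triplet is always built for a
    particle centred at the origin of its construction frame.

    ``oversample > 1`` inserts into a finer Fourier grid (cube edge
    ``oversample * box``, same pixel size, real-space box enlarged): the
    trilinear kernel then spans a fraction of a working voxel, which
    suppresses the interpolation attenuation and leakage of forward
    mapping.  Used for final-map reconstruction.
    """
    n = crops.box
    n_out = n * int(oversample)
    visible = [
        (e, m) for e, m in zip(crops.entries, mappings) if e.visible
    ]
    if not visible:
        raise ValueError("no visible tilts: cannot construct a pseudo-subtomogram")
    D = np.zeros((n_out, n_out, n_out), dtype=complex)
    W = np.zeros((n_out, n_out, n_out), dtype=float)
    M = np.zeros((n_out, n_out, n_out), dtype=float)
    hx, hy = freq_grid_2d(n)
    j2 = np.stack([hx.ravel(), hy.ravel()], axis=1)
    n_ins = n_skip = 0
    for entry, mapping in visible:
        pts = oversample * (j2 @ mapping.A)  # A^T j on the (fine) voxel grid
        vals = entry.fourier
        tx, ty = mapping.t
        if tx != 0.0 or ty != 0.0:
            # observed crop carries exp(-2 pi i j.t); remove it
            ramp = np.exp(
                +2j * np.pi * (hx * tx + hy * ty) / (n * crops.pixel_size)
            )
            vals = vals * ramp
        i, s = forward_insert(pts, vals.ravel(), entry.ctf.ravel(), D, W, M)
        n_ins += i
        n_skip += s
    return PseudoSubtomogram(
        D=D,
        W=W,
        M=M,
        box=n_out,
        pixel_size=crops.pixel_size,
        frame=np.eye(3) if frame is None else np.asarray(frame, dtype=float),
        n_inserted=n_ins,
        n_skipped=n_skip,
        oversample=int(oversample),
    )


def save_pseudo_set(pseudos: list, outdir) -> None:
    """Write a pseudo-subtomogram set as MRC triplets (D split into real
    and imaginary volumes, W, M) plus a STAR index table; the round trip
    through :func:`load_pseudo_set` is bit-exact at float32 precision."""
    from pathlib import Path

    import pandas as pd

    from .mrc import VolumeGrid, write_mrc
    from .star import StarDocument, write_star

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, P in enumerate(pseudos):
        names = {
            "ptDataReal": f"particle_{i:05d}_data_real.mrc",
            "ptDataImag": f"particle_{i:05d}_data_imag.mrc",
            "ptWeight": f"particle_{i:05d}_weight.mrc",
            "ptMultiplicity": f"particle_{i:05d}_mult.mrc",
        }
        write_mrc(VolumeGrid(P.D.real, P.pixel_size), outdir / names["ptDataReal"])
        write_mrc(VolumeGrid(P.D.imag, P.pixel_size), outdir / names["ptDataImag"])
        write_mrc(VolumeGrid(P.W, P.pixel_size), outdir / names["ptWeight"])
        write_mrc(VolumeGrid(P.M, P.pixel_size), outdir / names["ptMultiplicity"])
        row = {"ptIndex": i, **names, "ptBox": P.box, "ptPixelSize": P.pixel_size}
        for r in range(3):
            for c in range(3):
                row[f"ptFrame{r}{c}"] = P.frame[r, c]
        rows.append(row)
    doc = StarDocument()
    doc["pseudo_subtomograms"] = pd.DataFrame(rows)
    write_star(doc, outdir / "pseudo_set.star")


def load_pseudo_set(outdir) -> list:
    """Inverse of :func:`save_pseudo_set`."""
    from pathlib import Path

    import numpy as np

    from .mrc import read_mrc
    from .star import read_star

    outdir = Path(outdir)
    doc = read_star(outdir / "pseudo_set.star")
    table = doc["pseudo_subtomograms"]
    out = []
    for _, row in table.iterrows():
        dr = read_mrc(outdir / row["ptDataReal"]).data.astype(float)
        di = read_mrc(outdir / row["ptDataImag"]).data.astype(float)
        W = read_mrc(outdir / row["ptWeight"]).data.astype(float)
        M = read_mrc(outdir / row["ptMultiplicity"]).data.astype(float)
        frame = np.array(
            [[row[f"ptFrame{r}{c}"] for c in range(3)] for r in range(3)], dtype=float
        )
        out.append(
            PseudoSubtomogram(
                D=dr + 1j * di,
                W=W,
                M=M,
                box=int(row["ptBox"]),
                pixel_size=float(row["ptPixelSize"]),
                frame=frame,
            )
        )
    return out
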
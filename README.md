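# pseudotomo

Subtomogram averaging for electron cryo-tomography, built on
*pseudo-subtomograms*: instead of reconstructing 3D subvolumes and
averaging them (with all the missing-wedge headaches that brings), each
particle is represented by three 3D Fourier arrays built directly from
its 2D tilt-series crops —

* **D** — the CTF-premultiplied 2D Fourier pixels, forward-mapped onto
  their tilted central-slice frequencies,
* **W** — the matching sum of squared CTF values,
* **M** — the multiplicity (how often each voxel was observed).

A regularised likelihood on these triplets,

```
-log P(X|phi)  ∝  Σ_k |D_k − W_k V(R k)|² / (M_k σ_k²),
```

approximates the per-pixel likelihood of the underlying 2D tilt images,
so orientation search, expectation–maximisation map refinement
(`V_k = Σ D/σ² / (Σ W/σ² + 1/τ_k²)`, with per-shell noise σ² and signal
τ² re-estimated each iteration) and gold-standard FSC resolution all
work exactly as in single-particle analysis — the missing wedge is just
the region where M = 0. Once an average exists, its signal-to-noise is
exploited to re-estimate the tilt series itself: per-tilt defocus,
astigmatism and Zernike aberrations through condensed single-pass
scoring, per-tilt damage scale factors, rigid tilt re-alignment, and
spatially coherent per-particle 3D motion (Bayesian-polishing style,
with a third dimension). A built-in simulator generates tilt series with
full ground truth, so every estimator is verifiable end to end.

Intended users: structural biologists and methods developers who want a
compact, fully inspectable implementation of 2D-data-model subtomogram
averaging to study, extend or validate against — at desk scale (boxes of
32–64 voxels, hundreds of particles), not production scale.

## Worked example

Simulate a small project, build pseudo-subtomograms, align and
reconstruct:

```bash
pseudotomo simulate --out demo --seed 3 --n-particles 4 --box 32 --noise-sigma 1.0
#   wrote project to demo (4 particles, 41 tilts, SNR 0.393)

pseudotomo make-pseudo --project demo --out demo/pseudo
#   wrote 4 pseudo-subtomograms; sum(M) = 161076.0, inserted pixels = 161076

pseudotomo refine --project demo --out demo/refined --angular-step 10 --prior-sigma 10
#   half-set resolution: 13.61 A

pseudotomo fsc demo/refined/half1.mrc demo/refined/half2.mrc
#   ...
#   resolution at FSC=0.143: 13.61 A
```

The `sum(M)` line is the multiplicity conservation check: every
in-radius 2D Fourier pixel deposits exactly one unit of multiplicity
into the triplet, so the two numbers agree exactly. The refine step
searches orientations on a grid under a Gaussian prior around the
imported poses, polishes them continuously, and reconstructs even/odd
half-maps whose FSC gives the resolution printed. `ctf-refine` and
`frame-align` re-estimate per-tilt defoci and the tilt geometry against
the average; every command writes its fully resolved configuration next
to its outputs, and re-runs are deterministic given the same seed.

The same machinery is available as a library (`pseudotomo.workflow`,
`pseudotomo.benchmarks`) — the CLI is a thin wrapper.

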
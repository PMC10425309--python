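# Methods

`mpitrack` is a synthetic, fully seeded model of an MPI cell-tracking
experiment: SPIO-labeled dendritic cells injected into both hind footpads, a
few percent migrating to each popliteal lymph node (pLN) by day 2, and a
quantification chain that converts reconstructed image signal into iron mass
and cell number. This note records the model, its parameters, the numerical
choices, and what the synthetic study can and cannot show.

## Scene model (phantoms)

A scene is a set of compact iron sources in world coordinates (z, x, y; mm;
Z is the scanner bore axis, isocenter at the origin):

| source | position (z, x, y) | iron |
|---|---|---|
| injection site, left/right | (45, ∓8, 0) | `residual_fraction` (0.8) × dose × per-cell load |
| pLN, left/right | (35, ∓8, 0) | migration fraction × dose × per-cell load |
| GI confounder | (5, 0, 0) | 500 ng, σ = 3 mm |

The 10 mm footpad→pLN separation along Z is the anatomical constant of the
layout; lateral offsets and the GI position are plumbing chosen so the scene
resembles a prone mouse. Per-cell iron loading defaults to 4.4 pg/cell, the
value at which 1,000 cells carry 4.4 ng of iron. Migration fractions default
to independent uniform draws in [0.03, 0.05] per node — the literature range
is a range, not a distribution, so uniform is the least-informative choice.
The day-2 injection sites retain 80% of the dose (non-migrated and apoptotic
cells); this constant controls how hard the whole-animal imaging problem is
and cannot be validated against any measured number.

Sources are isotropic Gaussian blobs, σ = 0.5 mm by default (σ = 0 gives an
ideal point source, used in analytic oracle tests). Every scene carries an
exact ground-truth table; iron = cells × pg/cell × 10⁻³ holds to the last
bit for all cell-bearing labels.

Synthetic lymph-node cryosections for morphometry are elliptical masks in
which exactly `round(fraction × area)` pixels are set positive, so the
area-fraction readout has a closed-form expected value.

## Image formation (forward)

The scanner's tomographic internals (35 projections, drive fields, gradient)
are carried as sequence metadata only; acquisition is modeled directly in
reconstruction space. The point-spread function is radially decreasing,

h(r) ∝ (1 + (2^{2/3} − 1)(2r/w)²)^{−3/2},

with w the full width at half maximum (the shape constant makes the half-max
radius exactly w/2), truncated at r = 3w and normalized to unit integral on
its truncated support. Default w = 2.5 mm on a 0.5 mm voxel grid, consistent
with Momentum-class resolution at a 3.0 T/m selection gradient. Each source
is rendered on a local lattice aligned with the global grid (sub-voxel
positions handled exactly), blob-convolved where σ > 0, renormalized to unit
integral, and scaled by gain × iron (gain 100 a.u./ng). Sources outside the
FOV deposit their in-FOV tails; the whole-image integral of an interior
source equals gain × iron to better than 0.1%.

Two default sequences mirror the experiment: whole-animal `full12`
(12 cm Z × 6 cm X × 6 cm Y, centered at z = 0) and pLN-focused `focused2`
(2 cm Z, centered at z = 32 mm). The focus window is placed just proximal of
the nodes (which sit at z = 35, 7 mm inside the window) so that the
injection site at z = 45 lies beyond the PSF support of the nearest in-FOV
voxel's peak region; centering exactly on the nodes would put near-peak
injection signal on the window boundary and defeat the purpose of focusing.

Acquisition produces two orthogonal line-scan channels on the same lattice:
lines along Z and lines along X. Each measured line loses its own mean (the
DC offset along the transmit axis), so every stored line has exactly zero
mean; the lost offsets are retained on the raw object for testing only.
I.i.d. Gaussian noise is added per channel with

σ = σ_abs + ρ × (peak ideal value in the FOV),

σ_abs = 0.02 a.u., ρ = 0.0072. The peak coupling is the dynamic-range
shadowing mechanism: a FOV containing the injection site (peak ≈ 10³ a.u.)
has a noise floor ~10² times higher than a focused FOV that excludes it. ρ
was calibrated once so that the whole-animal SNR of a pLN crosses the
detectability gate at a migration fraction of ≈ 0.042 — i.e. 3–5% migration
is marginal in the whole-animal scan (both doses scale identically, so the
crossing is dose-independent) — while the focused scan detects the same
nodes at SNR ≈ 25–35 and a 4.4 ng source alone at SNR ≈ 60.

## Baseline recovery (recon)

**Native.** Each Z-line is shifted so the mean of its two edge samples is
zero. This is exact when no signal reaches the FOV edges and over-subtracts
otherwise, yielding the inverted negative artifact; the per-line error is
exactly the true edge mean, which the tests check in closed form.

**Multichannel joint.** Per-line offsets c_z(x, y) and c_x(z, y) are chosen
to minimize Σ[(Z + c_z) − (X + c_x)]², a convex least-squares problem solved
by block-coordinate descent: each sweep sets every offset to the mean
disagreement with the other channel. Because the design is balanced, the
first full sweep already reaches the exact minimizer (the classic two-way
additive fit); iteration continues only until the relative objective change
falls below `tol` (10⁻⁶), with the per-iteration objective logged and a
non-convergence warning flag rather than an exception. The dense
normal-equations solution on small grids agrees with the iterate's objective
to 10⁻⁶ relative.

Offsets are identifiable only up to one additive constant per Y slab — the
objective couples lines within a slab (both line families traverse it) but
never across slabs, since no line runs along Y. The gauge is therefore fixed
per slab by anchoring a percentile of the slab's values to zero. The default
anchor is the median: in a sparse-signal image the slab median is the
background level, and anchoring it costs no bias. (Anchoring a low
percentile of the noise distribution instead shifts every voxel up by
~2.3σ; that bias cancels through the calibration line only when the scene's
noise scales with the quantified source, which fails exactly in the cohort's
focused scans, where the noise floor is set by the injection-site edge
tail.) The anchor requires sources to occupy less than half of every Y slab;
the default geometries satisfy this with a wide margin, and the assumption
is stated on the settings object.

The final image is an inverse-combiner blend: each channel is linearly
down-weighted within a margin (2 voxels) of its own transmit-axis edges,
where its baseline information is weakest, and the weighted average is
optionally clipped at zero (on by default for the joint method).

## Quantification (quantify)

The chain follows standard MPI ROI practice, in this order:

1. **Segment**: greedy 26-neighborhood hill-climb from the seed voxel to a
   local peak; threshold at 0.5 × peak value; keep the 6-connected component
   containing the peak. Empty if the peak is non-positive.
2. **Measure**: total signal = ROI volume × mean (algebraically the voxel
   sum × voxel volume; asserted as an identity on random masks);
   SNR = ROI mean / SD of a source-free background box (default: the FOV
   corner farthest from all seeds; sample SD, ddof = 1).
3. **Gate**: detectable ⇔ SNR strictly > 5 (a flag flips to ≥ if desired).
   No iron or cell value is ever reported for a gated-out ROI.
4. **Calibrate**: ordinary least squares of total ROI signal on known iron
   over a 6-point series (0.5–8.8 µg, bracketing the 10⁶-cell pellet),
   simulated, reconstructed and segmented exactly like unknowns, under the
   same imaging sequence; a sequence-id mismatch between line and image is
   an error.
5. **Convert**: iron = total / slope (the intercept is ignored by default; a
   use-intercept mode exists), cells = iron × 10³ / (pg per cell), with the
   per-cell loading measured from a simulated pellet of known cell number
   through the same chain.

Because half-max segmentation captures a geometry-dependent fraction of a
source's total signal (≈ its core above half maximum), the chain is accurate
only when unknowns share the calibration sources' geometry; with the default
0.5 mm blobs the round trip is exact to ≪1% noise-free, while an ideal point
source would read ~16% low against a blob calibration. Negative voxels
(native-reconstruction artifact) enter ROI means as-is — this is what makes
whole-animal quantification fail realistically.

## Cohort pipeline (cohort)

Per mouse: one day-2 scene (fractions drawn per node), acquired and
reconstructed as `full12`+native and `focused2`+joint; each excised node is
additionally scanned alone, centered in a clean full FOV (`exvivo`+native) —
excision removes the shadowing sources, so the noise floor couples to the
node's own small peak. Each mode is quantified with its own calibration
line. A day-0 whole-body scan (full dose at the footpads) is simulated and
reported descriptively in a separate table.

A row's `detectable` flag requires both the SNR gate and *separability*: an
ROI whose mask reaches within 5 mm of an injection site or the GI source has
merged with it and is excluded from quantification, as a human analyst
excludes node signal that cannot be separated from the adjacent injection
site. Without this, a noise-bridged whole-animal ROI can swallow the
injection site, pass the SNR gate, and report a six-order-of-magnitude cell
overcount. The pure SNR verdict (`snr_pass`) and `separable` are kept as
separate columns.

All randomness descends from one master seed through spawned substreams
(fraction draws, calibration scans, per-mode acquisitions), so a cohort
table is bit-for-bit reproducible.

## Problem sizes and runtime

Default grids are 240×120×120 (full) and 40×120×120 (focused) voxels at
0.5 mm. A six-mouse cohort with both calibrations runs in ~15 s on one CPU;
the 20-seed detection-limit experiment in ~15 s; the full test suite in
~80 s. Unit tests use 24³-voxel configurations at 1 mm.

## What the synthetic study shows, and what it does not

Passing tests establish that the *pipeline* is correct and internally
consistent under the stated model: linear iron-to-signal physics, exact
per-line DC loss, Gaussian noise with a peak-coupled floor, and compact
Gaussian sources. They reproduce the structure of the experimental findings
— whole-animal scans lose marginal nodes to shadowing and ROI merging while
the focused scan with joint reconstruction quantifies all of them, in
agreement with ex-vivo scans — and the self-contained anchors (1,000 cells ↔
4.4 ng at 4.4 pg/cell; recovered migration < 5% of dose).

They do not validate the model against real scanners or animals: there is no
Langevin magnetization physics, no projection tomography, no anisotropic
resolution, no biological variability beyond the migration draw, no cell
death or label transfer, and the vendor's actual joint reconstruction and
inverse combiner are proprietary — the estimator here matches their
described failure mode and recovery mechanism, not their implementation.
Animal-cohort quantities that depend on real biology (specific detection
percentages of a six-mouse experiment, regression R² against ex-vivo
measurements) are reproduced qualitatively, not as numerical targets.

## Known limitations

- The gauge anchor assumes every Y slab is mostly background; scenes whose
  sources fill a slab need a different anchor (or a wider FOV).
- Whole-animal estimates near the SNR gate scatter ±12% and run ~15% low on
  average (threshold segmentation is noise-limited at the gate); focused and
  ex-vivo estimates are accurate to a few percent.
- The 5 mm merge radius and the 6 mm background box are analysis constants;
  pathological layouts (sources near FOV corners, nodes closer than ~8 mm to
  a confounder) would require adjusting them.
- The truncated PSF makes sources farther than 3×FWHM contribute exactly
  nothing — adequate for compact sources, but it sharpens the distinction
  between "in" and "out" of the focused window compared with a real scanner.
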
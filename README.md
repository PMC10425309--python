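# mpitrack

Synthetic magnetic particle imaging (MPI) pipeline for quantifying the in-vivo
migration of iron-oxide-labeled cells.

## The problem

In dendritic-cell (DC) immunotherapy, cells labeled with superparamagnetic
iron oxide (SPIO) are injected into the hind footpads of a mouse; only a few
percent migrate to the draining popliteal lymph node (pLN), and counting them
noninvasively is the readout that predicts therapeutic potency. MPI is suited
to the task because its signal is directly proportional to iron mass — but a
whole-animal field of view (FOV) suffers from limited dynamic range: the
bright injection site raises the noise floor under the faint pLN signal
("shadowing"), and a small FOV that excludes the injection site breaks the
zero-signal-at-the-edge assumption of native image reconstruction, producing
an inverted negative artifact.

`mpitrack` reproduces this whole measurement problem at desk scale, with
known ground truth at every step:

- **phantoms** — scenes of iron sources (footpad injection sites, pLN carrying
  3–5% of the dose, a gastrointestinal confounder), calibration series,
  cell pellets, and synthetic lymph-node sections for morphometry.
- **forward** — image formation: an isotropic Lorentzian-like PSF, gain
  proportional to iron, two orthogonal line-scan channels that each lose the
  DC offset of every line along their transmit axis, and a noise floor coupled
  to the brightest in-FOV voxel (the shadowing mechanism).
- **recon** — per-line baseline recovery: the *native* zero-edge method
  (exact for interior scenes, negative artifact for edge signal) and the
  *multichannel joint* method, which estimates all line offsets by minimizing
  the disagreement between the two channels and blends them with an inverse
  combiner that down-weights each channel near its own transmit edges.
- **quantify** — the analysis chain: seeded half-max segmentation, total ROI
  signal = volume × mean, SNR = ROI mean / background SD with a strict
  SNR > 5 detectability gate, signal→iron via the slope of a calibration line
  fitted under the same imaging sequence, iron→cells via a per-cell loading
  measured from a pellet of known cell number (default 4.4 pg/cell).
- **cohort** — the full experiment: six mice at doses of 3×10⁵ and 5×10⁵
  cells, day-2 scans with a 12-cm whole-animal FOV (native reconstruction)
  and a 2-cm pLN-focused FOV (joint reconstruction), ex-vivo scans of each
  excised node, detection rates, and in-vivo vs ex-vivo regression.

## Worked example

```python
from mpitrack import run_cohort, detection_rate, regress_invivo_exvivo

cohort = run_cohort(6, [3e5, 5e5], master_seed=7, include_day0=False)
for mode in ("full12", "focused2", "exvivo"):
    print(f"{mode:9s} detection rate: {detection_rate(cohort, mode):.2f}")
slope, intercept, r2 = regress_invivo_exvivo(cohort, "focused2")
print(f"focused vs ex vivo: slope={slope:.3f}, r2={r2:.3f}")
```

prints

```
full12    detection rate: 0.42
focused2  detection rate: 1.00
exvivo    detection rate: 1.00
focused vs ex vivo: slope=0.996, r2=0.998
```

Every pLN passes the SNR gate under the focused scan, while the whole-animal
scan quantifies only a fraction of them — the nodes it misses either fall
below the shadowing-raised noise floor or grow ROIs that cannot be separated
from the injection-site signal. Detectable focused-FOV estimates track the
ex-vivo ground-truth scans to within a few percent (slope ≈ 1), and every
recovered migrated fraction stays below the 5% biological ceiling (maximum
0.047 in this cohort).

The detection-limit experiment pushes a single 4.4 ng node-like source — the
iron content of 1,000 labeled cells — through the complete chain (calibration
line, pellet-measured per-cell iron, acquisition, joint reconstruction,
SNR-gated quantification):

```python
from mpitrack import detection_limit_experiment
print(detection_limit_experiment(n_seeds=5, base_seed=0).round(1))
# [ 999.5 1002.5 1002.6 1003.3 1018.5]
```

## Command line

The same pipeline is scriptable from a shell:

```sh
mpitrack scene --dose 300000 --out scene.json
mpitrack simulate --scene scene.json --fov focused --seed 3 --out raw.npz
mpitrack reconstruct --method joint --in raw.npz --out img.nii.gz
mpitrack quantify --image img.nii.gz --seed-voxel 26,44,60 \
    --calibration cal.csv --out quant.csv
mpitrack cohort --mice 6 --doses 300000,500000 --seed 7 --out results/ --report
```

Volumes are written as NIfTI, raw scans as compressed `.npz` archives, scenes
as JSON, and tables as CSV.

## Documentation

`docs/methods.md` describes the forward model, the reconstruction estimators,
the noise calibration, and the known limitations of the synthetic study.
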
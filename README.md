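# valvemorph

Hemodynamics and tissue-convergence analysis of the embryonic heart tube at
the onset of valve formation.

At early stages the zebrafish heart is a valveless pump: two chambers
(atrium, ventricle) joined by a narrowed atrioventricular canal (AVC)
drive, by phase-lagged wall contractions alone, a flow that is
unidirectional on average but strongly oscillatory — at times reversing
through the AVC.  Endocardial cells lining the AVC converge toward it
during valve formation, and the mechanical cue for that convergence is
carried by the *pattern* of wall shear stress rather than by the mean flow
direction.  This package provides the full computational chain needed to
study that question on synthetic data:

* **Flow model** — a 2D boundary-integral (regularized Stokeslet) solver
  for the moving-wall channel at zero Reynolds number, fully coupled to
  deformable red blood cells modeled as closed elastic curves
  (`stokes_solver`, `wall_kinematics`, `rbc_membrane`, `heart_simulator`).
* **Shear-stress decomposition** — the wall shear stress τ(t) at every wall
  station is split into its time average τ₀, the harmonic amplitudes
  τ₁, τ₂, … of its phase average (Fourier analysis at multiples of the beat
  frequency f₁), and the nonperiodic residual τ′ = RMS deviation from the
  periodic component, which is driven by the chaotic cell dynamics and
  vanishes without cells (`shear_decomposition`).
* **Tissue convergence** — two-timepoint, two-channel 3D stacks of a
  photolabeled tube are unfolded onto (arc length × azimuth) coordinates;
  the length L of the unlabeled gap between two photoconverted bands is
  measured per azimuth, and the shortening factor (L₂ − L₁)/L₁ is averaged
  over anatomical quadrants and compared between groups with Student's
  t-test (`avc_unfold`, `group_stats`).
* **Synthetic data** — image phantoms with exact ground-truth shortening
  and shear-stress-like signals with prescribed spectral content make every
  stage testable without downloads (`synthetic_data`).
* **Pipeline** — one YAML config, one root seed, a checksummed run manifest
  (`pipeline`, CLI `valvemorph`).

## Worked example

Simulate the default two-chamber pump without cells, decompose the wall
shear stress, and print the directional summary:

```python
import numpy as np
from valvemorph.heart_simulator import SimulationConfig, run
from valvemorph.shear_decomposition import spatial_profiles
from valvemorph.pipeline import report_directions

cfg = SimulationConfig(n_rbc=0, n_wall=128, steps_per_beat=100,
                       samples_per_beat=50, n_beats=8, discard_beats=2)
wss, traj, flux = run(cfg)
dec = spatial_profiles(wss, n_harmonics=3, bins=50)

up = dec.side_mask("upper")
x = dec.station_x[up]
print("tau1 peak at x =", x[np.argmax(dec.amplitudes[up, 0])])
print("mean AVC flux  =", flux.flux[:, 1].mean())
print(report_directions(dec, cfg.geometry, flux.flux[:, 1].mean()))
```

prints (abridged):

```
tau1 peak at x = 4.84375
mean AVC flux  = 0.0969
{'side': 'upper', 'tau0_sign_atrial_flank': -1,
 'tau0_sign_ventricular_flank': 1, 'grad_tau1_sign_atrial_flank': 1,
 'grad_tau1_sign_ventricular_flank': -1, 'mean_flux_sign': 1,
 'tau0_points_away_from_avc': True, 'grad_tau1_points_toward_avc': True,
 'mean_flow_unidirectional': True}
```

The AVC spans x ∈ [4.6, 5.6] in this geometry, so the fundamental
harmonic τ₁ peaks *inside* the canal; the mean flux is positive
(atrium → ventricle) even though the AVC flow reverses within each beat;
and the time-averaged stress τ₀ points *away* from the AVC on both flanks
while the gradient of τ₁ points *toward* it — the signature dissociation
between the shear-stress pattern and the mean flow direction that makes
the pattern, not the flow direction, the candidate cue for tissue
convergence.

The imaging side, end to end on a phantom with ground-truth shortening
−0.30:

```python
import numpy as np
from valvemorph.synthetic_data import PhantomSpec, make_phantom
from valvemorph.avc_unfold import fit_centerline, unfold, measure_L, shortening

spec = PhantomSpec()                      # gap 40 um -> 28 um
imgs = {tp: make_phantom(spec, tp)[0] for tp in (1, 2)}
seeds = np.array(spec.control_points)
L = {}
for tp, img in imgs.items():
    cl = fit_centerline(img, seeds, spec.voxel_spacing)
    L[tp] = measure_L(unfold(img, cl, spec.voxel_spacing, n_s=120, n_theta=24))
res = shortening(L[1], L[2])
print({k: round(v, 3) for k, v in res.quadrant_means.items()})
```

```
{'superior': -0.278, 'exterior': -0.298, 'inferior': -0.294, 'interior': -0.294}
```

Every quadrant recovers the true −0.30 to within ±0.03.

## Command line

```sh
valvemorph synth phantom --config phantom.yaml --out phantom/
valvemorph synth signal  --config signal.yaml  --out signal.csv
valvemorph simulate --config sim.yaml --out run/ --n-rbc 10 --seed 1
valvemorph decompose --in run/tau_series.csv --period 1.0 --harmonics 3 --out dec.csv
valvemorph unfold --t1 t1.tif --t2 t2.tif --seeds seeds.csv --config unfold.yaml --out out/
valvemorph stats --in table.csv --groups control,sih --out stats.csv
valvemorph run --config pipeline.yaml
```

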
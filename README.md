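# minicirc

Tools for studying sequence-dependent poloidal orientation in DNA
minicircles:

- **geometry** — build ideal three-site-per-nucleotide (sugar/phosphate/base)
  linear duplexes from six helical trajectories, quantize the twist to an
  integer number of turns, bend them into planar uniformly twisted
  minicircles, and close the bonded topology with the junction term set
  (6 bonds, 6 angles, 16 dihedrals).
- **poloidal** — compute the global-morphology poloidal angle of a closed
  duplex per frame (four-phosphate reference frame, 10-bp segment centroid
  origin, atan2 polar angle), signed horizontal displacement (positive =
  inside the circle), and circular statistics (resultant-vector mean,
  std = √(−2 ln R̄)).
- **afm** — flatten height images, segment particles above a threshold,
  classify DNA / protein / complex / aggregate by area and mean intensity,
  and compute the centroid-to-center-of-mass offset δ and the relative
  affinity α = N_DP/(N_D·N_P).
- **phase_fit** — weighted least-squares sinusoid fits with a fixed period
  (default 10.5 bp per helical turn), peak positions, inter-series lags, and
  lag→degree conversion.
- **synthetic** — generators with known ground truth: minicircle trajectories
  whose poloidal angle follows a prescribed von Mises law, AFM-like scenes of
  rings/spots/ring+marker complexes, and noisy sinusoidal δ-vs-position
  series.
- **io / workflow / cli** — LAMMPS-dialect data and dump text files (with a
  JSON sidecar type map), series CSVs, YAML-configured end-to-end workflows
  with reproducible JSON reports.

## Command line

```sh
# build a 105-bp minicircle data file (sequence literal, plain text or FASTA)
minicirc build AAAA...A --out circle.data

# synthetic data
minicirc simulate traj --n-bp 105 --frames 200 --mu 189 --kappa 10 --seed 1 --out traj.dump
minicirc simulate scene --rings 5 --spots 3 --complexes 2 --seed 1 --out scene.txt --truth truth.csv
minicirc simulate series --peak 1.3 --noise-sd 0.3 --seed 1 --out a.csv

# analysis
minicirc analyze-traj traj.dump --ref-bp 0 --out angles.csv
minicirc analyze-afm scene.txt --pixel-size 1.0 --threshold 1.0 --out blobs.csv
minicirc fit-phase --series a.csv --series b.csv --period 10.5 --out lag.json

# full workflow from a YAML config
minicirc run config.yaml
```

Example workflow config:

```yaml
workflow: series
seed: 1
series:
  period: 10.5
  synthetic:
    - {peak: 1.3, noise_sd: 0.0}
    - {peak: 6.8, noise_sd: 0.0}
```

## Notes

- Coordinates are in nm; user-facing angles in degrees (radians internally).
- `circularize` defaults to the seamless uniform-toroidal-angle bend
  (`angle_mode="centerline"`, t = z/R); `angle_mode="per-atom"` (t = z/y)
  preserves each atom's own arc length instead but leaves a junction gap for
  off-centerline atoms.
- A single reference base pair tracks helix-phase rotations only up to a
  small geometric wobble of the frame construction;
  `poloidal.recover_phase_shift` averages over all references and recovers
  applied rotations to below 1e-6 degrees on ideal circles.
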
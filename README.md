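# torusalign

Single-particle averaging and metrology for **toroidal structures in 3D
fluorescence z-stacks**, with acceptor-photobleaching FRET quantification.

Ring-shaped protein assemblies near the resolution limit — the membrane
anchoring ring of the yeast spindle pole body imaged by structured
illumination microscopy (SIM) is the motivating case — appear in any single
volume as a tilted, often incomplete circle of diffraction-blurred spots.
`torusalign` fits an explicit tilted-ring model to each particle, realigns
and averages many particles, and reads ring diameters (with Monte Carlo error
bars) off the averaged map.  A built-in scene simulator provides ground truth
for every stage, and a separate module quantifies relative FRET efficiency
from paired pre-/post-acceptor-bleach images.

## The model

A ring of radius $r$ centered at $(x_c, y_c, z_c)$, tilted from the image
plane by $\theta$ and rotated about the optical axis by $\phi$, is traced by
the travel angle $\rho$:

$$
\begin{aligned}
x(\rho) &= x_c - r\cos\rho\,\sin\phi + r\sin\rho\,\cos\theta\,\cos\phi,\\
y(\rho) &= y_c + r\cos\rho\,\cos\phi + r\sin\rho\,\cos\theta\,\sin\phi,\\
z(\rho) &= z_c - r\sin\rho\,\sin\theta.
\end{aligned}
$$

Four vertical cross sections through a user-seeded center (strips at 0°,
45°, 90° and 135°, each averaged over a 2-pixel width) intersect the ring in
eight spots.  The $\rho$ values at which the ring pierces each section plane
($x=0$, $y=0$, $x=y$, $x=-y$ relative to the guess) reduce to harmonic
equations $A\sin\rho + B\cos\rho + C = 0$ solved in closed form.  The eight
spots are then fit **globally** as asymmetric 2D Gaussians whose centers are
functions of the pose — not free parameters — with linked widths (one
lateral, one axial), per-section baselines, amplitude pairs constrained
within a factor of two, the center bounded near its initialisation, the
radius within 2× of its initial estimate, the z center within one slice, and
$\theta < 45°$.  Because $\phi$ is ill-determined for nearly flat rings it is
scanned on a 10° grid with a bounded least-squares fit at each value.

Fitted particles are rigidly rotated ($-\phi$ about z, then $-\theta$ about
the in-plane axis) so the ring lies flat at the center of a fresh canvas,
optionally rotated in-plane (randomly, or so a secondary-channel lobe points
up), brightness-normalised, and averaged.  Diameters come from two-Gaussian
fits to the vertical and horizontal line profiles of the average; errors are
the SD of a residual-calibrated parametric bootstrap, and conditions are
compared with a two-tailed t-test on the bootstrap distributions.

## Worked example

```python
import numpy as np
from torusalign import (SceneSpec, simulate_toroid_volume, TiltedRingModel,
                        ParticleSeed, flatten_transform, average_particles,
                        diameter_from_average, monte_carlo_error, ring_point)

# a 160 nm toroid, tilted 20 deg, imaged with an anisotropic PSF
spec = SceneSpec(diameter_nm=160.0, theta_deg=20.0, phi_deg=60.0, seed=1)
vol, truth = simulate_toroid_volume(spec)

# four clicked points near the 0/90/180/270-degree crossings
rng = np.random.default_rng(0)
pts = ring_point(truth.pose, np.array([0, np.pi/2, np.pi, 3*np.pi/2]))[:, :2]
pts += rng.uniform(-2, 2, pts.shape)

result = TiltedRingModel.from_volume(vol, ParticleSeed("spb-01", "Ndc1", pts)).fit()
print(result.summary())
```

```
Tilted-ring fit results
======================================================
center (x, y) [px]             (   74.00,    73.99)
center z [slice]                  27.02
radius [px]                       39.92
diameter [nm]                     159.7
tilt theta [deg]                  19.92
rotation phi [deg]                 60.0
sigma lateral [px]                 2.05
sigma z [slices]                   5.96
residual rms                      1.629
active constraints             none
```

The simulated ring (radius 40 px = 80 nm, tilt 20°, azimuth 60°) is
recovered to 0.08 px, 0.1° and the exact azimuth grid value; the fitted spot
widths report the PSF (2 px lateral, 6 slices axial).  Continuing through the
averaging and metrology stages:

```python
aligned = [flatten_transform(vol, result.pose, canvas_shape=(41, 201, 201))]
avg = average_particles(aligned)
est = monte_carlo_error(diameter_from_average(avg), n_reps=200, seed=2)
print(est.summary())
```

```
Ring diameter estimate
========================================
diameter: 159.7 +/- 0.0 nm (mean of vertical and horizontal)
  vertical: 159.8 +/- 0.0 nm
  horizontal: 159.6 +/- 0.0 nm
Monte Carlo replicates: 200 (errors are the SD of the replicate diameters)
```

The same stages are exposed on the command line:

```bash
torusalign simulate --preset diploid-ndc1 --seed 3 --out scene.ome.tif --truth truth.json
torusalign fit --stack scene.ome.tif --channel sim --seeds seeds.csv --out fits.json
torusalign align --stack scene.ome.tif --channel sim --fits fits.json --out aligned/
torusalign average --aligned aligned/ --rotate random --seed 7 --out avg.ome.tif
torusalign diameter --avg avg.ome.tif --reps 200 --seed 11 --out diam.json
torusalign fret --pre pre.tif --post post.tif \
    --control-pre c1.tif --control-post c2.tif --out fret.json
```

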
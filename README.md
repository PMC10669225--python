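# artikin — personalized virtual dental articulator

`artikin` is a Python library and CLI for building a **virtual dental
articulator** that is personalized to an individual patient. A dental
articulator reproduces the motion of the mandible relative to the maxilla
so that clinicians can analyse occlusion and design restorations.
Mechanical articulators need a facebow transfer and offer only a few fixed
guidance settings; `artikin` instead derives everything from data a modern
clinic already collects:

* **CT landmarks** (two condyle centers, an anterior reference point)
  define the articulator coordinate frame — a *virtual facebow*. The hinge
  axis through the condyles becomes X, the Frankfurt or Camper reference
  plane becomes z = 0.
* **Optically tracked jaw motion** (dual-marker pose streams) yields the
  trajectories of the condyles and the incisal edge; the condylar paths are
  fitted per side into a *personalized condylar guidance* that replaces the
  fixed mechanism of a mechanical articulator.
* A **6-DOF inverse-kinematics model** then drives the mandible from an
  incisal guidance path alone, with sphere-proxy collision handling for
  dynamic occlusion playback, and verification metrics (average trajectory
  error and discrete Fréchet distance) to quantify how well simulation
  matches tracking.

## The model

The mandibular pose about the working-side condyle is
`(θx, θy, θz, tx, ty, tz)` with rotation `R = Rz(θz)·Ry(θy)·Rx(θx)`
applied about the condyle's rest position `(x0, y0, z0)`. Given a measured
incisal target `Q`, six constraints determine the pose:

1–3. the posed incisal point equals `Q`;

4–5. the condyle translation follows the personalized path,
  `tx = f(y0 + ty) − x0` and `tz = g(y0 + ty) − z0`, where `x = f(y)` is
  the horizontal-plane line fit of the working-side lateral path (its slope
  angle is the **Bennett angle**) and `z = g(y)` is the sagittal-plane
  quadratic fit of the protrusive path (its slope at rest is the
  **condylar inclination**);

6. the roll angle satisfies `θy = atan((zL′ − zR′)/(xL′ − xR′))`, the
  height difference of the posed condyles.

The square system is solved per sample by damped Newton–Raphson with a
finite-difference Jacobian. The fitted 3D path is also exported as a
clamped cubic NURBS curve
`C(u) = Σ N_{j,p}(u) w_j P_j / Σ N_{j,p}(u) w_j` for visualization and
interchange.

Because patient CT and tracking recordings are not redistributable, the
package ships a first-class **synthetic patient** module: seeded virtual
patients with known articulator parameters, forward-simulated border
movements, synthetic dual-marker camera streams (with optional camera
wobble, which the relative-marker chain must cancel), condyle surface
patches for sphere fitting and face-like clouds for ICP — so the entire
pipeline is testable end to end against ground truth.

## Worked example

```python
from artikin import (generate_patient, simulate_movement, fit_condylar_path,
                     trajectory_ik, discrete_frechet)

patient = generate_patient(seed=7)            # ground truth: Bennett 18.46°, inclination 44.39°

# "track" a protrusion and a right lateral excursion at 0.1 mm noise
prot = simulate_movement(patient, "protrusion",      n_samples=100, cycles=1, noise_sigma=0.1)
lat  = simulate_movement(patient, "right_excursion", n_samples=100, cycles=1, noise_sigma=0.1)

# personalize the right condylar path from the tracked condyle
path_r = fit_condylar_path(prot.condyle_right, lat.condyle_right, "right", rest_y=0.0)
print(f"Bennett angle:        {path_r.bennett_angle:.2f} deg")
print(f"Condylar inclination: {path_r.inclination_angle:.2f} deg")

# drive the mandible from the incisal trajectory alone and compare condyles
lat_l = simulate_movement(patient, "left_excursion", n_samples=100, cycles=1, noise_sigma=0.1)
path_l = fit_condylar_path(prot.condyle_left, lat_l.condyle_left, "left", rest_y=0.0)
sim_r, sim_l, _ = trajectory_ik(prot.incisal, patient.landmarks, path_r, path_l, "right")
print(f"Frechet right condyle: {discrete_frechet(prot.condyle_right, sim_r):.3f} mm")
print(f"Frechet left condyle:  {discrete_frechet(prot.condyle_left, sim_l):.3f} mm")
```

Output:

```
Bennett angle:        17.43 deg
Condylar inclination: 45.28 deg
Frechet right condyle: 0.386 mm
Frechet left condyle:  0.474 mm
```

The fitted guidance angles recover the patient's ground truth to about a
degree at this noise level, and the inverse-kinematics reconstruction of
the condylar trajectories from the incisal path alone agrees with the
"tracked" condyles to a few tenths of a millimetre (exactly, at zero
noise).

The same pipeline is available from the shell:

```bash
artikin synth --seed 7 --movement protrusion --sigma 0.1 --out run/prot
artikin fit-path --protrusion run/prot/condyle_right.csv \
                 --lateral run/lat/condyle_right.csv --side right --out path_right.json
artikin ik --incisal run/prot/incisal.csv --landmarks run/prot/landmarks.json \
           --path-right path_right.json --path-left path_left.json --side right --out sim
artikin compare --tracked tracked/ --simulated simulated/ --out report.csv
```

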
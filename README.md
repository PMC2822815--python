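# cardioflow

Quantitative cardiovascular MR image analysis in Python: sub-pixel
contour and ROI quantification, velocity-encoded phase-contrast (PC)
flow with eddy-current background correction and temporal phase
unwrapping, ventricular volumetry with AHA 17-segment polar maps — all
driven by synthetic phantoms with exact ground truth, so every stage of
the pipeline is testable without clinical data.

It is aimed at researchers who analyse cine and phase-contrast MR and
want validated, scriptable building blocks rather than a GUI: load a
DICOM series, draw (or generate) contours, and get flow curves, volumes
and regional wall measures as CSV/JSON.

## What it computes

**Flow.** A phase image with intensities scaled to [0, 1] maps to
through-plane velocity as *v = (2p − 1)·VENC*. The pipeline corrects
spatially smooth, temporally static eddy-current/Maxwell phase offsets
by fitting a 2D polynomial surface (order 1–3) to the time-mean velocity
over automatically detected stationary tissue (temporal SD of the
velocity below a threshold, with a magnitude floor to reject air, and
the quantified vessel ROIs excluded). Velocities aliased beyond ±VENC
are restored by temporal unwrapping: frame-to-frame jumps with
|Δv| > VENC mark wrap events, and an opposite-signed pair brackets an
interval across which 2·VENC is added back. Vessel contours are
propagated over the cycle by re-centering on the intensity-weighted
centroid and snapping 64 radial rays to the strongest image gradient
within ±30 % of the previous radius. Flow is then

> Q(t) = Σ_pixels v_i(t) · A_pixel,  V_net = Σ_t Q(t)·Δt,

with pixels included when their center lies inside the sub-pixel
polygon, and the per-beat volume split into positive and negative parts.

**ROI quantification.** Areas are exact shoelace polygon areas at double
precision; intensity statistics are computed over the discrete pixels
inside the ROI. The sampling error of pixel counting versus the true
polygon area is quantified for circular ROIs as a function of pixel
size. Time curves support full-width-at-half-maximum, extrema and
temporal derivatives, with optional Gaussian smoothing implemented as
normalized averaging so signal endpoints are not attenuated.

**Volumetry.** Slice-summation (Simpson) volumes from short-axis endo-
and epicardial contours, LV mass as 1.05 g/ml times the epi−endo shell,
radial wall thickness/thickening per angular sector, and pooling of
regional values into the standard AHA 17-segment bullseye (6 basal, 6
mid, 4 apical segments plus the apex).

## Worked example

Generate a pulsatile two-channel flow phantom (26 mm channels, 100
ml/beat) corrupted with a linear background offset *and* aliasing (peak
velocity 1.5×VENC), then run the full correction pipeline:

```python
import numpy as np
from cardioflow import *

cfg = FlowPhantomConfig(background_offset=(1.2, 0.05, -0.02),
                        wrap_inducing=True, pulsatility=0.5, venc_cm_s=50.0)
mag, phase, truth = gen_flow_phantom(cfg, rate_ml=100.0)

v = phase_to_velocity(phase)
mask = detect_stationary(v, magnitude=mag, exclude_contours=truth.contours)
surf = fit_background(v, mask, order=1)
v = correct_background(v, surf)
v = unwrap_temporal(v)
res = compute_flow(v, truth.contours[0])
print(f"fitted offset plane: {dict(zip(surf.exponents, np.round(surf.coefficients, 6)))}")
print(f"net volume: {res.net_volume_ml:.2f} ml/beat (true 100.00)")
```

Output:

```
fitted offset plane: {(0, 0): np.float64(1.2), (0, 1): np.float64(-0.02), (1, 0): np.float64(0.05)}
net volume: 99.94 ml/beat (true 100.00)
```

The fitted surface recovers the injected offset (1.2 cm/s constant,
0.05 cm/s/px in x, −0.02 cm/s/px in y) exactly, and the measured
per-beat volume is within 0.06 % of truth — the residual is the pixel
discretization of the Poiseuille profile at 1 mm resolution.

The same pipeline is available from the shell:

```sh
cardioflow phantom flow --rate 60 --out phantom/
cardioflow flow --dicom phantom/ --venc 200 --roi phantom/roi.json --out results/
cardioflow samperr --pixel-sizes 1,0.5,0.25 --n 5000 --seed 1 --out fig6.csv
```

## Layout

- `src/cardioflow/stack.py` — image stack container and geometry
- `src/cardioflow/geometry.py` — contours, areas, rasterization, resampling, MPR
- `src/cardioflow/roi_stats.py` — ROI statistics, curve features, sampling error
- `src/cardioflow/flow_quant.py` — PC-MRI flow pipeline
- `src/cardioflow/cardiac_metrics.py` — volumes, mass, wall measures, polar maps
- `src/cardioflow/phantom_synth.py` — synthetic phantoms and DICOM fixtures
- `src/cardioflow/io_formats.py` — DICOM loading, `.sgx` exam archive, CSV
- `src/cardioflow/cli.py` — the `cardioflow` command
- `docs/methods.md` — models, parameters, numerical choices, limitations
- `docs/format.md` — the `.sgx` archive format
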
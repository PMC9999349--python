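# macnet

Quantitative image analysis for **membrane-bound actin networks**
(minimal actin cortices): reconstituted F-actin attached to a supported
lipid bilayer via a linker protein such as ezrin, imaged by fluorescence
microscopy, and optionally set in motion by myosin II motors.

The package turns micrographs and time series into the standard
observables of this system:

- **Tube-filter skeletonization** (`macnet.tubefilter`) — CLAHE +
  Gaussian preprocessing, ridge enhancement by the second eigenvalue
  λ₂(x, y) of the per-pixel intensity Hessian H_I(x, y), adaptive
  local-mean thresholding, and topology-preserving thinning to a 1-px
  skeleton.
- **Network architecture** (`macnet.netmetrics`) — skeleton network
  density (filamentous pixels / all pixels), node density (skeleton
  pixels with more than two foreground 8-neighbors, merged into
  intersections, per µm²), and the relative bundling factor (mean actin
  intensity at skeleton pixels, normalized to a low-bundling reference
  condition).
- **Nematic order** (`macnet.nematic`) — per-window orientation from the
  structure tensor and the local order parameter
  *q* = 2⟨cos²θ − 1/2⟩ over a 5×5 kernel of adjacent windows, with
  θ the alignment difference to the local director; *q* = 1 for perfect
  alignment, *q* = 0 at maximal disorder; plus the window-size sweep
  used to choose the analysis window (1–2 µm).
- **Contractility** (`macnet.dynamics`) — drift registration,
  frame-to-frame and actin/myosin cross-channel 2D correlation traces,
  an in-repo PIV implementation (windowed cross-correlation, sub-pixel
  Gaussian peak fit, coarse-to-fine passes, normalized-median vector
  validation) at a 10 s lag, velocity-magnitude distributions, and a
  three-way classification of each experiment as contracting, partially
  contracting, or noncontracting.
- **Interface physics** (`macnet.layerphys`) — RIfS optical-thickness
  conversion d = ΔOT / n_prot (n_prot = 1.455) and binding-step
  quantification; FRAP diffusion coefficient and immobile fraction from
  the closed-form uniform-disc 2D diffusion recovery model.
- **Synthetic data** (`macnet.synthgen`) — a ground-truthed generator of
  filament-network micrographs (controllable surface density, bundling
  multiplicity, π-periodic orientation order, Gaussian line spread,
  Poisson + Gaussian camera noise), aster-contraction time series with a
  co-accumulating myosin channel and known imposed flow, and FRAP/RIfS
  scalar traces. Every estimator in the package is validated against
  this generator's truth records.

## Worked example

Generate a synthetic actin field, skeletonize it, and quantify its
architecture and order:

```python
import numpy as np
from macnet import synthgen as sg, tubefilter as tf, netmetrics as nm, nematic as ne

params = sg.SynthParams(n_filaments=100, orientation_kappa=4.0,
                        n_director_domains=1, seed=3)
truth, geometry = sg.sample_filament_field(params)
img = sg.render_micrograph(geometry, params)

skel = tf.extract_skeleton(img)
stats = nm.network_stats(img, skel)
field = ne.orientation_field(img, window_px=8)     # 1.6 um windows
qmap = ne.local_q(field, kernel=5)

print(f"skeleton density : {stats.skeleton_density:.3f}")
print(f"node density     : {stats.node_density_per_um2:.3f} per um^2")
print(f"q_mean           : {ne.q_mean(qmap):.3f}")
print(f"true order       : {truth.analytic_order_parameter():.3f}")
```

Output:

```
skeleton density : 0.047
node density     : 0.024 per um^2
q_mean           : 0.683
true order       : 0.877
```

The skeleton covers ~5% of the pixels at this surface density; the
estimated mean order parameter (0.68) tracks the generator's analytic
order (0.88) — window-scale estimation mixes orientations at domain
boundaries and filament crossings, so the estimate is attenuated but
strictly increasing in the generating concentration κ (this
monotonicity is asserted by the test suite).

A contraction experiment end to end:

```python
from macnet import dynamics as dyn

optics, cparams = sg.contraction_scenario("global", seed=1)
actin, myosin, flows = sg.generate_contraction_series(
    sg.sample_filament_field(optics)[1], cparams, optics)
reg = dyn.register_series(actin)
lag1 = dyn.lag1_trace(reg.series)
fields = dyn.piv(reg.series, lag_s=10.0)
call = dyn.classify_contraction(lag1, None, fields)
print(call.label, f"dip={call.dip_depth:.2f}", f"recovery={call.recovery:.2f}")
```

```
contracting dip=0.39 recovery=0.83
```

The lag-1 correlation trace dips while the network restructures into
asters and recovers once they are formed — the signature used to call
the experiment contracting.

## Command line

```bash
macnet simulate field --seed 3 --out field/          # TIFF + truth JSON
macnet skeletonize field/actin.tif --pixel-size 0.2 --out skel.tif
macnet metrics field/actin.tif skel.tif --pixel-size 0.2 --out stats.csv
macnet nematic field/actin.tif --pixel-size 0.2 --sweep --out q.json
macnet simulate series --seed 1 --out series/
macnet dynamics series/actin.tif series/myosin.tif --pixel-size 0.2 \
    --interval 10 --out report.json
macnet layer rifs trace.csv --out layer.json
```

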
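# fluoroloc

Multi-view fluorescence localization of crop seedlings in a mirror imaging
chamber.

## The problem

Mechanical intra-row weeding needs to know, quickly and precisely, where the
crop plant is. Crop signaling sidesteps crop/weed appearance models: the crop
seed is treated with a systemic fluorescent dye (Rhodamine B), so under green
excitation and a narrow band-pass filter *only the crop* is bright. A dark-box
rig images the bed from above with four inclined mirrors adding side views, so
the plant's signal is visible even when weeds or its own canopy occlude the
direct view. `fluoroloc` implements the image-analysis half of that system:

* **segmentation** — smooth, global-threshold (default intensity 4, the
  background ceiling of untreated plants), 8-connected components with
  intensity-weighted sub-pixel centroids;
* **region partition** — each frame divides into the central crop area (MC),
  four mirror areas (TL/TR/BL/BR; TL–BR and TR–BL are opposing pairs) and
  background;
* **case dispatch** — which regions contain fluorescence selects one of 16
  localization cases (direct extraction, diagonal connections, mirror-edge
  perpendiculars, or the two geometry solvers below), or `NOT_FOUND`;
* **mirror geometry** — with camera height `c`, mirror offset `d`, lateral
  position `a` and fluorescence height `b` (cm), a mirror view obeys

  `x = (b+d)(c+d) / (−a + b + c + 2d)`

  and the opposing view `x1 = (b+d)(c+d) / (b − a − c)`. Two closed-form
  solvers invert these: one from a single frame of an opposing mirror pair,
  one from two frames of a single mirror separated by a known camera travel
  `l` at mirror angle `θ` (`a2 = a1 + l·sinθ`);
* **simulation & evaluation** — a seeded synthetic-scene generator renders
  geometrically consistent frames for every occlusion scenario, and the
  harness scores a localization as a success when the estimate falls within
  43.5 px (0.5 cm at the full-resolution pixel scale) of the true center.

## Worked example

```python
import numpy as np
from fluoroloc import Config, sample_scene, render_frames, locate_frames

cfg = Config.default()
layout = cfg.layout()
rng = np.random.default_rng(0)

scene = sample_scene("two_opposite", layout, cfg, rng)
frames = render_frames(scene, cfg)
res = locate_frames(frames, config=cfg)
print(int(res.case_id), res.status)
print("estimate:", res.center_px, " truth:", scene.truth_center_px)
print("recovered height b:", res.solver_output.b, " true b:", scene.b_cm)
```

prints

```
12 ok
estimate: (499.51653163877216, 611.7703444029204)  truth: (499.53014524833895, 611.7842997188831)
recovered height b: 1.3710843052530102  true b: 1.368761715425752
```

— fluorescence was visible only in the TL and BR mirror areas (Case 12), so
the opposite-pair solver reconstructed the plant center to within a few
hundredths of a pixel and its height above the bed to about 0.002 cm.

The same chain runs from the shell:

```bash
fluoroloc simulate --counts 2,1,1,1,1,1 --seed 5 --out-dir scenes/
fluoroloc locate scenes/scene_0000_f0.png
fluoroloc bench --seed 1 --out-report report.json
```

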
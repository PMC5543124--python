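# conductionscan

Analysis of the cardiac conduction system in contrast-enhanced micro-CT
volumes: attenuation-band tissue segmentation, structure-tensor extraction of
cardiomyocyte orientation with helical-angle mapping, morphometry of
conduction structures, and monodomain simulation of electrical activation
seeded at the sinus node.

Iodine-stained cardiac tissue attenuates X-rays differentially — fat,
working myocardium, paranodal tissue, sinus-node tissue and connective
tissue in decreasing order — so micro-CT at tens-of-micrometre pitch can
resolve the sinus node, the paranodal areas, the atrioventricular conduction
axis and the Purkinje network non-destructively, along with the orientation
of the myocyte chains themselves.  This package is for image-analysis and
cardiac-modelling researchers who want that processing chain as tested,
scriptable code rather than interactive-workstation clicks.  Since datasets
of this kind are not publicly deposited, the package ships synthetic-phantom
generators with exact ground truth (labels, fiber fields, landmarks) so
every stage is verifiable end to end.

## What is inside

| module | contents |
| --- | --- |
| `volumes` | `Volume`/`LabelVolume` containers, NIfTI/TIFF IO, virtual reslicing, cropping, `.vti` export |
| `phantom` | two-chamber heart phantom, fiber-texture volumes, helical-ramp shell phantom |
| `segmentation` | attenuation bands (`bands_from_means`, exact 1D k-means), per-voxel classification, seeded region growing, conduction-system extraction |
| `orientation` | 3D structure tensor `J = G_σt * (∇_σg I)(∇_σg I)ᵀ`, fiber axis = smallest-eigenvalue eigenvector, Westin coherence, helix angles α ∈ (−90°, 90°] vs the circumferential direction |
| `morphometry` | PCA-axis extents (length/width), minimum surface distances, component census |
| `ep` | conductivity `D = d_T I + (d_L − d_T) f fᵀ`, ionic models (ten Tusscher 2004 epicardial, Courtemanche 1998, Mitchell–Schaeffer), explicit operator-split monodomain solver `∂V/∂t = ∇·(D∇V) − I_ion/C_m`, activation maps, virtual-heart ordering runs |
| `pipeline` / `cli` | reproducible phantom→segment→orient→morph→simulate pipeline with checksummed manifest; `conductionscan` command-line entry |

## Worked example

```python
import numpy as np
from conductionscan import PhantomSpec, SeedSpec, generate_phantom, segment_conduction_system
from conductionscan.segmentation import bands_from_means
from conductionscan.morphometry import component_census
from conductionscan.ep.virtual_heart import run_virtual_heart, VirtualHeartConfig

spec = PhantomSpec().coarse()          # half-resolution two-chamber phantom
volume, truth = generate_phantom(spec)

bands = bands_from_means(spec.class_means)
seed = tuple(np.argwhere(truth.mask("node")).mean(axis=0).round().astype(int))
labels = segment_conduction_system(
    volume, bands, {"node": SeedSpec(seed, bands.bands["node"])})

node = labels.mask("node")
dice = 2 * (node & truth.mask("node")).sum() / (node.sum() + truth.mask("node").sum())
print(f"node Dice vs ground truth: {dice:.3f}")

census = component_census(labels).set_index("structure")
row = census.loc["node"]
print(f"node: {row.voxels} voxels, {row.volume_mm3:.2f} mm^3, "
      f"length {row.length_mm:.1f} mm, width {row.width_mm:.1f} mm")
print(f"paranodal components: {census.loc['paranodal'].components}")

activation, report = run_virtual_heart(truth, VirtualHeartConfig(duration_ms=150))
print(f"atria complete at {report['atrial_completion_ms']:.1f} ms, "
      f"ventricles begin at {report['ventricular_onset_ms']:.1f} ms")
print(f"physiological ordering: {report['all_pass']}")
```

Output:

```
node Dice vs ground truth: 0.990
node: 49.0 voxels, 5.42 mm^3, length 3.8 mm, width 1.5 mm
paranodal components: 3.0
atria complete at 46.2 ms, ventricles begin at 69.3 ms
physiological ordering: True
```

The segmentation recovers the sinus-node body almost voxel-exactly from the
noisy volume, finds exactly the three paranodal projections that were
generated, and the activation run shows the physiological sequence: the
whole atrium depolarises (by 46 ms) before the first ventricular voxel
(69 ms), because the slow conduction axis is the only pathway across the
insulating base.  Removing the axis label silences the ventricles entirely.

A full pipeline with artifacts, figures and a checksummed manifest:

```bash
conductionscan run --config pipeline.yaml     # see PipelineConfig for keys
```

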
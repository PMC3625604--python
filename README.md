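# tlseg — threshold-based level-set segmentation of intracranial aneurysms

`tlseg` segments the contrast-filled lumen of intracranial aneurysms and
their parent arteries from 3D angiographic volumes (CTA-like intensities on
the Hounsfield-Unit scale), for people who need watertight, reproducible
vascular geometry — e.g. as input to morphology measurement or hemodynamic
simulation — without hand-tuning seeds or thresholds per case.

## The method

The segmentation surface Γ(t) is the zero level set of a scalar field φ
(negative inside) evolved by the normal-speed law ∂φ/∂t + F|∇φ| = 0 with the
outward speed

    F = α (I − T)  −  β div( g ∇φ / |∇φ| ),        g = 1 / (1 + c |∇I|²)

The **region term** α(I − T) expands the surface over voxels brighter than
an intensity threshold T and retracts it elsewhere; the **geodesic term**
smooths the surface in proportion to curvature and anchors it on intensity
edges through the edge-stopping map g. With β = 0 the rule reduces to the
lower-bound acceptance criterion of region growing; with the region term
removed it is the geodesic-active-contour flow.

T is estimated automatically, not supplied by the operator. Writing μ_a, σ_a
for the mean and SD of the foreground intensities and μ_b, σ_b for the
background, distribution-free Chebyshev confidence intervals place the
foreground's lower intensity bound at T = μ_a − kσ_a. Requiring it to
coincide with the background's upper bound μ_b + kσ_b, with a shared
confidence multiplier k, gives

    k = (μ_a − μ_b) / (σ_a + σ_b),        T = μ_a − k σ_a.

The statistics come initially from a Chan-Vese pre-segmentation (box-surface
initialisation, no seed) and are re-estimated from the evolving mask after
each block of PDE steps; T converges as the surface settles on the vessel
wall and iteration stops when it changes by less than 0.5 HU.

The package also implements the two baselines the method is compared
against — connected-threshold **region growing** and the two-phase
**Chan-Vese** model — a six-metric validation suite (volume difference,
Jaccard/Dice overlap, false-positive/negative ratios, Hausdorff and mean
absolute surface distance), and a synthetic vessel+aneurysm phantom
generator with exact ground truth (straight or curved parent artery,
saccular aneurysm, optional bleb, partial-volume blur, noise).

## Worked example

```python
from tlseg import PhantomConfig, make_phantom, segment_tls, full_report

volume, truth = make_phantom(PhantomConfig(seed=1))   # 64³, fg 200, bg 100 HU
mask, estimate = segment_tls(volume)                  # fully automatic

print([round(t, 1) for t in estimate.history], round(estimate.k, 2))
r = full_report(truth, mask)
print(f"VD={r.VD:.2f}%  JM={r.JM:.2f}%  rfp={r.rfp:.2f}%  "
      f"rfn={r.rfn:.2f}%  HD={r.HD:.2f}  MASD={r.MASD:.3f}")
```

prints

```
[146.2, 146.6] 4.65
VD=0.68%  JM=96.66%  rfp=2.05%  rfn=1.37%  HD=1.41  MASD=0.088
```

The threshold history shows T settling at 146.6 HU after two outer
iterations — essentially the 150 HU midpoint of the two intensity
populations — and the resulting mask disagrees with the exact ground truth
only within a sub-voxel surface band: 0.68% volume difference, 96.7%
Jaccard overlap, and a mean surface distance of 0.09 voxels.

The same pipeline is scriptable from the shell:

```sh
tlseg phantom --out phantom.nii.gz --mask-out truth.nii.gz --seed 1
tlseg segment --method tls --in phantom.nii.gz --out mask.nii.gz
tlseg validate --gt truth.nii.gz --out report.csv mask.nii.gz
tlseg experiment --seed 1 --out results/      # full 4-case × 3-method battery
```

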
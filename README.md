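# soypod

Occlusion-controlled dual-mask scene synthesis and seeds-per-pod counting
for laboratory soybean pod phenotyping.

## The problem

Soybean yield components are assessed from pod-level traits: pod length,
pod width, pod area and, above all, seeds per pod (SPP). In laboratory
on-branch imaging the pods overlap each other heavily, so ordinary
instance segmentation only recovers *visible* masks, and every trait
computed from a partial mask is biased. Two things are needed and this
package provides both, for anyone building or evaluating an
occlusion-aware pod phenotyping pipeline:

1. **Synthetic dual-mask scenes.** Pod cutouts are composited onto a
   black canvas — freely (excised-pod style) or mounted by their tip
   vertex onto growth points along a branch silhouette — under an
   explicit per-pod occlusion-ratio threshold α. For a pod *j* with
   complete (amodal) mask *M*ⱼ^full, the occlusion ratio is

       δⱼ = Area(⋃_{z_k > z_j} M_j^full ∩ M_k^full) / Area(M_j^full)

   and a placement is accepted only if every pod keeps δⱼ ≤ α. Each
   scene carries exact dual masks: the amodal mask and the visible mask
   *M*ⱼ^vis = *M*ⱼ^full \ ⋃_{z_k > z_j} *M*ₖ^full, which tile the
   composite foreground. Scenes serialize to COCO-style JSON with an
   extra `amodal_segmentation` field per annotation.

2. **Morphology-driven SPP counting from amodal masks.** The chain is
   pose normalization (principal axis horizontal) → axial width profile
   w(x) = 2·maxᵧ D(x,y) from the Euclidean distance transform, standard
   radius r = 0.4·median(w) → fused density
   F = 0.45·N_D + 0.40·N_M + 0.15·N_E (normalized distance field,
   multi-scale smoothed response, inverted boundary gradient) →
   non-maximum-suppressed peaks (separation 0.8·r, floor 0.15) →
   marker-controlled watershed → morphological region filtering →
   dynamic-programming selection of an ordered, regularly spaced subset
   of seed centres (score sᵢ − 0.8·((δᵢ−δ̄)/δ̄)² − 0.6·oᵢ) → fusion with
   an auxiliary count from valleys of the width profile. Pod length
   (long side of the minimum-area rotated rectangle), width (maximal
   inscribed circle diameter) and area come from the same normalized
   mask.

A procedural fixture generator produces pod masks with *known* seed
counts and geometry (overlapping elliptical lobes with pinched waists)
and branch silhouettes, so the whole pipeline is testable offline with
constructed ground truth.

## Worked example

```python
from soypod import generate_pod, SyntheticPodSpec, count_spp, measure_traits

truth = generate_pod(SyntheticPodSpec(num_seeds=3, seed_radius=18,
                                      center_spacing=27, rng_seed=7))
res = count_spp(truth.mask)
rec = measure_traits(truth.mask)
print(f"constructed: seeds={truth.num_seeds}  length={truth.true_length:.1f}px  width={truth.true_width:.1f}px")
print(f"counted:     c_main={res.c_main}  c_aux={res.c_aux}  spp={res.spp}")
print(f"measured:    length={rec.length_px:.1f}px  width={rec.width_px:.1f}px  area={rec.area_px2}px^2")
```

prints

```
constructed: seeds=3  length=90.0px  width=35.3px
counted:     c_main=3  c_aux=3  spp=3
measured:    length=89.6px  width=35.1px  area=2533px^2
```

The constructed pod has three seed lobes of radius 18 px spaced 27 px
apart, so its true length is 2·27 + 2·18 = 90 px. The DP count
(`c_main`), the width-profile count (`c_aux`) and the fused count (`spp`)
all agree at 3, and the extracted length/width land within half a pixel
of the constructed truth.

The same operations are available from a CLI:

```bash
soypod fixtures --n 20 --seed 1 --out lib/            # pod library + truth
soypod synth-overlap --alpha 0.3 --n 10 --seed 42 --out data/   # dual-mask scenes
soypod synth-branch  --alpha 0.3 --n 10 --seed 42 --out branch/ # on-branch scenes
soypod count --masks lib/ --out counts.csv            # SPP + traits per mask
soypod eval  --pred counts.csv --truth truth.csv --out report.json
```

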
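# spotmorph

Quantitative analysis of dorsal spot patterns for discriminating
haplogroups of *Triatoma dimidiata* (Hemiptera: Reduviidae), the Chagas
disease vector complex — and, more generally, for any insect whose light
pattern elements on a dark cuticle carry taxonomic signal.

Cryptic taxa in the *T. dimidiata* complex are usually told apart with
molecular data. The dorsal abdomen, however, bears a stereotyped pattern of
light spots — two central spots on the midline and paired lateral spots
along the connexivum — whose sizes, shapes and orientations differ
consistently among the three Mexican haplogroups (H1–H3). `spotmorph`
turns dorsal photographs into a per-specimen feature vector describing that
pattern and classifies specimens by group, for taxonomists, vector
ecologists and health entomologists who need identification without
sequencing.

## What it computes

Each specimen image is desaturated, contrast-stretched to the central 50%
of its histogram, and brought into a canonical frame (insertion axis
horizontal, abdomen rescaled to a fixed reference width). Spots are
segmented by Minimum-method automatic thresholding, a radius-6/threshold-50
outlier-removal (median) filter and gap filling, then numbered: central
spots 1–2, left laterals odd, right laterals even, anterior to posterior.

Per spot, with Ta the abdomen area:

- relative area **Ra** = 100·area/Ta (%)
- maximum and minimum Feret diameters **MaxFd**, **MinFd** (rotating
  calipers on the convex hull), relative to √Ta
- Feret angle **Fa** of the MaxFd chord, folded to 0–90° so left/right
  inclinations are comparable
- aspect ratio **Ar** = MinFd/MaxFd ∈ (0, 1]

Per specimen: class means of the primaries, total Ra, the central:lateral
mean-Ra ratio, and the summed central–lateral centroid distances after a
generalized Procrustes registration of the 14-landmark centroid
configurations. Group structure is then assessed with per-group heat maps
(pixelwise spot frequency), medians/quartiles and tie-corrected
Kruskal–Wallis *H* tests, a forward-stepwise linear discriminant analysis
(variables enter by the partial *F* of their Wilks' Λ reduction), and a
single-hidden-layer perceptron trained full-batch with a quasi-Newton
optimizer on a per-group 60/40 split in which LDA-misclassified specimens
are forced into the validation sample. Variable importance is estimated by
permutation (error ratio ≈ 1 for an uninformative variable).

Because the original photographs required manual clipping, a synthetic
specimen generator (`spotmorph.synthetic`) renders the three haplogroup
archetypes — H2 with large round central spots and ~15.6% total relative
spot area, H3 with elongated laterals and ~8.7%, H1 intermediate (~11%)
with forward-tilted anterior lateral pairs — with exact per-spot ground
truth, so the whole pipeline is testable end to end without any downloads.

## Worked example

```python
from spotmorph.synthetic import generate_dataset
from spotmorph.pipeline import PipelineConfig, analyze_dataset

specimens = generate_dataset(n_per_group=(10, 10, 10), master_seed=7)
items = [(s.image.source_id, s.group, s.image, s.roi) for s in specimens]
result = analyze_dataset(items, PipelineConfig(hidden_grid=(20,), importance_reps=10))

print(result.features.groupby("group")["total_Ra"].mean().round(2))
print("LDA selected:", result.lda.selected_vars)
print("LDA resubstitution accuracy:", round(result.lda.accuracy_resub, 1), "%")
print("MLP validation accuracy:", round(result.mlp.accuracy_validation, 1), "%")
```

prints

```
group
H1    10.88
H2    16.84
H3     8.77
Name: total_Ra, dtype: float64
LDA selected: ['mean_Ar_lateral', 'central_lateral_ratio', 'mean_Fa_lateral', 'mean_Ar_central']
LDA resubstitution accuracy: 100.0 %
MLP validation accuracy: 100.0 %
```

The group means of total relative spot area land on the three archetype
targets (the spread within groups is lognormal, ~10%); the stepwise LDA
picks shape (Ar), orientation (Fa) and the central:lateral area balance —
the same variable families that separate the real haplogroups — and both
classifiers discriminate the three synthetic groups essentially perfectly
at this effect size. The corresponding Kruskal–Wallis test for the mean
central-spot area gives H = 25.81 (df = 2, p ≈ 2.5e-06).

The same pipeline runs from the shell:

```sh
spotmorph simulate --n 30 30 30 --seed 7 --out data/
spotmorph analyze --images data/images --rois data/rois \
    --labels data/labels.csv --out results/ --seed 7
```

`results/` then contains the standardized images, masks, per-spot and
per-specimen CSV tables, heat maps, statistics, LDA/MLP summaries and a
manifest with every seed and parameter. For real photographs, supply one
ROI JSON per image (abdomen outline polygon, the two thorax–abdomen
insertion points, and the posterior tip; see `spotmorph.io.AbdomenROI`).

## Layout

- `spotmorph.standardize` — desaturation, level stretch, geometric alignment
- `spotmorph.segmentation` — thresholding, despeckling, labeling
- `spotmorph.spot_features` — numbering, Feret metrics, Procrustes, feature table
- `spotmorph.heatmap` — per-group frequency overlays
- `spotmorph.stats` — descriptives and Kruskal–Wallis tests
- `spotmorph.classify` — stepwise LDA, split protocol, MLP, importance
- `spotmorph.synthetic` — archetype generator with ground truth
- `spotmorph.pipeline` / `spotmorph.cli` — orchestration and the `spotmorph` command

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
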
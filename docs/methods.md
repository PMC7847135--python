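# Methods

This note documents the procedures implemented in `spotmorph`, the
parameters that matter, the design choices made where the protocol was
genuinely open, and what the synthetic benchmark does and does not show.

## Image standardization

Conventions: origin top-left, x rightward, y downward, 0-based pixels.
Angles are reported mathematically (counterclockwise from +x with y
flipped), so 0° is the transverse (left–right) axis and 90° the
anterior–posterior axis.

**Desaturation.** RGB images are collapsed with the unweighted channel
mean, rounded half-up — the default 8-bit conversion of common
particle-analysis software. Rec. 601 luma weighting is available
(`luma_desaturate`) but not the default; for the dark-cuticle/light-spot
contrast the choice is immaterial.

**Level stretch.** Intensities at or below the 25% quantile map to 0, at
or above the 75% quantile to 255, linearly in between (monotone, so rank
order is preserved). The quantiles are taken over the *whole frame* by
default rather than the abdomen only: the abdomen interior is dominated by
one dark intensity mode, so an ROI-restricted 75% quantile falls inside
that mode and the stretch saturates the cuticle's upper tail together with
the spots, defeating the subsequent binarization. With the light
photographic background as the upper anchor, cuticle maps near 0, spots to
a distinct high band, and the spot/cuticle contrast survives the clip. An
`roi_mask` argument restores the restricted behaviour when wanted.

**Geometric alignment.** The segment between the two thorax–abdomen
insertion landmarks is rotated horizontal (flipping 180° if the posterior
tip ends up above it), the abdomen outline is isotropically rescaled so its
horizontal extent equals `ref_width` (default 1000 px for full-resolution
photographs; the pipeline default is 800 px to match the synthetic
rendering scale), and the outline's bounding box is translated to the frame
origin. The canonical frame is `ref_width × 1.5·ref_width`; taller
abdomens are clipped with a logged warning. Grayscale is interpolated
bilinearly, masks nearest-neighbor; everything outside the outline is set
to 0. The applied similarity transform is recorded so any source
coordinate can be mapped into the canonical frame. Because all downstream
variables are relativized (areas by Ta, lengths by √Ta), the reference
width only affects rasterization error; features are stable to ±1% under
0.5×/2× input rescaling at photographic resolution.

## Segmentation

**Threshold.** The Minimum method: the 256-bin ROI histogram is repeatedly
smoothed with a 3-bin mean until exactly two local maxima remain; the
threshold is the minimum bin between them. When the valley bottom is a
tied plateau — the usual case for well-separated modes, where the valley
is empty — the *middle* tied bin is used. This tie rule is symmetric under
contrast inversion and places the cut centrally between the modes, which
also centers the spot boundary within the interpolation ramp left by the
geometric warp (a first-minimum rule would bias spot areas by up to a
pixel of boundary). A fixed threshold can be supplied instead.

**Polarity.** Spots are the thresholded class covering the smaller ROI
fraction (light pattern elements are the minority); exact ties go to the
brighter class. An inverted-contrast image therefore yields the same mask.

**Outlier removal (radius 6, threshold 50).** A two-pass circular-median
replace-if-deviant filter on the 0/255 mask rendering: pass 1 removes
bright outliers, pass 2 dark ones. For binary input the circular median
(113-pixel footprint, odd, no ties) reduces to a neighborhood majority
vote, and "deviates by more than 50" is simply disagreement with that
majority, so the passes are computed with integer convolutions. Two
consequences worth knowing: the filter is a *curvature smoother*, moving a
convex boundary inward by ≈ r²/(6R) per pass (≈ 12% area change for a
disk of radius 10, ≈ 1% at radius 30) — spot areas are therefore only
accurate when spots are much larger than the filter radius, one reason the
synthetic specimens render at photographic resolution — and it is not
exactly idempotent: a second pass still shaves high-curvature boundary
pixels (a few percent of spot area) without changing the spot count.

**Gap filling.** Background regions not connected to the ROI border become
spot pixels; cavities open to the border are preserved.

**Labeling.** Connected components (8-connectivity default) smaller than
`min_spot_area` (25 px² default) are discarded; survivors get sub-pixel
boundary contours (marching squares at level 0.5), pixel-mean centroids and
Ta = ROI pixel count. Specimens whose spot count deviates from a
configured expectation are flagged in the QC report, never silently edited;
specimens that fail structurally (no spots, ambiguous central candidates)
are excluded and reported.

## Spot variables

Numbering follows the field convention: the two midline spots are 1 and 2
(anterior first), lateral spots get consecutive odd numbers on the left and
even on the right, each side anterior→posterior, y-ties broken by x. A
spot is "central" when its centroid lies within 15% of the body width of
the vertical midline (configurable); ≠ 2 candidates raise QC errors or
warnings rather than being silently guessed.

MaxFd is the largest pairwise distance between contour points, computed on
the convex hull (which attains it); among exactly tied pairs the smallest
angle is reported. MinFd is the minimum caliper width — the smallest
projection width over hull-edge orientations. The literal "minimum
distance between any pair of contour points" would be the pixel pitch and
carries no information, so the standard particle-analysis semantics is
used. Fa is the MaxFd chord orientation in [0, 180), folded to [0, 90] so
left- and right-side inclinations are comparable; central spots are folded
identically for consistency. Ar = MinFd/MaxFd. Areas are relativized to
%Ta, lengths to √Ta. Note that the chord direction is ill-conditioned at
ellipse tips (the pairwise-distance function is flat there), so
single-spot Fa values carry a few degrees of rasterization noise even on
noise-free renders; class means are much more stable.

Centroid configurations (equal landmark counts, consistent numbering) are
superimposed by generalized Procrustes analysis: translation to the
origin, scaling to unit centroid size, then iterative rotation (no
reflection) to the evolving consensus until the mean shape changes by
< 1e-8. The per-specimen `sum_central_lateral_dist` is the sum of all
central×lateral centroid distances in that aligned frame; specimens whose
spot count differs from the modal count are excluded from this step only
(all-pairs pairing chosen; the variable can be dropped downstream).
Angle means are arithmetic means of folded angles, matching how the angles
are recorded; circular statistics are deliberately not used.

## Statistics

Descriptives are median, quartiles (linear-interpolation rule) and range.
Group comparisons use the tie-corrected Kruskal–Wallis H with a χ²(k−1)
upper-tail p; for very small samples an exhaustive permutation p
(`p_method="exact"`, N ≤ 12) is available, since the asymptotic tail is
unreliable there (e.g. 3+3 observations: χ² gives 0.049 where the exact
tail is 0.10). No multiple-testing correction is applied by default (the
per-feature tests are reported raw); a Holm column is optional.

## Classification

**Stepwise LDA.** Forward selection on Wilks' Λ: at each step the
candidate maximizing the partial F enters if F ≥ `f_enter` (4.0), and
entered variables with partial F < `f_remove` (3.9) are removed — the
classical thresholds, configurable. The fitted model is a pooled-covariance
Gaussian classifier with equal priors (configurable to proportional);
canonical axes come from the generalized eigenproblem of the between- and
within-group covariances, scaled to unit within-group variance. Reported:
the step trace, canonical scores, resubstitution and leave-one-out
confusion matrices (LOO refits means and covariance per fold on the fixed
selected set), and the overall Λ with Rao's F approximation. If no
variable reaches `f_enter` the model errors by default;
`allow_empty=True` yields a prior-only model (majority-class predictions),
which is what null-data controls need.

**Split protocol.** Per group, round(0.6·n) specimens train and the rest
validate, after reserving LDA-misclassified specimens to the validation
side. If the forced ids exceed a group's validation quota the quota
expands with a warning — but never beyond half the group: a degenerate
upstream classifier that misclassifies most of a group must not strip that
group's training sample, so excess forced ids return to the random pool.
The split is deterministic given its seed.

**MLP.** One hidden layer (default 20 units, the best topology of the
automated search on the real material), tanh/logistic/sine activations,
softmax + cross-entropy or logistic + sum-of-squares loss, small L2
penalty (1e-4) for conditioning, inputs z-scored with training-set
statistics, trained full-batch with L-BFGS (analytic gradients, verified
against finite differences) for ≤ `max_epochs` iterations. The historical
protocol names both an entropy and a sum-of-squares error for the same
network; both are implemented, cross-entropy is the default, and neither
is claimed as "the" original configuration. tanh is the default hidden
activation — sine is supported for fidelity but its periodicity makes
small-sample optimization brittle. `search_topology` grids over
hidden-unit counts (5–25 default), ranking by validation accuracy with
ties broken by fewer units then lower loss. Everything is reproducible
given (seed, split).

**Importance.** Permutation importance on the validation set: the mean
over repetitions of (error after shuffling one column)/(baseline error),
with add-one smoothing ((miscount+1)/(n+1)) so a zero baseline cannot
diverge. ≈ 1 means uninformative. The ratio convention is used because
the original network package's proprietary "weights" algorithm is
unspecified.

## Synthetic specimens

The generator renders a dark elliptical abdomen (800×1120 px — the
photographic scale implied by a ~1000 px reference width; at half this
resolution the outlier filter's boundary erosion alone exceeds the 2%
area tolerances used in validation) on a light background, bearing 2
central + 6 lateral pairs of light elliptical spots. Spot counts follow
the appearance of the real material (not stated numerically anywhere);
positions sit on the midline and along the connexivum at 78% of the local
half-width, clamped so each ellipse fits fully inside the abdomen.

Archetype contrasts encode the reported group differences: total relative
area 15.6% (H2) and 8.7% (H3) exactly, H1 set to 11% (intermediate, value
not printed in the source); H2's central spots large, round, and carrying
slightly more total area than all laterals combined; H1 and H3
lateral-dominant; H1's three anterior lateral pairs forward-tilted (folded
means 28–32° vs ~60–76° elsewhere); H3's laterals elongated (axis ratio
0.39 vs 0.55/0.65). Orientation spreads, per-axis lognormal size jitter
(6%), positional jitter (1.2% of body width), specimen-level lognormal
total-area jitter (10%), pose jitter (rotation sd 4°, scale ±6%,
translation ±16 px), Gaussian intensity noise (sd 7) and salt-and-pepper
speckle inside the abdomen (density 0.5% default) were chosen once as
plausible biological/imaging variation at effect sizes that keep the
groups statistically separable at n = 30/group, mirroring the qualitative
findings; exact group means for most variables are not printed in the
source and were not tuned further. Spot overlap triggers positional
resampling (up to 100 attempts) unless fusion is explicitly enabled.
Ground truth (pre-noise masks, per-spot areas, centroids, folded
orientations) is exact by construction, and per-specimen seeds derive from
a master seed, so datasets are byte-reproducible.

**What the benchmark does not show.** Spots are ideal ellipses with sharp
edges and uniform intensity; real spots have irregular outlines, soft
edges, texture, reflectance gradients and occasional fusions, and real
backgrounds are not uniform. Passing the synthetic recovery checks
validates the measurement chain (geometry, segmentation semantics,
statistics, classifier plumbing), not field-accuracy on photographs; the
published accuracies on the real material are additionally conditioned on
manual clipping and manual noise edits that no code path can reproduce.
The synthetic classification problem is *easier* than the real one
(near-100% accuracies at default effect sizes, Wilks' Λ near 0), so
classifier results on it are a functional check, not a performance claim.

## Numerical choices and degenerate inputs

- Constant images: level stretch returns the input unchanged (warning);
  thresholding raises "unimodal histogram".
- Collinear contours: MaxFd works (angle of the line), MinFd returns 0
  with a warning; single points are rejected.
- All-tied samples: H ≡ 0, p ≡ 1.
- Singular candidate covariances in stepwise LDA: the candidate is skipped.
- GPA tolerance 1e-8 (Frobenius change of the consensus), maximum 1000
  iterations; configurations with mismatched landmark counts are rejected
  with the offending specimen ids.
- CSV outputs use fixed `%.10g` float formatting; reruns with identical
  configuration and seeds are byte-identical.

## Validation problem sizes

The test suite exercises the full pipeline at n = 30/group (positive and
identical-archetype negative controls), segmentation recovery on 100
speckled specimens, the Feret oracles on 200 random 25-gons, and
100-replicate stepwise-selection null simulations; these sizes give stable
pass/fail behaviour for the stated tolerances while keeping a full run in
the tens of minutes on one core. The acceptance script replays the
39/23/39 study design.
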
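# Methods

## The outline model

A cranial-vault outline is an ordered 2D point sequence in left-lateral
view, traversed anti-clockwise from a point on the occiput at the level of
the cranial base line, through lambda and bregma, to glabella.  The base
line itself (glabella back to the occiput point) is straight and carries no
curvature information, so it is excluded from analysis; the vault is split
at the anchors into three homologous open curves — occipital (occiput to
lambda), parietal (lambda to bregma) and frontal (bregma to glabella).

Each segment is resampled to equidistant semi-landmarks on its
piecewise-linear polyline.  No spline is fitted: at the working density of
200 points per outline the polyline-versus-spline difference is far below
digitizing error, and polyline arc length keeps resampling exactly
reproducible.  Semi-landmark counts are harmonized per segment across
specimens, by default to the maximum raw count observed, so the most
finely digitized curve sets the sampling density; a fixed count can be
forced via `harmonize_policy="fixed:<m>"` for controlled experiments.
Note that equal-arc resampling is exactly idempotent only on
constant-curvature (circular or straight) polylines; on general curves a
second pass shifts points by O(h²) of the sampling interval, which is
negligible at working densities.

The 200-point budget covers the vault only (the straight base is never
digitized by the synthetic generator and is ignored on loaded data).

## Superimposition

Generalized least-squares Procrustes alignment removes location
(centering), scale (exact normalization to unit centroid size) and
orientation (iterative rotation of every configuration to the running
consensus until the consensus root-mean-square change falls below 1e-10,
at most 100 iterations).  Reflections are excluded because all specimens
are digitized in the same lateral view.  The rotational gauge is pinned by
orienting the final consensus to the first specimen's input pose, making
results deterministic; permuting the input order changes the solution only
by a global rotation, which the downstream decomposition ignores (a global
rotation adds the same constant to every specimen's angle vector and is
removed by mean-centering).

## Tangent-angle (phi) representation and eigenshapes

A curve of P points has P − 1 chords; the turning angle at each interior
vertex is the signed angle between the incoming and outgoing chord
(atan2-based, wrapped to (−π, π]).  The package stores the classic
Zahn–Roskies phi-function — cumulative turnings plus the start pose and
step lengths — which inverts exactly back to coordinates and is the
primitive used to draw morphospace end-member shapes.

The decomposition, however, operates on the **tangent-angle function in
the GPA-aligned frame**: the vector of absolute chord angles (start angle
plus accumulated turning, one coordinate per chord).  Measuring angles
from each specimen's own first chord would make the whole cumulative
vector hostage to that single chord: a small change in the starting
direction offsets all ~200 coordinates equally and shows up as a dominant
artefactual first eigenvector.  Referencing the common aligned frame makes
the Procrustes step do exactly the work it is there for; the alignment and
the angle representation are complementary rather than redundant.

The specimen-by-angle matrix is mean-centered and decomposed by SVD.
Eigenvalues are covariance eigenvalues (divisor n − 1); at most
min(n − 1, p) axes are retained; variance fractions are eigenvalues over
their total, and per-specimen eigenscores are the centered data projected
on the eigenshapes.  The SVD sign ambiguity is pinned by making each
eigenshape's largest-magnitude loading positive, so scores and plots are
reproducible run to run.  Per-segment analyses slice the composite angle
vector by the segment layout (chord index ranges; each shared joint vertex
belongs to the earlier segment) and repeat the decomposition on the slice.
A ternary view of the first three axes is provided as normalized
squared-score proportions; this is an interpretation (barycentric loading
shares), not a standard construction.

## Discriminant analysis

Eigenscores feed a stepwise Wilks'-lambda discriminant analysis.  Wilks'
Λ = det(W)/det(T) on the candidate variable subset; overall significance
uses Rao's F approximation; entry and removal decisions use the partial
F = (Λ_without/Λ_with − 1)·(n − g − p)/(g − 1).  Defaults follow standard
practice for this analysis type: enter at p < 0.01, remove at p > 0.10,
at most six variables; ties in Λ break toward the lower variable index so
selection is deterministic.

Classification is the linear discriminant rule with pooled within-group
covariance and equal priors (proportional priors are a config option).
Cross-validation is leave-one-out; by default the variable selection made
on the full data is reused inside folds — the common way stepwise-DFA
cross-validation tables are reported — with per-fold reselection available
via `reselect=True` for a stricter estimate.  Pairwise group separation
uses Mahalanobis D² under the pooled covariance of **all** groups, with
the Hotelling-style F = D²·(n − g − k + 1)·n₁n₂ / (k·(n − g)·(n₁ + n₂)) on
(k, n − g − k + 1) degrees of freedom.

Exact stepwise-DFA implementations differ across packages in their
F-approximation details, so reproduced classification tables from other
software may deviate by single specimens; the package reports its variant
(Rao's F, partial-F entry/removal) explicitly here for that reason.

For the per-segment two-group runs the default uses **all**
well-conditioned eigenshapes rather than a stepwise subset (the
whole-outline run is stepwise).  "Well-conditioned" caps the axis count at
n − g − 1 — so the pooled covariance stays invertible inside every
leave-one-out fold — and drops axes with eigenvalues below 1e-10 of the
leading one.

## The synthetic generator

`eigenvault.synthetic` emulates three study conditions:

* **modern** (unmodified): a smooth half-oval vault, height/half-length
  0.85, with small normal-range height variation (multiplier 1.00 ± 0.04,
  capped at 1.06).
* **hungary** (two-bandage): moderate elongation (1.25 ± 0.04), slight
  obliquity, and a bregmatic depression — a Gaussian dent of depth
  0.10 ± 0.02 of vault height and arc-fraction width 0.12, centered
  0.65 ± 0.03 along the vault (the bregma sits at 0.65, so center jitter
  emulates pre/post-bregmatic bandage placement).  Low spreads: this group
  is morphologically restricted.
* **georgia** (diverse annular styles): a mixture of a tall-vertical
  component (elongation 1.45 ± 0.15, weight 0.45), an oblique component
  (1.28 ± 0.10 with shear angle 0.30 ± 0.08 rad, weight 0.40), and a
  minority two-bandage-style component (weight 0.15).  Wide spreads: this
  group's score dispersion exceeds the Hungarian group's on the leading
  eigenshapes.

Deformations are applied to a dense (801-point) parametric vault in
(arc, height) space — height scaling about the baseline, dent subtraction
tapered by local height so baseline endpoints stay fixed, postero-superior
shear — and the result is re-sampled to 200 semi-landmarks with fixed
per-segment counts (61/71/70, shared joints), so anchors are homologous by
construction for any parameter draw.

Two generator choices deserve explicit justification:

* **Noise is smoothly correlated.**  Digitizing error follows the traced
  curve; modeling it as independent per-point jitter at 200-point spacing
  would inject turning-angle noise of tens of degrees and swamp the shape
  signal.  Radial jitter has the stated per-point standard deviation
  (default 0.5% of local radius) but is correlated along the outline with
  a Gaussian kernel of ~2% of the trace length.
* **Modification status is definitional on morphology.**  Modified-group
  elongation draws are truncated by reflection at 1.22 (unmodified capped
  at 1.06): a vault only counts as intentionally modified when it is
  visibly elongated, and in the study system modified crania are
  recognizable at a glance.  Reflection rather than clipping avoids piling
  probability mass exactly at the class boundary.

What the generator does *not* emulate: cranial thickness and bone
surface detail, the face and cranial base, asymmetry, age/sex allometry,
inter-observer landmark placement differences, and any within-group
covariance structure beyond the parameter mixtures.  Passing pipeline
tests on synthetic cohorts therefore demonstrates that the machinery
recovers planted contrasts of this kind — clean height/obliquity/dent
contrasts with correlated noise — not that real collections will separate
at the same rates; synthetic groups are cleaner than real ones, and the
synthetic classification accuracies (typically 100% for the unmodified
group, 70–100% between modified groups, depending on seed) should be read
as upper bounds of that idealization.

## Numerical conventions and degenerate inputs

* Turning angles wrap to (−π, π]; coincident consecutive points are a
  hard error (the tangent is undefined).
* Zero-variance (constant) phi data yields all-zero eigenvalues, flagged
  by zero variance fractions rather than an exception.
* Singular within-group or pooled covariances raise with advice to reduce
  the variable count; an empty stepwise selection is a diagnostic result,
  not an error.
* Confusion tables report per-group accuracies rounded to one decimal in
  percent; all reports are JSON-serializable and byte-stable for fixed
  inputs, config and seed.
* Problem sizes: the shipped analyses use 20 specimens per group and 200
  semi-landmarks per outline, which keeps a full pipeline run in the
  low seconds on one CPU.
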
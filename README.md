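# eigenvault

Extended eigenshape analysis of 2D cranial-vault outlines, built for
studies of intentional cranial modification (head binding).  The package
takes landmark-anchored vault outlines in left-lateral view — as digitized
with the tps software family — and quantifies how binding styles
(single circular bandages producing tall or oblique vaults; the two-bandage
technique producing moderate elongation with a bregmatic depression) shape
the frontal, parietal and occipital arcs, then asks how well groups of
crania can be told apart on those shape variables.

It is aimed at biological anthropologists and morphometricians who want a
scriptable, tested version of the classic outline-analysis chain:

1. **TPS I/O** — read/write tpsDig-dialect landmark files; group labels and
   the four anchor landmarks (occiput baseline point, lambda, bregma,
   glabella) come from a sidecar YAML config.
2. **Geometry** — orient each outline to its glabella–porion baseline, split
   the vault at the anchors into occipital, parietal and frontal open
   curves, resample each to equidistant semi-landmarks, and harmonize
   point counts across specimens (the most finely digitized specimen sets
   the count per segment).
3. **Procrustes** — generalized least-squares superimposition to unit
   centroid size, reflection-free, with a deterministic orientation gauge.
4. **Eigenshapes** — convert each aligned composite curve to its
   tangent-angle (Zahn–Roskies phi) representation and decompose the
   specimen-by-angle matrix by SVD.  Eigenvectors ("eigenshapes"
   ES1, ES2, …) are hierarchical modes of outline-shape variation;
   each specimen's coordinates on them are its eigenscores, and any point
   of the morphospace can be inverted back to an outline for plotting.
5. **Discriminant analysis** — stepwise Wilks'-lambda selection of
   eigenshapes (enter at p < 0.01, remove at p > 0.10, at most six
   variables), linear classification with pooled within-group covariance,
   leave-one-out cross-validation, and pairwise Mahalanobis D² with
   Hotelling-style F tests.

A parametric generator of synthetic cranial outlines
(`eigenvault.synthetic`) emulates unmodified vaults and both binding
styles at group-specific variance levels, so the whole pipeline can be
exercised and tested without access to any collection.

## The statistics in brief

A vault outline with points p₁ … p_P is encoded by its tangent-angle
function φ(s): the direction of the curve (radians) at each arc position,
computed as the first chord's angle plus the accumulated signed turning at
each vertex.  After Procrustes alignment the φ vectors of n specimens form
an n × p matrix X; the eigenshape decomposition is the eigendecomposition
of its covariance (divisor n − 1), obtained by SVD of the centered matrix.
Group separation on the eigenscores is measured by Wilks'
Λ = det(W)/det(T) (within-group over total scatter), with Rao's F
approximation for significance, and by pairwise Mahalanobis
D² = (x̄₁ − x̄₂)ᵀ S⁻¹ (x̄₁ − x̄₂) under the pooled covariance S.

## Worked example

```python
from eigenvault import run_whole_outline
from eigenvault.synthetic import DEFAULT_PRESETS, CohortSpec, generate_cohort

cohort = []
for offset, (group, dist) in enumerate(sorted(DEFAULT_PRESETS.items())):
    spec = CohortSpec(group=group, n=20, param_distributions=dist, seed=1 + offset)
    cohort.extend(generate_cohort(spec))

report = run_whole_outline(cohort, seed=1)
for row in report["variance_table"][:3]:
    print(f"{row['axis']}: {100 * row['variance_fraction']:.1f}% of variance")
print("selected eigenshapes:", report["classification"]["selected_eigenshapes"])
print("resubstitution:", report["classification"]["resubstitution"]["accuracy_pct"])
for m in report["classification"]["mahalanobis"]:
    print(f"{m['pair'][0]} vs {m['pair'][1]}: D2 = {m['D2']:.1f}, p = {m['p']:.2e}")
```

prints

```
ES1: 51.7% of variance
ES2: 8.9% of variance
ES3: 7.8% of variance
selected eigenshapes: ['ES1', 'ES4', 'ES3', 'ES2']
resubstitution: {'georgia': 100.0, 'hungary': 100.0, 'modern': 100.0}
georgia vs hungary: D2 = 58.9, p = 8.68e-28
georgia vs modern: D2 = 56.6, p = 2.34e-27
hungary vs modern: D2 = 37.3, p = 4.89e-23
```

ES1 (half the variance) is the modified-versus-unmodified axis: it runs
from tall, antero-posteriorly narrow vaults to shallow, wide ones.  The
stepwise discriminant analysis separates all three synthetic groups
perfectly — synthetic cohorts are cleaner than real collections — and every
pairwise distance is significant.  The same run on real data replaces the
generator with `read_tps` + `attach_metadata` on a TPS file and its sidecar
config.

The command-line interface wraps the same pipeline:

```sh
eigenvault simulate --seed 1 --out fixture/          # synthetic TPS + config
eigenvault analyze fixture/cohort.tps --config fixture/meta.yaml --out report.json
eigenvault segments fixture/cohort.tps --config fixture/meta.yaml --out segments.json
eigenvault report report.json --out tables/          # CSV tables
```

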
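# Methods

This note records the models, algorithms, parameter choices, and numerical
decisions behind `rupturekit`. It is written for someone auditing results, not
for first-time users; see the README for a tour.

## 1. Biological model

Nuclear membrane rupture is a transient loss of nuclear compartmentalization
during interphase. In the fixed-cell assay modelled here, cells express two
reporters:

- **RFP-Cyto** — normally cytoplasmic. After a rupture it equilibrates into
  the nucleus, so a high **nucleus:cytoplasm RFP ratio** marks a cell that has
  ruptured at some point before fixation (RFP⁺, "ruptured").
- **GFP-Nuc** — normally nuclear. While a rupture is open it leaks out, so
  among RFP⁺ cells a high **cytoplasm:nucleus GFP ratio** marks a rupture that
  had not yet resealed at fixation (GFP⁺, "rupturing").

A companion 3D assay images the nuclear lamina (lamin immunostain plus a DAPI
fill) and asks whether the lamin shell has **gaps** — local discontinuities
through which an unobstructed path connects the nuclear interior to the
exterior.

## 2. Synthetic phantoms (ground truth)

All validation runs on generated data with known truth; no external data is
used anywhere.

**Screen phantoms.** Each well draws per-cell states (intact / ruptured /
rupturing / mitotic / dead / out-of-focus) from configured probabilities, then
intensity ratios from log-normal distributions: intact RFP nuc:cyto ratio has
median 0.35, ruptured 1.10 (log-SD 0.25); intact GFP cyto:nuc 0.30, rupturing
1.20. Contaminants carry their hallmark signatures: mitotic cells 2.5× Hoechst
with near-perfect solidity, dead cells 30% area at solidity 0.75, out-of-focus
cells 0.45× intensity. The generator can either emit measurement-level records
directly (used for statistics-scale simulations — rendering ~10⁵ cells per
plate to pixels and re-segmenting them would add hours without changing what
is being tested) or render 2D three-channel fields with label-mask truth (used
to validate segmentation).

**Lamina phantoms.** A sphere/ellipsoid nucleus of radius R with a lamin shell
of thickness 0.4 µm centred on the surface. Gaps are spherical caps of known
direction and angular radius θ removed from the shell; the analytic footprint
area 2πR²(1−cos θ) is stored as truth. Additive Gaussian noise sets the SNR
(signal level 100; the validation suite uses noise SD 20, i.e. SNR 5 — the
hardest level it is expected to tolerate — and binarization is validated at
that SNR separately).

## 3. Gap detection by distance-map equality

The core idea: a voxel outside the nucleus "sees" the nuclear interior through
a gap exactly when the shortest path from the interior that avoids the lamin
shell is no longer than the straight-line distance. So we compute, from a seed
(the eroded nucleus), (a) the unconstrained Euclidean distance map
(`scipy.ndimage.distance_transform_edt` with anisotropic sampling) and (b) a
geodesic distance map restricted to non-lamin voxels, and mark voxels where
the two agree. Gap footprints are the connected components of the agreement
map on the perimeter of the dilated nucleus.

### Stencil choice

The geodesic transform is Dijkstra on the voxel graph. Its edge set matters: a
26-neighborhood chamfer metric overestimates Euclidean distance by up to 12.8%
in the worst direction, which would swamp any equality tolerance. We use all
**primitive integer offsets within a Chebyshev radius of 3** (290 offsets;
offsets with a common factor are redundant). Linear programming over all
directions bounds this stencil's worst-case overestimate at **2.48%**
(radius 2 gives 4.9%). Equality is accepted when

    geodesic ≤ 1.04 · cartesian + 0.5 · max(voxel edge)

— a multiplicative chamfer allowance safely above 2.48% plus half a voxel for
discretization of the straight-line map. The 1.0248 ratio bound is a
lattice-unit property and therefore holds for isotropic sampling; anisotropic
voxels stretch the stencil and widen the worst direction (measured 4.3% at a
1.5:1 aspect). The pipeline is insulated from this because equality is judged
within ~1 µm of the surface, where the additive half-voxel term dominates.

### Blocking rule

Long stencil edges could jump a thin shell. Every edge admits traversal only
if all voxels crossed by the straight segment between the endpoint centres
(its supercover, sampled at 255 points and symmetrized so validity does not
depend on traversal direction) are traversable. Symmetrization matters: the
rounded sample sets of an edge and its reverse differ, and an asymmetric rule
makes the two sweep directions disagree.

### Verification and performance

`dijkstra_reference` builds the identical graph explicitly (vectorized array
shifts) and runs SciPy's sparse-graph Dijkstra; the production numba kernel
matches it to 0 ulp on random obstacle grids, with identical reachability
patterns. The production path is banded: only the seed boundary is a source,
the seed interior is blocked (no path profits from crossing it), and the
search stops at `max(cartesian at perimeter) · 1.04 + 2·max spacing`.

### Footprint measurement and filters

Raw voxel counts of a footprint are orientation-biased (a polar cap on an
axis-aligned grid under-counts by ~30%). Instead, gap area collects the faces
of a marching-cubes mesh of the dilated nucleus that lie within 0.6·‖spacing‖
of footprint voxels, then projects to the true nuclear surface by the ratio of
nucleus-mesh to dilated-mesh areas. Detected components then pass a filter
cascade, each step recording its removal reason: minimum size (noise specks),
lamin intensity at the footprint (apparent gaps over dim-but-present lamina;
default ceiling is the Otsu threshold of the lamin channel), a 5 µm³ merge cut
(components so large they indicate fused nuclei or segmentation failure), and
negative local mean curvature (deep concave folds, not gaps). Per-nucleus gap
counts are binned none / low (1–3) / high (≥4).

### Curvature

Surface curvature comes from a point cloud sampled on a marching-cubes mesh
(default 10 points/µm²): per point, a quadric height-field is least-squares
fit over the k=9 nearest neighbours in the tangent frame of the outward
normal; mean curvature is −(a+c) of the quadric, so a sphere of radius r
scores +1/r and a plane 0.

## 4. Screen pipeline

**Segmentation.** Nuclei: rescale (0.5–99.5 percentile) → 2× downsample →
median filter → tiled (adaptive) Otsu with per-block thresholds clamped to
[0.7, 1.5]× the global Otsu value (prevents spurious thresholds in empty
blocks) and bilinearly interpolated → fill holes → distance-transform
watershed declumping → minimum-area filter. Cells: seeded watershed on the
thresholded RFP channel with one region per nucleus; nuclei whose watershed
region has essentially no cytoplasm ring (<5% of nucleus area) are flagged
unsegmentable and dropped. Intensities are measured on compartment masks
eroded by 3 px to suppress boundary mixing, after subtracting a scalar
background (median outside the dilated object union).

**QC filters.** Fixed cascade, first failure recorded: low expression
(cytoplasmic RFP floor) → out-of-focus (Hoechst floor) → mitotic (Hoechst
ceiling coupled with a solidity floor — mitotic chromatin is bright *and*
round) → dead (per-condition area floor and solidity window). Intensity
filters are global; morphology thresholds are per condition (defaults: area
1st percentile, solidity 0.5–99.5 percentiles of that condition) because
treatments legitimately shift nuclear size and shape. The removal ledger
conserves cells exactly: retained + removed = input.

**Calling.** Per replicate, the threshold is median + 1·SD (sample SD) of the
pooled control-well ratio distribution; positivity is strict (>). GFP is
evaluated only among RFP⁺ cells. A condition enters GFP analysis only if every
replicate has ≥175 RFP⁺ nuclei.

**Statistics.** Condition vs control on pooled counts uses an exact
unconditional (Barnard-type) test with the pooled score statistic: p = sup
over the nuisance success probability π of P(|Z| ≥ |Z_obs|), the supremum
taken over a 1001-point grid with a 51-point local refinement. The
implementation factorizes the rejection region into per-x₁ acceptance
intervals (the score is monotone in x₂ for fixed x₁, established by bisection)
which makes group sizes of ~3000 tractable (~1 s). It is validated against a
full-enumeration oracle on all small tables to ~4·10⁻¹⁵ and cross-checked
against `scipy.stats.barnard_exact` (note scipy's column-wise table
convention). Effects are summarized as log2 fold change with Haldane
correction (+0.5) applied only when a zero count occurs; family-wise error is
controlled by Bonferroni; a hit requires adjusted p < α and |log2FC| ≥ 0.3.
Morphology comparisons use rank-sum/KS for two groups or Kruskal–Wallis with
tie-corrected Dunn post-hoc tests for more; enrichment is a hypergeometric
upper tail against the screened gene list (not the genome), with score
(k/n)/(K/N).

## 5. Reproducibility

All randomness flows through `numpy.random.default_rng(seed)`; a fixed seed
gives bit-identical tables. Every CLI stage writes a JSON manifest carrying
the package version, a SHA-256 of the canonical JSON of the effective
configuration, the seed, and row counts, so any output is traceable to
config + seed. Configuration is TOML; unknown sections or keys are rejected.

## 6. Known limitations

- The measurement-level generator samples ratios directly; it does not model
  segmentation errors, illumination gradients, or cell crowding. Rendered
  fields exist for exercising the segmentation stage but at small scale.
- The gap detector assumes one nucleus per stack and near-convex shape; the
  merge cut flags but does not split fused nuclei.
- Chamfer geodesics are exact only up to the stencil bound; sub-voxel gap
  geometry (θ well below ~5° at 0.1 µm sampling) is below resolution.
- The curvature estimator is noisy at mesh corners and should only be read as
  a local average (the gap filter uses the mean over a 1 µm neighbourhood).
- Barnard p-values are grid suprema; the refinement makes the residual grid
  error far smaller than any decision threshold but it is not a closed form.
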
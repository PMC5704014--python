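# Methods notes

## Scope and data model

The package analyses eyespot colour-component counts — a per-sector
complexity score for butterfly wings — on a rooted species phylogeny,
and tests digitized mosaic wings for compartment-boundary-respecting
clone outlines.  Trees are Newick with mandatory branch lengths on all
non-root edges; trait tables are species × trait CSV/TSV with columns
`<wing>.<surface>.s<sector>`.  Sector label sets are configuration
(default forewing −1..6, hindwing 0..7) because sector numbering
conventions differ between wings and authors; all pair machinery is
driven by the configured labels, never by hard-coded positions.

## Independent contrasts

Standardized contrasts follow the classic pruning recursion: at each
internal node of a bifurcating tree, `C = (x_i − x_j)/√(v_i + v_j)`,
nodal value = precision-weighted mean of the children, and the node's
own branch is inflated by `v_i v_j/(v_i + v_j)`.  Implementation
details that matter:

- **Deterministic ordering.**  Children are ordered by their smallest
  descendant tip label, so contrast signs and order are reproducible
  regardless of how the input Newick orders clades.
- **Exactness.**  The nodal mean is computed as
  `x_i + v_i/(v_i+v_j)·(x_j − x_i)`, which propagates identical child
  values without rounding, so a constant trait yields contrasts that
  are exactly zero.  The test suite verifies the contrasts against a
  generalized-least-squares identity: Σ C² equals the GLS residual sum
  of squares under the Brownian covariance (shared root-to-MRCA path
  lengths) to ≥ 10 significant digits, and against an independent
  reference implementation (`ape::pic`).
- **Linear-operator form.**  Contrasts are linear in tip values, so a
  `ContrastStructure` caches the (N−1)×N operator per tree; simulation
  studies reuse it across traits and replicates.
- **Zero denominators.**  `v_i + v_j = 0` can occur after zero-epsilon
  polytomy resolution.  Default policy inflates both branches by
  10⁻⁸ × tree depth with a logged warning; passing
  `zero_length_epsilon=None` makes it a hard error.  Never silent.
- **Branch lengths are used untransformed**; transforms are out of
  scope for the standard analysis path.

## Correlation of contrasts

Contrast signs are arbitrary but paired, so association is measured by
correlation **through the origin** (no mean-centring), with
`t = r√(df/(1−r²))` and **df = n_contrasts − 1**.  For the study design
of 23 species (22 contrasts, df = 21) this r → p map reproduces the
published p-values of the source analyses to within one unit of their
last printed digit, which is what fixes the df convention; df = 20 or
22 both fail that reconstruction.  `|r| ≥ 1` returns p = 0 with a
warning instead of raising, since it legitimately arises for duplicated
trait columns.  Raw p-values are compared to α = 0.05 with no
multiple-testing correction by default (matching the published
convention); Benjamini–Hochberg adjustment is available behind a flag.

Pairs with missing species are computed on the tree pruned to the
species carrying both traits, with df adjusted and the pruning logged;
pairs with fewer than 4 shared species or zero contrast variance are
skipped with a logged reason, never silently dropped.

The study summary (`all_surface_significant_pairs`) lists sector pairs
with significant **positive** correlations on every wing surface — the
compartment-boundary signature is symmetric covariation, and negative
correlations, while flagged in the full table, do not support it.

## Phylogenetic-signal gate

The Abouheif proximity between tips i and j is the inverse product of
the direct-descendant counts of the internal nodes on the path between
them; rows are normalized to sum to one and the statistic is Moran's I
on centred values.  Significance uses uniformly random tip
permutations with the add-one estimator `p = (1 + #{I* ≥ I})/(1 + B)`,
so p ∈ (0, 1] and the test is exact at any B.  Default B = 999.  The
p-value is invariant to affine transformation of the trait and, on
exchangeable data, uniform on the lattice {1/(B+1), …, 1} (verified by
KS test over 2000 null replicates).  Constant traits raise an explicit
no-variance error rather than returning p = 1.

## Brownian-motion adequacy diagnostic

The standardization check is the Pearson correlation between
|standardized contrast| and its standard deviation √(v_i + v_j) across
nodes, two-tailed.  Under an adequate BM standardization the two are
uncorrelated (the diagnostic rejects at ≈ the nominal rate in
calibration); branch lengths that fail to absorb the variance produce a
positive trend.  A non-significant diagnostic is the operational
meaning of "meets the Brownian-motion assumptions" in this pipeline.

## Synthetic data

The generator reproduces the statistical structure the analysis
assumes; it is a validation harness, not a claim about eyespot
developmental genetics.

- **Trees** are Yule (pure birth): from the root split, the epoch with
  k lineages lasts Exp(k·λ), and a final Exp(n·λ) epoch follows the
  last split, so E[depth] = Σ_{k=2..n} 1/(kλ) — a closed form the tests
  check by simulation.  Default λ = 1, 22 ingroup tips.  One outgroup
  is attached basally on a stem equal to the ingroup depth (deep root,
  ultrametric overall), mirroring an analysis rooted on a single
  retained outgroup.
- **Traits**: 32 = 2 wings × 2 surfaces × 8 sectors, correlated
  Brownian motion with increments ~ MVN(0, v·D R D).  R is, per wing,
  the Kronecker product of a 2×2 surface matrix (ρ_homology between
  dorsal and ventral, default 0) and an 8×8 sector matrix (ρ_block,
  default 0.8, between sectors 2–5 and 3–4) — PSD by construction for
  any admissible pair of parameters, with cross-surface non-homologous
  block pairs inheriting the product ρ_homology·ρ_block.  Wings are
  independent.
- **Scale.**  The rate parameter is expressed as `tip_sd`, the
  root-to-tip accumulated standard deviation in count units (the
  per-branch rate is tip_sd/√depth), so the marginal spread of species
  counts does not depend on the arbitrary time units of the simulated
  tree.  Default tip_sd = 2 with root value 3: species values 3 ± 2 SD
  span the full observable 0–6 count range, appropriate for a genus
  chosen for highly diverse eyespot phenotypes.
- **Discretization** is round-half-away-from-zero then clip to
  [0, max_count] (default 6): transparent, monotone, idempotent on
  in-range integers.  It acts on the analysis like unstructured
  measurement error and therefore attenuates contrast-level
  correlations substantially — rounding noise dominates the contrasts
  on the shortest branches, where the Brownian signal variance is
  smallest.  Measured on the default design, a planted ρ = 0.8 yields
  mean contrast r̂ ≈ 0.55 on counts versus ≈ 0.79 on the continuous
  traits.  Consequently the *designed-correlation recovery* checks run
  on the continuous variant (`discretize=False`), where the pipeline
  recovers exactly the planted pairs on all four surfaces in ≈ 99% of
  seeds; the count variant quantifies the attenuation (r̂ > 0.5).
  Passing tests on these simulations show the machinery is correct and
  calibrated — they do not show that real count data carries any given
  effect size, and the BM + rounding model understates the correlation
  that genuinely discrete, strongly covarying biological counts can
  carry.
- **Wing specimens**: four named vein-intersection landmarks on a
  template frame, perturbed per specimen by a random similarity
  (rotation ±0.25 rad, scale 0.85–1.15, shift ±0.2) plus Gaussian
  digitization noise (σ = 0.002 × scale) on landmarks.  Clones are
  regular 32-gons of circumradius 0.08 centred uniformly in a band of
  half-width 0.15 around the template F-P boundary; in `respect` mode
  they are clipped to the side their centre falls on with a 0.02
  safety margin (so landmark noise cannot push them across), in
  `ignore` mode they are unconstrained, with analytic crossing
  probability r_eff/h ≈ 0.53 used as a simulation cross-check.  The
  first specimen is the untransformed template and carries the
  boundary polyline.

## Clone geometry

- **Procrustes here means similarity** — translation, rotation,
  isotropic scale, no reflection (wings share chirality; a reflection
  would be a data error, not a fit).  The least-squares fit is closed
  form; the two-point fit maps the two anchor landmarks exactly and is
  the default alignment (posterior-most pair), matching how superposed
  wing images are aligned in practice.
- **Crossing semantics.**  A polygon crosses a boundary polyline when
  its outline has points strictly on both sides of the polyline within
  the polyline's extent.  Each point is classified against its
  *nearest segment*; points whose nearest polyline point is a vertex
  (beyond either end, or in the wedge at a bend) are unclassified, as
  is anything within ε of the polyline (touching ≠ crossing).  The
  implementation is exact rather than sampled: polygon edges are
  subdivided at their intersections with the polyline and with the
  perpendiculars bounding each segment's slab, after which every
  sub-edge midpoint is correctly classified.  A dense-sampling
  brute-force oracle agrees on 1000 random polygon/polyline cases.
  Default ε = 10⁻⁶ × landmark bounding-box diagonal (scale-free).
- **Smooth-edge flag**: a clone is flagged as running smoothly along a
  boundary when ≥ k consecutive outline vertices (default k = 3) lie
  within a coarser tolerance (default 100ε) of the polyline.  This is
  one operationalization of a qualitative criterion and is labelled as
  such in reports.

## Numerical and testing choices

Simulation sizes are chosen to give decisive statistics at interactive
runtimes: 2000 replicates for type-I-error and permutation-null
calibration (binomial/KS resolution ≈ ±0.01), 1000 replicates for
parameter recovery (SE of mean r̂ ≤ 0.003), 200 seeds for end-to-end
recovery, 1000 random cases for the geometry oracle.  All generators
and tests are seeded; identical seeds give byte-identical Newick, CSV
and specimen JSON outputs.

## Known limitations

- The hindwing sector label set is a convention choice; analyses using
  a different 8-label set must supply it in configuration.
- The signal test is applied per trait; no joint (multi-trait) signal
  statistic is provided.
- The boundary-crossing rule leaves vertex wedge regions unclassified;
  for sharply reversing polylines (not boundary-like inputs) a polygon
  near a bend may be judged conservatively.
- Ancestral node values computed during the contrast recursion are
  internal by-products, not reconstructions intended for downstream
  use.
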
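# Methods

## Problem and model

Interface hot spots — residues whose alanine mutation changes the binding
free energy by at least 2.0 kcal/mol — are spatially concentrated: they
pack into tight communities (hot regions) rather than spreading uniformly
over the interface. The pipeline exploits three consequences of that
picture:

* hot regions are *spatial* clusters, so unsupervised clustering of
  interface residue Cα coordinates can propose candidate regions without
  any trained classifier;
* hot spots are buried and energetically coupled, so two cheap per-residue
  descriptors — a knowledge-based pair potential and the relative
  solvent-accessible surface area in the complex — separate them from
  ordinary interface residues (the PPRA rule);
* hot spots are tightly packed, so their coordination number (count of
  spatial neighbours) is high, and candidates with below-average
  coordination are suspect (the RCNO rule).

### Definitions

For residues i, j with Cα positions xᵢ, xⱼ and author sequence numbers on
the same chain:

* **Contact**: Contactᵢⱼ = 1 iff |i − j| > 1 and d(i, j) ≤ 6.5 Å. The
  boundary is inclusive; a `strict` flag switches to d < 6.5 Å. Pairs on
  different chains are always sequence-eligible, because sequence
  adjacency is undefined across chains and interface contacts are
  inherently inter-chain.
* **Coordination number**: CNᵢ = Σⱼ Contactᵢⱼ over all residues of the
  complex.
* **Pair potential**: PP(i) = |Σⱼ potential(i, j)| with
  potential(i, j) = M[type(i), type(j)] when d(i, j) ≤ 7.0 Å and the pair
  is sequence-eligible at separation ≥ 4, else 0. The sum runs over all
  residues of the complex (a flag restricts it to interface residues).
* **Relative complex ASA**: 100 · ASA_complex(i) / maxASA(type(i)), where
  maxASA is the residue's maximal exposure in a Gly-X-Gly tripeptide.
* **Community adjacency**: residues are balls of radius r(type) (a single
  3.25 Å default, overridable per type); two hot spots are community-
  adjacent iff d < r(a) + r(b) + 2.0 Å (strictly). Hot regions are
  connected components of this relation with ≥ 3 members.

### Pipeline order

interface selection → silhouette-guided K-means (RH1) → PPRA filter with
recovery (RH2) → RCNO → community assembly. Interface residues default to
those burying surface on complexation (ASA_monomer − ASA_complex > 0 in
the feature table), falling back to cross-chain Cα proximity within the
contact cutoff when ASA columns are absent.

## Clustering

K-means is implemented in-package: k-means++ seeding from a seeded
generator, Lloyd iterations, best-of-10 restarts per k, empty clusters
repaired by reseeding from the point currently farthest from its center.
Convergence is declared when the relative WCSS improvement drops below
1e-6 (default) or assignments stop changing; 300 iterations maximum. The
reported WCSS is recomputed from the final assignments and centers, and
on fixtures with n ≤ 8 the restart scheme reaches the exhaustive-partition
optimum (asserted in the tests).

k is scanned over [2, min(10, n − 1)] and chosen by the maximal average
silhouette width; exact ties resolve to the smaller k (parsimony). Points
in singleton clusters take silhouette 0 by the usual convention. What is
clustered is a config choice: Cα coordinates (default — hot regions are
spatial communities) or z-scored feature vectors. Candidate points are
canonically sorted by residue id before clustering so results are
invariant to input order.

The three-residue edge case bypasses k selection (which needs n ≥ 3 and
k ≥ 2 with every k < n) and treats the input as one candidate cluster.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| ddg_hotspot_threshold | 2.0 | kcal/mol | hot-spot ΔΔG definition |
| contact_cutoff | 6.5 | Å | Cα contact distance (inclusive) |
| potential_cutoff | 7.0 | Å | pair-potential partner distance |
| min separation | 4 | residues | same-chain pair-potential eligibility |
| pp_threshold | 18.0 | matrix units | PPRA retention bound (≥) |
| rasa_threshold | 20.0 | % | PPRA retention bound (≤) |
| harmonic_distance | 2.0 | Å | community slack beyond summed radii |
| residue_radius | 3.25 | Å | ball radius, single default for all types |
| min_region_size | 3 | residues | smallest reportable hot region |
| rcno_factor | 1.0 | — | removal bound: CN < factor × mean CN |

The PPRA thresholds are calibrated to the pair-potential scale of the
hot-spot server lineage they come from. The packaged default matrix is a
**synthetic** hydrophobicity-derived 20×20 table (−0.5·(h_a + h_b) − 2.0
on the Kyte–Doolittle scale): published knowledge-based contact-potential
tables are not redistributable here, so the default is clearly labelled
synthetic and both the matrix (CSV with residue row labels) and the
threshold are configurable. Pipeline behaviour on feature tables is
unaffected by this choice, because PPRA consumes the `pair_potential`
column of the input table; the matrix matters only when features are
computed from geometry. The max-ASA reference ships the theoretical
Gly-X-Gly values of Tien et al. (2013), also overridable.

The residue radius is a genuinely free parameter: with the 3.25 Å default
the community limit for two average residues is 8.5 Å, comfortably above
the 6.5 Å contact cutoff, so contacting hot spots are always in the same
community.

### RCNO details

The mean coordination number is taken over the *current candidates*
(flag: over all interface residues), removal is strict (CN < factor·mean),
and a single pass is made by default (a flag iterates to a fixed point).
A uniform-CN candidate set is therefore left untouched, and the
maximum-CN candidate can never be removed.

### PPRA recovery

Recovery adds interface residues that pass both PPRA bounds and are
community-adjacent to a surviving candidate, closed transitively (BFS
from the survivors). The closure makes the filter idempotent — applying
it twice equals applying it once — which a single sweep would not
guarantee. Residues that pass the thresholds but are far from every
surviving candidate are *not* added; recovery repairs clustering misses
inside regions without creating isolated false positives.

## Evaluation

Residue-level confusion counts over an explicit universe; precision and
recall are flagged *undefined* (not coerced to 0) when their denominators
vanish; F1 = 2PR/(P + R). Display rounding is half-up to 2 decimals.
Cohen's kappa defaults to (p₀ − pₑ)/(1 − pₑ) with
pₑ = Σᵢ aᵢbᵢ / n²; a "literal" mode computes (p₀ − pₑ)/(1 − p₀) for
fidelity with one printed variant of the formula, and raises at p₀ = 1,
which is why it is not the default. The worked-example arithmetic takes
six printed residue-id lists (predicted/missed/false before optimization;
recovered/unrecovered/false-removed after) and enforces their set
consistency before counting.

## Synthetic data

The generator emulates what the pipeline assumes about interface residue
tables, not real protein geometry:

* two chains; the non-interface bulk runs as straight strands 24 Å apart
  (3.8 Å Cα steps), so strand decoys have coordination number ≈ 0;
* each planted region is a compact cross-chain motif at the interface
  midplane built from sequence-adjacent *pairs* and *triples* (one group
  per chain; sizes 3–6). All member pairs lie within the 6.5 Å contact
  cutoff, so planted members are pairwise community-adjacent and regions
  survive assembly by construction;
* a *balancer* decoy residue is packed against each triple's middle
  member (within the contact cutoff of it and of nothing else that
  counts), so every member of a region carries the same coordination
  number. This mirrors the uniform tight packing the RCNO rule assumes of
  genuine hot regions, and it is why RCNO does not erode planted regions.
  Region sizes are kept equal within one complex: the RCNO mean is global
  over candidates, so mixed sizes would systematically penalise the
  smaller region — a real property of the method worth knowing about;
* entry/exit residues joining motifs to the strands are placed by a
  deterministic direction search maximising clearance from members; after
  Gaussian jitter (σ = 0.15 Å default) on member coordinates, a validator
  recomputes contacts and coordination numbers on the generated structure
  and resamples the jitter if any invariant (pairwise adjacency, per-
  region CN uniformity, exact assembly) fails, erroring out after 25
  attempts;
* hot features: pair potential ~ Normal(25, 4) truncated at ≥ 18, relative
  ASA ~ Uniform(0, 20); decoys fail at least one bound (truncated-below
  pair potential, or relative ASA drawn above the threshold). Bounds are
  respected exactly, not just in distribution. Every residue buries
  surface on complexation, so the whole complex is "interface", as in
  server-derived interface tables. Defaults (2 regions × 5 hot spots,
  50 decoys) give a hot:non-hot balance of 0.20:1 per complex, leaner
  than curated hot-spot datasets — the generator's decoys stand for the
  whole interface neighbourhood, not a pre-filtered candidate list.

What passing on synthetic data does **not** show: robustness to
correlated/noisy feature values near the PPRA bounds, to irregular
packing where hot-spot coordination numbers vary within a region (there
RCNO genuinely trades recall for precision), or to real ASA/potential
computation pipelines. Those need real complexes and curated ΔΔG data.

## Numerical choices

* Alternate locations: first-listed conformer, occupancy ignored —
  deterministic and independent of refinement conventions.
* Nonstandard residues excluded by default (the potential matrix covers
  the 20 standard types); a flag includes them for I/O purposes.
* ASA: Shrake–Rupley with 960 sphere points per atom and probe 1.4 Å,
  fixed point ordering; monomer ASA is computed by re-running the same
  algorithm on the isolated chain subset. Cα-only input is a capability
  error directing the user to supply a feature table.
* Sequence separation uses author residue numbers; insertion codes are
  carried through I/O but do not enter separation arithmetic.
* Redundancy pruning scans columns in header order and keeps the first
  of any correlated group (|Pearson r| ≥ threshold), dropping
  zero-variance columns with a warning — deterministic where "remove one
  of the pair at random" would not be.
* CSV output formats numbers to 6 significant digits for reproducible
  diffs; fixture writing is byte-deterministic for a fixed seed.

## Problem sizes

The test suite and the acceptance script run on deliberately small
problems chosen to be decisive rather than large: 20 synthetic complexes
of 60 residues for parameter recovery, 50–100-residue random fixtures for
the brute-force oracle comparisons, n ≤ 8 for exhaustive k-means
enumeration, and 10 seeds × 40–45 points for cluster-count selection.

## Known limitations

* The clustering space for real complexes is a modelling choice; results
  on irregular interfaces can be sensitive to it (the diagnostic per-k
  table is exported so the silhouette landscape can be inspected).
* Pair-potential values depend on the chosen matrix; the PPRA threshold
  18.0 only makes sense on a matching scale.
* Region-level evaluation (did we find *this region*) is not implemented;
  all metrics are residue-level.
* Only the filtering stage of boundary-point-style region detectors is
  generic: `ppra_filter` accepts any externally produced candidate set,
  but no boundary-point clusterer is included.
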
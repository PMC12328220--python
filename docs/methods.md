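# Methods

This note documents the models, conventions and numerical choices behind
`structcons`, and what the synthetic benchmark does and does not establish.

## Structural mapping

Member structures are aligned to their orthogroup reference with a
matchmaker-style protocol:

1. Global sequence alignment with BLOSUM62 and affine gaps (open 10,
   extend 1). These are the conventional matchmaker-like defaults; the
   substitution matrix and gap costs are configurable. An optional
   secondary-structure match bonus (+1 per aligned position of equal class)
   switches the implementation to an in-house affine-gap (Gotoh) dynamic
   program, since position-specific bonuses cannot be expressed through the
   standard aligner interface.
2. Kabsch least-squares superposition on the aligned Cα pairs (SVD with
   reflection correction; collinear point sets are flagged as degenerate but
   still solved).
3. Iterative pruning: pairs with superposed Cα distance > `prune_cutoff`
   (2.0 Å) are removed and the superposition refitted, until stable or 20
   iterations. The fit RMSD over retained pairs is non-increasing across
   iterations.
4. Final 1:1 mapping: all sequence-aligned pairs within `map_cutoff`
   (5.0 Å) under the final superposition. The mapping is monotone in both
   residue indices by construction.

Members with fewer than three mappable pairs are excluded from profiles and
counted, so denominators remain reproducible.

**TM-score.** TM = (1/L) Σᵢ 1/(1 + (dᵢ/d₀)²), d₀ = max(0.5,
1.24·(L−15)^⅓ − 1.8). The 0.5 Å floor keeps the score defined for chains
shorter than 21 residues (the toy folds' segments can be short). The
bidirectional score symmetrises over the two length normalisations; the
arithmetic mean is the default, with min/max available, because the choice
of symmetrisation is a genuinely open convention. Orthogroup refinement
clusters structures by average linkage on 1 − TM and cuts the dendrogram at
cophenetic distance 0.2; ties are broken by lexicographic structure id.

## Conservation ratios

Per member: M = mapped residues, N = unmapped member residues
(M + N = member length), C = mapped residues identical to the reference.
MR = M/(M+N), CR = C/M. Orthogroup values are unweighted means over
non-reference members (per-protein averaging); a species-deduplication mode
collapses paralogues to their best-mapping representative first. Unknown
residues ('X') map but never count as identical, and are excluded from
class-CR denominators and compositions.

The class-based CR counts a substitution as conserved when both residues
share a physicochemical class (aliphatic/aromatic/polar/acidic/basic with
glycine, proline and cysteine as singletons); it is bounded below by the
identity CR. The hydrophobicity-change statistic is the mean |ΔlogP|
(Fauchère–Pliška side-chain octanol–water scale) over **all** mapped pairs,
identical pairs contributing zero. Averaging over all mapped pairs (rather
than substituted pairs only) makes the statistic a divergence measure with
the expected strong inverse relationship to CR; the substituted-only
variant, which instead measures the mean chemical step size per
substitution, is available via `substituted_only=True`.

A reference position is *fully conserved* when it is mapped in every
aligned member and identical in all of them; a relaxed quorum (e.g. 0.95)
is configurable.

## Residue features

- **SASA**: Shrake–Rupley with a deterministic golden-spiral lattice
  (default 960 points/atom, probe 1.4 Å, packaged van der Waals radii).
  960 points give per-atom areas within ~2% of a 10,000-point computation.
- **rSASA / exposure**: SASA divided by the residue's theoretical maximum
  (Gly-X-Gly context). Surface iff rSASA ≥ 0.25 — a common convention; the
  threshold is configurable and the tests exercise 0.20/0.35. 'X' residues
  fall back to raw SASA ≥ 25 Å².
- **Secondary structure**: backbone hydrogen bonds by the classic
  electrostatic criterion (E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH −
  1/r_CN) kcal/mol < −0.5, amide H placed 1 Å from N anti to the preceding
  C=O). Two consecutive i→i+4 (or i→i+3) turns give helices, bridge
  ladders give extended strands, isolated turn spans give turns, the rest
  is coil. Chains without complete backbones use a Cα-distance fallback and
  are flagged as such. Assignments come from the model's own geometry; no
  external assignment program is invoked.
- **Binding sites**: CSb = any residue heavy atom within 5 Å of a retained
  ligand heavy atom (waters, buffers, cryoprotectants and simple ions are
  excluded by a packaged list; metal ions are retained and flagged). UPb =
  curated per-residue annotations joined by author numbering; annotations
  on holo homologues transfer onto the reference through the residue
  mapping, with unmapped flagged residues dropped and counted.

## Conserved clusters

Fully conserved residues are nodes of a contact graph with edges between Cα
pairs ≤ 10 Å. Clusters are connected components with ≥ 3 residues
(`min_cluster_size`, exercised at 1/3/5 in the tests); components are a
deliberate choice over community detection — the graphs are small and the
notion of "spatially contiguous conserved region" is exactly a component.
Binding-site *sites* are connected components of flagged residues on the
same contact graph (binding pockets are sequence-discontiguous, so sequence
runs would fragment them). A site is covered when any of its residues lies
in a cluster; the enrichment ratio compares the binding fraction among
fully conserved residues with the binding fraction among all residues.

The cluster classifier is a histogram-based gradient-boosting tree on the
cluster feature vector (size, mean rSASA, secondary-structure composition,
mean relative cost, amino-acid class content, mean pLDDT, contact density),
evaluated by ten repeats of stratified five-fold cross-validation.
`min_samples_leaf` is 4 rather than the library default of 20 because
benchmark corpora contain tens of clusters, not thousands. Two null
baselines share folds and seed: labels reassigned at random within
cluster-size quartile strata (random-site), and globally permuted labels.

## Association statistics

Rank correlations use midranks; for n ≤ 8 the p-value is computed by full
permutation enumeration (8! evaluations), beyond that the standard
large-sample approximations apply. Cliff's Δ = (#(a>b) − #(a<b))/(n_a·n_b)
over all cross pairs. Quartile enrichment uses two-sided Fisher tests on
in-tail × in-set tables with boundary ties included in the tail
(deterministic at the cost of exact 25% cardinality), BH-adjusted within
the family of sets tested together. ROC/AUC uses the Mann–Whitney identity
with midrank ties. Missing data are removed pairwise and the n reported.
Phenotype splits exclude 'variable' species, require at least two species
per subgroup, and compare per-orthogroup subgroup means with the paired
two-sided Wilcoxon signed-rank test.

## Synthetic generator

The generator is the benchmark's ground truth, not a fixture: toy folds are
assembled from ideal φ/ψ fragments (helix −57/−47, strand −139/135, ω
180°, standard bond geometry via sequential internal-coordinate placement).
Secondary segments pack on a circle of axes (adjacent spacing 9 Å,
alternating direction; consecutive strands pair antiparallel at the
H-bond-optimal offset found by a cached grid search), coils are fixed-bond
self-avoiding walks bridging segments, and terminal coil tails (6 residues)
walk outward from the bundle. A binding pocket is planted by choosing six
mutually close (≤ 8 Å) central residues — packing the bundle tighter if
needed — placing a small synthetic ligand between them and the pocket
centroid, and *defining* the pocket as the ligand's 5 Å contact set
(exactly how CSb sites are detected, so detection recovers the planted
pocket by construction; typical pocket size 9–17 residues).

Members evolve from the ancestor independently (star phylogeny): per-site
Bernoulli substitution at the residue's class rate with replacement uniform
over the 19 alternatives (expected identity per class is exactly
1 − p_class), Gaussian coordinate noise (default σ 0.5 Å), and terminal
deletions (probability 0.5 per terminus, length 1–6, absorbed by the coil
tails). Default class rates are binding 0.02, core 0.20, surface 0.50 —
the planted hierarchy; cluster-recovery and classifier benchmarks use a
flat 0.40 background against binding 0.02 so the conserved network is
dominated by the planted sites. An optional per-orthogroup rate multiplier
(default range 0.4–1.6 in the coupling benchmarks) creates the divergence
spread across orthogroups that property couplings require. Property tables
couple abundance (positively), flux variability and k_cat variability
(negatively) to the true CR through linear models with Gaussian noise.

For the classifier benchmark, positive examples are conserved clusters
containing planted binding-site residues; negatives are spatially
contiguous random residue balls of matched size, so cluster size cannot
separate the classes and the classifier must exploit physicochemistry
(chiefly burial and composition).

**What the benchmark does not show.** The toy folds have backbone-only
atoms, idealised geometry, a single ~90-residue architecture, and
independent members without phylogenetic covariance; substitutions are
uniform over alternatives rather than exchange-matrix weighted; indels
never occur internally. Passing the planted-recovery tests demonstrates
the pipeline's bookkeeping, geometry and statistics are correct under
known truth — not that real predicted structures meet these assumptions.
Cross-species statistics on real data would additionally face phylogenetic
non-independence, which this package (by design) does not correct.

## Problem sizes

The validation suite runs 100 evolutionary replicates for the hierarchy and
cluster-recovery experiments (25 distinct ancestor folds reused across
replicate histories; ~90-residue folds, 10 members each), 50 corpora of 20
orthogroups for coupling recovery and its null, 200-run null simulations
for test calibration, and 20 seeded corpora for the classifier comparison;
these sizes give binomial standard errors comfortably inside the asserted
margins.

## Known limitations

- The Cα-only secondary-structure fallback is heuristic; full-backbone
  inputs are strongly preferred.
- CSb detection depends on the packaged additive exclusion list; unusual
  crystallisation agents not on the list will be treated as ligands.
- The Gotoh path (secondary-structure bonus enabled) is pure Python and
  markedly slower than the default aligner; use it for small corpora.
- Alternate conformations are resolved to the first conformer at parse
  time rather than strictly by highest occupancy.
- `refine_orthogroups` operates on a precomputed TM matrix; computing that
  matrix is quadratic in orthogroup size.
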
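# structcons

Structure-aware conservation analysis of enzyme orthogroups.

Comparative genomics usually measures sequence divergence in alignment
columns. When predicted structures are available for every orthologue, a
stronger unit of comparison exists: the 1:1 structural correspondence of
residues. `structcons` implements that analysis end to end for groups of
orthologous enzyme structures (orthogroups) anchored to reference
structures, and is aimed at structural bioinformaticians and molecular
evolution groups who want residue-level conservation statistics tied to
metabolic properties.

## What it computes

For each orthogroup with reference structure *r* and members *m*:

- **Residue mapping** — a matchmaker-style alignment: global sequence
  alignment (BLOSUM62, affine gaps) seeds Cα pairs, a Kabsch superposition
  is refined by iteratively pruning pairs with Cα distance > 2 Å, and the
  final 1:1 mapping keeps pairs within 5 Å.
- **Mapping ratio** MR = M/(M+N): the fraction of a member's residues in
  1:1 correspondence with the reference (M mapped, N unmapped).
- **Conservation ratio** CR = C/M: the fraction of mapped residues whose
  amino acid is identical to the reference's; averaged unweighted over
  members. Variants: CR by physicochemical class, CR restricted to
  structural elements, mean octanol–water partition change |ΔlogP|.
- **Structure similarity** — TM-score, TM = (1/L) Σᵢ 1/(1 + (dᵢ/d₀)²) with
  d₀ = max(0.5, 1.24·(L−15)^⅓ − 1.8), symmetrised over both length
  normalisations; orthogroups are refined by average-linkage clustering on
  1 − TM at a cophenetic cutoff of 0.2.
- **Residue features** — Shrake–Rupley solvent accessibility, relative SASA
  surface/core split (rSASA ≥ 0.25 ⇒ surface), hydrogen-bond based
  secondary structure (helix/extended/turn/coil), contact-site binding
  residues near retained ligands (CSb, 5 Å heavy-atom) and curated
  binding-site annotations (UPb).
- **Conserved clusters** — fully conserved residues (identical and mapped
  in every aligned member) form a contact graph (Cα ≤ 10 Å); connected
  components of ≥ 3 residues are clusters, scored for binding-site overlap
  and classified (histogram-based gradient boosting, 10×5-fold CV, two null
  baselines).
- **Cost & composition** — per-residue biosynthetic cost metrics
  (ATP-equivalent, opportunity cost, residue weight; median-normalised) and
  amino-acid composition per structural element.
- **Association statistics** — Spearman/Kendall/Pearson correlations,
  Mann–Whitney and Wilcoxon signed-rank tests with Cliff's Δ, quartile
  Fisher enrichment, ROC/AUC enrichment, Benjamini–Hochberg adjustment, and
  phenotype-based orthogroup subgrouping.
- **Synthetic benchmark** — a generator of toy folds (ideal φ/ψ fragments
  packed into bundles) evolved with planted class-dependent substitution
  rates (binding < core < surface), coordinate noise, terminal indels and
  property tables coupled to the true divergence. Every analysis above is
  validated against this planted ground truth.

## Worked example

```python
from structcons import ConservationAnalysis, SyntheticSpec, generate_corpus

spec = SyntheticSpec(seed=7, n_orthogroups=5, n_members=(8, 8),
                     og_rate_range=(0.5, 1.5))
orthogroups, truths = generate_corpus(spec)
results = ConservationAnalysis(list(orthogroups.values())).fit()
print(results.summary())
```

```
Structure-aware conservation analysis
======================================================
Orthogroups fitted:        5
Members aligned (total):   40   (failures: 0)
Median MR:                 0.988   (IQR 0.983-0.992)
Median CR:                 0.630   (IQR 0.608-0.709)
Element CR medians:
  core       0.783
  surface    0.453
  helix      0.714
  extended   0.585
  turn       0.444
  coil       0.589
  csb        0.975
Conserved clusters/OG:     median 1.00
Cluster size:              median 12.00 residues
```

Nearly every member residue maps onto the reference (median MR 0.99: the
members are the same fold with noise and short terminal truncations), while
the median CR of 0.63 reflects the planted substitution rates. The element
breakdown shows the planted conservation hierarchy: binding-site residues
(csb, CR 0.98) are the most conserved, the buried core (0.78) is more
conserved than the solvent-exposed surface (0.45). `results.orthogroup_table`
holds the per-orthogroup values; `results.associate(...)` correlates CR with
property tables; `results.cluster_table()` and `results.cluster_overlap()`
expose the conserved clusters.

The same analysis runs from the shell over PDB files plus a manifest TSV:

```bash
structcons run --seed 3 --out pipeline_out --preset small
```

which writes mappings, per-orthogroup and per-residue conservation tables,
feature/cluster/cost reports, association statistics and a `summary.json`
whose checksums are bit-identical for identical configuration and seed.

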
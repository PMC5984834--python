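# gcfkit

Comparative analysis of biosynthetic gene clusters (BGCs) across a bacterial
genus. Actinobacteria such as *Amycolatopsis* carry dozens of secondary-
metabolite pathways per chromosome; the questions this package addresses are
how those clusters group into **gene cluster families** (GCFs), how family
repertoires track strain phylogeny, how much pathway diversity remains
unsampled, where clusters sit on the chromosome relative to the replication
origin, and whether strains belong to the same genus at all. It is aimed at
microbial comparative genomicists who already have per-gene BGC annotations
(classes, Pfam domains, proteins) and want the family-level analysis layer.

## What it computes

* **Domain-content similarity network.** For BGCs *a*, *b* with domain sets
  *D<sub>a</sub>*, *D<sub>b</sub>* and copy numbers *a<sub>d</sub>*,
  *b<sub>d</sub>*:
  Jaccard *J = |D<sub>a</sub> ∩ D<sub>b</sub>| / |D<sub>a</sub> ∪ D<sub>b</sub>|*,
  domain duplication index
  *DDI = 1 − Σ|a<sub>d</sub> − b<sub>d</sub>| / Σ max(a<sub>d</sub>, b<sub>d</sub>)*,
  combined *S = 0.36 J + 0.64 DDI*; edges where *S ≥ 0.65*; connected
  components are candidate families.
* **Rule-based GCF assignment.** Two clusters join a family when they have
  (I) similar architecture, (II) mostly shared gene functions in any order,
  (III) a majority of genes with homologs at ≥ 50 % identity over ≥ 80 %
  coverage (Smith–Waterman, BLOSUM62, or a supplied hit table), and (IV) for
  modular PKS/NRPS clusters, KS/C domains ≥ 80 % identical at matching module
  positions; relations are closed by single linkage. Families are *common*
  (≥ 4 strains), *rare* (2–3) or *unique* (1).
* **Presence/absence profiling.** Strain × family 0/1 matrix, Dice
  coefficient *2|A∩B|/(|A|+|B|)*, UPGMA dendrogram (distance = 1 − Dice),
  and analytic sample-based rarefaction
  *S̃(k) = S<sub>obs</sub> − Σ<sub>j</sub> C(n−n<sub>j</sub>, k)/C(n, k)* per clade.
* **oriC-relative genome location.** Circular chromosomes are linearized at
  *dnaA* (mirrored when *dnaA* is on the minus strand); BGC midpoints become
  downstream fractions of genome length, binned into 8 regions, tested for
  positional conservation within clades, and intersected with
  conserved/hypervariable intervals.
* **POCP genus delimitation.** Percentage of conserved proteins
  *(C<sub>a</sub>+C<sub>b</sub>)/(T<sub>a</sub>+T<sub>b</sub>)×100* with the
  e-value ≤ 1e−5 / identity ≥ 40 % / aligned fraction ≥ 50 % cutoffs; ≥ 50 %
  means same genus.
* **Synthetic genus generator.** Planted core/clade/rare/unique families,
  clade structure, controlled protein divergence and a variable region
  opposite oriC, with full ground truth — every stage above is validated
  against it.

## Worked example

The numbered drivers under `analysis/` run the whole study on the synthetic
genus (4 clades × 5 strains + 2 outliers, seed 42) and write their tables to
`results/`:

```
$ python analysis/01_simulate.py
simulated 22 genomes with 425 BGCs in 180 planted families (seed 42)
family tiers: {'core': 5, 'clade': 32, 'rare': 10, 'unique': 133}
unique-family fraction: 74%

$ python analysis/03_gcf_assignment.py
425 BGCs -> 180 families; categories: {'common': 37, 'rare': 10, 'unique': 133}
assignment vs planted truth: ARI = 1.000

$ python analysis/05_genome_location.py
bin totals: [55, 75, 26, 55, 53, 29, 85, 47] (sum 425)
clade-tier families positionally conserved: 100%
unique/rare density in variable-region bins vs flanks: 77.5x
```

Read: the criteria-based assignment reconstructs all 180 planted families
exactly (adjusted Rand index 1.0); the 37 common families are the planted
core + clade tiers; unique families dominate the catalogue, and horizontally
acquired (unique/rare) clusters pile up in the variable region opposite the
origin, as they do on real actinobacterial chromosomes. `02` builds the
similarity network, `04` the Dice/UPGMA profile and rarefaction curves, and
`06` POCP between strain pairs (within-clade pair 79.7 % — same genus;
outlier pair 47.2 % — different genus).

The same stages are available as subcommands of the `gcfkit` CLI
(`simulate`, `network`, `gcf`, `profile`, `rarefy`, `locate`, `pocp`,
`run-all`) operating on the documented TSV/FASTA/BED formats, and as a
single `run_pipeline(PipelineConfig)` call driven by a YAML config.

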
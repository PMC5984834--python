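# Methods

## Data model and conventions

All coordinates are 0-based, half-open, in the forward frame of the deposited
sequence; readers convert 1-based inputs. A genome is a single circular
chromosome (plasmids and multi-replicon strains are out of scope); intervals
may wrap the coordinate origin, written with `end > length`. BGCs carry a
class (PKS, NRPS, PKS/NRPS-hybrid, RiPP, Terpene, Other), a gene list with
free-form functional role labels, an aggregated Pfam-domain multiset, and —
for modular classes — ordered ketosynthase (KS) and condensation (C) domains
indexed by module position.

## Similarity network

Pairwise similarity is a weighted sum of the Jaccard index over distinct
domain accessions and a copy-number-aware domain duplication index,
`DDI = 1 − Σ|a_d − b_d| / Σ max(a_d, b_d)` (equivalently `Σmin/Σmax`). The
literature behind this construction describes the combination qualitatively
but prints no formula; this form is used because it is exactly 1 for
identical count vectors, 0 for disjoint clusters, symmetric, and trivially
oracle-testable. Weights default to 0.36/0.64 (the conventional
Jaccard-light weighting for domain-content networking) and are configurable;
the edge threshold defaults to 0.65, the value that best separates
hand-curated families in genus-scale actinobacterial data. Edges use
`similarity ≥ threshold`; components are labelled by their lexicographically
smallest member so the partition is independent of input order. Two clusters
with no annotated domains score 0, not 1: missing annotation is no evidence
of relatedness.

## Family criteria

"Similar architecture" (criterion I) is operationalized as class identity
plus multiset-Jaccard over gene roles ≥ 0.5, since the original judgement was
manual. "Majority" is strict (> 50 %) and denominators always use the smaller
cluster's gene count, which makes every criterion symmetric by construction.
Criterion III uses deterministic local alignment (BLOSUM62, gap open −11 /
extend −1); identity is matches over aligned columns and coverage is the
aligned span of the shorter sequence over its length. A precomputed hit
table (query, subject, identity, query coverage, e-value) can replace
alignment, reproducing a BLAST-based workflow. Criterion IV pairs KS and C
domains by module index up to the shorter module list; surplus modules do
not veto membership, and clusters of modular classes without module
annotation get a not-applicable verdict that also does not veto. Pairwise
relations are resolved by single-linkage connected components — the same
treatment a thresholded network applies — so non-transitive pairwise
verdicts cannot produce overlapping families. Only same-class pairs are
evaluated; cross-class pairs fail criterion I by definition.

## Profiles, UPGMA, rarefaction

The presence/absence matrix is binary (copy number within a strain is
ignored) with columns ordered by consensus class and then descending
abundance. Strain distance is 1 − Dice; the Dice-to-distance transform is a
package choice, exposed in the API, as the original toolchain does not state
one. UPGMA is implemented directly rather than delegated, because the
contract fixes tie-breaking (lowest-index pair), node heights (half the
merge distance) and child ordering (smallest original leaf first), and the
tests require an independent naive recompute-all-averages oracle; a library
call on both sides would collapse that dual route. Output trees are
ultrametric by construction and serialized as Newick. Rarefaction is the
analytic sample-based (incidence) estimator
`S̃(k) = S_obs − Σ_j C(n−n_j, k)/C(n, k)` with exact binomial coefficients;
a Monte-Carlo resampling mode exists as a cross-check. Extrapolation beyond
the sample (Chao-type) is deliberately not attempted.

## Genome location

Linearization uses the dnaA gene start as the origin proxy; with dnaA on the
minus strand, coordinates are mirrored first (the analysis frame is then the
reverse complement), i.e. `p = ((L − m + dnaA_start) mod L)/L` for midpoint
`m`. A BGC's position is its interval midpoint (circular midpoint when the
interval wraps); midpoints are robust to boundary trimming, which cluster
start/ends are not. Densities bin `floor(p·n_bins)` over 8 equal regions by
default. A family is positionally conserved within a clade when the largest
pairwise circular distance between member positions is ≤ 0.05 of genome
length; a BGC is hypervariable-resident when > 50 % of its span lies outside
the supplied conserved intervals. Both thresholds formalize qualitative
visual judgements and are configurable.

## POCP

POCP follows the established procedure: a protein is conserved when it has a
hit at e-value ≤ 1e−5, identity ≥ 40 % and alignable region ≥ 50 % of its
length; `POCP = (C_a + C_b)/(T_a + T_b) × 100`, same genus at ≥ 50 %. In the
self-contained alignment mode (small proteomes, all-vs-all Smith–Waterman)
no database e-value exists, so only the identity and aligned-fraction
cutoffs apply — fabricating an e-value model was rejected. Larger proteomes
must come as external hit tables.

## Synthetic genus

The generator's defaults are the study conditions: 4 clades × 5 strains + 2
outliers, 1 Mbp circular chromosomes, 5 core + 8-per-clade + 10 rare
families and Poisson(6) unique families per strain (the per-strain novelty
rate observed in genus-scale actinobacterial sampling), domain alphabet of
300 accessions, domain gain/loss probability 0.05 per type per instance,
copy jitter 0.1, within-family divergence 0.15 substitutions/site.
Substitution is a uniform 20-state jump process (Poisson events per site),
giving the closed-form expected identity `1/20 + (19/20)·exp(−(20/19)d)`;
no indels by default so identity is analytically predictable. KS/C-carrying
genes mutate at 0.05 substitutions/site, reflecting the strong conservation
of these domains in nature; without this, member pairs would sit near 74 %
identity and the 80 % module-identity criterion could not hold for genuine
families. Core and clade families occupy fixed oriC-relative slots in the
conserved backbone with ±0.01 positional noise (below the 0.05 conservation
tolerance); rare and unique families land uniformly in the variable region
(default arc 0.3–0.7 opposite oriC), whose complement is emitted as the
conserved intervals. The clade tree is a star of cherries with nominal
branch lengths. With ~180 families the realized unique fraction is ~74 %.

What the generator does **not** emulate: nucleotide sequence, intergenic
DNA, realistic Pfam grammars of real BGC classes, gene gain/loss within
families, unequal module counts, or genome rearrangements. Passing tests
therefore demonstrate that the statistics and rules are implemented
correctly and recover structure of this planted kind; they do not certify
recovery rates on real genomes, where annotation noise and within-family
architectural variation are larger.

## Clade recovery evaluation

Planted-clade recovery is scored by cutting the UPGMA dendrogram of the
clade strains into `n_clades` groups and requiring each clade to appear as
exactly one group. Outlier strains are excluded from the cut: they share
only the core families with everyone, so they legitimately pair with each
other at intermediate Dice similarity, and a cut sized to include them
measures outlier behaviour rather than clade signal. (The general
`UpgmaTree.cut(k)` supports any k, and on the default seed a 6-way cut of
all 22 strains also isolates the four clades.)

## Problem sizes and numerics

Analysis drivers and the acceptance script run the default 22-genome genus
(~425 BGCs, ~2,500 proteins of 120 aa); multi-seed checks use 5–20 seeds
and property tests use 200–1,000 random instances — sizes chosen so the
planted effects are measured with comfortable margins while the whole study
stays desk-scale. Alignment is exact (no heuristics), so all results are
deterministic given the seed; UPGMA tie-breaks and component labels are
fixed as above, and the pipeline writes a manifest of SHA-256 checksums to
make run-to-run identity checkable.

## Known limitations

The network and criteria routes are validated against each other and against
planted truth, not against curated family catalogues. The ectoine-style
"primary metabolite" exclusion the original workflow applied is available
only as an upstream filter on the input table, not a built-in list. POCP on
full proteomes requires external search results; the built-in alignment mode
exists for desk-scale verification.
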
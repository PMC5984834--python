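"""Synthetic genomes with planted gene-cluster-family structure.

The generator emulates a genus-scale comparative dataset: several
phylogenetic clades of strains plus outlier strains, with GCFs planted
in four tiers —

* core: present in every strain, at a fixed oriC-relative position in
  the conserved backbone;
* clade: present in every strain of one clade, again positionally
  conserved (vertical inheritance);
* rare: present in 2-3 strains drawn across clades, placed at random
  positions in the variable region (older horizontal transfers);
* unique: present in a single strain, uniform in the variable region
  (recent horizontal acquisitions).

Within a family, instances diverge by protein substitution, domain
gain/loss and copy-number jitter; between families, domain content and
sequences are unrelated.  The emitted ground truth (family labels,
tiers, positional classes, clade tree) lets every downstream stage be
scored against the planted structure.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .model import (
    BgcRecord,
    DomainCount,
    GeneRecord,
    GenomeRecord,
    MODULAR_CLASSES,
    ValidationError,
)
from .io import merge_intervals

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

_BASE_ROLES = [
    "transporter", "regulator", "oxidoreductase", "methyltransferase",
    "glycosyltransferase", "halogenase", "cytochrome-P450", "thioesterase",
    "dehydratase", "aminotransferase",
]


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the synthetic genus.

    Defaults describe four clades of five strains plus two outliers on
    1 Mbp chromosomes, with a variable region spanning the 30-70%
    arc opposite oriC.  Protein divergence within a family is 0.15
    substitutions/site relative to the family seed (0.05 for modular
    KS/C-carrying genes, which are strongly conserved in nature).
    """

    n_clades: int = 4
    strains_per_clade: int = 5
    n_outlier_strains: int = 2
    genome_length: int = 1_000_000
    n_core_gcfs: int = 5
    n_clade_gcfs_per_clade: int = 8
    n_rare_gcfs: int = 10
    mean_unique_per_strain: float = 6.0
    domain_alphabet_size: int = 300
    domain_gain_loss_prob: float = 0.05
    copy_jitter_prob: float = 0.1
    within_gcf_protein_divergence: float = 0.15
    module_domain_divergence: float = 0.05
    between_gcf_identity_ceiling: float = 0.3
    variable_region: tuple[float, float] = (0.3, 0.7)
    core_region_positions: Optional[tuple[float, ...]] = None
    protein_length: int = 120
    genes_min: int = 4
    genes_max: int = 8
    position_noise: float = 0.01
    role_vocabulary_size: int = 80
    allow_indels: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("domain_gain_loss_prob", "copy_jitter_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0,1]")
        lo, hi = self.variable_region
        if not (0.0 <= lo < hi < 1.0):
            raise ValidationError("variable_region must be within [0,1)")
        if self.position_noise < 0 or self.position_noise > 0.02:
            raise ValidationError("position_noise must be in [0, 0.02]")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the generated genomes."""

    gcf_of: dict[str, str]                   # bgc_id -> planted family
    tier_of: dict[str, str]                  # family -> core/clade/rare/unique
    positional_class: dict[str, str]         # bgc_id -> conserved-position/variable-region
    clade_of: dict[str, str]                 # genome_id -> clade label
    tree_newick: str = ""
    params: Optional[SimulationParams] = None

    def families(self) -> list[str]:
        return sorted(self.tier_of)


@dataclass
class ClusterArchetype:
    """The family seed from which member BGCs are instantiated."""

    gcf_id: str
    tier: str
    bgc_class: str
    roles: list[str]
    gene_domains: list[list[tuple[str, int]]]    # per gene: (accession, copies)
    seed_proteins: list[str]
    module_domains: list[tuple[tuple[str, int], ...]]  # per gene
    position: Optional[float] = None             # oriC-relative, conserved tiers

    @property
    def n_genes(self) -> int:
        return len(self.roles)


# --------------------------------------------------------------- mutation


def mutate_protein(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Apply a Poisson(divergence) number of uniform substitutions per site.

    Each event replaces the current residue with one of the 19 others,
    so the expected identity to the seed is
    1/20 + (19/20) * exp(-(20/19) * divergence).
    """
    if divergence == 0:
        return seq
    arr = np.array(list(seq))
    counts = rng.poisson(divergence, size=len(arr))
    for i in np.nonzero(counts)[0]:
        for _ in range(counts[i]):
            choices = AMINO_ACIDS[AMINO_ACIDS != arr[i]]
            arr[i] = rng.choice(choices)
    return "".join(arr)


def expected_identity(divergence: float) -> float:
    """Closed-form expected identity to the seed after mutation."""
    return 1 / 20 + (19 / 20) * np.exp(-(20 / 19) * divergence)


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def _domain_accession(i: int) -> str:
    return f"PF{i + 1:05d}"


# -------------------------------------------------------------- archetypes


def _make_archetype(
    gcf_id: str, tier: str, params: SimulationParams, rng: np.random.Generator,
    roles_vocab: list[str], position: Optional[float],
) -> ClusterArchetype:
    bgc_class = str(rng.choice(
        ["PKS", "NRPS", "PKS/NRPS-hybrid", "RiPP", "Terpene", "Other"],
        p=[0.3, 0.3, 0.1, 0.12, 0.08, 0.1],
    ))
    n_genes = int(rng.integers(params.genes_min, params.genes_max + 1))
    roles = list(rng.choice(roles_vocab, size=n_genes, replace=False))
    gene_domains = []
    for _ in range(n_genes):
        n_dom = int(rng.integers(1, 4))
        accs = rng.choice(params.domain_alphabet_size, size=n_dom, replace=False)
        gene_domains.append(
            [(_domain_accession(int(a)), int(rng.integers(1, 3))) for a in accs]
        )
    proteins = [_random_protein(params.protein_length, rng) for _ in range(n_genes)]
    module_domains: list[tuple[tuple[str, int], ...]] = [() for _ in range(n_genes)]
    if bgc_class in MODULAR_CLASSES:
        n_modules = int(rng.integers(2, min(5, n_genes) + 1))
        kinds = {"PKS": ["KS"], "NRPS": ["C"], "PKS/NRPS-hybrid": ["KS", "C"]}[bgc_class]
        next_index = {k: 1 for k in kinds}
        for m in range(n_modules):
            kind = kinds[m % len(kinds)]
            module_domains[m] = ((kind, next_index[kind]),)
            next_index[kind] += 1
    return ClusterArchetype(
        gcf_id=gcf_id, tier=tier, bgc_class=bgc_class, roles=roles,
        gene_domains=gene_domains, seed_proteins=proteins,
        module_domains=module_domains, position=position,
    )


def instantiate_cluster(
    archetype: ClusterArchetype,
    params: SimulationParams,
    rng: np.random.Generator,
    genome_id: str,
    bgc_id: str,
    start: int,
) -> BgcRecord:
    """Realize one member BGC of a family on a genome.

    Domain types are gained/lost with ``domain_gain_loss_prob``, copy
    numbers jittered with ``copy_jitter_prob``, proteins mutated by the
    per-site substitution process (modular KS/C genes at the lower
    ``module_domain_divergence``), and adjacent genes occasionally
    swapped — family membership is order-insensitive.
    """
    n = archetype.n_genes
    order = list(range(n))
    # local shuffle: swap one adjacent pair half the time
    if n > 1 and rng.random() < 0.5:
        i = int(rng.integers(0, n - 1))
        order[i], order[i + 1] = order[i + 1], order[i]

    gene_len = 3 * params.protein_length
    gap = 100
    genes = []
    pos = start
    dom_counts: dict[str, int] = {}
    for rank, gi in enumerate(order):
        div = (
            params.module_domain_divergence
            if archetype.module_domains[gi]
            else params.within_gcf_protein_divergence
        )
        protein = mutate_protein(archetype.seed_proteins[gi], div, rng)
        gdoms = []
        for acc, copies in archetype.gene_domains[gi]:
            if rng.random() < params.domain_gain_loss_prob:
                continue  # domain type lost in this instance
            if rng.random() < params.copy_jitter_prob:
                copies = max(1, copies + int(rng.choice([-1, 1])))
            gdoms.append((acc, copies))
        if rng.random() < params.domain_gain_loss_prob:
            acc = _domain_accession(int(rng.integers(params.domain_alphabet_size)))
            gdoms.append((acc, 1))
        for acc, c in gdoms:
            dom_counts[acc] = dom_counts.get(acc, 0) + c
        genes.append(
            GeneRecord(
                gene_id=f"{bgc_id}_g{gi + 1}",
                start=pos,
                end=pos + gene_len,
                strand="+" if rng.random() < 0.7 else "-",
                role=archetype.roles[gi],
                protein=protein,
                module_domains=archetype.module_domains[gi],
            )
        )
        pos += gene_len + gap
    end = pos - gap
    return BgcRecord(
        bgc_id=bgc_id,
        genome_id=genome_id,
        bgc_class=archetype.bgc_class,
        start=start,
        end=end,
        genes=genes,
        domains=[DomainCount(a, c) for a, c in sorted(dom_counts.items())],
        source="own",
    )


# ------------------------------------------------------------- generation


def cluster_span(archetype: ClusterArchetype, params: SimulationParams) -> int:
    return archetype.n_genes * (3 * params.protein_length + 100) - 100


def _rel_to_genomic(
    a: float, b: float, genome: GenomeRecord
) -> list[tuple[int, int]]:
    """Map an oriC-relative interval [a, b) to genomic bp intervals,
    splitting at the origin when it wraps."""
    L = genome.length
    if genome.dnaA_strand == "+":
        s, e = genome.dnaA_start + a * L, genome.dnaA_start + b * L
    else:
        s, e = genome.dnaA_start - b * L, genome.dnaA_start - a * L
    s, e = s % L, s % L + (b - a) * L
    s_i, e_i = int(round(s)), int(round(e))
    if e_i <= L:
        return [(s_i, e_i)]
    return [(s_i, L), (0, e_i - L)]


def _genomic_start_for(p: float, span: int, genome: GenomeRecord) -> int:
    """Genomic start so that the cluster midpoint sits at oriC-relative p."""
    L = genome.length
    if genome.dnaA_strand == "+":
        m = (genome.dnaA_start + p * L) % L
    else:
        m = (genome.dnaA_start - p * L) % L
    return int(round(m - span / 2)) % L


def generate_dataset(
    params: SimulationParams = SimulationParams(),
) -> tuple[list[GenomeRecord], SyntheticTruth]:
    """Generate the synthetic genus and its ground truth.

    Deterministic for a fixed ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    clades = list(string.ascii_uppercase[: params.n_clades])
    strain_ids = [f"{c}{i + 1}" for c in clades for i in range(params.strains_per_clade)]
    outliers = [f"X{i + 1}" for i in range(params.n_outlier_strains)]
    clade_of = {s: s[0] for s in strain_ids}
    clade_of.update({o: "singleton" for o in outliers})
    all_strains = strain_ids + outliers

    vocab = _BASE_ROLES + [
        f"enzyme_{i:03d}" for i in range(params.role_vocabulary_size - len(_BASE_ROLES))
    ]

    lo, hi = params.variable_region
    margin = 0.05
    # slot positions for positionally conserved tiers, in the backbone
    n_slots = params.n_core_gcfs + params.n_clade_gcfs_per_clade
    backbone = (1.0 - lo) if hi >= 1.0 else (lo + (1.0 - hi))
    usable = backbone - 2 * margin * 2
    if usable <= 0:
        raise ValidationError("variable_region leaves no conserved backbone")
    slots = []
    seg1 = lo - 2 * margin          # usable width before the variable region
    seg2 = (1.0 - hi) - 2 * margin  # and after it
    for i in range(n_slots):
        t = (i + 0.5) / n_slots * (seg1 + seg2)
        if t < seg1:
            slots.append(margin + t)
        else:
            slots.append(hi + margin + (t - seg1))
    if params.core_region_positions is not None:
        if len(params.core_region_positions) < params.n_core_gcfs:
            raise ValidationError("not enough core_region_positions")
        core_positions = list(params.core_region_positions[: params.n_core_gcfs])
    else:
        core_positions = slots[: params.n_core_gcfs]
    clade_slot = slots[params.n_core_gcfs:]

    archetypes: list[ClusterArchetype] = []
    membership: dict[str, list[str]] = {}
    for i in range(params.n_core_gcfs):
        a = _make_archetype(f"core_{i + 1:02d}", "core", params, rng, vocab,
                            core_positions[i])
        archetypes.append(a)
        membership[a.gcf_id] = list(all_strains)
    for c in clades:
        for i in range(params.n_clade_gcfs_per_clade):
            a = _make_archetype(f"clade{c}_{i + 1:02d}", "clade", params, rng,
                                vocab, clade_slot[i])
            archetypes.append(a)
            membership[a.gcf_id] = [s for s in strain_ids if s[0] == c]
    for i in range(params.n_rare_gcfs):
        a = _make_archetype(f"rare_{i + 1:02d}", "rare", params, rng, vocab, None)
        archetypes.append(a)
        k = int(rng.integers(2, 4))
        membership[a.gcf_id] = sorted(rng.choice(all_strains, size=k, replace=False))
    for s in all_strains:
        for i in range(rng.poisson(params.mean_unique_per_strain)):
            a = _make_archetype(f"uniq_{s}_{i + 1:02d}", "unique", params, rng,
                                vocab, None)
            archetypes.append(a)
            membership[a.gcf_id] = [s]

    total_span = sum(
        cluster_span(a, params) * len(membership[a.gcf_id]) for a in archetypes
    ) / len(all_strains)
    if total_span > 0.8 * params.genome_length:
        raise ValidationError(
            "planted clusters would exceed 80% of the genome; "
            "increase genome_length or reduce cluster numbers"
        )

    genomes: list[GenomeRecord] = []
    truth = SyntheticTruth(
        gcf_of={}, tier_of={a.gcf_id: a.tier for a in archetypes},
        positional_class={}, clade_of=dict(clade_of), params=params,
    )
    by_strain: dict[str, list[ClusterArchetype]] = {s: [] for s in all_strains}
    for a in archetypes:
        for s in membership[a.gcf_id]:
            by_strain[s].append(a)

    for s in all_strains:
        L = params.genome_length
        genome = GenomeRecord(
            genome_id=s,
            length=L,
            topology="circular",
            dnaA_start=int(rng.integers(0, L)),
            dnaA_strand="+" if rng.random() < 0.5 else "-",
            clade=clade_of[s],
        )
        occupied: list[tuple[float, float]] = []

        def try_place(p: float, width: float) -> bool:
            for q0, q1 in occupied:
                if p - width / 2 < q1 and q0 < p + width / 2:
                    return False
            occupied.append((p - width / 2, p + width / 2))
            return True

        for a in by_strain[s]:
            span = cluster_span(a, params)
            width = span / L
            if a.position is not None:
                p = a.position + rng.uniform(-params.position_noise,
                                             params.position_noise)
                if not try_place(p, width):
                    occupied.append((p - width / 2, p + width / 2))
                pclass = "conserved-position"
            else:
                placed = False
                for _ in range(200):
                    p = rng.uniform(lo + margin / 2, hi - margin / 2)
                    if try_place(p, width):
                        placed = True
                        break
                if not placed:
                    raise ValidationError(
                        f"cannot place cluster {a.gcf_id} on genome {s}: "
                        "variable region too crowded"
                    )
                pclass = "variable-region"
            bgc_id = f"{s}__{a.gcf_id}"
            start = _genomic_start_for(p % 1.0, span, genome)
            bgc = instantiate_cluster(a, params, rng, s, bgc_id, start)
            genome.bgcs.append(bgc)
            truth.gcf_of[bgc_id] = a.gcf_id
            truth.positional_class[bgc_id] = pclass
        pieces = _rel_to_genomic(0.0, lo, genome) + _rel_to_genomic(hi, 1.0, genome)
        genome.conserved_intervals = merge_intervals(
            [(s0, min(e0, L)) for s0, e0 in pieces if e0 > s0]
        )
        genomes.append(genome)

    truth.tree_newick = _star_of_cherries(clades, params, outliers)
    return genomes, truth


def _star_of_cherries(clades, params: SimulationParams, outliers) -> str:
    """Clade polytomies hanging off an unresolved root; nominal branch
    lengths (no realism claimed)."""
    parts = []
    for c in clades:
        leaves = ",".join(
            f"{c}{i + 1}:0.1" for i in range(params.strains_per_clade)
        )
        parts.append(f"({leaves}):0.9")
    parts += [f"{o}:1.0" for o in outliers]
    return "(" + ",".join(parts) + ");"


# ----------------------------------------------------------------- export


def write_dataset(
    genomes: list[GenomeRecord], truth: SyntheticTruth, outdir: str | Path
) -> dict[str, Path]:
    """Emit the dataset in the pipeline's own input formats plus truth
    tables, so every stage can be driven from files alone."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "bgc_table": outdir / "bgcs.tsv",
        "genome_table": outdir / "genomes.tsv",
        "proteins": outdir / "proteins.faa",
        "truth": outdir / "truth.tsv",
        "tree": outdir / "clades.nwk",
        "params": outdir / "params.yaml",
    }
    with open(paths["bgc_table"], "w") as fh:
        fh.write("\t".join([
            "genome_id", "bgc_id", "bgc_class", "bgc_start", "bgc_end",
            "gene_id", "gene_start", "gene_end", "strand", "role",
            "domains", "module_domains", "protein_id",
        ]) + "\n")
        for g in genomes:
            for b in g.bgcs:
                per_gene_domains = _split_domains_per_gene(b)
                for gene, doms in zip(b.genes, per_gene_domains):
                    fh.write("\t".join([
                        g.genome_id, b.bgc_id, b.bgc_class,
                        str(b.start), str(b.end),
                        gene.gene_id, str(gene.start), str(gene.end),
                        gene.strand, gene.role,
                        ";".join(f"{a}:{c}" for a, c in doms),
                        ";".join(f"{k}:{i}" for k, i in gene.module_domains),
                        gene.gene_id,
                    ]) + "\n")
    with open(paths["genome_table"], "w") as fh:
        fh.write("genome_id\tlength\ttopology\tdnaA_start\tdnaA_strand\tclade\n")
        for g in genomes:
            fh.write(
                f"{g.genome_id}\t{g.length}\t{g.topology}\t{g.dnaA_start}\t"
                f"{g.dnaA_strand}\t{g.clade or ''}\n"
            )
    with open(paths["proteins"], "w") as fh:
        for g in genomes:
            for b in g.bgcs:
                for gene in b.genes:
                    if gene.protein:
                        fh.write(f">{gene.gene_id}\n{gene.protein}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("bgc_id\tgcf\ttier\tpositional_class\n")
        for bid in sorted(truth.gcf_of):
            fam = truth.gcf_of[bid]
            fh.write(
                f"{bid}\t{fam}\t{truth.tier_of[fam]}\t"
                f"{truth.positional_class[bid]}\n"
            )
    paths["tree"].write_text(truth.tree_newick + "\n")
    for g in genomes:
        bed = outdir / f"conserved_{g.genome_id}.bed"
        with open(bed, "w") as fh:
            for s, e in g.conserved_intervals or []:
                fh.write(f"{g.genome_id}\t{s}\t{e}\n")
    with open(paths["params"], "w") as fh:
        yaml.safe_dump(asdict(truth.params), fh) if truth.params else None
    return paths


def _split_domains_per_gene(bgc: BgcRecord) -> list[list[tuple[str, int]]]:
    """Distribute the cluster-level domain multiset back over genes for
    the table export; gene-level detail is not tracked beyond this."""
    per_gene: list[list[tuple[str, int]]] = [[] for _ in bgc.genes]
    items = sorted(bgc.domain_counts.items())
    if not bgc.genes:
        return per_gene
    for i, (acc, copies) in enumerate(items):
        per_gene[i % len(bgc.genes)].append((acc, copies))
    return per_gene
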
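"""Assignment of BGCs to gene cluster families (GCFs).

Two clusters belong to the same family when four criteria hold:

I.   similar architecture — same BGC class and substantial overlap of
     the gene-role repertoires;
II.  the majority of genes (of the smaller cluster) have a functional
     counterpart in the other cluster, order-insensitively;
III. the majority of genes have a homolog at >= 50% identity over
     >= 80% coverage;
IV.  for modular PKS/NRPS clusters, KS and C domains at the same module
     position are compared and the majority must exceed 80% identity.

Pairwise relations are resolved into families by single-linkage
connected components.  Family frequency categories follow strain
counts: common (>= 4 strains), rare (2-3), unique (1).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .model import BgcRecord, HitRecord, MODULAR_CLASSES, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GcfCriteriaParams:
    gene_identity_min: float = 0.50
    gene_coverage_min: float = 0.80
    module_domain_identity_min: float = 0.80
    majority_fraction: float = 0.5  # strictly greater than
    architecture_role_jaccard_min: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "gene_identity_min", "gene_coverage_min",
            "module_domain_identity_min", "majority_fraction",
            "architecture_role_jaccard_min",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0,1], got {v}")


@dataclass
class CriteriaReport:
    """Per-criterion outcome for one BGC pair.

    A criterion is ``None`` when not applicable (IV outside modular
    classes, or no module annotation on either side) or when evaluation
    was short-circuited by an earlier failure.
    """

    bgc_a: str
    bgc_b: str
    architecture: Optional[bool] = None
    function: Optional[bool] = None
    identity: Optional[bool] = None
    modules: Optional[bool] = None
    same_gcf: bool = False
    warnings: list[str] = field(default_factory=list)


@dataclass
class GcfPartition:
    """Disjoint families covering all own-source BGCs."""

    family_of: dict[str, str]                 # bgc_id -> family_id
    members: dict[str, list[str]]             # family_id -> sorted bgc ids
    strains: dict[str, set[str]]              # family_id -> strain set
    consensus_class: dict[str, str]           # family_id -> majority class
    category: dict[str, str] = field(default_factory=dict)

    @property
    def family_ids(self) -> list[str]:
        return sorted(self.members)


# -------------------------------------------------------------- alignment

_aligner = Align.PairwiseAligner()
_aligner.mode = "local"
_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
_aligner.open_gap_score = -11.0
_aligner.extend_gap_score = -1.0


def local_align(seq_a: str, seq_b: str) -> tuple[float, float, float]:
    """Smith-Waterman alignment under BLOSUM62 with affine gaps.

    Returns (identity, coverage_a, coverage_b): identity is matches over
    aligned columns (gap columns included); coverage is the aligned span
    on each sequence as a fraction of its length.  A pair with no
    positive-scoring alignment returns (0, 0, 0).
    """
    if not seq_a or not seq_b:
        raise ValidationError("cannot align an empty sequence")
    alignments = _aligner.align(seq_a, seq_b)
    try:
        aln = alignments[0]
    except IndexError:
        return 0.0, 0.0, 0.0
    if aln.score <= 0 or aln.length == 0:
        return 0.0, 0.0, 0.0
    identities = aln.counts().identities
    identity = identities / aln.length
    span_a = aln.coordinates[0][-1] - aln.coordinates[0][0]
    span_b = aln.coordinates[1][-1] - aln.coordinates[1][0]
    return identity, span_a / len(seq_a), span_b / len(seq_b)


def align_identity(seq_a: str, seq_b: str) -> tuple[float, float]:
    """Identity and coverage of the shorter sequence, symmetric in its
    arguments (the shorter sequence is treated as the query; ties broken
    lexicographically)."""
    if (len(seq_a), seq_a) > (len(seq_b), seq_b):
        seq_a, seq_b = seq_b, seq_a
    identity, cov_a, _ = local_align(seq_a, seq_b)
    return identity, cov_a


# -------------------------------------------------------------- criteria


def _role_multiset_jaccard(a: BgcRecord, b: BgcRecord) -> float:
    from collections import Counter

    ca, cb = Counter(g.role for g in a.genes), Counter(g.role for g in b.genes)
    num = sum(min(ca[r], cb[r]) for r in ca.keys() & cb.keys())
    den = sum((ca | cb).values())
    return num / den if den else 0.0


class _HitIndex:
    """Best-hit lookup built from an external search-hit table."""

    def __init__(self, hits: list[HitRecord], params: GcfCriteriaParams):
        self.good: set[tuple[str, str]] = set()
        for h in hits:
            if h.identity >= params.gene_identity_min and (
                h.query_coverage >= params.gene_coverage_min
            ):
                self.good.add((h.query_id, h.subject_id))
                self.good.add((h.subject_id, h.query_id))

    def has_match(self, gene, other_genes) -> bool:
        return any((gene.gene_id, o.gene_id) in self.good for o in other_genes)


def _gene_has_homolog(gene, candidates, params: GcfCriteriaParams) -> bool:
    """True if any candidate gene's protein matches at the identity and
    coverage cutoffs.  Same-role candidates are tried first: for related
    clusters the counterpart almost always shares the role label, which
    short-circuits most alignments."""
    if gene.protein is None:
        return False
    ordered = sorted(candidates, key=lambda g: g.role != gene.role)
    for cand in ordered:
        if cand.protein is None:
            continue
        ident, cov = align_identity(gene.protein, cand.protein)
        if ident >= params.gene_identity_min and cov >= params.gene_coverage_min:
            return True
    return False


def criteria_report(
    a: BgcRecord,
    b: BgcRecord,
    params: GcfCriteriaParams = GcfCriteriaParams(),
    hits: Optional[list[HitRecord]] = None,
    short_circuit: bool = False,
) -> CriteriaReport:
    """Evaluate family criteria I-IV for one BGC pair.

    ``hits`` substitutes a precomputed search-hit table for on-the-fly
    pairwise alignment in criterion III.  With ``short_circuit`` the
    expensive criteria are skipped once the verdict is decided (their
    slots stay ``None``).
    """
    rep = CriteriaReport(bgc_a=a.bgc_id, bgc_b=b.bgc_id)
    small, large = (a, b) if len(a.genes) <= len(b.genes) else (b, a)

    # I: architecture — class identity plus role-repertoire overlap
    rep.architecture = (
        a.bgc_class == b.bgc_class
        and _role_multiset_jaccard(a, b) >= params.architecture_role_jaccard_min
    )
    if short_circuit and not rep.architecture:
        return rep

    # II: majority of the smaller cluster's genes find their role in the other
    if not small.genes:
        rep.function = False
    else:
        large_roles = {g.role for g in large.genes}
        frac = sum(g.role in large_roles for g in small.genes) / len(small.genes)
        rep.function = frac > params.majority_fraction
    if short_circuit and not rep.function:
        return rep

    # III: majority of the smaller cluster's genes have a strong homolog
    if not small.genes:
        rep.identity = False
    else:
        index = _HitIndex(hits, params) if hits is not None else None
        n_hit = 0
        for g in small.genes:
            if index is not None:
                ok = index.has_match(g, large.genes)
            else:
                ok = _gene_has_homolog(g, large.genes, params)
            n_hit += ok
        rep.identity = n_hit / len(small.genes) > params.majority_fraction
    if short_circuit and not rep.identity:
        return rep

    # IV: modular KS/C domains compared at matching module positions
    applicable = a.bgc_class in MODULAR_CLASSES and b.bgc_class in MODULAR_CLASSES
    if applicable:
        pairs = []
        for kind in ("KS", "C"):
            la, lb = a.module_domain_list(kind), b.module_domain_list(kind)
            # extra modules beyond the shorter list do not veto membership
            for (_, pa), (_, pb) in zip(la, lb):
                if pa is not None and pb is not None:
                    pairs.append((pa, pb))
        if not pairs:
            rep.modules = None
            rep.warnings.append(
                f"criterion IV not applicable for ({a.bgc_id}, {b.bgc_id}): "
                "no comparable module domains"
            )
        else:
            n_good = sum(
                align_identity(pa, pb)[0] >= params.module_domain_identity_min
                for pa, pb in pairs
            )
            rep.modules = n_good / len(pairs) > params.majority_fraction

    rep.same_gcf = bool(
        rep.architecture and rep.function and rep.identity
        and (rep.modules is not False)
    )
    return rep


# -------------------------------------------------------------- grouping


def assign_gcfs(
    bgcs: list[BgcRecord],
    params: GcfCriteriaParams = GcfCriteriaParams(),
    hits: Optional[list[HitRecord]] = None,
) -> GcfPartition:
    """Group BGCs into families.

    All pairs within the same BGC class are evaluated (cross-class pairs
    fail criterion I by construction); pairwise same-family relations
    are closed transitively into single-linkage connected components.
    Family ids are deterministic: the lexicographically smallest member.
    """
    own = sorted((b for b in bgcs if b.source == "own"), key=lambda b: b.bgc_id)
    if not own:
        raise ValidationError("assign_gcfs requires at least one own-source BGC")
    g = nx.Graph()
    g.add_nodes_from(b.bgc_id for b in own)
    by_class: dict[str, list[BgcRecord]] = {}
    for b in own:
        by_class.setdefault(b.bgc_class, []).append(b)
    for group in by_class.values():
        for a, b in itertools.combinations(group, 2):
            rep = criteria_report(a, b, params, hits=hits, short_circuit=True)
            if rep.same_gcf:
                g.add_edge(a.bgc_id, b.bgc_id)

    by_id = {b.bgc_id: b for b in own}
    family_of, members, strains, classes = {}, {}, {}, {}
    for comp in sorted((sorted(c) for c in nx.connected_components(g)),
                       key=lambda c: c[0]):
        fid = comp[0]
        members[fid] = comp
        strains[fid] = {by_id[m].genome_id for m in comp}
        from collections import Counter

        classes[fid] = Counter(by_id[m].bgc_class for m in comp).most_common(1)[0][0]
        for m in comp:
            family_of[m] = fid
    part = GcfPartition(
        family_of=family_of, members=members, strains=strains,
        consensus_class=classes,
    )
    return categorize_gcfs(part)


def categorize_gcfs(partition: GcfPartition) -> GcfPartition:
    """Attach frequency categories based on strain counts.

    common: present in >= 4 strains; rare: 2-3 strains; unique: exactly
    one strain (a strain carrying two copies still counts once).
    """
    for fid, strain_set in partition.strains.items():
        n = len(strain_set)
        if n == 0:
            raise ValidationError(f"family {fid} has no strains")
        partition.category[fid] = (
            "common" if n >= 4 else "rare" if n >= 2 else "unique"
        )
    return partition


def category_table(partition: GcfPartition) -> dict[str, int]:
    from collections import Counter

    return dict(Counter(partition.category.values()))
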
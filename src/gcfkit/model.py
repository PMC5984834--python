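"""Core data model shared by all pipeline stages.

Coordinates are 0-based, half-open, in the forward-strand frame of the
deposited sequence.  A genome is a single replicon (one circular
chromosome); intervals on circular replicons may have ``end > length``
to denote wrap-around past the origin of the coordinate system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


class ValidationError(ValueError):
    """Input violates a documented invariant."""


class FormatError(ValueError):
    """Input file does not match the documented format."""


@dataclass(frozen=True)
class DomainCount:
    """A Pfam domain accession with its copy number inside one BGC."""

    accession: str
    copies: int

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("domain accession must be non-empty")
        if self.copies < 1:
            raise ValidationError(
                f"domain {self.accession}: copies must be >= 1, got {self.copies}"
            )


@dataclass(frozen=True)
class GeneRecord:
    """One gene inside a BGC.

    ``role`` is a free-form functional label ("glycosyltransferase",
    "transporter", ...).  ``module_domains`` lists modular ketosynthase
    (KS) and condensation (C) domains as ``(kind, module_index)`` pairs,
    ordered by strictly increasing module index.
    """

    gene_id: str
    start: int
    end: int
    strand: str = "+"
    role: str = ""
    protein: Optional[str] = None
    module_domains: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        idx = [i for _, i in self.module_domains]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError(
                f"gene {self.gene_id}: module indices must be strictly increasing"
            )
        for kind, _ in self.module_domains:
            if kind not in ("KS", "C"):
                raise ValidationError(
                    f"gene {self.gene_id}: module domain kind must be KS or C, got {kind!r}"
                )


BGC_CLASSES = ("PKS", "NRPS", "PKS/NRPS-hybrid", "RiPP", "Terpene", "Other")
#: classes whose members are built from enzymatic modules; criterion IV applies
MODULAR_CLASSES = ("PKS", "NRPS", "PKS/NRPS-hybrid")


@dataclass
class BgcRecord:
    """One biosynthetic gene cluster on a replicon."""

    bgc_id: str
    genome_id: str
    bgc_class: str
    start: int
    end: int
    genes: list[GeneRecord] = field(default_factory=list)
    domains: list[DomainCount] = field(default_factory=list)
    source: str = "own"

    def __post_init__(self) -> None:
        if self.bgc_class not in BGC_CLASSES:
            raise ValidationError(
                f"BGC {self.bgc_id}: unknown class {self.bgc_class!r}"
            )
        if self.start >= self.end:
            raise ValidationError(
                f"BGC {self.bgc_id}: start {self.start} must be < end {self.end}"
            )
        if self.source not in ("own", "reference"):
            raise ValidationError(f"BGC {self.bgc_id}: bad source {self.source!r}")
        for g in self.genes:
            if g.start < self.start or g.end > self.end:
                raise ValidationError(
                    f"BGC {self.bgc_id}: gene {g.gene_id} outside cluster interval"
                )

    @property
    def domain_set(self) -> frozenset[str]:
        return frozenset(d.accession for d in self.domains)

    @property
    def domain_counts(self) -> dict[str, int]:
        return {d.accession: d.copies for d in self.domains}

    def module_domain_list(self, kind: str) -> list[tuple[int, Optional[str]]]:
        """All (module_index, protein) pairs of the given kind across genes,
        sorted by module index."""
        out = []
        for g in self.genes:
            for k, i in g.module_domains:
                if k == kind:
                    out.append((i, g.protein))
        return sorted(out, key=lambda t: t[0])


@dataclass
class GenomeRecord:
    """One replicon with its BGC complement and positional anchors."""

    genome_id: str
    length: int
    topology: str = "circular"
    dnaA_start: int = 0
    dnaA_strand: str = "+"
    clade: Optional[str] = None
    bgcs: list[BgcRecord] = field(default_factory=list)
    conserved_intervals: Optional[list[tuple[int, int]]] = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"genome {self.genome_id}: non-positive length")
        if self.topology not in ("circular", "linear"):
            raise ValidationError(
                f"genome {self.genome_id}: bad topology {self.topology!r}"
            )
        if not (0 <= self.dnaA_start < self.length):
            raise ValidationError(
                f"genome {self.genome_id}: dnaA_start {self.dnaA_start} outside "
                f"[0, {self.length})"
            )
        if self.dnaA_strand not in ("+", "-"):
            raise ValidationError(f"genome {self.genome_id}: bad dnaA strand")
        if self.conserved_intervals is not None:
            for s, e in self.conserved_intervals:
                if not (0 <= s < e <= self.length):
                    raise ValidationError(
                        f"genome {self.genome_id}: conserved interval ({s},{e}) "
                        f"outside [0, {self.length})"
                    )


@dataclass(frozen=True)
class HitRecord:
    """One pairwise protein search hit (BLAST-style)."""

    query_id: str
    subject_id: str
    identity: float
    query_coverage: float
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValidationError(f"hit identity {self.identity} outside [0,1]")
        if not (0.0 <= self.query_coverage <= 1.0):
            raise ValidationError(
                f"hit query_coverage {self.query_coverage} outside [0,1]"
            )
        if self.evalue < 0:
            raise ValidationError("hit e-value must be non-negative")
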
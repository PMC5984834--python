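"""Percentage of conserved proteins (POCP) for genus delimitation.

Two genomes with POCP >= 50% are considered members of the same genus.
A protein is "conserved" when it has a hit in the other proteome with
e-value <= 1e-5, identity >= 40% and an alignable region covering at
least half of the query; POCP = (C_a + C_b) / (T_a + T_b) x 100 over
both search directions.  The cutoffs follow the established POCP
procedure and are exposed as parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .families import local_align
from .model import HitRecord, ValidationError

#: refuse all-vs-all alignment above this proteome size; supply hit tables
MAX_ALIGN_PROTEOME = 500


@dataclass(frozen=True)
class PocpParams:
    evalue_max: float = 1e-5
    identity_min: float = 0.40
    aligned_fraction_min: float = 0.50
    genus_threshold: float = 50.0  # percent

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_min <= 1.0):
            raise ValidationError("identity_min must be in [0,1]")
        if not (0.0 <= self.aligned_fraction_min <= 1.0):
            raise ValidationError("aligned_fraction_min must be in [0,1]")
        if not (0.0 <= self.genus_threshold <= 100.0):
            raise ValidationError("genus_threshold must be in [0,100]")


def _conserved_count(
    hits: Sequence[HitRecord], params: PocpParams, apply_evalue: bool
) -> int:
    """Distinct query proteins with at least one hit passing all cutoffs."""
    ok = set()
    for h in hits:
        if h.identity < params.identity_min:
            continue
        if h.query_coverage < params.aligned_fraction_min:
            continue
        if apply_evalue and h.evalue > params.evalue_max:
            continue
        ok.add(h.query_id)
    return len(ok)


def pocp(
    hits_ab: Sequence[HitRecord],
    hits_ba: Sequence[HitRecord],
    t_a: int,
    t_b: int,
    params: PocpParams = PocpParams(),
    apply_evalue: bool = True,
) -> tuple[float, bool]:
    """POCP from two directional hit tables and the proteome sizes.

    Returns (percentage in [0, 100], same-genus verdict).  Symmetric in
    the two genomes by construction.
    """
    if t_a < 1 or t_b < 1:
        raise ValidationError("proteome sizes must be positive")
    c_a = _conserved_count(hits_ab, params, apply_evalue)
    c_b = _conserved_count(hits_ba, params, apply_evalue)
    value = (c_a + c_b) / (t_a + t_b) * 100.0
    return value, value >= params.genus_threshold


def pocp_from_sequences(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    params: PocpParams = PocpParams(),
) -> tuple[float, bool]:
    """Self-contained POCP from two small proteomes.

    All-vs-all pairwise local alignments replace a database search, so
    no e-value is available and only the identity and aligned-fraction
    cutoffs apply.  Intended for desk-scale proteomes; larger inputs
    must come with precomputed hit tables.
    """
    if max(len(proteome_a), len(proteome_b)) > MAX_ALIGN_PROTEOME:
        raise ValidationError(
            f"proteome larger than {MAX_ALIGN_PROTEOME} sequences: "
            "supply precomputed hit tables to pocp() instead"
        )
    hits_ab = _align_hits(proteome_a, proteome_b)
    hits_ba = _align_hits(proteome_b, proteome_a)
    return pocp(
        hits_ab, hits_ba, len(proteome_a), len(proteome_b),
        params, apply_evalue=False,
    )


def _align_hits(
    queries: dict[str, str], subjects: dict[str, str]
) -> list[HitRecord]:
    hits = []
    for qid, qseq in queries.items():
        for sid, sseq in subjects.items():
            identity, cov_q, _ = local_align(qseq, sseq)
            if identity > 0:
                hits.append(HitRecord(qid, sid, identity, cov_q, 0.0))
    return hits
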
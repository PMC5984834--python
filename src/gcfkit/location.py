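"""BGC positions relative to the replication origin on circular genomes.

Circular chromosomes are linearized at the dnaA gene (the marker next
to oriC); each BGC's midpoint is then expressed as a downstream
distance from the origin as a fraction of genome length.  On top of
this the module bins positions into equal genome regions, tests
positional conservation of a family within a clade, and measures how
many BGCs fall outside the conserved backbone (hypervariable regions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import BgcRecord, GenomeRecord, ValidationError
from .io import merge_intervals


@dataclass(frozen=True)
class RelativePosition:
    bgc_id: str
    p: float  # downstream fraction from oriC, in [0, 1)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p < 1.0):
            raise ValidationError(f"relative position {self.p} outside [0,1)")


def circular_midpoint(start: int, end: int, length: int) -> float:
    """Midpoint of a (possibly origin-wrapping) interval, mod length.

    Wrap-around intervals are written with end > length, e.g.
    [950, 1050) on a 1000 bp replicon has midpoint 0.
    """
    if end <= start:
        raise ValidationError(f"bad interval ({start}, {end})")
    return ((start + end) / 2.0) % length


def relative_position(bgc: BgcRecord, genome: GenomeRecord) -> RelativePosition:
    """Downstream distance of the BGC midpoint from oriC, as a fraction
    of genome length.

    With dnaA on the minus strand the deposited sequence runs against
    the replication direction; coordinates are mirrored (the analysis
    then matches using the reverse complement for the alignment frame).
    Linear replicons have no circular origin and are rejected unless
    dnaA coordinates supply an explicit start.
    """
    if genome.topology != "circular" and genome.dnaA_start is None:
        raise ValidationError(
            f"genome {genome.genome_id} is linear: provide an explicit origin"
        )
    L = genome.length
    m = circular_midpoint(bgc.start, bgc.end, L)
    if genome.dnaA_strand == "+":
        p = ((m - genome.dnaA_start) % L) / L
    else:
        p = ((L - m + genome.dnaA_start) % L) / L
    return RelativePosition(bgc_id=bgc.bgc_id, p=p % 1.0)


def position_table(genomes: Sequence[GenomeRecord], n_bins: int = 8) -> pd.DataFrame:
    """Per-BGC relative positions, bins and (when conserved intervals
    are available) hypervariable membership, for all genomes."""
    rows = []
    for g in genomes:
        for bgc in g.bgcs:
            rp = relative_position(bgc, g)
            hv = None
            if g.conserved_intervals is not None:
                hv = is_hypervariable(bgc, g)
            rows.append({
                "bgc_id": bgc.bgc_id,
                "genome_id": g.genome_id,
                "bgc_class": bgc.bgc_class,
                "clade": g.clade,
                "p": rp.p,
                "bin": int(np.floor(rp.p * n_bins)),
                "hypervariable": hv,
            })
    return pd.DataFrame(rows)


def bin_densities(
    genomes: Sequence[GenomeRecord], n_bins: int = 8
) -> pd.DataFrame:
    """BGC counts per genome region.

    The unit interval of relative positions is split into ``n_bins``
    contiguous equal bins; a BGC at position p falls in bin
    floor(p * n_bins).  Returns one row per bin with a total column and
    one column per BGC class; bin counts sum to the total BGC count.
    """
    table = position_table(genomes, n_bins=n_bins)
    classes = sorted(table["bgc_class"].unique()) if len(table) else []
    out = pd.DataFrame(
        0, index=pd.RangeIndex(n_bins, name="bin"), columns=["total"] + classes
    )
    for _, row in table.iterrows():
        out.loc[row["bin"], "total"] += 1
        out.loc[row["bin"], row["bgc_class"]] += 1
    return out


def circular_distance(p: float, q: float) -> float:
    """Distance between two relative positions on the unit circle."""
    d = abs(p - q) % 1.0
    return min(d, 1.0 - d)


def positional_conservation(
    positions: Sequence[float], tolerance: float = 0.05
) -> Optional[bool]:
    """Whether a family's member positions are conserved within a clade.

    Conserved iff the largest pairwise circular distance between member
    positions is at most ``tolerance`` (default 5% of genome length).
    Returns None (not applicable) for fewer than two members.
    """
    ps = list(positions)
    if len(ps) < 2:
        return None
    worst = max(
        circular_distance(a, b) for i, a in enumerate(ps) for b in ps[i + 1:]
    )
    return worst <= tolerance


def _overlap_with_intervals(
    start: int, end: int, intervals: Sequence[tuple[int, int]], length: int
) -> int:
    """Overlap (bp) of a possibly wrapping interval with a set of
    non-wrapping intervals."""
    segments = [(start, min(end, length))]
    if end > length:
        segments.append((0, end - length))
    total = 0
    for s0, e0 in segments:
        for s1, e1 in intervals:
            total += max(0, min(e0, e1) - max(s0, s1))
    return total


def is_hypervariable(
    bgc: BgcRecord, genome: GenomeRecord, span_fraction: float = 0.5
) -> bool:
    """A BGC is hypervariable-resident when more than ``span_fraction``
    of its span lies outside the genome's conserved intervals."""
    if genome.conserved_intervals is None:
        raise ValidationError(
            f"genome {genome.genome_id} has no conserved intervals"
        )
    intervals = merge_intervals(genome.conserved_intervals)
    span = bgc.end - bgc.start
    inside = _overlap_with_intervals(bgc.start, bgc.end, intervals, genome.length)
    return (span - inside) / span > span_fraction


def hypervariable_fraction(genome: GenomeRecord) -> tuple[int, float]:
    """Count and fraction of a genome's BGCs residing in hypervariable
    regions."""
    if not genome.bgcs:
        return 0, 0.0
    n = sum(is_hypervariable(b, genome) for b in genome.bgcs)
    return n, n / len(genome.bgcs)
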
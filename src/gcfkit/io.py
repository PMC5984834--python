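"""Readers and writers for every external format the pipeline touches.

Tabular inputs are TSV; networks go out as GraphML plus a plain edge
list; trees as Newick with branch lengths; matrices as TSV.  Writing an
object and reading it back reproduces it field-for-field.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd
from Bio import SeqIO

from .model import (
    BgcRecord,
    DomainCount,
    FormatError,
    GeneRecord,
    GenomeRecord,
    HitRecord,
    ValidationError,
)

BGC_TABLE_COLUMNS = [
    "genome_id", "bgc_id", "bgc_class", "bgc_start", "bgc_end",
    "gene_id", "gene_start", "gene_end", "strand", "role",
    "domains", "module_domains", "protein_id",
]

GENOME_TABLE_COLUMNS = [
    "genome_id", "length", "topology", "dnaA_start", "dnaA_strand",
]


def _parse_domains(cell: str) -> list[tuple[str, int]]:
    """Parse a 'PF00109:2;PF00550:1' cell."""
    if not cell or pd.isna(cell):
        return []
    out = []
    for item in str(cell).split(";"):
        item = item.strip()
        if not item:
            continue
        if ":" in item:
            acc, _, n = item.rpartition(":")
            out.append((acc, int(n)))
        else:
            out.append((item, 1))
    return out


def _parse_module_domains(cell: str) -> tuple[tuple[str, int], ...]:
    """Parse a 'KS:1;KS:2' / 'C:1' cell."""
    if not cell or pd.isna(cell):
        return ()
    out = []
    for item in str(cell).split(";"):
        item = item.strip()
        if not item:
            continue
        kind, _, idx = item.partition(":")
        out.append((kind, int(idx)))
    return tuple(out)


def read_bgc_table(
    path: str | Path,
    source_label: str = "own",
    proteins: Optional[dict[str, str]] = None,
) -> list[BgcRecord]:
    """Read the per-gene BGC annotation table into one record per
    (genome_id, bgc_id).

    Gene rows are aggregated; the cluster-level domain multiset is the
    sum of per-gene domain copy counts.  ``proteins`` optionally maps
    protein_id to an amino-acid sequence (from :func:`read_protein_fasta`).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in BGC_TABLE_COLUMNS[:10] if c not in df.columns]
    if missing:
        raise FormatError(f"BGC table {path}: missing column(s) {', '.join(missing)}")
    records: list[BgcRecord] = []
    for (genome_id, bgc_id), grp in df.groupby(["genome_id", "bgc_id"], sort=True):
        genes = []
        dom_counts: dict[str, int] = {}
        for rownum, row in grp.iterrows():
            try:
                gstart, gend = int(row["gene_start"]), int(row["gene_end"])
            except ValueError as exc:
                raise FormatError(
                    f"BGC table {path} row {rownum}: non-integer coordinate"
                ) from exc
            if gend <= gstart:
                raise ValidationError(
                    f"BGC table {path} row {rownum}: gene end {gend} <= start {gstart}"
                )
            protein = None
            pid = row.get("protein_id", "")
            if proteins is not None and pid:
                protein = proteins.get(pid)
            genes.append(
                GeneRecord(
                    gene_id=row["gene_id"],
                    start=gstart,
                    end=gend,
                    strand=row["strand"],
                    role=row["role"],
                    protein=protein,
                    module_domains=_parse_module_domains(row.get("module_domains", "")),
                )
            )
            for acc, n in _parse_domains(row.get("domains", "")):
                dom_counts[acc] = dom_counts.get(acc, 0) + n
        first = grp.iloc[0]
        try:
            bstart, bend = int(first["bgc_start"]), int(first["bgc_end"])
        except ValueError as exc:
            raise FormatError(f"BGC table {path}: non-integer BGC coordinate") from exc
        records.append(
            BgcRecord(
                bgc_id=bgc_id,
                genome_id=genome_id,
                bgc_class=first["bgc_class"],
                start=bstart,
                end=bend,
                genes=genes,
                domains=[DomainCount(a, n) for a, n in sorted(dom_counts.items())],
                source=source_label,
            )
        )
    return records


def read_genome_table(path: str | Path) -> list[GenomeRecord]:
    """Read the genome metadata table (one row per replicon)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GENOME_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"genome table {path}: missing column(s) {', '.join(missing)}"
        )
    records = []
    for _, row in df.iterrows():
        clade = row["clade"] if "clade" in df.columns and row["clade"] else None
        records.append(
            GenomeRecord(
                genome_id=row["genome_id"],
                length=int(row["length"]),
                topology=row["topology"],
                dnaA_start=int(row["dnaA_start"]),
                dnaA_strand=row["dnaA_strand"],
                clade=clade,
            )
        )
    return records


def attach_bgcs(genomes: list[GenomeRecord], bgcs: Iterable[BgcRecord]) -> None:
    """Join BGC records onto genome records by genome_id (in place)."""
    by_id = {g.genome_id: g for g in genomes}
    for bgc in bgcs:
        if bgc.genome_id in by_id:
            by_id[bgc.genome_id].bgcs.append(bgc)


def read_regions_bed(path: str | Path) -> list[tuple[int, int]]:
    """Read a 3+-column BED file; return sorted, merged intervals."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path} line {lineno}: fewer than 3 BED columns")
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path} line {lineno}: non-integer coordinates"
                ) from exc
            if s > e:
                raise ValidationError(f"{path} line {lineno}: start {s} > end {e}")
            intervals.append((s, e))
    return merge_intervals(intervals)


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort half-open intervals and merge any that overlap or abut."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by FASTA record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_protein_fasta(proteins: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(proteins):
            fh.write(f">{pid}\n{proteins[pid]}\n")


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """TSV hit table: query, subject, identity, query_coverage, evalue."""
    df = pd.read_csv(path, sep="\t")
    needed = ["query_id", "subject_id", "identity", "query_coverage"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"hit table {path}: missing column(s) {', '.join(missing)}")
    return [
        HitRecord(
            query_id=str(r.query_id),
            subject_id=str(r.subject_id),
            identity=float(r.identity),
            query_coverage=float(r.query_coverage),
            evalue=float(getattr(r, "evalue", 0.0)),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------- outputs


def write_network_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Plain TSV edge list with the similarity weight."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["node_a", "node_b", "similarity"])
        for a, b, d in sorted(graph.edges(data=True)):
            w.writerow([a, b, f"{d.get('similarity', 1.0):.6f}"])


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_newick(newick: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(newick.rstrip("\n") + "\n")


def read_newick(path: str | Path) -> str:
    return Path(path).read_text().strip()
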
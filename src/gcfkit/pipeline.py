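"""End-to-end orchestration of the comparative GCF analysis.

A config (file or object) names the inputs and stage parameters; the
pipeline then runs simulate/load -> similarity network -> GCF
assignment -> frequency categories -> presence/absence + UPGMA +
rarefaction -> locations/densities/hypervariable overlap -> POCP, and
writes every stage table plus a machine-readable summary and a manifest
with content checksums.  Outputs are byte-identical for identical
config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as gio
from .families import (
    GcfCriteriaParams, GcfPartition, assign_gcfs, category_table,
)
from .location import bin_densities, position_table, positional_conservation
from .model import GenomeRecord, ValidationError
from .pocp import PocpParams, pocp_from_sequences
from .profiles import dice_distance_matrix, presence_absence, rarefaction, upgma
from .similarity import SimilarityParams, build_network, partition_vs_reference
from .simulate import SimulationParams, generate_dataset, write_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and stage parameters for one pipeline run."""

    output_dir: str = "results"
    seed: int = 0
    # either simulate ...
    simulate: bool = True
    simulation: SimulationParams = field(default_factory=SimulationParams)
    # ... or load from files
    bgc_table: Optional[str] = None
    genome_table: Optional[str] = None
    proteins: Optional[str] = None
    reference_bgc_table: Optional[str] = None
    regions_bed: Optional[str] = None
    similarity: SimilarityParams = field(default_factory=SimilarityParams)
    criteria: GcfCriteriaParams = field(default_factory=GcfCriteriaParams)
    pocp_params: PocpParams = field(default_factory=PocpParams)
    n_bins: int = 8
    conservation_tolerance: float = 0.05
    rarefaction_resamples: int = 0
    run_pocp: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (
            ("simulation", SimulationParams),
            ("similarity", SimilarityParams),
            ("criteria", GcfCriteriaParams),
            ("pocp_params", PocpParams),
        ):
            if key in raw and isinstance(raw[key], dict):
                if key == "simulation" and "variable_region" in raw[key]:
                    raw[key]["variable_region"] = tuple(raw[key]["variable_region"])
                raw[key] = sub(**raw[key])
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config field(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if not cfg.simulate and not cfg.bgc_table:
            raise ValidationError("config: bgc_table is required when simulate=false")
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; return the machine-readable summary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    # ---- load or simulate -------------------------------------------------
    if config.simulate:
        params = config.simulation
        if params.seed != config.seed:
            params = SimulationParams(**{**asdict(params), "seed": config.seed})
        genomes, truth = generate_dataset(params)
        write_dataset(genomes, truth, out / "synthetic")
        logger.info("simulated %d genomes", len(genomes))
    else:
        if not config.bgc_table or not config.genome_table:
            raise ValidationError("config: bgc_table and genome_table required")
        proteins = (
            gio.read_protein_fasta(config.proteins) if config.proteins else None
        )
        bgcs = gio.read_bgc_table(config.bgc_table, "own", proteins)
        genomes = gio.read_genome_table(config.genome_table)
        gio.attach_bgcs(genomes, bgcs)
        if config.regions_bed:
            regions = gio.read_regions_bed(config.regions_bed)
            for g in genomes:
                g.conserved_intervals = regions
        truth = None
    own_bgcs = [b for g in genomes for b in g.bgcs]
    summary["n_genomes"] = len(genomes)
    summary["n_bgcs"] = len(own_bgcs)

    # ---- similarity network ----------------------------------------------
    all_bgcs = list(own_bgcs)
    if config.reference_bgc_table:
        all_bgcs += gio.read_bgc_table(config.reference_bgc_table, "reference")
    network = build_network(all_bgcs, config.similarity)
    gio.write_network_graphml(network, out / "network.graphml")
    gio.write_edge_list(network, out / "network_edges.tsv")
    counts = partition_vs_reference(network)
    summary["network"] = counts
    logger.info("network: %d components", counts["total"])

    # ---- GCF assignment and categories ------------------------------------
    partition = assign_gcfs(own_bgcs, config.criteria)
    fam_df = pd.DataFrame(
        [
            {
                "bgc_id": bid,
                "family_id": fid,
                "category": partition.category[fid],
                "strain_count": len(partition.strains[fid]),
            }
            for bid, fid in sorted(partition.family_of.items())
        ]
    )
    fam_df.to_csv(out / "families.tsv", sep="\t", index=False)
    summary["n_gcfs"] = len(partition.members)
    summary["gcf_categories"] = category_table(partition)

    # ---- profiles: presence/absence, UPGMA, rarefaction --------------------
    strain_ids = [g.genome_id for g in genomes]
    matrix = presence_absence(partition, strain_ids)
    gio.write_matrix_tsv(matrix, out / "presence_absence.tsv")
    tree = upgma(dice_distance_matrix(matrix))
    gio.write_newick(tree.newick, out / "strain_dendrogram.nwk")
    groups = sorted({g.clade for g in genomes if g.clade and g.clade != "singleton"})
    curves = []
    for grp in groups:
        members = [g.genome_id for g in genomes if g.clade == grp]
        curve = rarefaction(matrix.loc[members], group=grp)
        curves.append(curve.as_frame())
    if curves:
        pd.concat(curves).to_csv(out / "rarefaction.tsv", sep="\t", index=False)
        summary["rarefaction_groups"] = groups

    # ---- genome locations ---------------------------------------------------
    positions = position_table(genomes, n_bins=config.n_bins)
    positions["family_id"] = positions["bgc_id"].map(partition.family_of)
    positions.to_csv(out / "positions.tsv", sep="\t", index=False)
    density = bin_densities(genomes, n_bins=config.n_bins)
    density.to_csv(out / "bin_densities.tsv", sep="\t")
    summary["bin_totals"] = density["total"].tolist()
    cons_rows = []
    for fid in partition.family_ids:
        for grp in groups:
            ps = positions.loc[
                (positions["family_id"] == fid) & (positions["clade"] == grp), "p"
            ].tolist()
            verdict = positional_conservation(ps, config.conservation_tolerance)
            if verdict is not None:
                cons_rows.append(
                    {"family_id": fid, "clade": grp,
                     "conserved": bool(verdict), "n_members": len(ps)}
                )
    cons_df = pd.DataFrame(cons_rows)
    cons_df.to_csv(out / "positional_conservation.tsv", sep="\t", index=False)
    if len(cons_df):
        summary["positionally_conserved_fraction"] = round(
            float(cons_df["conserved"].mean()), 4
        )
    hv = positions["hypervariable"].dropna()
    if len(hv):
        summary["hypervariable_fraction"] = round(float(hv.mean()), 4)

    # ---- POCP (optional, alignment-heavy) ----------------------------------
    if config.run_pocp:
        pocp_matrix = _pocp_matrix(genomes, config.pocp_params)
        gio.write_matrix_tsv(pocp_matrix, out / "pocp.tsv")
        summary["pocp_min"] = round(float(pocp_matrix.min().min()), 2)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    manifest = {
        p.name: _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary


def _pocp_matrix(genomes: list[GenomeRecord], params: PocpParams) -> pd.DataFrame:
    """All-vs-all POCP over the BGC proteomes (the only proteins the
    pipeline carries)."""
    proteomes = {}
    for g in genomes:
        proteomes[g.genome_id] = {
            gene.gene_id: gene.protein
            for b in g.bgcs for gene in b.genes if gene.protein
        }
    ids = sorted(proteomes)
    mat = pd.DataFrame(100.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            value, _ = pocp_from_sequences(proteomes[a], proteomes[b], params)
            mat.loc[a, b] = mat.loc[b, a] = round(value, 4)
    return mat
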
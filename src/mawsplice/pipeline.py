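"""End-to-end pipeline: MAW catalog -> filtration -> clustering ->
consensus -> junction calls -> decoy FDR.

All thresholds live in :class:`PipelineConfig`; the configuration is
echoed into every structured output header so a run can be reproduced
from any artifact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .clustering import (
    ConsensusSequence,
    ReadCluster,
    build_consensus,
    cluster_by_maw,
    merge_clusters,
)
from .decoys import FDRReport, build_decoy_boundary_index, compute_fdr, make_decoy_exons
from .filtering import FiltrationReport, ReadSet, RetainedRead, filter_reads
from .index import SubstringIndex, build_index
from .junctions import (
    BoundaryIndex,
    ExonModel,
    JunctionCall,
    build_boundary_index,
    call_junctions,
    export_junction_flanks,
    junction_table,
)
from .maws import MAWCatalog, enumerate_maws
from .reference import ReferenceSet


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable threshold of the pipeline with its default."""

    read_length: int = 25
    maw_max_len: int | None = None  # None -> read_length
    max_mm_filter: int = 2
    min_cluster_size: int = 5
    min_depth: int = 5
    max_read_mismatch: int = 1
    min_overlap: int = 10
    min_match: int = 5
    max_mm_per_side: int = 1
    boundary_window: int = 40
    flank: int = 24
    same_gene: bool = False
    same_chrom: bool = False
    run_decoy: bool = True

    @property
    def effective_maw_max_len(self) -> int:
        return self.maw_max_len if self.maw_max_len is not None else self.read_length

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass
class PipelineResult:
    config: PipelineConfig
    catalog: MAWCatalog
    filtration: FiltrationReport
    retained: list[RetainedRead]
    clusters: list[ReadCluster]
    consensi: list[ConsensusSequence]
    calls: list[JunctionCall]
    decoy_calls: list[JunctionCall] | None
    fdr: FDRReport | None

    def stage_counts(self) -> dict:
        counts = {
            "n_maws": len(self.catalog),
            "filtration": self.filtration.to_dict(),
            "n_clusters": len(self.clusters),
            "n_consensi": len(self.consensi),
            "n_junction_calls": len(self.calls),
        }
        if self.fdr is not None:
            counts["fdr"] = self.fdr.to_dict()
        return counts


def run_all(
    ref: ReferenceSet,
    exons: list[ExonModel],
    reads: ReadSet | list,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run every stage in order on in-memory inputs."""
    index = build_index(ref)
    catalog = enumerate_maws(index, config.effective_maw_max_len)
    retained, report = filter_reads(reads, index, catalog,
                                    max_mismatches=config.max_mm_filter)
    clusters = cluster_by_maw(retained, min_size=config.min_cluster_size)
    consensi = []
    for cluster in clusters:
        cons = build_consensus(
            cluster, min_depth=config.min_depth,
            max_read_mismatch=config.max_read_mismatch, catalog=catalog,
        )
        if cons is not None:
            consensi.append(cons)
    consensi = merge_clusters(consensi, min_overlap=config.min_overlap,
                              min_depth=config.min_depth)
    bindex = build_boundary_index(exons, ref, window=config.boundary_window)
    calls = call_junctions(
        consensi, bindex, min_match=config.min_match,
        max_mm_per_side=config.max_mm_per_side,
        same_gene=config.same_gene, same_chrom=config.same_chrom,
    )
    decoy_calls = None
    fdr = None
    if config.run_decoy:
        decoys = make_decoy_exons(exons, ref)
        dindex = build_decoy_boundary_index(decoys, window=config.boundary_window)
        decoy_calls = call_junctions(
            consensi, dindex, min_match=config.min_match,
            max_mm_per_side=config.max_mm_per_side,
            same_gene=config.same_gene, same_chrom=config.same_chrom,
            source="decoy",
        )
        fdr = compute_fdr(calls, decoy_calls)
    return PipelineResult(
        config=config, catalog=catalog, filtration=report, retained=retained,
        clusters=clusters, consensi=consensi, calls=calls,
        decoy_calls=decoy_calls, fdr=fdr,
    )


def write_junction_tsv(calls: list[JunctionCall], path: str | Path,
                       config: PipelineConfig) -> None:
    df = junction_table(calls)
    with open(path, "w") as fh:
        fh.write(f"# config: {config.to_json()}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_junction_bed12(calls: list[JunctionCall], path: str | Path,
                         config: PipelineConfig) -> None:
    """Same-chromosome calls as BED12, one block per exon side, the
    junction as the gap between blocks."""
    with open(path, "w") as fh:
        fh.write(f"# config: {config.to_json()}\n")
        for c in calls:
            if c.cross_chrom:
                continue
            left = min(c.donor_coord, c.acceptor_coord)
            right = max(c.donor_coord, c.acceptor_coord)
            start = max(0, left - 1)
            end = right + 1
            name = f"{c.donor_exon_id}|{c.acceptor_exon_id}"
            sizes = "1,1"
            starts = f"0,{end - start - 1}"
            fh.write(f"{c.donor_chrom}\t{start}\t{end}\t{name}\t{c.support}\t"
                     f"{c.donor_strand}\t{start}\t{end}\t0,0,0\t2\t{sizes}\t{starts}\n")


def write_flanks_fasta(calls: list[JunctionCall], bindex: BoundaryIndex,
                       path: str | Path, config: PipelineConfig,
                       flank: int | None = None) -> None:
    records = export_junction_flanks(calls, bindex,
                                     flank=flank or config.flank)
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    Path(str(path) + ".config.json").write_text(config.to_json() + "\n")


def write_consensi_fasta(consensi: list[ConsensusSequence], path: str | Path,
                         config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        for i, cons in enumerate(consensi):
            cuts = ",".join(map(str, cons.candidate_cuts.cut_indices)) \
                if cons.candidate_cuts else ""
            depth = ",".join(map(str, cons.depth.tolist()))
            fh.write(f">consensus{i:04d} key={cons.key} support={cons.support} "
                     f"cuts={cuts} depth={depth}\n{cons.seq}\n")
    Path(str(path) + ".config.json").write_text(config.to_json() + "\n")
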
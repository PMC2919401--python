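"""Seeded synthetic data: genome, exon models, junctions and reads.

The generator emulates the input regime the method targets: a genome,
non-overlapping exons, splice junctions joining exon pairs both near
and distant on the genome, and fixed-length (default 25 nt)
junction-spanning reads in mixed orientation with substitution errors,
plus background reads drawn from the genome.  Everything is
deterministic given the seed, and the truth set records per-read
provenance sufficient to reconstruct any read.

The genome is i.i.d. uniform over {A,C,G,T} by default (no repeat
structure); an optional repeat-injection knob copies a segment several
times to exercise the mappability filter.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .junctions import ExonModel, JunctionCall
from .reference import ReferenceSet, revcomp

_BASES = np.array(list("ACGT"))

NEAR = "near"
DISTANT = "distant"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated experiment.

    Defaults mirror the desk-scale regime used throughout: a 200 kb
    genome, 100 exons, 30 junctions of which half join exons at least
    20 kb apart, 25-nt reads at 200 spanning reads per junction with a
    0.5% substitution error rate, and half the reads reverse-
    complemented.
    """

    genome_length: int = 200_000
    n_exons: int = 100
    exon_length_range: tuple[int, int] = (80, 200)
    n_junctions: int = 30
    distant_fraction: float = 0.5
    distant_min_gap: int = 20_000
    read_length: int = 25
    reads_per_junction: int = 200
    n_background_reads: int = 4_000
    error_rate: float = 0.005
    revcomp_fraction: float = 0.5
    repeat_copies: int = 0
    repeat_length: int = 500
    seed: int = 0
    chrom_name: str = "chr1"

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate <= 0.05):
            raise ValueError("error_rate must be in [0, 0.05]")
        for name in ("genome_length", "n_exons", "n_junctions",
                     "read_length", "reads_per_junction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_background_reads < 0:
            raise ValueError("n_background_reads must be >= 0")
        if not (0.0 <= self.distant_fraction <= 1.0):
            raise ValueError("distant_fraction must be in [0, 1]")


@dataclass(frozen=True)
class TrueJunction:
    junction_id: str
    donor_exon_id: str
    acceptor_exon_id: str
    chrom: str
    donor_coord: int  # genomic cut coordinate on the donor side
    acceptor_coord: int  # genomic cut coordinate on the acceptor side
    distance: int
    distance_class: str
    n_reads: int


@dataclass(frozen=True)
class ReadProvenance:
    read_id: str
    origin: str  # junction id or "background"
    offset: int  # start offset in the junction window / genome
    orientation: str  # '+' as sampled, '-' reverse-complemented
    error_positions: tuple[int, ...]  # positions within the final read


@dataclass
class TruthSet:
    junctions: list[TrueJunction]
    provenance: dict[str, ReadProvenance]
    junction_windows: dict[str, tuple[str, int]]  # id -> (window seq, cut index)

    def read_cut_index(self, read_id: str, read_length: int) -> int | None:
        """True cut index within the read's own coordinates, or None
        for background reads."""
        prov = self.provenance.get(read_id)
        if prov is None or prov.origin == "background":
            return None
        _, cut = self.junction_windows[prov.origin]
        local = cut - prov.offset
        if prov.orientation == "-":
            local = read_length - local
        return local


@dataclass
class SimulationResult:
    config: SimConfig
    reference: ReferenceSet
    exons: list[ExonModel]
    reads: list[tuple[str, str]]  # (read_id, seq)
    truth: TruthSet

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write genome FASTA, exons BED6, reads FASTQ, truth TSVs and a
        config echo; returns the paths.  Output is byte-deterministic."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "exons": outdir / "exons.bed",
            "reads": outdir / "reads.fastq",
            "junctions": outdir / "truth_junctions.tsv",
            "provenance": outdir / "truth_reads.tsv",
            "config": outdir / "sim_config.json",
        }
        with open(paths["genome"], "w") as fh:
            for name, seq in self.reference:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
        with open(paths["exons"], "w") as fh:
            for e in self.exons:
                fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.exon_id}\t0\t{e.strand}\n")
        qual = "I" * self.config.read_length
        with open(paths["reads"], "w") as fh:
            for rid, seq in self.reads:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
        with open(paths["junctions"], "w") as fh:
            fh.write("junction_id\tdonor_exon\tacceptor_exon\tchrom\t"
                     "donor_coord\tacceptor_coord\tdistance\tdistance_class\tn_reads\n")
            for j in self.truth.junctions:
                fh.write(f"{j.junction_id}\t{j.donor_exon_id}\t{j.acceptor_exon_id}\t"
                         f"{j.chrom}\t{j.donor_coord}\t{j.acceptor_coord}\t"
                         f"{j.distance}\t{j.distance_class}\t{j.n_reads}\n")
        with open(paths["provenance"], "w") as fh:
            fh.write("read_id\torigin\toffset\torientation\terror_positions\n")
            for rid, _ in self.reads:
                p = self.truth.provenance[rid]
                errs = ",".join(map(str, p.error_positions))
                fh.write(f"{p.read_id}\t{p.origin}\t{p.offset}\t{p.orientation}\t{errs}\n")
        cfg = asdict(self.config)
        cfg["exon_length_range"] = list(cfg["exon_length_range"])
        with open(paths["config"], "w") as fh:
            json.dump(cfg, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _place_exons(rng: np.random.Generator, config: SimConfig) -> list[tuple[int, int]]:
    lo, hi = config.exon_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_exons)
    min_sep = config.read_length  # keep exon contexts disjoint
    slack = config.genome_length - int(lengths.sum()) - min_sep * (config.n_exons + 1)
    if slack < 0:
        raise ValueError("exons do not fit in the genome with the required separation")
    extra = np.sort(rng.integers(0, slack + 1, size=config.n_exons + 1)) if slack else \
        np.zeros(config.n_exons + 1, dtype=int)
    gaps = np.diff(np.concatenate(([0], extra)))  # non-negative, sums <= slack
    intervals = []
    pos = 0
    for length, gap in zip(lengths, gaps):
        pos += min_sep + int(gap)
        intervals.append((pos, pos + int(length)))
        pos += int(length)
    return intervals


def _pick_junctions(rng: np.random.Generator, exons: list[ExonModel],
                    config: SimConfig) -> list[tuple[int, int, str]]:
    """(donor index, acceptor index, distance class) for each junction."""
    n_distant = int(round(config.n_junctions * config.distant_fraction))
    n_near = config.n_junctions - n_distant
    pairs: list[tuple[int, int, str]] = []
    used: set[tuple[int, int]] = set()
    n = len(exons)

    def gap(i: int, j: int) -> int:
        a, b = exons[i], exons[j]
        if a.start < b.start:
            return max(0, b.start - a.end)
        return max(0, a.start - b.end)

    for want, klass in ((n_distant, DISTANT), (n_near, NEAR)):
        tries = 0
        found = 0
        while found < want:
            tries += 1
            if tries > 100_000:
                raise ValueError(f"cannot place enough {klass} junctions")
            i, j = (int(x) for x in rng.integers(0, n, size=2))
            if i == j or (i, j) in used:
                continue
            g = gap(i, j)
            if klass == DISTANT and g < config.distant_min_gap:
                continue
            if klass == NEAR and g >= config.distant_min_gap:
                continue
            used.add((i, j))
            pairs.append((i, j, klass))
            found += 1
    return pairs


def _apply_errors(rng: np.random.Generator, seq: str,
                  error_rate: float) -> tuple[str, tuple[int, ...]]:
    if error_rate <= 0:
        return seq, ()
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    if not len(hits):
        return seq, ()
    base_order = {b: i for i, b in enumerate("ACGT")}
    for pos in hits:
        cur = base_order[chr(arr[pos])]
        alt = (cur + 1 + int(rng.integers(0, 3))) % 4
        arr[pos] = ord("ACGT"[alt])
    return arr.tobytes().decode(), tuple(int(h) for h in hits)


def simulate(config: SimConfig) -> SimulationResult:
    """Generate genome, exons, junctions and reads from the seed."""
    rng = np.random.default_rng(config.seed)
    genome_arr = rng.integers(0, 4, size=config.genome_length)
    if config.repeat_copies > 0:
        # copy one segment several times to create multi-mapping windows
        seg_start = int(rng.integers(0, config.genome_length - config.repeat_length))
        seg = genome_arr[seg_start:seg_start + config.repeat_length].copy()
        for _ in range(config.repeat_copies):
            dest = int(rng.integers(0, config.genome_length - config.repeat_length))
            genome_arr[dest:dest + config.repeat_length] = seg
    genome = "".join(_BASES[genome_arr])
    reference = ReferenceSet.from_dict({config.chrom_name: genome})

    intervals = _place_exons(rng, config)
    exons = [
        ExonModel(exon_id=f"exon{i:03d}", chrom=config.chrom_name,
                  start=s, end=e, strand="+", gene_id=f"gene{i // 2:03d}")
        for i, (s, e) in enumerate(intervals)
    ]
    pairs = _pick_junctions(rng, exons, config)

    ctx = config.read_length - 1
    reads: list[tuple[str, str]] = []
    provenance: dict[str, ReadProvenance] = {}
    junction_windows: dict[str, tuple[str, int]] = {}
    junctions: list[TrueJunction] = []
    read_no = 0
    for jid_no, (di, ai, klass) in enumerate(pairs):
        donor, acceptor = exons[di], exons[ai]
        jid = f"junc{jid_no:03d}"
        dctx = genome[donor.end - ctx:donor.end]
        actx = genome[acceptor.start:acceptor.start + ctx]
        window = dctx + actx
        cut = len(dctx)
        junction_windows[jid] = (window, cut)
        a, b = exons[di], exons[ai]
        dist = max(0, (b.start - a.end) if a.start < b.start else (a.start - b.end))
        junctions.append(TrueJunction(
            junction_id=jid, donor_exon_id=donor.exon_id,
            acceptor_exon_id=acceptor.exon_id, chrom=config.chrom_name,
            donor_coord=donor.end, acceptor_coord=acceptor.start,
            distance=dist, distance_class=klass,
            n_reads=config.reads_per_junction,
        ))
        L = config.read_length
        for _ in range(config.reads_per_junction):
            offset = int(rng.integers(cut - L + 1, cut))  # >=1 nt each side
            raw = window[offset:offset + L]
            flip = rng.random() < config.revcomp_fraction
            oriented = revcomp(raw) if flip else raw
            seq, errs = _apply_errors(rng, oriented, config.error_rate)
            rid = f"r{read_no:06d}"
            read_no += 1
            reads.append((rid, seq))
            provenance[rid] = ReadProvenance(
                read_id=rid, origin=jid, offset=offset,
                orientation="-" if flip else "+", error_positions=errs,
            )
    L = config.read_length
    for _ in range(config.n_background_reads):
        start = int(rng.integers(0, config.genome_length - L + 1))
        raw = genome[start:start + L]
        flip = rng.random() < config.revcomp_fraction
        oriented = revcomp(raw) if flip else raw
        seq, errs = _apply_errors(rng, oriented, config.error_rate)
        rid = f"r{read_no:06d}"
        read_no += 1
        reads.append((rid, seq))
        provenance[rid] = ReadProvenance(
            read_id=rid, origin="background", offset=start,
            orientation="-" if flip else "+", error_positions=errs,
        )
    truth = TruthSet(junctions=junctions, provenance=provenance,
                     junction_windows=junction_windows)
    return SimulationResult(config=config, reference=reference, exons=exons,
                            reads=reads, truth=truth)


# ---------------------------------------------------------------------------
# Scoring


STRICT = "strict"
LENIENT = "lenient"


@dataclass(frozen=True)
class ScoreReport:
    sensitivity: float
    per_class_sensitivity: dict[str, float]
    n_true: int
    n_matched: int
    n_false_calls: int
    matched_junction_ids: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "per_class_sensitivity": dict(self.per_class_sensitivity),
            "n_true": self.n_true,
            "n_matched": self.n_matched,
            "n_false_calls": self.n_false_calls,
        }


def score_calls(calls: list[JunctionCall], truth: TruthSet,
                mode: str = STRICT, tolerance: int = 2,
                min_reads: int | None = None) -> ScoreReport:
    """Compare calls against the truth set.

    A call matches a true junction iff both genomic cut coordinates
    agree exactly (``strict``) or within ``tolerance`` nt (``lenient``).
    ``min_reads`` optionally restricts the denominator to junctions
    simulated with at least that many spanning reads.
    """
    if mode not in (STRICT, LENIENT):
        raise ValueError(f"unknown scoring mode: {mode!r}")
    tol = 0 if mode == STRICT else tolerance
    truths = [j for j in truth.junctions
              if min_reads is None or j.n_reads >= min_reads]
    matched: set[str] = set()
    false_calls = 0
    for call in calls:
        hit = False
        for j in truths:
            if (call.donor_chrom == j.chrom and call.acceptor_chrom == j.chrom
                    and abs(call.donor_coord - j.donor_coord) <= tol
                    and abs(call.acceptor_coord - j.acceptor_coord) <= tol):
                matched.add(j.junction_id)
                hit = True
        if not hit:
            false_calls += 1
    per_class: dict[str, float] = {}
    for klass in (NEAR, DISTANT):
        members = [j for j in truths if j.distance_class == klass]
        if members:
            per_class[klass] = sum(j.junction_id in matched for j in members) / len(members)
    sensitivity = len(matched) / len(truths) if truths else 0.0
    return ScoreReport(
        sensitivity=sensitivity, per_class_sensitivity=per_class,
        n_true=len(truths), n_matched=len(matched), n_false_calls=false_calls,
        matched_junction_ids=tuple(sorted(matched)),
    )
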
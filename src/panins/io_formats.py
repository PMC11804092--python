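"""On-disk formats, coordinate conventions, and the central parameter registry.

All internal coordinates are 0-based half-open.  GFF3 (1-based inclusive) is
converted at the parsing boundary and nowhere else.  Sequences are uppercase
strings over {A,C,G,T,N}; any other letter is mapped to N with a counted
warning.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable

logger = logging.getLogger("panins")

_VALID = set("ACGTN")
_NONACGTN = re.compile(r"[^ACGTN]")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence (chromosome, contig or consensus)."""

    name: str
    seq: str

    def __post_init__(self):
        if not self.name:
            raise ValueError("sequence name must be non-empty")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval; strand '.' when irrelevant."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start <= self.end):
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-.":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    span: Interval
    biotype: str = "other"          # protein_coding | lncRNA | pseudogene | other
    exons: tuple = ()

    def __post_init__(self):
        for ex in self.exons:
            if not (self.span.start <= ex.start and ex.end <= self.span.end):
                raise ValueError(f"exon outside gene span for {self.gene_id}")


@dataclass
class PipelineParams:
    """Every numeric threshold the pipeline consumes, in one place.

    Defaults are the published pipeline's values where it prints them; the
    remainder (mash/dust/repeat-hit/merge settings) are this package's
    explicit, recorded stand-ins for values the original deferred to external
    tools.
    """

    min_insertion_len: int = 50
    cluster_cov_min: int = 8
    cluster_cov_max: int = 100
    cluster_merge_gap: int = 100
    cluster_extension: int = 7000
    min_unique_bases: int = 50
    ref_match_identity: float = 0.95
    ref_match_coverage: float = 1.00
    bbh_identity: float = 0.95
    bbh_coverage: float = 0.95
    genotype_coverage: float = 0.80
    genotype_identity: float = 0.90
    maf_min: float = 0.05
    te_flank: int = 300
    nearest_gene_window: int = 20000
    graph_min_segment: int = 50          # strict >
    species_identity: float = 0.95
    species_coverage: float = 0.95
    mash_k: int = 21
    mash_sketch: int = 1000
    dust_window: int = 64
    dust_threshold: int = 20
    repeat_hit_identity: float = 0.80
    repeat_hit_minlen: int = 30
    merge_breakpoint_slop: int = 10
    merge_identity: float = 0.95
    lineage_min_identity: float = 0.80
    lineage_min_coverage: float = 0.50
    map_accept_fraction: float = 0.60    # of the maximum possible read score

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not (0.0 <= v <= 1.0):
                raise ValueError(f"{f.name} must lie in [0,1], got {v}")
            if isinstance(v, int) and v <= 0:
                raise ValueError(f"{f.name} must be positive, got {v}")

    def override(self, **kw) -> "PipelineParams":
        return replace(self, **kw)

    def as_header_lines(self) -> list[str]:
        """`#`-prefixed key=value lines recording effective parameter values."""
        return [f"# {f.name}={getattr(self, f.name)}" for f in fields(self)]


DEFAULT_PARAMS = PipelineParams()


# ---------------------------------------------------------------------------
# Sequence hygiene
# ---------------------------------------------------------------------------

def clean_sequence(seq: str) -> tuple[str, int]:
    """Uppercase and map non-ACGTN letters to N; returns (seq, n_replaced)."""
    s = seq.upper()
    n_bad = sum(1 for c in s if c not in _VALID)
    if n_bad:
        s = _NONACGTN.sub("N", s)
    return s, n_bad


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[GenomeSequence]:
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    name = None
    chunks: list[str] = []
    n_bad_total = 0

    def _flush():
        nonlocal n_bad_total
        if name is None:
            return
        seq, n_bad = clean_sequence("".join(chunks))
        n_bad_total += n_bad
        records.append(GenomeSequence(name, seq))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ValueError(f"{path}: empty FASTA header")
                if name in seen:
                    raise ValueError(f"{path}: duplicate header {name!r}")
                seen.add(name)
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence before first header")
                chunks.append(line.strip())
    _flush()
    if not records:
        raise ValueError(f"{path}: no records")
    if n_bad_total:
        logger.warning("%s: %d non-ACGTN characters mapped to N", path, n_bad_total)
    return records


def write_fasta(seqs: Iterable[GenomeSequence], path, wrap: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in seqs:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i:i + wrap] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> list[Interval]:
    out: list[Interval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs ≥3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "."
            if end <= start:
                raise ValueError(f"{path}:{ln}: end ≤ start")
            out.append(Interval(chrom, start, end, strand))
    return out


def write_bed(intervals: Iterable[Interval], path, names: Iterable[str] | None = None) -> None:
    names = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None:
                cols += [names[i], "0", iv.strand if iv.strand != "." else "+"]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# GFF3  (1-based inclusive on disk -> 0-based half-open in memory)
# ---------------------------------------------------------------------------

_BIOTYPES = {"protein_coding", "lncRNA", "pseudogene"}


def _gff_attrs(col9: str) -> dict[str, str]:
    out = {}
    for kv in col9.strip().split(";"):
        if "=" in kv:
            k, v = kv.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path) -> list[GeneModel]:
    """Parse gene + exon features into GeneModel records.

    Biotype comes from a `biotype`/`gene_biotype` attribute, falling back to
    the feature type for lncRNA/pseudogene rows and "other" otherwise.
    """
    genes: dict[str, dict] = {}
    exon_rows: list[tuple[str, Interval]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{ln}: GFF3 needs 9 columns")
            chrom, _src, ftype, start1, end1, _score, strand, _phase, attrs = parts[:9]
            start, end = int(start1) - 1, int(end1)
            if end <= start:
                raise ValueError(f"{path}:{ln}: end ≤ start after conversion")
            a = _gff_attrs(attrs)
            if ftype in ("gene", "ncRNA_gene", "pseudogene", "lnc_RNA", "lncRNA_gene"):
                gid = a.get("ID") or a.get("gene_id")
                if gid is None:
                    raise ValueError(f"{path}:{ln}: gene without ID")
                bt = a.get("biotype") or a.get("gene_biotype")
                if bt not in _BIOTYPES:
                    bt = {"pseudogene": "pseudogene", "lnc_RNA": "lncRNA",
                          "lncRNA_gene": "lncRNA"}.get(ftype, bt)
                if bt not in _BIOTYPES:
                    bt = "other"
                genes[gid] = {"span": Interval(chrom, start, end, strand if strand in "+-" else "."),
                              "biotype": bt, "exons": []}
            elif ftype == "exon":
                parent = a.get("Parent") or a.get("gene_id")
                if parent:
                    # Parent may be a transcript id formatted <gene>.tN or an
                    # explicit gene id; match on the longest gene-id prefix.
                    exon_rows.append((parent, Interval(chrom, start, end)))
    for parent, iv in exon_rows:
        gid = parent
        while gid and gid not in genes:
            gid = gid.rpartition(".")[0]
        if gid in genes:
            genes[gid]["exons"].append(iv)
    out = []
    for gid, g in genes.items():
        exons = tuple(sorted(set(g["exons"]), key=lambda e: (e.start, e.end)))
        out.append(GeneModel(gid, g["span"], g["biotype"], exons))
    out.sort(key=lambda g: (g.span.chrom, g.span.start, g.gene_id))
    return out


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s = g.span
            fh.write("\t".join([s.chrom, "panins", "gene", str(s.start + 1), str(s.end),
                                ".", s.strand if s.strand != "." else "+", ".",
                                f"ID={g.gene_id};biotype={g.biotype}"]) + "\n")
            for i, ex in enumerate(g.exons, 1):
                fh.write("\t".join([s.chrom, "panins", "exon", str(ex.start + 1), str(ex.end),
                                    ".", s.strand if s.strand != "." else "+", ".",
                                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}"]) + "\n")


# ---------------------------------------------------------------------------
# GFA1
# ---------------------------------------------------------------------------

REFERENCE_LABEL = "reference"


@dataclass
class PangenomeGraph:
    """Sequence graph: segments carry an origin set (which genomes contain
    them); links are directed (segment, end) -> (segment, end) adjacencies.
    """

    segments: dict = field(default_factory=dict)    # id -> (seq, origin_set)
    links: set = field(default_factory=set)         # (id1, or1, id2, or2)
    backbone_order: list = field(default_factory=list)

    def add_segment(self, sid: str, seq: str, origins: set[str]) -> None:
        if not origins:
            raise ValueError(f"segment {sid}: empty origin set")
        self.segments[sid] = (seq, set(origins))

    def add_link(self, a: str, oa: str, b: str, ob: str) -> None:
        for sid in (a, b):
            if sid not in self.segments:
                raise ValueError(f"link references unknown segment {sid!r}")
        self.links.add((a, oa, b, ob))

    def is_reference(self, sid: str) -> bool:
        return REFERENCE_LABEL in self.segments[sid][1]

    def seq(self, sid: str) -> str:
        return self.segments[sid][0]

    def origins(self, sid: str) -> set[str]:
        return self.segments[sid][1]


def read_gfa(path) -> PangenomeGraph:
    g = PangenomeGraph()
    pending_links = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line[0] == "H" or line[0] == "#":
                continue
            parts = line.split("\t")
            if parts[0] == "S":
                if len(parts) < 3:
                    raise ValueError(f"{path}:{ln}: bad S line")
                sid, seq = parts[1], parts[2]
                origins = {REFERENCE_LABEL}
                for tag in parts[3:]:
                    if tag.startswith("SR:Z:"):
                        origins = set(tag[5:].split(","))
                g.add_segment(sid, seq, origins)
            elif parts[0] == "L":
                if len(parts) < 5:
                    raise ValueError(f"{path}:{ln}: bad L line")
                pending_links.append((parts[1], parts[2], parts[3], parts[4]))
    for a, oa, b, ob in pending_links:
        g.add_link(a, oa, b, ob)
    return g


def write_gfa(graph: PangenomeGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for sid in sorted(graph.segments):
            seq, origins = graph.segments[sid]
            fh.write(f"S\t{sid}\t{seq}\tLN:i:{len(seq)}\tSR:Z:{','.join(sorted(origins))}\n")
        for a, oa, b, ob in sorted(graph.links):
            fh.write(f"L\t{a}\t{oa}\t{b}\t{ob}\t0M\n")


# ---------------------------------------------------------------------------
# TSV report helper
# ---------------------------------------------------------------------------

def write_tsv(path, header: list[str], rows: Iterable[Iterable], params: PipelineParams | None = None) -> None:
    with open(path, "w") as fh:
        if params is not None:
            fh.write("\n".join(params.as_header_lines()) + "\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
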
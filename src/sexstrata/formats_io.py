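"""Readers and writers for the external formats the pipeline touches.

All coordinates exposed by this package are 0-based, half-open. Conversions
happen only at the file boundary: samtools-depth positions (1-based) and
GFF3 coordinates (1-based, inclusive) are shifted on read and shifted back
on write; BedGraph and BED are already 0-based half-open.

Depth tracks are stored run-length encoded. Positions absent from a
samtools-depth file are treated as depth 0 (samtools depth omits zero rows
by default).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """A malformed row in an input file; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def contains(self, pos: float) -> bool:
        return self.start <= pos < self.end

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class DepthTrack:
    """Run-length encoded read depth for one pool on one chromosome.

    ``starts``/``ends``/``depths`` are parallel arrays of non-overlapping,
    sorted runs; any base of [0, length) not covered by a run has depth 0.
    """

    chrom: str
    length: int
    starts: np.ndarray
    ends: np.ndarray
    depths: np.ndarray
    pool_label: str = "unlabeled"

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if not (len(self.starts) == len(self.ends) == len(self.depths)):
            raise ValueError("RLE arrays must have equal length")
        if len(self.starts):
            if np.any(self.depths < 0):
                raise ValueError("depths must be non-negative")
            if np.any(self.ends <= self.starts):
                raise ValueError("empty or inverted run")
            if np.any(self.starts[1:] < self.ends[:-1]):
                raise ValueError("runs must be sorted and non-overlapping")
            if self.starts[0] < 0 or self.ends[-1] > self.length:
                raise ValueError("runs must lie within [0, length)")
        # prefix sums of depth*span, for O(log n) range sums
        spans = self.ends - self.starts
        self._cum = np.concatenate([[0], np.cumsum(self.depths * spans)])

    def _cum_at(self, x: np.ndarray) -> np.ndarray:
        """Total depth-bases over [0, x) for each x (vectorized)."""
        x = np.asarray(x, dtype=np.int64)
        i = np.searchsorted(self.starts, x, side="right") - 1
        out = np.zeros(x.shape, dtype=np.float64)
        has = i >= 0
        ii = i[has]
        inside = np.minimum(x[has], self.ends[ii]) - self.starts[ii]
        inside = np.maximum(inside, 0)
        out[has] = self._cum[ii] + self.depths[ii] * inside
        return out

    def range_sum(self, start: int, end: int) -> float:
        """Sum of per-base depth over [start, end)."""
        sums = self._cum_at(np.array([start, end]))
        return float(sums[1] - sums[0])

    def mean_depth(self, start: int | None = None, end: int | None = None) -> float:
        start = 0 if start is None else start
        end = self.length if end is None else end
        if end <= start:
            raise ValueError("empty range")
        return self.range_sum(start, end) / (end - start)

    def to_dense(self) -> np.ndarray:
        """Per-base depth array of shape (length,). For small tracks/tests."""
        out = np.zeros(self.length, dtype=np.int64)
        for s, e, d in zip(self.starts, self.ends, self.depths):
            out[s:e] = d
        return out

    @classmethod
    def from_dense(cls, chrom: str, depths, pool_label: str = "unlabeled") -> "DepthTrack":
        depths = np.asarray(depths, dtype=np.int64)
        if len(depths) == 0:
            return cls(chrom, 0, [], [], [], pool_label)
        change = np.flatnonzero(np.diff(depths)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(depths)]])
        vals = depths[starts]
        keep = vals != 0
        return cls(chrom, len(depths), starts[keep], ends[keep], vals[keep], pool_label)


@dataclass
class GeneRecord:
    """One gene feature from a GFF3 annotation."""

    gene_id: str
    interval: GenomicInterval
    attributes: dict = field(default_factory=dict)


@dataclass(frozen=True)
class HomologyHit:
    """One homology relation between an SLR gene and a subject gene."""

    query_id: str
    subject_id: str
    subject_chrom: str
    identity: float
    source: str  # {synteny, blast}

    def __post_init__(self):
        if not (0 <= self.identity <= 100):
            raise ValueError(f"identity must be in [0,100], got {self.identity}")
        if self.source not in ("synteny", "blast"):
            raise ValueError(f"source must be synteny or blast, got {self.source!r}")


# ---------------------------------------------------------------------------
# Depth tracks
# ---------------------------------------------------------------------------

def read_depth_track(
    path,
    dialect: str,
    chrom: str | None = None,
    chrom_length: int | None = None,
    pool_label: str = "unlabeled",
) -> DepthTrack:
    """Read one chromosome's depth from a samtools-depth TSV or a BedGraph.

    samtools-depth rows are ``chrom  pos(1-based)  depth``; BedGraph rows are
    ``chrom  start  end  depth`` with 0-based half-open intervals. Rows must
    be sorted by (chrom, position). If the file covers several chromosomes,
    ``chrom`` selects one; otherwise exactly one must be present. The track
    length defaults to the last covered base.
    """
    if dialect not in ("samtools_depth", "bedgraph"):
        raise ValueError(f"unknown dialect {dialect!r}")
    starts, ends, depths = [], [], []
    seen_chroms: list[str] = []
    last_end = -1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            try:
                if dialect == "samtools_depth":
                    c, pos, depth = fields[0], int(fields[1]), int(fields[2])
                    s, e = pos - 1, pos  # 1-based -> 0-based half-open
                else:
                    c, s, e, depth = (
                        fields[0], int(fields[1]), int(fields[2]), int(fields[3])
                    )
            except (IndexError, ValueError) as exc:
                raise ParseError(f"malformed {dialect} row: {line!r}", lineno) from exc
            if depth < 0 or s < 0 or e <= s:
                raise ParseError(f"invalid coordinates/depth: {line!r}", lineno)
            if c not in seen_chroms:
                seen_chroms.append(c)
                if chrom is None or c == chrom:
                    last_end = -1
            if chrom is not None and c != chrom:
                continue
            if len(seen_chroms) > 1 and chrom is None:
                raise ParseError(
                    f"multiple chromosomes present ({seen_chroms}); pass chrom=", lineno
                )
            if s < last_end:
                raise ParseError(f"unsorted/overlapping input at {line!r}", lineno)
            last_end = e
            # merge with previous run when contiguous and equal depth
            if starts and ends[-1] == s and depths[-1] == depth:
                ends[-1] = e
            elif depth != 0:
                starts.append(s)
                ends.append(e)
                depths.append(depth)
    if chrom is None:
        if not seen_chroms:
            raise ParseError(f"no data rows in {path}")
        chrom = seen_chroms[0]
    length = chrom_length if chrom_length is not None else (ends[-1] if ends else 0)
    return DepthTrack(chrom, length, starts, ends, depths, pool_label)


def write_depth_track(track: DepthTrack, path, dialect: str) -> None:
    """Write a track back out; inverse of :func:`read_depth_track`."""
    with open(path, "w") as fh:
        if dialect == "samtools_depth":
            for s, e, d in zip(track.starts, track.ends, track.depths):
                for pos0 in range(s, e):
                    fh.write(f"{track.chrom}\t{pos0 + 1}\t{d}\n")
        elif dialect == "bedgraph":
            for s, e, d in zip(track.starts, track.ends, track.depths):
                fh.write(f"{track.chrom}\t{s}\t{e}\t{d}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# GFF3 / BED
# ---------------------------------------------------------------------------

_ID_RE = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def read_gff3_genes(path, feature_type: str = "gene") -> list[GeneRecord]:
    """Read gene features from a GFF3 file.

    Only rows whose type equals ``feature_type`` are returned. 1-based
    inclusive coordinates become 0-based half-open. A missing ID attribute or
    start > end is an error naming the offending line.
    """
    genes: list[GeneRecord] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"expected 9 GFF3 columns, got {len(cols)}", lineno)
            if cols[2] != feature_type:
                continue
            try:
                start1, end1 = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinates: {line!r}", lineno) from exc
            if start1 > end1:
                raise ParseError(f"start > end in {line!r}", lineno)
            m = _ID_RE.search(cols[8])
            if not m:
                raise ParseError(f"missing ID attribute in {line!r}", lineno)
            gene_id = m.group(1).strip()
            if gene_id in seen_ids:
                raise ParseError(f"duplicate gene ID {gene_id!r}", lineno)
            seen_ids.add(gene_id)
            attributes = {}
            for item in cols[8].split(";"):
                item = item.strip()
                if item and "=" in item:
                    k, v = item.split("=", 1)
                    attributes[k] = v
            strand = cols[6] if cols[6] in ("+", "-") else "."
            interval = GenomicInterval(cols[0], start1 - 1, end1, strand)
            genes.append(GeneRecord(gene_id, interval, attributes))
    return genes


def write_gff3_genes(genes: list[GeneRecord], path, source: str = "sexstrata") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            attrs = dict(g.attributes)
            attrs["ID"] = g.gene_id
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand if iv.strand != '.' else '+'}\t.\t{attr_str}\n"
            )


def read_bed_intervals(path) -> list[GenomicInterval]:
    """Read BED3(+) rows as 0-based half-open intervals."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            try:
                out.append(GenomicInterval(cols[0], int(cols[1]), int(cols[2])))
            except (IndexError, ValueError) as exc:
                raise ParseError(f"malformed BED row: {line!r}", lineno) from exc
    return out


def write_bed_intervals(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Homology tables
# ---------------------------------------------------------------------------

HOMOLOGY_COLUMNS = ["query_id", "subject_id", "subject_chrom", "identity", "source"]


def read_homology_table(path) -> list[HomologyHit]:
    """Read a TSV with header ``query_id subject_id subject_chrom identity source``."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in HOMOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"homology table {path} missing columns {missing}")
    return [
        HomologyHit(
            str(r.query_id), str(r.subject_id), str(r.subject_chrom),
            float(r.identity), str(r.source),
        )
        for r in df.itertuples(index=False)
    ]


def write_homology_table(hits, path) -> None:
    pd.DataFrame(
        [(h.query_id, h.subject_id, h.subject_chrom, h.identity, h.source) for h in hits],
        columns=HOMOLOGY_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Labeled trees (newick)
# ---------------------------------------------------------------------------

def read_labeled_tree(path_or_string, label_pattern: str = "SPECIES|COPY",
                      gene_group_id: str | None = None):
    """Parse a newick tree whose leaf names encode species and gametolog copy.

    The default pattern splits leaf names on ``|``: ``sp|X``, ``sp|Y`` for
    gametologs and ``sp|A`` for an autosomal/outgroup copy. Support values
    are preserved. Returns a :class:`~sexstrata.gametolog_trees.LabeledTree`.
    """
    from .gametolog_trees import LabeledTree, parse_leaf_label

    import dendropy

    src = str(path_or_string)
    if src.lstrip().startswith("(") and src.rstrip().endswith(";"):
        tree = dendropy.Tree.get(data=src, schema="newick")
    else:
        tree = dendropy.Tree.get(path=src, schema="newick")
    labels = {}
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label if leaf.taxon else None
        if name is None:
            raise ParseError("unlabeled leaf in tree")
        labels[name] = parse_leaf_label(name, label_pattern)
    return LabeledTree(tree=tree, labels=labels, gene_group_id=gene_group_id)


def write_labeled_tree(labeled_tree, path) -> None:
    labeled_tree.tree.write(path=str(path), schema="newick",
                            suppress_rooting=True)


# ---------------------------------------------------------------------------
# Paired codon alignments
# ---------------------------------------------------------------------------

def read_pair_fasta(path) -> dict[str, dict[str, str]]:
    """Read gametolog pairs from FASTA with record ids ``<pair_id>|X`` / ``<pair_id>|Y``.

    Returns {pair_id: {"X": seq, "Y": seq}} with both copies required.
    """
    from Bio import SeqIO

    pairs: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ParseError(f"record id {rec.id!r} lacks '|COPY' suffix")
        pair_id, copy = rec.id.rsplit("|", 1)
        if copy not in ("X", "Y"):
            raise ParseError(f"record id {rec.id!r}: copy must be X or Y")
        pairs.setdefault(pair_id, {})[copy] = str(rec.seq).upper()
    for pid, d in pairs.items():
        if set(d) != {"X", "Y"}:
            raise ParseError(f"pair {pid!r} missing copy {'X' if 'X' not in d else 'Y'}")
    return pairs


def write_pair_fasta(pairs: dict[str, dict[str, str]], path) -> None:
    with open(path, "w") as fh:
        for pid in pairs:
            for copy in ("X", "Y"):
                fh.write(f">{pid}|{copy}\n{pairs[pid][copy]}\n")


def mb(bp: float) -> float:
    """Base pairs -> megabases rounded half-up to 2 decimals (report display)."""
    import decimal

    return float(
        (decimal.Decimal(bp) / decimal.Decimal(1_000_000)).quantize(
            decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP
        )
    )
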
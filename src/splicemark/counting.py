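"""Read filtering and junction / exon-block counting.

The filter rule: a read is used only if it is a primary alignment with
MAPQ > 10 and fewer mismatches than 5% of its aligned length.  Each
skipped-region gap (CIGAR ``N``) of a passing read increments one junction;
a read spanning two gaps increments two junctions.  Exon-block counting
increments every block a read's aligned segments overlap by at least one
base, once per (read, block) pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel, GenomicInterval, Junction

__all__ = [
    "CountingError",
    "AlignedRead",
    "JunctionCountTable",
    "ExonCountTable",
    "passes_filters",
    "read_sam",
    "count_junction_reads",
    "count_exon_reads",
    "read_star_sj",
    "write_star_sj",
    "read_bed12_junctions",
    "rpm_normalize",
    "write_rpm_bedgraph",
]

logger = logging.getLogger(__name__)


class CountingError(ValueError):
    pass


@dataclass(frozen=True)
class AlignedRead:
    """The slice of an alignment the counting stage needs.

    ``blocks`` are gapless aligned reference segments (0-based half-open);
    ``gaps`` are the skipped reference spans (CIGAR N) between them.
    ``mismatch_count`` is the edit-distance tag value, None when absent.
    """

    name: str
    chrom: str
    mapq: int
    blocks: tuple[tuple[int, int], ...]
    gaps: tuple[tuple[int, int], ...] = ()
    mismatch_count: int | None = 0
    is_secondary: bool = False
    is_supplementary: bool = False
    is_unmapped: bool = False

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


def passes_filters(
    read: AlignedRead,
    max_mismatch_frac: float = 0.05,
    min_mapq: int = 10,
    missing_mismatch: str = "pass",
) -> bool:
    """Apply the uniquely-mapped read filter.

    True iff the read is a primary mapped alignment with MAPQ strictly above
    ``min_mapq`` and mismatch count strictly below ``max_mismatch_frac`` of
    its aligned length.  A missing mismatch tag passes (with a warning) or
    fails depending on ``missing_mismatch`` ("pass" | "fail").
    """
    if read.is_unmapped:
        raise CountingError(f"read {read.name} is unmapped")
    if read.is_secondary or read.is_supplementary:
        return False
    if read.mapq <= min_mapq:
        return False
    if read.mismatch_count is None:
        if missing_mismatch == "pass":
            logger.warning("read %s has no mismatch tag; treated as passing", read.name)
            return True
        return False
    return read.mismatch_count < max_mismatch_frac * read.aligned_length


def read_sam(path: str | Path) -> Iterator[AlignedRead]:
    """Stream mapped reads from a SAM/BAM file via pysam."""
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            blocks: list[tuple[int, int]] = []
            gaps: list[tuple[int, int]] = []
            pos = seg.reference_start
            block_start = pos
            open_block = False
            for op, length in seg.cigartuples or []:
                if op in (0, 7, 8):  # M, =, X
                    if not open_block:
                        block_start = pos
                        open_block = True
                    pos += length
                elif op == 2:  # D: consumes reference, stays in block
                    pos += length
                elif op == 3:  # N: splice gap
                    if open_block:
                        blocks.append((block_start, pos))
                        open_block = False
                    gaps.append((pos, pos + length))
                    pos += length
                # I, S, H, P consume no reference
            if open_block:
                blocks.append((block_start, pos))
            try:
                nm = seg.get_tag("NM")
            except KeyError:
                nm = None
            yield AlignedRead(
                name=seg.query_name or "",
                chrom=seg.reference_name or "",
                mapq=seg.mapping_quality,
                blocks=tuple(blocks),
                gaps=tuple(gaps),
                mismatch_count=nm,
                is_secondary=seg.is_secondary,
                is_supplementary=seg.is_supplementary,
            )


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

class _CountTable:
    """Integer count matrix (feature keys x sample ids) backed by pandas."""

    def __init__(self, counts: pd.DataFrame):
        if (counts.to_numpy() < 0).any():
            raise CountingError("negative counts")
        self.counts = counts.astype(np.int64)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path, index_label: str = "key") -> None:
        self.counts.to_csv(path, sep="\t", index_label=index_label)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, _CountTable) and self.counts.equals(other.counts)


class JunctionCountTable(_CountTable):
    """Per-sample unique-read counts for splice junctions.

    Rows are junction keys (``chrom:intron_start-intron_end:strand``); the
    :class:`~splicemark.annotation.Junction` objects are kept alongside.
    """

    def __init__(self, counts: pd.DataFrame, junctions: Mapping[str, Junction]):
        super().__init__(counts)
        self.junctions = dict(junctions)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[Junction, str, int]]
    ) -> "JunctionCountTable":
        cells: dict[str, dict[str, int]] = {}
        junctions: dict[str, Junction] = {}
        for junction, sample, count in records:
            junctions[junction.key] = junction
            row = cells.setdefault(junction.key, {})
            row[sample] = row.get(sample, 0) + int(count)
        frame = (
            pd.DataFrame.from_dict(cells, orient="index")
            .fillna(0)
            .sort_index()
            .sort_index(axis=1)
        )
        return cls(frame, junctions)

    def count_of(self, junction: Junction, sample: str) -> int:
        """Count for a junction, falling back to a strand-ambiguous row.

        A catalog junction absent from the table counts 0.
        """
        key = junction.key
        if key in self.counts.index:
            return int(self.counts.at[key, sample])
        amb = f"{junction.chrom}:{junction.intron_start}-{junction.intron_end}:."
        if amb in self.counts.index:
            return int(self.counts.at[amb, sample])
        return 0

    def row_of(self, junction: Junction) -> pd.Series:
        key = junction.key
        if key in self.counts.index:
            return self.counts.loc[key]
        amb = f"{junction.chrom}:{junction.intron_start}-{junction.intron_end}:."
        if amb in self.counts.index:
            return self.counts.loc[amb]
        return pd.Series(0, index=self.counts.columns, dtype=np.int64)

    def merged(self, other: "JunctionCountTable") -> "JunctionCountTable":
        counts = self.counts.add(other.counts, fill_value=0).astype(np.int64)
        junctions = {**self.junctions, **other.junctions}
        return JunctionCountTable(counts.sort_index().sort_index(axis=1), junctions)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "JunctionCountTable":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        junctions = {}
        for key in frame.index:
            chrom, span, strand = key.rsplit(":", 2)
            s, e = span.split("-")
            junctions[key] = Junction.from_intron(chrom, int(s), int(e), strand)
        return cls(frame, junctions)


class ExonCountTable(_CountTable):
    """Per-sample read counts for flattened exon blocks (gene_id + interval)."""


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def _strand_index(annotated: Iterable[Junction] | None) -> dict[tuple, Junction]:
    index: dict[tuple, Junction] = {}
    for j in annotated or ():
        index[(j.chrom, j.intron_start, j.intron_end)] = j
    return index


def count_junction_reads(
    reads_by_sample: Mapping[str, Iterable[AlignedRead]],
    annotated_junctions: Iterable[Junction] | None = None,
    max_mismatch_frac: float = 0.05,
    min_mapq: int = 10,
) -> JunctionCountTable:
    """Count junction-spanning reads per sample.

    Each N-gap in a passing read increments the junction at that intron.
    Gap strand is taken from a matching annotated junction when provided,
    else recorded as ambiguous (``.``).
    """
    index = _strand_index(annotated_junctions)
    records: list[tuple[Junction, str, int]] = []
    per_sample_seen: dict[str, dict[str, int]] = {}
    for sample, reads in reads_by_sample.items():
        tallies = per_sample_seen.setdefault(sample, {})
        for read in reads:
            if not passes_filters(read, max_mismatch_frac, min_mapq):
                continue
            for gap_start, gap_end in read.gaps:
                if gap_end <= gap_start:
                    logger.warning(
                        "read %s: non-positive gap %d-%d skipped",
                        read.name, gap_start, gap_end,
                    )
                    continue
                j = index.get((read.chrom, gap_start, gap_end))
                if j is None:
                    j = Junction.from_intron(read.chrom, gap_start, gap_end, ".")
                tallies[j.key] = tallies.get(j.key, 0) + 1
                records.append((j, sample, 1))
    if not records:
        # empty table with the requested sample columns
        frame = pd.DataFrame(
            {s: pd.Series(dtype=np.int64) for s in reads_by_sample}
        )
        return JunctionCountTable(frame, {})
    table = JunctionCountTable.from_records(records)
    missing = [s for s in reads_by_sample if s not in table.counts.columns]
    for s in missing:
        table.counts[s] = 0
    table.counts = table.counts.sort_index(axis=1)
    return table


def _flatten_exon_blocks(
    models: Mapping[str, GeneModel]
) -> list[tuple[str, GenomicInterval]]:
    """Merge overlapping exons within each gene into disjoint blocks."""
    blocks: list[tuple[str, GenomicInterval]] = []
    for gene_id, model in models.items():
        intervals = sorted(
            (e.start, e.end) for exons in model.transcripts.values() for e in exons
        )
        merged: list[list[int]] = []
        for s, e in intervals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            blocks.append((gene_id, GenomicInterval(model.chrom, s, e, model.strand)))
    return blocks


def count_exon_reads(
    reads_by_sample: Mapping[str, Iterable[AlignedRead]],
    models: Mapping[str, GeneModel],
    max_mismatch_frac: float = 0.05,
    min_mapq: int = 10,
) -> ExonCountTable:
    """Count reads per flattened exon block (>=1-base overlap rule)."""
    blocks = _flatten_exon_blocks(models)
    keys = [f"{g}|{iv.chrom}:{iv.start}-{iv.end}" for g, iv in blocks]
    trees: dict[str, IntervalTree] = {}
    for key, (_, iv) in zip(keys, blocks):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, key)

    frame = pd.DataFrame(0, index=keys, columns=sorted(reads_by_sample), dtype=np.int64)
    for sample, reads in reads_by_sample.items():
        for read in reads:
            if not passes_filters(read, max_mismatch_frac, min_mapq):
                continue
            tree = trees.get(read.chrom)
            if tree is None:
                continue
            hit: set[str] = set()
            for s, e in read.blocks:
                for iv in tree.overlap(s, e):
                    hit.add(iv.data)
            for key in hit:
                frame.at[key, sample] += 1
    return ExonCountTable(frame)


# ---------------------------------------------------------------------------
# file dialects
# ---------------------------------------------------------------------------

_SJ_STRAND = {"0": ".", "1": "+", "2": "-"}
_SJ_STRAND_BACK = {".": "0", "+": "1", "-": "2"}


def read_star_sj(path: str | Path, sample_id: str) -> JunctionCountTable:
    """Read a STAR ``SJ.out.tab`` file (9 columns, 1-based inclusive introns).

    The unique-read column is used as the count.  Rows with undefined strand
    (code 0) are retained as strand-ambiguous junctions.
    """
    records: list[tuple[Junction, str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise CountingError(
                    f"{path}: line {lineno}: expected 9 columns, got {len(fields)}"
                )
            chrom, start, end, strand_code = fields[0], fields[1], fields[2], fields[3]
            unique = fields[6]
            try:
                start_i, end_i, unique_i = int(start), int(end), int(unique)
            except ValueError:
                raise CountingError(
                    f"{path}: line {lineno}: non-integer fields"
                ) from None
            strand = _SJ_STRAND.get(strand_code)
            if strand is None:
                raise CountingError(
                    f"{path}: line {lineno}: bad strand code {strand_code!r}"
                )
            # 1-based inclusive intron -> 0-based half-open
            try:
                j = Junction.from_intron(chrom, start_i - 1, end_i, strand)
            except Exception as exc:
                raise CountingError(f"{path}: line {lineno}: {exc}") from None
            records.append((j, sample_id, unique_i))
    if not records:
        frame = pd.DataFrame({sample_id: pd.Series(dtype=np.int64)})
        return JunctionCountTable(frame, {})
    return JunctionCountTable.from_records(records)


def write_star_sj(table: JunctionCountTable, sample_id: str, path: str | Path) -> None:
    """Write one sample of a junction table in the SJ.out.tab dialect."""
    with open(path, "w") as fh:
        for key in table.counts.index:
            j = table.junctions[key]
            count = int(table.counts.at[key, sample_id])
            fh.write(
                "\t".join(
                    [
                        j.chrom,
                        str(j.intron_start + 1),
                        str(j.intron_end),
                        _SJ_STRAND_BACK[j.strand],
                        "0",
                        "1",
                        str(count),
                        "0",
                        "50",
                    ]
                )
                + "\n"
            )


def read_bed12_junctions(path: str | Path, sample_id: str) -> JunctionCountTable:
    """Read a BED12 junction track: blocks define junctions, score = count."""
    records: list[tuple[Junction, str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise CountingError(
                    f"{path}: line {lineno}: expected 12 BED columns"
                )
            chrom = fields[0]
            try:
                chrom_start = int(fields[1])
                score = int(float(fields[4]))
                strand = fields[5]
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError:
                raise CountingError(
                    f"{path}: line {lineno}: malformed numeric fields"
                ) from None
            if strand not in ("+", "-", "."):
                raise CountingError(f"{path}: line {lineno}: bad strand {strand!r}")
            for (s1, l1), s2 in zip(
                zip(starts, sizes), starts[1:]
            ):
                intron_start = chrom_start + s1 + l1
                intron_end = chrom_start + s2
                if intron_end <= intron_start:
                    raise CountingError(
                        f"{path}: line {lineno}: non-positive intron span"
                    )
                j = Junction.from_intron(chrom, intron_start, intron_end, strand)
                records.append((j, sample_id, score))
    if not records:
        frame = pd.DataFrame({sample_id: pd.Series(dtype=np.int64)})
        return JunctionCountTable(frame, {})
    return JunctionCountTable.from_records(records)


# ---------------------------------------------------------------------------
# normalization / coverage
# ---------------------------------------------------------------------------

def rpm_normalize(values, total_unique_reads: int):
    """Scale counts to reads-per-million uniquely mapped reads."""
    if total_unique_reads <= 0:
        raise CountingError("total_unique_reads must be positive")
    arr = np.asarray(values, dtype=float) * 1e6 / total_unique_reads
    if isinstance(values, pd.Series):
        return pd.Series(arr, index=values.index)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(arr, index=values.index, columns=values.columns)
    if np.isscalar(values):
        return float(arr)
    return arr


def write_rpm_bedgraph(
    reads: Iterable[AlignedRead],
    total_unique_reads: int,
    path: str | Path,
    max_mismatch_frac: float = 0.05,
    min_mapq: int = 10,
) -> None:
    """Write RPM-scaled per-base coverage of passing reads as bedGraph."""
    if total_unique_reads <= 0:
        raise CountingError("total_unique_reads must be positive")
    edges: dict[str, dict[int, int]] = {}
    for read in reads:
        if not passes_filters(read, max_mismatch_frac, min_mapq):
            continue
        diff = edges.setdefault(read.chrom, {})
        for s, e in read.blocks:
            diff[s] = diff.get(s, 0) + 1
            diff[e] = diff.get(e, 0) - 1
    scale = 1e6 / total_unique_reads
    with open(path, "w") as fh:
        for chrom in sorted(edges):
            depth = 0
            positions = sorted(edges[chrom])
            for pos, nxt in zip(positions, positions[1:] + [None]):
                depth += edges[chrom][pos]
                if nxt is not None and depth > 0:
                    fh.write(f"{chrom}\t{pos}\t{nxt}\t{depth * scale:.6g}\n")
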
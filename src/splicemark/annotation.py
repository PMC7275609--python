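"""Gene models and the splicing-event catalog.

Coordinates are 0-based half-open internally; GTF (1-based inclusive) and
refFlat (already 0-based half-open) convert at the file boundary.

Splice-site vocabulary is transcript-oriented: the donor (5' splice site) is
the last exonic base of the upstream exon, the acceptor (3' splice site) the
first exonic base of the downstream exon.  On the minus strand the donor is
therefore the genomically *rightmost* of the two sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "AnnotationError",
    "GenomicInterval",
    "GeneModel",
    "Junction",
    "CassetteEvent",
    "SiteGroup",
    "TerminalExonEvent",
    "junction_between",
    "read_gene_models",
    "write_refflat",
    "build_cassette_events",
    "build_site_groups",
    "classify_terminal_events",
    "transcript_junctions",
    "write_event_catalog",
]

STRANDS = ("+", "-")


class AnnotationError(ValueError):
    """Raised for malformed annotation input or invariant violations."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval on a fixed strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Junction:
    """A strand-aware splice junction keyed by its donor and acceptor sites.

    ``donor_site`` is the genomic coordinate (0-based) of the last base of
    the upstream exon; ``acceptor_site`` the first base of the downstream
    exon.  Junctions of undetermined strand (e.g. unannotated SJ rows with
    strand code 0) carry strand ``"."`` with a plus-like site layout and are
    flagged :attr:`ambiguous`.
    """

    chrom: str
    donor_site: int
    acceptor_site: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand == "+" or self.strand == ".":
            ok = self.donor_site < self.acceptor_site
        elif self.strand == "-":
            ok = self.donor_site > self.acceptor_site
        else:
            raise AnnotationError(f"invalid junction strand {self.strand!r}")
        if not ok:
            raise AnnotationError(
                f"donor/acceptor order violates strand {self.strand}: "
                f"{self.chrom}:{self.donor_site}/{self.acceptor_site}"
            )

    @property
    def ambiguous(self) -> bool:
        return self.strand == "."

    @property
    def intron_start(self) -> int:
        """0-based first intronic base."""
        if self.strand == "-":
            return self.acceptor_site + 1
        return self.donor_site + 1

    @property
    def intron_end(self) -> int:
        """0-based exclusive end of the intron."""
        if self.strand == "-":
            return self.donor_site
        return self.acceptor_site

    @property
    def key(self) -> str:
        """Stable row key: intron coordinates plus strand."""
        return f"{self.chrom}:{self.intron_start}-{self.intron_end}:{self.strand}"

    @classmethod
    def from_intron(
        cls, chrom: str, intron_start: int, intron_end: int, strand: str
    ) -> "Junction":
        if intron_end <= intron_start:
            raise AnnotationError(
                f"non-positive intron span {chrom}:{intron_start}-{intron_end}"
            )
        if strand == "-":
            return cls(chrom, intron_end, intron_start - 1, "-")
        return cls(chrom, intron_start - 1, intron_end, strand)


def junction_between(
    left: GenomicInterval, right: GenomicInterval, strand: str
) -> Junction:
    """Junction spliced between a genomically left and right exon."""
    if left.end > right.start:
        raise AnnotationError("exons overlap or touch; no intron between them")
    return Junction.from_intron(left.chrom, left.end, right.start, strand)


@dataclass
class GeneModel:
    """A gene with one or more transcripts, each an ordered exon chain."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, tuple[GenomicInterval, ...]] = field(default_factory=dict)

    def add_transcript(self, tx_id: str, exons: Sequence[GenomicInterval]) -> None:
        if not exons:
            raise AnnotationError(f"transcript {tx_id} has no exons")
        exons = tuple(sorted(exons, key=lambda e: e.start))
        for e in exons:
            if e.chrom != self.chrom or e.strand != self.strand:
                raise AnnotationError(
                    f"transcript {tx_id}: exon {e} disagrees with gene "
                    f"{self.gene_id} location {self.chrom}{self.strand}"
                )
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"transcript {tx_id}: overlapping exons {a} / {b}"
                )
        self.transcripts[tx_id] = exons


def transcript_junctions(
    exons: Sequence[GenomicInterval], strand: str
) -> tuple[Junction, ...]:
    """Junctions between consecutive exons of one transcript."""
    return tuple(
        junction_between(a, b, strand) for a, b in zip(exons, exons[1:])
    )


@dataclass(frozen=True)
class CassetteEvent:
    """A cassette (skipped) exon with its three diagnostic junctions.

    The upstream and skip junctions share a donor site; the downstream and
    skip junctions share an acceptor site.
    """

    event_id: str
    gene_id: str
    alt_exon: GenomicInterval
    upstream_junction: Junction
    downstream_junction: Junction
    skip_junction: Junction

    def __post_init__(self) -> None:
        trio = {self.upstream_junction, self.downstream_junction, self.skip_junction}
        if len(trio) != 3:
            raise AnnotationError(f"{self.event_id}: junctions not pairwise distinct")
        if self.upstream_junction.donor_site != self.skip_junction.donor_site:
            raise AnnotationError(f"{self.event_id}: upstream/skip donor mismatch")
        if self.downstream_junction.acceptor_site != self.skip_junction.acceptor_site:
            raise AnnotationError(f"{self.event_id}: downstream/skip acceptor mismatch")

    @property
    def junctions(self) -> tuple[Junction, Junction, Junction]:
        return (self.upstream_junction, self.downstream_junction, self.skip_junction)


@dataclass(frozen=True)
class SiteGroup:
    """All junctions sharing one splice site (donor side or acceptor side)."""

    group_id: str
    side: str  # "donor" | "acceptor"
    chrom: str
    shared_site: int
    strand: str
    members: tuple[Junction, ...]

    def __post_init__(self) -> None:
        if self.side not in ("donor", "acceptor"):
            raise AnnotationError(f"invalid side {self.side!r}")
        if len(self.members) < 2:
            raise AnnotationError(f"{self.group_id}: a site group needs >=2 members")
        for j in self.members:
            site = j.donor_site if self.side == "donor" else j.acceptor_site
            if (j.chrom, site, j.strand) != (self.chrom, self.shared_site, self.strand):
                raise AnnotationError(
                    f"{self.group_id}: member {j.key} does not share the site"
                )


@dataclass(frozen=True)
class TerminalExonEvent:
    """Alternative first- or last-exon usage within one gene."""

    event_id: str
    gene_id: str
    kind: str  # "alternative_first" | "alternative_last"
    candidates: tuple[tuple[GenomicInterval, tuple[Junction, ...]], ...]

    def __post_init__(self) -> None:
        if self.kind not in ("alternative_first", "alternative_last"):
            raise AnnotationError(f"invalid kind {self.kind!r}")
        if len(self.candidates) < 2:
            raise AnnotationError(f"{self.event_id}: needs >=2 candidate exons")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(attr: str, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise AnnotationError(f"line {lineno}: bad GTF attribute {chunk!r}")
        out[parts[0]] = parts[1].strip().strip('"')
    return out


def _iter_gtf_exons(path: Path) -> Iterator[tuple[str, str, GenomicInterval]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"line {lineno}: expected 9 tab-separated GTF fields, "
                    f"got {len(fields)}"
                )
            if fields[2] != "exon":
                continue
            chrom, _, _, start, end, _, strand, _, attr = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise AnnotationError(
                    f"line {lineno}: non-integer coordinates {start!r}/{end!r}"
                ) from None
            attrs = _parse_gtf_attributes(attr, lineno)
            for key in ("gene_id", "transcript_id"):
                if key not in attrs:
                    raise AnnotationError(f"line {lineno}: missing {key} attribute")
            try:
                # GTF is 1-based inclusive
                iv = GenomicInterval(chrom, start_i - 1, end_i, strand)
            except AnnotationError as exc:
                raise AnnotationError(f"line {lineno}: {exc}") from None
            yield attrs["gene_id"], attrs["transcript_id"], iv


def _iter_refflat(path: Path) -> Iterator[tuple[str, str, list[GenomicInterval]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 11:
                raise AnnotationError(
                    f"line {lineno}: expected 11 refFlat columns, got {len(fields)}"
                )
            gene, tx, chrom, strand, *_rest = fields[:4] + fields[4:]
            exon_count = fields[8]
            starts, ends = fields[9], fields[10]
            try:
                n = int(exon_count)
                start_list = [int(x) for x in starts.rstrip(",").split(",")]
                end_list = [int(x) for x in ends.rstrip(",").split(",")]
            except ValueError:
                raise AnnotationError(
                    f"line {lineno}: non-integer exon fields"
                ) from None
            if len(start_list) != n or len(end_list) != n:
                raise AnnotationError(
                    f"line {lineno}: exonCount {n} does not match exon lists"
                )
            try:
                exons = [
                    GenomicInterval(chrom, s, e, strand)
                    for s, e in zip(start_list, end_list)
                ]
            except AnnotationError as exc:
                raise AnnotationError(f"line {lineno}: {exc}") from None
            yield gene, tx, exons


def read_gene_models(path: str | Path, dialect: str = "gtf") -> dict[str, GeneModel]:
    """Load gene models from a GTF or refFlat annotation file.

    Returns a dict gene_id -> :class:`GeneModel` with exons in the internal
    0-based half-open convention.
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"annotation file not found: {path}")
    models: dict[str, GeneModel] = {}

    if dialect == "gtf":
        per_tx: dict[tuple[str, str], list[GenomicInterval]] = defaultdict(list)
        for gene, tx, iv in _iter_gtf_exons(path):
            per_tx[(gene, tx)].append(iv)
        for (gene, tx), exons in per_tx.items():
            model = models.setdefault(
                gene, GeneModel(gene, exons[0].chrom, exons[0].strand)
            )
            model.add_transcript(tx, exons)
    elif dialect == "refflat":
        for gene, tx, exons in _iter_refflat(path):
            model = models.setdefault(
                gene, GeneModel(gene, exons[0].chrom, exons[0].strand)
            )
            model.add_transcript(tx, exons)
    else:
        raise AnnotationError(f"unknown annotation dialect {dialect!r}")
    return models


def write_refflat(models: Mapping[str, GeneModel], path: str | Path) -> None:
    """Write gene models as UCSC 11-column refFlat (0-based half-open)."""
    with open(path, "w") as fh:
        for gene_id in sorted(models):
            m = models[gene_id]
            for tx_id in sorted(m.transcripts):
                exons = m.transcripts[tx_id]
                tx_start, tx_end = exons[0].start, exons[-1].end
                fh.write(
                    "\t".join(
                        [
                            gene_id,
                            tx_id,
                            m.chrom,
                            m.strand,
                            str(tx_start),
                            str(tx_end),
                            str(tx_start),
                            str(tx_end),
                            str(len(exons)),
                            ",".join(str(e.start) for e in exons) + ",",
                            ",".join(str(e.end) for e in exons) + ",",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# event catalog construction
# ---------------------------------------------------------------------------

def build_cassette_events(models: Mapping[str, GeneModel]) -> list[CassetteEvent]:
    """Enumerate cassette exons with annotated inclusion AND skipping.

    An internal exon of one transcript yields an event when another
    transcript of the same gene splices its two flanking exons directly
    together (the skip junction is annotated).  De-novo junctions never
    create events here; they may only join site groups.
    """
    events: list[CassetteEvent] = []
    seen: set[tuple] = set()
    for gene_id, model in models.items():
        junc_sets = {
            tx: set(transcript_junctions(exons, model.strand))
            for tx, exons in model.transcripts.items()
        }
        for tx, exons in model.transcripts.items():
            for i in range(1, len(exons) - 1):
                up, alt, down = exons[i - 1], exons[i], exons[i + 1]
                up_j = junction_between(up, alt, model.strand)
                down_j = junction_between(alt, down, model.strand)
                skip_j = junction_between(up, down, model.strand)
                if model.strand == "-":
                    # transcript orientation: genomically-right neighbor is upstream
                    up_j, down_j = down_j, up_j
                skipped_elsewhere = any(
                    skip_j in js for other, js in junc_sets.items() if other != tx
                )
                if not skipped_elsewhere:
                    continue
                key = (gene_id, alt, up_j, down_j, skip_j)
                if key in seen:
                    continue
                seen.add(key)
                events.append(
                    CassetteEvent(
                        event_id=f"{gene_id}:cassette:{alt.chrom}:{alt.start}-{alt.end}",
                        gene_id=gene_id,
                        alt_exon=alt,
                        upstream_junction=up_j,
                        downstream_junction=down_j,
                        skip_junction=skip_j,
                    )
                )
    events.sort(key=lambda e: e.event_id)
    return events


def build_site_groups(junctions: Iterable[Junction]) -> list[SiteGroup]:
    """Partition junctions by shared donor site and by shared acceptor site.

    Only groups with >=2 members are returned; a junction can appear in at
    most one donor group and one acceptor group.
    """
    donor: dict[tuple, list[Junction]] = defaultdict(list)
    acceptor: dict[tuple, list[Junction]] = defaultdict(list)
    for j in set(junctions):
        donor[(j.chrom, j.donor_site, j.strand)].append(j)
        acceptor[(j.chrom, j.acceptor_site, j.strand)].append(j)

    groups: list[SiteGroup] = []
    for side, index in (("donor", donor), ("acceptor", acceptor)):
        for (chrom, site, strand), members in sorted(index.items()):
            if len(members) < 2:
                continue
            groups.append(
                SiteGroup(
                    group_id=f"{side[:3]}:{chrom}:{site}:{strand}",
                    side=side,
                    chrom=chrom,
                    shared_site=site,
                    strand=strand,
                    members=tuple(sorted(members, key=lambda j: j.key)),
                )
            )
    return groups


def classify_terminal_events(
    models: Mapping[str, GeneModel],
) -> list[TerminalExonEvent]:
    """Find genes whose transcripts use alternative first or last exons."""
    events: list[TerminalExonEvent] = []
    for gene_id, model in sorted(models.items()):
        for kind in ("alternative_first", "alternative_last"):
            # transcript orientation: first exon of a minus-strand transcript
            # is the genomically last one
            want_first = kind == "alternative_first"
            take_left = want_first == (model.strand == "+")
            candidates: dict[GenomicInterval, set[Junction]] = defaultdict(set)
            for tx, exons in model.transcripts.items():
                terminal = exons[0] if take_left else exons[-1]
                juncs = transcript_junctions(exons, model.strand)
                if juncs:
                    link = juncs[0] if take_left else juncs[-1]
                    candidates[terminal].add(link)
                else:
                    candidates.setdefault(terminal, set())
            if len(candidates) < 2:
                continue
            events.append(
                TerminalExonEvent(
                    event_id=f"{gene_id}:{kind}",
                    gene_id=gene_id,
                    kind=kind,
                    candidates=tuple(
                        (exon, tuple(sorted(links, key=lambda j: j.key)))
                        for exon, links in sorted(candidates.items())
                    ),
                )
            )
    return events


def write_event_catalog(
    cassette: Sequence[CassetteEvent],
    terminal: Sequence[TerminalExonEvent],
    groups: Sequence[SiteGroup],
    path: str | Path,
) -> None:
    """Write the event catalog as a TSV (one row per event or group member)."""
    with open(path, "w") as fh:
        fh.write("event_id\tgene\ttype\tcoordinates\tjunction_keys\n")
        for ev in cassette:
            coords = f"{ev.alt_exon.chrom}:{ev.alt_exon.start}-{ev.alt_exon.end}"
            keys = ",".join(j.key for j in ev.junctions)
            fh.write(f"{ev.event_id}\t{ev.gene_id}\tcassette\t{coords}\t{keys}\n")
        for ev in terminal:
            coords = ";".join(
                f"{e.chrom}:{e.start}-{e.end}" for e, _ in ev.candidates
            )
            keys = ",".join(
                j.key for _, links in ev.candidates for j in links
            )
            fh.write(f"{ev.event_id}\t{ev.gene_id}\t{ev.kind}\t{coords}\t{keys}\n")
        for g in groups:
            coords = f"{g.chrom}:{g.shared_site}:{g.strand}"
            keys = ",".join(j.key for j in g.members)
            fh.write(f"{g.group_id}\t-\tsite_group_{g.side}\t{coords}\t{keys}\n")
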
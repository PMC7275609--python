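"""Percent-spliced-in statistics and junction usage.

Three estimators over junction read counts:

* ``psi_exon`` — cassette exon inclusion from the upstream (a), downstream
  (b) and skip (c) junction counts: PSI = (a + b) / (a + b + 2c).  The skip
  count is doubled because an included exon exposes two junctions where the
  skipping isoform exposes one.
* ``psi_junc`` (5' or 3' flavour) — usage of one junction among all
  junctions sharing the same donor (5') or acceptor (3') splice site:
  PSI = count(junction) / sum(counts over the site group).
* ``junction_usage`` — a junction's quantification divided by the mean
  quantification of all junctions of the same gene in the same person.

A PSI value is reported only when the event's total informative reads reach
``min_total`` (default 10); otherwise it is missing (NaN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import CassetteEvent, Junction, SiteGroup
from .counting import JunctionCountTable

__all__ = [
    "PsiError",
    "PsiMatrix",
    "UsageMatrix",
    "psi_exon",
    "psi_junc",
    "compute_psi_matrix",
    "junction_usage",
    "read_usage_tsv",
]

MIN_TOTAL_READS = 10

PSI_EXON = "psi_exon"
PSI_JUNC5 = "psi_junc5"
PSI_JUNC3 = "psi_junc3"


class PsiError(ValueError):
    pass


def psi_exon(a: int, b: int, c: int, min_total: int = MIN_TOTAL_READS) -> float:
    """Cassette-exon PSI from the three junction counts (NaN below min_total)."""
    if a < 0 or b < 0 or c < 0:
        raise PsiError(f"negative junction counts ({a}, {b}, {c})")
    if a + b + c < min_total:
        return math.nan
    return (a + b) / (a + b + 2 * c)


def psi_junc(
    junction: Junction,
    group: SiteGroup,
    counts: Mapping[Junction, int],
    min_total: int = MIN_TOTAL_READS,
) -> float:
    """Usage of one junction among all junctions sharing its splice site."""
    if junction not in group.members:
        raise PsiError(f"{junction.key} is not a member of {group.group_id}")
    member_counts = []
    for m in group.members:
        cnt = counts.get(m, 0)
        if cnt < 0:
            raise PsiError(f"negative count for {m.key}")
        member_counts.append(cnt)
    total = sum(member_counts)
    if total < min_total:
        return math.nan
    return counts.get(junction, 0) / total


@dataclass
class PsiMatrix:
    """Event x sample PSI values with per-cell informative-read totals."""

    method: str
    values: pd.DataFrame   # float in [0,1], NaN = missing
    totals: pd.DataFrame   # informative reads per cell

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and ((finite < 0) | (finite > 1)).any():
            raise PsiError("PSI values outside [0, 1]")

    @property
    def events(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="event_id", na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path, method: str = "external") -> "PsiMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
        totals = pd.DataFrame(np.nan, index=values.index, columns=values.columns)
        return cls(method, values, totals)


def compute_psi_matrix(
    counts: JunctionCountTable,
    cassette_events: Sequence[CassetteEvent] = (),
    site_groups: Sequence[SiteGroup] = (),
    min_total: int = MIN_TOTAL_READS,
) -> dict[str, PsiMatrix]:
    """Compute PSI matrices for all three methods from one count table.

    Catalog junctions absent from the count table contribute 0 reads.
    Returns the methods that have at least one catalog entry.
    """
    samples = counts.samples
    out: dict[str, PsiMatrix] = {}

    if cassette_events:
        vals = np.full((len(cassette_events), len(samples)), np.nan)
        tots = np.zeros((len(cassette_events), len(samples)), dtype=np.int64)
        for i, ev in enumerate(cassette_events):
            a = counts.row_of(ev.upstream_junction).to_numpy()
            b = counts.row_of(ev.downstream_junction).to_numpy()
            c = counts.row_of(ev.skip_junction).to_numpy()
            total = a + b + c
            tots[i] = total
            with np.errstate(invalid="ignore", divide="ignore"):
                psi = (a + b) / (a + b + 2 * c)
            psi = np.where(total >= min_total, psi, np.nan)
            vals[i] = psi
        index = [ev.event_id for ev in cassette_events]
        out[PSI_EXON] = PsiMatrix(
            PSI_EXON,
            pd.DataFrame(vals, index=index, columns=samples),
            pd.DataFrame(tots, index=index, columns=samples),
        )

    for method, side in ((PSI_JUNC5, "donor"), (PSI_JUNC3, "acceptor")):
        groups = [g for g in site_groups if g.side == side]
        if not groups:
            continue
        rows: list[str] = []
        vals_rows: list[np.ndarray] = []
        tots_rows: list[np.ndarray] = []
        for g in groups:
            member_counts = np.vstack(
                [counts.row_of(m).to_numpy() for m in g.members]
            )
            total = member_counts.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = member_counts / total
            frac = np.where(total >= min_total, frac, np.nan)
            for m, row in zip(g.members, frac):
                rows.append(f"{g.group_id}|{m.key}")
                vals_rows.append(row)
                tots_rows.append(total)
        out[method] = PsiMatrix(
            method,
            pd.DataFrame(np.vstack(vals_rows), index=rows, columns=samples),
            pd.DataFrame(np.vstack(tots_rows), index=rows, columns=samples),
        )
    return out


@dataclass
class UsageMatrix:
    """Junction x person usage values, junctions annotated with their gene."""

    values: pd.DataFrame
    gene_map: dict[str, str]

    def to_tsv(self, path: str | Path) -> None:
        frame = self.values.copy()
        frame.insert(0, "gene", [self.gene_map[j] for j in frame.index])
        frame.to_csv(path, sep="\t", index_label="junction", na_rep="NA")


def junction_usage(
    quantifications: pd.DataFrame, gene_map: Mapping[str, str]
) -> UsageMatrix:
    """Normalize junction quantifications to per-gene per-person usage.

    usage(j, p) = quant(j, p) / mean over the gene's junctions of quant(., p).
    A person whose gene mean is zero gets missing usage for that gene.  Every
    junction must be mapped to exactly one gene.
    """
    unmapped = [j for j in quantifications.index if j not in gene_map]
    if unmapped:
        raise PsiError(f"junctions with no gene mapping: {unmapped[:5]}")
    if (quantifications.to_numpy(dtype=float) < 0).any():
        raise PsiError("negative quantification values")
    usage = pd.DataFrame(
        np.nan, index=quantifications.index, columns=quantifications.columns
    )
    genes = pd.Series({j: gene_map[j] for j in quantifications.index})
    for gene, junctions in genes.groupby(genes).groups.items():
        block = quantifications.loc[junctions].astype(float)
        gene_mean = block.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = block / gene_mean
        norm[gene_mean.index[gene_mean == 0]] = np.nan
        usage.loc[junctions] = norm
    return UsageMatrix(usage, {j: gene_map[j] for j in quantifications.index})


def read_usage_tsv(path: str | Path) -> UsageMatrix:
    """Read a junction x person usage (or quantification) TSV.

    Expects a ``junction`` index column and a ``gene`` column; remaining
    columns are persons/samples.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    if "gene" not in frame.columns:
        raise PsiError(f"{path}: missing required 'gene' column")
    gene_map = frame["gene"].to_dict()
    values = frame.drop(columns=["gene"]).astype(float)
    return UsageMatrix(values, gene_map)
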
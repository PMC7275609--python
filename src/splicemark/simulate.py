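"""Synthetic junction-count, usage and survival data with planted truth.

Every generator is seeded and bit-reproducible, writes/returns the same
containers the pipeline consumes, and ships its ground truth alongside so
recovery can be asserted end-to-end.  Defaults emulate the study conditions:
paired tumor/normal cohorts of 18 patients, ~200 informative reads per event
(negative-binomial), planted cassette effects of PSI 0.5 -> 0.85 (CLK1-like)
and 0.1 -> 0.45 (COL6A3-like), a tumor/normal usage matrix of 382 vs 51
samples with a 3-block correlation structure, and exponential survival with
a planted hazard ratio between usage groups.

Read sampling for cassette events follows the junction-read model: an
inclusion isoform exposes two junctions (upstream + downstream) where the
skipping isoform exposes one, so a junction read is inclusion-type with
probability 2*psi / (1 + psi).  Under this model the estimator
(a + b) / (a + b + 2c) is consistent for the planted psi.  An optional
beta-binomial over-dispersion knob stresses the estimator's binomial
assumption.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import (
    CassetteEvent,
    GenomicInterval,
    Junction,
    SiteGroup,
    build_site_groups,
)
from .counting import JunctionCountTable

__all__ = [
    "SimulateError",
    "PlantedCassette",
    "simulate_cassette_counts",
    "simulate_site_group_counts",
    "simulate_trio_cohort",
    "simulate_usage_matrix",
    "simulate_survival",
    "write_toy_sam",
    "TOY_SAM_READS",
]


class SimulateError(ValueError):
    pass


def _check_psi(*values: float) -> None:
    for v in values:
        if v is not None and not (0.0 <= v <= 1.0):
            raise SimulateError(f"PSI parameter {v} outside [0, 1]")


def _nb_depth(
    rng: np.random.Generator, mean: float, dispersion: float, size
) -> np.ndarray:
    """Negative-binomial depths with the given mean and size (dispersion)."""
    if mean <= 0 or dispersion <= 0:
        raise SimulateError("depth mean and dispersion must be positive")
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _inclusion_prob(
    psi: np.ndarray | float, rng: np.random.Generator, overdispersion: float | None
):
    """Per-read inclusion probability 2*psi/(1+psi), optionally beta-jittered."""
    p = 2.0 * np.asarray(psi, dtype=float) / (1.0 + np.asarray(psi, dtype=float))
    if overdispersion is None:
        return p
    conc = 1.0 / overdispersion
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return rng.beta(p * conc, (1.0 - p) * conc)


@dataclass(frozen=True)
class PlantedCassette:
    """A cassette event's true group PSIs (metastasis level optional)."""

    psi_normal: float
    psi_tumor: float
    psi_metastasis: float | None = None

    def __post_init__(self) -> None:
        _check_psi(self.psi_normal, self.psi_tumor, self.psi_metastasis)


def _cassette_catalog(n_events: int) -> list[CassetteEvent]:
    """Disjoint synthetic cassette events laid out along one chromosome."""
    events = []
    for i in range(n_events):
        base = 10_000 * (i + 1)
        up = GenomicInterval("chrS", base, base + 100, "+")
        alt = GenomicInterval("chrS", base + 300, base + 400, "+")
        down = GenomicInterval("chrS", base + 600, base + 700, "+")
        gene = f"GENE{i:04d}"
        events.append(
            CassetteEvent(
                event_id=f"{gene}:cassette:chrS:{alt.start}-{alt.end}",
                gene_id=gene,
                alt_exon=alt,
                upstream_junction=Junction.from_intron("chrS", up.end, alt.start, "+"),
                downstream_junction=Junction.from_intron(
                    "chrS", alt.end, down.start, "+"
                ),
                skip_junction=Junction.from_intron("chrS", up.end, down.start, "+"),
            )
        )
    return events


def _draw_cassette_counts(
    rng: np.random.Generator,
    psi: float,
    n_samples: int,
    depth_mean: float,
    depth_dispersion: float,
    overdispersion: float | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample (a, b, c) junction read counts for one event and group."""
    total = _nb_depth(rng, depth_mean, depth_dispersion, n_samples)
    p_inc = _inclusion_prob(psi, rng, overdispersion)
    inc = rng.binomial(total, p_inc)
    a = rng.binomial(inc, 0.5)
    b = inc - a
    c = total - inc
    return a, b, c


def simulate_cassette_counts(
    planted: Sequence[PlantedCassette] = (
        PlantedCassette(0.50, 0.85),
        PlantedCassette(0.10, 0.45),
    ),
    n_null_events: int = 100,
    n_pairs: int = 18,
    depth_mean: float = 200.0,
    depth_dispersion: float = 10.0,
    overdispersion: float | None = None,
    seed: int | np.random.Generator | None = None,
    group_labels: tuple[str, str] = ("NC", "CRC"),
) -> tuple[JunctionCountTable, list[CassetteEvent], pd.DataFrame]:
    """Paired two-group junction counts for cassette events.

    Planted events shift PSI between the groups; null events draw one PSI
    from Uniform(0.1, 0.9) shared by both groups.  Returns the count table,
    the event catalog, and the truth table (event_id, psi per group, delta,
    kind).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events = _cassette_catalog(len(planted) + n_null_events)
    labels_a, labels_b = group_labels
    samples = [f"P{i:03d}_{labels_a}" for i in range(n_pairs)] + [
        f"P{i:03d}_{labels_b}" for i in range(n_pairs)
    ]

    null_psi = rng.uniform(0.1, 0.9, size=n_null_events)
    truth_rows = []
    psi_pairs: list[tuple[float, float, str]] = []
    for p in planted:
        psi_pairs.append((p.psi_normal, p.psi_tumor, "planted"))
    for v in null_psi:
        psi_pairs.append((float(v), float(v), "null"))

    records: list[tuple[Junction, str, int]] = []
    for ev, (psi_a, psi_b, kind) in zip(events, psi_pairs):
        for psi, offset in ((psi_a, 0), (psi_b, n_pairs)):
            a, b, c = _draw_cassette_counts(
                rng, psi, n_pairs, depth_mean, depth_dispersion, overdispersion
            )
            for i in range(n_pairs):
                sample = samples[offset + i]
                records.append((ev.upstream_junction, sample, int(a[i])))
                records.append((ev.downstream_junction, sample, int(b[i])))
                records.append((ev.skip_junction, sample, int(c[i])))
        truth_rows.append(
            {
                "event_id": ev.event_id,
                "kind": kind,
                f"psi_{labels_a}": psi_a,
                f"psi_{labels_b}": psi_b,
                "delta_psi": psi_b - psi_a,
            }
        )
    table = JunctionCountTable.from_records(records)
    return table, events, pd.DataFrame(truth_rows).set_index("event_id")


def simulate_site_group_counts(
    proportions_normal: Sequence[float] = (0.2, 0.4, 0.4),
    proportions_tumor: Sequence[float] = (0.8, 0.1, 0.1),
    n_null_groups: int = 20,
    n_members: int = 3,
    n_pairs: int = 18,
    depth_mean: float = 200.0,
    depth_dispersion: float = 10.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[JunctionCountTable, list[SiteGroup], pd.DataFrame]:
    """Multinomial junction counts over donor-sharing site groups.

    One planted group shifts the first member's proportion between groups
    (CD44-like: one donor feeding several acceptors); null groups share one
    uniform-ish proportion vector drawn per group.  Returns counts, site
    groups (donor side), and truth.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    props_n = np.asarray(proportions_normal, dtype=float)
    props_t = np.asarray(proportions_tumor, dtype=float)
    for props in (props_n, props_t):
        if not np.isclose(props.sum(), 1.0):
            raise SimulateError(f"proportions {props} do not sum to 1")
    if len(props_n) != len(props_t):
        raise SimulateError("group proportion vectors differ in length")

    samples = [f"P{i:03d}_NC" for i in range(n_pairs)] + [
        f"P{i:03d}_CRC" for i in range(n_pairs)
    ]
    records: list[tuple[Junction, str, int]] = []
    junctions: list[Junction] = []
    truth_rows = []

    def _emit(group_idx: int, members: int, p_nc, p_crc, kind: str):
        donor_base = 50_000 * (group_idx + 1)
        group_juncs = [
            Junction.from_intron(
                "chrG", donor_base, donor_base + 1_000 * (m + 1), "+"
            )
            for m in range(members)
        ]
        junctions.extend(group_juncs)
        for props, offset in ((p_nc, 0), (p_crc, n_pairs)):
            totals = _nb_depth(rng, depth_mean, depth_dispersion, n_pairs)
            for i in range(n_pairs):
                counts = rng.multinomial(totals[i], props)
                for j, cnt in zip(group_juncs, counts):
                    records.append((j, samples[offset + i], int(cnt)))
        for m, j in enumerate(group_juncs):
            truth_rows.append(
                {
                    "junction": j.key,
                    "kind": kind,
                    "prop_NC": float(p_nc[m]),
                    "prop_CRC": float(p_crc[m]),
                }
            )

    _emit(0, len(props_n), props_n, props_t, "planted")
    for g in range(n_null_groups):
        props = rng.dirichlet(np.full(n_members, 5.0))
        _emit(g + 1, n_members, props, props, "null")

    table = JunctionCountTable.from_records(records)
    groups = [g for g in build_site_groups(junctions) if g.side == "donor"]
    return table, groups, pd.DataFrame(truth_rows).set_index("junction")


def simulate_trio_cohort(
    planted_mc: Sequence[tuple[float, float, float]] = ((0.6, 0.4, 0.2),),
    distractors: Sequence[tuple[float, float, float]] = ((0.6, 0.4, 0.4),),
    n_null_events: int = 100,
    n_pairs: int = 18,
    n_pairs_second: int = 10,
    depth_mean: float = 200.0,
    depth_dispersion: float = 10.0,
    seed: int | np.random.Generator | None = None,
):
    """NC/CRC/MC trio cohort plus a paired NC/CRC second cohort.

    ``planted_mc`` rows are (psi_NC, psi_CRC, psi_MC) with a genuine further
    metastatic shift; ``distractors`` shift NC -> CRC only.  Both cohorts
    share the same event catalog and NC -> CRC effects.  Returns
    (counts_trio, counts_second, events, truth); counts_trio has per-patient
    NC/CRC/MC samples.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    specs: list[tuple[float, float, float, str]] = []
    for nc, crc, mc in planted_mc:
        _check_psi(nc, crc, mc)
        specs.append((nc, crc, mc, "planted_mc"))
    for nc, crc, mc in distractors:
        _check_psi(nc, crc, mc)
        specs.append((nc, crc, mc, "distractor"))
    for v in rng.uniform(0.1, 0.9, size=n_null_events):
        specs.append((float(v), float(v), float(v), "null"))

    events = _cassette_catalog(len(specs))
    trio_samples = {
        grp: [f"P{i:03d}_{grp}" for i in range(n_pairs)]
        for grp in ("NC", "CRC", "MC")
    }
    second_samples = {
        grp: [f"Q{i:03d}_{grp}" for i in range(n_pairs_second)]
        for grp in ("NC", "CRC")
    }

    records_trio: list[tuple[Junction, str, int]] = []
    records_second: list[tuple[Junction, str, int]] = []
    truth_rows = []
    for ev, (psi_nc, psi_crc, psi_mc, kind) in zip(events, specs):
        for grp, psi in (("NC", psi_nc), ("CRC", psi_crc), ("MC", psi_mc)):
            a, b, c = _draw_cassette_counts(
                rng, psi, n_pairs, depth_mean, depth_dispersion, None
            )
            for i, sample in enumerate(trio_samples[grp]):
                records_trio.append((ev.upstream_junction, sample, int(a[i])))
                records_trio.append((ev.downstream_junction, sample, int(b[i])))
                records_trio.append((ev.skip_junction, sample, int(c[i])))
        for grp, psi in (("NC", psi_nc), ("CRC", psi_crc)):
            a, b, c = _draw_cassette_counts(
                rng, psi, n_pairs_second, depth_mean, depth_dispersion, None
            )
            for i, sample in enumerate(second_samples[grp]):
                records_second.append((ev.upstream_junction, sample, int(a[i])))
                records_second.append((ev.downstream_junction, sample, int(b[i])))
                records_second.append((ev.skip_junction, sample, int(c[i])))
        truth_rows.append(
            {
                "event_id": ev.event_id,
                "kind": kind,
                "psi_NC": psi_nc,
                "psi_CRC": psi_crc,
                "psi_MC": psi_mc,
            }
        )
    return (
        JunctionCountTable.from_records(records_trio),
        JunctionCountTable.from_records(records_second),
        events,
        pd.DataFrame(truth_rows).set_index("event_id"),
    )


def simulate_usage_matrix(
    n_tumor: int = 382,
    n_normal: int = 51,
    block_sizes: Sequence[int] = (3, 2, 3),
    within_block_loading: float = 0.8,
    class_shift_sd: float = 3.0,
    shifted_per_block: int = 1,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Tumor/normal predictor matrix with 3-block correlation structure.

    Each block shares a latent factor (within-block correlation ~=
    ``within_block_loading``); the first ``shifted_per_block`` predictors of
    each block get a tumor-mean shift of ``class_shift_sd`` total standard
    deviations.  Returns (matrix samples x predictors, labels 1=tumor,
    truth per predictor).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = n_tumor + n_normal
    labels = pd.Series(
        [1] * n_tumor + [0] * n_normal,
        index=[f"T{i:03d}" for i in range(n_tumor)]
        + [f"N{i:03d}" for i in range(n_normal)],
        name="label",
    )
    w = within_block_loading
    if not (0 <= w < 1):
        raise SimulateError("within_block_loading must lie in [0, 1)")
    cols = {}
    truth_rows = []
    for b, size in enumerate(block_sizes):
        factor = rng.normal(size=n)
        for m in range(size):
            name = f"junc_b{b + 1}_{m + 1}"
            noise = rng.normal(size=n)
            vals = np.sqrt(w) * factor + np.sqrt(1 - w) * noise
            shifted = m < shifted_per_block
            if shifted and class_shift_sd != 0:
                vals = vals + class_shift_sd * labels.to_numpy()
            cols[name] = vals
            truth_rows.append(
                {
                    "predictor": name,
                    "block": b + 1,
                    "shifted": bool(shifted and class_shift_sd != 0),
                    "class_shift_sd": class_shift_sd if shifted else 0.0,
                }
            )
    matrix = pd.DataFrame(cols, index=labels.index)
    return matrix, labels, pd.DataFrame(truth_rows).set_index("predictor")


def simulate_survival(
    usage: pd.Series,
    baseline_hazard: float = 1.0 / 1000.0,
    hazard_ratio: float = 3.0,
    censoring_rate: float = 0.4,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exponential survival with hazard tied to the usage median split.

    Patients above the usage median get hazard ``baseline_hazard *
    hazard_ratio``.  Independent exponential censoring is calibrated so the
    expected fraction censored is roughly ``censoring_rate``; rate 1.0 means
    everyone is censored at their drawn censoring time.  Returns a frame
    indexed by person with time, event and group columns.
    """
    from .survival import median_split

    if hazard_ratio <= 0:
        raise SimulateError("hazard ratio must be positive")
    if not (0 <= censoring_rate <= 1):
        raise SimulateError("censoring rate must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    groups = median_split(usage)
    hazard = np.where(
        groups.to_numpy() == "high",
        baseline_hazard * hazard_ratio,
        baseline_hazard,
    )
    event_times = rng.exponential(1.0 / hazard)
    if censoring_rate >= 1.0:
        times = rng.exponential(1.0 / baseline_hazard, size=len(groups))
        events = np.zeros(len(groups), dtype=int)
    elif censoring_rate == 0.0:
        times, events = event_times, np.ones(len(groups), dtype=int)
    else:
        # P(censored) = c/(c+h) per arm -> calibrate against the mean hazard
        mean_h = float(hazard.mean())
        c_rate = censoring_rate / (1.0 - censoring_rate) * mean_h
        censor_times = rng.exponential(1.0 / c_rate, size=len(groups))
        events = (event_times <= censor_times).astype(int)
        times = np.minimum(event_times, censor_times)
    return pd.DataFrame(
        {"time": times, "event": events, "group": groups.to_numpy()},
        index=groups.index,
    )


# ---------------------------------------------------------------------------
# toy SAM fixture generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyRead:
    """Specification of one toy SAM read over the chrT 3-exon gene."""

    name: str
    pos: int                # 0-based leftmost reference position
    cigar: str
    mapq: int = 60
    nm: int | None = 0


# chrT toy gene: exons [100,200), [300,400), [500,600) on +.
TOY_EXONS = ((100, 200), (300, 400), (500, 600))
TOY_SAM_READS: tuple[ToyRead, ...] = (
    ToyRead("r_junc_e1e2", 150, "50M100N50M"),            # junction E1-E2
    ToyRead("r_junc_low_mapq", 150, "50M100N50M", mapq=5),
    ToyRead("r_junc_mismatch", 150, "50M100N50M", nm=6),  # 6 >= 5% of 100
    ToyRead("r_two_gaps", 150, "50M100N100M100N50M"),     # spans E1-E2 and E2-E3
    ToyRead("r_exonic", 120, "60M"),                      # inside E1
    ToyRead("r_skip_e2", 150, "50M300N50M"),              # junction E1-E3
    ToyRead("r_no_nm", 320, "50M", nm=None),
)


def write_toy_sam(
    path: str | Path,
    reads: Sequence[ToyRead] = TOY_SAM_READS,
    sample_id: str = "toy",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write a minimal single-sample SAM file and its expected count tables.

    Returns (expected junction counts, expected exon-block counts), both
    computed from the read specifications by replaying the filter and
    counting rules by hand-traceable arithmetic (filter: primary, MAPQ > 10,
    mismatches < 5% of aligned length; each N gap increments its junction;
    each exon block overlapped by >= 1 base increments once per read).
    """
    lines = ["@HD\tVN:1.6\tSO:unsorted", "@SQ\tSN:chrT\tLN:10000"]
    junc_counts: dict[str, int] = {}
    exon_counts = {f"TOY|chrT:{s}-{e}": 0 for s, e in TOY_EXONS}
    for read in reads:
        seq_len, ref_blocks, gaps = _parse_toy_cigar(read.pos, read.cigar)
        opt = [] if read.nm is None else [f"NM:i:{read.nm}"]
        lines.append(
            "\t".join(
                [
                    read.name, "0", "chrT", str(read.pos + 1), str(read.mapq),
                    read.cigar, "*", "0", "0", "A" * seq_len, "I" * seq_len,
                ]
                + opt
            )
        )
        aligned = sum(e - s for s, e in ref_blocks)
        nm_ok = read.nm is None or read.nm < 0.05 * aligned
        if read.mapq <= 10 or not nm_ok:
            continue
        for gs, ge in gaps:
            key = f"chrT:{gs}-{ge}:."
            junc_counts[key] = junc_counts.get(key, 0) + 1
        for (es, ee), key in zip(TOY_EXONS, exon_counts):
            if any(s < ee and es < e for s, e in ref_blocks):
                exon_counts[key] += 1
    Path(path).write_text("\n".join(lines) + "\n")
    expected_junctions = pd.DataFrame(
        {sample_id: pd.Series(junc_counts, dtype=np.int64)}
    ).sort_index()
    expected_exons = pd.DataFrame(
        {sample_id: pd.Series(exon_counts, dtype=np.int64)}
    ).sort_index()
    return expected_junctions, expected_exons


def _parse_toy_cigar(pos: int, cigar: str):
    import re

    seq_len = 0
    blocks: list[tuple[int, int]] = []
    gaps: list[tuple[int, int]] = []
    cur = pos
    block_start = pos
    open_block = False
    for length, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        length = int(length)
        if op in "M=X":
            if not open_block:
                block_start = cur
                open_block = True
            cur += length
            seq_len += length
        elif op == "D":
            cur += length
        elif op == "N":
            if open_block:
                blocks.append((block_start, cur))
                open_block = False
            gaps.append((cur, cur + length))
            cur += length
        elif op in "IS":
            seq_len += length
    if open_block:
        blocks.append((block_start, cur))
    return seq_len, blocks, gaps
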
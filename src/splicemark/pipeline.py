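"""End-to-end orchestration: discovery and validation stages with a manifest.

``run_discovery`` goes from junction counts (real SJ tables or the seeded
simulator) to PSI matrices, per-contrast differential tables, cross-cohort
intersections and the metastasis selection.  ``run_validation`` goes from a
junction-usage matrix with labels to Bonferroni-adjusted per-junction
contrasts, the group-constrained predictor-set evaluation, and per-junction
survival.  All outputs are plain TSV with fixed column order; a JSON
manifest records thresholds, seeds and a sha256 per output so identical
configs reproduce identical bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier, diffsplice, psi as psi_mod, simulate, survival as surv_mod
from .counting import read_star_sj

__all__ = ["PipelineError", "RunConfig", "run_discovery", "run_validation", "run"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Flat key-value run configuration (see :meth:`from_file`)."""

    out_dir: Path
    seed: int = 1
    # discovery inputs: either simulate=cassette|trio or sj_dir + design
    simulate: str | None = "cassette"
    sj_dir: Path | None = None
    design_path: Path | None = None
    contrast: tuple[str, str] = ("NC", "CRC")
    p_max: float = 0.05
    dpsi_min: float = 0.20
    min_total: int = 10
    n_pairs: int = 18
    depth_mean: float = 200.0
    n_null_events: int = 100
    # validation inputs
    usage_path: Path | None = None
    labels_path: Path | None = None
    clinical_path: Path | None = None
    reps: int = 5
    train_frac: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.p_max < 1) or not (0 < self.dpsi_min < 1):
            raise PipelineError("thresholds outside valid ranges")
        for p in (self.sj_dir, self.design_path, self.usage_path,
                  self.labels_path, self.clinical_path):
            if p is not None and not Path(p).exists():
                raise PipelineError(f"configured path does not exist: {p}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kv: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise PipelineError(f"{path}: line {lineno}: expected key=value")
            key, value = line.split("=", 1)
            kv[key.strip()] = value.strip()
        kwargs: dict = {}
        if "out_dir" not in kv:
            raise PipelineError(f"{path}: missing required key out_dir")
        kwargs["out_dir"] = Path(kv.pop("out_dir"))
        casts = {
            "seed": int, "p_max": float, "dpsi_min": float, "min_total": int,
            "n_pairs": int, "depth_mean": float, "n_null_events": int,
            "reps": int, "train_frac": float,
        }
        paths = {"sj_dir", "design_path", "usage_path", "labels_path",
                 "clinical_path"}
        for key, value in kv.items():
            if key in casts:
                kwargs[key] = casts[key](value)
            elif key in paths:
                kwargs[key] = Path(value)
            elif key == "contrast":
                a, b = value.split(":")
                kwargs["contrast"] = (a, b)
            elif key == "simulate":
                kwargs["simulate"] = value if value.lower() != "none" else None
            else:
                raise PipelineError(f"{path}: unknown config key {key!r}")
        return cls(**kwargs)


def _write_tsv(frame: pd.DataFrame, path: Path, index_label: str) -> None:
    frame.to_csv(path, sep="\t", index_label=index_label, na_rep="NA",
                 float_format="%.10g")


def _manifest(out_dir: Path, stage: str, config: RunConfig,
              files: list[Path]) -> None:
    entries = {}
    for f in files:
        entries[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    manifest_path = out_dir / f"manifest_{stage}.json"
    manifest_path.write_text(
        json.dumps(
            {
                "stage": stage,
                "seed": config.seed,
                "thresholds": {
                    "p_max": config.p_max,
                    "dpsi_min": config.dpsi_min,
                    "min_total": config.min_total,
                },
                "outputs": entries,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )


def _load_design(path: Path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t")
    if frame.empty or not {"sample", "group"} <= set(frame.columns):
        raise PipelineError(
            "design stage: design table must be non-empty with sample/group columns"
        )
    return dict(zip(frame["sample"], frame["group"]))


def _discovery_inputs(config: RunConfig):
    """Counts + catalog + design for discovery, simulated or loaded."""
    if config.simulate == "cassette":
        counts, events, truth = simulate.simulate_cassette_counts(
            n_pairs=config.n_pairs,
            depth_mean=config.depth_mean,
            n_null_events=config.n_null_events,
            seed=config.seed,
        )
        design = {s: s.rsplit("_", 1)[1] for s in counts.samples}
        return {"CRC": (counts, events, design)}, truth, None
    if config.simulate == "trio":
        counts, counts2, events, truth = simulate.simulate_trio_cohort(
            n_pairs=config.n_pairs,
            depth_mean=config.depth_mean,
            n_null_events=config.n_null_events,
            seed=config.seed,
        )
        design1 = {s: s.rsplit("_", 1)[1] for s in counts.samples}
        design2 = {s: s.rsplit("_", 1)[1] for s in counts2.samples}
        return (
            {"cohort1": (counts, events, design1),
             "cohort2": (counts2, events, design2)},
            truth,
            "trio",
        )
    if config.sj_dir is None or config.design_path is None:
        raise PipelineError(
            "design stage: need simulate=cassette|trio or sj_dir + design_path"
        )
    design = _load_design(config.design_path)
    tables = []
    for sj in sorted(Path(config.sj_dir).glob("*.tab")):
        tables.append(read_star_sj(sj, sj.stem))
    if not tables:
        raise PipelineError(f"counting stage: no *.tab files in {config.sj_dir}")
    counts = tables[0]
    for t in tables[1:]:
        counts = counts.merged(t)
    from .annotation import build_site_groups

    groups = build_site_groups(counts.junctions.values())
    return {"cohort": (counts, None, design)}, None, "sj"


def run_discovery(config: RunConfig) -> dict:
    """PSI -> per-contrast tests -> intersection / metastasis selection."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohorts, truth, mode = _discovery_inputs(config)

    written: list[Path] = []
    results: dict = {"per_cohort": {}}
    crc_results: dict[str, pd.DataFrame] = {}
    mc_result: pd.DataFrame | None = None

    for name, (counts, events, design) in cohorts.items():
        matrices = psi_mod.compute_psi_matrix(
            counts, cassette_events=events or (), min_total=config.min_total
        )
        if psi_mod.PSI_EXON not in matrices:
            raise PipelineError(f"psi stage ({name}): no cassette events")
        matrix = matrices[psi_mod.PSI_EXON]
        psi_path = out_dir / f"psi_exon_{name}.tsv"
        matrix.to_tsv(psi_path)
        written.append(psi_path)

        try:
            res = diffsplice.test_events(
                matrix, design, config.contrast,
                p_max=config.p_max, dpsi_min=config.dpsi_min,
            )
        except diffsplice.DiffspliceError as exc:
            raise PipelineError(f"diff stage ({name}): {exc}") from exc
        res_path = out_dir / f"diff_{config.contrast[1]}_vs_{config.contrast[0]}_{name}.tsv"
        _write_tsv(res, res_path, "event_id")
        written.append(res_path)
        crc_results[name] = res
        results["per_cohort"][name] = res

        if mode == "trio" and name == "cohort1":
            mc_result = diffsplice.test_events(
                matrix, design, (config.contrast[0], "MC"),
                p_max=config.p_max, dpsi_min=config.dpsi_min,
            )
            mc_path = out_dir / f"diff_MC_vs_{config.contrast[0]}_{name}.tsv"
            _write_tsv(mc_result, mc_path, "event_id")
            written.append(mc_path)

    if len(crc_results) > 1:
        inter = diffsplice.intersect_cohorts(crc_results)
        inter_path = out_dir / "intersection.tsv"
        _write_tsv(inter, inter_path, "event_id")
        written.append(inter_path)
        results["intersection"] = inter

    if mc_result is not None:
        selection = diffsplice.select_metastasis_events(mc_result, crc_results)
        sel_path = out_dir / "metastasis_selection.tsv"
        _write_tsv(selection, sel_path, "event_id")
        written.append(sel_path)
        results["metastasis"] = selection

    if truth is not None:
        truth_path = out_dir / "planted_truth.tsv"
        _write_tsv(truth, truth_path, "event_id")
        written.append(truth_path)
        results["truth"] = truth

    _manifest(out_dir, "discovery", config, written)
    results["outputs"] = written
    return results


def run_validation(config: RunConfig) -> dict:
    """Usage contrasts + predictor-set search + optional survival stage."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    results: dict = {}

    if config.usage_path is not None:
        usage = psi_mod.read_usage_tsv(config.usage_path)
        matrix = usage.values.T  # samples x junctions
        if config.labels_path is None:
            raise PipelineError("validation stage: missing labels")
        labels_frame = pd.read_csv(config.labels_path, sep="\t", index_col=0)
        labels = labels_frame.iloc[:, 0].reindex(matrix.index)
        if labels.isna().any():
            raise PipelineError("validation stage: labels missing for some samples")
    else:
        matrix, labels, truth = simulate.simulate_usage_matrix(seed=config.seed)
        results["truth"] = truth

    # per-junction Wilcoxon with Bonferroni over the junction set
    rows = []
    tumor = matrix.index[labels == 1]
    normal = matrix.index[labels == 0]
    for junction in matrix.columns:
        res = diffsplice.wilcoxon_rank_sum(
            matrix.loc[tumor, junction], matrix.loc[normal, junction]
        )
        rows.append({"junction": junction,
                     "p_value": np.nan if res.p_value is None else res.p_value})
    per_junction = pd.DataFrame(rows).set_index("junction")
    tested = per_junction["p_value"].notna()
    per_junction["p_adj"] = np.nan
    if tested.any():
        per_junction.loc[tested, "p_adj"] = diffsplice.bonferroni(
            per_junction.loc[tested, "p_value"], m=int(tested.sum())
        )
    pj_path = out_dir / "usage_contrasts.tsv"
    _write_tsv(per_junction, pj_path, "junction")
    written.append(pj_path)
    results["per_junction"] = per_junction

    grouping = classifier.correlation_groups(matrix, k=3)
    evaluations = classifier.evaluate_all_sets(
        matrix, labels, grouping,
        reps=config.reps, train_frac=config.train_frac, seed=config.seed,
    )
    eval_frame = classifier.evaluations_to_frame(evaluations)
    eval_path = out_dir / "predictor_set_evaluations.tsv"
    eval_frame.to_csv(eval_path, sep="\t", index=False, float_format="%.10g")
    written.append(eval_path)
    best = classifier.select_best_model(evaluations)
    best_frame = pd.DataFrame(
        {
            "term": ["intercept"] + list(best.members),
            "coefficient": [best.best_intercept] + list(best.best_coefficients),
        }
    )
    best_path = out_dir / "final_model.tsv"
    best_frame.to_csv(best_path, sep="\t", index=False, float_format="%.10g")
    written.append(best_path)
    results["evaluations"] = evaluations
    results["best"] = best
    results["grouping"] = grouping

    if config.clinical_path is not None:
        clinical = pd.read_csv(config.clinical_path, sep="\t", index_col=0)
        surv_rows = []
        for junction in matrix.columns:
            out = surv_mod.survival_by_usage(clinical, matrix[junction])
            lr = out["logrank"]
            surv_rows.append(
                {
                    "junction": junction,
                    "statistic": np.nan if lr.statistic is None else lr.statistic,
                    "p_value": np.nan if lr.p_value is None else lr.p_value,
                    "n_low": int((out["groups"] == "low").sum()),
                    "n_high": int((out["groups"] == "high").sum()),
                }
            )
        surv_frame = pd.DataFrame(surv_rows).set_index("junction")
        surv_path = out_dir / "survival.tsv"
        _write_tsv(surv_frame, surv_path, "junction")
        written.append(surv_path)
        results["survival"] = surv_frame
    else:
        logger.info("no clinical table configured; survival stage skipped")

    _manifest(out_dir, "validation", config, written)
    results["outputs"] = written
    return results


def run(config: RunConfig) -> dict:
    """Discovery followed by validation under one config."""
    out = {"discovery": run_discovery(config)}
    out["validation"] = run_validation(config)
    return out
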
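"""End-to-end orchestration: metrics → consensus → agreement → statistics.

``run_pipeline`` ties all stages together in either *simulate* mode
(generate a synthetic study from a seed) or *files* mode (load mask
pairs and reader answers from disk), producing a :class:`ReportBundle`:
per-consensus-group metric summaries, Kruskal–Wallis tests, kappa
agreement curves with their maximizing thresholds, no-rejection
boundaries, and exclusion tallies.  Runs are deterministic given the
seed and the report echoes its full configuration so it can be re-run
bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .agreement import HIGHER_IS_BETTER, no_rejection_threshold, sweep
from .consensus import ConsensusLabel, consensus
from .masks import METRIC_NAMES, MaskPair, MetricRecord, compute_record
from .simulate import ReaderModel, SyntheticStudy, SyntheticStudyConfig, generate_study
from . import io as cio
from .stats import group_summaries, kruskal_wallis

__all__ = ["REPORT_SCHEMA_VERSION", "PipelineConfig", "ReportBundle", "analyze", "run_pipeline"]

REPORT_SCHEMA_VERSION = "1.0.0"

log = logging.getLogger("contourqa")


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (simulate- or files-mode)."""

    mode: str = "simulate"
    study: Optional[SyntheticStudyConfig] = None
    reader_model: Optional[ReaderModel] = None
    masks_path: Optional[str] = None
    masks_layout: str = "slice_directory"
    answers_path: Optional[str] = None
    alpha: float = 0.05
    hd_percentile: float = 95.0
    symmetric_hd: bool = False
    use_spacing: bool = False
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ValueError(f"mode must be 'simulate' or 'files', got {self.mode!r}")
        if self.mode == "simulate" and self.study is None:
            self.study = SyntheticStudyConfig()
        if self.mode == "files" and (self.masks_path is None or self.answers_path is None):
            raise ValueError("files mode requires masks_path and answers_path")


@dataclass
class ReportBundle:
    """Every stage output of one run, JSON-serializable and traceable."""

    version: str
    seed: Optional[int]
    config_echo: dict
    n_slices: int
    exclusions: Dict[str, int]
    group_summaries: Dict[str, list]
    kruskal_wallis: Dict[str, dict]
    agreement_curves: Dict[str, dict]
    no_rejection: Dict[str, dict]
    notes: List[str]

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, default=str)


def _align(records: Sequence[MetricRecord], labels: Sequence[ConsensusLabel]):
    by_id = {l.slice_id: l for l in labels}
    missing = [r.slice_id for r in records if r.slice_id not in by_id]
    if missing:
        raise ValueError(f"no consensus label for slices {missing[:5]}")
    return [by_id[r.slice_id] for r in records]


def analyze(
    records: Sequence[MetricRecord],
    labels: Sequence[ConsensusLabel],
    alpha: float = 0.05,
    config_echo: Optional[dict] = None,
    seed: Optional[int] = None,
) -> ReportBundle:
    """Agreement curves, no-rejection boundaries, group summaries and KW tests.

    Undefined (nan) metric values are excluded per metric with a
    reported tally; input row count always equals analyzed + excluded.
    """
    labels = _align(records, labels)
    accepted = np.array([l.accepted for l in labels], dtype=bool)
    curves: Dict[str, dict] = {}
    no_rej: Dict[str, dict] = {}
    kw: Dict[str, dict] = {}
    exclusions: Dict[str, int] = {}
    for m_idx, name in enumerate(METRIC_NAMES):
        vals = np.array([r.values()[m_idx] for r in records], dtype=float)
        ok = ~np.isnan(vals)
        exclusions[name] = int((~ok).sum())
        if exclusions[name]:
            log.warning("%s: excluding %d slices with undefined values", name, exclusions[name])
        direction = "higher_is_better" if HIGHER_IS_BETTER[name] else "lower_is_better"
        if ok.sum() >= 2:
            curves[name] = sweep(vals[ok], accepted[ok], direction, name).to_dict()
            no_rej[name] = no_rejection_threshold(vals[ok], accepted[ok], direction, name).to_dict()
        else:
            curves[name] = {"metric_name": name, "degenerate": True}
            no_rej[name] = {"metric_name": name, "degenerate": True}
        groups = {}
        for lab, v, o in zip(labels, vals, ok):
            if o:
                groups.setdefault(lab.consensus_answer, []).append(v)
        groups = {k: v for k, v in groups.items() if v}
        if len(groups) >= 2 and sum(len(v) for v in groups.values()) >= 3:
            kw[name] = kruskal_wallis([groups[k] for k in sorted(groups)], alpha=alpha).to_dict()
            kw[name]["groups"] = sorted(groups)
        else:
            kw[name] = {"degenerate": True, "groups": sorted(groups)}
    summaries = {
        "four_level": [g.to_dict() for g in group_summaries(records, labels, "four_level")],
        "binary": [g.to_dict() for g in group_summaries(records, labels, "binary")],
    }
    notes = [
        "thresholds are boundary-inclusive (accept >= t for higher-is-better metrics, <= t for lower)",
        "hd95 is the directed prediction-to-truth distance unless symmetric_hd was set",
        "no multiple-testing correction is applied across the five metrics",
    ]
    return ReportBundle(
        version=REPORT_SCHEMA_VERSION,
        seed=seed,
        config_echo=config_echo or {},
        n_slices=len(records),
        exclusions=exclusions,
        group_summaries=summaries,
        kruskal_wallis=kw,
        agreement_curves=curves,
        no_rejection=no_rej,
        notes=notes,
    )


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage and (optionally) write all outputs to out_dir."""
    study: Optional[SyntheticStudy] = None
    if config.mode == "simulate":
        log.info("simulate: generating study (n=%d)", config.study.n_slices)
        study = generate_study(config.study, config.reader_model)
        records, labels = study.records, study.labels
        seed = config.study.seed
    else:
        log.info("files: loading mask pairs from %s", config.masks_path)
        pairs = cio.load_mask_pairs(config.masks_path, layout=config.masks_layout)
        records = [
            compute_record(
                p,
                percentile=config.hd_percentile,
                symmetric=config.symmetric_hd,
                use_spacing=config.use_spacing,
            )
            for p in pairs
        ]
        panels = cio.read_answers_csv(config.answers_path)
        labels = [consensus(p) for p in panels]
        seed = None
    echo = asdict(config)
    if echo.get("study") is not None and not isinstance(echo["study"], dict):
        echo["study"] = asdict(config.study)
    report = analyze(records, labels, alpha=config.alpha, config_echo=echo, seed=seed)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        cio.write_metrics_csv(records, out / "metrics.csv")
        cio.write_consensus_csv(labels, out / "consensus.csv")
        if study is not None:
            study.table.to_csv(out / "study.csv", index=False)
        for name, curve in report.agreement_curves.items():
            if curve.get("degenerate") and "thresholds" not in curve:
                continue
            pd.DataFrame(
                {"threshold": curve["thresholds"], "kappa": curve["kappas"]}
            ).to_csv(out / f"curve_{name}.csv", index=False)
    return report
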
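"""End-to-end orchestration: annotations → labels → alignment → features →
balancing → decoding, with every intermediate written to disk and a manifest
recording seeds and content hashes so any stage can be audited or resumed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .alignment import assign_tr_labels, trim_lead_in
from .annotations import build_sentences, parse_word_annotations, sentences_to_frame
from .balancing import LabeledDataset, balance
from .decode import (
    EvalReport,
    MLPSpec,
    SplitSpec,
    evaluate_holdout,
    evaluate_kfold,
    shuffle_labels,
)
from .roifeatures import (
    FeatureMatrix,
    ROISpec,
    assemble_feature_matrix,
    extract_roi_timeseries,
    load_roi_specs,
    load_timeseries_dir,
)
from .sentiment import Lexicon, PolarityCase, label_sentences

logger = logging.getLogger("stimlabel")


@dataclass
class RunConfig:
    """Fully-resolved configuration for one pipeline run."""

    annotations: str | Path
    out_dir: str | Path
    lexicon: str | Path | None = None       # None → bundled demo lexicon
    images: Sequence[str | Path] = ()       # per-subject 4-D NIfTI files
    timeseries_dir: str | Path | None = None  # TSV bypass
    subjects: Sequence[str] = ()
    roi_specs: str | Path | Sequence[ROISpec] = ()
    case: str = "binary1"
    tr: float = 1.0
    lead_in_s: float = 0.0
    t_start: float = 0.0
    t_end: float | None = None
    gap_policy: str = "carry_previous"
    initial_policy: str = "backfill"
    boundary: str = "flag"
    balance_method: str = "none"
    k_neighbors: int = 5
    model: str = "rf"
    eval_mode: str = "holdout"
    k_folds: int = 10
    shuffle: bool = False
    split_seed: int = 0
    balance_seed: int = 0
    model_seed: int = 0
    shuffle_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> EvalReport:
    """Execute all stages in order, writing intermediates and a manifest.

    Stage order: parse annotations → build sentences → lexicon labels →
    TR alignment (+ lead-in trim) → ROI feature matrix → balancing →
    (optional label shuffle) → train/evaluate.  Any stage error aborts with
    the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seeds": {
            "split_seed": config.split_seed,
            "balance_seed": config.balance_seed,
            "model_seed": config.model_seed,
            "shuffle_seed": config.shuffle_seed,
        },
        "resolved": {
            "case": config.case, "tr": config.tr,
            "lead_in_s": config.lead_in_s, "gap_policy": config.gap_policy,
            "initial_policy": config.initial_policy,
            "balance_method": config.balance_method, "model": config.model,
            "eval_mode": config.eval_mode, "shuffle": config.shuffle,
        },
        "artifacts": {},
    }

    def emit(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path), "sha256": _sha256(path)
        }

    stage = "parse_annotations"
    try:
        words = parse_word_annotations(config.annotations)
        stage = "build_sentences"
        sentences = build_sentences(words, boundary=config.boundary)
        sentences_path = out / "sentences.tsv"
        sentences_to_frame(sentences).to_csv(sentences_path, sep="\t", index=False)
        emit("sentences", sentences_path)
        logger.info("built %d sentences from %d words", len(sentences), len(words))

        stage = "sentiment_labels"
        lexicon = (
            Lexicon.from_tsv(config.lexicon) if config.lexicon else Lexicon.demo()
        )
        label_table = label_sentences(sentences, lexicon)
        labels_path = out / "sentence_labels.tsv"
        label_table.to_csv(labels_path, sep="\t", index=False)
        emit("sentence_labels", labels_path)

        stage = "tr_alignment"
        case = PolarityCase.from_name(config.case)
        class_col = {
            PolarityCase.BINARY_1: "class_binary1",
            PolarityCase.BINARY_2: "class_binary2",
            PolarityCase.THREE_CLASS: "class_3class",
        }[case]
        tr_series = assign_tr_labels(
            onsets=[s.onset for s in sentences],
            durations=[s.duration for s in sentences],
            labels=label_table[class_col].to_numpy(),
            tr=config.tr,
            t_start=config.t_start,
            t_end=config.t_end,
            gap_policy=config.gap_policy,
            initial_policy=config.initial_policy,
        )
        if config.lead_in_s > 0:
            tr_series = trim_lead_in(tr_series, config.lead_in_s)
        tr_path = out / "tr_labels.tsv"
        tr_series.to_tsv(tr_path)
        emit("tr_labels", tr_path)
        logger.info("aligned %d volumes (case=%s)", tr_series.n_volumes, case.value)

        stage = "roi_features"
        roi_specs = (
            load_roi_specs(config.roi_specs)
            if isinstance(config.roi_specs, (str, Path))
            else list(config.roi_specs)
        )
        per_subject = []
        if config.timeseries_dir:
            roi_names = [r.name for r in roi_specs] if roi_specs else None
            for subject in config.subjects:
                series = load_timeseries_dir(
                    config.timeseries_dir, subject, roi_names
                )
                per_subject.append((series, tr_series))
        elif config.images:
            subjects = (
                list(config.subjects)
                or [f"sub-{i + 1:02d}" for i in range(len(config.images))]
            )
            for subject, img in zip(subjects, config.images):
                series = [
                    extract_roi_timeseries(img, roi, subject=subject)
                    for roi in roi_specs
                ]
                per_subject.append((series, tr_series))
        else:
            raise ValueError("config provides neither images nor timeseries_dir")
        fm = assemble_feature_matrix(per_subject)
        fm_path = out / "feature_matrix.tsv"
        fm.to_tsv(fm_path)
        emit("feature_matrix", fm_path)
        logger.info("feature matrix %d x %d", *fm.shape)

        stage = "balancing"
        data = balance(
            LabeledDataset(fm.features, fm.labels),
            method=config.balance_method,
            k_neighbors=config.k_neighbors,
            seed=config.balance_seed,
        )

        stage = "shuffle_control"
        if config.shuffle:
            data = shuffle_labels(data, seed=config.shuffle_seed)

        stage = "decode"
        if config.eval_mode == "kfold":
            spec = SplitSpec(mode="kfold", k=config.k_folds,
                             seed=config.split_seed)
            report = evaluate_kfold(data, model=config.model, spec=spec,
                                    seed=config.model_seed)
        else:
            spec = SplitSpec(seed=config.split_seed)
            report = evaluate_holdout(data, model=config.model, spec=spec,
                                      seed=config.model_seed)
        report_path = out / "eval_report.json"
        report.to_json(report_path)
        report.confusion_to_tsv(out / "confusion.tsv")
        emit("eval_report", report_path)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("run complete: accuracy=%.3f", report.accuracy)
    return report
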
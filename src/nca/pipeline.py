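"""End-to-end evaluation: detect on every image, match, aggregate, report.

Outcome accounting mirrors the clinical reading of single-lesion images:
for each positive image the lesion either is marked (one TP) or is not
(one FN), and the image contributes one FP when any spurious marking
appears; detections on lesion-free images are tallied separately as
``negative_images_fp``.  Per-type rows therefore read "x of n images",
and totals are the column sums.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .config import RunConfig
from .core import LesionCandidate, detect_lesions
from .image import GrayImage
from .metrics import (
    LESION_TYPES,
    Annotation,
    ConfusionCounts,
    MetricReport,
    aggregate_by_type,
    match_detections,
)
from .phantom import PhantomSample

__all__ = ["evaluate_samples", "run_pipeline", "report_tables"]


def _image_outcome(
    candidates: Sequence[LesionCandidate],
    annotations: Sequence[Annotation],
    iou_threshold: float,
    match_mode: str = "iou",
) -> tuple[dict[str, ConfusionCounts], int]:
    """Per-type binary counts for one image, plus FP flag for negatives."""
    dets = [(c.box, c.score) for c in candidates]
    counts, matches = match_detections(dets, list(annotations), iou_threshold, match_mode)
    matched_gt = {j for _, j in matches}
    per_type: dict[str, ConfusionCounts] = {}
    for j, ann in enumerate(annotations):
        hit = 1 if j in matched_gt else 0
        prev = per_type.get(ann.lesion_type, ConfusionCounts())
        per_type[ann.lesion_type] = prev + ConfusionCounts(tp=hit, fn=1 - hit)
    has_fp = 1 if counts.fp > 0 else 0
    if annotations and has_fp:
        # attribute the spurious-marking flag to the image's lesion type
        t = annotations[0].lesion_type
        per_type[t] = per_type[t] + ConfusionCounts(fp=1)
    return per_type, has_fp


def evaluate_samples(
    samples: Sequence[PhantomSample | tuple[GrayImage, Sequence[Annotation]]],
    config: RunConfig | None = None,
    detections: Sequence[Sequence[LesionCandidate]] | None = None,
) -> MetricReport:
    """Detect (or reuse ``detections``) and aggregate a MetricReport."""
    config = config or RunConfig()
    per_image: list[dict[str, ConfusionCounts]] = []
    negative_fp = 0
    for i, sample in enumerate(samples):
        if isinstance(sample, PhantomSample):
            image, anns = sample.image, sample.annotations
        else:
            image, anns = sample
        cands = (
            detections[i]
            if detections is not None
            else detect_lesions(image, config.nca_params)
        )
        per_type, has_fp = _image_outcome(
            cands, list(anns), config.iou_threshold, config.match_mode
        )
        if anns:
            per_image.append(per_type)
        else:
            negative_fp += has_fp
    return aggregate_by_type(
        per_image,
        rounding_mode=config.rounding_mode,
        betas=config.betas,
        negative_images_fp=negative_fp,
    )


def report_tables(report: MetricReport) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabular views: per-type TP/FP rows plus Total, and the metric table."""
    rows = []
    for t in LESION_TYPES:
        c = report.per_type.get(t, ConfusionCounts())
        n = c.tp + c.fn
        rows.append({"lesion_type": t, "n": n, "tp": c.tp, "fp": c.fp, "fn": c.fn})
    tot = report.totals
    rows.append(
        {
            "lesion_type": "Total",
            "n": tot.tp + tot.fn,
            "tp": tot.tp,
            "fp": tot.fp,
            "fn": tot.fn,
        }
    )
    per_type = pd.DataFrame(rows)
    metric_rows = [
        {"metric": "precision", "value": report.precision},
        {"metric": "recall", "value": report.recall},
        {"metric": "f1", "value": report.f1},
    ] + [
        {"metric": f"f_beta[{b:g}]", "value": v}
        for b, v in report.f_beta_values.items()
        if b != 1.0
    ]
    return per_type, pd.DataFrame(metric_rows)


def run_pipeline(
    config: RunConfig,
    samples: Sequence[PhantomSample],
    output_dir: str | Path | None = None,
    write_overlays: bool = False,
) -> MetricReport:
    """Detect on every sample, write artifacts, and return the report.

    Artifacts (when ``output_dir`` is given): per-image detection JSON,
    optional overlays, a per-type CSV table, a metric CSV table, and a
    report.json embedding the exact config and seed that produced it.
    """
    from . import io as nca_io

    out = Path(output_dir) if output_dir else (Path(config.output_dir) if config.output_dir else None)
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    all_detections: list[list[LesionCandidate]] = []
    for i, sample in enumerate(samples):
        image = sample.image
        if config.preprocess is not None:
            from .preprocess import truncation_normalize

            image = truncation_normalize(image, config.preprocess)
        cands = detect_lesions(image, config.nca_params)
        all_detections.append(cands)
        if out is not None:
            nca_io.write_detections(out / f"det_{i:04d}.json", cands)
            if write_overlays:
                nca_io.write_overlay(
                    out / f"overlay_{i:04d}.png", sample.image, cands, sample.annotations
                )
    report = evaluate_samples(samples, config, detections=all_detections)
    if out is not None:
        per_type, metric_table = report_tables(report)
        per_type.to_csv(out / "per_type.csv", index=False)
        metric_table.to_csv(out / "metrics.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump({"config": config.to_dict(), "report": report.to_dict()}, fh, indent=1)
    return report
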
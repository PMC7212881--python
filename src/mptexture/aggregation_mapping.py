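"""Sample-level diagnostic ratings, probability maps and evaluation reports.

Per-FoV posterior tumor probabilities are aggregated into one rating per
sample (patient/biopsy) as the sample median — robust against a minority of
atypical FoVs.  A median above 0.5 calls the sample "tumor", below 0.5
"nontumor"; exactly 0.5 is surfaced as "indeterminate" (and counted as
misclassified in evaluation) rather than silently resolved.

Tiled scans are rendered as false-color probability maps with a diverging
blue (nontumor, p=0) → gray (p=0.5) → red (tumor, p=1) scale, the standard
display for tumor-border delineation.

Evaluation reports sensitivity (correct rate among tumor samples),
specificity (correct rate among nontumor samples) and the pooled correct
rate, with per-type counts; display percentages are rounded half-up to
integers while the unrounded values are retained.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import LinearSegmentedColormap

from .lda_classifier import FovPrediction

CLASS_NONTUMOR = "nontumor"
CLASS_TUMOR = "tumor"
CLASS_INDETERMINATE = "indeterminate"

#: Diverging probability colormap: pure blue at 0, gray at 0.5, pure red at 1.
TUMOR_PROBABILITY_CMAP = LinearSegmentedColormap.from_list(
    "tumor_probability", [(0.0, (0.0, 0.0, 1.0)),
                          (0.5, (0.5, 0.5, 0.5)),
                          (1.0, (1.0, 0.0, 0.0))])
TUMOR_PROBABILITY_CMAP.set_bad((1.0, 1.0, 1.0, 0.0))  # missing tiles transparent


class AggregationError(Exception):
    """Invalid input to aggregation or evaluation."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SampleRating:
    """Median-probability diagnostic rating of one sample."""

    sample_id: str
    median_p: float
    predicted_class: str
    n_fovs: int
    fraction_fovs_tumor_call: float


@dataclass(frozen=True)
class ProbabilityMap:
    """Tumor probabilities on a scan's tile grid (NaN marks missing tiles)."""

    grid: np.ndarray
    sample_id: str = ""


@dataclass(frozen=True)
class EvaluationReport:
    """Sensitivity / specificity / correct rate with per-type counts.

    Rates are percentages; a rate whose class is absent is ``None``
    (undefined), never 0.  ``per_type_counts`` maps type tag →
    ``(n, n_correct)``.
    """

    sensitivity: float | None
    specificity: float | None
    correct_rate: float | None
    per_type_counts: dict[str, tuple[int, int]]
    level: str = "sample"

    @property
    def rounded(self) -> dict[str, int | None]:
        """Display percentages, rounded half-up to integers."""
        return {k: (None if v is None else _round_half_up(v))
                for k, v in (("sensitivity", self.sensitivity),
                             ("specificity", self.specificity),
                             ("correct_rate", self.correct_rate))}

    def to_dict(self) -> dict:
        return {"level": self.level,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "correct_rate": self.correct_rate,
                "rounded": self.rounded,
                "per_type_counts": {k: list(v) for k, v in self.per_type_counts.items()}}


def aggregate_sample(predictions: Sequence[FovPrediction], sample_id: str) -> SampleRating:
    """Median-aggregate the FoV probabilities of one sample.

    The sample median (mean of the middle two for even n) is the diagnostic
    rating; ties at exactly 0.5 yield the class "indeterminate".
    """
    if not predictions:
        raise AggregationError(f"no predictions for sample {sample_id!r}")
    for pred in predictions:
        if pred.provenance and pred.provenance[0] not in ("", sample_id):
            raise AggregationError(
                f"prediction from sample {pred.provenance[0]!r} mixed into "
                f"{sample_id!r}")
    p = np.array([pred.p_tumor for pred in predictions], dtype=float)
    median = float(np.median(p))
    if median > 0.5:
        cls = CLASS_TUMOR
    elif median < 0.5:
        cls = CLASS_NONTUMOR
    else:
        cls = CLASS_INDETERMINATE
    return SampleRating(sample_id=sample_id, median_p=median, predicted_class=cls,
                        n_fovs=len(p), fraction_fovs_tumor_call=float(np.mean(p > 0.5)))


def fraction_correct_fovs(predictions: Sequence[FovPrediction], true_label: str) -> float:
    """Fraction of FoVs whose thresholded call matches the truth.

    A FoV is called tumor when p_tumor > 0.5 and nontumor when p_tumor < 0.5;
    exact ties are counted as incorrect.
    """
    if not predictions:
        raise AggregationError("no predictions")
    if true_label not in (CLASS_NONTUMOR, CLASS_TUMOR):
        raise AggregationError(f"unknown label {true_label!r}")
    p = np.array([pred.p_tumor for pred in predictions], dtype=float)
    correct = (p > 0.5) if true_label == CLASS_TUMOR else (p < 0.5)
    return float(np.mean(correct))


def probability_map(predictions: Sequence[FovPrediction], sample_id: str = "") -> ProbabilityMap:
    """Arrange FoV predictions on their tile grid (missing tiles → NaN)."""
    if not predictions:
        raise AggregationError("no predictions to map")
    coords = []
    for pred in predictions:
        if len(pred.provenance) < 3:
            raise AggregationError("predictions lack grid provenance")
        coords.append((int(pred.provenance[1]), int(pred.provenance[2]), pred.p_tumor))
    n_r = max(r for r, _, _ in coords) + 1
    n_c = max(c for _, c, _ in coords) + 1
    grid = np.full((n_r, n_c), np.nan)
    for r, c, p in coords:
        grid[r, c] = p
    return ProbabilityMap(grid=grid, sample_id=sample_id)


def render_map(pmap: ProbabilityMap, out_path: str | Path, dpi: int = 100) -> Path:
    """Render a probability map as a PNG with a blue–gray–red colorbar."""
    grid = np.asarray(pmap.grid, dtype=float)
    if grid.size == 0:
        raise AggregationError("empty probability grid")
    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(max(2.0, grid.shape[1] * 0.6),
                                    max(1.6, grid.shape[0] * 0.45)))
    im = ax.imshow(np.ma.masked_invalid(grid), cmap=TUMOR_PROBABILITY_CMAP,
                   vmin=0.0, vmax=1.0, interpolation="nearest")
    ax.set_xlabel("tile column")
    ax.set_ylabel("tile row")
    if pmap.sample_id:
        ax.set_title(pmap.sample_id)
    cbar = fig.colorbar(im, ax=ax)
    cbar.set_label("probability of class assignment (tumor)")
    try:
        fig.savefig(out_path, dpi=dpi, metadata={"Software": "mptexture"})
    except OSError as exc:
        raise AggregationError(f"cannot write map to {out_path}: {exc}") from exc
    finally:
        plt.close(fig)
    return out_path


def probability_color(p: float) -> tuple[float, float, float, float]:
    """RGBA color assigned to a probability by the diverging scale."""
    return tuple(TUMOR_PROBABILITY_CMAP(float(np.clip(p, 0.0, 1.0))))


def report_from_counts(per_type: Iterable[tuple[str, str, int, int]],
                       level: str = "sample") -> EvaluationReport:
    """Build an evaluation report from per-type counts.

    ``per_type`` yields ``(type_tag, true_label, n, n_correct)`` with
    ``true_label`` in {tumor, nontumor}.
    """
    tumor_n = tumor_ok = nontumor_n = nontumor_ok = 0
    per_type_counts: dict[str, tuple[int, int]] = {}
    for type_tag, true_label, n, n_correct in per_type:
        if n < 0 or not (0 <= n_correct <= n):
            raise AggregationError(f"bad counts for {type_tag!r}: {n_correct}/{n}")
        per_type_counts[type_tag] = (n, n_correct)
        if true_label == CLASS_TUMOR:
            tumor_n += n
            tumor_ok += n_correct
        elif true_label == CLASS_NONTUMOR:
            nontumor_n += n
            nontumor_ok += n_correct
        else:
            raise AggregationError(f"unknown label {true_label!r}")
    if tumor_n + nontumor_n == 0:
        raise AggregationError("no counts supplied")
    sens = 100.0 * tumor_ok / tumor_n if tumor_n else None
    spec = 100.0 * nontumor_ok / nontumor_n if nontumor_n else None
    correct = 100.0 * (tumor_ok + nontumor_ok) / (tumor_n + nontumor_n)
    return EvaluationReport(sensitivity=sens, specificity=spec, correct_rate=correct,
                            per_type_counts=per_type_counts, level=level)


def evaluate(ratings: Sequence[tuple[SampleRating, str, str]],
             level: str = "sample") -> EvaluationReport:
    """Score sample ratings against truth.

    ``ratings`` holds ``(rating, true_label, type_tag)`` triples; an
    indeterminate rating matches neither class and counts as misclassified.
    """
    if not ratings:
        raise AggregationError("no ratings to evaluate")
    tally: dict[str, list[int]] = {}
    labels: dict[str, str] = {}
    for rating, true_label, type_tag in ratings:
        if true_label not in (CLASS_NONTUMOR, CLASS_TUMOR):
            raise AggregationError(f"unknown label {true_label!r}")
        if labels.setdefault(type_tag, true_label) != true_label:
            raise AggregationError(f"type {type_tag!r} maps to both classes")
        n, ok = tally.setdefault(type_tag, [0, 0])
        tally[type_tag][0] = n + 1
        tally[type_tag][1] = ok + int(rating.predicted_class == true_label)
    return report_from_counts(
        ((t, labels[t], n, ok) for t, (n, ok) in tally.items()), level=level)
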
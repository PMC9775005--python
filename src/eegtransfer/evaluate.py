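"""Subject-level evaluation protocol for cross-subject transfer.

Each evaluation group samples 8 healthy + 8 depressed subjects and splits
them into a labelled source domain and an unlabelled target domain, either
7:1 (7+7 source subjects, 1+1 target) or 4:4 (4+4 / 4+4).  Groups are drawn
independently, mirroring an experiment that repeats the protocol over
random subject combinations and reports per-group accuracy plus the
cross-group mean ± sd.

Accuracy is per window (each encoded 1-s image is one prediction); a
per-subject majority-vote accuracy is reported as a secondary metric.  No
window of a target subject ever enters training as labelled data — the
split is at the subject level, so leakage is excluded by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .adapt import (LABEL_TO_INDEX, AccuracyCurve, TrainConfig, build_model,
                    predict, train)
from .cohort import Recording
from .encode import Encoding, RasterSpec, encode_windowset
from .errors import InvalidArgumentError
from .preprocess import (DEFAULT_CORE_FRACTION, DEFAULT_WINDOW_LEN, FilterSpec,
                         preprocess_recording)

Ratio = Literal["seven_to_one", "four_to_four"]


@dataclass
class DomainSplit:
    """Disjoint source/target subject groupings for one evaluation group."""

    group_id: str
    source_subjects: list[str]
    target_subjects: list[str]
    ratio: Ratio

    def __post_init__(self) -> None:
        overlap = set(self.source_subjects) & set(self.target_subjects)
        if overlap:
            raise InvalidArgumentError(f"subjects in both domains: {sorted(overlap)}")


@dataclass
class GroupResult:
    """Outcome of one group's preprocess → encode → train → predict run."""

    group_id: str
    method: str
    encoding: str
    final_accuracy: float
    accuracy_curve: AccuracyCurve
    seed: int
    subject_accuracy: float = float("nan")
    n_target_windows: int = 0
    model: object | None = field(default=None, repr=False)


def _split_counts(ratio: Ratio) -> tuple[int, int]:
    """(source per class, target per class) out of 8 subjects per class."""
    if ratio == "seven_to_one":
        return 7, 1
    if ratio == "four_to_four":
        return 4, 4
    raise InvalidArgumentError(f"unknown ratio {ratio!r}")


def make_splits(cohort: Sequence[Recording], ratio: Ratio = "seven_to_one",
                n_groups: int = 11, seed: int = 0) -> list[DomainSplit]:
    """Draw independent groups of 8+8 subjects and partition each per ratio.

    Each group samples 8 healthy and 8 depressed subjects without
    replacement *within* the group; different groups are independent draws
    (subjects may recur across groups).
    """
    healthy = [r.subject_id for r in cohort if r.label == "healthy"]
    depressed = [r.subject_id for r in cohort if r.label == "depressed"]
    if len(healthy) < 8 or len(depressed) < 8:
        raise InvalidArgumentError(
            f"need ≥ 8 subjects per class, got {len(healthy)} healthy / "
            f"{len(depressed)} depressed")
    n_src, _ = _split_counts(ratio)
    rng = np.random.default_rng(seed)
    splits = []
    for g in range(n_groups):
        h = rng.choice(healthy, size=8, replace=False).tolist()
        d = rng.choice(depressed, size=8, replace=False).tolist()
        splits.append(DomainSplit(
            group_id=f"G{g + 1:02d}",
            source_subjects=h[:n_src] + d[:n_src],
            target_subjects=h[n_src:8] + d[n_src:8],
            ratio=ratio,
        ))
    return splits


def _encode_subject(recording: Recording, encoding: Encoding,
                    raster: RasterSpec, filt: FilterSpec,
                    core_fraction: tuple[float, float],
                    window_len: int):
    ws = preprocess_recording(recording, spec=filt, core_fraction=core_fraction,
                              window_len=window_len)
    return encode_windowset(ws, encoding=encoding, spec=raster)


def run_group(split: DomainSplit, cohort: Sequence[Recording],
              method: str = "dan", encoding: Encoding = "rgb_synthesis",
              cfg: TrainConfig | None = None,
              raster: RasterSpec | None = None,
              filt: FilterSpec | None = None,
              core_fraction: tuple[float, float] = DEFAULT_CORE_FRACTION,
              window_len: int = DEFAULT_WINDOW_LEN,
              image_cache: dict | None = None) -> GroupResult:
    """Execute the full pipeline on one domain split.

    Target recordings are preprocessed and encoded like source ones, but
    their labels are withheld from training and used only to score the
    per-epoch curve and the final per-window / per-subject accuracies.
    ``image_cache`` (keyed by subject id) lets repeated protocol runs skip
    re-encoding subjects shared between groups; encoding is deterministic,
    so caching cannot change any result.
    """
    cfg = cfg or TrainConfig()
    raster = raster or RasterSpec()
    filt = filt or FilterSpec()
    by_id = {r.subject_id: r for r in cohort}
    missing = [s for s in split.source_subjects + split.target_subjects
               if s not in by_id]
    if missing:
        raise InvalidArgumentError(f"subjects absent from cohort: {missing}")

    def encoded(sid: str):
        if image_cache is not None and sid in image_cache:
            return image_cache[sid]
        imgs = _encode_subject(by_id[sid], encoding, raster, filt,
                               core_fraction, window_len)
        if image_cache is not None:
            image_cache[sid] = imgs
        return imgs

    source_images = []
    for sid in split.source_subjects:
        source_images.extend(encoded(sid))
    target_images = []
    target_subject_of = []
    for sid in split.target_subjects:
        imgs = encoded(sid)
        target_images.extend(imgs)
        target_subject_of.extend([sid] * len(imgs))
    if not source_images or not target_images:
        raise InvalidArgumentError("a domain produced no windows")

    target_labels = np.array([LABEL_TO_INDEX[img.label] for img in target_images])
    n_ch = 1 if encoding == "merged_chart" else 3
    model = build_model(method, backbone=cfg.backbone,
                        input_shape=(n_ch, raster.height, raster.width),
                        seed=cfg.seed)
    model, curve = train(model, source_images, target_images, cfg,
                         target_labels=target_labels)
    pred, _ = predict(model, target_images)
    final_acc = float((pred == target_labels).mean())

    # secondary metric: majority vote over each target subject's windows
    votes = {}
    for sid, p, y in zip(target_subject_of, pred, target_labels):
        votes.setdefault(sid, {"pred": [], "true": int(y)})["pred"].append(int(p))
    subject_acc = float(np.mean([
        int(np.round(np.mean(v["pred"])) == v["true"]) for v in votes.values()]))

    return GroupResult(group_id=split.group_id, method=method,
                       encoding=encoding, final_accuracy=final_acc,
                       accuracy_curve=curve, seed=cfg.seed,
                       subject_accuracy=subject_acc,
                       n_target_windows=len(target_images), model=model)


def summarize(results: Sequence[GroupResult]) -> pd.DataFrame:
    """Per-method mean ± sd of final accuracies plus the group grid.

    Returns a tidy DataFrame with one row per (group, method) and attaches
    the per-method summary in ``DataFrame.attrs['summary']`` (mean and
    sample sd, n−1 convention).
    """
    if not results:
        raise InvalidArgumentError("no results to summarize")
    df = pd.DataFrame([{
        "group_id": r.group_id,
        "method": r.method,
        "encoding": r.encoding,
        "final_accuracy": r.final_accuracy,
        "subject_accuracy": r.subject_accuracy,
        "seed": r.seed,
    } for r in results])
    summary = (df.groupby("method")["final_accuracy"]
               .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
               .reset_index())
    df.attrs["summary"] = summary
    return df
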
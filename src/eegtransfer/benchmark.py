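"""Frozen desk-scale benchmark conditions for the synthetic cohort study.

These helpers define the package's standard experimental conditions once
so that tests, examples and the reproduction script all run the identical
study:

* **shift benchmark** — class effect 1.5, subject-shift dispersion 0.5,
  8+8-subject cohorts split 7:1, one evaluation group per seed; measures
  mean final target accuracy per method across seeds.
* **null calibration** — class effect 0 (the two classes' generating
  distributions are identical): target accuracy must be statistically
  indistinguishable from 0.5.
* **multi-group protocol** — one 29-healthy / 26-depressed cohort, 11
  independently drawn source→target groups, per-group accuracy and the
  cross-group mean ± sd for each adaptation method.

Problem sizes (40-s recordings → 16 one-second windows per subject,
48×48 canvases, 100-epoch benchmark training, 30-epoch protocol training)
are the package's desk-scale choices; they trade statistical resolution
against runtime and are documented in the methods note.
"""

from __future__ import annotations

import numpy as np

from .adapt import TrainConfig
from .cohort import generate_cohort
from .encode import RasterSpec
from .evaluate import DomainSplit, GroupResult, make_splits, run_group, summarize

#: Per-method adaptation weight λ used by the standard benchmark.  The
#: MK-MMD sum over three head layers needs a much smaller weight than the
#: single adversarial or covariance term to leave the source fit intact.
METHOD_LAMBDA = {"dan": 0.05, "dann": 1.0, "deepcoral": 1.0, "source_only": 0.0}

CLASS_EFFECT = 1.5
SHIFT_SD = 0.5
DURATION_S = 40.0
CANVAS = 48
BENCH_EPOCHS = 100
NULL_EPOCHS = 50
PROTOCOL_EPOCHS = 30


def standard_raster() -> RasterSpec:
    return RasterSpec(width=CANVAS, height=CANVAS)


def standard_config(method: str, seed: int, epochs: int = BENCH_EPOCHS
                    ) -> TrainConfig:
    return TrainConfig(epochs=epochs, seed=seed,
                       lambda_=METHOD_LAMBDA[method])


def shift_benchmark(methods: tuple[str, ...] = ("dan", "source_only"),
                    n_seeds: int = 5, epochs: int = BENCH_EPOCHS,
                    class_effect: float = CLASS_EFFECT,
                    shift_sd: float = SHIFT_SD,
                    encoding: str = "rgb_synthesis",
                    base_seed: int = 0) -> dict[str, list[float]]:
    """Seeded synthetic shift benchmark: per-method final target accuracies.

    Each seed draws a fresh 8+8 cohort, one 7:1 split, and trains every
    method on the identical images with the identical training seed.
    """
    raster = standard_raster()
    out: dict[str, list[float]] = {m: [] for m in methods}
    for i in range(n_seeds):
        seed = base_seed + i
        cohort = generate_cohort(8, 8, class_effect=class_effect,
                                 shift_sd=shift_sd, seed=seed,
                                 duration_s=DURATION_S)
        split = make_splits(cohort, "seven_to_one", n_groups=1, seed=seed)[0]
        cache: dict = {}
        for m in methods:
            res = run_group(split, cohort, method=m, encoding=encoding,
                            cfg=standard_config(m, seed, epochs),
                            raster=raster, image_cache=cache)
            out[m].append(res.final_accuracy)
    return out


def null_calibration(n_seeds: int = 10, epochs: int = NULL_EPOCHS,
                     method: str = "dan", base_seed: int = 0) -> np.ndarray:
    """Target accuracies under the class-effect-0 null, one run per seed.

    Cohorts of 9+9 subjects are split into 8+8 labelled source subjects
    and a 1+1 target pair; with identical class distributions the expected
    target accuracy is 0.5 (the target pair is balanced, so even a
    degenerate one-class predictor scores exactly 0.5).
    """
    raster = standard_raster()
    accs = []
    for i in range(n_seeds):
        seed = base_seed + i
        cohort = generate_cohort(9, 9, class_effect=0.0, shift_sd=SHIFT_SD,
                                 seed=seed, duration_s=DURATION_S)
        h = [r.subject_id for r in cohort if r.label == "healthy"]
        d = [r.subject_id for r in cohort if r.label == "depressed"]
        split = DomainSplit("null", h[:8] + d[:8], h[8:] + d[8:],
                            "seven_to_one")
        res = run_group(split, cohort, method=method,
                        cfg=standard_config(method, seed, epochs),
                        raster=raster)
        accs.append(res.final_accuracy)
    return np.array(accs)


def run_protocol(methods: tuple[str, ...] = ("dan", "dann", "deepcoral"),
                 n_groups: int = 11, epochs: int = PROTOCOL_EPOCHS,
                 n_healthy: int = 29, n_depressed: int = 26,
                 seed: int = 0, encoding: str = "rgb_synthesis"
                 ) -> list[GroupResult]:
    """The multi-group protocol: n_groups independent S→T combinations.

    One cohort of Table-1 shape (29 healthy / 26 depressed by default);
    every method sees the same groups, images and training seed.  Use
    :func:`eegtransfer.evaluate.summarize` on the result for the
    groups × methods grid and the mean ± sd summary.
    """
    cohort = generate_cohort(n_healthy, n_depressed, class_effect=CLASS_EFFECT,
                             shift_sd=SHIFT_SD, seed=seed,
                             duration_s=DURATION_S)
    splits = make_splits(cohort, "seven_to_one", n_groups=n_groups, seed=seed)
    raster = standard_raster()
    cache: dict = {}
    results = []
    for g, split in enumerate(splits):
        for m in methods:
            res = run_group(split, cohort, method=m, encoding=encoding,
                            cfg=standard_config(m, seed + g, epochs),
                            raster=raster, image_cache=cache)
            results.append(res)
    return results
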
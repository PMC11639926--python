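"""End-to-end bruise detection pipeline and accuracy reporting.

``run_pipeline`` chains calibration, three-phase demodulation, background
masking, enhancement (histogram equalization or AC/DC ratio plus median
filtering), threshold segmentation, small-component removal and the final
bruised/normal call.  ``evaluate`` aggregates predicted labels against
ground truth into the per-class / per-set accuracy layout used for
reporting detection studies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import demodulation, enhancement, segmentation
from .demodulation import DemodulatedPair, ForegroundMask, PhaseTriplet, ReferencePair
from .phantom import PhantomSample, PhantomSpec, generate_dataset, render_phantom
from .segmentation import SampleClassification, SegmentationResult
from .utils import round_half_up

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "EvaluationReport",
    "evaluate",
    "bruise_detection_study",
    "dark_spot_false_positive_study",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the detection chain in one place.

    image_style
        'rt' segments the (rescaled, median-filtered) AC/DC ratio image;
        'ac' segments the histogram-equalized AC image.
    method
        'iotsu' (improved Otsu), 'otsu', or 'global' (requires
        ``fixed_threshold``).
    min_area
        connected components smaller than this many pixels are treated as
        noise, not bruise.
    min_dynamic_range
        automatic thresholding is only attempted if the enhanced image
        spans at least this intensity range over the mask (after median
        filtering, before rescaling).  A featureless image -- residual
        sensor noise flattened by the median filter -- would otherwise be
        stretched to full range and split into meaningless classes.
    histogram_domain
        'image' (default) builds the threshold-selection histogram over
        the whole background-removed image, zeros included, exactly as the
        thresholding stage sees it: the background mass anchors the dark
        class at level 0 and the selected threshold falls between the dark
        (background + bruise) and sound-tissue modes.  'foreground'
        restricts the histogram to masked pixels; the bruise mode must
        then be very deep before the objective separates it from sound
        tissue.
    """

    mask_threshold: int = 15
    image_style: str = "rt"
    equalize_ac: bool = True  # equalize when segmenting the AC image
    rt_from_equalized: bool = False  # feed equalized AC into the ratio
    median_window: tuple[int, int] = (10, 10)
    apply_median: bool = True
    method: str = "iotsu"
    fixed_threshold: int | None = None
    polarity: str = "below"
    min_area: int = 50
    connectivity: int = 8
    min_dynamic_range: float = 0.05
    histogram_domain: str = "image"

    def __post_init__(self):
        if self.image_style not in ("rt", "ac"):
            raise ValueError("image_style must be 'rt' or 'ac'")
        if self.method not in ("iotsu", "otsu", "global"):
            raise ValueError("method must be 'iotsu', 'otsu' or 'global'")
        if self.method == "global" and self.fixed_threshold is None:
            raise ValueError("global thresholding needs fixed_threshold")
        if self.histogram_domain not in ("image", "foreground"):
            raise ValueError("histogram_domain must be 'image' or 'foreground'")


@dataclass(frozen=True)
class PipelineResult:
    """Final classification plus the intermediates of every stage."""

    classification: SampleClassification
    segmentation: SegmentationResult
    demodulated: DemodulatedPair
    mask: ForegroundMask
    enhanced: np.ndarray  # the image that was thresholded (unit range)


def _stage(name: str):
    """Re-raise stage failures with the stage name attached."""

    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"pipeline stage '{name}': {exc}") from exc
            return False

    return _ctx()


class _StageError(RuntimeError):
    pass


def run_pipeline(
    sample: PhantomSample | PhaseTriplet,
    config: PipelineConfig | None = None,
    references: ReferencePair | None = None,
) -> PipelineResult:
    """Run the full detection chain on one sample.

    Accepts either a rendered phantom (its references are used
    automatically) or a bare :class:`PhaseTriplet` with optional
    references.  A degenerate enhanced image (single occupied gray level)
    cannot support automatic thresholding and yields an empty bruise mask,
    i.e. a 'normal' call.
    """
    cfg = config or PipelineConfig()
    if isinstance(sample, PhantomSample):
        triplet = sample.triplet
        references = references or sample.references
    else:
        triplet = sample

    with _stage("calibration"):
        if references is not None:
            triplet = demodulation.correct_triplet(triplet, references)
    with _stage("demodulation"):
        pair = demodulation.demodulate_three_phase(triplet)
    with _stage("background mask"):
        mask = demodulation.create_background_mask(pair, cfg.mask_threshold)
        if not mask.mask.any():
            raise ValueError("foreground mask is empty; check the mask threshold")
    with _stage("enhancement"):
        if cfg.image_style == "rt":
            ratio = enhancement.ratio_image(pair, mask, equalize_ac=cfg.rt_from_equalized)
            working = ratio.rt
        else:
            ac = demodulation.apply_mask(pair.ac, mask)
            working = enhancement.histogram_equalize(ac, mask) if cfg.equalize_ac else ac
        if cfg.apply_median:
            # mask-aware median: background zeros must not erode the rim
            working = enhancement.median_filter(working, cfg.median_window, mask=mask)
        fg = working[mask.mask]
        featureless = float(fg.max() - fg.min()) < cfg.min_dynamic_range
        # min-max rescale after filtering so outliers cannot set the range
        working = enhancement.rescale_unit(working, mask)
    with _stage("segmentation"):
        if featureless and cfg.method != "global":
            seg = SegmentationResult(
                method=cfg.method,
                threshold=0,
                bruise_mask=np.zeros(mask.shape, dtype=bool),
            )
        elif cfg.method == "global":
            seg = segmentation.global_threshold_segment(
                working, mask, cfg.fixed_threshold, polarity=cfg.polarity
            )
        else:
            if cfg.histogram_domain == "image":
                hist_domain = np.ones(mask.shape, dtype=bool)
            else:
                hist_domain = mask.mask
            hist = segmentation.masked_histogram(working, hist_domain)
            if hist.n_occupied_levels < 2:
                seg = SegmentationResult(
                    method=cfg.method,
                    threshold=0,
                    bruise_mask=np.zeros(mask.shape, dtype=bool),
                )
            else:
                if cfg.method == "otsu":
                    t, curve = segmentation.otsu_threshold(hist)
                else:
                    t, curve = segmentation.improved_otsu_threshold(hist)
                seg = segmentation.apply_threshold(
                    working,
                    mask,
                    t,
                    polarity=cfg.polarity,
                    method=cfg.method,
                    objective_curve=curve,
                )
    with _stage("component cleanup"):
        seg = segmentation.remove_small_components(seg, cfg.min_area, cfg.connectivity)
    with _stage("classification"):
        result = segmentation.classify_sample(seg, cfg.connectivity)

    return PipelineResult(
        classification=result,
        segmentation=seg,
        demodulated=pair,
        mask=mask,
        enhanced=working,
    )


@dataclass(frozen=True)
class EvaluationReport:
    """Per-set, per-class and overall accuracies of a detection study.

    ``table`` has one row per (set, class) with columns
    ``['set', 'sample_class', 'n', 'correct', 'wrong', 'accuracy_pct']``;
    ``class_accuracy_pct`` pools both sets per class and
    ``total_accuracy_pct`` pools everything.  Accuracies are percentages
    rounded half-up to one decimal.
    """

    table: pd.DataFrame
    class_accuracy_pct: dict[str, float]
    total_accuracy_pct: float
    n_total: int
    n_correct: int

    def to_json_dict(self) -> dict:
        return {
            "per_set": self.table.to_dict(orient="records"),
            "class_accuracy_pct": self.class_accuracy_pct,
            "total_accuracy_pct": self.total_accuracy_pct,
            "n_total": self.n_total,
            "n_correct": self.n_correct,
        }


def evaluate(
    predictions: Sequence[str],
    truth: Sequence[str],
    split: Sequence[str] | None = None,
) -> EvaluationReport:
    """Score predicted labels against ground truth.

    ``split`` assigns each sample to a named set (e.g. 'training' /
    'testing'); omitted, all samples fall into a single 'all' set.
    Accuracy is ``100 * correct / n`` per (set, class), per class pooled
    over sets, and overall.
    """
    predictions = list(predictions)
    truth = list(truth)
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth differ in length")
    split = list(split) if split is not None else ["all"] * len(truth)
    if len(split) != len(truth):
        raise ValueError("split assignment differs in length")
    df = pd.DataFrame({"set": split, "truth": truth, "pred": predictions})
    df["correct"] = df["truth"] == df["pred"]

    rows = []
    for (set_name, cls), grp in df.groupby(["set", "truth"], sort=True):
        n = len(grp)
        correct = int(grp["correct"].sum())
        rows.append(
            {
                "set": set_name,
                "sample_class": cls,
                "n": n,
                "correct": correct,
                "wrong": n - correct,
                "accuracy_pct": round_half_up(100.0 * correct / n),
            }
        )
    table = pd.DataFrame(rows)
    class_acc = {
        cls: round_half_up(100.0 * grp["correct"].sum() / len(grp))
        for cls, grp in df.groupby("truth", sort=True)
    }
    n_correct = int(df["correct"].sum())
    return EvaluationReport(
        table=table,
        class_accuracy_pct=class_acc,
        total_accuracy_pct=round_half_up(100.0 * n_correct / len(df)),
        n_total=len(df),
        n_correct=n_correct,
    )


def bruise_detection_study(
    n_normal: int = 50,
    n_bruised: int = 100,
    n_sets: int = 1,
    config: PipelineConfig | None = None,
    base_spec: PhantomSpec | None = None,
    f: float = 0.10,
    wavelength: float = 700.0,
    seed: int = 0,
) -> EvaluationReport:
    """Generate phantom sets and score the pipeline end to end.

    Each set holds ``n_normal`` normal and ``n_bruised`` bruised phantoms
    (one set emulates a training or testing cohort); sets get distinct
    derived seeds.
    """
    cfg = config or PipelineConfig()
    set_names = ["training", "testing"] if n_sets == 2 else [f"set{i}" for i in range(n_sets)]
    preds: list[str] = []
    truths: list[str] = []
    splits: list[str] = []
    for k, name in enumerate(set_names):
        samples = generate_dataset(
            n_normal, n_bruised, base_spec=base_spec, f=f, wavelength=wavelength,
            seed=seed + 7919 * k,
        )
        for s in samples:
            preds.append(run_pipeline(s, cfg).classification.label)
            truths.append(s.label)
            splits.append(name)
    return evaluate(preds, truths, splits)


def dark_spot_false_positive_study(
    n_phantoms: int = 100,
    configs: dict[str, PipelineConfig] | None = None,
    base_spec: PhantomSpec | None = None,
    f: float = 0.10,
    wavelength: float = 700.0,
    seed: int = 0,
) -> dict[str, int]:
    """Count false bruise calls on bruise-free phantoms with dark spots.

    Renders ``n_phantoms`` normal samples (every one carrying dark-spot
    noise) and reports, per named configuration, how many are wrongly
    called bruised.  By default compares improved Otsu on the ratio image
    against plain Otsu on the equalized AC image at matched settings.
    """
    if configs is None:
        configs = {
            "iotsu_rt": PipelineConfig(method="iotsu", image_style="rt"),
            "otsu_ac": PipelineConfig(method="otsu", image_style="ac"),
        }
    spec = base_spec or PhantomSpec()
    if spec.n_dark_spots < 1:
        spec = dataclasses.replace(spec, n_dark_spots=3)
    # force at least one pit per phantom: the suite probes pit robustness
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_phantoms)
    samples = []
    for child in children:
        rng = np.random.default_rng(child)
        sample_spec = dataclasses.replace(
            spec,
            n_dark_spots=int(rng.integers(1, spec.n_dark_spots + 1)),
            spot_radius=float(rng.uniform(2.0, 5.5)),
            bruise=None,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        samples.append(render_phantom(sample_spec, f, wavelength, rng=rng))
    counts = {}
    for name, cfg in configs.items():
        fp = sum(
            1 for s in samples if run_pipeline(s, cfg).classification.label == "bruised"
        )
        counts[name] = fp
    return counts
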
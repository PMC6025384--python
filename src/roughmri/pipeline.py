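"""End-to-end composition: phantoms -> segmentation -> features -> rules.

The helpers here wire the stages together the way the command-line
``run`` subcommand and the reproduction script use them; each stage
remains independently usable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import compare_grid, paired_t
from .features import TextureFeatureExtractor, feature_names
from .phantom import LabeledImage, PhantomSpec, generate_dataset
from .roughset import RoughSetClassifier
from .segmentation import BrainSegmenter, SegmentationConfig, dice

__all__ = [
    "segment_dataset",
    "feature_table",
    "phantom_study",
]


def segment_dataset(
    images: list[LabeledImage], cfg: SegmentationConfig | None = None
) -> tuple[list[np.ndarray], list[np.ndarray], list[float]]:
    """Segment every phantom; returns (rois, masks, per-image Dice)."""
    seg = BrainSegmenter(**(cfg.__dict__ if cfg else {}))
    pairs = seg.fit([]).transform([li.image for li in images])
    rois = [roi for roi, _ in pairs]
    masks = [mask for _, mask in pairs]
    dices = [dice(mask, li.truth_mask) for mask, li in zip(masks, images)]
    return rois, masks, dices


def feature_table(
    rois: list[np.ndarray],
    labels: list[str] | None = None,
    transform: str = "dwpt",
    image_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Feature matrix as a DataFrame (one row per image, 180 columns)."""
    ext = TextureFeatureExtractor(transform_kind=transform).fit([])
    X = ext.transform(rois)
    df = pd.DataFrame(X, columns=feature_names(transform))
    if image_ids is not None:
        df.insert(0, "image_id", image_ids)
    if labels is not None:
        df["label"] = list(labels)
    return df


def phantom_study(
    n_normal: int = 30,
    n_abnormal: int = 30,
    n_repeats: int = 20,
    train_frac: float = 2 / 3,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    n_bins: int = 3,
    transforms: tuple[str, ...] = ("dwpt", "dct"),
) -> dict:
    """The full synthetic study: generate, segment, featurize, evaluate.

    Returns a dict with the generated labels, per-image Dice scores, one
    :class:`EvalResult` per transform (shared splits, rough-set LEM2
    classifier), and the paired t-test between the first two transforms
    when at least two are requested.
    """
    images = generate_dataset(n_normal, n_abnormal, base_spec, seed=seed)
    y = np.array([li.label for li in images])
    rois, masks, dices = segment_dataset(images)
    feature_sets = {
        t: feature_table(rois, transform=t).to_numpy() for t in transforms
    }
    results = compare_grid(
        feature_sets,
        y,
        classifiers={"rough_set": lambda: RoughSetClassifier(n_bins=n_bins)},
        n_repeats=n_repeats,
        train_frac=train_frac,
        seed=seed,
    )
    out = {
        "labels": y,
        "dice": np.array(dices),
        "results": results,
    }
    if len(transforms) >= 2:
        a = results[f"{transforms[0]}|rough_set"]
        b = results[f"{transforms[1]}|rough_set"]
        out["paired_t"] = paired_t(a.accuracies, b.accuracies)
    return out
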
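"""Quantitative and perceptual evaluation of generated tassel imagery.

Covers the four assessment protocols used to judge the synthetic data:

* bounding-box morphometrics — tassel widths/heights from Otsu-thresholded
  luma, compared between training and generated sets via (population)
  standard deviations and a wide-tassel fraction;
* SSIM protocols — randomly paired cross-set SSIM (averaged over repeats)
  and intraclass SSIM as a variability indicator;
* a KNN data-augmentation experiment — test accuracy of a 5-NN classifier
  on (width, height) features as generated samples are appended to the
  training half in 25% steps;
* perceptual-study utilities — deck construction (shuffled real+generated
  images with an answer key), the 2×2 column-normalised confusion table, and
  the inter-annotator disagreement lower bound

      e ≥ (1 / K·N) · Σ_i min_j (K − X(i, j)),

  where X(i, j) counts annotators giving item i the label j; 0 means
  unanimity, 1 complete disagreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier

from .color import luma
from .errors import DegenerateInputError, ParameterError, ShapeError
from .preprocess import otsu_threshold

__all__ = [
    "BoundingBox",
    "bounding_box",
    "morph_stats",
    "ssim",
    "paired_ssim_score",
    "intraclass_ssim",
    "interannotator_error",
    "rank_annotators",
    "knn_augmentation_experiment",
    "build_perception_deck",
    "confusion_table",
]


@dataclass(frozen=True)
class BoundingBox:
    """Tightest axis-aligned box of the foreground, 0-based inclusive."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    @property
    def width(self) -> int:
        return self.col_max - self.col_min + 1

    @property
    def height(self) -> int:
        return self.row_max - self.row_min + 1


def bounding_box(img_or_mask: np.ndarray) -> BoundingBox:
    """Bounding box of the foreground.  An RGB image is first reduced to its
    luma channel and Otsu-thresholded (foreground = brighter class); a 2-D
    array is treated as a mask directly."""
    arr = np.asarray(img_or_mask)
    if arr.ndim == 3:
        y = np.clip(np.rint(luma(arr)), 0, 255).astype(np.uint8)
        t = otsu_threshold(y)
        fg = y > t
    elif arr.ndim == 2:
        fg = arr.astype(bool)
    else:
        raise ShapeError("expected an H×W mask or H×W×3 image")
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    if rows.size == 0:
        raise DegenerateInputError("no foreground pixels")
    return BoundingBox(int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1]))


def morph_stats(table: pd.DataFrame, wide_cutoff: float = 60.0) -> pd.DataFrame:
    """Per-source summary of a morphometrics table.

    ``table`` needs columns ``width``, ``height``, ``source`` (e.g.
    "training" / "generated").  Returns per-source mean and *population*
    standard deviation of widths and heights, plus the fraction of tassels
    strictly wider than ``wide_cutoff`` pixels.  Requires ≥ 2 rows per
    source so the spread is defined.
    """
    required = {"width", "height", "source"}
    if not required <= set(table.columns):
        raise ParameterError(f"table must have columns {sorted(required)}")
    if (table[["width", "height"]] <= 0).any().any():
        raise ParameterError("widths and heights must be positive")
    rows = []
    for source, grp in table.groupby("source"):
        if len(grp) < 2:
            raise ParameterError(f"source {source!r} has fewer than 2 rows")
        rows.append(
            {
                "source": source,
                "n": len(grp),
                "width_mean": grp["width"].mean(),
                "width_std": float(np.std(grp["width"], ddof=0)),
                "height_mean": grp["height"].mean(),
                "height_std": float(np.std(grp["height"], ddof=0)),
                "frac_wider_than_cutoff": float((grp["width"] > wide_cutoff).mean()),
            }
        )
    return pd.DataFrame(rows).set_index("source")


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Single-scale SSIM on the 8-bit luma channel.

    Standard constants: K1=0.01, K2=0.03, dynamic range 255, 11×11 Gaussian
    window with σ=1.5.  1 means identical images.
    """
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ShapeError(f"image shapes differ: {a.shape} vs {b.shape}")
    ya = luma(a) if a.ndim == 3 else a.astype(np.float64)
    yb = luma(b) if b.ndim == 3 else b.astype(np.float64)
    return float(
        structural_similarity(
            ya,
            yb,
            data_range=255.0,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def paired_ssim_score(
    set_a: list[np.ndarray],
    set_b: list[np.ndarray],
    n_repeats: int = 3,
    seed: int = 0,
) -> float:
    """Random-pairing SSIM protocol: per repeat, each image of ``set_a`` is
    paired with a uniformly drawn partner from ``set_b`` and the SSIMs are
    averaged; the final score is the mean over ``n_repeats`` repeats."""
    if not set_a or not set_b:
        raise ParameterError("both sets must be non-empty")
    if n_repeats < 1:
        raise ParameterError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(n_repeats):
        partners = rng.integers(0, len(set_b), size=len(set_a))
        scores.append(np.mean([ssim(a, set_b[j]) for a, j in zip(set_a, partners)]))
    return float(np.mean(scores))


def intraclass_ssim(images: list[np.ndarray], n_repeats: int = 3, seed: int = 0) -> float:
    """Within-set variability score: each image is compared against a random
    *other* image of the same set (self-pairing excluded), averaged as in
    :func:`paired_ssim_score`.  High values mean low diversity."""
    n = len(images)
    if n < 2:
        raise ParameterError("need at least 2 images")
    if n_repeats < 1:
        raise ParameterError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(n_repeats):
        vals = []
        for i in range(n):
            j = int(rng.integers(0, n - 1))
            if j >= i:
                j += 1
            vals.append(ssim(images[i], images[j]))
        scores.append(np.mean(vals))
    return float(np.mean(scores))


def _vote_counts(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix)
    if m.ndim != 2:
        raise ShapeError("annotation matrix must be N items × K annotators")
    n, k = m.shape
    if n < 1:
        raise ParameterError("need at least 1 item")
    if k < 2:
        raise ParameterError("need at least 2 annotators")
    labels = np.unique(m)
    counts = np.stack([(m == lab).sum(axis=1) for lab in labels], axis=1)
    return counts  # N × L


def interannotator_error(matrix: np.ndarray) -> float:
    """Lower bound on inter-annotator disagreement for an N×K categorical
    label matrix: e ≥ (1/KN)·Σ_i min_j (K − X(i,j)).  0 iff every item is
    unanimous; ≤ 0.5 for binary labels."""
    counts = _vote_counts(matrix)
    n, _ = np.asarray(matrix).shape
    k = np.asarray(matrix).shape[1]
    disagreements = (k - counts.max(axis=1)).sum()
    return float(disagreements / (k * n))


def rank_annotators(matrix: np.ndarray, truth: np.ndarray, positive_label: int = 1) -> np.ndarray:
    """Annotator indices sorted by descending number of truly-positive items
    they labelled correctly (ties broken by annotator index).  Used to pick
    a top-expert subset before recomputing the disagreement bound."""
    m = np.asarray(matrix)
    truth = np.asarray(truth)
    if truth.shape[0] != m.shape[0]:
        raise ShapeError("truth length must equal number of items")
    pos = truth == positive_label
    correct = (m[pos] == positive_label).sum(axis=0)
    return np.argsort(-correct, kind="stable")


def knn_augmentation_experiment(
    real_features: np.ndarray,
    real_labels: np.ndarray,
    gen_features: np.ndarray,
    gen_labels: np.ndarray,
    fractions: list[float] = (0.0, 0.25, 0.5, 0.75),
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Does appending generated samples help a simple classifier?

    The real data is split 50/50 into train/test (stratified, seeded).  For
    each fraction f, ⌊f·|train|⌋ generated samples are appended to the
    training half (a seeded shuffle of the generated pool, taken as a
    prefix, so successive rows nest) and a k-NN classifier (Euclidean,
    majority vote) is scored on the fixed test half.
    """
    if k % 2 == 0:
        raise ParameterError("k must be odd (majority vote)")
    X = np.asarray(real_features, dtype=np.float64)
    y = np.asarray(real_labels)
    Xg = np.asarray(gen_features, dtype=np.float64)
    yg = np.asarray(gen_labels)
    if len(np.unique(y)) != 2:
        raise ParameterError("expected exactly two classes in the real labels")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.5, random_state=seed, stratify=y
    )
    if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
        raise ParameterError("a class is absent from one split")
    order = np.random.default_rng(seed).permutation(len(Xg))
    rows = []
    for f in fractions:
        n_app = int(np.floor(f * len(X_tr)))
        n_app = min(n_app, len(Xg))
        idx = order[:n_app]
        X_fit = np.vstack([X_tr, Xg[idx]]) if n_app else X_tr
        y_fit = np.concatenate([y_tr, yg[idx]]) if n_app else y_tr
        clf = KNeighborsClassifier(n_neighbors=k, metric="euclidean")
        clf.fit(X_fit, y_fit)
        rows.append(
            {
                "fraction": f,
                "n_train": len(X_tr),
                "n_appended": n_app,
                "n_test": len(X_te),
                "accuracy": float(clf.score(X_te, y_te)),
            }
        )
    return pd.DataFrame(rows)


def build_perception_deck(
    real_images: list[np.ndarray],
    generated_images: list[np.ndarray],
    seed: int = 0,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Shuffled presentation deck for a real-vs-generated perception study.

    Returns ``(deck, key)``: the concatenated images in a seeded uniform
    shuffle, and a parallel array with 1 for real, 0 for generated."""
    if not real_images or not generated_images:
        raise ParameterError("both image lists must be non-empty")
    deck = list(real_images) + list(generated_images)
    key = np.array([1] * len(real_images) + [0] * len(generated_images))
    order = np.random.default_rng(seed).permutation(len(deck))
    return [deck[i] for i in order], key[order]


def confusion_table(responses: np.ndarray, key: np.ndarray) -> pd.DataFrame:
    """2×2 perception-test summary as column percentages.

    Rows = perceived (real/generated), columns = true class; each column is
    normalised to sum to 100%, so a perfectly ambiguous generator would show
    50% everywhere."""
    responses = np.asarray(responses)
    key = np.asarray(key)
    if responses.shape != key.shape:
        raise ShapeError("responses and key must align")
    table = np.zeros((2, 2))
    for true_cls, col in ((1, 0), (0, 1)):
        sel = key == true_cls
        n = sel.sum()
        if n == 0:
            raise ParameterError("a true class is absent from the key")
        table[0, col] = 100.0 * (responses[sel] == 1).sum() / n
        table[1, col] = 100.0 * (responses[sel] == 0).sum() / n
    return pd.DataFrame(
        table,
        index=["perceived_real", "perceived_generated"],
        columns=["true_real", "true_generated"],
    )
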
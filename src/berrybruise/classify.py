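"""Pixel-spectrum classification: SVM training, evaluation, image maps.

A soft-margin RBF support-vector machine separates normalized healthy
and bruised tissue spectra.  Parameters stay at the LibSVM defaults
(cost 1, kernel width 1/#bands): the method's point is the baseline
separability of the two tissue classes, not a tuned classifier.

Whole-image classification applies the trained model to every berry
pixel except the calyx-end exclusion disc, producing a categorical
raster (background / healthy / bruised / excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .cube import HyperCube
from .library import BRUISED, HEALTHY, SpectralLibrary, normalize_spectrum
from .segment import LabelMap

__all__ = [
    "ConfusionMatrix",
    "ClassifiedImage",
    "ClassifierModel",
    "train_classifier",
    "cross_validate",
    "evaluate",
    "confusion_stats",
    "classify_image",
    "BACKGROUND",
    "HEALTHY_CODE",
    "BRUISED_CODE",
    "EXCLUDED_CODE",
]

# categorical raster codes
BACKGROUND, HEALTHY_CODE, BRUISED_CODE, EXCLUDED_CODE = 0, 1, 2, 3


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; the positive class is bruised tissue."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion_stats(cm: ConfusionMatrix) -> dict[str, float]:
    """True/false positive and negative rates and accuracy, in percent.

    Percentages are rounded to 2 decimals, the precision used when
    reporting tissue-classification confusion tables.
    """
    pos, neg = cm.tp + cm.fn, cm.fp + cm.tn
    if pos == 0 or neg == 0:
        raise ValueError("confusion matrix needs at least one row per actual class")
    tpr = 100.0 * cm.tp / pos
    tnr = 100.0 * cm.tn / neg
    return {
        "tpr_pct": round(tpr, 2),
        "tnr_pct": round(tnr, 2),
        "fpr_pct": round(100.0 - tnr, 2),
        "fnr_pct": round(100.0 - tpr, 2),
        "accuracy_pct": round(100.0 * (cm.tp + cm.tn) / cm.total, 2),
    }


@dataclass
class ClassifierModel:
    """Trained SVM plus the metadata needed to reapply it consistently."""

    svc: SVC
    wavelengths: np.ndarray
    normalization: str
    params: dict
    library_tag: str = ""

    def predict(self, spectra: np.ndarray) -> np.ndarray:
        """Class labels ('healthy'/'bruised') for already-normalized spectra."""
        return self.svc.predict(np.atleast_2d(spectra))

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not hold a ClassifierModel")
        return model


def _check_trainable(lib: SpectralLibrary) -> None:
    counts = lib.class_counts()
    if len(counts) < 2:
        raise ValueError(f"library holds a single class: {sorted(counts)}")
    if not lib.normalized:
        raise ValueError("classifier expects a normalized library")


def train_classifier(
    lib: SpectralLibrary, C: float = 1.0, gamma: str | float = "auto"
) -> ClassifierModel:
    """Fit the RBF SVM on a balanced, normalized library.

    ``gamma='auto'`` is 1/#bands, matching the LibSVM default kernel
    width; ``C=1`` is the default soft-margin cost.
    """
    _check_trainable(lib)
    svc = SVC(C=C, kernel="rbf", gamma=gamma)
    svc.fit(lib.spectra, lib.class_labels.astype(str))
    return ClassifierModel(
        svc=svc,
        wavelengths=lib.wavelengths.copy(),
        normalization="mean",
        params={"C": C, "kernel": "rbf", "gamma": gamma},
        library_tag=lib.source_tag,
    )


def cross_validate(
    lib: SpectralLibrary,
    k: int = 10,
    repeats: int = 5,
    seed: int = 0,
    C: float = 1.0,
    gamma: str | float = "auto",
) -> tuple[float, float]:
    """Repeated stratified k-fold CV accuracy.

    Returns ``(mean_pct, sd_pct)``: the accuracy averaged over folds and
    repeats, and the standard deviation across the ``repeats``
    re-randomized fold assignments (the quoted +/- spread).
    """
    _check_trainable(lib)
    labels = lib.class_labels.astype(str)
    min_class = min(lib.class_counts().values())
    if k > min_class:
        raise ValueError(f"k={k} exceeds smallest class size {min_class}")
    repeat_means = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        fold_acc = []
        for train_idx, test_idx in skf.split(lib.spectra, labels):
            svc = SVC(C=C, kernel="rbf", gamma=gamma)
            svc.fit(lib.spectra[train_idx], labels[train_idx])
            pred = svc.predict(lib.spectra[test_idx])
            fold_acc.append(np.mean(pred == labels[test_idx]))
        repeat_means.append(100.0 * float(np.mean(fold_acc)))
    mean = float(np.mean(repeat_means))
    sd = float(np.std(repeat_means, ddof=1)) if repeats > 1 else 0.0
    return mean, sd


def evaluate(model: ClassifierModel, test_lib: SpectralLibrary) -> ConfusionMatrix:
    """Confusion counts of the model on an independent test library."""
    if len(test_lib) == 0:
        raise ValueError("test library is empty")
    if not test_lib.normalized:
        raise ValueError("test library must be normalized like the training library")
    if test_lib.wavelengths.size != model.wavelengths.size or not np.allclose(
        test_lib.wavelengths, model.wavelengths
    ):
        raise ValueError("test library wavelength grid differs from the model's")
    pred = model.predict(test_lib.spectra)
    actual = test_lib.class_labels.astype(str)
    return ConfusionMatrix(
        tp=int(np.sum((actual == BRUISED) & (pred == BRUISED))),
        fn=int(np.sum((actual == BRUISED) & (pred == HEALTHY))),
        fp=int(np.sum((actual == HEALTHY) & (pred == BRUISED))),
        tn=int(np.sum((actual == HEALTHY) & (pred == HEALTHY))),
    )


@dataclass
class ClassifiedImage:
    """Per-pixel categorical raster tied to its berry label map."""

    classes: np.ndarray  # uint8 codes: background/healthy/bruised/excluded
    labelmap: LabelMap

    def __post_init__(self) -> None:
        if self.classes.shape != self.labelmap.labels.shape:
            raise ValueError("class raster and label map shapes differ")

    def counts(self) -> dict[str, int]:
        c = self.classes
        return {
            "background": int(np.sum(c == BACKGROUND)),
            "healthy": int(np.sum(c == HEALTHY_CODE)),
            "bruised": int(np.sum(c == BRUISED_CODE)),
            "excluded": int(np.sum(c == EXCLUDED_CODE)),
        }


def classify_image(
    model: ClassifierModel,
    cube: HyperCube,
    labelmap: LabelMap,
    exclusion_mask: np.ndarray | None = None,
    normalization: str = "mean",
) -> ClassifiedImage:
    """Classify every berry pixel of a calibrated cube.

    Background comes straight from the label map; calyx-excluded pixels
    are marked ``excluded`` and never receive a tissue class.  The
    remaining berry pixels are normalized exactly as the training
    library was, then labeled healthy or bruised by the SVM.
    """
    if cube.kind != "reflectance":
        raise ValueError("classify_image expects a calibrated reflectance cube")
    if cube.shape[:2] != labelmap.labels.shape:
        raise ValueError("cube and label map shapes differ")
    if exclusion_mask is None:
        exclusion_mask = np.zeros(labelmap.labels.shape, dtype=bool)
    exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
    if exclusion_mask.shape != labelmap.labels.shape:
        raise ValueError("exclusion mask and label map shapes differ")

    berry = labelmap.labels > 0
    out = np.full(labelmap.labels.shape, BACKGROUND, dtype=np.uint8)
    out[berry & exclusion_mask] = EXCLUDED_CODE
    target = berry & ~exclusion_mask
    if target.any():
        spectra = normalize_spectrum(cube.data[target], method=normalization)
        pred = model.predict(spectra)
        codes = np.where(pred == BRUISED, BRUISED_CODE, HEALTHY_CODE).astype(np.uint8)
        out[target] = codes
    return ClassifiedImage(out, labelmap)
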
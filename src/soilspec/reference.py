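"""Reported confusion matrices of the originating soil-type recognition study.

These are the published true-by-predicted counts for the all-feature PLSDA
model and the GA-selected (GA-PLSDA) model, each evaluated on the training
set (calibration), by leave-one-out cross-validation, and on the held-out
testing set.  Only the raw counts are stored; every percentage is
recomputed from them with :func:`soilspec.plsda.overall_accuracy` and
:func:`soilspec.plsda.per_class_accuracy`.

Class order (rows = true class, columns = predicted class):
Albic Luvisols, Haplic Luvisols, Chernozems, Eutric Cambisols, Phaeozems.
"""

from __future__ import annotations

import numpy as np

from .dataset import DEFAULT_CLASS_ORDER
from .plsda import ConfusionMatrix

#: reported per-class totals: 36+72+29+45+48 = 230 samples, split 153/77
CLASS_TOTALS = {c: n for c, n in zip(DEFAULT_CLASS_ORDER, (36, 72, 29, 45, 48))}

_PLSDA = {
    "training": [
        [24, 0, 0, 0, 0],
        [0, 48, 0, 0, 0],
        [0, 0, 19, 0, 0],
        [0, 0, 0, 30, 0],
        [0, 0, 0, 0, 32],
    ],
    "loo": [
        [21, 0, 0, 0, 3],
        [0, 48, 0, 0, 0],
        [1, 3, 12, 0, 3],
        [0, 1, 0, 28, 1],
        [0, 2, 3, 0, 27],
    ],
    "testing": [
        [12, 0, 0, 0, 0],
        [1, 15, 0, 6, 2],
        [0, 0, 9, 0, 1],
        [0, 2, 0, 13, 0],
        [1, 0, 0, 0, 15],
    ],
}

_GA_PLSDA = {
    "training": [
        [23, 0, 0, 0, 1],
        [0, 48, 0, 0, 0],
        [0, 1, 18, 0, 0],
        [0, 0, 0, 30, 0],
        [0, 1, 0, 0, 31],
    ],
    "loo": [
        [21, 2, 0, 0, 1],
        [0, 47, 0, 0, 1],
        [1, 2, 15, 0, 1],
        [0, 1, 0, 29, 0],
        [0, 1, 2, 0, 29],
    ],
    "testing": [
        [12, 0, 0, 0, 0],
        [1, 20, 0, 3, 0],
        [0, 0, 10, 0, 0],
        [0, 0, 0, 15, 0],
        [0, 0, 1, 0, 15],
    ],
}


def reported_confusions(model: str = "plsda") -> dict[str, ConfusionMatrix]:
    """Published confusion matrices for ``"plsda"`` or ``"ga_plsda"``.

    Keys are the evaluation blocks: ``training``, ``loo``, ``testing``.
    """
    tables = {"plsda": _PLSDA, "ga_plsda": _GA_PLSDA}
    if model not in tables:
        raise ValueError(f"model must be one of {sorted(tables)}, got {model!r}")
    return {
        block: ConfusionMatrix(np.asarray(counts), DEFAULT_CLASS_ORDER)
        for block, counts in tables[model].items()
    }
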
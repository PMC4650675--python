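"""Spectra containers, wide-CSV I/O, and the stratified 2:1 train/test split.

The universal in-memory object is :class:`SpectraSet`: a wavenumber grid
(strictly decreasing, cm^-1), an ``n x p`` absorbance matrix, unique sample
ids, and class labels drawn from a declared ordered class list.  The class
order matters downstream: it fixes the column order of the class-indicator
matrix and the tie-break rule of the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: The five FAO soil classes of the study area, in reporting order.
DEFAULT_CLASS_ORDER: tuple[str, ...] = (
    "Albic Luvisols",
    "Haplic Luvisols",
    "Chernozems",
    "Eutric Cambisols",
    "Phaeozems",
)


@dataclass
class SpectraSet:
    """A set of NIR spectra with class labels.

    Parameters
    ----------
    wavenumbers : (p,) array
        Spectral grid in cm^-1, strictly decreasing (high to low energy,
        the conventional FT-NIR presentation).
    absorbance : (n, p) array
        Unitless absorbance, one row per sample.
    sample_ids : sequence of n unique strings
    labels : sequence of n class names, each a member of ``class_order``
    class_order : ordered class list defining indicator columns and
        reporting order; defaults to the five FAO soil classes.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]
    labels: list[str]
    class_order: tuple[str, ...] = field(default=DEFAULT_CLASS_ORDER)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = [str(l) for l in self.labels]
        self.class_order = tuple(self.class_order)
        n, p = self.absorbance.shape
        if n < 1 or p < 1:
            raise ValueError(f"empty spectra set (n={n}, p={p})")
        if self.wavenumbers.shape != (p,):
            raise ValueError(
                f"wavenumber grid length {self.wavenumbers.shape[0]} does not "
                f"match absorbance columns {p}"
            )
        if not np.all(np.diff(self.wavenumbers) < 0):
            raise ValueError("wavenumbers must be strictly decreasing")
        if not np.all(np.isfinite(self.absorbance)):
            bad = np.argwhere(~np.isfinite(self.absorbance))[0]
            raise ValueError(
                f"non-finite absorbance at sample {self.sample_ids[bad[0]]!r}, "
                f"column {bad[1]}"
            )
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError("sample_ids and labels must have one entry per row")
        seen: set[str] = set()
        for s in self.sample_ids:
            if s in seen:
                raise ValueError(f"duplicate sample id {s!r}")
            seen.add(s)
        known = set(self.class_order)
        for s, l in zip(self.sample_ids, self.labels):
            if l not in known:
                raise ValueError(
                    f"sample {s!r} has label {l!r} not in declared class order "
                    f"{list(self.class_order)}"
                )

    # -- convenience -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_features(self) -> int:
        return self.absorbance.shape[1]

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def class_counts(self) -> dict[str, int]:
        lab = self.label_array()
        return {c: int(np.sum(lab == c)) for c in self.class_order}

    def take(self, indices: Sequence[int]) -> "SpectraSet":
        """Row subset (samples), preserving order of ``indices``."""
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            absorbance=self.absorbance[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=[self.labels[i] for i in idx],
        )

    def select_features(self, feature_indices: Sequence[int]) -> "SpectraSet":
        """Column subset (wavenumbers), e.g. a GA-selected subset."""
        idx = np.asarray(sorted(set(int(i) for i in feature_indices)), dtype=int)
        if idx.size == 0:
            raise ValueError("feature subset is empty")
        if idx[0] < 0 or idx[-1] >= self.n_features:
            raise ValueError(
                f"feature index out of range 0..{self.n_features - 1}: "
                f"{idx[idx >= self.n_features].tolist() or idx[idx < 0].tolist()}"
            )
        return replace(
            self,
            wavenumbers=self.wavenumbers[idx],
            absorbance=self.absorbance[:, idx],
        )


def read_spectra_table(
    path: str | Path,
    class_order: Sequence[str] | None = None,
    reorder: bool = False,
) -> SpectraSet:
    """Read a wide spectra CSV: ``id,label,<wn1>,<wn2>,...`` header.

    Wavenumber column headers must be numeric and (by default) strictly
    decreasing left to right; pass ``reorder=True`` to accept an ascending
    grid and flip it.  If ``class_order`` is omitted, the default soil
    classes are used when all labels belong to them, otherwise classes are
    taken in order of first appearance.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={0: str, 1: str}, float_precision="round_trip")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need id, label and at least one wavenumber column")
    wn_cols = list(df.columns[2:])
    try:
        wn = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        bad = [c for c in wn_cols if not _is_number(c)]
        raise ValueError(f"{path}: non-numeric wavenumber column header(s) {bad}") from exc
    X = df[wn_cols].to_numpy(dtype=float)
    order = np.arange(len(wn))
    if not np.all(np.diff(wn) < 0):
        if not reorder:
            raise ValueError(
                f"{path}: wavenumber columns are not strictly decreasing; "
                "pass reorder=True to sort the grid"
            )
        order = np.argsort(-wn, kind="stable")
        wn = wn[order]
        X = X[:, order]
    ids = df.iloc[:, 0].tolist()
    labels = df.iloc[:, 1].tolist()
    if class_order is None:
        if set(labels) <= set(DEFAULT_CLASS_ORDER):
            class_order = DEFAULT_CLASS_ORDER
        else:
            class_order = tuple(dict.fromkeys(labels))
    return SpectraSet(wn, X, ids, labels, tuple(class_order))


def write_spectra_table(spectra: SpectraSet, path: str | Path) -> None:
    """Write the wide CSV read by :func:`read_spectra_table` (full precision)."""
    df = pd.DataFrame(
        spectra.absorbance, columns=[repr(float(w)) for w in spectra.wavenumbers]
    )
    df.insert(0, "label", spectra.labels)
    df.insert(0, "id", spectra.sample_ids)
    df.to_csv(path, index=False, float_format="%.17g")  # lossless for float64


def train_count(n_class: int, train_fraction: float = 2.0 / 3.0) -> int:
    """Per-class training allocation: round to the nearest integer.

    For the study's 2:1 split this reproduces the reported class counts,
    e.g. 29 samples -> 19 training / 10 testing.
    """
    # fraction*n has denominator 3 for the 2:1 split, so no .5 ties arise;
    # floor(x+0.5) is used to stay independent of banker's rounding.
    return int(np.floor(train_fraction * n_class + 0.5))


def stratified_split(
    spectra: SpectraSet,
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> tuple[SpectraSet, SpectraSet]:
    """Per-class random 2:1 allocation into training and testing sets.

    Every class must have at least 2 samples.  Deterministic for a fixed
    seed; the two outputs are disjoint and their union is the input.
    """
    rng = np.random.default_rng(seed)
    labels = spectra.label_array()
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in spectra.class_order:
        idx = np.flatnonzero(labels == c)
        if idx.size == 0:
            continue
        if idx.size < 2:
            raise ValueError(f"class {c!r} has {idx.size} sample(s); need at least 2")
        perm = rng.permutation(idx.size)
        k = train_count(idx.size, train_fraction)
        train_idx.extend(idx[perm[:k]].tolist())
        test_idx.extend(idx[perm[k:]].tolist())
    return spectra.take(sorted(train_idx)), spectra.take(sorted(test_idx))


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
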
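"""Report writers: confusion tables and accuracy curves as CSV.

The confusion layout mirrors the study's recognition-rate tables: one row
per true class with predicted-class counts, a trailing per-class accuracy
column, and a final ``Mean`` row carrying the overall accuracy.  All
percentages are printed to two decimals.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .plsda import ConfusionMatrix, overall_accuracy, per_class_accuracy


def confusion_frame(cm: ConfusionMatrix) -> pd.DataFrame:
    """Confusion matrix + accuracy column + Mean row as a DataFrame."""
    classes = list(cm.class_order)
    acc = per_class_accuracy(cm)
    rows = []
    for i, c in enumerate(classes):
        row: dict[str, object] = {"true_class": c}
        row.update({p: int(cm.counts[i, j]) for j, p in enumerate(classes)})
        row["accuracy_pct"] = "" if pd.isna(acc[i]) else f"{acc[i]:.2f}"
        rows.append(row)
    mean_row: dict[str, object] = {"true_class": "Mean"}
    mean_row.update({p: "" for p in classes})
    mean_row["accuracy_pct"] = f"{overall_accuracy(cm):.2f}"
    rows.append(mean_row)
    return pd.DataFrame(rows)


def write_confusion_report(cm: ConfusionMatrix, path: str | Path) -> None:
    confusion_frame(cm).to_csv(path, index=False)


def read_confusion_report(path: str | Path) -> ConfusionMatrix:
    """Re-parse a written confusion report back into counts."""
    df = pd.read_csv(path, dtype={"true_class": str})
    body = df[df["true_class"] != "Mean"]
    classes = tuple(body["true_class"].tolist())
    counts = body[list(classes)].to_numpy(dtype=int)
    return ConfusionMatrix(counts, classes)


def write_manifest(path: str | Path, **entries) -> None:
    """Machine-readable run manifest (inputs, seed, parameters)."""
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
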
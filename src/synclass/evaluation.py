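"""Confusion counting and metrics for classifier predictions.

Per read: a true positive when the predicted label equals the ground
truth, a false positive when it differs (including any prediction for a
read whose true source is absent from the reference database), a false
negative when no label was assigned but the truth is in the database, and
a true negative when no label was assigned and the truth is out of the
database.  Out-of-database truth is flagged with the sentinel label
``OUT_OF_DB``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping
import warnings

from .errors import ConfigurationError, InputError

__all__ = [
    "OUT_OF_DB",
    "ConfusionCounts",
    "confusion_counts",
    "metrics",
    "rollup_labels",
    "read_truth_tsv",
    "read_predictions_tsv",
]

OUT_OF_DB = "OUT_OF_DB"


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion_counts(
    predictions: Mapping[str, str | None],
    truth: Mapping[str, str],
) -> ConfusionCounts:
    """Count TP/FP/FN/TN over reads.

    ``predictions`` maps read id to a label or None (unclassified);
    ``truth`` maps read id to the true label or ``OUT_OF_DB``.  Every
    predicted read must have a truth entry.
    """
    c = ConfusionCounts()
    for read_id, pred in predictions.items():
        if read_id not in truth:
            raise InputError(f"read {read_id!r} has no ground-truth entry")
        true = truth[read_id]
        if pred is None:
            if true == OUT_OF_DB:
                c.TN += 1
            else:
                c.FN += 1
        elif true != OUT_OF_DB and pred == true:
            c.TP += 1
        else:
            c.FP += 1
    return c


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Recall, precision, accuracy and F1 from confusion counts.

    recall = TP/(TP+FN), precision = TP/(TP+FP),
    accuracy = (TP+TN)/total, F1 = harmonic mean of precision and recall.
    Metrics with a zero denominator are reported as None (undefined),
    never as 0.
    """
    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    recall = ratio(c.TP, c.TP + c.FN)
    precision = ratio(c.TP, c.TP + c.FP)
    accuracy = ratio(c.TP + c.TN, c.total)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {"recall": recall, "precision": precision, "accuracy": accuracy, "f1": f1}


def _check_acyclic(parent_map: Mapping[str, str]) -> None:
    for start in parent_map:
        seen = {start}
        node = start
        while node in parent_map and parent_map[node] != node:
            node = parent_map[node]
            if node in seen:
                raise ConfigurationError(
                    f"parent map contains a cycle through {node!r}"
                )
            seen.add(node)


def rollup_labels(
    predictions: Mapping[str, str | None],
    truth: Mapping[str, str],
    parent_map: Mapping[str, str],
) -> tuple[dict[str, str | None], dict[str, str]]:
    """Replace labels on both sides with their parents (one level up).

    Enables genus-level scoring from species-level output.  Labels absent
    from the map pass through unchanged with a warning (mirroring the
    convention that a rank-less node is its own parent); the ``OUT_OF_DB``
    sentinel is never remapped.  A cyclic map is rejected.
    """
    _check_acyclic(parent_map)
    missing: set[str] = set()

    def remap(label: str | None) -> str | None:
        if label is None or label == OUT_OF_DB:
            return label
        if label not in parent_map:
            missing.add(label)
            return label
        return parent_map[label]

    new_pred = {r: remap(v) for r, v in predictions.items()}
    new_truth = {r: remap(v) for r, v in truth.items()}
    if missing:
        warnings.warn(
            f"{len(missing)} label(s) absent from the parent map pass "
            f"through unchanged: {sorted(missing)[:5]}..."
        )
    return new_pred, new_truth


# ---------------------------------------------------------------------------
# TSV I/O


def read_truth_tsv(path: str | Path) -> dict[str, str]:
    """Read ground truth: two tab-separated columns, read_id and label
    (or ``OUT_OF_DB``); '#' lines and a header line are ignored."""
    truth: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "read_id":
                continue
            if len(parts) < 2:
                raise InputError(f"malformed truth line in {path}: {line!r}")
            truth[parts[0]] = parts[1]
    return truth


def read_predictions_tsv(path: str | Path) -> dict[str, str | None]:
    """Read predictions as written by ``classify_stream`` ('-' = none)."""
    preds: dict[str, str | None] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "read_id":
                continue
            if len(parts) < 3:
                raise InputError(f"malformed prediction line in {path}: {line!r}")
            label = parts[2]
            preds[parts[0]] = None if label in ("-", "") else label
    return preds


def read_parent_map_tsv(path: str | Path) -> dict[str, str]:
    """Read a label -> parent TSV (two columns, '#' lines ignored)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputError(f"malformed parent-map line in {path}: {line!r}")
            out[parts[0]] = parts[1]
    return out
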
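"""Delimited-text I/O for labeled feature tables and synthesis sidecars.

Table dialect: d feature columns followed by a label column in {1, -1},
TSV by default; a header row is auto-detected on read.  Provenance columns
(``protein_id``, ``residue_index``) written by the feature pipeline are
recognized and stripped before learning.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from sosbind.errors import ValidationError
from sosbind.sampling import LabeledDataset, SyntheticBatch

PROVENANCE_COLUMNS = ("protein_id", "residue_index")


def _has_header(path: Path, sep: str) -> bool:
    with open(path) as fh:
        first = fh.readline()
    for token in first.rstrip("\n").split(sep):
        try:
            float(token)
        except ValueError:
            return True
    return False


def read_labeled_table(
    path, sep: str = "\t"
) -> tuple[LabeledDataset, Optional[np.ndarray]]:
    """Read a labeled feature table; returns (dataset, group_ids or None).

    The last column is the label; provenance columns, when present, supply
    the group ids and are excluded from the features.
    """
    path = Path(path)
    header = 0 if _has_header(path, sep) else None
    df = pd.read_csv(path, sep=sep, header=header)
    if df.shape[1] < 2:
        raise ValidationError("table needs at least one feature column and a label")
    groups = None
    if header is not None and PROVENANCE_COLUMNS[0] in df.columns:
        groups = df[PROVENANCE_COLUMNS[0]].to_numpy()
        df = df.drop(columns=[c for c in PROVENANCE_COLUMNS if c in df.columns])
    labels = df.iloc[:, -1].to_numpy()
    features = df.iloc[:, :-1].to_numpy(dtype=float)
    return LabeledDataset(features=features, labels=labels), groups


def write_labeled_table(dataset: LabeledDataset, path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        dataset.features, columns=[f"f{j + 1}" for j in range(dataset.d)]
    )
    df["label"] = dataset.labels
    df.to_csv(path, sep=sep, index=False)


def write_batch_sidecar(batch: SyntheticBatch, path, sep: str = "\t") -> None:
    """Export a synthesis batch: parent_a, parent_b, lambda, confidence, f1..fd."""
    d = batch.vectors.shape[1]
    df = pd.DataFrame(
        {
            "parent_a": batch.parent_indices[:, 0],
            "parent_b": batch.parent_indices[:, 1],
            "lambda": batch.lambdas,
            "confidence": (
                batch.confidences if batch.confidences is not None
                else [""] * len(batch)
            ),
        }
    )
    for j in range(d):
        df[f"f{j + 1}"] = batch.vectors[:, j]
    df.to_csv(path, sep=sep, index=False)


def read_batch_sidecar(path, sep: str = "\t") -> SyntheticBatch:
    df = pd.read_csv(path, sep=sep)
    feature_cols = [c for c in df.columns if c.startswith("f")]
    conf = df["confidence"].to_numpy()
    has_conf = not pd.isna(conf).all()
    return SyntheticBatch(
        vectors=df[feature_cols].to_numpy(dtype=float),
        parent_indices=df[["parent_a", "parent_b"]].to_numpy(dtype=int),
        lambdas=df["lambda"].to_numpy(dtype=float),
        confidences=df["confidence"].to_numpy(dtype=float) if has_conf else None,
    )
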
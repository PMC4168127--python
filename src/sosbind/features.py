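"""Per-residue feature vectors from sequence profiles.

Builds the combined feature representation used for binding-residue
prediction: each residue is described by a sliding window (default width 17)
over (a) the logistic-normalized position-specific scoring matrix (20 columns
per position) and (b) predicted secondary-structure probabilities (3 columns
per position), concatenated into a 17*20 + 17*3 = 391-dimensional vector.

Window positions beyond the sequence termini contribute all-zero rows; zero
lies outside the open range (0, 1) of the logistic-normalized scores, so
padding is distinguishable from real signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from sosbind.errors import ValidationError

AMINO_ACIDS = "ARNDCQEGHILKVMFPSTWY"  # column order also written by fixtures
VALID_RESIDUES = set(AMINO_ACIDS) | {"X"}
SS_STATES = ("C", "H", "E")
DEFAULT_WINDOW = 17


@dataclass
class ProteinProfile:
    """A protein sequence with its L x 20 PSSM, L x 3 secondary-structure
    probabilities, and per-residue binding labels."""

    id: str
    sequence: str
    pssm: np.ndarray
    ss_probs: np.ndarray
    binding_mask: np.ndarray

    def __post_init__(self) -> None:
        self.pssm = np.asarray(self.pssm, dtype=float)
        self.ss_probs = np.asarray(self.ss_probs, dtype=float)
        self.binding_mask = np.asarray(self.binding_mask, dtype=bool)
        L = len(self.sequence)
        if L == 0:
            raise ValidationError("empty sequence")
        if self.pssm.shape != (L, 20):
            raise ValidationError(f"pssm shape {self.pssm.shape} != ({L}, 20)")
        if self.ss_probs.shape != (L, 3):
            raise ValidationError(f"ss_probs shape {self.ss_probs.shape} != ({L}, 3)")
        if self.binding_mask.shape != (L,):
            raise ValidationError("binding_mask length mismatch")
        bad = set(self.sequence.upper()) - VALID_RESIDUES
        if bad:
            raise ValidationError(f"invalid residue letters: {sorted(bad)}")
        sums = self.ss_probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 0.02):
            raise ValidationError("ss_probs rows must sum to 1 within 0.02")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ResidueFeatureSet:
    """L x (w*23) feature matrix with labels and 1-based residue indices."""

    protein_id: str
    vectors: np.ndarray
    labels: np.ndarray
    residue_indices: np.ndarray


def logistic_normalize(m: np.ndarray) -> np.ndarray:
    """Elementwise logistic 1/(1+exp(-x)); overflow-safe, output in (0, 1)."""
    m = np.asarray(m, dtype=float)
    out = np.empty_like(m)
    pos = m >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-m[pos]))
    exp_x = np.exp(m[~pos])
    out[~pos] = exp_x / (1.0 + exp_x)
    return out


def parse_pssm(text: str, sequence: Optional[str] = None) -> np.ndarray:
    """Parse a PSI-BLAST ASCII PSSM ("-Q" style output).

    Returns the first 20 numeric columns (log-odds) in file order.  When a
    sequence is given, residue letters are cross-checked against it.
    """
    rows = []
    letters = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        parts = line.split()
        # residue rows start with a 1-based index followed by a letter
        if len(parts) < 2 or not parts[0].isdigit() or len(parts[1]) != 1:
            continue
        if not parts[1].isalpha():
            continue
        values = parts[2:22]
        if len(values) < 20:
            raise ValidationError(
                f"line {lineno}: expected 20 log-odds columns, found {len(values)}"
            )
        try:
            rows.append([float(v) for v in values])
        except ValueError as exc:
            raise ValidationError(f"line {lineno}: non-numeric cell ({exc})") from exc
        letters.append(parts[1].upper())
    if not rows:
        raise ValidationError("no residue rows found in PSSM")
    matrix = np.array(rows, dtype=float)
    if sequence is not None:
        if len(sequence) != matrix.shape[0]:
            raise ValidationError(
                f"PSSM has {matrix.shape[0]} rows but sequence has {len(sequence)}"
            )
        for i, (a, b) in enumerate(zip(letters, sequence.upper()), start=1):
            if a != b and "X" not in (a, b):
                raise ValidationError(
                    f"residue mismatch at position {i}: PSSM {a!r} vs sequence {b!r}"
                )
    return matrix


def parse_ss2(text: str) -> np.ndarray:
    """Parse a PSIPRED VFORMAT .ss2 file into an L x 3 (C, H, E) matrix."""
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != 6:
            raise ValidationError(
                f"line {lineno}: expected 6 fields (idx aa state pC pH pE), "
                f"found {len(parts)}"
            )
        try:
            rows.append([float(parts[3]), float(parts[4]), float(parts[5])])
        except ValueError as exc:
            raise ValidationError(f"line {lineno}: non-numeric probability") from exc
    if not rows:
        raise ValidationError("no residue rows found in .ss2 file")
    return np.array(rows, dtype=float)


def parse_fasta(text: str) -> tuple[str, str]:
    """Return (id, sequence) of the first record in a FASTA string."""
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise ValidationError("not a FASTA record")
    seq_id = lines[0][1:].split()[0]
    seq = "".join(ln for ln in lines[1:] if not ln.startswith(">"))
    if not seq:
        raise ValidationError("FASTA record has no sequence")
    return seq_id, seq.upper()


def parse_annotations(text: str) -> dict[str, list[int]]:
    """Parse a binding-annotation TSV: ``protein_id <tab> i1,i2,...`` (1-based).

    A missing/empty second column means no binding residues.
    """
    out: dict[str, list[int]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        pid = parts[0].strip()
        if not pid:
            raise ValidationError(f"line {lineno}: empty protein id")
        spec = parts[1].strip() if len(parts) > 1 else ""
        try:
            idx = [int(tok) for tok in spec.split(",") if tok.strip()] if spec else []
        except ValueError as exc:
            raise ValidationError(f"line {lineno}: bad index list {spec!r}") from exc
        if any(i < 1 for i in idx):
            raise ValidationError(f"line {lineno}: indices must be 1-based positive")
        out[pid] = idx
    return out


def window_features(m: np.ndarray, i: int, w: int = DEFAULT_WINDOW) -> np.ndarray:
    """Flatten the w rows of ``m`` centered on 1-based row ``i``.

    Rows outside [1, L] contribute zeros (terminal padding).
    """
    m = np.asarray(m, dtype=float)
    if w % 2 == 0:
        raise ValidationError(f"window size must be odd, got {w}")
    L, c = m.shape
    if not (1 <= i <= L):
        raise ValidationError(f"index {i} out of range 1..{L}")
    half = (w - 1) // 2
    out = np.zeros((w, c))
    for offset in range(-half, half + 1):
        pos = i - 1 + offset
        if 0 <= pos < L:
            out[offset + half] = m[pos]
    return out.ravel()


def build_feature_vectors(
    profile: ProteinProfile, w: int = DEFAULT_WINDOW
) -> ResidueFeatureSet:
    """Per-residue concatenation of windowed normalized-PSSM and windowed
    secondary-structure features; labels +1 at binding residues, else -1."""
    norm = logistic_normalize(profile.pssm)
    L = profile.length
    vectors = np.empty((L, w * 20 + w * 3))
    for i in range(1, L + 1):
        vectors[i - 1] = np.concatenate(
            [window_features(norm, i, w), window_features(profile.ss_probs, i, w)]
        )
    labels = np.where(profile.binding_mask, 1, -1)
    return ResidueFeatureSet(
        protein_id=profile.id,
        vectors=vectors,
        labels=labels,
        residue_indices=np.arange(1, L + 1),
    )


def load_profile(
    fasta_path, pssm_path, ss2_path, annotations: dict[str, list[int]]
) -> ProteinProfile:
    """Assemble a ProteinProfile from on-disk inputs."""
    seq_id, seq = parse_fasta(Path(fasta_path).read_text())
    pssm = parse_pssm(Path(pssm_path).read_text(), sequence=seq)
    ss_probs = parse_ss2(Path(ss2_path).read_text())
    if ss_probs.shape[0] != len(seq):
        raise ValidationError(
            f".ss2 has {ss_probs.shape[0]} rows but sequence has {len(seq)}"
        )
    mask = np.zeros(len(seq), dtype=bool)
    for idx in annotations.get(seq_id, []):
        if idx > len(seq):
            raise ValidationError(f"binding index {idx} beyond sequence length {len(seq)}")
        mask[idx - 1] = True
    return ProteinProfile(id=seq_id, sequence=seq, pssm=pssm, ss_probs=ss_probs,
                          binding_mask=mask)


def feature_table(feature_sets: list[ResidueFeatureSet]) -> pd.DataFrame:
    """Concatenate per-protein feature sets into a labeled table with
    provenance columns (protein_id, residue_index) first and the label last."""
    frames = []
    for fs in feature_sets:
        df = pd.DataFrame(fs.vectors, columns=[f"f{j + 1}" for j in range(fs.vectors.shape[1])])
        df.insert(0, "protein_id", fs.protein_id)
        df.insert(1, "residue_index", fs.residue_indices)
        df["label"] = fs.labels
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
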
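"""Synthetic data generators: imbalanced two-class feature tables and toy
protein profiles with a planted, learnable binding signal, plus on-disk
fixture writers whose outputs round-trip through the parsers in
``sosbind.features``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from sosbind.errors import ValidationError
from sosbind.features import AMINO_ACIDS, ProteinProfile
from sosbind.sampling import LabeledDataset


@dataclass
class ImbalanceSpec:
    """Two Gaussian class-conditionals with unit within-class covariance and
    mean distance ``separation`` (in within-class SD units)."""

    n_min: int
    n_maj: int
    d: int = 5
    separation: float = 2.0
    squash: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_min < 1 or self.n_maj < 1:
            raise ValidationError("class sizes must be positive")
        if self.n_maj < self.n_min:
            raise ValidationError("n_maj must be >= n_min (imbalanced regime)")
        if self.d < 1:
            raise ValidationError("d must be positive")
        if self.separation < 0:
            raise ValidationError("separation must be >= 0")


def gen_imbalanced(spec: ImbalanceSpec) -> LabeledDataset:
    """Sample an imbalanced dataset: minority rows first, then majority.

    Minority ~ N(mu1, I), majority ~ N(0, I) with ||mu1|| = separation spread
    evenly over the dimensions.  ``squash=True`` applies the logistic map to
    mimic normalized-profile feature ranges.
    """
    rng = np.random.default_rng(spec.seed)
    mu1 = np.full(spec.d, spec.separation / np.sqrt(spec.d))
    minority = rng.standard_normal((spec.n_min, spec.d)) + mu1
    majority = rng.standard_normal((spec.n_maj, spec.d))
    features = np.vstack([minority, majority])
    if spec.squash:
        features = 1.0 / (1.0 + np.exp(-features))
    labels = np.concatenate([np.ones(spec.n_min, dtype=int),
                             -np.ones(spec.n_maj, dtype=int)])
    return LabeledDataset(features=features, labels=labels)


def gen_toy_profile(
    L: int,
    binding_idx: list[int],
    shift: float = 3.0,
    seed: int = 0,
    signal_radius: int = 2,
) -> ProteinProfile:
    """A toy protein profile with a mean-shift signal around binding residues.

    PSSM rows are integer-rounded N(0, 2^2) scores (matching the ASCII PSSM
    dialect); rows within ``signal_radius`` of a binding residue get +shift
    before rounding.  Secondary-structure rows are Dirichlet(1,1,1) draws.
    """
    if L < 1:
        raise ValidationError("L must be positive")
    binding_idx = sorted(set(binding_idx))
    if binding_idx and (binding_idx[0] < 1 or binding_idx[-1] > L):
        raise ValidationError(f"binding indices must lie in 1..{L}")
    rng = np.random.default_rng(seed)
    pssm = 2.0 * rng.standard_normal((L, 20))
    mask = np.zeros(L, dtype=bool)
    for idx in binding_idx:
        mask[idx - 1] = True
        lo = max(0, idx - 1 - signal_radius)
        hi = min(L, idx + signal_radius)
        pssm[lo:hi] += shift
    pssm = np.round(pssm)
    ss_probs = rng.dirichlet(np.ones(3), size=L)
    seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=L))
    return ProteinProfile(
        id=f"toy{seed:04d}", sequence=seq, pssm=pssm, ss_probs=ss_probs,
        binding_mask=mask,
    )


# ---------------------------------------------------------------------------
# fixture writers (plain-text dialects readable by sosbind.features parsers)
# ---------------------------------------------------------------------------


def _format_pssm(profile: ProteinProfile) -> str:
    header = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "   ".join(AMINO_ACIDS) + "   " + "   ".join(AMINO_ACIDS),
    ]
    lines = header
    for i, (aa, row) in enumerate(zip(profile.sequence, profile.pssm), start=1):
        scores = " ".join(f"{int(round(v)):4d}" for v in row)
        percents = " ".join("   0" for _ in range(20))
        lines.append(f"{i:5d} {aa} {scores} {percents}  0.00 0.00")
    lines.append("")
    return "\n".join(lines)


def _format_ss2(profile: ProteinProfile) -> str:
    lines = ["# PSIPRED VFORMAT (toy fixture)", ""]
    states = "CHE"
    for i, (aa, row) in enumerate(zip(profile.sequence, profile.ss_probs), start=1):
        state = states[int(np.argmax(row))]
        lines.append(
            f"{i:4d} {aa} {state}  {row[0]:6.3f} {row[1]:6.3f} {row[2]:6.3f}"
        )
    lines.append("")
    return "\n".join(lines)


def write_fixtures(profile: ProteinProfile, out_dir) -> dict[str, Path]:
    """Write FASTA / PSSM / .ss2 / annotation TSV for one profile.

    Returns the paths keyed by kind.  PSSM values are written as integers and
    .ss2 probabilities with 3 decimals, matching the native dialects.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pid = profile.id
    paths = {
        "fasta": out_dir / f"{pid}.fasta",
        "pssm": out_dir / f"{pid}.pssm",
        "ss2": out_dir / f"{pid}.ss2",
        "annotations": out_dir / f"{pid}.bind.tsv",
    }
    seq_lines = [profile.sequence[i : i + 60] for i in range(0, profile.length, 60)]
    paths["fasta"].write_text(f">{pid}\n" + "\n".join(seq_lines) + "\n")
    paths["pssm"].write_text(_format_pssm(profile))
    paths["ss2"].write_text(_format_ss2(profile))
    binding = ",".join(str(i + 1) for i in np.flatnonzero(profile.binding_mask))
    paths["annotations"].write_text(f"{pid}\t{binding}\n")
    return paths


def write_manifest(out_dir, seed: int, entries: dict) -> Path:
    """Seed-stamped manifest of generated outputs."""
    path = Path(out_dir) / "manifest.json"
    payload = {"seed": seed, "entries": {k: str(v) for k, v in entries.items()}}
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path
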
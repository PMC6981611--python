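"""Synthetic test data: composition-driven peptides and planted feature matrices.

Two generators cover everything the rest of the package needs for testing
without external downloads:

* :func:`generate_peptides` draws peptides with i.i.d. residues from a
  class-specific composition model.  The default models are the published
  residue frequencies of quorum-sensing peptides (QSPs) and non-QSPs, so a
  synthetic two-class set reproduces the compositional contrast between the
  classes (e.g. phenylalanine enriched in QSPs, lysine depleted) while having
  no positional structure.
* :func:`generate_planted` draws two-class Gaussian feature matrices in which
  a known subset of features carries a class-mean shift of ``delta`` standard
  deviations; ground truth is returned so feature-selection recovery can be
  scored exactly.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .aaindex_io import STANDARD_AMINO_ACIDS
from .featurize import FeatureMatrix, LabeledPeptideSet, Peptide

__all__ = [
    "QSP_COMPOSITION",
    "NON_QSP_COMPOSITION",
    "CompositionModel",
    "PlantedDataSpec",
    "generate_peptides",
    "generate_two_class_set",
    "generate_planted",
]

# Published per-residue composition (fractions) of the two peptide classes.
# These are the generator's default study conditions.
QSP_COMPOSITION: Mapping[str, float] = {
    "F": 0.109, "K": 0.047, "L": 0.076, "V": 0.043, "W": 0.034,
    "I": 0.063, "A": 0.053, "Y": 0.042, "R": 0.039, "C": 0.049,
    "S": 0.079, "G": 0.078, "P": 0.041, "N": 0.070, "T": 0.051,
    "D": 0.033, "E": 0.026, "M": 0.028, "H": 0.010, "Q": 0.029,
}

NON_QSP_COMPOSITION: Mapping[str, float] = {
    "F": 0.049, "K": 0.093, "L": 0.106, "V": 0.054, "W": 0.015,
    "I": 0.067, "A": 0.084, "Y": 0.020, "R": 0.050, "C": 0.061,
    "S": 0.062, "G": 0.094, "P": 0.043, "N": 0.043, "T": 0.041,
    "D": 0.029, "E": 0.030, "M": 0.016, "H": 0.017, "Q": 0.026,
}


@dataclass(frozen=True)
class CompositionModel:
    """Residue-frequency model for one peptide class.

    Residues are i.i.d. within a sequence and lengths are uniform on
    ``[length_min, length_max]``.  The default length range 5-30 reflects the
    short signaling peptides this package models.
    """

    probabilities: Mapping[str, float]
    length_min: int = 5
    length_max: int = 30

    def __post_init__(self) -> None:
        probs = dict(self.probabilities)
        if set(probs) != set(STANDARD_AMINO_ACIDS):
            raise ValueError("probabilities must cover exactly the 20 residues")
        p = np.array([probs[aa] for aa in STANDARD_AMINO_ACIDS], dtype=float)
        if (p < 0).any():
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1 (got {p.sum():.12f})")
        if not (1 <= self.length_min <= self.length_max):
            raise ValueError("need 1 <= length_min <= length_max")
        object.__setattr__(self, "probabilities", probs)

    def probability_vector(self) -> np.ndarray:
        """Probabilities in alphabetical residue order (A..Y)."""
        return np.array(
            [self.probabilities[aa] for aa in STANDARD_AMINO_ACIDS], dtype=float
        )


def qsp_model(length_min: int = 5, length_max: int = 30) -> CompositionModel:
    return CompositionModel(QSP_COMPOSITION, length_min, length_max)


def non_qsp_model(length_min: int = 5, length_max: int = 30) -> CompositionModel:
    return CompositionModel(NON_QSP_COMPOSITION, length_min, length_max)


def generate_peptides(
    model: CompositionModel,
    n: int,
    seed: int,
    label: int = 1,
    id_prefix: str = "pep",
) -> LabeledPeptideSet:
    """Draw *n* peptides of one class from a composition model.

    Reproducible: identical (model, n, seed) give identical sets.
    """
    rng = np.random.default_rng(seed)
    p = model.probability_vector()
    alphabet = np.frombuffer(STANDARD_AMINO_ACIDS.encode(), dtype="S1")
    peptides = []
    for i in range(n):
        length = int(rng.integers(model.length_min, model.length_max + 1))
        seq = b"".join(rng.choice(alphabet, size=length, p=p)).decode()
        peptides.append(Peptide(f"{id_prefix}{i + 1}", seq))
    return LabeledPeptideSet(tuple(peptides), tuple([label] * n))


def generate_two_class_set(
    n_pos: int,
    n_neg: int,
    seed: int,
    pos_model: CompositionModel | None = None,
    neg_model: CompositionModel | None = None,
) -> LabeledPeptideSet:
    """Two-class peptide pool: positives then negatives, distinct sub-seeds."""
    pos_model = pos_model or qsp_model()
    neg_model = neg_model or non_qsp_model()
    pos = generate_peptides(pos_model, n_pos, seed=seed * 2 + 1, label=1,
                            id_prefix="qsp")
    neg = generate_peptides(neg_model, n_neg, seed=seed * 2 + 2, label=-1,
                            id_prefix="non")
    return LabeledPeptideSet.concatenate(pos, neg)


@dataclass(frozen=True)
class PlantedDataSpec:
    """Two-class Gaussian matrix with planted informative features.

    Noise features are standard normal in both classes; informative feature j
    has class means +delta/2 (positives) and -delta/2 (negatives), unit sd, so
    ``delta`` is the class-mean separation in sd units.  Each redundancy copy
    duplicates an informative feature plus N(0, 0.1) jitter.
    """

    n_per_class: int
    n_features: int
    informative: tuple[int, ...]
    delta: float = 2.0
    redundancy: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "informative", tuple(self.informative))
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not all(0 <= j < self.n_features for j in self.informative):
            raise ValueError("informative indices out of range")
        if self.redundancy and self.redundancy * len(self.informative) > (
            self.n_features - len(self.informative)
        ):
            raise ValueError("not enough columns for the requested redundancy")


def generate_planted(
    spec: PlantedDataSpec,
) -> tuple[FeatureMatrix, np.ndarray, np.ndarray]:
    """Return (raw FeatureMatrix, labels in {-1,+1}, true informative mask)."""
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_per_class
    y = np.concatenate(
        [np.ones(spec.n_per_class, dtype=int), -np.ones(spec.n_per_class, dtype=int)]
    )
    X = rng.standard_normal((n, spec.n_features))
    mask = np.zeros(spec.n_features, dtype=bool)
    for j in spec.informative:
        X[:, j] += y * (spec.delta / 2.0)
        mask[j] = True
    if spec.redundancy:
        free = [j for j in range(spec.n_features) if not mask[j]]
        k = 0
        for j in spec.informative:
            for _ in range(spec.redundancy):
                tgt = free[k]
                X[:, tgt] = X[:, j] + 0.1 * rng.standard_normal(n)
                mask[tgt] = True
                k += 1
    names = tuple(f"SYNF{j + 1:06d}" for j in range(spec.n_features))
    ids = tuple(f"s{i + 1}" for i in range(n))
    return FeatureMatrix(names, X, ids), y, mask
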
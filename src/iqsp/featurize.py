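"""Peptides, labeled peptide sets, and physicochemical-property featurization.

A peptide of length ``L`` is encoded into one value per property scale: the
arithmetic mean of the scale's residue values over the sequence.  The encoding
is therefore length-independent (peptides of different lengths live in the
same feature space) and permutation-invariant within a sequence.  Feature
columns are z-score standardized with parameters fitted on the training split
only; independent/test data are transformed with the training parameters and
never refitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .aaindex_io import STANDARD_AMINO_ACIDS, PropertyCollection

__all__ = [
    "Peptide",
    "LabeledPeptideSet",
    "FeatureMatrix",
    "Scaler",
    "InvalidResidueError",
    "ZeroVarianceError",
    "FeatureMismatchError",
    "encode_peptide",
    "encode_peptides",
    "fit_standardizer",
    "apply_standardizer",
    "standardize",
    "compute_aac",
    "aac_matrix",
    "read_fasta",
    "write_fasta",
    "read_labeled_tsv",
    "write_labeled_tsv",
]

_RESIDUE_INDEX = {aa: i for i, aa in enumerate(STANDARD_AMINO_ACIDS)}

QSP_LABEL = 1
NON_QSP_LABEL = -1


class InvalidResidueError(ValueError):
    """Sequence contains a character outside the 20-residue alphabet.

    Ambiguity codes (B, Z, X, U, ...) are rejected rather than imputed: no
    property values exist for them and silent imputation would shift features.
    """

    def __init__(self, identifier: str, residue: str, position: int):
        super().__init__(
            f"{identifier}: invalid residue {residue!r} at position {position} "
            f"(1-based); allowed: {STANDARD_AMINO_ACIDS}"
        )
        self.identifier = identifier
        self.residue = residue
        self.position = position


class ZeroVarianceError(ValueError):
    """A feature column is constant, so it cannot be standardized."""


class FeatureMismatchError(ValueError):
    """Feature names of a matrix and a scaler/model do not agree."""


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence over the 20 standard amino acids."""

    identifier: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.identifier}: empty sequence")
        for pos, res in enumerate(self.sequence, start=1):
            if res not in _RESIDUE_INDEX:
                raise InvalidResidueError(self.identifier, res, pos)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LabeledPeptideSet:
    """Peptides with parallel class labels (+1 positive/QSP, -1 negative)."""

    peptides: tuple[Peptide, ...]
    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "peptides", tuple(self.peptides))
        object.__setattr__(self, "labels", tuple(int(y) for y in self.labels))
        if len(self.peptides) != len(self.labels):
            raise ValueError("peptides and labels must have equal length")
        if any(y not in (QSP_LABEL, NON_QSP_LABEL) for y in self.labels):
            raise ValueError("labels must be +1 or -1")

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[tuple[Peptide, int]]:
        return iter(zip(self.peptides, self.labels))

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=int)

    def subset(self, indices: Sequence[int]) -> "LabeledPeptideSet":
        return LabeledPeptideSet(
            tuple(self.peptides[i] for i in indices),
            tuple(self.labels[i] for i in indices),
        )

    @staticmethod
    def concatenate(*sets: "LabeledPeptideSet") -> "LabeledPeptideSet":
        peps: list[Peptide] = []
        labs: list[int] = []
        for s in sets:
            peps.extend(s.peptides)
            labs.extend(s.labels)
        return LabeledPeptideSet(tuple(peps), tuple(labs))


@dataclass(frozen=True)
class Scaler:
    """Per-feature (mean, sd) pairs fitted on a training matrix.

    The sd uses the n-1 (sample) convention.
    """

    feature_names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": list(self.feature_names),
                "mean": self.mean.tolist(),
                "sd": self.sd.tolist(),
            }
        )

    @staticmethod
    def from_json(text: str) -> "Scaler":
        d = json.loads(text)
        return Scaler(
            tuple(d["feature_names"]),
            np.asarray(d["mean"], dtype=float),
            np.asarray(d["sd"], dtype=float),
        )


@dataclass(frozen=True)
class FeatureMatrix:
    """An n_samples x n_features real matrix with named feature columns."""

    feature_names: tuple[str, ...]
    values: np.ndarray
    sample_ids: tuple[str, ...] = ()
    scaler: Scaler | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("values must be 2-D")
        object.__setattr__(self, "values", vals)
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if vals.shape[1] != len(self.feature_names):
            raise ValueError("column count must equal feature-name count")
        if self.sample_ids:
            object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
            if len(self.sample_ids) != vals.shape[0]:
                raise ValueError("sample_ids length must equal row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        """Column subset by feature name, preserving the given order."""
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(
            tuple(names), self.values[:, idx], self.sample_ids, scaler=None
        )

    def to_tsv(self) -> str:
        head = "sample\t" + "\t".join(self.feature_names)
        ids = self.sample_ids or tuple(str(i) for i in range(self.n_samples))
        rows = [
            sid + "\t" + "\t".join(f"{v:.10g}" for v in row)
            for sid, row in zip(ids, self.values)
        ]
        return head + "\n" + "\n".join(rows) + "\n"


def compute_aac(peptide: Peptide) -> np.ndarray:
    """Amino-acid composition: residue fractions in alphabetical residue order.

    Components are count(r)/L and sum to 1.
    """
    counts = np.zeros(20)
    for res in peptide.sequence:
        counts[_RESIDUE_INDEX[res]] += 1
    return counts / len(peptide)


def aac_matrix(peptides: Iterable[Peptide]) -> np.ndarray:
    return np.array([compute_aac(p) for p in peptides])


def _property_value_matrix(properties: PropertyCollection) -> np.ndarray:
    """20 x P lookup matrix, residues alphabetical, columns in collection order."""
    return np.array([t.value_array(STANDARD_AMINO_ACIDS) for t in properties]).T


def encode_peptide(peptide: Peptide, properties: PropertyCollection) -> np.ndarray:
    """Encode one peptide: per-property mean of residue values over the sequence.

    Output order follows the property-collection order.
    """
    return compute_aac(peptide) @ _property_value_matrix(properties)


def encode_peptides(
    peptides: Iterable[Peptide], properties: PropertyCollection
) -> FeatureMatrix:
    """Encode peptides into a raw (unstandardized) feature matrix."""
    peptides = list(peptides)
    lookup = _property_value_matrix(properties)
    values = aac_matrix(peptides) @ lookup
    return FeatureMatrix(
        tuple(properties.accessions),
        values,
        tuple(p.identifier for p in peptides),
    )


def fit_standardizer(matrix: FeatureMatrix) -> FeatureMatrix:
    """Fit per-column mean/sd (sample convention) and attach them as a scaler.

    Values are unchanged.  Raises :class:`ZeroVarianceError` naming the first
    constant feature.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples to fit a standardizer")
    mean = matrix.values.mean(axis=0)
    sd = matrix.values.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ZeroVarianceError(
            f"constant feature(s): {', '.join(matrix.feature_names[i] for i in bad)}"
        )
    scaler = Scaler(matrix.feature_names, mean, sd)
    return replace(matrix, scaler=scaler)


def apply_standardizer(matrix: FeatureMatrix, scaler: Scaler) -> FeatureMatrix:
    """Transform values to (x - mean)/sd using *training-set* parameters."""
    if tuple(matrix.feature_names) != tuple(scaler.feature_names):
        raise FeatureMismatchError(
            "feature names of matrix and scaler differ "
            f"({matrix.feature_names[:3]}... vs {scaler.feature_names[:3]}...)"
        )
    z = (matrix.values - scaler.mean) / scaler.sd
    return FeatureMatrix(matrix.feature_names, z, matrix.sample_ids, scaler)


def standardize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Fit on *matrix* and transform it (training-split convenience)."""
    fitted = fit_standardizer(matrix)
    assert fitted.scaler is not None
    return apply_standardizer(matrix, fitted.scaler)


def read_fasta(path) -> list[Peptide]:
    """Read peptides from a (multi-record) FASTA file.

    Invalid residues raise :class:`InvalidResidueError`; callers that must
    keep going on bad records (e.g. the CLI) catch it per record.
    """
    return [
        Peptide(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(peptides: Iterable[Peptide], path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.identifier, description="")
        for p in peptides
    ]
    SeqIO.write(records, str(path), "fasta")


def read_labeled_tsv(path) -> LabeledPeptideSet:
    """Read a labeled set from TSV.

    Two layouts are accepted: ``sequence<TAB>label`` or
    ``identifier<TAB>sequence<TAB>label``; label may be +1/-1 or the strings
    QSP / Non-QSP (case-insensitive).  A header row is detected and skipped.
    """
    peptides: list[Peptide] = []
    labels: list[int] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[-1].strip().lower() in ("label", "class"):
                continue
            if len(parts) == 2:
                ident, seq, lab = f"seq{len(peptides) + 1}", parts[0], parts[1]
            elif len(parts) == 3:
                ident, seq, lab = parts
            else:
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns")
            labels.append(_parse_label(lab, f"{path}:{lineno}"))
            peptides.append(Peptide(ident.strip(), seq.strip().upper()))
    return LabeledPeptideSet(tuple(peptides), tuple(labels))


def write_labeled_tsv(peptide_set: LabeledPeptideSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("identifier\tsequence\tlabel\n")
        for pep, lab in peptide_set:
            name = "QSP" if lab == QSP_LABEL else "Non-QSP"
            fh.write(f"{pep.identifier}\t{pep.sequence}\t{name}\n")


def _parse_label(text: str, where: str) -> int:
    t = text.strip().lower()
    if t in ("1", "+1", "qsp", "positive", "pos"):
        return QSP_LABEL
    if t in ("-1", "non-qsp", "nonqsp", "negative", "neg"):
        return NON_QSP_LABEL
    raise ValueError(f"{where}: unrecognized label {text!r}")
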
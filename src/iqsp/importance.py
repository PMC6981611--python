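"""Feature-importance and composition analysis.

Mean decrease of Gini index (MDGI) scores a feature by the total
Gini-impurity reduction attributable to it in a tree ensemble, averaged over
trees.  A single forest's ranking depends on its random draws, so importance
is averaged over an ensemble of forests built with varying ``mtry``
(features considered per split): by default 100 forests of 500 trees with
mtry = 1, 2, ..., 100 (values beyond the feature count are clamped to it, so
the 100-model average remains defined for small feature spaces).  Values are
reported in training-sample units, the scale used by R's randomForest
``MeanDecreaseGini``; only relative magnitudes and ranks are meaningful.

Composition comparison contrasts per-sequence amino-acid fractions between
two peptide classes with an unpaired two-sided location test per residue
(Welch's t by default, rank-sum optionally) and attaches difference ranks.
Terminal counts tabulate residue occurrences over the first/last ten
positions, the count matrices behind sequence-logo plots of terminal regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .aaindex_io import STANDARD_AMINO_ACIDS
from .featurize import FeatureMatrix, Peptide, aac_matrix

__all__ = [
    "ImportanceConfig",
    "ImportanceResult",
    "mdgi_importance",
    "composition_compare",
    "terminal_counts",
]


@dataclass(frozen=True)
class ImportanceConfig:
    """Settings for the multi-forest MDGI average."""

    n_models: int = 100
    ntree: int = 500
    seed: int = 0

    def mtry_values(self, n_features: int) -> list[int]:
        """mtry grid 1..n_models with values clamped to the feature count."""
        return [min(m, n_features) for m in range(1, self.n_models + 1)]


@dataclass(frozen=True)
class ImportanceResult:
    """Per-feature mean MDGI and 1-based rank (descending importance)."""

    feature_names: tuple[str, ...]
    mdgi: np.ndarray
    rank: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.feature_names, "MDGI": self.mdgi, "rank": self.rank}
        ).sort_values("rank", ignore_index=True)


def _forest_gini_decrease(forest: RandomForestClassifier, n_samples: int) -> np.ndarray:
    """Per-feature impurity decrease averaged over trees, in sample units."""
    total = np.zeros(forest.n_features_in_)
    for tree in forest.estimators_:
        total += tree.tree_.compute_feature_importances(normalize=False)
    return total / len(forest.estimators_) * n_samples


def mdgi_importance(
    matrix: FeatureMatrix, y: Sequence[int], config: ImportanceConfig | None = None
) -> ImportanceResult:
    """MDGI averaged across forests with mtry varied over the config grid."""
    config = config or ImportanceConfig()
    yv = np.asarray(y, dtype=int)
    if len(np.unique(yv)) < 2:
        raise ValueError("importance needs both classes present")
    n, p = matrix.values.shape
    acc = np.zeros(p)
    for i, mtry in enumerate(config.mtry_values(p)):
        forest = RandomForestClassifier(
            n_estimators=config.ntree,
            max_features=mtry,
            random_state=config.seed + i,
            n_jobs=1,
        )
        forest.fit(matrix.values, yv)
        acc += _forest_gini_decrease(forest, n)
    mdgi = acc / config.n_models
    order = np.argsort(-mdgi, kind="stable")
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)
    return ImportanceResult(tuple(matrix.feature_names), mdgi, rank)


def composition_compare(
    positives: Iterable[Peptide],
    negatives: Iterable[Peptide],
    test: str = "welch",
    mdgi: ImportanceResult | None = None,
) -> pd.DataFrame:
    """Per-residue composition contrast between two peptide classes.

    Returns a frame indexed by residue with columns ``pos_mean``,
    ``neg_mean``, ``difference`` (pos - neg; sums to 0), ``p_value``
    (two-sided, per-sequence fractions as the test samples) and
    ``diff_rank`` (1 = most positive difference).  When an
    :class:`ImportanceResult` over the 20 composition features is supplied,
    ``MDGI`` and ``mdgi_rank`` columns are attached.
    """
    pos = aac_matrix(list(positives))
    neg = aac_matrix(list(negatives))
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    pos_mean = pos.mean(axis=0)
    neg_mean = neg.mean(axis=0)
    diff = pos_mean - neg_mean
    pvals = np.ones(20)
    for j in range(20):
        a, b = pos[:, j], neg[:, j]
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        if se == 0:
            pvals[j] = 1.0 if diff[j] == 0 else 0.0
            continue
        if test == "welch":
            pvals[j] = stats.ttest_ind(a, b, equal_var=False).pvalue
        elif test == "ranksum":
            pvals[j] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        else:
            raise ValueError(f"unknown test {test!r}")
    order = np.argsort(-diff, kind="stable")
    diff_rank = np.empty(20, dtype=int)
    diff_rank[order] = np.arange(1, 21)
    frame = pd.DataFrame(
        {
            "pos_mean": pos_mean,
            "neg_mean": neg_mean,
            "difference": diff,
            "p_value": pvals,
            "diff_rank": diff_rank,
        },
        index=list(STANDARD_AMINO_ACIDS),
    )
    if mdgi is not None:
        lookup = dict(zip(mdgi.feature_names, zip(mdgi.mdgi, mdgi.rank)))
        frame["MDGI"] = [lookup[aa][0] for aa in frame.index]
        frame["mdgi_rank"] = [int(lookup[aa][1]) for aa in frame.index]
    return frame


def terminal_counts(
    peptides: Iterable[Peptide], end: str = "N", n_positions: int = 10
) -> pd.DataFrame:
    """Position x residue count matrix for a terminal region.

    ``end="N"`` counts positions 1..n from the N-terminus; ``end="C"`` indexes
    from the C-terminus inward (position 1 = last residue).  Peptides shorter
    than ``n_positions`` contribute only their existing positions, so the
    total count is sum(min(L_i, n_positions)).
    """
    if end not in ("N", "C"):
        raise ValueError("end must be 'N' or 'C'")
    counts = np.zeros((n_positions, 20), dtype=int)
    res_idx = {aa: j for j, aa in enumerate(STANDARD_AMINO_ACIDS)}
    for pep in peptides:
        seq = pep.sequence if end == "N" else pep.sequence[::-1]
        for i, res in enumerate(seq[:n_positions]):
            counts[i, res_idx[res]] += 1
    return pd.DataFrame(
        counts,
        index=pd.RangeIndex(1, n_positions + 1, name="position"),
        columns=list(STANDARD_AMINO_ACIDS),
    )
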
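"""Binarized-expression tissue signatures via one-vs-one linear SVMs.

Each sample's profile is reduced to a boolean expressed/not-expressed
vector (top half of the genes above an abundance floor).  Genes expressed
in essentially all samples of every tissue ("widely expressed") carry no
tissue information and are excluded, as are genes failing the
not-expressed-fraction filter.  A linear max-margin classifier is trained
for every tissue pair on the boolean features; a new sample is assigned by
voting, with vote share as the prediction probability and an "Other" class
for samples below the probability floor.  The per-gene variable importance
(VI) is the average of the squared hyperplane weights over all pairwise
models — the genes with the largest VI form the tissue-specific signature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "binarize",
    "flag_widely_expressed",
    "filter_uninformative",
    "BinaryTissueClassifier",
    "TissueSignatureResults",
    "predict_with_other",
]

OTHER = "Other"


def binarize(
    matrix: pd.DataFrame, min_abundance: float = 2.0, top_fraction: float = 0.5
) -> pd.DataFrame:
    """Boolean expressed/not-expressed matrix.

    Per sample, genes with abundance strictly above ``min_abundance`` are
    candidates and the k = round-half-up(top_fraction * n_candidates)
    most abundant candidates are marked expressed.  Ties at the cutoff are
    broken by abundance, then gene id, so the result is deterministic.
    """
    binary = pd.DataFrame(False, index=matrix.index, columns=matrix.columns)
    for sample in matrix.columns:
        col = matrix[sample]
        candidates = col[col > min_abundance]
        if candidates.empty:
            warnings.warn(f"sample {sample!r}: no genes above {min_abundance}; all not-expressed")
            continue
        k = math.floor(top_fraction * len(candidates) + 0.5)  # round half up
        order = candidates.reset_index()
        order.columns = ["gene_id", "value"]
        order = order.sort_values(["value", "gene_id"], ascending=[False, True])
        expressed = order["gene_id"].iloc[:k]
        binary.loc[expressed, sample] = True
    return binary


def _per_tissue_fraction(binary: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Fraction of samples in which each gene is expressed, per tissue."""
    fractions = {}
    for tissue, samples in labels.groupby(labels).groups.items():
        fractions[tissue] = binary[list(samples)].mean(axis=1)
    return pd.DataFrame(fractions)


def flag_widely_expressed(
    binary: pd.DataFrame, labels: pd.Series, fraction: float = 0.9
) -> set[str]:
    """Genes expressed in more than ``fraction`` of samples in every tissue."""
    frac = _per_tissue_fraction(binary, labels)
    return set(binary.index[(frac > fraction).all(axis=1)])


def filter_uninformative(
    binary: pd.DataFrame,
    labels: pd.Series,
    fraction: float = 0.5,
    mode: str = "all_tissues",
) -> set[str]:
    """Gene ids retained after removing uninformative genes.

    ``mode="all_tissues"`` (default) removes genes whose not-expressed
    fraction is below ``fraction`` within every tissue — genes expressed
    too consistently to separate tissues.  ``mode="overall"`` applies the
    same rule to the pooled cohort instead.
    """
    if mode == "all_tissues":
        not_expr = 1.0 - _per_tissue_fraction(binary, labels)
        removed = (not_expr < fraction).all(axis=1)
    elif mode == "overall":
        removed = (1.0 - binary.mean(axis=1)) < fraction
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return set(binary.index[~removed])


def predict_with_other(
    vote_share: pd.Series | dict[str, float], threshold: float = 0.5
) -> tuple[str, float]:
    """Most-voted tissue, or ``Other`` when its share is below threshold.

    A share exactly at the threshold keeps the tissue (the rejection rule
    is strictly "lower than").  Ties break alphabetically.
    """
    shares = pd.Series(vote_share).sort_index()
    best = shares.idxmax()
    prob = float(shares[best])
    return (best if prob >= threshold else OTHER), prob


class BinaryTissueClassifier:
    """One-vs-one linear SVM over boolean expression features.

    Parameters
    ----------
    binary : DataFrame (genes x samples, bool)
    labels : Series mapping sample -> tissue
    C : regularization strength of each pairwise SVM
    folds : cross-validation folds (stratified by tissue)
    other_threshold : minimum vote share to accept the top tissue
    """

    def __init__(
        self,
        binary: pd.DataFrame,
        labels: pd.Series,
        C: float = 1.0,
        folds: int = 10,
        other_threshold: float = 0.5,
    ):
        labels = labels.reindex(binary.columns)
        if labels.isna().any():
            raise ValueError("every sample column needs a tissue label")
        tissues = sorted(labels.unique())
        if len(tissues) < 2:
            raise ValueError("need at least 2 tissues")
        counts = labels.value_counts()
        small = counts[counts < folds]
        if not small.empty:
            raise ValueError(
                f"tissues with fewer samples than folds: {dict(small)}; use fewer folds"
            )
        self.binary = binary
        self.labels = labels
        self.tissues = tissues
        self.C = C
        self.folds = folds
        self.other_threshold = other_threshold

    # -- internals ---------------------------------------------------------

    def _fit_pairwise(self, X: np.ndarray, y: np.ndarray) -> dict[tuple[str, str], SVC]:
        models = {}
        for a, b in combinations(self.tissues, 2):
            mask = (y == a) | (y == b)
            clf = SVC(kernel="linear", C=self.C)
            clf.fit(X[mask], y[mask])
            models[(a, b)] = clf
        return models

    def _vote(self, models: dict[tuple[str, str], SVC], X: np.ndarray) -> pd.DataFrame:
        votes = pd.DataFrame(0.0, index=range(len(X)), columns=self.tissues)
        for (a, b), clf in models.items():
            pred = clf.predict(X)
            for tissue in (a, b):
                votes.loc[:, tissue] += pred == tissue
        return votes / (len(self.tissues) - 1)

    # -- fitting -----------------------------------------------------------

    def fit(self, seed: int = 0) -> "TissueSignatureResults":
        """Cross-validate, then train the final model on all samples."""
        X = self.binary.to_numpy(dtype=float).T  # samples x genes
        y = self.labels.to_numpy()
        samples = np.asarray(self.binary.columns)

        skf = StratifiedKFold(n_splits=self.folds, shuffle=True, random_state=seed)
        pred_rows = []
        fold_confusions = []
        columns = self.tissues + [OTHER]
        for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
            models = self._fit_pairwise(X[train_idx], y[train_idx])
            shares = self._vote(models, X[test_idx])
            confusion = pd.DataFrame(0.0, index=self.tissues, columns=columns)
            for row_pos, test_pos in enumerate(test_idx):
                call, prob = predict_with_other(
                    shares.iloc[row_pos], self.other_threshold
                )
                pred_rows.append(
                    {
                        "sample": samples[test_pos],
                        "tissue": y[test_pos],
                        "predicted": call,
                        "probability": prob,
                        "fold": fold,
                    }
                )
                confusion.loc[y[test_pos], call] += 1
            row_sums = confusion.sum(axis=1)
            fold_confusions.append(
                confusion.div(row_sums.where(row_sums > 0, 1), axis=0) * 100
            )
        predictions = pd.DataFrame(pred_rows).set_index("sample")
        confusion_pct = sum(fold_confusions) / len(fold_confusions)

        final_models = self._fit_pairwise(X, y)
        weights = np.stack([clf.coef_[0] for clf in final_models.values()])
        vi = (weights**2).mean(axis=0)
        signature = (
            pd.DataFrame({"gene_id": self.binary.index, "vi": vi})
            .sort_values(["vi", "gene_id"], ascending=[False, True])
            .reset_index(drop=True)
        )
        signature["rank"] = np.arange(1, len(signature) + 1)

        return TissueSignatureResults(
            model=self,
            pairwise_models=final_models,
            predictions=predictions,
            confusion_percent=confusion_pct,
            accuracy=float((predictions["predicted"] == predictions["tissue"]).mean()),
            signature=signature.set_index("gene_id"),
            seed=seed,
        )


@dataclass
class TissueSignatureResults:
    """Cross-validated predictions, confusion report and VI signature."""

    model: BinaryTissueClassifier
    pairwise_models: dict
    predictions: pd.DataFrame
    confusion_percent: pd.DataFrame  # rows true tissue, columns tissue + Other, row % averaged over folds
    accuracy: float
    signature: pd.DataFrame  # index gene_id; columns vi, rank
    seed: int

    def variable_importance(self) -> pd.DataFrame:
        return self.signature.copy()

    def top_genes(self, n: int) -> list[str]:
        return list(self.signature.index[:n])

    def predict(self, binary: pd.DataFrame) -> pd.DataFrame:
        """Classify new samples (genes x samples boolean, same gene order)."""
        X = binary.reindex(self.model.binary.index).fillna(False).to_numpy(dtype=float).T
        shares = self.model._vote(self.pairwise_models, X)
        rows = []
        for i, sample in enumerate(binary.columns):
            call, prob = predict_with_other(shares.iloc[i], self.model.other_threshold)
            rows.append({"sample": sample, "predicted": call, "probability": prob})
        return pd.DataFrame(rows).set_index("sample")

    def summary(self) -> str:
        lines = [
            "Binarized-expression tissue signature (one-vs-one linear SVM)",
            f"  tissues:           {len(self.model.tissues)}",
            f"  samples:           {self.model.binary.shape[1]}",
            f"  genes (features):  {self.model.binary.shape[0]}",
            f"  folds:             {self.model.folds}   seed: {self.seed}",
            f"  CV accuracy:       {self.accuracy:.3f}",
            "",
            "Confusion (row %, averaged over folds):",
            self.confusion_percent.to_string(float_format=lambda v: f"{v:5.1f}"),
            "",
            "Top variable-importance genes:",
            self.signature.head(10).to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)
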
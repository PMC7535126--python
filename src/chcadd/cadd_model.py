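"""Ridge-penalized logistic classifier and PHRED-scaled rank scores.

The classifier separates simulated (proxy-deleterious, label 1) from derived
(proxy-benign, label 0) variants.  Its posterior for the simulated class is
never reported directly: variants are ranked by posterior and the rank n is
mapped to a PHRED-like scale,

    score = -10 * log10(n / N),

where N is the size of the score universe (for a real genome, 3x the length
of the scored chromosomes — every possible alternative allele).  A score of
20 therefore means "among the top 1% of all possible variants"; 10 means
top 10%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .features import FeatureMatrix

LOG_LOSS_EPS = 1e-15
DEFAULT_PENALTIES = (0.1, 1.0, 10.0)


@dataclass
class ModelWeights:
    """Fitted coefficients plus the training metadata needed to reuse them."""

    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    penalty: float
    seed: int | None = None
    train_size: int = 0
    test_size: int = 0
    metrics: pd.DataFrame | None = None  # per-penalty ROC-AUC / log-loss

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.feature_names) != self.coefficients.size:
            raise ValueError("coefficient vector length != feature count")

    def posterior(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(float)
        z = X @ self.coefficients + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def save(self, path: str | Path) -> None:
        """Persist as a text coefficient table with a metadata header."""
        with open(path, "w") as fh:
            fh.write(f"#penalty={self.penalty}\n")
            fh.write(f"#intercept={self.intercept!r}\n")
            fh.write(f"#seed={self.seed}\n")
            fh.write(f"#train_size={self.train_size}\t#test_size={self.test_size}\n")
            fh.write("feature\tweight\n")
            for name, w in zip(self.feature_names, self.coefficients):
                fh.write(f"{name}\t{float(w)!r}\n")

    @classmethod
    def load(cls, path: str | Path) -> "ModelWeights":
        meta: dict[str, str] = {}
        names, weights = [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for piece in line.lstrip("#").split("\t#"):
                        k, _, v = piece.partition("=")
                        meta[k] = v
                elif line and line != "feature\tweight":
                    name, w = line.split("\t")
                    names.append(name)
                    weights.append(float(w))
        return cls(
            feature_names=names, coefficients=np.array(weights),
            intercept=float(meta["intercept"]), penalty=float(meta["penalty"]),
            seed=None if meta.get("seed") in (None, "None") else int(meta["seed"]),
            train_size=int(meta.get("train_size", 0)),
            test_size=int(meta.get("test_size", 0)),
        )


def split(matrix: FeatureMatrix, test_fraction: float = 1 / 11,
          seed: int = 0) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Label-stratified train/test partition (default 10:1)."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    if matrix.y is None:
        raise ValueError("split requires labels")
    idx = np.arange(len(matrix.X))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=matrix.y)
    return matrix.subset(np.sort(train_idx)), matrix.subset(np.sort(test_idx))


def log_loss(labels: np.ndarray, posteriors: np.ndarray,
             eps: float = LOG_LOSS_EPS) -> float:
    """Natural-log loss with probability clipping at ``eps``."""
    y = np.asarray(labels, dtype=float)
    p = np.clip(np.asarray(posteriors, dtype=float), eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def evaluate(posteriors: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """ROC-AUC (rank statistic, tie-corrected) and log-loss."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC-AUC undefined for single-class labels")
    return {
        "roc_auc": float(roc_auc_score(labels, posteriors)),
        "log_loss": log_loss(labels, posteriors),
    }


def train(
    matrix: FeatureMatrix,
    penalties: tuple[float, ...] = DEFAULT_PENALTIES,
    seed: int = 0,
    test_fraction: float = 1 / 11,
    max_iter: int = 2_000,
) -> ModelWeights:
    """Fit one ridge logistic model per penalty; keep the best by test
    log-loss (ROC-AUC as tiebreaker).

    The L2 penalty strength lambda maps to scikit-learn's C = 1/lambda.
    """
    if matrix.y is None:
        raise ValueError("training requires labels")
    if len(np.unique(matrix.y)) < 2:
        raise ValueError("both classes must be present")
    X = matrix.X.to_numpy(float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    train_m, test_m = split(matrix, test_fraction=test_fraction, seed=seed)
    Xtr, ytr = train_m.X.to_numpy(float), train_m.y
    Xte, yte = test_m.X.to_numpy(float), test_m.y

    rows = []
    fitted = {}
    for lam in penalties:
        clf = LogisticRegression(
            C=1.0 / lam, solver="lbfgs",
            max_iter=max_iter, random_state=seed,
        )
        clf.fit(Xtr, ytr)
        p = clf.predict_proba(Xte)[:, 1]
        m = evaluate(p, yte)
        rows.append({"penalty": lam, **m})
        fitted[lam] = clf
    metrics = pd.DataFrame(rows)
    best = metrics.sort_values(
        ["log_loss", "roc_auc"], ascending=[True, False]).iloc[0]
    clf = fitted[best["penalty"]]
    return ModelWeights(
        feature_names=list(matrix.X.columns),
        coefficients=clf.coef_.ravel(),
        intercept=float(clf.intercept_[0]),
        penalty=float(best["penalty"]),
        seed=seed, train_size=len(ytr), test_size=len(yte),
        metrics=metrics,
    )


def rank_scores(posteriors: np.ndarray) -> np.ndarray:
    """Rank posteriors descending; rank 1 is the highest posterior.

    Tied posteriors all receive the maximum (worst) rank of their tie group,
    so ties get the less-deleterious score.
    """
    p = np.asarray(posteriors, dtype=float)
    if p.size == 0:
        raise ValueError("empty posterior array")
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite posteriors")
    return rankdata(-p, method="max").astype(int)


def phred_scale(n, N) -> np.ndarray | float:
    """PHRED-scaled rank score: -10 * log10(n / N)."""
    n_arr = np.asarray(n, dtype=float)
    if np.asarray(N, dtype=float) <= 0:
        raise ValueError("N must be positive")
    if np.any(n_arr < 1) or np.any(n_arr > N):
        raise ValueError("ranks must satisfy 1 <= n <= N")
    out = -10.0 * np.log10(n_arr / N)
    return float(out) if np.isscalar(n) else out


def phred_to_rank_fraction(score: float) -> float:
    """Invert the PHRED transform: fraction of the score universe ranking at
    or above ``score`` (n/N = 10^(-score/10))."""
    if score < 0:
        raise ValueError("scores are non-negative")
    return float(10.0 ** (-score / 10.0))


@dataclass
class ScoreTable:
    """Per-variant posterior, rank, and PHRED-scaled score over a universe of
    N possible alternative alleles."""

    table: pd.DataFrame  # chrom, pos, ref, alt, posterior, rank, phred
    N: int

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#" + "\t".join(self.table.columns) + f"\t(N={self.N})\n")
            self.table.to_csv(fh, sep="\t", header=False, index=False)


def score_variants(
    weights: ModelWeights,
    matrix: FeatureMatrix,
    identities: pd.DataFrame | None = None,
    N: int | None = None,
) -> ScoreTable:
    """Posterior -> rank -> PHRED score for a set of encoded variants.

    ``N`` defaults to the number of scored variants (ranking within the
    given universe); pass 3x the assembly length to score against all
    possible alternative alleles.
    """
    p = weights.posterior(matrix.X)
    n_var = p.size
    universe = int(N) if N is not None else n_var
    if universe < n_var:
        raise ValueError("N smaller than the number of scored variants")
    ranks = rank_scores(p)
    phred = phred_scale(ranks, universe)
    cols = {}
    if identities is not None:
        for c in identities.columns:
            cols[c] = identities[c].to_numpy()
    cols.update({"posterior": p, "rank": ranks, "phred": phred})
    return ScoreTable(pd.DataFrame(cols), N=universe)
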
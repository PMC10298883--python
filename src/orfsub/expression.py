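"""Differential-expression calls, cancer grouping and PCA with imputation.

Each (gene, cancer) cell carries a tumor-vs-normal log2 fold-change and a
p-value; the ternary call is ``up`` when log2FC >= +threshold (default 2, a
four-fold change) with p < 0.05, ``down`` for the mirror condition, ``ns``
otherwise, and ``missing`` when the inputs are absent.  The boundary
|log2FC| = 2 counts as differentially expressed.

Genes can be grouped as cancer-specific (called in exactly one cancer) or
pan-cancer (called in >= 5 cancers, further labelled preferentially up /
down when one direction carries more than 2/3 of the calls, else mixed).

The gene x cancer call matrix (signed encoding up=+1, down=-1, ns=0) is
summarized by principal components via iterative SVD imputation of missing
cells: columns are centered, no row scaling, missing cells are refilled from
a rank-k reconstruction until convergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NS = "ns"
CALL_MISSING = "missing"

_CALL_TO_VALUE = {CALL_UP: 1.0, CALL_DOWN: -1.0, CALL_NS: 0.0}


def de_call(
    log2fc: np.ndarray | pd.DataFrame,
    p: np.ndarray | pd.DataFrame,
    fc_threshold: float = 2.0,
    p_cut: float = 0.05,
) -> np.ndarray:
    """Ternary differential-expression calls from effect sizes and p-values.

    NaN in either input yields ``missing``; |log2FC| at the threshold exactly
    counts as differentially expressed (inclusive boundary).
    """
    fc = np.asarray(log2fc, dtype=float)
    pv = np.asarray(p, dtype=float)
    if fc.shape != pv.shape:
        raise ValueError("log2fc and p must share a shape")
    calls = np.full(fc.shape, CALL_NS, dtype=object)
    missing = np.isnan(fc) | np.isnan(pv)
    sig = ~missing & (pv < p_cut)
    calls[sig & (fc >= fc_threshold)] = CALL_UP
    calls[sig & (fc <= -fc_threshold)] = CALL_DOWN
    calls[missing] = CALL_MISSING
    return calls


@dataclass
class DECallMatrix:
    """Gene x cancer differential-expression calls with effect sizes."""

    genes: list[str]
    cancers: list[str]
    log2fc: np.ndarray  # NaN = missing
    p: np.ndarray  # NaN = missing
    call: np.ndarray = field(default=None)  # object array over the call labels
    fc_threshold: float = 2.0
    p_cut: float = 0.05

    def __post_init__(self) -> None:
        self.log2fc = np.asarray(self.log2fc, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        expected = (len(self.genes), len(self.cancers))
        if self.log2fc.shape != expected or self.p.shape != expected:
            raise ValueError(f"matrices must be shaped {expected}")
        if self.call is None:
            self.call = de_call(self.log2fc, self.p, self.fc_threshold, self.p_cut)

    @classmethod
    def from_long_tsv(cls, path, fc_threshold: float = 2.0, p_cut: float = 0.05) -> "DECallMatrix":
        """Read a long-format TSV with columns gene, cancer, log2fc, p."""
        df = pd.read_csv(path, sep="\t")
        required = {"gene", "cancer", "log2fc", "p"}
        if not required.issubset(df.columns):
            raise ValueError(f"long DE TSV must have columns {sorted(required)}")
        fc = df.pivot(index="gene", columns="cancer", values="log2fc")
        pv = df.pivot(index="gene", columns="cancer", values="p").reindex_like(fc)
        return cls(
            genes=[str(g).upper() for g in fc.index],
            cancers=list(fc.columns),
            log2fc=fc.to_numpy(float),
            p=pv.to_numpy(float),
            fc_threshold=fc_threshold,
            p_cut=p_cut,
        )

    def call_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.call, index=self.genes, columns=self.cancers)

    def signed_matrix(self, encoding: str = "ternary") -> np.ndarray:
        """Numeric gene x cancer matrix for PCA: signed calls or log2FC.

        ``ternary``: up=+1, down=-1, ns=0, missing=NaN (the default, since
        the clustering of cancers reflects shared DE *patterns*);
        ``log2fc``: raw fold-changes with non-significant cells set to 0.
        """
        if encoding == "ternary":
            out = np.full(self.call.shape, np.nan)
            for label, value in _CALL_TO_VALUE.items():
                out[self.call == label] = value
            return out
        if encoding == "log2fc":
            out = np.where(self.call == CALL_MISSING, np.nan, self.log2fc)
            return np.where(self.call == CALL_NS, 0.0, out)
        raise ValueError(f"unknown encoding {encoding!r}")


def cancer_specific_genes(calls: DECallMatrix, cancer: str, direction: str = CALL_DOWN) -> list[str]:
    """Genes with the stated call in one cancer and no call anywhere else."""
    if cancer not in calls.cancers:
        raise KeyError(f"unknown cancer code {cancer!r}")
    if direction not in (CALL_UP, CALL_DOWN):
        raise ValueError("direction must be 'up' or 'down'")
    j = calls.cancers.index(cancer)
    out = []
    for i, gene in enumerate(calls.genes):
        if calls.call[i, j] != direction:
            continue
        others = np.delete(calls.call[i], j)
        if np.all((others == CALL_NS) | (others == CALL_MISSING)):
            out.append(gene)
    return out


def pan_cancer_group(calls: DECallMatrix, min_cancers: int = 5) -> dict[str, str]:
    """Categorize genes differentially expressed in >= min_cancers cancers.

    All calls one way -> preferentially_up / preferentially_down; with both
    directions present, a direction carrying more than 2/3 of the calls is
    still "preferential"; otherwise the gene is ``mixed``.
    """
    out: dict[str, str] = {}
    for i, gene in enumerate(calls.genes):
        row = calls.call[i]
        n_up = int((row == CALL_UP).sum())
        n_down = int((row == CALL_DOWN).sum())
        total = n_up + n_down
        if total < min_cancers:
            continue
        if n_up > (2 / 3) * total:
            out[gene] = "preferentially_up"
        elif n_down > (2 / 3) * total:
            out[gene] = "preferentially_down"
        else:
            out[gene] = "mixed"
    return out


@dataclass
class PCAResult:
    """Principal-component scores of the cancers and explained variance."""

    scores: np.ndarray  # cancers x components
    variance_explained: np.ndarray
    n_imputed: int
    converged: bool
    loadings: np.ndarray | None = None  # genes x components


class SVDImputePCA:
    """PCA of a matrix with missing cells via iterative SVD imputation.

    Rows are observations (here: cancers), columns variables (genes).
    Missing cells start at their row mean; the algorithm alternates a rank-k
    SVD reconstruction of the column-centered matrix with a refill of the
    missing cells until the largest imputed-cell change falls below ``tol``
    or ``max_iter`` is reached.  Columns are centered, rows are not scaled.

    Follows the scikit-learn estimator idiom: ``fit(X)`` learns the
    completion and components, ``transform(X)`` / ``fit_transform(X)`` return
    the observation scores, fitted attributes carry trailing underscores.
    """

    def __init__(self, n_components: int = 2, max_iter: int = 5000, tol: float = 1e-6):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components, "max_iter": self.max_iter, "tol": self.tol}

    def set_params(self, **params) -> "SVDImputePCA":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X: np.ndarray, y=None) -> "SVDImputePCA":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        mask = np.isnan(X)
        if mask.all(axis=1).any() or mask.all(axis=0).any():
            raise ValueError("every row and column needs at least one observed cell")
        k = min(self.n_components, min(X.shape))

        filled = X.copy()
        if mask.any():
            row_means = np.nanmean(X, axis=1)
            filled[mask] = np.take(row_means, np.nonzero(mask)[0])

        converged = not mask.any()
        for _ in range(self.max_iter if mask.any() else 0):
            col_means = filled.mean(axis=0)
            centered = filled - col_means
            u, s, vt = np.linalg.svd(centered, full_matrices=False)
            recon = (u[:, :k] * s[:k]) @ vt[:k] + col_means
            delta = np.abs(recon[mask] - filled[mask]).max()
            filled[mask] = recon[mask]
            if delta < self.tol:
                converged = True
                break
        if not converged:
            logger.warning("SVD imputation did not converge within %d iterations", self.max_iter)

        self.mean_ = filled.mean(axis=0)
        centered = filled - self.mean_
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        total = float((s**2).sum())
        self.components_ = vt[:k]
        self.singular_values_ = s[:k]
        self.explained_variance_ratio_ = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
        self.completed_ = filled
        self.n_imputed_ = int(mask.sum())
        self.converged_ = converged
        self.scores_ = u[:, :k] * s[:k]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "components_"):
            raise RuntimeError("fit the estimator before calling transform")
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("transform expects a complete matrix; use fit for imputation")
        return (X - self.mean_) @ self.components_.T

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).scores_


def pca_svd_impute(
    matrix: np.ndarray,
    n_components: int = 2,
    max_iter: int = 5000,
    tol: float = 1e-6,
) -> PCAResult:
    """PCA of an observations x variables matrix with NaN cells.

    Thin wrapper over :class:`SVDImputePCA`; for a gene x cancer call matrix
    pass the transpose so that rows are cancers and the scores place each
    cancer in PC space.
    """
    est = SVDImputePCA(n_components=n_components, max_iter=max_iter, tol=tol).fit(matrix)
    return PCAResult(
        scores=est.scores_,
        variance_explained=np.asarray(est.explained_variance_ratio_),
        n_imputed=est.n_imputed_,
        converged=est.converged_,
        loadings=est.components_.T,
    )
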
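"""Genotype PCA: standardization, decomposition, projection and comparison.

The decomposition follows the classic genotype-PCA construction: the N x N
kernel XX^T of the standardized dosage matrix is eigendecomposed, its top-k
orthonormal eigenvectors are the sample scores S, and SNP loadings are
defined as B = X^T S L^-1 (L the diagonal eigenvalue matrix) so that
projection X B reproduces S exactly on the training samples.  Fitting
loadings on a sample subset (e.g. controls only) and multiplying the full
standardized matrix onto B yields projected scores for everyone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.sparse.linalg import LinearOperator, eigsh

from .data import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_DENSE_N_MAX = 4000


@dataclass
class PCAModel:
    """Fitted genotype PCA: frequencies, eigenvalues, scores and loadings."""

    freqs: np.ndarray        # per-SNP allele2 frequency used for standardization
    eigenvalues: np.ndarray  # length k, nonincreasing
    scores: np.ndarray       # (N, k) orthonormal columns
    loadings: np.ndarray     # (P, k)
    snp_ids: np.ndarray
    sample_ids: np.ndarray
    scale: bool = True       # whether columns were variance-scaled

    @property
    def k(self) -> int:
        return len(self.eigenvalues)

    def scores_frame(self) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.scores[:, i] for i in range(self.k)}
        return pd.DataFrame({"sample_id": self.sample_ids, **cols})

    def loadings_frame(self) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.loadings[:, i] for i in range(self.k)}
        return pd.DataFrame({"snp_id": self.snp_ids, **cols})


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def standardize(
    genotypes: GenotypeMatrix,
    freqs: np.ndarray | None = None,
    scale: bool = True,
    drop_monomorphic: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-impute, center at 2p and (optionally) scale by sqrt(2p(1-p)).

    When ``freqs`` is supplied (projection onto an existing model) the given
    frequencies are used instead of the observed ones and no SNP is dropped,
    so the column space matches the model's.

    Returns ``(X, freqs, kept)`` where ``kept`` is the boolean mask of
    retained SNP columns.
    """
    d = genotypes.dosages.astype(np.float64)
    miss = genotypes.dosages == MISSING
    d[miss] = np.nan

    if freqs is None:
        with np.errstate(invalid="ignore"):
            p = np.nanmean(d, axis=0) / 2.0
        all_missing = np.isnan(p)
        if all_missing.any():
            logger.warning("dropping %d all-missing SNPs", int(all_missing.sum()))
        p = np.where(all_missing, 0.0, p)
        kept = ~all_missing
        if drop_monomorphic:
            mono = (p <= 0.0) | (p >= 1.0)
            n_mono = int((mono & kept).sum())
            if n_mono:
                logger.info("dropping %d monomorphic SNPs", n_mono)
            kept &= ~mono
    else:
        p = np.asarray(freqs, dtype=np.float64)
        if p.shape[0] != genotypes.n_snps:
            raise ValueError("frequency vector length does not match SNP count")
        kept = np.ones(genotypes.n_snps, dtype=bool)

    # missing calls impute to the column mean 2p, i.e. contribute 0 centered
    d = np.where(np.isnan(d), 2.0 * p, d)
    x = d - 2.0 * p
    if scale:
        denom = np.sqrt(np.clip(2.0 * p * (1.0 - p), 1e-12, None))
        x = x / denom
    return x[:, kept], p[kept], kept


# ---------------------------------------------------------------------------
# Decomposition
# ---------------------------------------------------------------------------

def compute_pca(
    x: np.ndarray,
    k: int = 10,
    freqs: np.ndarray | None = None,
    snp_ids: np.ndarray | None = None,
    sample_ids: np.ndarray | None = None,
    scale: bool = True,
) -> PCAModel:
    """Top-k eigendecomposition of the sample kernel XX^T.

    Uses a dense symmetric solver up to N=4000 samples and an iterative
    Lanczos solver beyond.  Component signs are fixed so the largest-
    magnitude loading of each component is positive.
    """
    n, p = x.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    k_req = k
    k = min(k, n - 1, p)
    if k < k_req:
        logger.warning("k truncated from %d to %d (rank limit)", k_req, k)

    if n <= _DENSE_N_MAX:
        kernel = x @ x.T
        vals, vecs = scipy.linalg.eigh(kernel, subset_by_index=(n - k, n - 1))
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
    else:  # pragma: no cover - exercised only on large cohorts
        op = _KernelOperator(x)
        vals, vecs = eigsh(op, k=k, which="LA")
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]

    positive = vals > max(1e-9, 1e-12 * max(vals.max(), 1.0))
    if not positive.all():
        logger.warning("k truncated to %d positive eigenvalues", int(positive.sum()))
        vals, vecs = vals[positive], vecs[:, positive]

    loadings = (x.T @ vecs) / vals  # B = X^T S L^-1  =>  X B = S
    scores = vecs
    # sign convention: largest-|loading| entry positive per component
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]

    return PCAModel(
        freqs=np.asarray(freqs) if freqs is not None else np.full(p, np.nan),
        eigenvalues=vals,
        scores=scores,
        loadings=loadings,
        snp_ids=np.asarray(snp_ids) if snp_ids is not None else np.arange(p),
        sample_ids=np.asarray(sample_ids) if sample_ids is not None else np.arange(n),
        scale=scale,
    )


class _KernelOperator(LinearOperator):
    """Matrix-free XX^T for the iterative eigensolver."""

    def __init__(self, x: np.ndarray):
        self.x = x
        super().__init__(dtype=np.float64, shape=(x.shape[0], x.shape[0]))

    def _matvec(self, v):
        return self.x @ (self.x.T @ v)


def fit_pca(
    genotypes: GenotypeMatrix, k: int = 10, scale: bool = True
) -> PCAModel:
    """Standardize and decompose a genotype matrix in one step."""
    x, freqs, kept = standardize(genotypes, scale=scale)
    return compute_pca(
        x,
        k=k,
        freqs=freqs,
        snp_ids=genotypes.snp_ids[kept],
        sample_ids=genotypes.sample_ids,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------

def project(
    genotypes: GenotypeMatrix, model: PCAModel, min_overlap: float = 0.9
) -> pd.DataFrame:
    """Project samples onto a fitted model's loadings.

    New dosages are standardized with the *model's* allele frequencies (so a
    missing or absent SNP contributes exactly zero) and multiplied onto B.
    Projecting the training samples returns their stored scores.
    """
    idx = pd.Index(genotypes.snp_ids).get_indexer(model.snp_ids)
    overlap = float((idx >= 0).mean())
    if overlap < min_overlap:
        raise ValueError(
            f"only {overlap:.1%} of model SNPs present; need >= {min_overlap:.0%}"
        )
    n = genotypes.n_samples
    x = np.zeros((n, len(model.snp_ids)))
    present = idx >= 0
    sub = genotypes.subset_snps(idx[present])
    xs, _, _ = standardize(sub, freqs=model.freqs[present], scale=model.scale)
    x[:, present] = xs
    scores = x @ model.loadings
    cols = {f"PC{i + 1}": scores[:, i] for i in range(model.k)}
    return pd.DataFrame({"sample_id": genotypes.sample_ids, **cols})


# ---------------------------------------------------------------------------
# Comparison statistics
# ---------------------------------------------------------------------------

def _aligned_scores(model_or_frame) -> pd.DataFrame:
    if isinstance(model_or_frame, PCAModel):
        return model_or_frame.scores_frame()
    return model_or_frame


def pc_correlation_table(model_a, model_b) -> pd.DataFrame:
    """Pearson correlations between two models' scores on shared samples.

    Rows are A's components, columns B's; signed values (the paper-style
    display convention of showing |r| is left to callers).
    """
    a = _aligned_scores(model_a).set_index("sample_id")
    b = _aligned_scores(model_b).set_index("sample_id")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("models share no samples")
    a, b = a.loc[shared], b.loc[shared]
    table = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    am = a.to_numpy() - a.to_numpy().mean(axis=0)
    bm = b.to_numpy() - b.to_numpy().mean(axis=0)
    denom = np.outer(np.linalg.norm(am, axis=0), np.linalg.norm(bm, axis=0))
    table.iloc[:, :] = (am.T @ bm) / np.clip(denom, 1e-300, None)
    return table


def variance_explained_by_combo(target: np.ndarray, predictors: np.ndarray) -> float:
    """OLS R-squared of one component's scores on a set of other components."""
    y = np.asarray(target, dtype=float)
    z = np.atleast_2d(np.asarray(predictors, dtype=float))
    if z.shape[0] == y.shape[0]:
        pass
    elif z.shape[1] == y.shape[0]:
        z = z.T
    else:
        raise ValueError("predictor shape does not match target length")
    if np.linalg.matrix_rank(z) < min(z.shape):
        raise ValueError("degenerate (rank-deficient) predictor set")
    design = np.column_stack([np.ones(len(y)), z])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("target has zero variance")
    return float(1.0 - np.sum(resid**2) / ss_tot)
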
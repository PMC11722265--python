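"""Sparse reduced-rank regression from gene expression to model parameters.

The model predicts the (z-scored) biophysical parameter matrix Y (cells x 13)
from preprocessed expression X (cells x genes) through a rank-2 bottleneck,

    Y ~ X W V^T,    V^T V = I,

where W (genes x rank) carries a row-wise (per-gene) elastic-net penalty

    lambda * (alpha * ||w_j||_2 + (1 - alpha)/2 * ||w_j||_2^2),

so genes drop out as whole rows and the nonzero rows of W form the selected
gene set. Fitting alternates an orthogonal Procrustes update of V with a
group-elastic-net update of W by block coordinate descent; the objective is
non-increasing across alternations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneMatrix",
    "SRRRModel",
    "preprocess_expression",
    "fit_srrr",
    "lambda_max",
    "cv_srrr",
    "r2_per_parameter",
    "latent_coords",
    "group_compare",
]


@dataclass
class GeneMatrix:
    """Preprocessed cells x genes expression with optional cell labels."""

    values: np.ndarray
    gene_names: np.ndarray
    cell_labels: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_names = np.asarray(self.gene_names)
        if self.values.ndim != 2 or self.values.shape[1] != self.gene_names.size:
            raise ValueError("values and gene_names are misaligned")
        if len(np.unique(self.gene_names)) != self.gene_names.size:
            raise ValueError("gene names must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains non-finite values")


def preprocess_expression(
    counts: np.ndarray | pd.DataFrame,
    gene_names: Optional[Sequence[str]] = None,
    gene_subset: Optional[Sequence[str]] = None,
    target_sum: float = 1e4,
) -> GeneMatrix:
    """Library-size normalize, log(1+x) transform and per-gene z-score.

    Each cell is scaled to a fixed total count before the log transform, so
    the result is invariant to sequencing depth. Genes with zero variance
    (e.g. all-zero genes) are dropped with a warning. ``gene_subset``
    restricts to an a-priori list such as ion-channel and marker genes.
    """
    if isinstance(counts, pd.DataFrame):
        gene_names = counts.columns.to_numpy()
        counts = counts.to_numpy(dtype=float)
    else:
        counts = np.asarray(counts, dtype=float)
        if gene_names is None:
            gene_names = np.array([f"g{i}" for i in range(counts.shape[1])])
        gene_names = np.asarray(gene_names)
    if gene_subset is not None:
        keep = np.isin(gene_names, np.asarray(gene_subset))
        counts = counts[:, keep]
        gene_names = gene_names[keep]
    libsize = counts.sum(axis=1, keepdims=True)
    if np.any(libsize == 0):
        raise ValueError("cells with zero total counts cannot be normalized")
    logx = np.log1p(counts / libsize * target_sum)
    sd = logx.std(axis=0)
    dead = sd == 0
    if dead.any():
        warnings.warn(
            f"dropping {int(dead.sum())} zero-variance genes "
            f"({', '.join(map(str, gene_names[dead][:5]))}...)"
        )
        logx = logx[:, ~dead]
        gene_names = gene_names[~dead]
        sd = sd[~dead]
    z = (logx - logx.mean(axis=0)) / sd
    return GeneMatrix(values=z, gene_names=gene_names)


@dataclass
class SRRRModel:
    """Fitted rank-r sparse reduced-rank regression."""

    W: np.ndarray                 # genes x rank encoder
    V: np.ndarray                 # params x rank decoder, V^T V = I
    lam: float
    alpha: float
    gene_names: np.ndarray
    x_mean: np.ndarray            # column means used as intercepts
    y_mean: np.ndarray
    objective_path: list = field(default_factory=list)

    @property
    def rank(self) -> int:
        return self.W.shape[1]

    @property
    def selected(self) -> np.ndarray:
        """Indices of genes with nonzero encoder rows."""
        return np.flatnonzero(np.linalg.norm(self.W, axis=1) > 0)

    @property
    def selected_genes(self) -> np.ndarray:
        return self.gene_names[self.selected]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.y_mean + (X - self.x_mean) @ self.W @ self.V.T

    def latent(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) @ self.W


def _objective(Xc, Yc, W, V, lam, alpha) -> float:
    n = Xc.shape[0]
    resid = Yc - Xc @ W @ V.T
    norms = np.linalg.norm(W, axis=1)
    pen = lam * (alpha * norms.sum() + 0.5 * (1 - alpha) * (norms**2).sum())
    return 0.5 * np.sum(resid**2) / n + pen


def _group_enet_cd(
    Xc: np.ndarray,
    Z: np.ndarray,
    W: np.ndarray,
    lam: float,
    alpha: float,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> np.ndarray:
    """Row-wise group elastic-net regression of Z on Xc by coordinate descent."""
    n, p = Xc.shape
    col_ss = (Xc**2).sum(axis=0) / n
    R = Z - Xc @ W
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            wj = W[j]
            if wj.any():
                R += np.outer(Xc[:, j], wj)
            cj = Xc[:, j] @ R / n
            cn = np.linalg.norm(cj)
            thr = lam * alpha
            if cn <= thr:
                new = np.zeros_like(wj)
            else:
                new = (1.0 - thr / cn) * cj / (col_ss[j] + lam * (1 - alpha))
            if new.any():
                R -= np.outer(Xc[:, j], new)
            delta = np.abs(new - wj).max()
            if delta > max_delta:
                max_delta = delta
            W[j] = new
        if max_delta < tol:
            break
    return W


def lambda_max(X: np.ndarray, Y: np.ndarray, rank: int = 2, alpha: float = 0.5) -> float:
    """Smallest penalty at which the encoder is entirely zero."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    n = X.shape[0]
    U, _, Vt = np.linalg.svd(Yc.T @ Xc, full_matrices=False)
    V0 = U[:, :rank]
    C = Xc.T @ (Yc @ V0) / n
    return float(np.linalg.norm(C, axis=1).max() / max(alpha, 1e-12))


def fit_srrr(
    X: np.ndarray | GeneMatrix,
    Y: np.ndarray,
    rank: int = 2,
    lam: float = 0.1,
    alpha: float = 0.5,
    max_iter: int = 200,
    tol: float = 1e-6,
    W0: Optional[np.ndarray] = None,
) -> SRRRModel:
    """Alternating Procrustes / group-elastic-net fit of the sRRR model."""
    if isinstance(X, GeneMatrix):
        gene_names = X.gene_names
        X = X.values
    else:
        X = np.asarray(X, dtype=float)
        gene_names = np.array([f"g{i}" for i in range(X.shape[1])])
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have aligned rows")
    if rank > min(X.shape[1], Y.shape[1]):
        raise ValueError(f"rank {rank} exceeds min dimension")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    n = X.shape[0]

    U, _, _ = np.linalg.svd(Yc.T @ Xc, full_matrices=False)
    V = U[:, :rank]
    if W0 is not None:
        W = W0.copy()
    else:
        W = np.zeros((X.shape[1], rank))
    obj = [_objective(Xc, Yc, W, V, lam, alpha)]
    for _ in range(max_iter):
        W = _group_enet_cd(Xc, Yc @ V, W, lam, alpha)
        M = Yc.T @ (Xc @ W)
        P, _, Qt = np.linalg.svd(M, full_matrices=False)
        V = P @ Qt
        obj.append(_objective(Xc, Yc, W, V, lam, alpha))
        if abs(obj[-2] - obj[-1]) <= tol * max(abs(obj[-2]), 1e-12):
            break
    return SRRRModel(
        W=W, V=V, lam=lam, alpha=alpha, gene_names=gene_names,
        x_mean=x_mean, y_mean=y_mean, objective_path=obj,
    )


def r2_per_parameter(model: SRRRModel, X: np.ndarray | GeneMatrix, Y: np.ndarray) -> np.ndarray:
    """Coefficient of determination of each parameter column."""
    if isinstance(X, GeneMatrix):
        X = X.values
    Y = np.asarray(Y, dtype=float)
    resid = Y - model.predict(X)
    ss_res = (resid**2).sum(axis=0)
    ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    return 1.0 - ss_res / ss_tot


def latent_coords(model: SRRRModel, X: np.ndarray | GeneMatrix) -> np.ndarray:
    """Cells x rank coordinates in the sparse latent space."""
    if isinstance(X, GeneMatrix):
        X = X.values
    return model.latent(X)


def cv_srrr(
    X: np.ndarray | GeneMatrix,
    Y: np.ndarray,
    lam_path: Optional[np.ndarray] = None,
    rank: int = 2,
    alpha: float = 0.5,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 20,
) -> pd.DataFrame:
    """Cross-validated R^2 and mean selected-gene count along a lambda path.

    Held-out R^2 uses the training-fold column means as the null predictor:
    R^2 = 1 - ||Y - Yhat||^2 / ||Y - Ybar_train||^2. The path defaults to
    log-spaced values downward from the data-driven lambda_max.
    """
    if isinstance(X, GeneMatrix):
        Xv = X.values
    else:
        Xv = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = Xv.shape[0]
    if lam_path is None:
        lmax = lambda_max(Xv, Y, rank=rank, alpha=alpha)
        # two decades below lambda_max: the CV optimum sits mid-path and
        # near-unpenalized fits are both slow and never selected
        lam_path = np.geomspace(lmax * 1.001, lmax * 1e-2, n_lambdas)
    lam_path = np.asarray(lam_path, dtype=float)

    rng = np.random.default_rng(seed)
    fold_of = np.repeat(np.arange(folds), int(np.ceil(n / folds)))[:n]
    rng.shuffle(fold_of)

    r2 = np.full((lam_path.size, folds), np.nan)
    n_sel = np.full((lam_path.size, folds), np.nan)
    for f in range(folds):
        tr = fold_of != f
        te = ~tr
        W_warm = None
        for li, lam in enumerate(lam_path):
            model = fit_srrr(Xv[tr], Y[tr], rank=rank, lam=lam, alpha=alpha, W0=W_warm)
            W_warm = model.W
            pred = model.predict(Xv[te])
            ss_res = np.sum((Y[te] - pred) ** 2)
            ss_tot = np.sum((Y[te] - Y[tr].mean(axis=0)) ** 2)
            r2[li, f] = 1.0 - ss_res / ss_tot
            n_sel[li, f] = model.selected.size
    return pd.DataFrame(
        {
            "lam": lam_path,
            "cv_r2_mean": r2.mean(axis=1),
            "cv_r2_sd": r2.std(axis=1),
            "n_genes_mean": n_sel.mean(axis=1),
        }
    )


def group_compare(
    theta_map: np.ndarray,
    theta_pred: np.ndarray,
    labels: Sequence,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Compare group-mean parameter matrices of fitted vs predicted parameters.

    Both matrices are z-scored with the mean and standard deviation of the
    *fitted* (MAP) cohort, then averaged within each label group; the
    returned distance is the Euclidean (Frobenius) norm of the difference of
    the two group-mean matrices.
    """
    theta_map = np.asarray(theta_map, dtype=float)
    theta_pred = np.asarray(theta_pred, dtype=float)
    labels = np.asarray(labels)
    if theta_map.shape != theta_pred.shape or theta_map.shape[0] != labels.size:
        raise ValueError("shape mismatch between matrices and labels")
    mu = theta_map.mean(axis=0)
    sd = theta_map.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero variance in a fitted parameter column")
    z_map = (theta_map - mu) / sd
    z_pred = (theta_pred - mu) / sd
    groups = np.unique(labels)
    gm_map = np.vstack([z_map[labels == g].mean(axis=0) for g in groups])
    gm_pred = np.vstack([z_pred[labels == g].mean(axis=0) for g in groups])
    dist = float(np.linalg.norm(gm_map - gm_pred))
    idx = pd.Index(groups, name="group")
    return (
        pd.DataFrame(gm_map, index=idx),
        pd.DataFrame(gm_pred, index=idx),
        dist,
    )
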
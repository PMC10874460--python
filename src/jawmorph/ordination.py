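"""Principal component analysis of shape and functional data.

Shape PCA runs on Procrustes-aligned coordinates without further scaling
(relative-warps style with uniform and non-uniform components together);
functional PCA runs on z-scored characters. A deterministic sign convention
(largest-magnitude loading of each component positive) keeps scores stable
across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["OrdinationResult", "pca"]


@dataclass
class OrdinationResult:
    """Scores, loadings and variance accounting for one PCA."""

    taxa: list
    variables: list
    scores: np.ndarray  # taxa x components
    loadings: np.ndarray  # variables x components (orthonormal columns)
    eigenvalues: np.ndarray  # descending, >= 0
    variance_proportions: np.ndarray  # sums to 1
    center: np.ndarray
    scale: np.ndarray
    source: str = "function"

    def scores_frame(self):
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=pd.Index(self.taxa, name="taxon"),
                            columns=cols)

    def reconstruct(self):
        """Back-project all retained components onto the original scale."""
        X = self.scores @ self.loadings.T
        return X * self.scale + self.center


def pca(matrix, taxa=None, variables=None, center=True, scale=False,
        n_components=None, source="function"):
    """PCA via singular value decomposition of the (optionally centred and
    scaled) data matrix.

    Eigenvalues are the sample (n-1) variances along each component; the
    component count is capped at ``min(n - 1, p)``. Rank-0 input is
    rejected.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least 3 rows")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values")
    n, p = X.shape
    taxa = list(taxa) if taxa is not None else [f"r{i}" for i in range(n)]
    variables = (
        list(variables) if variables is not None else [f"v{j}" for j in range(p)]
    )
    mu = X.mean(axis=0) if center else np.zeros(p)
    Xc = X - mu
    sd = np.ones(p)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        if (sd < 1e-300).any():
            raise ValueError("cannot scale a constant column")
        Xc = Xc / sd
    if np.linalg.norm(Xc) < 1e-12:
        raise ValueError("rank-0 matrix: no variation to ordinate")
    k_max = min(n - 1, p)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(k_max, n_components) if n_components else k_max
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    eig = s**2 / (n - 1)
    total_var = (Xc**2).sum() / (n - 1)
    # sign convention: largest-magnitude loading per component positive
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U * s
    props = eig / total_var
    return OrdinationResult(
        taxa=taxa,
        variables=variables,
        scores=scores,
        loadings=Vt.T,
        eigenvalues=eig,
        variance_proportions=props,
        center=mu,
        scale=sd,
        source=source,
    )
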
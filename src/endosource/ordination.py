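"""Covariance PCA with samples as variables, for TRFLP biplots.

The input matrix has one row per (dye, size) category (the
observations) and one column per sample (the variables); entries are
the presence/absence counts of PCR trials (0..n_trials) in which each
category was detected.  Columns are mean-centered, their covariance
matrix is eigendecomposed, and each sample is drawn in the biplot as a
vector whose coordinates are its loadings on the leading components:
vector length reflects that sample's variance, angles between vectors
reflect covariance between samples.  No scaling is applied (covariance,
not correlation, PCA).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PCAResult:
    """Eigenstructure of the sample covariance matrix.

    ``sample_coords`` holds the biplot vector coordinates (loadings,
    eigenvector times sqrt eigenvalue) per sample; ``feature_scores``
    the observation scores (centered data projected on the
    eigenvectors).  Components are sign-fixed so the largest-magnitude
    loading of each component is positive.
    """

    eigenvalues: np.ndarray  # descending
    variance_explained: np.ndarray  # fractions, sums to 1
    sample_coords: pd.DataFrame  # samples x components
    feature_scores: pd.DataFrame  # observations x components
    components: pd.DataFrame  # unit eigenvectors, samples x components

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


def pca_covariance(matrix: pd.DataFrame) -> PCAResult:
    """PCA of the covariance of the matrix columns (samples).

    Deterministic up to the fixed sign convention.  A constant matrix
    (zero covariance) yields all-zero eigenvalues with a warning.  To
    ordinate with features as the variables, pass ``matrix.T``.
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples (columns) and 2 features (rows)")
    if matrix.columns.duplicated().any():
        raise ValueError("sample (column) labels must be unique")
    X = np.asarray(matrix, dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    n_obs = X.shape[0]
    cov = (Xc.T @ Xc) / (n_obs - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    eigval = np.where(np.abs(eigval) < 1e-12 * max(1.0, np.abs(eigval).max(initial=1.0)),
                      0.0, eigval)
    eigval = np.clip(eigval, 0.0, None)

    # sign convention: largest-|loading| entry of each component positive
    for j in range(eigvec.shape[1]):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]

    total = eigval.sum()
    if total <= 0:
        warnings.warn("constant matrix: all eigenvalues are zero", stacklevel=2)
        var_exp = np.zeros_like(eigval)
    else:
        var_exp = eigval / total

    comp_labels = [f"PC{j + 1}" for j in range(len(eigval))]
    components = pd.DataFrame(eigvec, index=matrix.columns, columns=comp_labels)
    loadings = components * np.sqrt(eigval)
    scores = pd.DataFrame(Xc @ eigvec, index=matrix.index, columns=comp_labels)
    return PCAResult(
        eigenvalues=eigval,
        variance_explained=var_exp,
        sample_coords=loadings,
        feature_scores=scores,
        components=components,
    )


def variance_first_k(result: PCAResult, k: int) -> float:
    """Cumulative variance explained by the first k components, percent."""
    if k < 0 or k > len(result.variance_explained):
        raise ValueError(f"k must be in [0, {len(result.variance_explained)}]")
    return float(100.0 * result.variance_explained[:k].sum())


def plot_biplot(result: PCAResult, ax=None, annotate: bool = True):
    """Draw the first two components as a vector biplot."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, row in result.sample_coords.iterrows():
        ax.annotate(
            "", xy=(row["PC1"], row["PC2"]), xytext=(0, 0),
            arrowprops={"arrowstyle": "->"},
        )
        if annotate:
            ax.annotate(str(label), xy=(row["PC1"], row["PC2"]))
    ax.set_xlabel(f"PC1 ({100 * result.variance_explained[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * result.variance_explained[1]:.1f}%)")
    ax.axhline(0.0, lw=0.5, color="grey")
    ax.axvline(0.0, lw=0.5, color="grey")
    return ax
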
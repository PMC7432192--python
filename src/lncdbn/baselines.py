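"""Comparison methods: PCA-CNN (PCA replaces the DBN encoder) and DBN-DNN
(a fully connected network replaces the CNN).

PCA keeps 13 components to mirror the DBN code length, so the three methods
consume features of identical dimension and the comparison isolates the
encoder/classifier choice. The cross-validation harness itself lives in
:mod:`lncdbn.evaluation`; this module provides the PCA transform plus thin
entry points that select the method tag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA


class FitError(ValueError):
    pass


@dataclass
class PCATransform:
    """Centered principal-component projection with a fixed sign convention."""

    components: np.ndarray  # (n_components, n_features)
    mean: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def fit_pca(
    gene_matrix: np.ndarray,
    n_components: int = 13,
    on_deficient: str = "allow",
) -> PCATransform:
    """Fit PCA on the gene feature matrix.

    Requires ``n > n_components`` rows. With rank-deficient data the trailing
    components carry zero variance; ``on_deficient="error"`` turns that into
    a fit error instead. Component signs follow a deterministic convention:
    the largest-magnitude loading of each component is positive.
    """
    X = np.asarray(gene_matrix, dtype=float)
    if X.ndim != 2:
        raise FitError("gene_matrix must be 2-D")
    n = X.shape[0]
    if n <= n_components:
        raise FitError(f"need more than {n_components} samples to fit PCA, got {n}")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    comps = pca.components_.copy()
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    if on_deficient == "error" and np.any(pca.explained_variance_ < 1e-12):
        rank = int(np.sum(pca.explained_variance_ > 1e-12))
        raise FitError(
            f"data rank {rank} < requested {n_components} components"
        )
    return PCATransform(
        components=comps,
        mean=pca.mean_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def pca_encode(v: np.ndarray, transform: PCATransform) -> np.ndarray:
    """Project (a) feature vector(s) onto the principal components."""
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    vb = v[None, :] if single else v
    if vb.shape[1] != transform.mean.shape[0]:
        raise ValueError(
            f"expected {transform.mean.shape[0]} features, got {vb.shape[1]}"
        )
    out = (vb - transform.mean) @ transform.components.T
    return out[0] if single else out


def run_pca_cnn(dataset, cv_spec, config=None):
    """PCA-CNN over every retained cancer; identical folds/negatives to the
    primary method under the same experiment seed."""
    from .evaluation import evaluate_all

    return evaluate_all(dataset, ["pca-cnn"], cv_spec, config)


def run_dbn_dnn(dataset, cv_spec, config=None):
    """DBN-DNN over every retained cancer (shared folds/negatives as above)."""
    from .evaluation import evaluate_all

    return evaluate_all(dataset, ["dbn-dnn"], cv_spec, config)
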
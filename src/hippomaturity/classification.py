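"""PCA grouping of models into development-like vs aging-like phenotypes.

The model x reference matrix of signed -log10 overlap indices is
column-standardized, projected onto its first two principal components,
and split by deterministic 2-means on the component scores (initialized
at the two models with extreme PC1 scores). The group whose members have
the higher mean signed index over the development columns is labeled
"development_like"; the other "aging_like".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .indices import IndexTable, maturity_index

DEVELOPMENT_LIKE = "development_like"
AGING_LIKE = "aging_like"


class CompletenessError(ValueError):
    """A model-reference comparison required by the matrix is missing."""


class DegenerateMatrixError(ValueError):
    """A column has zero variance; PCA standardization is undefined."""


@dataclass(frozen=True)
class GroupAssignment:
    groups: dict  # model_id -> DEVELOPMENT_LIKE | AGING_LIKE
    pc_scores: pd.DataFrame  # columns PC1, PC2
    explained_variance_fractions: tuple


def build_index_matrix(overlaps: dict, models, references) -> pd.DataFrame:
    """Assemble the signed -log10 index matrix from pairwise comparisons.

    overlaps: {(model_id, reference_id): SignedOverlap}. Every model x
    reference cell must be present.
    """
    missing = [(m, r) for m in models for r in references if (m, r) not in overlaps]
    if missing:
        raise CompletenessError(f"missing comparisons: {missing}")
    mat = pd.DataFrame(index=list(models), columns=list(references), dtype=float)
    for m in models:
        for r in references:
            ov = overlaps[(m, r)]
            log10p = getattr(ov, "overall_log10p", None)
            if log10p is None:
                mat.loc[m, r] = maturity_index(ov.overall_p, ov.sign)
            else:
                mat.loc[m, r] = ov.sign * -log10p
    return mat


def _two_means(scores: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Deterministic Lloyd 2-means initialized at the extreme-PC1 points."""
    init = np.array([scores[np.argmin(scores[:, 0])], scores[np.argmax(scores[:, 0])]])
    centers = init.astype(float)
    labels = np.zeros(len(scores), dtype=int)
    for _ in range(max_iter):
        d = ((scores[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d.argmin(axis=1)
        if (new_labels == labels).all() and _ > 0:
            break
        labels = new_labels
        for k in (0, 1):
            if (labels == k).any():
                centers[k] = scores[labels == k].mean(axis=0)
    return labels


def classify_models(
    matrix: pd.DataFrame, development_columns=None
) -> GroupAssignment:
    """Standardize, project to two PCs, and split into the two phenotype groups.

    development_columns defaults to columns whose names start with "dev";
    they drive only the group labeling, not the clustering itself.
    """
    if matrix.shape[0] < 3 or matrix.shape[1] < 2:
        raise ValueError("need at least 3 models and 2 references")
    if development_columns is None:
        development_columns = [c for c in matrix.columns if str(c).startswith("dev")]
    if not development_columns:
        raise ValueError("no development columns identified for labeling")
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = [c for c, s in zip(matrix.columns, sd) if s == 0]
        raise DegenerateMatrixError(f"zero-variance columns: {bad}")
    z = (x - x.mean(axis=0)) / sd
    n_comp = min(2, min(z.shape) - 0)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(z)
    if scores.shape[1] < 2:  # single-component edge case
        scores = np.column_stack([scores, np.zeros(len(scores))])
    labels = _two_means(scores[:, :2])
    dev_mean = [
        matrix.loc[matrix.index[labels == k], development_columns].to_numpy().mean()
        if (labels == k).any()
        else -np.inf
        for k in (0, 1)
    ]
    dev_cluster = int(np.argmax(dev_mean))
    groups = {
        m: (DEVELOPMENT_LIKE if labels[i] == dev_cluster else AGING_LIKE)
        for i, m in enumerate(matrix.index)
    }
    return GroupAssignment(
        groups=groups,
        pc_scores=pd.DataFrame(
            scores[:, :2], index=matrix.index, columns=["PC1", "PC2"]
        ),
        explained_variance_fractions=tuple(
            float(v) for v in pca.explained_variance_ratio_
        ),
    )
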
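"""Distance matrices and classical principal coordinate analysis (PCoA).

Samples are columns of an oTRF abundance table.  Euclidean distance and
Bray-Curtis dissimilarity (1 - 2*sum(min)/sum(x+y), in [0, 1]) are
supported; PCoA is classical metric scaling: Gower double-centering of
-D^2/2 followed by an eigendecomposition, with only positive-eigenvalue
axes reported and a fixed sign convention (the largest-magnitude loading
on each axis is positive) for reproducible output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .binning import OTRFTable

logger = logging.getLogger(__name__)

METRICS = ("euclidean", "bray-curtis")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative sample distance matrix with zero diagonal."""

    ids: list[str]
    data: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.data) != 0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.data < 0):
            raise ValueError("distances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


@dataclass
class OrdinationResult:
    """PCoA coordinates plus eigenvalues and per-axis variance fractions."""

    coordinates: pd.DataFrame  # samples x axes (PCo1..)
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    covariates: Optional[pd.DataFrame] = None


def distance(
    table: Union[OTRFTable, pd.DataFrame], metric: str = "euclidean"
) -> DistanceMatrix:
    """Pairwise distances between the sample columns of an abundance table."""
    df = table.abundances if isinstance(table, OTRFTable) else table
    metric = metric.lower().replace("_", "-")
    if metric == "braycurtis":
        metric = "bray-curtis"
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if df.shape[1] < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    X = df.T.to_numpy(dtype=float)  # samples x features
    if np.any(X < 0):
        raise ValueError("negative abundances are not allowed")
    if metric == "euclidean":
        d = pdist(X, metric="euclidean")
    else:
        d = pdist(X, metric="braycurtis")
        if np.any(np.isnan(d)):  # two all-zero samples: 0/0, defined as 0
            logger.warning(
                "bray-curtis between all-zero samples is undefined; set to 0"
            )
            d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(
        ids=[str(c) for c in df.columns], data=squareform(d), metric=metric
    )


def pcoa(
    dm: DistanceMatrix,
    n_axes: Optional[int] = None,
    *,
    covariates: Optional[pd.DataFrame] = None,
) -> OrdinationResult:
    """Classical scaling of a distance matrix.

    Negative eigenvalues (possible for non-Euclidean dissimilarities such
    as Bray-Curtis) are dropped and their total magnitude logged; variance
    proportions are relative to the positive-eigenvalue total.  Requesting
    more axes than there are positive eigenvalues truncates with a
    warning.  Covariates (indexed by sample id) are passed through for
    downstream overlay.
    """
    D = dm.data
    n = D.shape[0]
    B = -0.5 * (D ** 2)
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ B @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(abs(eigvals[0]), 1.0) * 1e-12 if n else 0.0
    positive = eigvals > tol
    neg_mass = float(-eigvals[eigvals < -tol].sum())
    if neg_mass > 0:
        logger.info(
            "pcoa: dropped negative eigenvalues with total magnitude %.6g", neg_mass
        )
    pos_vals = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(pos_vals)

    # fixed sign convention: largest-magnitude loading positive
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col

    if n_axes is not None:
        if n_axes > coords.shape[1]:
            logger.warning(
                "pcoa: requested %d axes but only %d positive; truncating",
                n_axes, coords.shape[1],
            )
        coords = coords[:, : n_axes]
        reported_vals = pos_vals[: n_axes]
    else:
        reported_vals = pos_vals

    denom = pos_vals.sum() if pos_vals.size else 1.0
    proportion = reported_vals / denom
    coordinates = pd.DataFrame(
        coords[:, : len(reported_vals)],
        index=dm.ids,
        columns=[f"PCo{k + 1}" for k in range(len(reported_vals))],
    )
    cov = None
    if covariates is not None:
        cov = covariates.reindex(dm.ids)
    return OrdinationResult(
        coordinates=coordinates,
        eigenvalues=reported_vals,
        proportion_explained=proportion,
        covariates=cov,
    )


def write_ordination(
    result: OrdinationResult, coords_path, eigen_path
) -> None:
    """Coordinates TSV (sample, axes, covariates) and eigenvalue TSV."""
    out = result.coordinates.copy()
    if result.covariates is not None:
        out = out.join(result.covariates)
    out.index.name = "sample"
    out.to_csv(coords_path, sep="\t")
    pd.DataFrame(
        {
            "axis": [f"PCo{k + 1}" for k in range(len(result.eigenvalues))],
            "eigenvalue": result.eigenvalues,
            "proportion_explained": result.proportion_explained,
        }
    ).to_csv(eigen_path, sep="\t", index=False)
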
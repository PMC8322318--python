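"""Top-variance CpG selection and classical multidimensional scaling.

For joint visualisation of the reference panel and a query sample, the
``n_top`` most variable CpGs (across samples, complete cases only) are
selected and the samples are embedded in two dimensions by classical
(Torgerson) MDS on Euclidean beta-space distances: square the distance
matrix, double-centre, take the top two eigenpairs.  For point sets of
intrinsic dimension <= 2 the embedding reproduces the input distances
exactly (up to rotation/reflection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = ["MDSResult", "top_variable_cpgs", "mds_embed"]


@dataclass
class MDSResult:
    coordinates: pd.DataFrame     # samples x 2, centred at the origin
    cpg_ids: list[str]
    eigenvalues: np.ndarray       # non-increasing


def top_variable_cpgs(betas: pd.DataFrame, n_top: int = 100) -> list[str]:
    """The ``n_top`` CpGs with largest across-sample variance.

    Candidates are restricted to complete cases (no missing betas).  Ties
    and the ordering of the result are lexicographic by probe id.  If fewer
    than ``n_top`` complete CpGs exist, all are used with a warning.
    """
    complete = betas.columns[~betas.isna().any(axis=0)]
    if len(complete) == 0:
        raise ValueError("no complete-case CpGs")
    if len(complete) < n_top:
        warnings.warn(f"only {len(complete)} complete CpGs available "
                      f"(requested {n_top}); using all", stacklevel=2)
        n_top = len(complete)
    var = betas[complete].var(axis=0, ddof=1)
    order = sorted(complete, key=lambda c: (-var[c], c))
    return sorted(order[:n_top])


def mds_embed(betas: pd.DataFrame, cpg_ids=None) -> MDSResult:
    """Classical (Torgerson) MDS of samples into two dimensions.

    ``betas`` is samples x CpGs (optionally pre-restricted via ``cpg_ids``),
    complete cases required.  Coordinates are centred; eigenvalues of the
    scaling solution are returned in non-increasing order.
    """
    if cpg_ids is not None:
        betas = betas[list(cpg_ids)]
    if len(betas) < 3:
        raise ValueError("MDS needs at least 3 samples")
    X = betas.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing betas among the selected CpGs")
    D2 = squareform(pdist(X, metric="euclidean")) ** 2
    n = len(X)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)          # ascending
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    lam = np.clip(vals[:2], 0.0, None)
    coords = vecs[:, :2] * np.sqrt(lam)[None, :]
    coords -= coords.mean(axis=0, keepdims=True)   # exact centring
    cdf = pd.DataFrame(coords, index=betas.index, columns=["dim1", "dim2"])
    return MDSResult(coordinates=cdf, cpg_ids=list(betas.columns),
                     eigenvalues=vals)
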
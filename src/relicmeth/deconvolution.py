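"""Tissue-marker selection, reference matrix, and NNLS deconvolution.

Marker CpGs are chosen one-vs-rest: for a candidate CpG ``c`` and tissue
``t`` the score is ``|mean_t - mean_rest| - lambda * (sd_t + sd_rest)/2`` —
large mean separation, penalised by within-group spread.  Selection is run
with stratified k-fold cross-validation over the training samples: each fold
is held out, the score is computed on the remaining folds, CpGs are ranked
per tissue, and the per-fold ranks are aggregated by mean; the top ``k`` per
tissue (default 5) by aggregate rank are selected, with deterministic
lexicographic tie-breaks.

The reference matrix holds the mean beta of each selected CpG per tissue in
the training samples; a query sample's proportions are the non-negative
least-squares (NNLS) coefficients over the shared (non-missing) rows,
normalised to sum to one.  An external atlas with finer classes can be used
the same way after restriction to the sample's retained CpGs, with post-hoc
grouping of class proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _scipy_nnls

from .array_core import TissuePanel

__all__ = [
    "MarkerSelection",
    "DeconvResult",
    "score_cpg",
    "score_table",
    "select_markers",
    "build_reference",
    "nnls_deconvolve",
    "deconvolve_with_external_atlas",
]

_SUM_TOL = 1e-6   # below this total NNLS mass the mixture is undetermined


@dataclass
class MarkerSelection:
    """Per-tissue ordered marker lists plus the fold-aggregation record."""

    markers: dict[str, list[str]]          # tissue -> top-k probe ids
    k: int
    n_folds: int
    lam: float
    mean_ranks: pd.DataFrame | None = None  # candidates x tissues

    def all_markers(self) -> list[str]:
        """Deduplicated union of selected CpGs, sorted."""
        out: set[str] = set()
        for ids in self.markers.values():
            out.update(ids)
        return sorted(out)


@dataclass
class DeconvResult:
    """NNLS mixture estimate: raw coefficients, proportions, residual."""

    coefficients: pd.Series
    proportions: pd.Series
    residual: float
    undetermined: bool
    n_cpgs: int

    @property
    def argmax(self) -> str | None:
        if self.undetermined:
            return None
        return str(self.proportions.idxmax())


def _group_stats(betas: np.ndarray, in_group: np.ndarray):
    g = betas[in_group]
    r = betas[~in_group]
    return g.mean(axis=0), g.std(axis=0, ddof=1), r.mean(axis=0), r.std(axis=0, ddof=1)


def score_cpg(panel: TissuePanel, cpg: str, tissue: str, lam: float = 1.0
              ) -> tuple[float, float, float]:
    """(delta_mean, pooled_sd, score) for one CpG and one target tissue."""
    t = score_table(panel, tissue, candidates=[cpg], lam=lam)
    row = t.iloc[0]
    return float(row["delta_mean"]), float(row["pooled_sd"]), float(row["score"])


def score_table(panel: TissuePanel, tissue: str, candidates=None,
                lam: float = 1.0) -> pd.DataFrame:
    """Vectorised one-vs-rest scores for every candidate CpG.

    delta_mean = |mean_t - mean_rest|; pooled_sd = (sd_t + sd_rest) / 2;
    score = delta_mean - lam * pooled_sd.  Requires >= 2 samples in the
    target group and in the rest.
    """
    if tissue not in set(panel.meta["tissue"]):
        raise KeyError(f"unknown tissue {tissue!r}")
    cols = panel.betas.columns if candidates is None else pd.Index(candidates)
    betas = panel.betas[cols].to_numpy(dtype=float)
    in_group = (panel.meta["tissue"] == tissue).to_numpy()
    if in_group.sum() < 2 or (~in_group).sum() < 2:
        raise ValueError(f"tissue {tissue!r} needs >= 2 samples in each group")
    mt, st, mr, sr = _group_stats(betas, in_group)
    delta = np.abs(mt - mr)
    pooled = (st + sr) / 2.0
    return pd.DataFrame(
        {"delta_mean": delta, "pooled_sd": pooled, "score": delta - lam * pooled},
        index=cols,
    )


def _stratified_folds(meta: pd.DataFrame, n_folds: int, rng: np.random.Generator
                      ) -> np.ndarray:
    """Fold index per sample, stratified so every tissue spans the folds."""
    fold = np.empty(len(meta), dtype=int)
    for t in meta["tissue"].unique():
        idx = np.flatnonzero((meta["tissue"] == t).to_numpy())
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def select_markers(panel: TissuePanel, k: int = 5, n_folds: int = 10,
                   lam: float = 1.0, seed: int = 0,
                   candidates=None) -> MarkerSelection:
    """Cross-validated top-k marker CpGs per tissue from the training split.

    ``candidates`` restricts the search (e.g. to the retained CpG set of the
    degraded query sample); CpGs with any missing beta among the training
    samples are excluded.  If some tissue has fewer samples than folds the
    fold count is reduced with a warning, never silently.
    """
    train = panel.subset("train") if (panel.meta["split"] != "train").any() else panel
    cols = train.betas.columns if candidates is None else pd.Index(
        [c for c in candidates if c in train.betas.columns])
    complete = ~train.betas[cols].isna().any(axis=0)
    cols = cols[complete.to_numpy()]
    if len(cols) == 0:
        raise ValueError("no complete candidate CpGs to select from")

    counts = train.meta["tissue"].value_counts()
    min_n = int(counts.min())
    if min_n < n_folds:
        warnings.warn(
            f"smallest tissue has {min_n} training samples; reducing folds "
            f"from {n_folds} to {min_n}", stacklevel=2)
        n_folds = min_n
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(train.meta, n_folds, rng)

    tissues = sorted(train.meta["tissue"].unique())
    rank_sum = {t: np.zeros(len(cols)) for t in tissues}
    for fi in range(n_folds):
        keep = fold != fi
        sub = TissuePanel(train.betas.loc[keep, cols], train.meta.loc[keep],
                          truth=None)
        for t in tissues:
            s = score_table(sub, t, lam=lam)["score"]
            # rank 0 = best; lexicographic probe_id as the deterministic tie-break
            order = sorted(range(len(cols)), key=lambda i: (-s.iloc[i], cols[i]))
            r = np.empty(len(cols))
            r[order] = np.arange(len(cols))
            rank_sum[t] += r

    mean_ranks = pd.DataFrame(
        {t: rank_sum[t] / n_folds for t in tissues}, index=cols)
    markers = {}
    for t in tissues:
        mr = mean_ranks[t]
        order = sorted(cols, key=lambda c: (mr[c], c))
        markers[t] = list(order[: min(k, len(cols))])
    return MarkerSelection(markers=markers, k=k, n_folds=n_folds, lam=lam,
                           mean_ranks=mean_ranks)


def build_reference(panel: TissuePanel, selection: MarkerSelection) -> pd.DataFrame:
    """Reference matrix: rows = selected CpGs (deduplicated), columns = tissues.

    Entry (c, t) is the mean beta of CpG c over training samples of tissue t.
    Selected CpGs with missing training betas are dropped with a warning.
    """
    train = panel.subset("train") if (panel.meta["split"] != "train").any() else panel
    rows = selection.all_markers()
    missing = [c for c in rows if c not in train.betas.columns]
    if missing:
        raise KeyError(f"selected CpGs not in panel: {missing[:5]}")
    sub = train.betas[rows]
    incomplete = sub.columns[sub.isna().any(axis=0)].tolist()
    if incomplete:
        warnings.warn(f"dropping {len(incomplete)} selected CpG(s) with "
                      f"missing training betas", stacklevel=2)
        sub = sub.drop(columns=incomplete)
    ref = sub.groupby(train.meta["tissue"]).mean().T
    ref.columns.name = None
    return ref


def nnls_deconvolve(ref: pd.DataFrame, sample_beta: pd.Series) -> DeconvResult:
    """Non-negative least-squares mixture estimate over the shared rows.

    Rows of the reference with a missing sample beta are dropped pairwise.
    Proportions are the coefficients normalised to sum to one; the result is
    flagged undetermined when the total coefficient mass is below tolerance.
    """
    shared = ref.index.intersection(sample_beta.index)
    b = sample_beta.reindex(shared)
    keep = b.notna()
    shared = shared[keep.to_numpy()]
    if len(shared) == 0:
        raise ValueError("no shared CpGs between reference and sample")
    A = ref.loc[shared].to_numpy(dtype=float)
    y = sample_beta.reindex(shared).to_numpy(dtype=float)
    x, rnorm = _scipy_nnls(A, y)
    coeffs = pd.Series(x, index=ref.columns)
    total = float(x.sum())
    undetermined = total < _SUM_TOL
    props = coeffs / total if not undetermined else coeffs * np.nan
    return DeconvResult(coefficients=coeffs, proportions=props,
                        residual=float(rnorm), undetermined=undetermined,
                        n_cpgs=len(shared))


def deconvolve_with_external_atlas(atlas: pd.DataFrame, sample_beta: pd.Series,
                                   group_map: dict[str, str] | None = None
                                   ) -> DeconvResult:
    """Deconvolve against an external multi-class atlas, then group classes.

    The atlas (rows = CpGs, columns = classes) is restricted to the CpGs
    present and non-missing in the sample; NNLS runs on the intersection and
    the class proportions are summed per group of ``group_map`` afterwards
    (e.g. blood subtypes -> "Leukocytes", remainder -> "Other").
    """
    shared = atlas.index.intersection(sample_beta.dropna().index)
    if len(shared) == 0:
        raise ValueError("no atlas CpGs among the sample's retained set")
    res = nnls_deconvolve(atlas.loc[shared], sample_beta)
    if not group_map:
        return res
    groups = pd.Series({c: group_map.get(c, c) for c in atlas.columns})
    coeffs = res.coefficients.groupby(groups).sum()
    props = (res.proportions.groupby(groups).sum()
             if not res.undetermined else coeffs * np.nan)
    return DeconvResult(coefficients=coeffs, proportions=props,
                        residual=res.residual, undetermined=res.undetermined,
                        n_cpgs=res.n_cpgs)
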
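"""Reduced epigenetic-age predictor and detection-rate sex inference.

When only a small minority of array probes survive the detection filter of a
degraded sample, published clock coefficients cannot be applied directly:
the clock is instead *retrained* on the intersection of its CpGs with the
sample's retained set, as a plain multivariable linear model of
chronological age on betas (no log-linear age transform), using the
reference panel's training split.  Diagnostics (R^2 on the train and
validation splits) travel with the model.

Sex is called from chromosome-wise detection rates: on a female array the Y
probes carry background only, so the fraction of detected CpGs is much
higher on X than on Y; conventional intensity-based sex predictors are not
applicable to the reduced probe set.  The rule uses
``r = d_X / (d_X + d_Y)`` over all type I probes (before allosome removal):
female if r >= 0.75, male if r <= 0.6, indeterminate between.  The cutoffs
are package defaults for a qualitative rule and are always reported with
the call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .array_core import ProbeManifest, TissuePanel

__all__ = [
    "AgeModel",
    "AgePrediction",
    "SexCall",
    "intersect_clock",
    "train_age_model",
    "predict_age",
    "infer_sex",
]


@dataclass
class AgeModel:
    """Linear age predictor: age = intercept + sum(coef_i * beta_i)."""

    cpg_ids: list[str]
    intercept: float
    coefficients: list[float]
    r2_train: float
    r2_validation: float | None = None
    rmse_validation: float | None = None
    n_train: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AgeModel":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class AgePrediction:
    years: float
    clipped: bool   # True if the raw affine prediction was negative


@dataclass(frozen=True)
class SexCall:
    d_x: float
    d_y: float
    ratio: float
    label: str                      # female | male | indeterminate
    female_cutoff: float
    male_cutoff: float
    n_x_probes: int
    n_y_probes: int


def intersect_clock(clock_cpgs, retained) -> list[str]:
    """Order-preserving intersection of a clock's CpGs with the retained set.

    Raises if empty: the reduced model is untrainable without any clock CpG.
    """
    retained_set = set(retained)
    out = [c for c in clock_cpgs if c in retained_set]
    if not out:
        raise ValueError("no clock CpGs among the retained set; "
                         "reduced age model is untrainable")
    return out


def _r2(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def train_age_model(panel: TissuePanel, cpg_subset) -> AgeModel:
    """OLS of chronological age on the betas of ``cpg_subset`` (train split).

    Raw (untransformed) age is regressed; R^2 is reported on the train and,
    when present, validation split.  Errors on too few samples
    (n_train <= k + 1) and on rank-deficient designs, naming the collinear
    CpGs.
    """
    cpgs = list(cpg_subset)
    k = len(cpgs)
    if k < 1:
        raise ValueError("need at least one CpG")
    train = panel.subset("train")
    missing = [c for c in cpgs if c not in panel.betas.columns]
    if missing:
        raise KeyError(f"CpG(s) not in panel: {missing}")
    Xt = train.betas[cpgs].to_numpy(dtype=float)
    if np.isnan(Xt).any():
        raise ValueError("missing betas at the clock subset in training samples")
    n = Xt.shape[0]
    if n <= k + 1:
        raise ValueError(f"too few training samples: n={n} <= k+1={k + 1}")
    design = np.column_stack([np.ones(n), Xt])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the offending columns: those whose removal restores full rank
        collinear = [
            cpgs[j] for j in range(k)
            if np.linalg.matrix_rank(np.delete(design, j + 1, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear CpGs: {collinear}")
    y = train.meta["age"].to_numpy(dtype=float)
    w, *_ = np.linalg.lstsq(design, y, rcond=None)
    r2_train = _r2(y, design @ w)

    r2_val = rmse_val = None
    val = panel.meta["split"] == "validation"
    if val.any():
        Xv = panel.betas.loc[val, cpgs].to_numpy(dtype=float)
        if not np.isnan(Xv).any():
            yv = panel.meta.loc[val, "age"].to_numpy(dtype=float)
            yhat = np.column_stack([np.ones(len(yv)), Xv]) @ w
            r2_val = _r2(yv, yhat)
            rmse_val = float(np.sqrt(np.mean((yv - yhat) ** 2)))
    return AgeModel(cpg_ids=cpgs, intercept=float(w[0]),
                    coefficients=[float(c) for c in w[1:]],
                    r2_train=float(r2_train),
                    r2_validation=None if r2_val is None else float(r2_val),
                    rmse_validation=rmse_val, n_train=n)


def predict_age(model: AgeModel, betas) -> AgePrediction:
    """Affine prediction from a beta vector; negative ages clip to 0 (flagged).

    ``betas`` is a mapping/Series over probe ids; every model CpG must be
    present and non-missing, otherwise a KeyError lists what is absent.
    """
    b = pd.Series(betas)
    missing = [c for c in model.cpg_ids if c not in b.index or pd.isna(b[c])]
    if missing:
        raise KeyError(f"missing beta(s) for model CpG(s): {missing}")
    raw = model.intercept + float(
        np.dot(model.coefficients, b[model.cpg_ids].to_numpy(dtype=float)))
    if raw < 0:
        return AgePrediction(years=0.0, clipped=True)
    return AgePrediction(years=raw, clipped=False)


def infer_sex(det_row: pd.Series, manifest: ProbeManifest,
              threshold: float = 0.01, female_cutoff: float = 0.75,
              male_cutoff: float = 0.6, min_probes: int = 20) -> SexCall:
    """Sex call from X/Y detection fractions over type I probes.

    d_X, d_Y = detected fraction (p < threshold) among all type I probes on
    that chromosome (computed before allosome removal, on the same type I
    basis as the rest of the pipeline); r = d_X / (d_X + d_Y).
    """
    man = manifest.df.reindex(det_row.index)
    type_i = man["design_type"] == "I"
    on_x = type_i & (man["chromosome"] == "X")
    on_y = type_i & (man["chromosome"] == "Y")
    n_x, n_y = int(on_x.sum()), int(on_y.sum())
    if n_x < min_probes or n_y < min_probes:
        raise ValueError(
            f"too few allosomal type I probes (X: {n_x}, Y: {n_y}, "
            f"need >= {min_probes} each)")
    d_x = float((det_row[on_x] < threshold).mean())
    d_y = float((det_row[on_y] < threshold).mean())
    denom = d_x + d_y
    ratio = d_x / denom if denom > 0 else 0.5
    if ratio >= female_cutoff:
        label = "female"
    elif ratio <= male_cutoff:
        label = "male"
    else:
        label = "indeterminate"
    return SexCall(d_x=d_x, d_y=d_y, ratio=ratio, label=label,
                   female_cutoff=female_cutoff, male_cutoff=male_cutoff,
                   n_x_probes=n_x, n_y_probes=n_y)
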
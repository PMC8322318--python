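"""Background correction, detection p-values, and the stringent probe filter.

This is the computational core of the degraded-sample pipeline:

1.  Per-sample, per-channel normal + exponential (normexp) background
    parameters are estimated by moments from the out-of-band (OOB) values of
    type I probes: the OOB measurements are background-only by design, so
    their mean/sd give the Normal background, and the in-band excess over
    that mean gives the Exponential signal scale.  This is a single-sample,
    moment-based rendering of the noob family of corrections.
2.  Each in-band intensity is replaced by the conditional expectation
    E[S | X = x] of the true signal under the normexp convolution,
    ``m + sigma * phi(m/sigma) / Phi(m/sigma)`` with
    ``m = x - mu - sigma^2 / alpha`` — strictly positive and strictly
    increasing in x.
3.  Detection p-values follow the out-of-band empirical-null approach
    (pOOBAH): a probe's raw in-band total M + U is ranked against the pooled
    per-probe OOB totals of the sample (per colour channel; type II probes
    use the combined null), with a pseudo-count so that p in (0, 1].  Raw
    intensities are used for detection, corrected intensities for betas,
    mirroring the division of labour between detection masking and
    background correction in standard array pipelines.
4.  The strict filter retains type I probes with p < threshold and then
    removes X/Y-chromosome and SNP-associated CpGs.  Type II probes are
    never retained: without usable normalization-control signal their
    between-channel dye bias cannot be corrected in a degraded sample.

The whole module is deterministic (no RNG).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .array_core import (
    DetectionMatrix, IntensitySet, ProbeManifest, compute_beta,
    DEFAULT_BETA_OFFSET,
)

__all__ = [
    "SIGMA_FLOOR",
    "ALPHA_FLOOR",
    "NormexpParams",
    "FilterReport",
    "estimate_normexp_params",
    "normexp_correct",
    "oob_null_totals",
    "poobah_pvalue",
    "detection_pvalues",
    "apply_strict_filter",
    "preprocess_sample",
]

SIGMA_FLOOR = 1.0   # intensity units; numerical stability on degenerate input
ALPHA_FLOOR = 1.0

# corrected intensities are floored here if the conditional expectation
# underflows (flagged in NormexpParams usage sites)
_CORRECTED_FLOOR = 1e-6


@dataclass(frozen=True)
class NormexpParams:
    """Background mean/sd and exponential signal mean for one channel."""

    mu: float
    sigma: float
    alpha: float

    def __post_init__(self):
        if self.sigma < SIGMA_FLOOR or self.alpha < ALPHA_FLOOR:
            raise ValueError("sigma/alpha below their floors")


@dataclass
class FilterReport:
    """Outcome of the strict probe filter for one sample."""

    sample_id: str
    threshold: float
    n_typeI_detected: int
    n_typeII_detected: int
    n_after_xy_snp_removal: int
    retained: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.n_after_xy_snp_removal > self.n_typeI_detected:
            raise ValueError("allosome/SNP removal cannot add probes")
        self.retained = sorted(self.retained)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "threshold": self.threshold,
            "n_typeI_detected": self.n_typeI_detected,
            "n_typeII_detected": self.n_typeII_detected,
            "n_after_xy_snp_removal": self.n_after_xy_snp_removal,
            "retained": self.retained,
        }


def estimate_normexp_params(oob_values, inband_values,
                            sigma_floor: float = SIGMA_FLOOR,
                            alpha_floor: float = ALPHA_FLOOR) -> NormexpParams:
    """Moment estimates of the normexp parameters from OOB and in-band values.

    mu, sigma = mean and sd of the OOB (background-only) values, sigma floored;
    alpha = max(mean(inband) - mu, alpha_floor).  Requires >= 2 OOB values.
    """
    oob = np.asarray(oob_values, dtype=float)
    inband = np.asarray(inband_values, dtype=float)
    if oob.size < 2:
        raise ValueError("need at least 2 OOB values to estimate background")
    mu = float(oob.mean())
    sigma = max(float(oob.std(ddof=1)), sigma_floor)
    alpha = max(float(inband.mean()) - mu, alpha_floor)
    return NormexpParams(mu=mu, sigma=sigma, alpha=alpha)


def normexp_correct(x, params: NormexpParams):
    """Conditional expectation E[S | X = x] under the normexp convolution.

    ``m + sigma * phi(m/sigma)/Phi(m/sigma)`` with
    ``m = x - mu - sigma**2/alpha``; evaluated in log space for stability in
    the deep lower tail.  Result is positive and strictly increasing in x;
    underflowed values are floored at a small positive constant.
    """
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("intensities must be >= 0")
    m = x - params.mu - params.sigma**2 / params.alpha
    z = m / params.sigma
    ratio = np.exp(norm.logpdf(z) - norm.logcdf(z))   # phi/Phi, stable
    out = m + params.sigma * ratio
    out = np.where(np.isfinite(out) & (out > 0), out, _CORRECTED_FLOOR)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# pOOBAH detection
# ---------------------------------------------------------------------------

def _opposite(channel: str) -> str:
    return "Red" if channel == "Grn" else "Grn"


def oob_null_totals(intens: IntensitySet) -> dict[str, np.ndarray]:
    """Per-channel empirical null: sorted per-probe OOB totals (M_oob + U_oob).

    The OOB measurement of a type I probe lives in the channel opposite to
    its design channel, so the null for channel ``c`` comes from type I
    probes designed for the other channel.  Totals (not individual values)
    are pooled so that the null statistic matches the in-band statistic
    M + U — a sum of two draws — and the p-values are calibrated under pure
    background.
    """
    man = intens.manifest.df.reindex(intens.df.index)
    type_i = man["design_type"] == "I"
    totals = intens.df["M_oob"] + intens.df["U_oob"]
    null = {}
    for c in ("Grn", "Red"):
        vals = totals[type_i & (man["channel"] == _opposite(c))].to_numpy()
        null[c] = np.sort(vals)
    null["both"] = np.sort(np.concatenate([null["Grn"], null["Red"]]))
    return null


def poobah_pvalue(total_inband, oob_null_sorted: np.ndarray):
    """Empirical detection p-value p = (1 + #{null >= total}) / (N + 1).

    ``oob_null_sorted`` must be sorted ascending and non-empty.  Ties count
    as >= (conservative); the pseudo-count keeps p in (0, 1].
    """
    null = np.asarray(oob_null_sorted, dtype=float)
    if null.size == 0:
        raise ValueError("empty OOB null")
    t = np.asarray(total_inband, dtype=float)
    n_ge = null.size - np.searchsorted(null, t, side="left")
    p = (1.0 + n_ge) / (null.size + 1.0)
    return float(p) if p.ndim == 0 else p


def detection_pvalues(intens: IntensitySet) -> pd.Series:
    """pOOBAH detection p-values for every probe of one sample (raw totals)."""
    null = oob_null_totals(intens)
    man = intens.manifest.df.reindex(intens.df.index)
    total = intens.total_inband().to_numpy()
    p = np.empty(len(man))
    for c in ("Grn", "Red"):
        sel = ((man["design_type"] == "I") & (man["channel"] == c)).to_numpy()
        if sel.any():
            p[sel] = poobah_pvalue(total[sel], null[c])
    sel2 = (man["design_type"] == "II").to_numpy()
    if sel2.any():
        p[sel2] = poobah_pvalue(total[sel2], null["both"])
    return pd.Series(p, index=intens.df.index, name=intens.sample_id)


# ---------------------------------------------------------------------------
# strict filter
# ---------------------------------------------------------------------------

def apply_strict_filter(det: DetectionMatrix, manifest: ProbeManifest,
                        threshold: float = 0.01,
                        sample_id: str | None = None) -> FilterReport:
    """The stringent probe filter for one sample.

    Retained = type I probes with p < threshold, minus X/Y-chromosome and
    SNP-associated probes.  Detected counts are reported for both designs
    before the removal step.
    """
    if sample_id is None:
        if len(det.values.index) != 1:
            raise ValueError("sample_id required for multi-sample matrices")
        sample_id = det.values.index[0]
    if sample_id not in det.values.index:
        raise KeyError(f"unknown sample {sample_id!r}")
    p = det.values.loc[sample_id]
    man = manifest.df.reindex(p.index)
    detected = p < threshold
    type_i = man["design_type"] == "I"
    n_i = int((detected & type_i).sum())
    n_ii = int((detected & ~type_i).sum())
    keep = detected & type_i & ~man["chromosome"].isin(["X", "Y"]) & ~man["snp_associated"]
    return FilterReport(
        sample_id=sample_id, threshold=threshold,
        n_typeI_detected=n_i, n_typeII_detected=n_ii,
        n_after_xy_snp_removal=int(keep.sum()),
        retained=p.index[keep].tolist(),
    )


def preprocess_sample(intens: IntensitySet, manifest: ProbeManifest,
                      offset: float = DEFAULT_BETA_OFFSET,
                      threshold: float = 0.01,
                      ) -> tuple[pd.Series, pd.Series, FilterReport]:
    """Full single-sample preprocessing: correct, beta, detect, filter.

    Per channel, normexp parameters are estimated from the sample's own OOB
    values; M and U are corrected with the parameters of the channel they
    were measured in (type I: both in the design channel; type II: M in Grn,
    U in Red).  Betas use corrected intensities; detection uses raw totals
    against the raw OOB null.  Betas of non-retained probes are set to
    missing (NaN).

    Returns ``(beta_row, detection_row, FilterReport)``.
    """
    man = manifest.df.reindex(intens.df.index)
    type_i = (man["design_type"] == "I").to_numpy()
    is_grn = (man["channel"] == "Grn").to_numpy()
    is_red = (man["channel"] == "Red").to_numpy()
    M = intens.df["M_inband"].to_numpy()
    U = intens.df["U_inband"].to_numpy()
    M_oob = intens.df["M_oob"].to_numpy()
    U_oob = intens.df["U_oob"].to_numpy()

    params = {}
    for c in ("Grn", "Red"):
        opp = (man["channel"] == _opposite(c)).to_numpy()
        oob_vals = np.concatenate([M_oob[opp & type_i], U_oob[opp & type_i]])
        own = (type_i & (is_grn if c == "Grn" else is_red))
        inband_vals = np.concatenate(
            [M[own], U[own], M[~type_i] if c == "Grn" else U[~type_i]]
        )
        params[c] = estimate_normexp_params(oob_vals, inband_vals)

    Mc = np.empty_like(M)
    Uc = np.empty_like(U)
    for c, sel in (("Grn", is_grn & type_i), ("Red", is_red & type_i)):
        Mc[sel] = normexp_correct(M[sel], params[c])
        Uc[sel] = normexp_correct(U[sel], params[c])
    Mc[~type_i] = normexp_correct(M[~type_i], params["Grn"])
    Uc[~type_i] = normexp_correct(U[~type_i], params["Red"])

    beta = pd.Series(compute_beta(Mc, Uc, offset), index=intens.df.index,
                     name=intens.sample_id)
    det = detection_pvalues(intens)
    dm = DetectionMatrix(det.to_frame().T, threshold=threshold)
    report = apply_strict_filter(dm, manifest, threshold=threshold,
                                 sample_id=intens.sample_id)
    masked = beta.copy()
    masked[~masked.index.isin(report.retained)] = np.nan
    return masked, det, report
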
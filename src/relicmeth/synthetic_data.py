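"""Synthetic BeadChip data with the statistical structure the pipeline assumes.

The generator emulates, at desk scale, the data regime of a methylation study
on severely degraded (mummified) tissue:

* a labelled reference panel of beta-value profiles over nine tissues, with a
  bimodal baseline beta distribution, planted tissue-marker CpGs, planted
  age-linear CpGs (the stand-in for a reduced multi-tissue epigenetic clock),
  and sex structure on the X/Y probes;
* an inverse measurement model turning betas into two-channel probe
  intensities under the normal + exponential (normexp) convolution: true
  signal ~ Exponential, observed = signal share + Normal background truncated
  at zero, with background-only out-of-band values for type I probes;
* a degradation model with a single parameter ``f`` (signal_fraction): each
  probe independently retains its full-scale signal with probability ``f``
  and is background-only otherwise.  A degraded array therefore shows
  overall extremely low intensities while the minority of surviving probes
  still carries clean low/high methylation signal — the regime observed on
  real degraded specimens, where the detection-filtered subset recovers the
  bimodal beta distribution.  (A pure-attenuation model, T ~ Exp(alpha * f),
  cannot do this: by memorylessness the detected probes then sit just above
  the detection bound and their betas are compressed toward mid-range.);
* damage-bearing synthetic aligned reads with 5'-enriched C->T conversions
  decaying geometrically with read position.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .array_core import ProbeManifest, IntensitySet, TissuePanel

__all__ = [
    "TISSUES9",
    "PanelConfig",
    "SignalConfig",
    "DamageConfig",
    "MummyPreset",
    "PRESETS",
    "PanelTruth",
    "simulate_panel",
    "simulate_sample_betas",
    "betas_to_intensities",
    "intensities_from_betas",
    "degrade_sample",
    "simulate_reads",
]

#: The nine tissue classes of the reference-panel setting.
TISSUES9 = ("blood", "brain", "gut", "heart", "kidney", "liver", "lung", "muscle", "skin")


@dataclass(frozen=True)
class PanelConfig:
    """Configuration of the synthetic reference panel.

    Marker CpGs are hypo- or hyper-methylated in their target tissue
    (means 0.15 vs 0.85, alternating direction).  Age CpGs are linear in age,
    ``beta = clip(intercept + slope * age)``, with alternating slope sign so
    that betas span [0.2, 0.8] over the default 20-80 year age range.  Noise
    is added on the logit scale (sd ``beta_noise_sd``; age CpGs use the
    larger ``age_noise_sd``, sized so that a reduced clock trained on a
    handful of these CpGs reaches only a moderate validation R^2, the regime
    reported for severely reduced clocks) and clipped to [0.001, 0.999].
    """

    n_tissues: int = 9
    samples_per_tissue: int = 15
    n_probes: int = 6000
    frac_type_I: float = 0.5
    n_markers_per_tissue: int = 50
    n_age_cpgs: int = 7
    age_slope: float = 0.01          # beta units per year, alternating sign
    n_x_probes: int = 800
    n_y_probes: int = 800
    baseline_beta_mix: tuple = ((0.5, 8.0), (8.0, 0.5), 0.5)  # (a1,b1),(a2,b2),w1
    beta_noise_sd: float = 0.3       # logit-scale
    age_noise_sd: float = 1.5        # logit-scale, age CpGs only
    snp_fraction: float = 0.05
    marker_low: float = 0.15
    marker_high: float = 0.85
    age_range: tuple = (20.0, 80.0)
    train_fraction: float = 2 / 3
    seed: int = 0

    def __post_init__(self):
        planted = self.n_tissues * self.n_markers_per_tissue + self.n_age_cpgs
        n_auto = self.n_probes - self.n_x_probes - self.n_y_probes
        n_auto_type_i = int(round(self.frac_type_I * n_auto))
        if planted > n_auto_type_i:
            raise ValueError(
                f"planted CpG sets ({planted}) exceed the available autosomal "
                f"type I probes ({n_auto_type_i})"
            )
        for name in ("frac_type_I", "snp_fraction", "marker_low", "marker_high",
                     "train_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class SignalConfig:
    """Intensity measurement model: observed = true signal + background.

    True signal is Exponential with mean ``mean_true_signal`` for the
    fraction ``signal_fraction`` of probes that survive degradation and zero
    for the rest; background is Normal(``bg_mean``, ``bg_sd``^2) truncated
    at 0.  The default signal scale is set so that an intact sample
    (``signal_fraction = 1``) passes the detection filter at > 95 % of
    type I probes, as on a good array.
    """

    mean_true_signal: float = 10_000.0
    bg_mean: float = 500.0
    bg_sd: float = 100.0
    signal_fraction: float = 1.0

    def __post_init__(self):
        if min(self.mean_true_signal, self.bg_mean, self.bg_sd) <= 0:
            raise ValueError("mean_true_signal, bg_mean, bg_sd must be > 0")
        if not 0 <= self.signal_fraction <= 1:
            raise ValueError("signal_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class DamageConfig:
    """Post-mortem C->T deamination profile for synthetic reads.

    Conversion probability at 1-based 5' offset ``i`` is ``p0 * decay**(i-1)``.
    """

    p0: float = 0.045
    decay: float = 0.5
    read_length: int = 50
    n_reads: int = 2000
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.p0 <= 1 or not 0 <= self.decay <= 1:
            raise ValueError("p0 and decay must lie in [0, 1]")


@dataclass(frozen=True)
class MummyPreset:
    """Named degradation regime: signal fraction + damage profile."""

    signal_fraction: float
    damage: DamageConfig
    tissue: str
    age: float
    sex: str


#: The two degraded-specimen presets.  "TH" targets ~17 % type I probe
#: detection, the observed regime of the recoverable specimen (23,875 of the
#: ~142k type I assays on the platform passed the filter; lung tissue of a
#: 28-year-old woman); "ACB" is near-total signal loss (gut tissue, analysis
#: expected to stop after filtering).  Damage rates are the two observed
#: 5'-terminal C->T frequencies, 0.045 and 0.012.
PRESETS: dict[str, MummyPreset] = {
    "TH": MummyPreset(signal_fraction=0.192, damage=DamageConfig(p0=0.045),
                      tissue="lung", age=28.0, sex="female"),
    "ACB": MummyPreset(signal_fraction=0.001, damage=DamageConfig(p0=0.012),
                       tissue="gut", age=68.0, sex="female"),
}


@dataclass
class PanelTruth:
    """Generating ground truth of a simulated panel (per-probe parameters)."""

    config: PanelConfig
    manifest: ProbeManifest
    baseline_beta: pd.Series               # per probe
    markers: dict[str, list[str]]          # tissue -> planted marker probe ids
    marker_low_in_target: pd.Series        # bool per marker probe
    age_cpgs: list[str]
    age_slopes: pd.Series                  # per age CpG, beta units / year
    age_intercepts: pd.Series

    def marker_target_mean(self, tissue: str) -> pd.Series:
        """Expected beta at each planted marker for a sample of ``tissue``."""
        cfg = self.config
        vals = {}
        for t, ids in self.markers.items():
            for pid in ids:
                low = self.marker_low_in_target[pid]
                if t == tissue:
                    vals[pid] = cfg.marker_low if low else cfg.marker_high
                else:
                    vals[pid] = cfg.marker_high if low else cfg.marker_low
        return pd.Series(vals)


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _make_manifest(cfg: PanelConfig, rng: np.random.Generator) -> tuple[ProbeManifest, dict]:
    n_auto = cfg.n_probes - cfg.n_x_probes - cfg.n_y_probes
    chroms = (
        [str(rng.integers(1, 23)) for _ in range(n_auto)]
        + ["X"] * cfg.n_x_probes + ["Y"] * cfg.n_y_probes
    )
    probe_ids = [f"cg{i:06d}" for i in range(cfg.n_probes)]
    # per-stratum type I assignment keeps the allosomal type I counts on target
    design = np.empty(cfg.n_probes, dtype=object)
    for lo, hi in ((0, n_auto), (n_auto, n_auto + cfg.n_x_probes),
                   (n_auto + cfg.n_x_probes, cfg.n_probes)):
        n = hi - lo
        k = int(round(cfg.frac_type_I * n))
        lab = np.array(["I"] * k + ["II"] * (n - k), dtype=object)
        rng.shuffle(lab)
        design[lo:hi] = lab
    channel = np.where(design == "I",
                       rng.choice(["Grn", "Red"], size=cfg.n_probes), None)
    position = rng.integers(1, 2**27, size=cfg.n_probes)

    auto_type_i = [i for i in range(n_auto) if design[i] == "I"]
    rng.shuffle(auto_type_i)
    n_markers = cfg.n_tissues * cfg.n_markers_per_tissue
    planted_idx = auto_type_i[: n_markers + cfg.n_age_cpgs]
    free = np.ones(cfg.n_probes, dtype=bool)
    free[planted_idx] = False
    snp = free & (np.arange(cfg.n_probes) < n_auto) & (rng.random(cfg.n_probes) < cfg.snp_fraction)

    df = pd.DataFrame(
        {
            "design_type": design,
            "channel": channel,
            "chromosome": chroms,
            "position": position,
            "snp_associated": snp,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    manifest = ProbeManifest(df)
    layout = {
        "marker_idx": planted_idx[:n_markers],
        "age_idx": planted_idx[n_markers: n_markers + cfg.n_age_cpgs],
    }
    return manifest, layout


def simulate_panel(cfg: PanelConfig) -> tuple[TissuePanel, ProbeManifest]:
    """Simulate a labelled reference panel and its probe manifest.

    Returns a :class:`TissuePanel` (with the generating :class:`PanelTruth`
    attached as ``panel.truth``) and the shared :class:`ProbeManifest`.
    Fully reproducible given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    manifest, layout = _make_manifest(cfg, rng)
    ids = manifest.probe_ids

    (a1, b1), (a2, b2), w1 = cfg.baseline_beta_mix
    comp = rng.random(cfg.n_probes) < w1
    baseline = np.where(comp, rng.beta(a1, b1, cfg.n_probes), rng.beta(a2, b2, cfg.n_probes))
    baseline = pd.Series(baseline, index=ids)

    tissues = list(TISSUES9[: cfg.n_tissues])
    if cfg.n_tissues > len(TISSUES9):
        tissues += [f"tissue{i}" for i in range(len(TISSUES9), cfg.n_tissues)]
    markers: dict[str, list[str]] = {}
    low_flags = {}
    mi = layout["marker_idx"]
    for j, t in enumerate(tissues):
        sl = mi[j * cfg.n_markers_per_tissue: (j + 1) * cfg.n_markers_per_tissue]
        markers[t] = [ids[i] for i in sl]
        for r, i in enumerate(sl):
            low_flags[ids[i]] = (r % 2 == 0)
    age_cpgs = [ids[i] for i in layout["age_idx"]]
    slopes = pd.Series(
        [cfg.age_slope if j % 2 == 0 else -cfg.age_slope for j in range(cfg.n_age_cpgs)],
        index=age_cpgs,
    )
    intercepts = pd.Series(
        [0.0 if j % 2 == 0 else 1.0 for j in range(cfg.n_age_cpgs)], index=age_cpgs
    )
    truth = PanelTruth(
        config=cfg, manifest=manifest, baseline_beta=baseline, markers=markers,
        marker_low_in_target=pd.Series(low_flags), age_cpgs=age_cpgs,
        age_slopes=slopes, age_intercepts=intercepts,
    )

    rows, meta_rows, sample_ids = [], [], []
    lo_age, hi_age = cfg.age_range
    for t in tissues:
        n = cfg.samples_per_tissue
        n_train = max(2, int(round(cfg.train_fraction * n)))
        split = np.array(["train"] * n_train + ["validation"] * (n - n_train), dtype=object)
        rng.shuffle(split)
        for j in range(n):
            age = float(rng.uniform(lo_age, hi_age))
            sex = "female" if j % 2 == 0 else "male"
            sid = f"{t}_{j:02d}"
            rows.append(simulate_sample_betas(truth, t, age, sex, rng))
            meta_rows.append({"tissue": t, "age": age, "sex": sex, "split": split[j]})
            sample_ids.append(sid)
    betas = pd.DataFrame(rows, index=sample_ids)
    meta = pd.DataFrame(meta_rows, index=sample_ids)
    panel = TissuePanel(betas, meta, truth=truth)
    return panel, manifest


def simulate_sample_betas(truth: PanelTruth, tissue: str, age: float, sex: str,
                          rng: np.random.Generator) -> pd.Series:
    """True-beta vector for one sample, with planted structure and logit noise.

    Y-chromosome probes are missing (background-only) for female samples.
    """
    cfg = truth.config
    beta = truth.baseline_beta.copy()
    beta.update(truth.marker_target_mean(tissue))
    age_true = truth.age_intercepts + truth.age_slopes * age
    beta.update(age_true.clip(0.001, 0.999))

    sd = np.full(len(beta), cfg.beta_noise_sd)
    sd[beta.index.get_indexer(truth.age_cpgs)] = cfg.age_noise_sd
    z = _logit(beta.clip(0.001, 0.999).to_numpy()) + rng.normal(0.0, sd)
    vals = np.clip(_sigmoid(z), 0.001, 0.999)
    out = pd.Series(vals, index=beta.index)
    if sex == "female":
        y_ids = truth.manifest.df.index[truth.manifest.df["chromosome"] == "Y"]
        out[y_ids] = np.nan
    return out


# ---------------------------------------------------------------------------
# beta -> intensity inverse measurement model
# ---------------------------------------------------------------------------

def _trunc_normal(rng, mean, sd, size):
    # truncation (not rejection) at 0: negative fluorescence is clipped
    return np.clip(rng.normal(mean, sd, size), 0.0, None)


def intensities_from_betas(betas: pd.Series, manifest: ProbeManifest,
                           sig: SignalConfig, sex: str = "female",
                           sample_id: str = "sample",
                           rng: np.random.Generator | None = None,
                           seed: int | None = None) -> IntensitySet:
    """Draw an :class:`IntensitySet` for one sample from its beta vector.

    Per probe: with probability ``signal_fraction`` the probe survives and
    carries T ~ Exponential(mean_true_signal * scale), else T = 0
    (background-only); methylated share ``beta * T``, unmethylated share
    ``(1 - beta) * T``, plus truncated-Normal background on every measured
    value.  The sex scale is 1 for autosomes; females have background-only Y
    probes (scale 0, matching their missing betas) and males carry X at half
    intensity and Y autosomally (one X / one Y copy against a two-copy
    autosomal baseline).  OOB values of type I probes are background-only
    draws.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    betas = betas.reindex(manifest.probe_ids)
    n = len(manifest)
    chrom = manifest.df["chromosome"].to_numpy()
    scale = np.ones(n)
    if sex == "female":
        scale[chrom == "Y"] = 0.0
    elif sex == "male":
        scale[chrom == "X"] = 0.5
    else:
        raise ValueError(f"unknown sex {sex!r}")

    survives = rng.random(n) < sig.signal_fraction
    mean_t = sig.mean_true_signal * scale * survives
    T = np.where(mean_t > 0, rng.exponential(np.where(mean_t > 0, mean_t, 1.0)), 0.0)
    b = betas.to_numpy(dtype=float)
    b_eff = np.where(np.isnan(b), 0.0, b)
    T = np.where(np.isnan(b), 0.0, T)  # missing beta == no true signal
    M = np.clip(b_eff * T + rng.normal(sig.bg_mean, sig.bg_sd, n), 0.0, None)
    U = np.clip((1.0 - b_eff) * T + rng.normal(sig.bg_mean, sig.bg_sd, n), 0.0, None)

    type_i = manifest.is_type_i().to_numpy()
    M_oob = np.where(type_i, _trunc_normal(rng, sig.bg_mean, sig.bg_sd, n), np.nan)
    U_oob = np.where(type_i, _trunc_normal(rng, sig.bg_mean, sig.bg_sd, n), np.nan)
    df = pd.DataFrame(
        {"M_inband": M, "U_inband": U, "M_oob": M_oob, "U_oob": U_oob},
        index=manifest.probe_ids,
    )
    return IntensitySet(sample_id, df, manifest)


def betas_to_intensities(panel: TissuePanel, sig: SignalConfig,
                         seed: int = 0) -> dict[str, IntensitySet]:
    """Intensity sets for every sample of a panel (deterministic given seed)."""
    manifest = panel.truth.manifest if panel.truth is not None else None
    if manifest is None:
        raise ValueError("panel carries no manifest (simulate_panel output expected)")
    rng = np.random.default_rng(seed)
    out = {}
    for sid in panel.meta.index:
        out[sid] = intensities_from_betas(
            panel.betas.loc[sid], manifest, sig,
            sex=panel.meta.loc[sid, "sex"], sample_id=sid, rng=rng,
        )
    return out


def degrade_sample(intens: IntensitySet, f: float, seed: int = 0,
                   sig: SignalConfig = SignalConfig()) -> IntensitySet:
    """Degrade a sample: each probe keeps its signal with probability ``f``.

    The signal component is estimated as the excess over the background
    mean; a probe either retains it (probability ``f``) or loses it
    entirely, and fresh background is drawn in both cases; OOB values are
    re-drawn background.  Survival indicators for different ``f`` are nested
    on the same seed stream (one uniform per probe), so the detected
    fraction is non-increasing as ``f`` decreases, while the background
    distribution is unchanged.
    """
    if not 0 <= f <= 1:
        raise ValueError("f must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    df = intens.df
    n = len(df)
    survives = rng.random(n) < f
    signal = np.clip(df[["M_inband", "U_inband"]].to_numpy() - sig.bg_mean, 0.0, None)
    inband = np.clip(survives[:, None] * signal
                     + rng.normal(sig.bg_mean, sig.bg_sd, (n, 2)), 0.0, None)
    type_i = intens.manifest.is_type_i().reindex(df.index).to_numpy()
    M_oob = np.where(type_i, _trunc_normal(rng, sig.bg_mean, sig.bg_sd, n), np.nan)
    U_oob = np.where(type_i, _trunc_normal(rng, sig.bg_mean, sig.bg_sd, n), np.nan)
    out = pd.DataFrame(
        {"M_inband": inband[:, 0], "U_inband": inband[:, 1],
         "M_oob": M_oob, "U_oob": U_oob},
        index=df.index,
    )
    return IntensitySet(intens.sample_id, out, intens.manifest)


# ---------------------------------------------------------------------------
# damage-bearing reads
# ---------------------------------------------------------------------------

def simulate_reads(reference_seq: str, dmg: DamageConfig) -> pd.DataFrame:
    """Aligned synthetic reads with 5' C->T deamination damage.

    Reads of ``read_length`` are copied from uniform start positions of the
    reference; at 1-based 5' offset ``i`` each reference C becomes T with
    probability ``p0 * decay**(i-1)``.  The output is a long table with one
    row per read base: columns ``read_id``, ``pos_5prime``, ``ref_base``,
    ``read_base``, ``strand`` (a deliberate simplification of SAM; all reads
    are forward strand, ungapped).
    """
    if not reference_seq:
        raise ValueError("empty reference sequence")
    L = dmg.read_length
    if len(reference_seq) < L:
        raise ValueError("reference shorter than read_length")
    rng = np.random.default_rng(dmg.seed)
    ref = np.frombuffer(reference_seq.upper().encode(), dtype="S1")
    starts = rng.integers(0, len(ref) - L + 1, size=dmg.n_reads)
    idx = starts[:, None] + np.arange(L)[None, :]
    ref_bases = ref[idx]                                   # n_reads x L
    p = dmg.p0 * dmg.decay ** np.arange(L)                 # per-position rate
    convert = (ref_bases == b"C") & (rng.random((dmg.n_reads, L)) < p)
    read_bases = np.where(convert, b"T", ref_bases)

    n = dmg.n_reads * L
    return pd.DataFrame(
        {
            "read_id": np.repeat([f"read{i:06d}" for i in range(dmg.n_reads)], L),
            "pos_5prime": np.tile(np.arange(1, L + 1), dmg.n_reads),
            "ref_base": ref_bases.reshape(n).astype(str),
            "read_base": read_bases.reshape(n).astype(str),
            "strand": ["+"] * n,
        }
    )
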
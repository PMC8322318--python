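"""End-to-end orchestration: simulate -> preprocess -> deconvolve -> age -> sex.

A single config (dict, or YAML via the CLI) drives the full analysis of one
query sample against a simulated reference panel and produces a
self-describing JSON :class:`RunReport`.  Stage order and every threshold
are fixed by the config; all randomness derives from one seed.

Degraded samples may not support every stage.  The fallback policy mirrors
per-sample analysis of severely degraded specimens: a stage that lacks its
minimum usable CpGs is *skipped with a recorded reason* rather than failing
the run — deconvolution requires at least ``k * n_tissues`` retained
candidate CpGs and at least ``min_reference_rows`` shared reference rows;
the age stage requires a non-empty intersection of the clock CpGs with the
retained set.  A run with skipped stages still exits successfully.
"""

from __future__ import annotations

import datetime
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .array_core import write_beta_matrix
from .synthetic_data import (
    PRESETS, DamageConfig, PanelConfig, SignalConfig,
    intensities_from_betas, simulate_panel, simulate_sample_betas,
    simulate_reads,
)
from .preprocess import preprocess_sample
from .deconvolution import build_reference, nnls_deconvolve, select_markers
from .age_sex import intersect_clock, predict_age, train_age_model, infer_sex
from .embedding import mds_embed, top_variable_cpgs
from .damage import damage_profile

__all__ = ["RunReport", "run_pipeline", "default_config"]

_BASES = np.array(list("ACGT"))


@dataclass
class RunReport:
    """Aggregated, serialisable outcome of one pipeline run."""

    config: dict
    seed: int
    version: str
    filter: dict
    sex: dict | None = None
    deconvolution: dict | None = None
    age: dict | None = None
    mds: dict | None = None
    damage: dict | None = None
    skipped: dict = field(default_factory=dict)   # stage -> reason
    timestamp: str = ""

    def to_dict(self) -> dict:
        return {
            "config": self.config, "seed": self.seed, "version": self.version,
            "filter": self.filter, "sex": self.sex,
            "deconvolution": self.deconvolution, "age": self.age,
            "mds": self.mds, "damage": self.damage, "skipped": self.skipped,
            "timestamp": self.timestamp,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def default_config(preset: str | None = None, seed: int = 0) -> dict:
    """A complete config dict, optionally filled from a named preset."""
    cfg = {
        "seed": seed,
        "panel": {},
        "signal": {},
        "query": {"tissue": "lung", "age": 35.0, "sex": "female",
                  "signal_fraction": 1.0},
        "offset": 100.0,
        "pval_threshold": 0.01,
        "deconv": {"k": 5, "n_folds": 10, "lam": 1.0, "min_reference_rows": 10},
        "sex": {"female_cutoff": 0.75, "male_cutoff": 0.6},
        "mds": {"n_top": 100, "include_query": True},
        "damage": None,
        "out_dir": None,
    }
    if preset is not None:
        name = preset.removesuffix("_synthetic")
        if name not in PRESETS:
            raise KeyError(f"unknown preset {preset!r}")
        p = PRESETS[name]
        cfg["query"] = {"tissue": p.tissue, "age": p.age, "sex": p.sex,
                        "signal_fraction": p.signal_fraction}
        # the planted age CpGs stand in for a full multi-tissue clock
        # signature; only the detected subset survives filtering and the
        # reduced model is retrained on that intersection
        cfg["panel"] = {"n_age_cpgs": 100}
        cfg["damage"] = {"p0": p.damage.p0, "decay": p.damage.decay,
                         "read_length": p.damage.read_length,
                         "n_reads": p.damage.n_reads}
    return cfg


def _validate(config: dict) -> dict:
    cfg = default_config()
    for key, val in config.items():
        if key not in cfg:
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict) and isinstance(val, dict):
            unknown = set(val) - set(cfg[key])
            if unknown and key != "panel" and key != "signal":
                raise ValueError(f"unknown config key(s) {key}.{sorted(unknown)}")
            cfg[key] = {**cfg[key], **val}
        else:
            cfg[key] = val
    if not 0 < cfg["pval_threshold"] <= 1:
        raise ValueError("pval_threshold must lie in (0, 1]")
    if cfg["query"]["sex"] not in ("female", "male"):
        raise ValueError("query sex must be 'female' or 'male'")
    return cfg


def run_pipeline(config: dict) -> RunReport:
    """Execute all stages for one simulated query sample.

    Invalid configs raise before any stage runs; optional-stage failures are
    recorded under ``report.skipped`` and do not abort the run.
    """
    cfg = _validate(config)
    seed = int(cfg["seed"])
    out_dir = Path(cfg["out_dir"]) if cfg["out_dir"] else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    panel_cfg = PanelConfig(**{**cfg["panel"], "seed": seed})
    sig = SignalConfig(**{**cfg["signal"],
                          "signal_fraction": cfg["query"]["signal_fraction"]})
    panel, manifest = simulate_panel(panel_cfg)
    truth = panel.truth

    q = cfg["query"]
    rng = np.random.default_rng(seed + 1)
    query_betas = simulate_sample_betas(truth, q["tissue"], q["age"], q["sex"], rng)
    intens = intensities_from_betas(query_betas, manifest, sig, sex=q["sex"],
                                    sample_id="query", rng=rng)

    beta_row, det_row, freport = preprocess_sample(
        intens, manifest, offset=cfg["offset"], threshold=cfg["pval_threshold"])
    retained = freport.retained
    report = RunReport(
        config=cfg, seed=seed, version=__version__,
        filter={k: v for k, v in freport.to_dict().items() if k != "retained"}
        | {"n_retained": len(retained)},
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )

    sex_call = infer_sex(det_row, manifest, threshold=cfg["pval_threshold"],
                         female_cutoff=cfg["sex"]["female_cutoff"],
                         male_cutoff=cfg["sex"]["male_cutoff"])
    report.sex = {
        "d_x": sex_call.d_x, "d_y": sex_call.d_y, "ratio": sex_call.ratio,
        "label": sex_call.label,
        "female_cutoff": sex_call.female_cutoff,
        "male_cutoff": sex_call.male_cutoff,
    }

    # --- deconvolution --------------------------------------------------
    dc = cfg["deconv"]
    min_candidates = dc["k"] * panel_cfg.n_tissues
    if len(retained) < min_candidates:
        report.skipped["deconvolution"] = (
            f"only {len(retained)} retained CpGs; marker selection needs "
            f">= {min_candidates} (k * n_tissues)")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selection = select_markers(panel, k=dc["k"], n_folds=dc["n_folds"],
                                       lam=dc["lam"], seed=seed + 2,
                                       candidates=retained)
            reference = build_reference(panel, selection)
        shared = reference.index.intersection(beta_row.dropna().index)
        if len(shared) < dc["min_reference_rows"]:
            report.skipped["deconvolution"] = (
                f"only {len(shared)} shared reference rows; need "
                f">= {dc['min_reference_rows']}")
        else:
            res = nnls_deconvolve(reference, beta_row)
            report.deconvolution = {
                "proportions": {t: float(v) for t, v in res.proportions.items()},
                "argmax_tissue": res.argmax,
                "residual": res.residual,
                "n_cpgs": res.n_cpgs,
                "undetermined": res.undetermined,
                "markers": selection.markers,
            }
            if out_dir:
                reference.to_csv(out_dir / "reference_matrix.tsv", sep="\t",
                                 index_label="probe_id")

    # --- age ------------------------------------------------------------
    clock = truth.age_cpgs   # planted age CpGs stand in for the published clock
    try:
        reduced = intersect_clock(clock, retained)
    except ValueError as exc:
        report.skipped["age"] = str(exc)
    else:
        model = train_age_model(panel, reduced)
        pred = predict_age(model, beta_row)
        report.age = {
            "predicted_years": pred.years, "clipped": pred.clipped,
            "n_clock_cpgs": len(clock), "n_used_cpgs": len(reduced),
            "r2_train": model.r2_train, "r2_validation": model.r2_validation,
            "rmse_validation": model.rmse_validation,
            "model": json.loads(model.to_json()),
        }

    # --- MDS ------------------------------------------------------------
    shared_cols = [c for c in retained if c in panel.betas.columns]
    mat = panel.betas[shared_cols]
    if cfg["mds"]["include_query"]:
        mat = pd.concat([mat, beta_row[shared_cols].to_frame("query").T])
    complete = mat.columns[~mat.isna().any(axis=0)]
    if len(complete) < 2 or len(mat) < 3:
        report.skipped["mds"] = "not enough complete CpGs/samples for MDS"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            top = top_variable_cpgs(mat[complete], n_top=cfg["mds"]["n_top"])
            emb = mds_embed(mat, cpg_ids=top)
        coords_path = None
        if out_dir:
            coords_path = str(out_dir / "mds_coords.tsv")
            emb.coordinates.to_csv(coords_path, sep="\t", index_label="sample_id")
        report.mds = {
            "n_cpgs": len(top),
            "eigenvalues_top2": [float(v) for v in emb.eigenvalues[:2]],
            "query_coords": (
                [float(v) for v in emb.coordinates.loc["query"]]
                if cfg["mds"]["include_query"] else None),
            "coords_path": coords_path,
        }

    # --- damage ---------------------------------------------------------
    if cfg["damage"] is not None:
        dmg = DamageConfig(**cfg["damage"], seed=seed + 3)
        ref_rng = np.random.default_rng(seed + 4)
        ref_seq = "".join(ref_rng.choice(_BASES, size=20_000))
        reads = simulate_reads(ref_seq, dmg)
        prof = damage_profile(reads, max_pos=min(25, dmg.read_length))
        report.damage = {
            "p0_config": dmg.p0,
            "freq_c_to_t_pos1": float(prof.loc[1, "freq_c_to_t"]),
            "se_pos1": float(prof.loc[1, "se_c_to_t"]),
            "profile_first10": [float(x) for x in
                                prof["freq_c_to_t"].iloc[:10].fillna(-1.0)],
        }
        if out_dir:
            prof.to_csv(out_dir / "damage_profile.tsv", sep="\t")

    if out_dir:
        write_beta_matrix(beta_row.to_frame().T, out_dir / "query_betas.tsv")
        (out_dir / "report.json").write_text(report.to_json())
    return report
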
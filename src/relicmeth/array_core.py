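"""Domain data model for BeadChip-like methylation data.

Infinium-style arrays interrogate each CpG with one of two probe designs:
type I probes use two bead types (methylated and unmethylated allele) read in
a single colour channel, leaving the opposite channel "out-of-band" (OOB);
type II probes use one bead type read in both channels (green carries the
methylated signal, red the unmethylated signal, by convention).  The OOB
measurements of type I probes are background-only by design and are the
empirical null used downstream for background correction and detection
p-values.

This module defines the validated containers (:class:`ProbeManifest`,
:class:`IntensitySet`, :class:`BetaMatrix`, :class:`DetectionMatrix`,
:class:`TissuePanel`) and readers/writers for the project's tab-separated
dialect: UTF-8, one header row, ``.`` for empty OOB cells, floats written
with at least six significant digits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CHROMOSOMES",
    "AUTOSOMES",
    "DEFAULT_BETA_OFFSET",
    "ProbeManifest",
    "IntensitySet",
    "BetaMatrix",
    "DetectionMatrix",
    "TissuePanel",
    "read_manifest",
    "write_manifest",
    "read_intensities",
    "write_intensities",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_panel",
    "write_panel",
    "compute_beta",
]

#: Closed set of accepted chromosome tokens (no "chr" prefix; 1-based point
#: positions).
AUTOSOMES: frozenset[str] = frozenset(str(i) for i in range(1, 23))
CHROMOSOMES: frozenset[str] = AUTOSOMES | {"X", "Y"}

#: Default offset in the beta formula M / (M + U + offset); the de-facto
#: Illumina convention (used e.g. by minfi).
DEFAULT_BETA_OFFSET: float = 100.0

_FLOAT_FMT = "%.6g"
_MISSING_TOKEN = "."


class ProbeManifest:
    """Probe identities, assay design, channel and genomic annotation.

    Wraps a DataFrame indexed by ``probe_id`` with columns ``design_type``
    (``"I"``/``"II"``), ``channel`` (``"Grn"``/``"Red"`` for type I, ``NA``
    i.e. missing for type II), ``chromosome``, ``position`` (1-based) and
    ``snp_associated`` (bool).  Validation is strict: invalid rows raise
    rather than being coerced.
    """

    def __init__(self, df: pd.DataFrame):
        required = ["design_type", "channel", "chromosome", "position", "snp_associated"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe_id(s): {dupes}")
        if not df["design_type"].isin(["I", "II"]).all():
            bad = sorted(set(df["design_type"]) - {"I", "II"})
            raise ValueError(f"unknown design_type token(s): {bad}")
        type_i = df["design_type"] == "I"
        ch = df["channel"]
        if not ch[type_i].isin(["Grn", "Red"]).all():
            raise ValueError("type I probes must have channel 'Grn' or 'Red'")
        if not ch[~type_i].isna().all():
            bad = df.index[~type_i & ch.notna()].tolist()
            raise ValueError(f"type II probes must have no channel (NA): {bad}")
        unknown = set(df["chromosome"].astype(str)) - CHROMOSOMES
        if unknown:
            raise ValueError(f"unknown chromosome token(s): {sorted(unknown)}")
        pos = df["position"]
        if not (np.issubdtype(pos.dtype, np.integer) or (pos == pos.astype(int)).all()):
            raise ValueError("positions must be integers")
        if (pos < 1).any():
            raise ValueError("positions must be >= 1 (1-based)")
        df = df.copy()
        df["channel"] = df["channel"].astype(object)
        df.loc[~type_i, "channel"] = np.nan  # canonical missing marker
        df["chromosome"] = df["chromosome"].astype(str)
        df["position"] = df["position"].astype(int)
        df["snp_associated"] = df["snp_associated"].astype(bool)
        self.df = df

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    @property
    def type_i_ids(self) -> pd.Index:
        return self.df.index[self.df["design_type"] == "I"]

    @property
    def type_ii_ids(self) -> pd.Index:
        return self.df.index[self.df["design_type"] == "II"]

    def is_type_i(self) -> pd.Series:
        return self.df["design_type"] == "I"

    def allosomal(self) -> pd.Series:
        return self.df["chromosome"].isin(["X", "Y"])

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.df.index


class IntensitySet:
    """Per-sample two-channel probe intensities.

    ``df`` is indexed by probe_id with float columns ``M_inband``,
    ``U_inband``, ``M_oob``, ``U_oob``.  OOB entries are present exactly for
    type I probes (NaN for type II).  All intensities are finite and >= 0,
    in arbitrary fluorescence units.
    """

    def __init__(self, sample_id: str, df: pd.DataFrame, manifest: ProbeManifest):
        required = ["M_inband", "U_inband", "M_oob", "U_oob"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"intensity table missing columns: {missing}")
        unknown = df.index.difference(manifest.probe_ids)
        if len(unknown):
            raise ValueError(f"probe(s) not in manifest: {unknown.tolist()[:5]}")
        df = df[required].astype(float)
        inband = df[["M_inband", "U_inband"]].to_numpy()
        if not np.isfinite(inband).all():
            raise ValueError("in-band intensities must be finite")
        if (inband < 0).any():
            raise ValueError("negative intensity")
        type_i = manifest.is_type_i().reindex(df.index)
        oob = df[["M_oob", "U_oob"]]
        if oob[~type_i].notna().any().any():
            bad = df.index[~type_i & oob.notna().any(axis=1)].tolist()
            raise ValueError(f"OOB value given for type II probe(s): {bad[:5]}")
        if oob[type_i].isna().any().any():
            bad = df.index[type_i & oob.isna().any(axis=1)].tolist()
            raise ValueError(f"missing OOB value for type I probe(s): {bad[:5]}")
        oob_vals = oob[type_i].to_numpy()
        if (oob_vals < 0).any() or not np.isfinite(oob_vals).all():
            raise ValueError("OOB intensities must be finite and >= 0")
        self.sample_id = sample_id
        self.df = df
        self.manifest = manifest

    def total_inband(self) -> pd.Series:
        return self.df["M_inband"] + self.df["U_inband"]


@dataclass
class BetaMatrix:
    """Samples x probes methylation fractions in [0, 1]; NaN marks
    undetected/missing entries (never 0 or 0.5)."""

    values: pd.DataFrame

    def __post_init__(self):
        arr = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (arr < 0) | (arr > 1)
        if np.nansum(bad):
            raise ValueError("beta values must lie in [0, 1] (or be missing)")


@dataclass
class DetectionMatrix:
    """Samples x probes detection p-values in (0, 1]."""

    values: pd.DataFrame
    threshold: float = 0.01

    def __post_init__(self):
        arr = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (arr <= 0) | (arr > 1)
        if np.nansum(bad):
            raise ValueError("detection p-values must lie in (0, 1]")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must lie in (0, 1]")

    def mask(self, threshold: float | None = None) -> pd.DataFrame:
        """Boolean detected mask: p < threshold."""
        t = self.threshold if threshold is None else threshold
        return self.values < t


class TissuePanel:
    """A labelled reference panel: beta matrix plus per-sample metadata.

    ``betas`` is samples x probes; ``meta`` is indexed by sample_id with
    columns ``tissue``, ``age`` (years), ``sex`` (``female``/``male``) and
    ``split`` (``train``/``validation``).  Simulated panels additionally
    carry the generating ground truth in ``truth`` (see
    :mod:`relicmeth.synthetic_data`).
    """

    def __init__(self, betas: pd.DataFrame, meta: pd.DataFrame, truth=None):
        if not betas.index.equals(meta.index):
            raise ValueError("betas and meta must share the same sample index")
        required = ["tissue", "age", "sex", "split"]
        missing = [c for c in required if c not in meta.columns]
        if missing:
            raise ValueError(f"panel metadata missing columns: {missing}")
        if meta[required].isna().any().any():
            raise ValueError("every sample needs tissue, age, sex and split labels")
        if not meta["sex"].isin(["female", "male"]).all():
            raise ValueError("sex must be 'female' or 'male'")
        if not meta["split"].isin(["train", "validation"]).all():
            raise ValueError("split must be 'train' or 'validation'")
        if (meta["age"] < 0).any():
            raise ValueError("ages must be >= 0")
        train_counts = meta.loc[meta["split"] == "train", "tissue"].value_counts()
        tissues = meta["tissue"].unique()
        thin = [t for t in tissues if train_counts.get(t, 0) < 2]
        if thin:
            raise ValueError(f"each tissue needs >= 2 training samples; too few for {thin}")
        BetaMatrix(betas)  # range validation
        self.betas = betas
        self.meta = meta
        self.truth = truth

    @property
    def tissues(self) -> list[str]:
        return sorted(self.meta["tissue"].unique())

    def subset(self, split: str) -> "TissuePanel":
        keep = self.meta["split"] == split
        return TissuePanel(self.betas.loc[keep], self.meta.loc[keep], truth=self.truth)

    def __len__(self) -> int:
        return len(self.meta)


# ---------------------------------------------------------------------------
# beta computation
# ---------------------------------------------------------------------------

def compute_beta(M, U, offset: float = DEFAULT_BETA_OFFSET):
    """Methylation fraction beta = M / (M + U + offset).

    Accepts scalars or arrays.  ``offset`` regularises low-intensity probes
    (default 100, the minfi convention), so the result lies in [0, 1).
    Negative inputs raise.
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if offset <= 0:
        raise ValueError("offset must be > 0")
    if (M < 0).any() or (U < 0).any():
        raise ValueError("intensities must be >= 0")
    beta = M / (M + U + offset)
    return float(beta) if beta.ndim == 0 else beta


# ---------------------------------------------------------------------------
# TSV dialect readers/writers
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return _MISSING_TOKEN if pd.isna(x) else _FLOAT_FMT % x


def read_manifest(path) -> ProbeManifest:
    df = pd.read_csv(
        path, sep="\t", dtype={"probe_id": str, "chromosome": str, "channel": str},
        na_values=[_MISSING_TOKEN], keep_default_na=False,
    )
    required = ["probe_id", "design_type", "channel", "chromosome", "position", "snp_associated"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"manifest file missing columns: {missing}")
    if df["probe_id"].duplicated().any():
        dupes = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValueError(f"duplicate probe_id(s): {dupes}")
    df["snp_associated"] = df["snp_associated"].map(
        {"True": True, "False": False, True: True, False: False, 1: True, 0: False}
    )
    if df["snp_associated"].isna().any():
        raise ValueError("snp_associated must be True/False")
    return ProbeManifest(df.set_index("probe_id"))


def write_manifest(manifest: ProbeManifest, path) -> None:
    df = manifest.df.copy()
    df["channel"] = df["channel"].fillna(_MISSING_TOKEN)
    df.to_csv(path, sep="\t", index_label="probe_id")


def read_intensities(path, manifest: ProbeManifest) -> IntensitySet:
    df = pd.read_csv(
        path, sep="\t", dtype={"probe_id": str},
        na_values=[_MISSING_TOKEN], keep_default_na=False,
    )
    required = ["probe_id", "M_inband", "U_inband", "M_oob", "U_oob"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"intensity file missing columns: {missing}")
    sample_id = str(df["sample_id"].iloc[0]) if "sample_id" in df.columns and len(df) else "sample"
    return IntensitySet(sample_id, df.set_index("probe_id"), manifest)


def write_intensities(intens: IntensitySet, path) -> None:
    df = intens.df
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\tsample_id\tM_inband\tU_inband\tM_oob\tU_oob\n")
        for pid, row in zip(df.index, df.to_numpy()):
            cells = "\t".join(_fmt(v) for v in row)
            fh.write(f"{pid}\t{intens.sample_id}\t{cells}\n")


def write_beta_matrix(betas: pd.DataFrame, path) -> None:
    """Samples x probes betas as TSV (rows = probes, columns = samples)."""
    out = betas.T
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\t" + "\t".join(map(str, out.columns)) + "\n")
        for pid, row in zip(out.index, out.to_numpy()):
            fh.write(str(pid) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_beta_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="probe_id",
                     na_values=[_MISSING_TOKEN], keep_default_na=False)
    return df.astype(float).T  # back to samples x probes


def write_panel(panel: TissuePanel, beta_path, meta_path) -> None:
    write_beta_matrix(panel.betas, beta_path)
    panel.meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_panel(beta_path, meta_path) -> TissuePanel:
    betas = read_beta_matrix(beta_path)
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    meta.index = meta.index.astype(str)
    betas.index = betas.index.astype(str)
    return TissuePanel(betas.loc[meta.index], meta)
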
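"""Position-wise nucleotide misincorporation frequencies from aligned reads.

Post-mortem cytosine deamination shows up as C->T substitutions enriched at
the 5' ends of ancient-DNA fragments (and, mirrored, G->A at 3' ends).  This
module computes the per-position frequency profile

    freq_CtoT(i) = #{ref = C, read = T at 5' offset i} / #{ref = C at i}

from the simplified aligned-read table (columns read_id, pos_5prime,
ref_base, read_base, strand), keeping the counts so binomial standard
errors can be formed.  Positions with no reference C have an undefined
(missing) frequency, never zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["damage_profile", "read_reads_table", "write_reads_table"]

_COLUMNS = ["read_id", "pos_5prime", "ref_base", "read_base", "strand"]


def read_reads_table(path) -> pd.DataFrame:
    """Read and validate the 5-column read table; malformed rows error with
    their line number."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"read table missing columns: {missing}")
    pos = pd.to_numeric(df["pos_5prime"], errors="coerce")
    bad = pos.isna() | (pos < 1) | (pos != pos.round())
    bases_ok = df["ref_base"].str.fullmatch("[ACGTN]") & df["read_base"].str.fullmatch("[ACGTN]")
    bad |= ~bases_ok.fillna(False)
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ValueError(f"malformed read-table row at line {line}")
    df = df.copy()
    df["pos_5prime"] = pos.astype(int)
    return df


def write_reads_table(reads: pd.DataFrame, path) -> None:
    reads[_COLUMNS].to_csv(path, sep="\t", index=False)


def damage_profile(reads: pd.DataFrame, max_pos: int = 25,
                   include_g_to_a: bool = True) -> pd.DataFrame:
    """Per-position substitution frequencies over 5' offsets 1..max_pos.

    Returns a DataFrame indexed by position with columns ``n_ref_c``,
    ``n_c_to_t``, ``freq_c_to_t``, ``se_c_to_t`` (binomial standard error)
    and, optionally, the G->A analogues.  Frequencies are NaN where the
    denominator is zero.
    """
    missing = [c for c in _COLUMNS[:4] if c not in reads.columns]
    if missing:
        raise ValueError(f"read table missing columns: {missing}")
    sub = reads[reads["pos_5prime"] <= max_pos]
    pos = sub["pos_5prime"].to_numpy()
    ref = sub["ref_base"].to_numpy()
    rd = sub["read_base"].to_numpy()
    idx = pd.RangeIndex(1, max_pos + 1, name="pos_5prime")

    def _freq(ref_b: str, read_b: str):
        den = np.bincount(pos[ref == ref_b], minlength=max_pos + 1)[1:]
        num = np.bincount(pos[(ref == ref_b) & (rd == read_b)],
                          minlength=max_pos + 1)[1:]
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(den > 0, num / np.maximum(den, 1), np.nan)
            se = np.where(den > 0, np.sqrt(f * (1 - f) / np.maximum(den, 1)), np.nan)
        return den, num, f, se

    den_c, num_ct, f_ct, se_ct = _freq("C", "T")
    out = pd.DataFrame(
        {"n_ref_c": den_c, "n_c_to_t": num_ct,
         "freq_c_to_t": f_ct, "se_c_to_t": se_ct}, index=idx)
    if include_g_to_a:
        den_g, num_ga, f_ga, se_ga = _freq("G", "A")
        out["n_ref_g"] = den_g
        out["n_g_to_a"] = num_ga
        out["freq_g_to_a"] = f_ga
        out["se_g_to_a"] = se_ga
    return out
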
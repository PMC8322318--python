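import numpy as np
import pandas as pd
import pytest

import relicmeth as rm


@pytest.fixture(scope="session")
def tiny_manifest() -> rm.ProbeManifest:
    """10 probes: 5 type I (with OOB capability), 5 type II, incl. X/Y/SNP."""
    df = pd.DataFrame(
        {
            "design_type": ["I", "I", "I", "I", "I", "II", "II", "II", "II", "II"],
            "channel": ["Grn", "Red", "Grn", "Red", "Grn", None, None, None, None, None],
            "chromosome": ["1", "2", "X", "Y", "3", "4", "5", "X", "6", "7"],
            "position": [100, 200, 300, 400, 500, 600, 700, 800, 900, 1000],
            "snp_associated": [False, False, False, False, True,
                               False, False, False, True, False],
        },
        index=pd.Index([f"cg{i:06d}" for i in range(10)], name="probe_id"),
    )
    return rm.ProbeManifest(df)


@pytest.fixture(scope="session")
def tiny_intensities(tiny_manifest) -> rm.IntensitySet:
    rng = np.random.default_rng(7)
    n = len(tiny_manifest)
    type_i = tiny_manifest.is_type_i().to_numpy()
    df = pd.DataFrame(
        {
            "M_inband": rng.uniform(100, 5000, n),
            "U_inband": rng.uniform(100, 5000, n),
            "M_oob": np.where(type_i, rng.uniform(200, 800, n), np.nan),
            "U_oob": np.where(type_i, rng.uniform(200, 800, n), np.nan),
        },
        index=tiny_manifest.probe_ids,
    )
    return rm.IntensitySet("tiny", df, tiny_manifest)


@pytest.fixture(scope="session")
def default_panel():
    """One default-conditions panel + manifest, shared across tests."""
    return rm.simulate_panel(rm.PanelConfig(seed=11))


@pytest.fixture(scope="session")
def small_panel():
    """A light panel for fast deconvolution/age tests."""
    cfg = rm.PanelConfig(
        n_probes=800, n_x_probes=60, n_y_probes=60, n_markers_per_tissue=5,
        samples_per_tissue=10, n_age_cpgs=7, beta_noise_sd=0.05, seed=23,
    )
    return rm.simulate_panel(cfg)
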
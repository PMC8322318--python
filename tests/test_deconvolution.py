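"""Marker scoring/selection, reference matrix, NNLS with a grid-search oracle."""

import warnings

import numpy as np
import pandas as pd
import pytest

import relicmeth as rm
from relicmeth.deconvolution import score_table


def _panel_from_arrays(betas, tissues, split=None):
    n = len(betas)
    meta = pd.DataFrame(
        {"tissue": tissues, "age": 40.0, "sex": "female",
         "split": split if split is not None else ["train"] * n},
        index=betas.index)
    return rm.TissuePanel(betas, meta)


def simplex_grid_nnls(A, b, step=0.001):
    """Independent oracle: best proportions by brute-force search over the
    simplex (with an analytically optimal non-negative scale per point)."""
    k = A.shape[1]
    if k == 2:
        p1 = np.arange(0, 1 + step / 2, step)
        Q = np.column_stack([p1, 1 - p1])
    elif k == 3:
        pts = []
        vals = np.arange(0, 1 + step / 2, step)
        for a in vals:
            rest = np.arange(0, 1 - a + step / 2, step)
            pts.append(np.column_stack([np.full_like(rest, a), rest, 1 - a - rest]))
        Q = np.vstack(pts)
    else:
        raise NotImplementedError
    AQ = Q @ A.T                       # grid-points x rows
    num = AQ @ b
    den = np.einsum("ij,ij->i", AQ, AQ)
    c = np.clip(num / np.maximum(den, 1e-300), 0, None)
    resid = np.sum(b**2) - 2 * c * num + c**2 * den
    return Q[np.argmin(resid)]


class TestScore:
    def test_planted_marker_score(self):
        """Means 0.15 vs 0.85 with sd 0.05: score = 0.70 - 0.05 = 0.65."""
        rng = np.random.default_rng(2)
        n = 40
        vals = np.concatenate([rng.normal(0.15, 0.05, n), rng.normal(0.85, 0.05, n)])
        betas = pd.DataFrame({"cg_m": np.clip(vals, 0, 1)},
                             index=[f"s{i}" for i in range(2 * n)])
        panel = _panel_from_arrays(betas, ["lung"] * n + ["liver"] * n)
        dmean, pooled, score = rm.score_cpg(panel, "cg_m", "lung")
        assert dmean == pytest.approx(0.70, abs=0.04)
        assert pooled == pytest.approx(0.05, abs=0.02)
        assert score == pytest.approx(0.65, abs=0.05)

    def test_constant_cpg_scores_nonpositive(self):
        betas = pd.DataFrame({"cg_c": [0.4] * 8})
        betas.index = [f"s{i}" for i in range(8)]
        panel = _panel_from_arrays(betas, ["lung"] * 4 + ["liver"] * 4)
        dmean, _, score = rm.score_cpg(panel, "cg_c", "lung")
        assert dmean == 0.0
        assert score <= 0.0

    def test_matches_bruteforce_recomputation(self, small_panel):
        panel, _ = small_panel
        train = panel.subset("train")
        cols = train.betas.columns[:50]
        table = score_table(train, "heart", candidates=cols)
        lab = (train.meta["tissue"] == "heart").to_numpy()
        for c in cols[:10]:
            v = train.betas[c].to_numpy()
            dmean = abs(v[lab].mean() - v[~lab].mean())
            pooled = (v[lab].std(ddof=1) + v[~lab].std(ddof=1)) / 2
            assert table.loc[c, "delta_mean"] == pytest.approx(dmean)
            assert table.loc[c, "score"] == pytest.approx(dmean - pooled)

    def test_small_group_errors(self):
        betas = pd.DataFrame({"cg": [0.1, 0.2, 0.3, 0.4]},
                             index=[f"s{i}" for i in range(4)])
        panel = _panel_from_arrays(betas, ["lung", "lung", "liver", "liver"])
        with pytest.raises(KeyError):
            rm.score_cpg(panel, "cg", "brain")


class TestSelectMarkers:
    def test_recovers_planted_markers(self, small_panel):
        """>= 4 of 5 planted markers per tissue at logit noise 0.05, k=5."""
        panel, _ = small_panel
        sel = rm.select_markers(panel, k=5, n_folds=5, seed=0)
        for t, planted in panel.truth.markers.items():
            assert len(set(sel.markers[t]) & set(planted)) >= 4

    def test_deterministic_given_seed(self, small_panel):
        panel, _ = small_panel
        s1 = rm.select_markers(panel, k=5, n_folds=5, seed=3)
        s2 = rm.select_markers(panel, k=5, n_folds=5, seed=3)
        assert s1.markers == s2.markers

    def test_label_permutation_gives_chance_recovery(self, small_panel):
        """With shuffled tissue labels planted markers are recovered at
        chance rate (permutation oracle for the selection statistic)."""
        panel, _ = small_panel
        rng = np.random.default_rng(17)
        meta = panel.meta.copy()
        meta["tissue"] = rng.permutation(meta["tissue"].to_numpy())
        shuffled = rm.TissuePanel(panel.betas, meta, truth=panel.truth)
        sel = rm.select_markers(shuffled, k=5, n_folds=5, seed=0)
        hits = [len(set(sel.markers[t]) & set(panel.truth.markers[t]))
                for t in sel.markers]
        # chance: 5 of ~700 candidates in 5 slots -> << 1 hit per tissue
        assert np.mean(hits) <= 1.0

    def test_reduces_folds_with_warning(self, small_panel):
        panel, _ = small_panel  # 7 training samples per tissue
        with pytest.warns(UserWarning, match="reducing folds"):
            rm.select_markers(panel, k=2, n_folds=10, seed=0)


class TestReference:
    def test_hand_computed_means(self):
        betas = pd.DataFrame(
            {"cg1": [0.1, 0.3, 0.8, 0.6], "cg2": [0.9, 0.7, 0.2, 0.4]},
            index=["a", "b", "c", "d"])
        panel = _panel_from_arrays(betas, ["lung", "lung", "liver", "liver"])
        sel = rm.MarkerSelection(markers={"lung": ["cg1"], "liver": ["cg2"]},
                                 k=1, n_folds=2, lam=1.0)
        ref = rm.build_reference(panel, sel)
        assert ref.loc["cg1", "lung"] == pytest.approx(0.2)
        assert ref.loc["cg1", "liver"] == pytest.approx(0.7)
        assert ref.loc["cg2", "lung"] == pytest.approx(0.8)
        assert ref.loc["cg2", "liver"] == pytest.approx(0.3)
        assert ((ref >= 0) & (ref <= 1)).all().all()

    def test_missing_beta_drops_cpg_with_warning(self):
        betas = pd.DataFrame(
            {"cg1": [0.1, np.nan, 0.8, 0.6], "cg2": [0.9, 0.7, 0.2, 0.4]},
            index=["a", "b", "c", "d"])
        panel = _panel_from_arrays(betas, ["lung", "lung", "liver", "liver"])
        sel = rm.MarkerSelection(markers={"lung": ["cg1", "cg2"]}, k=2,
                                 n_folds=2, lam=1.0)
        with pytest.warns(UserWarning, match="dropping"):
            ref = rm.build_reference(panel, sel)
        assert list(ref.index) == ["cg2"]


@pytest.fixture(scope="module")
def reference(small_panel):
    panel, _ = small_panel
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel = rm.select_markers(panel, k=5, n_folds=5, seed=1)
    return rm.build_reference(panel, sel)


@pytest.fixture(scope="module")
def atlas():
    rng = np.random.default_rng(4)
    classes = [f"cls{i}" for i in range(12)]
    rows = [f"cg_atlas{i:04d}" for i in range(300)]
    return pd.DataFrame(
        rng.beta(0.4, 0.4, size=(300, 12)), index=rows, columns=classes)


class TestNNLS:
    def test_exact_member_recovered(self, reference):
        res = rm.nnls_deconvolve(reference, reference["lung"])
        assert res.proportions["lung"] == pytest.approx(1.0, abs=1e-6)
        assert res.argmax == "lung"

    def test_two_tissue_mixture_matches_grid_oracle(self, reference):
        A = reference[["lung", "liver"]]
        b = 0.3 * A["lung"] + 0.7 * A["liver"]
        res = rm.nnls_deconvolve(A, b)
        assert res.proportions["lung"] == pytest.approx(0.3, abs=1e-4)
        oracle = simplex_grid_nnls(A.to_numpy(), b.to_numpy())
        assert np.allclose(res.proportions.to_numpy(), oracle, atol=0.002)

    def test_all_zero_sample_is_undetermined(self, reference):
        res = rm.nnls_deconvolve(reference, pd.Series(0.0, index=reference.index))
        assert res.undetermined
        assert res.argmax is None

    def test_no_shared_rows_errors(self, reference):
        with pytest.raises(ValueError, match="shared"):
            rm.nnls_deconvolve(reference, pd.Series({"nope": 0.5}))

    def test_nonnegative_and_beats_clipped_lstsq(self, reference):
        """x >= 0 and the NNLS residual is no worse than the unconstrained
        solution projected onto the non-negative orthant."""
        rng = np.random.default_rng(3)
        A = reference.to_numpy()
        b = np.clip(A @ rng.dirichlet(np.ones(A.shape[1]))
                    + rng.normal(0, 0.05, A.shape[0]), 0, 1)
        res = rm.nnls_deconvolve(reference, pd.Series(b, index=reference.index))
        assert (res.coefficients >= 0).all()
        x_uncon, *_ = np.linalg.lstsq(A, b, rcond=None)
        clipped = np.clip(x_uncon, 0, None)
        assert res.residual <= np.linalg.norm(A @ clipped - b) + 1e-9

    def test_missing_rows_dropped_pairwise(self, reference):
        b = reference["gut"].copy()
        b.iloc[:5] = np.nan
        res = rm.nnls_deconvolve(reference, b)
        assert res.n_cpgs == len(reference) - 5
        assert res.argmax == "gut"


class TestExternalAtlas:
    def test_identity_group_map_matches_plain_nnls(self, atlas):
        b = atlas["cls3"]
        plain = rm.nnls_deconvolve(atlas, b)
        grouped = rm.deconvolve_with_external_atlas(atlas, b, group_map=None)
        pd.testing.assert_series_equal(plain.proportions, grouped.proportions)

    def test_group_proportions_are_additive(self, atlas):
        b = 0.2 * atlas["cls0"] + 0.3 * atlas["cls1"] + 0.5 * atlas["cls2"]
        gmap = {"cls0": "Leukocytes", "cls1": "Leukocytes"}
        res = rm.deconvolve_with_external_atlas(atlas, b, group_map=gmap)
        assert res.proportions["Leukocytes"] == pytest.approx(0.5, abs=1e-3)
        assert res.proportions["cls2"] == pytest.approx(0.5, abs=1e-3)

    def test_row_subsetting_degrades_but_keeps_argmax(self, atlas):
        """Restricting the atlas to 10% of rows preserves the dominant class
        of a 0.8/0.2 mixture in >= 90% of runs."""
        keep_argmax = 0
        n_runs = 100
        for s in range(n_runs):
            rng = np.random.default_rng(s)
            b = 0.8 * atlas["cls5"] + 0.2 * atlas["cls7"]
            b = b + rng.normal(0, 0.02, len(b))
            rows = rng.choice(atlas.index, size=30, replace=False)
            res = rm.deconvolve_with_external_atlas(atlas.loc[rows],
                                                    b.loc[rows])
            keep_argmax += res.argmax == "cls5"
        assert keep_argmax >= 90

    def test_empty_intersection_errors(self, atlas):
        with pytest.raises(ValueError, match="retained"):
            rm.deconvolve_with_external_atlas(atlas, pd.Series({"x": 0.1}))
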
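"""Observer normalisation, concordance, summaries, model comparison, and the
CIEDE2000 triangle-inequality Monte Carlo."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pointillism import analysis as an
from pointillism import observer as ob
from pointillism.exceptions import DomainError, InsufficientDataError
from pointillism.transitions import enumerate_cardinal_pairs


def _two_observer_table(transform=lambda x: x):
    """Observer 'a' reports the latent values; observer 'b' a transform."""
    rows = []
    for a, b in enumerate_cardinal_pairs():
        latent = ob.latent_distinctiveness(a + b, ob.GroundTruth())
        rows.append({"observer_id": "a", "condition": "hard-mono", "pair": a + b,
                     "contrast": latent})
        rows.append({"observer_id": "b", "condition": "hard-mono", "pair": a + b,
                     "contrast": transform(latent)})
    return pd.DataFrame(rows)


class TestNormalizeObservers:
    def test_identical_observers_unchanged(self):
        tbl = _two_observer_table()
        norm = an.normalize_observers(tbl)
        assert np.allclose(norm.observer_fits["slope"], 1.0)
        assert np.allclose(norm.observer_fits["intercept"], 0.0, atol=1e-12)
        assert np.allclose(norm.table["normalized_contrast"], norm.table["contrast"])

    def test_affine_observer_recovered_and_inverted(self):
        tbl = _two_observer_table(lambda x: 2 * x + 0.1)
        norm = an.normalize_observers(tbl)
        # cross-observer median of {x, 2x+0.1} is the midpoint 1.5x+0.05,
        # so each observer's fitted line is exact against it
        fit_b = norm.observer_fits.loc["b"]
        assert fit_b["slope"] == pytest.approx(2 / 1.5, rel=1e-9)
        b_rows = norm.table[norm.table["observer_id"] == "b"]
        a_rows = norm.table[norm.table["observer_id"] == "a"]
        assert np.allclose(
            b_rows["normalized_contrast"].to_numpy(),
            a_rows["normalized_contrast"].to_numpy(),
            atol=1e-9,
        )

    def test_normalization_shrinks_injected_spread(self, session_table):
        norm = an.normalize_observers(session_table)
        raw_spread = session_table.groupby(["condition", "pair"])["contrast"].std().mean()
        norm_spread = norm.table.groupby(["condition", "pair"])["normalized_contrast"].std().mean()
        assert norm_spread < raw_spread

    def test_renormalization_idempotent_for_affine_observers(self):
        # exactly affine observers: the first pass aligns them perfectly,
        # so a second pass is the identity to rounding error
        tbl = _two_observer_table(lambda x: 1.7 * x - 0.05)
        once = an.normalize_observers(tbl)
        renamed = once.table.drop(columns=["contrast"]).rename(
            columns={"normalized_contrast": "contrast"}
        )
        twice = an.normalize_observers(renamed)
        assert np.allclose(twice.table["normalized_contrast"], renamed["contrast"], atol=1e-9)
        assert np.allclose(twice.observer_fits["slope"], 1.0, atol=1e-9)

    def test_renormalization_nearly_idempotent_with_noise(self, session_table):
        # with response noise the median anchor shifts slightly between
        # passes, so idempotence is only approximate
        once = an.normalize_observers(session_table)
        renamed = once.table.drop(columns=["contrast"]).rename(
            columns={"normalized_contrast": "contrast"}
        )
        twice = an.normalize_observers(renamed)
        delta = np.abs(twice.table["normalized_contrast"] - renamed["contrast"])
        assert delta.max() < 0.02
        assert np.allclose(twice.observer_fits["slope"], 1.0, atol=0.05)
        assert np.allclose(twice.observer_fits["intercept"], 0.0, atol=0.02)

    def test_constant_observer_flagged(self):
        tbl = _two_observer_table()
        tbl.loc[tbl["observer_id"] == "b", "contrast"] = 0.5
        with pytest.raises(InsufficientDataError):
            an.normalize_observers(tbl)


class TestConcordance:
    def test_self_agreement_and_reversal(self):
        tbl = _two_observer_table()
        res = an.concordance(tbl)
        assert res["tau"].loc["a", "b"] == pytest.approx(1.0)
        rev = _two_observer_table(lambda x: 1 - x)
        assert an.concordance(rev)["tau"].loc["a", "b"] == pytest.approx(-1.0)

    def test_independent_responses_near_zero(self):
        rng = np.random.default_rng(3)
        taus = []
        for _ in range(50):
            rows = []
            for a, b in enumerate_cardinal_pairs():
                for obsid in ("a", "b"):
                    rows.append({"observer_id": obsid, "condition": "c", "pair": a + b,
                                 "contrast": rng.random()})
            taus.append(an.concordance(pd.DataFrame(rows))["tau"].loc["a", "b"])
        # permutation null: mean tau ~ 0, sd ~ sqrt(2(2n+5)/(9n(n-1))) at n=15
        assert abs(np.mean(taus)) < 3 * 0.19 / np.sqrt(50)

    def test_insignificant_entries_masked(self):
        rng = np.random.default_rng(8)
        rows = []
        for a, b in enumerate_cardinal_pairs():
            for obsid in ("a", "b"):
                rows.append({"observer_id": obsid, "condition": "c", "pair": a + b,
                             "contrast": rng.random()})
        res = an.concordance(pd.DataFrame(rows))
        if res["p"].loc["a", "b"] > 0.05:
            assert np.isnan(res["masked"].loc["a", "b"])

    def test_too_few_cells_rejected(self):
        tbl = _two_observer_table().head(4)  # 2 pairs only
        with pytest.raises(InsufficientDataError):
            an.concordance(tbl)


class TestSummaries:
    def test_constant_cell_quartiles_collapse(self):
        tbl = pd.DataFrame(
            {"observer_id": ["a"] * 4, "condition": ["c"] * 4, "pair": ["YB"] * 4,
             "normalized_contrast": [0.4] * 4}
        )
        out = an.summarize_pairs(tbl)
        row = out[(out["pair"] == "YB")].iloc[0]
        assert row["q1"] == row["median"] == row["q3"] == 0.4

    def test_quartiles_invariant_under_permutation(self, session_table, rng):
        norm = an.normalize_observers(session_table).table
        shuffled = norm.sample(frac=1.0, random_state=0)
        a = an.summarize_pairs(norm).sort_values(["condition", "pair"]).reset_index(drop=True)
        b = an.summarize_pairs(shuffled).sort_values(["condition", "pair"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_complementary_class_above_analogous(self, session_table):
        norm = an.normalize_observers(session_table).table
        out = an.summarize_pairs(norm)
        cls = out[out["pair"] == "(all)"].groupby("pair_class")["median"].median()
        assert cls["complementary"] > cls["analogous"]


class TestPairMatrix:
    def test_rgb_cube_matrix_has_three_grey_bands(self, cal):
        pm = an.pair_matrix(an.model_predictions("rgb_cube", cal))
        off = pm.grey[~np.eye(6, dtype=bool)]
        assert len(np.unique(np.round(off, 9))) == 3
        # doubly periodic bands: same value along each cyclic offset
        for k in (1, 2, 3):
            assert np.allclose(pm.band(k), pm.band(k)[0])

    def test_symmetry_zero_diagonal_and_scaling(self, cal):
        pm = an.pair_matrix(an.model_predictions("ciede2000", cal))
        assert np.allclose(pm.values, pm.values.T)
        assert np.allclose(np.diag(pm.values), 0.0)
        off = pm.grey[~np.eye(6, dtype=bool)]
        assert off.min() == 0.0 and off.max() == 1.0

    def test_constant_predictions_all_equal(self):
        pm = an.pair_matrix({a + b: 2.0 for a, b in enumerate_cardinal_pairs()})
        off = pm.grey[~np.eye(6, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_missing_pair_rejected(self):
        vals = {a + b: 1.0 for a, b in enumerate_cardinal_pairs()}
        del vals["YB"]
        with pytest.raises(DomainError):
            an.pair_matrix(vals)


class TestModelPredictions:
    def test_luminance_contrast_yellow_blue(self, cal):
        preds = an.model_predictions("luminance_contrast", cal)
        assert preds["YB"] == pytest.approx(0.6677, abs=1e-4)
        assert max(preds.values()) == preds["YB"]

    def test_rgb_cube_complementary_tie_at_sqrt3(self, cal):
        preds = an.model_predictions("rgb_cube", cal)
        for p in ("YB", "GM", "CR"):
            assert preds[p] == pytest.approx(np.sqrt(3))

    def test_colour_circle_steps(self, cal):
        preds = an.model_predictions("colour_circle", cal)
        assert preds["YG"] == 1.0 and preds["YC"] == 2.0 and preds["YB"] == 3.0

    def test_equiluminant_pairs_predicted_invisible(self):
        # a calibration with equal primary luminances makes e.g. R and G
        # equiluminant; the luminance model then predicts zero contrast
        from pointillism.colour import DisplayCalibration

        flat = DisplayCalibration(primary_luminances=(100.0, 100.0, 100.0))
        preds = an.model_predictions("luminance_contrast", flat)
        for p in ("RG", "GB", "BR") :
            key = p if p in preds else p[::-1]
            assert preds[key] == pytest.approx(0.0, abs=1e-12)


class TestCompareModels:
    def test_perfect_and_reversed_predictions(self, cal):
        preds = an.model_predictions("rgb_cube", cal)
        rows = []
        for pair, v in preds.items():
            rows.append({"observer_id": "a", "condition": "c", "pair": pair,
                         "normalized_contrast": v})
            rows.append({"observer_id": "b", "condition": "c", "pair": pair,
                         "normalized_contrast": v})
        tbl = pd.DataFrame(rows)
        out = an.compare_models(tbl, cal, models=("rgb_cube",))
        pooled = out[(out["condition"] == "pooled")].iloc[0]
        assert pooled["kendall_tau"] == pytest.approx(1.0)
        assert pooled["pearson_r"] == pytest.approx(1.0)
        tbl["normalized_contrast"] = -tbl["normalized_contrast"]
        rev = an.compare_models(tbl, cal, models=("rgb_cube",))
        assert rev[rev["condition"] == "pooled"].iloc[0]["kendall_tau"] == pytest.approx(-1.0)

    def test_tau_invariant_under_monotone_transform_r_not(self, session_table, cal):
        norm = an.normalize_observers(session_table).table
        base = an.compare_models(norm, cal, models=("ciede2000",))
        warped = norm.copy()
        warped["normalized_contrast"] = np.exp(3 * warped["normalized_contrast"])
        out = an.compare_models(warped, cal, models=("ciede2000",))
        b = base[base["condition"] == "pooled"].iloc[0]
        w = out[out["condition"] == "pooled"].iloc[0]
        assert w["kendall_tau"] == pytest.approx(b["kendall_tau"], abs=1e-12)
        assert w["pearson_r"] != pytest.approx(b["pearson_r"], abs=1e-6)

    def test_true_model_wins_identifiability(self, cal):
        rng = np.random.default_rng(99)
        wins = 0
        n_rep = 40
        for _ in range(n_rep):
            panel = ob.make_observers(5, rng)
            tbl = ob.simulate_session(panel, ob.GroundTruth.calibrated("rgb_cube", cal), rng)
            norm = an.normalize_observers(tbl).table
            out = an.compare_models(norm, cal, models=("rgb_cube", "luminance_contrast"))
            pooled = out[out["condition"] == "pooled"].set_index("model")["kendall_tau"]
            wins += pooled["rgb_cube"] > pooled["luminance_contrast"]
        assert wins / n_rep >= 0.95


class TestTriangleMC:
    def test_fraction_bounds_and_se(self, cal, rng):
        res = an.triangle_inequality_mc(2000, cal, rng)
        assert 0.0 <= res.fraction <= 1.0
        assert res.standard_error == pytest.approx(
            np.sqrt(res.fraction * (1 - res.fraction) / 2000)
        )

    def test_degenerate_triples_cannot_violate(self, cal):
        # two coincident corners: one side is 0, inequality reduces to symmetry
        from pointillism.colour import ciede2000, rgb_to_lab

        la = rgb_to_lab((0.2, 0.7, 0.1), cal)
        lb = rgb_to_lab((0.9, 0.1, 0.4), cal)
        assert ciede2000(la, lb) <= ciede2000(la, la) + ciede2000(la, lb) + 1e-12

    def test_reproducible_across_seeds_within_3se(self, cal):
        r1 = an.triangle_inequality_mc(20000, cal, np.random.default_rng(1))
        r2 = an.triangle_inequality_mc(20000, cal, np.random.default_rng(2))
        pooled_se = np.hypot(r1.standard_error, r2.standard_error)
        assert abs(r1.fraction - r2.fraction) <= 3 * pooled_se

    def test_any_mode_counts_more_than_path_mode(self, cal):
        ra = an.triangle_inequality_mc(20000, cal, np.random.default_rng(4), mode="any")
        rp = an.triangle_inequality_mc(20000, cal, np.random.default_rng(4), mode="path")
        assert ra.fraction > rp.fraction


class TestHexagonSummary:
    def test_equal_inputs_give_equal_unit_weights(self):
        vals = {a + b: 3.0 for a, b in enumerate_cardinal_pairs()}
        w = an.hexagon_summary("Y", vals)
        assert len(w) == 5
        assert np.allclose(list(w.values()), 1.0)

    def test_mean_weight_is_one(self, cal):
        w = an.hexagon_summary("Y", an.model_predictions("ciede2000", cal))
        assert np.mean(list(w.values())) == pytest.approx(1.0)

    def test_rgb_cube_ordering_from_yellow(self, cal):
        w = an.hexagon_summary("Y", an.model_predictions("rgb_cube", cal))
        assert w["B"] > w["C"] > w["G"]
        assert w["C"] == pytest.approx(w["M"]) and w["G"] == pytest.approx(w["R"])
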
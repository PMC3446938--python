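import logging

import numpy as np
import pandas as pd
import pytest

from landuse_affinity import (
    anova_type3_backward,
    build_occurrence_table,
    manova_type3,
    order_affinity_summary,
    tukey_letters,
)

ORDERS = ("Coleoptera", "Diptera", "Hymenoptera", "Lepidoptera")


def one_way_f_oracle(groups):
    """Closed-form one-way ANOVA F = MS_between / MS_within."""
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((g - np.mean(g)) ** 2).sum() for g in groups)
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def factorial_frame(rng, n_per_cell=8, order_effect=0.0, freq_effect=0.0,
                    interaction=0.0, sigma=1.0):
    rows = []
    for i, order in enumerate(ORDERS):
        for j, freq in enumerate(("frequent", "infrequent")):
            mu = (
                order_effect * (i - 1.5)
                + freq_effect * (j - 0.5)
                + interaction * (i - 1.5) * (j - 0.5)
            )
            for _ in range(n_per_cell):
                y = rng.normal(mu, sigma, size=3)
                rows.append(
                    {
                        "order": order,
                        "frequency_class": freq,
                        "M_urban": y[0],
                        "M_agri": y[1],
                        "M_natural": y[2],
                    }
                )
    return pd.DataFrame(rows)


class TestBuildOccurrenceTable:
    def _pieces(self):
        idx = pd.DataFrame(
            {
                "collection_id": ["c1", "c2", "c3"],
                "M_urban": [0.1, 0.2, 0.3],
                "M_agri": [0.0, 0.0, 0.0],
                "M_natural": [-0.1, -0.2, -0.3],
            }
        )
        taxa = pd.DataFrame(
            {
                "taxon_id": ["t1", "t2"],
                "order": ["Diptera", "Coleoptera"],
                "frequency_class": ["frequent", "frequent"],
            }
        )
        obs = pd.DataFrame(
            {
                "collection_id": ["c1", "c2", "c3"] * 2,
                "taxon_id": ["t1"] * 3 + ["t2"] * 3,
            }
        )
        return obs, idx, taxa

    def test_one_row_per_occurrence(self):
        obs, idx, taxa = self._pieces()
        occ = build_occurrence_table(obs, idx, taxa)
        assert len(occ) == 6
        assert occ.loc[occ["collection_id"] == "c2", "M_urban"].eq(0.2).all()

    def test_discarded_collections_dropped_and_logged(self, caplog):
        obs, idx, taxa = self._pieces()
        obs.loc[len(obs)] = ["c_gone", "t1"]
        with caplog.at_level(logging.INFO, logger="landuse_affinity.group_stats"):
            occ = build_occurrence_table(obs, idx, taxa, discarded_ids={"c_gone"})
        assert len(occ) == 6
        assert "dropped 1" in caplog.text

    def test_unknown_ids_are_errors(self):
        obs, idx, taxa = self._pieces()
        with pytest.raises(ValueError, match="unknown collection"):
            build_occurrence_table(
                obs.assign(collection_id=["cX"] + list(obs["collection_id"][1:])),
                idx, taxa,
            )
        with pytest.raises(ValueError, match="unknown taxon"):
            build_occurrence_table(
                obs.assign(taxon_id=["tX"] + list(obs["taxon_id"][1:])), idx, taxa
            )

    def test_empty_observations_warn(self, caplog):
        obs, idx, taxa = self._pieces()
        with caplog.at_level(logging.WARNING, logger="landuse_affinity.group_stats"):
            occ = build_occurrence_table(obs.iloc[:0], idx, taxa)
        assert occ.empty
        assert "empty" in caplog.text


class TestTypeIIIMachinery:
    def test_single_response_one_factor_equals_oneway_f(self):
        rng = np.random.default_rng(0)
        g1 = rng.normal(0.0, 1.0, 40)
        g2 = rng.normal(0.7, 1.0, 40)
        df = pd.DataFrame(
            {
                "M_urban": np.concatenate([g1, g2]),
                "order": ["Diptera"] * 40 + ["Coleoptera"] * 40,
                "frequency_class": "frequent",
            }
        )
        [res] = manova_type3(df, responses=("M_urban",), terms=["order"])
        expected = one_way_f_oracle([g1, g2])
        assert res.F == pytest.approx(expected, rel=1e-8)
        assert res.df_num == 1 and res.df_den == 78

    def test_balanced_four_group_anova_matches_oracle(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(m, 1.0, 20) for m in (0.0, 0.2, 0.4, 0.6)]
        df = pd.DataFrame(
            {
                "M_agri": np.concatenate(groups),
                "order": np.repeat(ORDERS, 20),
                "frequency_class": "frequent",
            }
        )
        [res] = manova_type3(df, responses=("M_agri",), terms=["order"])
        assert res.F == pytest.approx(one_way_f_oracle(groups), rel=1e-8)

    def test_degenerate_constant_responses(self):
        df = factorial_frame(np.random.default_rng(2))
        for c in ("M_urban", "M_agri", "M_natural"):
            df[c] = 1.0
        res = manova_type3(df, responses=("M_urban",), terms=["order"])
        assert res[0].F == pytest.approx(0.0, abs=1e-8) or res[0].p > 0.999

    def test_multivariate_null_has_large_p(self):
        df = factorial_frame(np.random.default_rng(3))
        res = {t.term: t for t in manova_type3(df)}
        assert set(res) == {"order", "frequency_class", "order:frequency_class"}
        assert all(t.F >= 0 for t in res.values())

    def test_rank_deficient_design_suggests_dropping_interaction(self):
        df = factorial_frame(np.random.default_rng(4))
        df = df[~((df["order"] == "Diptera") & (df["frequency_class"] == "frequent"))]
        with pytest.raises(ValueError, match="interaction"):
            manova_type3(df)

    def test_single_level_factor_rejected(self):
        df = factorial_frame(np.random.default_rng(5))
        df["frequency_class"] = "frequent"
        with pytest.raises(ValueError, match="frequency_class"):
            manova_type3(df)


class TestBackwardSimplification:
    def test_strong_order_effect_only_keeps_order(self):
        df = factorial_frame(
            np.random.default_rng(6), n_per_cell=20, order_effect=2.0, sigma=0.5
        )
        model, results = anova_type3_backward(df, "M_urban")
        retained = {r.term for r in results if r.retained}
        assert retained == {"order"}

    def test_strong_interaction_keeps_full_model(self):
        df = factorial_frame(
            np.random.default_rng(7), n_per_cell=20, interaction=3.0, sigma=0.5
        )
        model, results = anova_type3_backward(df, "M_urban")
        retained = {r.term for r in results if r.retained}
        assert retained == {"order", "frequency_class", "order:frequency_class"}

    def test_main_effects_never_leave_before_interaction(self):
        # even with null main effects, a retained interaction pins them
        df = factorial_frame(
            np.random.default_rng(8), n_per_cell=25, interaction=4.0, sigma=0.5
        )
        _, results = anova_type3_backward(df, "M_agri")
        res = {r.term: r for r in results}
        if res["order:frequency_class"].retained:
            assert res["order"].retained and res["frequency_class"].retained

    def test_all_null_often_reduces_to_intercept(self):
        hits = 0
        reps = 40
        rng = np.random.default_rng(9)
        for _ in range(reps):
            df = factorial_frame(rng, n_per_cell=10)
            _, results = anova_type3_backward(df, "M_natural")
            if not any(r.retained for r in results):
                hits += 1
        assert hits >= int(0.80 * reps)  # nominal ~0.9 with alpha 0.05 per step


class TestTukeyLetters:
    def test_two_groups_ten_sds_apart_get_distinct_letters(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            {
                "M_urban": np.concatenate(
                    [rng.normal(0, 1, 30), rng.normal(10, 1, 30)]
                ),
                "order": ["Diptera"] * 30 + ["Coleoptera"] * 30,
            }
        )
        out = tukey_letters(df, "M_urban", "order")
        letters = dict(zip(out["level"], out["letters"]))
        assert set(letters["Diptera"]) & set(letters["Coleoptera"]) == set()

    def test_identical_duplicated_groups_share_letters(self):
        rng = np.random.default_rng(11)
        base = rng.normal(0, 1, 25)
        df = pd.DataFrame(
            {
                "M_urban": np.concatenate([base, base]),
                "order": ["Diptera"] * 25 + ["Coleoptera"] * 25,
            }
        )
        out = tukey_letters(df, "M_urban", "order")
        assert out["mean"].nunique() == 1
        assert out["letters"].nunique() == 1

    def test_invariant_to_level_ordering(self):
        rng = np.random.default_rng(12)
        df = factorial_frame(rng, n_per_cell=15, order_effect=1.0, sigma=0.6)
        out1 = tukey_letters(df, "M_urban", "order")
        out2 = tukey_letters(
            df.sample(frac=1.0, random_state=3).reset_index(drop=True),
            "M_urban", "order",
        )
        pd.testing.assert_frame_equal(out1, out2)

    def test_sparse_level_rejected(self):
        df = pd.DataFrame(
            {"M_urban": [0.1, 0.2, 0.3], "order": ["Diptera", "Diptera", "Coleoptera"]}
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            tukey_letters(df, "M_urban", "order")


class TestOrderAffinitySummary:
    def test_worked_example(self):
        df = pd.DataFrame(
            {
                "order": "Diptera",
                "frequency_class": "frequent",
                "M_urban": [0.2, -0.1, -0.1],
                "M_agri": [0.0, 0.0, 0.0],
                "M_natural": [0.1, 0.1, 0.1],
            }
        )
        out = order_affinity_summary(df).set_index("landuse")
        assert out.loc["urban", "mean"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["urban", "se"] == pytest.approx(0.1, rel=1e-9)
        assert out.loc["natural", "se"] == pytest.approx(0.0, abs=1e-12)

    def test_singleton_group_flagged(self):
        df = pd.DataFrame(
            {
                "order": ["Diptera"],
                "frequency_class": ["frequent"],
                "M_urban": [0.5],
                "M_agri": [0.2],
                "M_natural": [0.1],
            }
        )
        out = order_affinity_summary(df)
        assert (out["se"] == 0.0).all()
        assert out["se_undefined"].all()

    def test_identical_groups_get_identical_summaries(self):
        rng = np.random.default_rng(13)
        vals = rng.normal(size=(10, 3))
        frames = []
        for order in ("Diptera", "Coleoptera"):
            f = pd.DataFrame(vals, columns=["M_urban", "M_agri", "M_natural"])
            f["order"] = order
            f["frequency_class"] = "frequent"
            frames.append(f)
        out = order_affinity_summary(pd.concat(frames))
        a = out[out["order"] == "Diptera"].drop(columns="order").reset_index(drop=True)
        b = out[out["order"] == "Coleoptera"].drop(columns="order").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
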
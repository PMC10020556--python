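"""Tests for the interpretation layer: attention summaries, top-k review
selection, bag summaries, group tests, and rules mining against a
brute-force power-set oracle."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from histomil import audit
from histomil.synthetic import ReviewEffects, generate_review_table


def _attention_frame():
    rows = []
    rng = np.random.default_rng(3)
    for sid in ("a", "b", "c"):
        w = rng.random(12)
        w /= w.sum()
        cls = (["tumor"] * 6 + ["necrosis"] * 3 + ["normal"] * 3)
        for i, (wi, ci) in enumerate(zip(w, cls)):
            rows.append({"slide_id": sid, "patch_index": i, "weight": wi,
                         "morphology_call": ci})
    return pd.DataFrame(rows)


class TestAttentionByMorphology:
    def test_uniform_single_class_median_is_inverse_bag_size(self):
        df = pd.DataFrame({"slide_id": "s", "patch_index": range(10),
                           "weight": [0.1] * 10,
                           "morphology_call": ["tumor"] * 10})
        out = audit.attention_by_morphology(df, "all_patches")
        assert out.loc[out.morphology_call == "tumor", "median"].iloc[0] \
            == pytest.approx(0.1)

    def test_concentrated_class_ranks_higher(self):
        df = pd.DataFrame({
            "slide_id": "s", "patch_index": range(4),
            "weight": [0.4, 0.4, 0.1, 0.1],
            "morphology_call": ["tumor", "tumor", "stroma", "stroma"]})
        out = audit.attention_by_morphology(df).set_index("morphology_call")
        assert out.loc["tumor", "median"] > out.loc["stroma", "median"]

    @pytest.mark.parametrize("grouping", ["all_patches", "median_per_slide",
                                          "max_per_slide"])
    def test_matches_bruteforce_recomputation(self, grouping):
        df = _attention_frame()
        out = audit.attention_by_morphology(df, grouping) \
                   .set_index("morphology_call")
        for cls in df["morphology_call"].unique():
            if grouping == "all_patches":
                vals = df.loc[df.morphology_call == cls, "weight"].to_numpy()
            else:
                agg = np.median if grouping == "median_per_slide" else np.max
                vals = np.array([
                    agg(df[(df.slide_id == sid)
                           & (df.morphology_call == cls)]["weight"])
                    for sid in df.slide_id.unique()])
            assert out.loc[cls, "median"] == pytest.approx(np.median(vals))
            assert out.loc[cls, "max"] == pytest.approx(np.max(vals))

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ValueError):
            audit.attention_by_morphology(_attention_frame(), "bogus")


class TestTopK:
    def test_49_bags_of_250_give_1225_reviewed(self):
        rng = np.random.default_rng(0)
        total = 0
        for b in range(49):
            bag = pd.DataFrame({"weight": rng.random(250)})
            total += len(audit.top_k_patches(bag, k=25))
        assert total == 1225

    def test_k_equals_bag_size_returns_whole_bag(self):
        bag = pd.DataFrame({"weight": [0.2, 0.5, 0.3]})
        assert len(audit.top_k_patches(bag, k=3)) == 3

    def test_k_one_is_argmax(self):
        bag = pd.DataFrame({"weight": [0.2, 0.5, 0.3]})
        assert audit.top_k_patches(bag, k=1)["weight"].iloc[0] == 0.5

    def test_descending_with_index_tiebreak(self):
        bag = pd.DataFrame({"weight": [0.3, 0.5, 0.3, 0.5]})
        top = audit.top_k_patches(bag, k=4)
        assert list(top.index) == [1, 3, 0, 2]

    def test_small_bag_rejected(self):
        with pytest.raises(ValueError):
            audit.top_k_patches(pd.DataFrame({"weight": [0.1]}), k=2)


class TestBagSummaries:
    def test_identical_rows_sd_zero_mode_is_row(self):
        table = generate_review_table(1, 1, seed=0)
        rows = pd.concat([table] * 5, ignore_index=True)
        out = audit.summarize_bag(rows, "mutant")
        assert out["tumor_nuclei_fraction_sd"] == 0.0
        assert out["cytology"] == rows["cytology"].iloc[0]

    def test_numeric_stats(self):
        table = generate_review_table(1, 3, seed=0).copy()
        table["necrosis_fraction"] = [0.1, 0.2, 0.9]
        out = audit.summarize_bag(table, "wildtype")
        assert out["necrosis_fraction_mean"] == pytest.approx(0.4)
        assert out["necrosis_fraction_min"] == pytest.approx(0.1)
        assert out["necrosis_fraction_max"] == pytest.approx(0.9)

    def test_mode_matches_bruteforce_on_25_rows(self):
        table = generate_review_table(1, 25, seed=5)
        out = audit.summarize_bag(table, "mutant")
        for fld in ("predominant_architecture", "cytology"):
            counts = table[fld].value_counts()
            winners = sorted(counts[counts == counts.max()].index)
            assert out[fld] == winners[0]
            assert out[f"{fld}_tie"] == (len(winners) > 1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            audit.summarize_bag(generate_review_table(1, 1).iloc[:0], "mutant")

    def test_summaries_keep_top_k_only(self):
        table = generate_review_table(4, 50, seed=2)
        rng = np.random.default_rng(0)
        table["weight"] = rng.random(len(table))
        out = audit.summarize_bags(table, k=25)
        assert len(out) == 4
        assert (out["n_patches"] == 25).all()


class TestGroupComparisons:
    def _summaries(self, n=40, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            status = "mutant" if i % 2 == 0 else "wildtype"
            base = 0.5 + (shift if status == "mutant" else 0.0)
            rows.append({"bag_id": f"B{i}", "predicted_status": status,
                         "tumor_nuclei_fraction_mean": rng.normal(base, 0.1),
                         "predominant_architecture":
                             "solid" if rng.random() < 0.5 else "acinar"})
        return pd.DataFrame(rows)

    def test_identical_groups_p_one(self):
        s = self._summaries(seed=1)
        # statuses alternate, so repeating each value twice gives the two
        # groups identical value multisets
        s["tumor_nuclei_fraction_mean"] = np.repeat(
            np.tile([0.2, 0.5, 0.8, 0.4], 5), 2)
        out = audit.compare_numeric(s, "tumor_nuclei_fraction", "mean")
        assert out["p"] == pytest.approx(1.0, abs=1e-9)

    def test_planted_three_sd_difference_significant_with_fdr(self):
        # 3-sd group difference at n = 25 per group: q < 0.05 in nearly
        # every replicate
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rows = []
            for i in range(50):
                status = "mutant" if i < 25 else "wildtype"
                val = rng.normal(0.3 if status == "mutant" else 0.6, 0.1)
                row = {"bag_id": f"B{i}", "predicted_status": status}
                for fld in audit.NUMERIC_REVIEW_FIELDS:
                    for stat in ("mean", "sd", "min", "max"):
                        row[f"{fld}_{stat}"] = rng.normal(0.5, 0.1)
                row["tumor_nuclei_fraction_mean"] = val
                rows.append(row)
            res = audit.compare_all_numeric(pd.DataFrame(rows))
            q = res.loc[(res.variable == "tumor_nuclei_fraction")
                        & (res.statistic == "mean"), "q"].iloc[0]
            hits += q < 0.05
        assert hits >= 19

    def test_r_sign_matches_planted_direction(self):
        out = audit.compare_numeric(self._summaries(shift=0.3, seed=2),
                                    "tumor_nuclei_fraction", "mean")
        assert out["r"] > 0  # mutant coded 1 and shifted upward

    def test_empty_group_rejected(self):
        s = self._summaries()
        s["predicted_status"] = "mutant"
        with pytest.raises(ValueError):
            audit.compare_numeric(s, "tumor_nuclei_fraction", "mean")

    def test_chi_square_closed_form_2x2(self):
        s = pd.DataFrame({
            "predicted_status": ["mutant"] * 10 + ["wildtype"] * 10,
            "predominant_architecture": ["lepidic"] * 10 + ["solid"] * 10})
        out = audit.compare_categorical(s, "predominant_architecture")
        assert out["chi2"] == pytest.approx(20.0)

    def test_chi_square_identical_distributions_p_near_one(self):
        s = pd.DataFrame({
            "predicted_status": ["mutant", "mutant", "wildtype", "wildtype"] * 10,
            "predominant_architecture": ["solid", "acinar"] * 20})
        out = audit.compare_categorical(s, "predominant_architecture")
        assert out["p"] > 0.9

    def test_chi_square_matches_bruteforce_expected_counts(self):
        s = self._summaries(seed=4)
        out = audit.compare_categorical(s, "predominant_architecture")
        table = pd.crosstab(s["predicted_status"],
                            s["predominant_architecture"]).to_numpy()
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2 = ((table - expected) ** 2 / expected).sum()
        assert out["chi2"] == pytest.approx(chi2)


def brute_force_rules(transactions, consequent, min_support, min_confidence):
    """Power-set oracle over all item subsets (feasible for <= 8 transactions
    with few items)."""
    items = sorted({i for t in transactions for i in t})
    n = len(transactions)

    def supp(s):
        return sum(1 for t in transactions if set(s) <= t) / n

    rules = []
    others = [i for i in items if i != consequent]
    for r in range(1, len(others) + 1):
        for antecedent in combinations(others, r):
            s_full = supp(set(antecedent) | {consequent})
            s_ant = supp(antecedent)
            if s_full < min_support or s_ant == 0:
                continue
            conf = s_full / s_ant
            if conf >= min_confidence:
                rules.append((frozenset(antecedent), s_full, conf,
                              conf / supp({consequent})))
    return {r[0]: r[1:] for r in rules}


class TestMineRules:
    def test_single_transaction_lift_one(self):
        rules = audit.mine_rules([{"A", "mutant"}], "mutant",
                                 min_support=0.1, min_confidence=0.5)
        (rule,) = [r for r in rules if r.antecedent == frozenset({"A"})]
        assert rule.lift == pytest.approx(1.0)
        assert rule.support == 1.0

    def test_matches_powerset_oracle_on_8_transactions(self):
        transactions = [
            {"a", "b", "wt"}, {"a", "wt"}, {"b", "c", "wt"}, {"c", "mut"},
            {"a", "b", "c", "mut"}, {"b", "wt"}, {"a", "c", "wt"},
            {"b", "c", "mut"},
        ]
        mined = audit.mine_rules(transactions, "wt", min_support=0.125,
                                 min_confidence=0.25)
        oracle = brute_force_rules(transactions, "wt", 0.125, 0.25)
        assert {r.antecedent for r in mined} == set(oracle)
        for r in mined:
            s, c, l = oracle[r.antecedent]
            assert r.support == pytest.approx(s)
            assert r.confidence == pytest.approx(c)
            assert r.lift == pytest.approx(l)

    def test_lift_identity_holds_for_every_rule(self):
        table = generate_review_table(30, 5, seed=3)
        summaries = audit.summarize_bags(table)
        transactions = audit.transactions_from_summaries(summaries)
        supp_c = np.mean([("status=wildtype" in t) for t in transactions])
        for r in audit.mine_rules(transactions, "status=wildtype",
                                  min_support=0.1, min_confidence=0.3):
            assert r.lift == pytest.approx(r.confidence / supp_c)

    def test_ranked_by_lift_then_support(self):
        table = generate_review_table(40, 5, seed=6)
        rules = audit.mine_rules(
            audit.transactions_from_summaries(audit.summarize_bags(table)),
            "status=mutant", min_support=0.1, min_confidence=0.3)
        keys = [(-r.lift, -r.support) for r in rules]
        assert keys == sorted(keys)

    def test_null_association_lift_converges_to_one(self):
        # independent planted items: every mined single-item rule's lift
        # approaches 1 as the number of bags grows
        table = generate_review_table(600, 3, seed=1,
                                      effects=ReviewEffects.null())
        summaries = audit.summarize_bags(table)
        transactions = audit.transactions_from_summaries(summaries)
        rules = audit.mine_rules(transactions, "status=wildtype",
                                 min_support=0.15, min_confidence=0.2,
                                 max_len=2)
        assert rules, "expected at least one frequent single-item rule"
        for r in rules:
            assert r.lift == pytest.approx(1.0, abs=0.25)

    def test_nonpositive_support_rejected(self):
        with pytest.raises(ValueError):
            audit.mine_rules([{"a"}], "a", min_support=0.0)

    def test_planted_solid_wildtype_rule_beats_independence(self):
        table = generate_review_table(300, 15, seed=8,
                                      effects=ReviewEffects.default())
        summaries = audit.summarize_bags(table)
        transactions = audit.transactions_from_summaries(summaries)
        rules = audit.mine_rules(transactions, "status=wildtype",
                                 min_support=0.05, min_confidence=0.3,
                                 max_len=2)
        solid = [r for r in rules if r.antecedent
                 == frozenset({"predominant_architecture=solid"})]
        assert solid and solid[0].lift > 1.2
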
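"""Screening statistics: Fleiss' kappa, ICC(2,1), and the pure-sample rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nsavoice import (
    PanelSpec,
    RatingTable,
    filter_pure,
    fleiss_kappa,
    icc_two_way_random,
    intra_rater_reliability,
    simulate_panel,
)


def table_from_rows(rows, duplicate_map=None):
    df = pd.DataFrame(rows, columns=["sample_id", "rater_id", "category", "confidence"])
    return RatingTable(df, duplicate_map or {})


def panel_rows(votes: dict[str, list[str]], conf=0.9):
    rows = []
    for sid, cats in votes.items():
        for r, cat in enumerate(cats):
            rows.append((sid, f"r{r}", cat, conf))
    return rows


class TestFleissKappa:
    def test_unanimous_panels_kappa_one(self):
        counts = np.array([[5, 0, 0, 0]] * 10)
        assert fleiss_kappa(counts) == 1.0
        two_cats = np.array([[5, 0, 0, 0], [0, 5, 0, 0]])
        assert fleiss_kappa(two_cats) == pytest.approx(1.0, abs=1e-12)

    def test_small_matrix_long_hand_oracle(self):
        # 3 items x 3 raters x 2 categories: P = (1, 1/3, 1/3), Pbar = 5/9,
        # column shares (2/3, 1/3) give Pe = 5/9, hence kappa = 0.
        counts = np.array([[3, 0], [2, 1], [1, 2]])
        assert fleiss_kappa(counts) == pytest.approx(0.0, abs=1e-9)

    def test_matches_statsmodels_on_random_counts(self, rng):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        counts = rng.multinomial(5, [0.4, 0.3, 0.2, 0.1], size=40)
        assert fleiss_kappa(counts) == pytest.approx(sm_fleiss(counts), abs=1e-12)

    def test_unbalanced_panel_rejected(self):
        with pytest.raises(ValueError, match="balanced"):
            fleiss_kappa(np.array([[5, 0, 0, 0], [3, 1, 0, 0]]))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_kappa_at_most_one(self, seed):
        counts = np.random.default_rng(seed).multinomial(
            5, [0.25, 0.25, 0.25, 0.25], size=12
        )
        assert fleiss_kappa(counts) <= 1.0 + 1e-12


class TestICC:
    def test_identical_raters_perfect_agreement(self):
        y = np.tile(np.arange(1.0, 6.0)[:, None], (1, 3))
        assert icc_two_way_random(y) == pytest.approx(1.0)

    def test_constant_offset_penalized(self):
        base = np.arange(1.0, 6.0)
        y = np.column_stack([base, base + 2.0])
        assert icc_two_way_random(y) < 1.0

    def test_anova_mean_squares_oracle(self):
        # frozen value verified against an independent two-way ANOVA
        # decomposition (pingouin's ICC(A,1) on the same matrix)
        m = np.array([[9.0, 2.0, 5.0], [6.0, 1.0, 3.0], [8.0, 4.0, 6.0], [7.0, 1.0, 2.0]])
        assert icc_two_way_random(m) == pytest.approx(0.16806722689075623, abs=1e-12)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        y = rng.normal(0, 1, (8, 4)) + rng.normal(0, 1, (8, 1))
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(8), 4),
                "raters": np.tile(np.arange(4), 8),
                "scores": y.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="targets", raters="raters", ratings="scores")
        assert icc_two_way_random(y) == pytest.approx(
            float(ref.loc[ref.Type == "ICC(A,1)", "ICC"].iloc[0]), abs=1e-9
        )
        assert icc_two_way_random(y, measure="average") == pytest.approx(
            float(ref.loc[ref.Type == "ICC(A,k)", "ICC"].iloc[0]), abs=1e-9
        )

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            icc_two_way_random(np.ones((4, 3)))


class TestFilterPure:
    def test_unanimous_high_confidence_pure(self):
        table = table_from_rows(panel_rows({"a": ["breathy"] * 5}, conf=0.9))
        out = filter_pure(table)
        assert out.pure_labels == {"a": "breathy"}

    def test_one_low_confidence_agreeing_rater_rejects(self):
        rows = [
            ("a", "r0", "modal", 0.9),
            ("a", "r1", "modal", 0.9),
            ("a", "r2", "modal", 0.9),
            ("a", "r3", "modal", 0.7),  # agreeing but under the gate
            ("a", "r4", "breathy", 0.9),
        ]
        out = filter_pure(table_from_rows(rows))
        assert out.pure_labels == {} and out.rejected_ids == ["a"]

    def test_below_agreement_floor_rejects(self):
        votes = {"a": ["pressed", "pressed", "pressed", "modal", "modal"]}
        out = filter_pure(table_from_rows(panel_rows(votes)))
        assert out.rejected_ids == ["a"]

    def test_none_majority_rejected(self):
        votes = {"a": ["none"] * 5}
        out = filter_pure(table_from_rows(panel_rows(votes)))
        assert out.rejected_ids == ["a"]

    def test_disagreeing_rater_confidence_irrelevant(self):
        rows = [("a", f"r{i}", "modal", 0.85) for i in range(4)]
        rows.append(("a", "r4", "pressed", 0.1))  # dissenter's confidence ignored
        out = filter_pure(table_from_rows(rows))
        assert out.pure_labels == {"a": "modal"}

    @given(st.integers(0, 2**32 - 1), st.floats(0.5, 1.0), st.integers(3, 5))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_in_both_thresholds(self, seed, min_conf, min_agree):
        rng = np.random.default_rng(seed)
        rows = []
        cats = ["modal", "breathy", "pressed", "none"]
        for s in range(8):
            for r in range(5):
                rows.append(
                    (f"s{s}", f"r{r}", cats[rng.integers(4)], float(rng.uniform(0, 1)))
                )
        table = table_from_rows(rows)
        base = set(filter_pure(table, min_agree, min_conf).pure_labels)
        stricter_conf = set(filter_pure(table, min_agree, min(min_conf + 0.1, 1.0)).pure_labels)
        stricter_agree = set(filter_pure(table, min_agree + 1, min_conf).pure_labels)
        assert stricter_conf <= base and stricter_agree <= base

    def test_identity_panel_all_pure_with_true_labels(self):
        labels = ["modal", "breathy", "pressed"] * 10
        spec = PanelSpec(confidence_beta=(5000.0, 500.0), n_duplicates=3, seed=6)
        table = simulate_panel(labels, spec)
        out = filter_pure(table)
        assert out.n_pure == len(labels)
        assert all(out.pure_labels[f"s{i:04d}"] == labels[i] for i in range(len(labels)))
        assert set(out.pure_labels) & set(table.duplicate_map.values()) == set()


class TestIntraRater:
    def test_perfectly_consistent_rater(self):
        labels = ["modal", "breathy", "pressed", "modal"]
        table = simulate_panel(labels, PanelSpec(n_duplicates=4, seed=1))
        rel = intra_rater_reliability(table)
        assert (rel["kappa"] == 1.0).all()

    def test_requires_duplicates(self):
        table = simulate_panel(["modal"] * 3, PanelSpec(seed=1))
        with pytest.raises(ValueError, match="duplicated"):
            intra_rater_reliability(table)


class TestRatingTableValidation:
    def test_duplicate_rating_rows_rejected(self):
        rows = [("a", "r0", "modal", 0.9), ("a", "r0", "modal", 0.8)]
        with pytest.raises(ValueError, match="duplicate"):
            table_from_rows(rows)

    def test_confidence_range_enforced(self):
        with pytest.raises(ValueError, match="confidence"):
            table_from_rows([("a", "r0", "modal", 1.5)])

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="categories"):
            table_from_rows([("a", "r0", "falsetto", 0.9)])
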
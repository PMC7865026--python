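import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaqomics.mirna_integration import (
    aggregate_target_predictions,
    anticorrelation_filter,
    fold_change_quadrants,
    lda_discriminant_genes,
    mirna_cytokine_correlation,
    stars_for_p,
)
from plaqomics.omics_io import CytokinePanel, ExpressionMatrix, OmicsIOError


def _mat(values, groups=None, kind="normalized"):
    df = pd.DataFrame(values)
    if groups is None:
        groups = pd.Series({c: "A" for c in df.columns})
    return ExpressionMatrix(df, groups, kind)


class TestAggregatePredictions:
    def _raw(self, rows):
        return pd.DataFrame(rows, columns=["mirna", "gene", "algorithm"])

    def test_two_algorithms_retained(self):
        raw = self._raw([("m1", "g1", "diana"), ("m1", "g1", "mirdb")])
        out = aggregate_target_predictions(raw)
        assert len(out) == 1 and out.iloc[0]["support"] == 2

    def test_single_algorithm_dropped(self):
        raw = self._raw([("m1", "g1", "diana")])
        assert len(aggregate_target_predictions(raw)) == 0

    def test_duplicate_vote_counts_once(self):
        raw = self._raw([("m1", "g1", "diana"), ("m1", "g1", "diana")])
        assert len(aggregate_target_predictions(raw)) == 0

    def test_unknown_algorithm(self):
        raw = self._raw([("m1", "g1", "made_up")])
        with pytest.raises(OmicsIOError, match="made_up"):
            aggregate_target_predictions(raw)

    def test_row_order_invariance(self, rng):
        rows = [
            ("m1", "g1", "diana"),
            ("m1", "g1", "mirdb"),
            ("m2", "g2", "pictar"),
            ("m2", "g2", "targetscan"),
            ("m2", "g2", "miranda"),
        ]
        raw = self._raw(rows)
        shuffled = raw.sample(frac=1.0, random_state=1)
        pd.testing.assert_frame_equal(
            aggregate_target_predictions(raw), aggregate_target_predictions(shuffled)
        )

    def test_support_monotone_in_algorithms(self):
        base = self._raw([("m1", "g1", "diana"), ("m1", "g1", "mirdb")])
        more = pd.concat(
            [base, self._raw([("m1", "g1", "pictar")])], ignore_index=True
        )
        s0 = aggregate_target_predictions(base).iloc[0]["support"]
        s1 = aggregate_target_predictions(more).iloc[0]["support"]
        assert s1 >= s0


class TestAnticorrelationFilter:
    def _pair_tables(self, x, y):
        samples = [f"s{j}" for j in range(len(x))]
        groups = pd.Series({s: "HIV" for s in samples})
        mir = ExpressionMatrix(
            pd.DataFrame([x], index=["m1"], columns=samples), groups, "normalized"
        )
        mrna = ExpressionMatrix(
            pd.DataFrame([y], index=["g1"], columns=samples), groups, "normalized"
        )
        targets = pd.DataFrame({"mirna": ["m1"], "gene": ["g1"], "support": [3]})
        return targets, mir, mrna

    def test_perfectly_repressed_retained(self):
        x = np.arange(12, dtype=float)
        y = 24.0 - 2.0 * x + np.r_[np.zeros(6), 0.1 * np.ones(6)]
        targets, mir, mrna = self._pair_tables(x, y)
        out = anticorrelation_filter(targets, mir, mrna)
        assert len(out) == 1
        assert out.iloc[0]["r"] < -0.9

    def test_weak_negative_excluded(self, rng):
        # build a vector pair with r about -0.4
        x = rng.normal(size=200)
        y = -0.4 * x + np.sqrt(1 - 0.16) * rng.normal(size=200)
        targets, mir, mrna = self._pair_tables(x - x.min(), y - y.min())
        out = anticorrelation_filter(targets, mir, mrna, r_max=-0.5)
        assert len(out) == 0

    def test_positive_excluded_regardless_of_p(self):
        x = np.arange(12, dtype=float)
        targets, mir, mrna = self._pair_tables(x, 2 * x + 1)
        assert len(anticorrelation_filter(targets, mir, mrna)) == 0

    def test_too_few_samples(self):
        targets, mir, mrna = self._pair_tables(np.arange(3.0), np.arange(3.0))
        with pytest.raises(OmicsIOError):
            anticorrelation_filter(targets, mir, mrna)

    def test_stricter_thresholds_subset(self, rng):
        samples = [f"s{j}" for j in range(12)]
        groups = pd.Series({s: "HIV" for s in samples})
        mir = ExpressionMatrix(
            pd.DataFrame(
                rng.uniform(0, 10, size=(20, 12)),
                index=[f"m{i}" for i in range(20)],
                columns=samples,
            ),
            groups,
            "normalized",
        )
        mrna = ExpressionMatrix(
            pd.DataFrame(
                rng.uniform(0, 10, size=(20, 12)),
                index=[f"g{i}" for i in range(20)],
                columns=samples,
            ),
            groups,
            "normalized",
        )
        targets = pd.DataFrame(
            [(f"m{i}", f"g{j}", 2) for i in range(20) for j in range(20)],
            columns=["mirna", "gene", "support"],
        )
        strict = anticorrelation_filter(targets, mir, mrna, r_max=-0.5, p_max=0.05)
        loose = anticorrelation_filter(targets, mir, mrna, r_max=-0.4, p_max=0.10)
        strict_pairs = set(zip(strict["mirna"], strict["gene"]))
        loose_pairs = set(zip(loose["mirna"], loose["gene"]))
        assert strict_pairs <= loose_pairs


class TestLDASelection:
    def _expr(self, X, genes, samples, labels):
        groups = pd.Series(labels, index=samples)
        return (
            ExpressionMatrix(
                pd.DataFrame(X, index=genes, columns=samples), groups, "normalized"
            ),
            groups,
        )

    def test_perfect_gene_ranked_first(self, rng):
        n = 12
        genes = [f"g{i}" for i in range(10)]
        samples = [f"s{j}" for j in range(n)]
        labels = ["A"] * 6 + ["B"] * 6
        X = rng.uniform(4, 6, size=(10, n))
        # near-perfect separator: tiny within-class noise, huge between-class gap
        X[4] = np.r_[1.0 + 0.05 * rng.normal(size=6), 9.0 + 0.05 * rng.normal(size=6)]
        expr, groups = self._expr(X, genes, samples, labels)
        sel = lda_discriminant_genes(expr, groups, k=3)
        assert sel.ranked.index[0] == "g4"
        assert sel.separated

    def test_gene_order_permutation_invariant(self, rng):
        n = 12
        genes = [f"g{i}" for i in range(15)]
        samples = [f"s{j}" for j in range(n)]
        labels = ["A"] * 6 + ["B"] * 6
        X = rng.uniform(2, 8, size=(15, n))
        expr, groups = self._expr(X, genes, samples, labels)
        perm = rng.permutation(15)
        expr2, _ = self._expr(X[perm], [genes[i] for i in perm], samples, labels)
        s1 = lda_discriminant_genes(expr, groups, k=5)
        s2 = lda_discriminant_genes(expr2, groups, k=5)
        assert set(s1.selected) == set(s2.selected)

    def test_affine_rescale_invariance(self, rng):
        n = 12
        genes = [f"g{i}" for i in range(8)]
        samples = [f"s{j}" for j in range(n)]
        labels = ["A"] * 6 + ["B"] * 6
        X = rng.uniform(2, 8, size=(8, n))
        expr, groups = self._expr(X, genes, samples, labels)
        X2 = X.copy()
        X2[3] = 7.0 * X2[3] + 2.0
        expr2, _ = self._expr(X2, genes, samples, labels)
        s1 = lda_discriminant_genes(expr, groups, k=4)
        s2 = lda_discriminant_genes(expr2, groups, k=4)
        assert list(s1.ranked.index) == list(s2.ranked.index)

    def test_three_labels_error(self, rng):
        genes = ["g0", "g1"]
        samples = [f"s{j}" for j in range(9)]
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        expr, groups = self._expr(rng.uniform(1, 2, (2, 9)), genes, samples, labels)
        with pytest.raises(OmicsIOError):
            lda_discriminant_genes(expr, groups)

    def test_planted_overlap_single_seed(self, rng):
        n0 = n1 = 6
        p, k = 200, 27
        X = rng.normal(8, 1, size=(p, n0 + n1))
        X[:k, n0:] += 2.5
        genes = [f"g{i:03d}" for i in range(p)]
        samples = [f"s{j}" for j in range(n0 + n1)]
        labels = ["A"] * n0 + ["B"] * n1
        expr, groups = self._expr(X, genes, samples, labels)
        sel = lda_discriminant_genes(expr, groups, k=k)
        assert len(set(sel.selected) & set(genes[:k])) >= 20


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.04, "*"), (0.004, "**"), (0.0005, "***"), (0.05, ""), (0.2, ""), (0.001, "**")],
    )
    def test_mapping(self, p, expected):
        assert stars_for_p(p) == expected

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=100, deadline=None)
    def test_pure_function_consistent(self, p):
        s = stars_for_p(p)
        if p < 0.001:
            assert s == "***"
        elif p < 0.005:
            assert s == "**"
        elif p < 0.05:
            assert s == "*"
        else:
            assert s == ""


class TestMirnaCytokineCorrelation:
    def _inputs(self, x, y):
        samples = [f"s{j}" for j in range(len(x))]
        groups = pd.Series({s: "HIV" for s in samples})
        mir = ExpressionMatrix(
            pd.DataFrame([x], index=["m1"], columns=samples), groups, "normalized"
        )
        panel = CytokinePanel(pd.DataFrame({"IL6": y}, index=samples))
        return mir, panel

    def test_monotone_rho_one(self):
        mir, panel = self._inputs([1.0, 2.0, 3.0, 4.0, 5.0], [2.0, 8.0, 9.0, 30.0, 31.0])
        out = mirna_cytokine_correlation(mir, panel)
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_tied_ranks_match_brute_force(self, rng):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0])
        y = rng.uniform(1, 5, size=6)
        mir, panel = self._inputs(x, y)
        out = mirna_cytokine_correlation(mir, panel)

        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        rxc, ryc = rx - rx.mean(), ry - ry.mean()
        rho = (rxc @ ryc) / np.sqrt((rxc @ rxc) * (ryc @ ryc))
        assert out.iloc[0]["r"] == pytest.approx(rho, abs=1e-10)

    def test_constant_vector_missing(self):
        mir, panel = self._inputs([3.0] * 6, [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        out = mirna_cytokine_correlation(mir, panel)
        assert np.isnan(out.iloc[0]["r"]) and out.iloc[0]["stars"] == ""


class TestFoldChangeQuadrants:
    def _de(self, mapping):
        return pd.DataFrame({"log2fc": mapping}).rename_axis("feature_id")

    def test_up_down(self):
        a = self._de({"g1": 1.0})
        b = self._de({"g1": -1.0})
        out = fold_change_quadrants(a, b, ["g1"])
        assert out.iloc[0]["quadrant"] == "up/down"

    def test_zero_is_null(self):
        a = self._de({"g1": 0.0})
        b = self._de({"g1": 0.0})
        assert fold_change_quadrants(a, b, ["g1"]).iloc[0]["quadrant"] == "null"

    def test_missing_gene_excluded(self):
        a = self._de({"g1": 1.0})
        b = self._de({"g2": 1.0})
        out = fold_change_quadrants(a, b, ["g1", "g2"])
        assert list(out["quadrant"]) == ["missing", "missing"]

    def test_counts_match_truth(self, rng):
        genes = [f"g{i}" for i in range(27)]
        fa = rng.normal(size=27)
        fb = rng.normal(size=27)
        fa[:15] = np.abs(fa[:15]) + 0.1
        fb[:15] = -np.abs(fb[:15]) - 0.1
        a = self._de(dict(zip(genes, fa)))
        b = self._de(dict(zip(genes, fb)))
        out = fold_change_quadrants(a, b, genes)
        counts = out["quadrant"].value_counts()
        expected_updown = int(
            sum((fa > 0) & (fb < 0))
        )
        assert counts["up/down"] == expected_updown
        assert expected_updown >= 15
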
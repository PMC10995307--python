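import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from herbmine.extraction import Transaction
from herbmine.reference import phylum_herb_counts
from herbmine.stats import (
    ContingencyTable,
    build_gene_herb_tables,
    build_phylum_herb_table,
    chi_square_independence,
    choose_test,
    fisher_exact,
    log2_transform,
    pubmed_query,
    results_table,
    table_report,
)

from oracles import fisher_exact_oracle


def table(counts, rows=None, cols=None):
    counts = np.asarray(counts)
    r, c = counts.shape
    return ContingencyTable(
        rows or [f"r{i}" for i in range(r)],
        cols or [f"c{j}" for j in range(c)],
        counts,
    )


def random_table(rng, r, c, total):
    while True:
        flat = rng.multinomial(total, np.full(r * c, 1 / (r * c)))
        counts = flat.reshape(r, c)
        if (counts.sum(0) > 0).all() and (counts.sum(1) > 0).all():
            return table(counts)


class TestChiSquare:
    def test_published_reference_matrix(self):
        with pytest.warns(UserWarning, match="expected counts below 5"):
            res = chi_square_independence(phylum_herb_counts())
        assert res.statistic == pytest.approx(695.2055226775681, rel=1e-12)
        assert res.dof == 70
        assert res.p_value < 0.001
        assert res.method == "chi_square"

    def test_perfectly_independent_table(self):
        res = chi_square_independence(table([[10, 10], [10, 10]]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, 3, 3, 200)
        res = chi_square_independence(t)
        ref = sps.chi2_contingency(t.counts, correction=False)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)
        assert res.dof == ref.dof

    def test_statistic_invariant_under_permutation(self):
        rng = np.random.default_rng(0)
        t = random_table(rng, 3, 4, 120)
        perm = table(t.counts[::-1, ::-1])
        assert chi_square_independence(perm).statistic == pytest.approx(
            chi_square_independence(t).statistic
        )

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="zero marginal"):
            chi_square_independence(table([[0, 0], [5, 5]]))


class TestFisherExact:
    def test_two_by_two_known_value(self):
        res = fisher_exact(table([[1, 9], [11, 3]]))
        assert res.method == "fisher_exact"
        assert res.p_value == pytest.approx(0.00276, abs=5e-6)

    def test_most_probable_table_has_p_one(self):
        assert fisher_exact(table([[5, 5], [5, 5]])).p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_two_by_two_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, 2, 2, int(rng.integers(8, 41)))
        ours = fisher_exact(t).p_value
        ref = sps.fisher_exact(t.counts).pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    @pytest.mark.parametrize("shape", [(2, 2), (3, 2)])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, shape, seed):
        rng = np.random.default_rng(100 + seed)
        t = random_table(rng, *shape, int(rng.integers(6, 41)))
        assert fisher_exact(t).p_value == pytest.approx(
            fisher_exact_oracle(t.counts), abs=1e-10
        )

    def test_enumeration_cap_raises(self):
        big = table((np.ones((4, 4)) * 50).astype(int))
        with pytest.raises(ValueError, match="chi-square"):
            fisher_exact(big, max_tables=100)


class TestChooseTest:
    def test_large_total_uses_chi_square(self):
        res = choose_test(table([[500, 600], [700, 800]]))
        assert res.method == "chi_square"

    def test_small_total_uses_fisher(self):
        res = choose_test(table([[2, 3], [7, 8]]))
        assert res.method == "fisher_exact"

    def test_boundary_total_goes_to_fisher(self):
        t = table([[10, 5], [5, 10]])
        assert t.total == 30
        assert choose_test(t, sample_threshold=30).method == "fisher_exact"

    def test_large_counts_fisher_and_chi_square_agree_in_magnitude(self):
        t = table([[40, 10], [15, 35]])
        pf = fisher_exact(t).p_value
        pc = chi_square_independence(t).p_value
        ratio = max(pf, pc) / min(pf, pc)
        assert ratio < 10


class TestBuilders:
    def txs(self):
        return [
            Transaction("E0", frozenset({"甘草", "人參"}), phylum="心臟門"),
            Transaction("E1", frozenset({"甘草"}), phylum="心臟門"),
            Transaction("E2", frozenset({"人參"}), phylum="肝臟門"),
            Transaction("E3", frozenset({"甘草", "人參"}), phylum="肝臟門"),
        ]

    def test_phylum_herb_counts_match_manual_count(self):
        t = build_phylum_herb_table(self.txs(), ["甘草", "人參"])
        df = t.to_dataframe()
        assert df.loc["心臟門", "甘草"] == 2
        assert df.loc["心臟門", "人參"] == 1
        assert df.loc["肝臟門", "甘草"] == 1
        assert df.loc["肝臟門", "人參"] == 2

    def test_unknown_herb_listed_in_error(self):
        with pytest.raises(ValueError, match="麝香"):
            build_phylum_herb_table(self.txs(), ["甘草", "麝香"])

    def test_zero_margin_rows_dropped_with_warning(self):
        t = table([[3, 4], [0, 0]])
        with pytest.warns(UserWarning, match="dropping"):
            small = t.drop_zero_margins()
        assert small.counts.shape == (1, 2)

    def gene_counts(self):
        return pd.DataFrame(
            [[12, 30], [45, 60], [100, 210]],
            index=["知母", "甘草", "參芪注射液"],
            columns=["CASP3", "BCL2L1"],
        )

    def test_gene_herb_tables_are_3x2_with_control_rows(self):
        out = build_gene_herb_tables(self.gene_counts(), "甘草", "參芪注射液")
        assert len(out) == 1
        herb, g1, g2, t = out[0]
        assert (herb, g1, g2) == ("知母", "CASP3", "BCL2L1")
        assert t.row_labels == ["知母", "甘草", "參芪注射液"]
        assert t.counts.tolist() == [[12, 30], [45, 60], [100, 210]]

    def test_candidate_equal_to_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            build_gene_herb_tables(
                self.gene_counts(), "甘草", "參芪注射液", candidates=["甘草"]
            )

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            build_gene_herb_tables(self.gene_counts(), "當歸", "參芪注射液")

    def test_all_equal_counts_give_p_one(self):
        counts = pd.DataFrame(
            [[50, 50], [50, 50], [50, 50]],
            index=["知母", "甘草", "參芪注射液"],
            columns=["CASP3", "BCL2L1"],
        )
        (_, _, _, t), = build_gene_herb_tables(counts, "甘草", "參芪注射液")
        res = choose_test(t)
        assert res.method == "chi_square"
        assert res.p_value == pytest.approx(1.0)


class TestLog2Transform:
    def test_closed_form_values(self):
        out = log2_transform(np.array([[0, 1], [7, 3]]))
        assert out.tolist() == [[0.0, 1.0], [3.0, 2.0]]

    def test_monotone_and_preserves_labels(self):
        rng = np.random.default_rng(0)
        m = rng.integers(0, 100, (4, 5))
        out = log2_transform(m)
        order = np.argsort(m, axis=None)
        assert (np.diff(out.flatten()[order]) >= 0).all()
        df = pd.DataFrame(m, index=list("abcd"), columns=list("vwxyz"))
        out_df = log2_transform(df)
        assert list(out_df.index) == list("abcd")

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log2_transform(np.array([[-1, 2]]))


class TestReporting:
    def test_stars_track_thresholds(self):
        rows = [
            ("知母", "CASP3", "BCL2L1",
             chi_square_independence(table([[1, 40], [40, 1], [20, 20]]))),
            ("人參", "AKT2", "STAT3", fisher_exact(table([[2, 3], [3, 2]]))),
        ]
        df = results_table(rows)
        assert list(df.columns[:4]) == ["Herbs", "Gene_1", "Gene_2", "p-value"]
        assert df.iloc[0]["Significant"] == "**"  # tiny p
        assert df.iloc[1]["Significant"] == ""    # p near 1
        assert set(df["Chi-square"]) <= {"T", "F"}

    def test_bh_adjustment_column_optional(self):
        rows = [
            ("a", "g1", "g2", fisher_exact(table([[1, 9], [11, 3]]))),
            ("b", "g1", "g2", fisher_exact(table([[5, 5], [5, 5]]))),
        ]
        assert "p-adjusted (BH)" not in results_table(rows).columns
        adj = results_table(rows, bh_correction=True)
        assert (adj["p-adjusted (BH)"] >= adj["p-value"] - 1e-12).all()

    def test_report_footer_lines(self):
        t = phylum_herb_counts()
        with pytest.warns(UserWarning):
            res = chi_square_independence(t)
        report = table_report(t, res)
        assert "Statistic: 695.2055226775681." in report
        assert "Degree of freedom: 70." in report
        assert "p-value <0.001: True." in report


def test_pubmed_query_builder():
    q = pubmed_query("Glycyrrhiza uralensis", "CASP3")
    assert "Glycyrrhiza uralensis" in q and "CASP3" in q and " AND " in q


def test_contingency_table_csv_round_trip(tmp_path):
    t = phylum_herb_counts()
    path = tmp_path / "counts.csv"
    t.to_dataframe().to_csv(path)
    back = ContingencyTable.from_csv(path)
    assert back.row_labels == t.row_labels
    assert (back.counts == t.counts).all()
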
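import math

import numpy as np
import pandas as pd
import pytest

from smallrna_libbias.abundance import (
    UndetectableFoldDifference,
    correlation_matrix,
    families_in_all,
    fold_difference_qpcr,
    fold_difference_seq,
    pearson,
    qpcr_quantify,
    relative_abundance,
)
from smallrna_libbias.annotation import FamilyCountsTable
from smallrna_libbias.io_formats import CTTable


def ct_table(sample, rows):
    """rows: list of (mirna, [ct replicates])"""
    records = [
        {"sample_id": sample, "mirna": m, "ct": c, "replicate": i + 1}
        for m, cts in rows
        for i, c in enumerate(cts)
    ]
    return CTTable(pd.DataFrame(records))


@pytest.fixture
def counts():
    return FamilyCountsTable(
        families=["miR-1", "miR-206", "let-7b"],
        libraries=["lib_a", "lib_b"],
        counts=np.array([[30, 10], [10, 10], [10, 30]]),
    )


class TestRelativeAbundance:
    def test_fractions(self, counts):
        ra = relative_abundance(counts, "lib_a")
        assert ra.fractions == {"miR-1": 0.6, "miR-206": 0.2, "let-7b": 0.2}
        assert ra.n_total == 50

    def test_zero_column_rejected(self):
        table = FamilyCountsTable(["f"], ["a"], np.array([[0]]))
        with pytest.raises(ValueError, match="zero"):
            relative_abundance(table, "a")

    def test_fractions_sum_to_one(self, counts):
        for lib in counts.libraries:
            assert sum(relative_abundance(counts, lib).fractions.values()) == pytest.approx(1.0)


class TestPearson:
    def test_identity(self):
        assert pearson([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_anticorrelation(self):
        assert pearson([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # cov/(sd_x * sd_y) computed by hand for (1,2,3) vs (2,4,7)
        assert pearson([1, 2, 3], [2, 4, 7]) == pytest.approx(0.99339927, abs=1e-6)

    def test_agrees_with_covariance_oracle(self):
        rng = np.random.default_rng(100)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            x, y = rng.normal(size=n), rng.normal(size=n)
            direct = ((x - x.mean()) * (y - y.mean())).sum() / (
                np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
            )
            assert abs(pearson(x, y) - direct) < 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pearson([1, 2, 3], [1, 2])


class TestCorrelationMatrix:
    def test_identical_vectors_give_unit_offdiagonal(self):
        t = {"a": {"f1": 0.5, "f2": 0.3, "f3": 0.2}, "b": {"f1": 0.5, "f2": 0.3, "f3": 0.2}}
        mat = correlation_matrix(t, ["f1", "f2", "f3"])
        assert mat.loc["a", "b"] == pytest.approx(1.0)

    def test_symmetric_with_unit_diagonal(self):
        t = {
            "a": {"f1": 0.5, "f2": 0.3, "f3": 0.2},
            "b": {"f1": 0.1, "f2": 0.6, "f3": 0.3},
            "c": {"f1": 0.4, "f2": 0.4, "f3": 0.2},
        }
        mat = correlation_matrix(t, ["f1", "f2", "f3"])
        assert np.allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 1.0)

    def test_missing_family_named_in_error(self):
        t = {"a": {"f1": 1.0, "f2": 0.0, "f3": 0.0}, "b": {"f1": 0.2, "f2": 0.8}}
        with pytest.raises(ValueError, match="f3"):
            correlation_matrix(t, ["f1", "f2", "f3"])


class TestQPCRQuantify:
    def test_reference_is_exactly_one(self):
        ct = ct_table("s1", [("miR-16", [21, 21, 21]), ("miR-1", [19, 19, 19])])
        quants = qpcr_quantify(ct)["s1"]
        assert quants["miR-16"].relative_abundance == 1.0

    def test_one_cycle_lower_doubles_abundance(self):
        ct = ct_table("s1", [("miR-16", [21, 21, 21]), ("miR-1", [20, 20, 20])])
        assert qpcr_quantify(ct)["s1"]["miR-1"].relative_abundance == pytest.approx(2.0)

    def test_replicates_averaged_before_differencing(self):
        ct = ct_table("s1", [("miR-16", [21, 21, 21]), ("miR-1", [20, 20, 23])])
        q = qpcr_quantify(ct)["s1"]["miR-1"]
        assert q.delta_ct == pytest.approx(0.0)
        assert q.relative_abundance == pytest.approx(1.0)

    def test_missing_reference_rejected(self):
        ct = ct_table("s1", [("miR-1", [20, 20, 20])])
        with pytest.raises(ValueError, match="miR-16"):
            qpcr_quantify(ct)


class TestFoldDifferenceQPCR:
    def test_identical_tables_give_zero(self):
        ct = ct_table("s", [("miR-16", [21]), ("miR-1", [19])])
        assert fold_difference_qpcr(ct, ct, "miR-1") == pytest.approx(0.0)

    def test_sign_convention(self):
        # delta CT 5 in A vs 6 in B: A is one cycle closer -> 2-fold higher
        ct_a = ct_table("a", [("miR-16", [20]), ("miR-1", [25])])
        ct_b = ct_table("b", [("miR-16", [20]), ("miR-1", [26])])
        assert fold_difference_qpcr(ct_a, ct_b, "miR-1") == pytest.approx(1.0)

    def test_reference_fold_is_zero_by_construction(self):
        ct_a = ct_table("a", [("miR-16", [20]), ("miR-1", [25])])
        ct_b = ct_table("b", [("miR-16", [23]), ("miR-1", [26])])
        assert fold_difference_qpcr(ct_a, ct_b, "miR-16") == 0.0

    def test_missing_mirna_rejected(self):
        ct = ct_table("s", [("miR-16", [21])])
        with pytest.raises(ValueError, match="miR-1"):
            fold_difference_qpcr(ct, ct, "miR-1")


class TestFoldDifferenceSeq:
    def test_equal_frequencies_give_zero(self):
        table = FamilyCountsTable(["f1", "f2"], ["a", "b"], np.array([[10, 20], [10, 20]]))
        assert fold_difference_seq(table, "a", "b", "f1", pseudocount=0) == pytest.approx(0.0)

    def test_frequency_doubling_gives_one(self):
        # f1 frequency 0.2 in a, 0.1 in b
        table = FamilyCountsTable(["f1", "f2"], ["a", "b"], np.array([[20, 10], [80, 90]]))
        assert fold_difference_seq(table, "a", "b", "f1", pseudocount=0) == pytest.approx(1.0)

    def test_zero_count_with_zero_pseudocount_is_undetectable(self):
        table = FamilyCountsTable(["f1", "f2"], ["a", "b"], np.array([[0, 10], [90, 90]]))
        with pytest.raises(UndetectableFoldDifference):
            fold_difference_seq(table, "a", "b", "f1", pseudocount=0)

    def test_pseudocount_rescues_zero_counts(self):
        table = FamilyCountsTable(["f1", "f2"], ["a", "b"], np.array([[0, 10], [90, 90]]))
        value = fold_difference_seq(table, "a", "b", "f1", pseudocount=0.5)
        assert math.isfinite(value) and value < 0

    def test_antisymmetric_under_library_swap(self, counts):
        fwd = fold_difference_seq(counts, "lib_a", "lib_b", "miR-1")
        rev = fold_difference_seq(counts, "lib_b", "lib_a", "miR-1")
        assert fwd == pytest.approx(-rev)


def test_families_in_all_requires_nonzero_everywhere():
    table = FamilyCountsTable(
        ["f1", "f2", "f3"],
        ["a", "b"],
        np.array([[3, 1], [0, 5], [2, 2]]),
    )
    assert families_in_all(table, ["a", "b"]) == ["f1", "f3"]
    assert families_in_all(table, ["b"]) == ["f1", "f2", "f3"]
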
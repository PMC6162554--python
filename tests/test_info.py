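"""Information-measure unit and property tests against naive loop oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiweight import info
from epiweight.info import (
    DiscreteDistribution,
    JointTable,
    entropy,
    entropy_from_counts,
    interaction_gain,
    interaction_weight_factor,
    joint_counts,
    joint_entropy,
    joint_mutual_information,
    mutual_information,
    symmetrical_uncertainty,
)

from _oracles import (
    entropy_of_column,
    interaction_gain_loop,
    interaction_weight_factor_loop,
    joint_entropy_of_columns,
    joint_mutual_information_loop,
    mutual_information_definitional,
    symmetrical_uncertainty_loop,
)
from conftest import dataset_from_cells, make_dataset, random_dataset


def dist(probs):
    return DiscreteDistribution(tuple(range(len(probs))), tuple(probs), n=100)


class TestEntropy:
    @pytest.mark.parametrize(
        "probs, expected",
        [
            ((1 / 3, 1 / 3, 1 / 3), math.log(3)),
            ((1.0, 0.0, 0.0), 0.0),
            ((0.5, 0.25, 0.25), 1.5 * math.log(2)),
        ],
    )
    def test_closed_forms(self, probs, expected):
        assert entropy(dist(probs)) == pytest.approx(expected, abs=1e-12)

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            DiscreteDistribution((0, 1), (0.6, 0.6), n=10)
        with pytest.raises(ValueError):
            DiscreteDistribution((0, 1), (-0.2, 1.2), n=10)

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            entropy_from_counts(np.zeros((3, 3)))


class TestJointCounts:
    def test_single_snp_with_phenotype(self):
        ds = make_dataset([[0, 0, 0, 0]], [0, 0, 1, 1])
        table = joint_counts(ds, [0], include_phenotype=True)
        assert table.counts.shape == (3, 2)
        assert table.counts[0, 0] == 2 and table.counts[0, 1] == 2
        assert table.counts[1:].sum() == 0

    def test_three_way_table_has_27_genotype_cells(self):
        rng = np.random.default_rng(0)
        ds = random_dataset(rng, n=50, n_snps=4)
        table = joint_counts(ds, [0, 1, 2], include_phenotype=False)
        assert table.counts.shape == (3, 3, 3)
        assert table.counts.size == 27

    def test_cells_conserve_sample_count(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            ds = random_dataset(rng)
            t = joint_counts(ds, [0, 1], include_phenotype=True)
            assert t.counts.sum() == ds.n_samples

    def test_duplicate_index_rejected(self):
        ds = make_dataset([[0, 1], [1, 2]], [0, 1])
        with pytest.raises(ValueError, match="duplicate"):
            joint_counts(ds, [0, 0])

    def test_missing_genotypes_demand_imputation(self):
        ds = make_dataset([[0, -1], [1, 2]], [0, 1])
        with pytest.raises(ValueError, match="impute"):
            joint_counts(ds, [0])


class TestJointEntropy:
    def test_duplicated_snp_adds_nothing(self):
        col = [0, 1, 2, 1, 0, 2, 1, 1]
        ds = make_dataset([col, col], [0, 1] * 4)
        h_pair = joint_entropy(joint_counts(ds, [0, 1], include_phenotype=False))
        h_one = joint_entropy(joint_counts(ds, [0], include_phenotype=False))
        assert h_pair == pytest.approx(h_one, abs=1e-12)

    def test_additive_for_independent_uniform_pair(self):
        cells = {(0, 0, 0): 13, (0, 1, 0): 12, (1, 0, 0): 13, (1, 1, 0): 12,
                 (0, 0, 1): 12, (0, 1, 1): 13, (1, 0, 1): 12, (1, 1, 1): 13}
        # product structure 25/25/25/25 over the two genotype axes
        ds = dataset_from_cells(cells, n_snps=2)
        h = joint_entropy(joint_counts(ds, [0, 1], include_phenotype=False))
        assert h == pytest.approx(2 * math.log(2), abs=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 30, size=(3, 3))
        counts[0, 0] += 1  # non-empty
        table = JointTable(["a", "b"], counts, int(counts.sum()))
        n = counts.sum()
        expect = -sum(
            (c / n) * math.log(c / n) for c in counts.ravel() if c > 0
        )
        assert joint_entropy(table) == pytest.approx(expect, abs=1e-12)

    def test_at_least_max_marginal_entropy(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            ds = random_dataset(rng)
            t = joint_counts(ds, [0, 1], include_phenotype=False)
            h_joint = joint_entropy(t)
            h_margins = [
                entropy_from_counts(t.counts.sum(axis=ax)) for ax in (0, 1)
            ]
            assert h_joint >= max(h_margins) - 1e-12


class TestMutualInformation:
    def test_independent_product_counts_give_zero(self):
        cells = {(0, 0): 30, (0, 1): 30, (1, 0): 20, (1, 1): 20}
        ds = dataset_from_cells(cells, n_snps=1)
        assert mutual_information(joint_counts(ds, [0])) == pytest.approx(0, abs=1e-12)

    def test_identity_equals_phenotype_entropy(self):
        ds = make_dataset([[0, 0, 1, 1]], [0, 0, 1, 1])
        assert mutual_information(joint_counts(ds, [0])) == pytest.approx(
            math.log(2), abs=1e-12
        )

    def test_definitional_sum_agrees_with_entropy_difference(self):
        cells = {(0, 0): 30, (0, 1): 10, (1, 0): 10, (1, 1): 30}
        ds = dataset_from_cells(cells, n_snps=1)
        by_entropy = mutual_information(joint_counts(ds, [0]))
        by_sum = mutual_information_definitional(
            ds.genotypes[:, 0].tolist(), ds.phenotype.tolist()
        )
        assert by_entropy == pytest.approx(by_sum, abs=1e-10)

    def test_requires_single_snp_axis_and_phenotype(self):
        ds = make_dataset([[0, 1], [1, 2]], [0, 1])
        with pytest.raises(ValueError):
            mutual_information(joint_counts(ds, [0], include_phenotype=False))


class TestJointMutualInformation:
    def test_k1_reduces_to_mutual_information(self):
        rng = np.random.default_rng(11)
        ds = random_dataset(rng)
        assert joint_mutual_information(ds, [0]) == pytest.approx(
            mutual_information(joint_counts(ds, [0])), abs=1e-12
        )

    def test_deterministic_pair_reaches_phenotype_entropy(self, xor_dataset):
        assert joint_mutual_information(xor_dataset, [0, 1]) == pytest.approx(
            math.log(2), abs=1e-12
        )

    def test_permuted_phenotype_is_near_zero(self):
        rng = np.random.default_rng(12)
        n = 6000
        geno = rng.integers(0, 3, size=(n, 2)).astype(np.int8)
        pheno = rng.permutation(np.repeat([0, 1], n // 2)).astype(np.int8)
        ds = make_dataset([geno[:, 0], geno[:, 1]], pheno)
        jmi = joint_mutual_information(ds, [0, 1])
        # under independence 2n*I ~ chi2(df=8); stay below a generous quantile
        assert 0 <= jmi < 50.0 / (2 * n)

    def test_k_above_limit_names_cell_bound(self):
        rng = np.random.default_rng(13)
        ds = random_dataset(rng, n=30, n_snps=8)
        with pytest.raises(ValueError, match="3\\^7"):
            joint_mutual_information(ds, list(range(7)))


class TestInteractionGain:
    def test_duplicate_partner_is_pure_redundancy(self):
        cells = {(0, 0): 30, (0, 1): 10, (1, 0): 10, (1, 1): 30}
        ds1 = dataset_from_cells(cells, n_snps=1)
        ds = make_dataset(
            [ds1.genotypes[:, 0], ds1.genotypes[:, 0]], ds1.phenotype
        )
        i_x = mutual_information(joint_counts(ds, [0]))
        assert interaction_gain(0, 1, ds) == pytest.approx(-i_x, abs=1e-12)

    def test_xor_gain_is_phenotype_entropy(self, xor_dataset):
        assert interaction_gain(0, 1, xor_dataset) == pytest.approx(
            math.log(2), abs=1e-12
        )

    def test_mutually_independent_triple_gives_zero(self):
        cells = {}
        for a in (0, 1):
            for b in (0, 1):
                for c in (0, 1):
                    cells[(a, b, c)] = 10
        ds = dataset_from_cells(cells, n_snps=2)
        assert interaction_gain(0, 1, ds) == pytest.approx(0.0, abs=1e-12)

    def test_same_snp_rejected(self):
        ds = make_dataset([[0, 1], [1, 2]], [0, 1])
        with pytest.raises(ValueError):
            interaction_gain(0, 0, ds)


class TestInteractionWeightFactor:
    def test_independent_triple_is_neutral(self):
        cells = {(a, b, c): 10 for a in (0, 1) for b in (0, 1) for c in (0, 1)}
        ds = dataset_from_cells(cells, n_snps=2)
        assert interaction_weight_factor(0, 1, ds) == pytest.approx(1.0, abs=1e-12)

    def test_redundant_duplicate_pair_is_at_most_one(self):
        cells = {(0, 0): 30, (0, 1): 10, (1, 0): 10, (1, 1): 30}
        ds1 = dataset_from_cells(cells, n_snps=1)
        ds = make_dataset([ds1.genotypes[:, 0], ds1.genotypes[:, 0]], ds1.phenotype)
        assert interaction_weight_factor(0, 1, ds) <= 1.0

    def test_xor_matches_oracle(self, xor_dataset):
        x = xor_dataset.genotypes[:, 0].tolist()
        y = xor_dataset.genotypes[:, 1].tolist()
        denom = entropy_of_column(x) + entropy_of_column(y)
        assert interaction_weight_factor(0, 1, xor_dataset) == pytest.approx(
            1.0 + math.log(2) / denom, abs=1e-12
        )

    def test_both_constant_defined_as_neutral(self):
        ds = make_dataset([[0, 0, 0, 0], [1, 1, 1, 1]], [0, 1, 0, 1])
        assert interaction_weight_factor(0, 1, ds) == 1.0


class TestSymmetricalUncertainty:
    def test_identity_standard_one_modified_two(self):
        ds = make_dataset([[0, 0, 1, 1]], [0, 0, 1, 1])
        assert symmetrical_uncertainty(0, ds, "standard") == pytest.approx(1.0)
        assert symmetrical_uncertainty(0, ds, "modified") == pytest.approx(2.0)

    def test_independence_zero_in_both_modes(self):
        cells = {(0, 0): 30, (0, 1): 30, (1, 0): 20, (1, 1): 20}
        ds = dataset_from_cells(cells, n_snps=1)
        assert symmetrical_uncertainty(0, ds, "standard") == pytest.approx(0, abs=1e-12)
        assert symmetrical_uncertainty(0, ds, "modified") == pytest.approx(0, abs=1e-12)

    def test_mode_ratio_matches_entropy_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            ds = random_dataset(rng)
            std = symmetrical_uncertainty(0, ds, "standard")
            mod = symmetrical_uncertainty(0, ds, "modified")
            if std == 0:
                continue
            x = ds.genotypes[:, 0].tolist()
            c = ds.phenotype.tolist()
            expect = (entropy_of_column(x) + entropy_of_column(c)) / (
                joint_entropy_of_columns([x, c])
            )
            assert mod / std == pytest.approx(expect, abs=1e-10)

    def test_constant_phenotype_is_an_error(self):
        ds = make_dataset([[0, 1, 2, 1]], [1, 1, 1, 1])
        with pytest.raises(ValueError, match="constant"):
            symmetrical_uncertainty(0, ds)

    def test_unknown_mode_rejected(self):
        ds = make_dataset([[0, 1, 2, 1]], [0, 1, 0, 1])
        with pytest.raises(ValueError):
            symmetrical_uncertainty(0, ds, mode="fancy")


@settings(deadline=None, max_examples=60, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_properties_on_random_datasets(seed):
    """MI identity, bounds, axis-permutation invariance, SU mode ordering."""
    rng = np.random.default_rng(seed)
    ds = random_dataset(rng, n=int(rng.integers(20, 120)), n_snps=3)
    x = ds.genotypes[:, 0].tolist()
    c = ds.phenotype.tolist()
    hx = entropy_of_column(x)
    hc = entropy_of_column(c)

    i_entropy = mutual_information(joint_counts(ds, [0]))
    i_sum = mutual_information_definitional(x, c)
    assert abs(i_entropy - i_sum) <= 1e-10
    assert -1e-12 <= i_entropy <= min(hx, hc) + 1e-12

    t01 = joint_counts(ds, [0, 1], include_phenotype=False)
    t10 = joint_counts(ds, [1, 0], include_phenotype=False)
    assert joint_entropy(t01) == pytest.approx(joint_entropy(t10), abs=1e-12)

    std = symmetrical_uncertainty(0, ds, "standard")
    mod = symmetrical_uncertainty(0, ds, "modified")
    assert mod >= std - 1e-12


@settings(deadline=None, max_examples=40, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_all_measures_match_sample_loop_oracles(seed):
    """Counting-path results equal naive nested-loop oracles on raw samples."""
    rng = np.random.default_rng(seed)
    ds = random_dataset(rng, n=int(rng.integers(20, 201)), n_snps=int(rng.integers(3, 11)))
    cols = [ds.genotypes[:, j].tolist() for j in range(min(3, ds.n_snps))]
    c = ds.phenotype.tolist()

    assert joint_mutual_information(ds, list(range(len(cols)))) == pytest.approx(
        max(0.0, joint_mutual_information_loop(cols, c)), abs=1e-10
    )
    assert interaction_gain(0, 1, ds) == pytest.approx(
        interaction_gain_loop(cols[0], cols[1], c), abs=1e-10
    )
    assert interaction_weight_factor(0, 1, ds) == pytest.approx(
        interaction_weight_factor_loop(cols[0], cols[1], c), abs=1e-10
    )
    for mode in ("standard", "modified"):
        assert symmetrical_uncertainty(0, ds, mode) == pytest.approx(
            symmetrical_uncertainty_loop(cols[0], c, mode), abs=1e-10
        )
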
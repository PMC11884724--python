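import math

import numpy as np
import pytest

from ssrpopgen import (
    GenotypeMatrix,
    SimulationSpec,
    allele_frequencies,
    gene_flow,
    grade_fst,
    grade_nm,
    nei_distance,
    pairwise_fst,
    per_locus_fstats,
    simulate,
)


def _matrix(calls, pops):
    calls = np.asarray(calls)
    return GenotypeMatrix(
        [f"i{k}" for k in range(calls.shape[0])],
        [f"L{j}" for j in range(calls.shape[1])],
        calls,
        pops,
    )


def test_definitional_ratios_hold_on_every_row(study_like):
    matrix, _ = study_like
    freqs = allele_frequencies(matrix)
    table = per_locus_fstats(freqs).loc[matrix.loci]
    for _, r in table.iterrows():
        assert r["Fis"] == pytest.approx(
            (r["Mean He"] - r["Mean Ho"]) / r["Mean He"]
        )
        assert r["Fit"] == pytest.approx((r["Ht"] - r["Mean Ho"]) / r["Ht"])
        assert r["Fst"] == pytest.approx((r["Ht"] - r["Mean He"]) / r["Ht"])
        assert r["Nm"] == pytest.approx((1 / r["Fst"] - 1) / 4)


def test_zero_observed_heterozygosity_forces_fis_fit_one():
    # all homozygotes, polymorphic in both pops -> Mean Ho = 0, Mean He > 0
    m = _matrix(
        [
            [[1, 1]], [[2, 2]], [[1, 1]], [[2, 2]],
            [[2, 2]], [[3, 3]], [[2, 2]], [[3, 3]],
        ],
        ["A"] * 4 + ["B"] * 4,
    )
    row = per_locus_fstats(allele_frequencies(m)).loc["L0"]
    assert row["Mean Ho"] == 0.0
    assert row["Mean He"] > 0.0
    assert row["Fis"] == pytest.approx(1.0)
    assert row["Fit"] == pytest.approx(1.0)


def test_fixed_for_different_alleles_complete_differentiation():
    m = _matrix([[[1, 1]], [[1, 1]], [[2, 2]], [[2, 2]]], ["A", "A", "B", "B"])
    row = per_locus_fstats(allele_frequencies(m)).loc["L0"]
    # tp = (0.5, 0.5): Ht = 0.5, mean He = 0 -> Fst = 1, Nm = 0
    assert row["Ht"] == pytest.approx(0.5)
    assert row["Mean He"] == pytest.approx(0.0)
    assert row["Fst"] == pytest.approx(1.0)
    assert row["Nm"] == pytest.approx(0.0)


def test_identical_frequencies_no_differentiation():
    m = _matrix([[[1, 2]], [[1, 2]], [[1, 2]], [[1, 2]]], ["A", "A", "B", "B"])
    row = per_locus_fstats(allele_frequencies(m)).loc["L0"]
    assert row["Ht"] == pytest.approx(row["Mean He"])
    assert row["Fst"] == pytest.approx(0.0)
    assert np.isinf(row["Nm"])


def test_pairwise_fst_duplicate_population_is_zero():
    m = _matrix(
        [[[1, 2]], [[1, 1]], [[1, 2]], [[1, 1]]], ["A", "A", "B", "B"]
    )
    d = pairwise_fst(allele_frequencies(m))
    assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_pairwise_fst_fixed_difference_is_one():
    m = _matrix(
        [[[1, 1], [3, 3]], [[1, 1], [3, 3]], [[2, 2], [4, 4]], [[2, 2], [4, 4]]],
        ["A", "A", "B", "B"],
    )
    d = pairwise_fst(allele_frequencies(m))
    assert d.values[0, 1] == pytest.approx(1.0)


def test_pairwise_fst_two_population_recovery():
    """Mean estimate matches the two-population expectation F/(2-F).

    The pairwise estimator (Ht - mean He)/Ht compares each pair to the
    average of the pair, so a drift parameter F is recovered as about
    F/(2-F); the Monte-Carlo mean over replicates must sit near that
    value, not near F itself.
    """
    nominal = 0.15
    expected = nominal / (2 - nominal)
    ests = []
    for seed in range(200):
        m, _ = simulate(
            SimulationSpec(
                n_populations=2, sizes=(50, 50), fst=nominal, fis=0.5, seed=seed
            )
        )
        d = pairwise_fst(allele_frequencies(m))
        ests.append(d.values[0, 1])
    assert np.mean(ests) == pytest.approx(expected, abs=0.02)


def test_nei_distance_identical_populations_zero():
    m = _matrix([[[1, 2]], [[1, 1]], [[1, 2]], [[1, 1]]], ["A", "A", "B", "B"])
    d = nei_distance(allele_frequencies(m))
    assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_nei_distance_disjoint_alleles_infinite():
    m = _matrix([[[1, 1]], [[1, 1]], [[2, 2]], [[2, 2]]], ["A", "A", "B", "B"])
    d = nei_distance(allele_frequencies(m))
    assert np.isinf(d.values[0, 1])


def test_nei_distance_two_locus_hand_worked():
    # pop A: locus1 p=(1.0) allele 1; locus2 p=(0.5,0.5) alleles (3,4)
    # pop B: locus1 p=(0.5,0.5) alleles (1,2); locus2 p=(1.0) allele 3
    m = _matrix(
        [
            [[1, 1], [3, 4]], [[1, 1], [3, 4]],
            [[1, 2], [3, 3]], [[1, 2], [3, 3]],
        ],
        ["A", "A", "B", "B"],
    )
    # Jx = 1 + 0.5, Jy = 0.5 + 1, Jxy = 0.5 + 0.5
    expected = -math.log(1.0 / math.sqrt(1.5 * 1.5))
    d = nei_distance(allele_frequencies(m))
    assert d.values[0, 1] == pytest.approx(expected)


def test_nei_unbiased_not_larger_than_standard(study_like):
    matrix, _ = study_like
    freqs = allele_frequencies(matrix)
    d72 = nei_distance(freqs, "nei1972").values
    d78 = nei_distance(freqs, "nei1978-unbiased").values
    # the correction shrinks within-population identities -> smaller D
    assert (d78 <= d72 + 1e-9).all()


@pytest.mark.parametrize(
    "fst,nm", [(0.2, 1.0), (1.0, 0.0), (0.5, 0.25)]
)
def test_gene_flow_closed_form(fst, nm):
    assert gene_flow(np.array([fst]))[0] == pytest.approx(nm)


def test_gene_flow_matrix_and_sentinel():
    from ssrpopgen import DistanceMatrix

    d = DistanceMatrix(["a", "b"], np.array([[0.0, 0.2], [0.2, 0.0]]),
                       kind="pairwise-fst")
    nm = gene_flow(d)
    assert nm.values[0, 1] == pytest.approx(1.0)
    d0 = DistanceMatrix(["a", "b"], np.zeros((2, 2)), kind="pairwise-fst")
    assert np.isinf(gene_flow(d0).values[0, 1])


@pytest.mark.parametrize(
    "fst,grade",
    [(0.19, "high"), (0.15, "high"), (0.05, "medium"), (0.149, "medium"),
     (0.049, "low")],
)
def test_grade_fst(fst, grade):
    assert grade_fst(fst) == grade


@pytest.mark.parametrize(
    "nm,grade",
    [(1.15, "high"), (1.0, "high"), (0.99, "medium"), (0.25, "medium"),
     (0.249, "low")],
)
def test_grade_nm(nm, grade):
    assert grade_nm(nm) == grade


def test_grades_reject_negative():
    with pytest.raises(ValueError):
        grade_fst(-0.1)
    with pytest.raises(ValueError):
        grade_nm(-0.1)
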
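import itertools

import numpy as np
import pytest

from ssrpopgen import (
    GenotypeMatrix,
    SimulationSpec,
    individual_squared_distances,
    run_amova,
    simulate,
)
from ssrpopgen.genotypes import MISSING


def _matrix(calls, pops):
    calls = np.asarray(calls)
    return GenotypeMatrix(
        [f"i{k}" for k in range(calls.shape[0])],
        [f"L{j}" for j in range(calls.shape[1])],
        calls,
        pops,
    )


def _sp_distance(g1, g2):
    """Exhaustive one-locus squared genotypic distance oracle."""
    a = sorted(g1)
    b = sorted(g2)
    if a == b:
        return 0
    shared = 0
    bb = list(b)
    for x in a:
        if x in bb:
            bb.remove(x)
            shared += 1
    het1, het2 = a[0] != a[1], b[0] != b[1]
    if shared == 1:
        if het1 and het2:
            return 1  # (ij, ik)
        return 1  # (ii, ij)
    # no shared allele
    if het1 and het2:
        return 2  # (ij, kl)
    if het1 != het2:
        return 3  # (ii, jk)
    return 4  # (ii, jj)


@pytest.mark.parametrize(
    "g1,g2,expected",
    [
        ((1, 1), (1, 1), 0),
        ((1, 2), (1, 2), 0),
        ((1, 1), (1, 2), 1),
        ((1, 2), (1, 3), 1),
        ((1, 2), (3, 4), 2),
        ((1, 1), (2, 3), 3),
        ((1, 1), (2, 2), 4),
    ],
)
def test_squared_distance_table(g1, g2, expected):
    m = _matrix([[g1], [g2]], ["A", "A"])
    d = individual_squared_distances(m)
    assert d.values[0, 1] == pytest.approx(expected)
    assert _sp_distance(g1, g2) == expected


def test_distances_match_exhaustive_tabulation():
    rng = np.random.default_rng(42)
    calls = rng.integers(1, 5, size=(5, 3, 2))
    m = _matrix(calls, ["A"] * 5)
    d = individual_squared_distances(m)
    for i, j in itertools.combinations(range(5), 2):
        expected = sum(
            _sp_distance(tuple(m.calls[i, l]), tuple(m.calls[j, l]))
            for l in range(3)
        )
        assert d.values[i, j] == pytest.approx(expected)


def test_missing_locus_excluded_from_pair_sum():
    calls = [[[1, 2], [3, 3]], [[1, 1], [0, 0]]]
    m = _matrix(calls, ["A", "A"])
    d = individual_squared_distances(m)
    assert d.values[0, 1] == pytest.approx(1)  # only locus 1 counted


def test_degrees_of_freedom_study_design(study_like):
    matrix, _ = study_like
    res = run_amova(
        individual_squared_distances(matrix),
        matrix.pop_of,
        n_permutations=0,
    )
    assert list(res.table["df"]) == [4, 86, 90]
    assert res.p_value is None


def test_all_identical_individuals_degenerate():
    calls = [[[1, 1]]] * 6
    m = _matrix(calls, ["A"] * 3 + ["B"] * 3)
    res = run_amova(individual_squared_distances(m), m.pop_of, 99, seed=0)
    assert res.table["SS"].sum() == pytest.approx(0.0)
    assert res.percent_among == 0.0
    assert res.percent_within == 100.0
    assert res.p_value == 1.0


def test_ss_identity_and_percent_sum(study_like):
    matrix, _ = study_like
    res = run_amova(
        individual_squared_distances(matrix), matrix.pop_of, n_permutations=0
    )
    t = res.table
    assert t.loc["Total", "SS"] == pytest.approx(
        t.loc["Among Pops", "SS"] + t.loc["Within Pops", "SS"], abs=1e-6
    )
    assert res.percent_among + res.percent_within == pytest.approx(100.0)


def test_population_relabeling_invariance(study_like):
    matrix, _ = study_like
    d = individual_squared_distances(matrix)
    res1 = run_amova(d, matrix.pop_of, n_permutations=0)
    renamed = {ind: f"zone-{p}" for ind, p in matrix.pop_of.items()}
    res2 = run_amova(d, renamed, n_permutations=0)
    assert np.allclose(
        res1.table.fillna(0).values, res2.table.fillna(0).values
    )


def test_among_percentage_monotone_in_differentiation():
    pcts = []
    for fst in (0.0, 0.1, 0.3):
        vals = []
        for seed in range(5):
            m, _ = simulate(
                SimulationSpec(
                    n_populations=2, sizes=(30, 30), fst=fst, fis=0.5,
                    seed=1000 + seed,
                )
            )
            res = run_amova(
                individual_squared_distances(m), m.pop_of, n_permutations=0
            )
            vals.append(res.percent_among)
        pcts.append(np.mean(vals))
    assert pcts[0] < pcts[1] < pcts[2]


def test_null_differentiation_small_among_component():
    m, _ = simulate(
        SimulationSpec(n_populations=2, sizes=(40, 40), fst=0.0, fis=0.5, seed=9)
    )
    res = run_amova(
        individual_squared_distances(m), m.pop_of, n_permutations=199, seed=1
    )
    assert res.percent_among < 5.0
    assert res.p_value > 0.05


def test_singleton_population_rejected():
    m = _matrix([[[1, 1]], [[1, 2]], [[2, 2]]], ["A", "A", "B"])
    with pytest.raises(ValueError, match="B"):
        run_amova(individual_squared_distances(m), m.pop_of, 0)
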
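import numpy as np
import pytest

from ssrpopgen import (
    BinningSpec,
    GenotypeMatrix,
    SimulationSpec,
    bin_alleles,
    read_genotypes,
    simulate,
    write_genotypes,
)
from ssrpopgen.genotypes import MISSING, GenotypeParseError, GenotypeStructureError


@pytest.mark.parametrize("dialect", ["long-table", "genalex-codominant"])
def test_round_trip_is_identity(tiny_matrix, tmp_path, dialect):
    path = tmp_path / "m.csv"
    write_genotypes(tiny_matrix, path, dialect)
    assert read_genotypes(path, dialect) == tiny_matrix


def test_round_trip_study_sized(tmp_path, study_like):
    matrix, _ = study_like
    path = tmp_path / "big.csv"
    write_genotypes(matrix, path, "genalex-codominant")
    back = read_genotypes(path, "genalex-codominant")
    assert back == matrix
    # one data row per individual after the three header rows
    assert len(path.read_text().strip().splitlines()) == 3 + matrix.n_individuals


def test_missing_code_written_verbatim(tiny_matrix, tmp_path):
    path = tmp_path / "m.csv"
    write_genotypes(tiny_matrix, path, "long-table", missing_code="-9")
    assert ",-9,-9" in path.read_text()
    assert read_genotypes(path, "long-table", missing_code="-9") == tiny_matrix


def test_single_band_becomes_homozygote(tmp_path):
    path = tmp_path / "single.csv"
    path.write_text("ind1,popA,Xcup53,150\n")
    m = read_genotypes(path, "long-table")
    assert m.n_individuals == 1 and m.n_loci == 1
    assert tuple(m.calls[0, 0]) == (150, 150)
    assert not m.missing_mask().any()


def test_pair_canonicalized_min_max():
    m = GenotypeMatrix(["a"], ["L"], np.array([[[204, 200]]]), ["P"])
    assert tuple(m.calls[0, 0]) == (200, 204)


def test_malformed_row_names_row(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("ind1,popA,loc1,150\nind2,popA,loc1,abc\n")
    with pytest.raises(GenotypeParseError, match="row 2"):
        read_genotypes(path, "long-table")


def test_genalex_header_body_mismatch(tiny_matrix, tmp_path):
    path = tmp_path / "m.csv"
    write_genotypes(tiny_matrix, path, "genalex-codominant")
    rows = path.read_text().splitlines()
    rows[0] = rows[0].replace("4", "5", 1)  # claim 5 individuals
    path.write_text("\n".join(rows) + "\n")
    with pytest.raises(GenotypeStructureError):
        read_genotypes(path, "genalex-codominant")


def test_all_missing_locus_warns_but_is_kept(tmp_path):
    path = tmp_path / "m.csv"
    path.write_text(
        "i1,P,locA,150,150\ni1,P,locB,0,0\ni2,P,locA,152,152\ni2,P,locB,0,0\n"
    )
    with pytest.warns(UserWarning, match="locB"):
        m = read_genotypes(path, "long-table")
    assert m.loci == ["locA", "locB"]


def test_population_sizes_sum_to_individual_count(study_like):
    matrix, _ = study_like
    sizes = [len(v) for v in matrix.population_indices().values()]
    assert sum(sizes) == matrix.n_individuals == 91
    assert matrix.n_loci == 13


# --- binning ---------------------------------------------------------------


def _one_locus(sizes):
    calls = np.array([[[s, s]] for s in sizes])
    return GenotypeMatrix(
        [f"i{k}" for k in range(len(sizes))],
        ["L"],
        calls,
        ["P"] * len(sizes),
    )


def test_tolerance_cluster_splits_on_large_gap():
    m = _one_locus([150, 151, 158])
    out = bin_alleles(m, BinningSpec(mode="tolerance-cluster", tolerance_bp=2))
    observed = set(out.calls[out.calls != MISSING].ravel())
    # single-linkage over {150, 151, 158}: gap 1 joins, gap 7 cuts
    assert observed == {150, 158}


def test_ladder_round_half_to_even():
    m = _one_locus([151])
    out = bin_alleles(
        m, BinningSpec(mode="ladder-round", ladder_offset=100, ladder_repeat=2)
    )
    # (151-100)/2 = 25.5 rounds to 26 (half to even) -> 100 + 52
    assert tuple(out.calls[0, 0]) == (152, 152)


def test_exact_mode_is_identity(tiny_matrix):
    assert bin_alleles(tiny_matrix, BinningSpec(mode="exact")) == tiny_matrix


def test_zero_tolerance_equals_exact(study_like):
    matrix, _ = study_like
    binned = bin_alleles(
        matrix, BinningSpec(mode="tolerance-cluster", tolerance_bp=0)
    )
    assert binned == matrix


@pytest.mark.parametrize("tol", [1, 3, 7])
def test_binning_never_increases_allele_count(tol):
    matrix, _ = simulate(SimulationSpec(seed=tol, ladder_repeat=3))
    binned = bin_alleles(
        matrix, BinningSpec(mode="tolerance-cluster", tolerance_bp=tol)
    )
    for j in range(matrix.n_loci):
        before = matrix.calls[:, j][matrix.calls[:, j] != MISSING]
        after = binned.calls[:, j][binned.calls[:, j] != MISSING]
        assert len(np.unique(after)) <= len(np.unique(before))


def test_negative_tolerance_rejected():
    with pytest.raises(ValueError):
        BinningSpec(mode="tolerance-cluster", tolerance_bp=-1)
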
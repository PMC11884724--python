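"""Distance-based analysis of molecular variance (AMOVA).

Genetic variance is partitioned into among- and within-population
components from a matrix of squared genotypic distances between
individuals.  The squared distance between two codominant diploid
genotypes at one locus follows Smouse & Peakall: half the squared
Euclidean distance between the allele-count vectors, which takes the
values 0 (same genotype), 1 (one allele swapped), 2 (heterozygotes with
no allele in common), 3 (homozygote vs heterozygote sharing nothing) and
4 (different homozygotes); per-individual-pair distances sum over the
loci both individuals have genotyped.

With N individuals in k populations of sizes n_p:

    SS_total  = (1/N) * sum_{i<j} d2_ij
    SS_within = sum_p (1/n_p) * sum_{i<j in p} d2_ij
    SS_among  = SS_total - SS_within
    sigma2_within = MS_within
    sigma2_among  = (MS_among - MS_within) / n0,
        n0 = (N - sum n_p^2 / N) / (k - 1)

Negative variance components are truncated to zero before percentages are
formed.  Significance of the among-population component is assessed by
permuting individuals across populations; the p-value includes the
observed statistic, p = (1 + #{sigma2_among_perm >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distance import DistanceMatrix
from .genotypes import MISSING, GenotypeMatrix

__all__ = ["AmovaResult", "individual_squared_distances", "run_amova"]


@dataclass
class AmovaResult:
    """AMOVA table plus the permutation test for the among component."""

    table: pd.DataFrame  # rows Among Pops / Within Pops / Total
    p_value: float | None
    n_permutations: int
    seed: int | None

    @property
    def percent_among(self) -> float:
        return float(self.table.loc["Among Pops", "Percentage of variation"])

    @property
    def percent_within(self) -> float:
        return float(self.table.loc["Within Pops", "Percentage of variation"])


def individual_squared_distances(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise squared genotypic distances between all individuals.

    Entries are sums over co-genotyped loci; a pair with no co-genotyped
    locus is NaN (an error downstream in AMOVA).
    """
    calls = matrix.calls
    n, L, _ = calls.shape
    present = ~matrix.missing_mask()  # (n, L)
    # allele-count representation per locus: dict allele -> column
    d2 = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    for j in range(L):
        col = calls[:, j, :]
        alleles = np.unique(col[col != MISSING])
        if alleles.size == 0:
            continue
        counts = np.zeros((n, alleles.size))
        for a_idx, a in enumerate(alleles):
            counts[:, a_idx] = (col == a).sum(axis=1)
        # 0.5 * squared Euclidean distance between count vectors
        sq = ((counts[:, None, :] - counts[None, :, :]) ** 2).sum(axis=2) / 2.0
        both = np.outer(present[:, j], present[:, j])
        d2 += np.where(both, sq, 0.0)
        shared += both.astype(int)
    d2[shared == 0] = np.nan
    np.fill_diagonal(d2, 0.0)
    return DistanceMatrix(list(matrix.individuals), d2, kind="individual-squared")


def _components(
    d2: np.ndarray, groups: np.ndarray, k: int
) -> tuple[float, float, float, float]:
    """(SS_among, SS_within, sigma2_among, sigma2_within) for integer groups."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    sizes = np.zeros(k)
    for g in range(k):
        idx = np.flatnonzero(groups == g)
        sizes[g] = idx.size
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += np.triu(sub, k=1).sum() / idx.size
    ss_among = ss_total - ss_within
    df_among = k - 1
    df_within = n - k
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (n - (sizes**2).sum() / n) / df_among
    s2_within = ms_within
    s2_among = (ms_among - ms_within) / n0
    return ss_among, ss_within, s2_among, s2_within


def run_amova(
    dist: DistanceMatrix,
    pop_of: dict[str, str],
    n_permutations: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level AMOVA on a squared-distance matrix.

    ``pop_of`` maps each individual label to its population.  Requires at
    least two populations, each with at least two individuals.  With
    ``n_permutations < 1`` the permutation test is skipped (p absent).
    """
    labels = dist.labels
    d2 = dist.values
    if np.isnan(d2).any():
        raise ValueError("distance matrix has undefined entries")
    pops = sorted({pop_of[l] for l in labels})
    k = len(pops)
    if k < 2:
        raise ValueError("AMOVA requires at least two populations")
    groups = np.array([pops.index(pop_of[l]) for l in labels])
    n = len(labels)
    sizes = np.bincount(groups, minlength=k)
    for p, s in zip(pops, sizes):
        if s < 2:
            raise ValueError(f"population {p!r} has fewer than two individuals")

    ss_among, ss_within, s2_among, s2_within = _components(d2, groups, k)
    df_among, df_within, df_total = k - 1, n - k, n - 1
    ss_total = ss_among + ss_within
    comp_among = max(s2_among, 0.0)
    comp_within = max(s2_within, 0.0)
    total_comp = comp_among + comp_within
    if total_comp > 0:
        pct_among = 100.0 * comp_among / total_comp
        pct_within = 100.0 * comp_within / total_comp
    else:  # degenerate all-zero distances
        pct_among, pct_within = 0.0, 100.0
    table = pd.DataFrame(
        {
            "df": [df_among, df_within, df_total],
            "SS": [ss_among, ss_within, ss_total],
            "MS": [ss_among / df_among, ss_within / df_within, np.nan],
            "Est. Var.": [comp_among, comp_within, comp_among + comp_within],
            "Percentage of variation": [pct_among, pct_within, 100.0],
        },
        index=pd.Index(["Among Pops", "Within Pops", "Total"], name="Source"),
    )

    p_value = None
    if n_permutations >= 1:
        if total_comp == 0:
            p_value = 1.0
        else:
            rng = np.random.default_rng(seed)
            hits = 0
            g = groups.copy()
            for _ in range(n_permutations):
                rng.shuffle(g)
                _, _, s2a, _ = _components(d2, g, k)
                if s2a >= s2_among:
                    hits += 1
            p_value = (1 + hits) / (1 + n_permutations)
    return AmovaResult(
        table=table, p_value=p_value, n_permutations=max(n_permutations, 0), seed=seed
    )
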
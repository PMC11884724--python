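"""Per-locus diversity statistics for codominant SSR data.

Allele frequencies are tallied over gene copies (2 per genotyped diploid
individual).  Two scopes are exposed explicitly: per-population frequencies
(used by the F-statistics and allelic-pattern modules) and pooled-sample
frequencies over all individuals (used for the marker summary table: major
allele frequency, allele number, gene diversity, PIC and observed
heterozygosity).

PIC follows Botstein et al. as implemented in PowerMarker:
``PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "FrequencyTable",
    "LocusSummary",
    "allele_frequencies",
    "locus_summary",
    "pic_from_frequencies",
    "gene_diversity",
    "classify_pic",
]


@dataclass
class FrequencyTable:
    """Per-locus allele frequencies, by population and pooled.

    Attributes
    ----------
    loci, populations : ordered labels.
    by_pop : locus -> DataFrame (populations x alleles) of frequencies;
        a row is NaN where the locus is entirely missing in that population.
    n : DataFrame (loci x populations) of genotyped individual counts.
    ho : DataFrame (loci x populations) of observed heterozygosity
        (NaN where the locus is untyped in the population).
    pooled : locus -> Series (allele -> frequency) over all individuals.
    pooled_n : Series (locus -> genotyped individual count, pooled).
    pooled_ho : Series (locus -> pooled observed heterozygosity).
    """

    loci: list[str]
    populations: list[str]
    by_pop: dict[str, pd.DataFrame]
    n: pd.DataFrame
    ho: pd.DataFrame
    pooled: dict[str, pd.Series]
    pooled_n: pd.Series
    pooled_ho: pd.Series

    def frequencies(self, locus: str, population: str | None = None) -> pd.Series:
        if population is None:
            return self.pooled[locus]
        return self.by_pop[locus].loc[population].dropna()


@dataclass(frozen=True)
class LocusSummary:
    """One marker row of the per-locus diversity report."""

    locus: str
    major_allele_frequency: float
    sample_size: int
    allele_number: int
    pic: float
    observed_heterozygosity: float
    gene_diversity: float


def _tally(calls: np.ndarray) -> tuple[pd.Series, int, float]:
    """Frequencies, genotyped count and Ho for one locus column (m, 2)."""
    genotyped = ~(calls == MISSING).all(axis=1)
    m = int(genotyped.sum())
    if m == 0:
        return pd.Series(dtype=float), 0, np.nan
    obs = calls[genotyped]
    alleles, counts = np.unique(obs.ravel(), return_counts=True)
    freqs = pd.Series(counts / (2 * m), index=alleles, dtype=float)
    ho = float((obs[:, 0] != obs[:, 1]).mean())
    return freqs, m, ho


def allele_frequencies(matrix: GenotypeMatrix) -> FrequencyTable:
    """Tally per-population and pooled allele frequencies for every locus."""
    pops = matrix.population_names()
    pop_idx = matrix.population_indices()
    by_pop: dict[str, pd.DataFrame] = {}
    pooled: dict[str, pd.Series] = {}
    n = pd.DataFrame(0, index=matrix.loci, columns=pops, dtype=int)
    ho = pd.DataFrame(np.nan, index=matrix.loci, columns=pops, dtype=float)
    pooled_n = pd.Series(0, index=matrix.loci, dtype=int)
    pooled_ho = pd.Series(np.nan, index=matrix.loci, dtype=float)
    for j, locus in enumerate(matrix.loci):
        col = matrix.calls[:, j, :]
        pfreq, pn, pho = _tally(col)
        pooled[locus] = pfreq
        pooled_n[locus] = pn
        pooled_ho[locus] = pho
        alleles = list(pfreq.index)
        table = pd.DataFrame(np.nan, index=pops, columns=alleles, dtype=float)
        for pop in pops:
            f, m, h = _tally(col[pop_idx[pop]])
            n.loc[locus, pop] = m
            ho.loc[locus, pop] = h
            if m > 0:
                table.loc[pop, :] = 0.0
                table.loc[pop, f.index] = f.values
        by_pop[locus] = table
    return FrequencyTable(
        loci=list(matrix.loci),
        populations=pops,
        by_pop=by_pop,
        n=n,
        ho=ho,
        pooled=pooled,
        pooled_n=pooled_n,
        pooled_ho=pooled_ho,
    )


def gene_diversity(p: np.ndarray | pd.Series) -> float:
    """Expected heterozygosity 1 - sum(p_i^2)."""
    p = np.asarray(p, dtype=float)
    return float(1.0 - np.sum(p**2))


def pic_from_frequencies(p: np.ndarray | pd.Series) -> float:
    """Polymorphic information content (Botstein et al.)."""
    p = np.asarray(p, dtype=float)
    s2 = np.sum(p**2)
    s4 = np.sum(p**4)
    # sum_{i<j} 2 p_i^2 p_j^2 == (sum p^2)^2 - sum p^4
    return float(1.0 - s2 - (s2**2 - s4))


_COLUMNS = [
    "Major Allele Frequency",
    "Sample Size",
    "Allele No",
    "PIC",
    "Observed Heterozygosity",
    "Gene Diversity",
]


def locus_summary(
    freqs: FrequencyTable, matrix: GenotypeMatrix | None = None
) -> pd.DataFrame:
    """Per-marker diversity report over the pooled sample.

    Returns a DataFrame indexed by locus with columns MAF, sample size,
    allele number, PIC, observed heterozygosity and gene diversity, plus
    ``Mean`` / ``Maximum value`` / ``Minimum value`` rows.  Loci with no
    genotyped individuals are reported as NaN and excluded from the
    summary rows.
    """
    rows = []
    for locus in freqs.loci:
        p = freqs.pooled[locus]
        if len(p) == 0:
            rows.append([np.nan] * 6)
            continue
        rows.append(
            [
                float(p.max()),
                int(freqs.pooled_n[locus]),
                int((p > 0).sum()),
                pic_from_frequencies(p.values),
                float(freqs.pooled_ho[locus]),
                gene_diversity(p.values),
            ]
        )
    df = pd.DataFrame(rows, index=pd.Index(freqs.loci, name="Markers"), columns=_COLUMNS)
    body = df.dropna(how="all")
    summary = pd.DataFrame(
        [body.mean(), body.max(), body.min()],
        index=["Mean", "Maximum value", "Minimum value"],
    )
    summary.loc[["Maximum value", "Minimum value"], "Sample Size"] = np.nan
    return pd.concat([df, summary])


def locus_summaries(freqs: FrequencyTable) -> list[LocusSummary]:
    """The per-locus rows of :func:`locus_summary` as records."""
    df = locus_summary(freqs).loc[freqs.loci]
    return [
        LocusSummary(
            locus=str(locus),
            major_allele_frequency=row["Major Allele Frequency"],
            sample_size=int(row["Sample Size"]),
            allele_number=int(row["Allele No"]),
            pic=row["PIC"],
            observed_heterozygosity=row["Observed Heterozygosity"],
            gene_diversity=row["Gene Diversity"],
        )
        for locus, row in df.dropna(how="all").iterrows()
    ]


def classify_pic(pic: float) -> str:
    """Marker informativeness grade.

    ``> 0.5`` highly informative, ``0.25–0.5`` (inclusive) moderately
    informative, ``< 0.25`` slightly informative.
    """
    if not 0.0 <= pic <= 1.0:
        raise ValueError(f"PIC must lie in [0, 1], got {pic}")
    if pic > 0.5:
        return "highly informative"
    if pic >= 0.25:
        return "moderately informative"
    return "slightly informative"
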
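"""Per-population allelic patterns.

For each population the report averages, over loci, the number of different
alleles (Na), the number with frequency >= 5%, the effective number of
alleles Ne = 1/sum(p^2), Shannon's information index I = -sum(p ln p),
private-allele and locally-common-allele counts, observed and expected
heterozygosity, the small-sample unbiased He, and the fixation index
F = 1 - Ho/He.

"Locally common" alleles (frequency >= 5% in the focal population) follow
the GenAlEx convention: alleles found in only a single population are
counted as private, not locally common, so the <=25%-of-populations column
is zero whenever 25% of the population count rounds below two populations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .locus_stats import FrequencyTable

__all__ = ["allelic_patterns", "PATTERN_COLUMNS"]

PATTERN_COLUMNS = [
    "Na",
    "Na Freq.>= 5%",
    "Ne",
    "I",
    "No. Private Alleles",
    "No. LComm Alleles (<=25%)",
    "No. LComm Alleles (<=50%)",
    "Ho",
    "He",
    "uHe",
    "F",
]


def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def allelic_patterns(
    freqs: FrequencyTable, matrix: GenotypeMatrix | None = None
) -> pd.DataFrame:
    """Mean allelic patterns across populations.

    Returns a DataFrame indexed by population with the columns of
    ``PATTERN_COLUMNS`` plus ``Maximum value`` / ``Minimum value`` rows.
    Each cell is the arithmetic mean over loci genotyped in that
    population; F is averaged only over loci with He > 0.
    """
    pops = freqs.populations
    if len(pops) < 1:
        raise ValueError("at least one population required")
    k = len(pops)
    for pop in pops:
        if (freqs.n[pop] > 0).sum() == 0:
            raise ValueError(f"population {pop!r} has no genotyped individuals")

    # presence of each allele in each population, per locus
    rows = []
    for pop in pops:
        per_locus: dict[str, list[float]] = {c: [] for c in PATTERN_COLUMNS}
        for locus in freqs.loci:
            table = freqs.by_pop[locus]
            if freqs.n.loc[locus, pop] == 0 or table.loc[pop].isna().all():
                continue
            p = table.loc[pop].values.astype(float)
            present = table.notna().all(axis=1)
            presence = (table.loc[present] > 0).sum(axis=0)  # pops per allele
            here = table.loc[pop] > 0
            s2 = float(np.sum(p**2))
            he = 1.0 - s2
            n = int(freqs.n.loc[locus, pop])
            ho = float(freqs.ho.loc[locus, pop])
            common = table.loc[pop] >= 0.05
            multi_pop = presence >= 2
            per_locus["Na"].append(int(here.sum()))
            per_locus["Na Freq.>= 5%"].append(int(common.sum()))
            per_locus["Ne"].append(1.0 / s2)
            per_locus["I"].append(_shannon(p))
            per_locus["No. Private Alleles"].append(
                int((here & (presence == 1)).sum())
            )
            per_locus["No. LComm Alleles (<=25%)"].append(
                int((common & multi_pop & (presence <= k * 0.25)).sum())
            )
            per_locus["No. LComm Alleles (<=50%)"].append(
                int((common & multi_pop & (presence <= k * 0.50)).sum())
            )
            per_locus["Ho"].append(ho)
            per_locus["He"].append(he)
            per_locus["uHe"].append((2 * n) / (2 * n - 1) * he if n > 0 else np.nan)
            if he > 0:
                per_locus["F"].append(1.0 - ho / he)
        rows.append(
            [
                float(np.mean(per_locus[c])) if per_locus[c] else np.nan
                for c in PATTERN_COLUMNS
            ]
        )
    df = pd.DataFrame(rows, index=pd.Index(pops, name="Population"), columns=PATTERN_COLUMNS)
    summary = pd.DataFrame(
        [df.max(), df.min()], index=["Maximum value", "Minimum value"]
    )
    return pd.concat([df, summary])
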
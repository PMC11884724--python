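"""Published reference values for a 91-accession sweet sorghum SSR panel.

A survey of Ethiopian sweet sorghum germplasm genotyped 91 accessions from
five zone populations (South Wollo, South Tigray, Oromia Liyu Zone, North
Shewa, East Gojam) at 13 SSR markers.  The per-marker diversity summary,
per-marker F-statistics, pairwise population differentiation/distance/gene
flow and the AMOVA and PCoA summaries reported for that panel are embedded
here as reference tables.  They serve as consistency fixtures: the printed
column means must be reproducible from the printed per-marker rows by the
same formulas this package implements.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import LocusMeta

__all__ = [
    "marker_panel",
    "reference_locus_summary",
    "reference_fstats",
    "reference_pairwise",
    "reference_gene_flow",
    "reference_amova",
    "reference_pcoa_axes",
    "POPULATIONS",
]

POPULATIONS = [
    "South Wollo",
    "South Tigray",
    "Oromia Liyu Zone",
    "North Shewa",
    "East Gojam",
]

_PANEL = [
    ("Xcup53", "(TTTA)5", "1", "GCAGGAGTATAGGCAGAGGC", "CGACATGACAAGCTCAAACG", 56),
    ("Xtxp015", "(TC)16", "5", "CACAAACACTAGTGCCTTATC", "CATAGACACCTAGGCCATC", 54),
    ("Xisep0310", "(CCAAT)4", "2", "TGCCTTGTGCCTTGTTTATCT", "GGATCGATGCCTATCTCGTC", 57),
    ("Xtxp114", "(AGG)8", "3", "CGTCTTCTACCGCGTCCT", "CATAATCCCACTCAACAATCC", 57),
    ("Xtxp012", "(CT)22", "4", "AGATCTGGCGGCAACG", "AGTCACCCATCGATCATC", 57),
    ("Xtxp273", "(TTG)20", "8", "GTACCCATTTAAATTGTTTGCAGTAG", "CAGAGGAGGAGGAAGAGAAGG", 56),
    ("Xtxp321", "(GT)4+(AT)6+(CT)21", "8", "TAACCCAAGCCTGAGCATAAGA", "CCCATTCACACATGAGACGAG", 60),
    ("Xtxp265", "(GAA)19", "6", "GTCTACAGGCGTGCAAATAAAA", "TTACCATGCTACCCCTAAAAGTGG", 56),
    ("SbAGE01", "(AG)30", "2", "GACCGATCTAATGATGCAG", "ACGGTAGAGAAGACCCATC", 54),
    ("Xtxp21", "(AG)18", "4", "GAGCTGCCATAGATTTGGTCG", "ACCTCGTCCCACCTTTGTTG", 52),
    ("Xtxp12", "(CT)22", "4", "AGATCTGGCGGCAACG", "AGTCACCCATCGATCATC", 56),
    ("Xtxp3", "(CT)8+(CT)36", "2", "AGCAGGCGTTTATGGAAG", "ATCCTCATACTGCAGGACC", 57),
    ("Xtxp43", "(CT)28", "1", "AGTCACAGCACACTGCTTGTC", "AATTTACCTGGCGCTCTGC", 60),
]

# per-marker: MAF, sample size, allele number, PIC, Ho, gene diversity
_LOCUS_SUMMARY = {
    "Xcup53": (0.19, 91, 13, 0.85, 0.00, 0.87),
    "Xtxp015": (0.23, 91, 11, 0.82, 0.00, 0.84),
    "Xisep0310": (0.22, 91, 8, 0.80, 0.40, 0.83),
    "Xtxp114": (0.41, 91, 6, 0.68, 0.00, 0.72),
    "Xtxp012": (0.16, 91, 15, 0.88, 0.19, 0.89),
    "Xtxp273": (0.30, 91, 11, 0.78, 0.10, 0.81),
    "Xtxp321": (0.36, 91, 10, 0.71, 0.24, 0.75),
    "Xtxp265": (0.18, 91, 11, 0.86, 0.15, 0.87),
    "SbAGE01": (0.19, 91, 11, 0.84, 0.00, 0.86),
    "Xtxp21": (0.21, 91, 8, 0.82, 0.01, 0.84),
    "Xtxp12": (0.25, 91, 9, 0.79, 0.26, 0.82),
    "Xtxp3": (0.32, 91, 9, 0.76, 0.02, 0.79),
    "Xtxp43": (0.21, 91, 14, 0.83, 0.16, 0.84),
}

# per-marker: Ht, mean He, mean Ho, Fis, Fit, Fst, Nm
_FSTATS = {
    "Xcup53": (0.86, 0.66, 0.00, 1.00, 1.00, 0.22, 0.84),
    "Xtxp015": (0.83, 0.67, 0.00, 1.00, 1.00, 0.19, 1.05),
    "Xisep0310": (0.83, 0.69, 0.35, 0.48, 0.57, 0.16, 1.28),
    "Xtxp114": (0.71, 0.54, 0.00, 1.00, 1.00, 0.24, 0.77),
    "Xtxp012": (0.88, 0.79, 0.21, 0.73, 0.76, 0.10, 2.17),
    "Xtxp273": (0.83, 0.62, 0.14, 0.77, 0.80, 0.25, 0.74),
    "Xtxp321": (0.78, 0.64, 0.34, 0.46, 0.56, 0.17, 1.14),
    "Xtxp265": (0.85, 0.67, 0.11, 0.83, 0.86, 0.21, 0.93),
    "SbAGE01": (0.82, 0.71, 0.00, 1.00, 1.00, 0.13, 1.61),
    "Xtxp21": (0.82, 0.61, 0.04, 0.93, 0.95, 0.26, 0.70),
    "Xtxp12": (0.81, 0.73, 0.35, 0.51, 0.55, 0.09, 2.29),
    "Xtxp3": (0.81, 0.58, 0.04, 0.91, 0.93, 0.28, 0.63),
    "Xtxp43": (0.85, 0.66, 0.19, 0.70, 0.77, 0.22, 0.84),
}

# Fst below the diagonal, Nei distance above (population order as POPULATIONS)
_PAIRWISE = [
    [0.000, 0.949, 1.067, 0.860, 0.972],
    [0.144, 0.000, 0.819, 0.757, 1.080],
    [0.196, 0.159, 0.000, 0.769, 1.201],
    [0.111, 0.091, 0.128, 0.000, 0.543],
    [0.145, 0.134, 0.186, 0.071, 0.000],
]

# pairwise gene flow Nm, lower triangle
_GENE_FLOW = [
    [0.000, np.nan, np.nan, np.nan, np.nan],
    [0.939, 0.000, np.nan, np.nan, np.nan],
    [0.618, 0.815, 0.000, np.nan, np.nan],
    [1.359, 1.474, 1.101, 0.000, np.nan],
    [1.114, 1.061, 0.675, 2.879, 0.000],
]

_AMOVA = {
    "df": [4, 86, 90],
    "SS": [278.399, 1541.710, 1820.110],
    "MS": [69.600, 17.927, np.nan],
    "Est. Var.": [3.387, 17.927, 21.313],
    "Percentage of variation": [16.0, 84.0, 100.0],
}

_PCOA_AXES = {"Axis": [1, 2, 3], "%": [12.55, 10.38, 8.33],
              "Cumulative %": [12.55, 22.93, 31.26]}


def marker_panel() -> list[LocusMeta]:
    """The 13 SSR markers (motif, chromosome, primers, annealing temp)."""
    return [
        LocusMeta(
            name=n,
            repeat_motif=motif,
            chromosome=chrom,
            forward_primer=fwd,
            reverse_primer=rev,
            annealing_temp_c=float(ta),
        )
        for n, motif, chrom, fwd, rev, ta in _PANEL
    ]


def reference_locus_summary() -> pd.DataFrame:
    """Reported per-marker MAF, sample size, Na, PIC, Ho and gene diversity."""
    return pd.DataFrame.from_dict(
        _LOCUS_SUMMARY,
        orient="index",
        columns=[
            "Major Allele Frequency",
            "Sample Size",
            "Allele No",
            "PIC",
            "Observed Heterozygosity",
            "Gene Diversity",
        ],
    ).rename_axis("Markers")


def reference_fstats() -> pd.DataFrame:
    """Reported per-marker Ht, mean He/Ho, Fis, Fit, Fst and Nm."""
    return pd.DataFrame.from_dict(
        _FSTATS,
        orient="index",
        columns=["Ht", "Mean He", "Mean Ho", "Fis", "Fit", "Fst", "Nm"],
    ).rename_axis("Markers")


def reference_pairwise() -> tuple[pd.DataFrame, pd.DataFrame]:
    """(pairwise Fst, pairwise Nei distance) between the five populations."""
    m = np.array(_PAIRWISE)
    fst = np.tril(m) + np.tril(m, -1).T
    nei = np.triu(m) + np.triu(m, 1).T
    idx = pd.Index(POPULATIONS)
    return (
        pd.DataFrame(fst, index=idx, columns=idx),
        pd.DataFrame(nei, index=idx, columns=idx),
    )


def reference_gene_flow() -> pd.DataFrame:
    """Reported pairwise gene flow Nm (lower triangle)."""
    return pd.DataFrame(_GENE_FLOW, index=POPULATIONS, columns=POPULATIONS)


def reference_amova() -> pd.DataFrame:
    """Reported AMOVA partition (among/within populations)."""
    return pd.DataFrame(
        _AMOVA, index=pd.Index(["Among Pops", "Within Pops", "Total"], name="Source")
    )


def reference_pcoa_axes() -> pd.DataFrame:
    """Reported percentage of variation on the first three PCoA axes."""
    return pd.DataFrame(_PCOA_AXES).set_index("Axis")
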
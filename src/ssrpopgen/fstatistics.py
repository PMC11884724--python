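"""Wright F-statistics and gene flow for subdivided populations.

Per locus, with per-population allele frequencies p_i and observed
heterozygosities Ho:

* ``Mean He`` and ``Mean Ho`` are unweighted arithmetic averages over the
  populations in which the locus is genotyped.
* The total frequency of allele i, ``tp_i``, is the unweighted mean of the
  per-population frequencies (a pooled gene-copy count is available behind
  ``total="pooled"``), and ``Ht = 1 - sum(tp_i^2)``.
* ``Fis = (Mean He - Mean Ho) / Mean He``
* ``Fit = (Ht - Mean Ho) / Ht``
* ``Fst = (Ht - Mean He) / Ht``
* ``Nm = ((1 / Fst) - 1) / 4``

``Fst = 0`` yields an infinite Nm sentinel; ``Mean He = 0`` leaves Fis
undefined for that locus (excluded from the column mean).  Pairwise Fst
between two populations applies the same per-locus estimator to the pair
and averages over loci; pairwise Nm applies the four-island-model formula
to pairwise Fst.

Nei's genetic distance between populations x and y uses gene identities
J_x = sum p_x^2, J_y = sum p_y^2, J_xy = sum p_x p_y accumulated over loci:
``D = -ln( J_xy / sqrt(J_x J_y) )``; the unbiased (1978) variant replaces
the within-population identities with ``(2N sum p^2 - 1) / (2N - 1)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .distance import DistanceMatrix
from .locus_stats import FrequencyTable

__all__ = [
    "per_locus_fstats",
    "pairwise_fst",
    "nei_distance",
    "gene_flow",
    "grade_fst",
    "grade_nm",
    "FSTAT_COLUMNS",
]

FSTAT_COLUMNS = ["Ht", "Mean He", "Mean Ho", "Fis", "Fit", "Fst", "Nm"]


def _locus_pop_stats(
    freqs: FrequencyTable, locus: str, pops: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """(freq matrix pops x alleles, He vector, Ho vector) over typed pops."""
    table = freqs.by_pop[locus]
    typed = [p for p in pops if freqs.n.loc[locus, p] > 0]
    if not typed:
        return None
    f = table.loc[typed].values.astype(float)
    he = 1.0 - (f**2).sum(axis=1)
    ho = freqs.ho.loc[locus, typed].values.astype(float)
    return f, he, ho


def nm_from_fst(fst: float) -> float:
    """Island-model gene flow Nm = ((1/Fst) - 1) / 4; +inf at Fst = 0."""
    if fst < 0:
        raise ValueError("Fst must be >= 0")
    if fst == 0:
        return np.inf
    return (1.0 / fst - 1.0) / 4.0


def per_locus_fstats(
    freqs: FrequencyTable, total: str = "mean"
) -> pd.DataFrame:
    """Per-locus Ht, mean He/Ho, Fis, Fit, Fst and Nm over all populations.

    ``total`` selects how the total allele frequencies tp_i are formed:
    ``"mean"`` (unweighted average of population frequencies, the default)
    or ``"pooled"`` (weighted by gene-copy counts).  Returns a DataFrame
    indexed by locus with ``Mean`` / ``Maximum value`` / ``Minimum value``
    rows appended; undefined cells are NaN and excluded from the mean.
    """
    if total not in ("mean", "pooled"):
        raise ValueError("total must be 'mean' or 'pooled'")
    if len(freqs.populations) < 2:
        raise ValueError("F-statistics require at least two populations")
    rows = []
    for locus in freqs.loci:
        stats = _locus_pop_stats(freqs, locus, freqs.populations)
        if stats is None:
            rows.append([np.nan] * len(FSTAT_COLUMNS))
            continue
        f, he, ho = stats
        typed = [p for p in freqs.populations if freqs.n.loc[locus, p] > 0]
        if total == "mean":
            tp = f.mean(axis=0)
        else:
            w = freqs.n.loc[locus, typed].values.astype(float)
            tp = (f * w[:, None]).sum(axis=0) / w.sum()
        ht = 1.0 - float((tp**2).sum())
        mean_he = float(he.mean())
        mean_ho = float(ho.mean())
        fis = (mean_he - mean_ho) / mean_he if mean_he > 0 else np.nan
        fit = (ht - mean_ho) / ht if ht > 0 else np.nan
        fst = (ht - mean_he) / ht if ht > 0 else np.nan
        nm = nm_from_fst(max(fst, 0.0)) if np.isfinite(fst) else np.nan
        rows.append([ht, mean_he, mean_ho, fis, fit, fst, nm])
    df = pd.DataFrame(
        rows, index=pd.Index(freqs.loci, name="Markers"), columns=FSTAT_COLUMNS
    )
    body = df.replace(np.inf, np.nan)
    summary = pd.DataFrame(
        [body.mean(), body.max(), body.min()],
        index=["Mean", "Maximum value", "Minimum value"],
    )
    return pd.concat([df, summary])


def pairwise_fst(freqs: FrequencyTable, total: str = "mean") -> DistanceMatrix:
    """Pairwise population Fst, averaged arithmetically over loci.

    For each pair the per-locus estimator uses the two-population Ht and
    mean He; pairs sharing no genotyped locus get a NaN entry.
    """
    pops = freqs.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    k = len(pops)
    out = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            vals = []
            for locus in freqs.loci:
                if (
                    freqs.n.loc[locus, pops[a]] == 0
                    or freqs.n.loc[locus, pops[b]] == 0
                ):
                    continue
                f = freqs.by_pop[locus].loc[[pops[a], pops[b]]].values
                he = 1.0 - (f**2).sum(axis=1)
                if total == "mean":
                    tp = f.mean(axis=0)
                else:
                    w = freqs.n.loc[locus, [pops[a], pops[b]]].values.astype(float)
                    tp = (f * w[:, None]).sum(axis=0) / w.sum()
                ht = 1.0 - float((tp**2).sum())
                if ht > 0:
                    vals.append((ht - float(he.mean())) / ht)
            out[a, b] = out[b, a] = np.mean(vals) if vals else np.nan
    return DistanceMatrix(list(pops), out, kind="pairwise-fst")


def nei_distance(freqs: FrequencyTable, variant: str = "nei1972") -> DistanceMatrix:
    """Nei's genetic distance between all population pairs.

    ``variant="nei1972"`` is the standard distance; ``"nei1978-unbiased"``
    applies the sample-size correction to the within-population identities.
    Disjoint allele sets give an infinite entry.
    """
    if variant not in ("nei1972", "nei1978-unbiased"):
        raise ValueError(f"unknown variant {variant!r}")
    pops = freqs.populations
    k = len(pops)
    out = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            jx = jy = jxy = 0.0
            shared = False
            for locus in freqs.loci:
                na = freqs.n.loc[locus, pops[a]]
                nb = freqs.n.loc[locus, pops[b]]
                if na == 0 or nb == 0:
                    continue
                shared = True
                table = freqs.by_pop[locus]
                px = table.loc[pops[a]].values.astype(float)
                py = table.loc[pops[b]].values.astype(float)
                sx = float((px**2).sum())
                sy = float((py**2).sum())
                if variant == "nei1978-unbiased":
                    sx = (2 * na * sx - 1) / (2 * na - 1)
                    sy = (2 * nb * sy - 1) / (2 * nb - 1)
                jx += sx
                jy += sy
                jxy += float((px * py).sum())
            if not shared:
                out[a, b] = out[b, a] = np.nan
                continue
            denom = np.sqrt(jx * jy)
            if jxy <= 0 or denom <= 0:
                out[a, b] = out[b, a] = np.inf
            else:
                out[a, b] = out[b, a] = max(-np.log(jxy / denom), 0.0)
    return DistanceMatrix(list(pops), out, kind="nei-distance")


def gene_flow(fst: DistanceMatrix | pd.Series | np.ndarray):
    """Elementwise gene flow Nm = ((1/Fst) - 1)/4.

    Accepts a pairwise-Fst :class:`DistanceMatrix` (returns an Nm matrix)
    or a per-locus Fst column (returns the Nm column).
    """
    if isinstance(fst, DistanceMatrix):
        vals = fst.values.copy()
        off = ~np.eye(len(fst), dtype=bool)
        with np.errstate(divide="ignore"):
            vals[off] = (1.0 / vals[off] - 1.0) / 4.0
        np.fill_diagonal(vals, 0.0)
        return DistanceMatrix(list(fst.labels), vals, kind="nm")
    arr = np.asarray(fst, dtype=float)
    if (arr[np.isfinite(arr)] < 0).any():
        raise ValueError("Fst must be >= 0")
    with np.errstate(divide="ignore"):
        nm = (1.0 / arr - 1.0) / 4.0
    if isinstance(fst, pd.Series):
        return pd.Series(nm, index=fst.index, name="Nm")
    return nm


def grade_fst(fst: float) -> str:
    """Differentiation grade: < 0.05 low, 0.05–0.15 medium, >= 0.15 high."""
    if fst < 0:
        raise ValueError("Fst must be >= 0")
    if fst < 0.05:
        return "low"
    if fst < 0.15:
        return "medium"
    return "high"


def grade_nm(nm: float) -> str:
    """Gene-flow grade: >= 1.0 high, 0.25–0.99 medium, below that low."""
    if nm < 0:
        raise ValueError("Nm must be >= 0")
    if nm >= 1.0:
        return "high"
    if nm >= 0.25:
        return "medium"
    return "low"
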
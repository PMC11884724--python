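"""Synthetic codominant SSR genotype generator.

Populations drift away from shared ancestral allele frequencies under the
Balding–Nichols model: for ancestral frequencies p_anc at a locus and a
drift parameter F (the nominal Fst), each population's frequencies are
drawn Dirichlet(p_anc * (1 - F) / F).  Genotypes are then sampled with an
instantaneous autozygosity probability Fis (a partially selfing crop shows
a strong homozygote excess): with probability Fis one allele is drawn and
duplicated, otherwise two alleles are drawn independently.  An optional
admixture mode draws each individual's ancestry vector q from a symmetric
Dirichlet over two source clusters and each allele copy's source cluster
from q.  Allele indices map onto a fragment-size ladder
(offset + repeat * index) so simulated calls look like scored gel bands,
and calls can be masked at a nominal missing rate.

The defaults emulate a published survey of Ethiopian sweet sorghum
germplasm: 91 accessions in 5 zone populations, 13 SSR loci carrying 6–15
alleles each, mean Fis ≈ 0.79 and mean Fst ≈ 0.19.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix

__all__ = ["SimulationSpec", "SimulationTruth", "simulate"]

#: study-like per-population sample sizes (sum 91)
DEFAULT_SIZES = (18, 18, 18, 18, 19)
#: study-like allele counts across the 13 loci, spanning 6–15
DEFAULT_ALLELE_COUNTS = (13, 11, 8, 6, 15, 11, 10, 11, 11, 8, 9, 9, 14)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic dataset.

    ``fst`` is the Balding–Nichols drift parameter applied to every
    population; ``fis`` the autozygosity probability; ``admixture``
    selects ``"none"`` (discrete populations) or ``"two-cluster"``
    (individual ancestries q ~ Dirichlet(admix_alpha) over two clusters,
    population label = majority cluster).
    """

    n_populations: int = 5
    sizes: tuple[int, ...] = DEFAULT_SIZES
    allele_counts: tuple[int, ...] = DEFAULT_ALLELE_COUNTS
    fst: float = 0.19
    fis: float = 0.79
    admixture: str = "none"
    admix_alpha: float = 0.1
    missing_rate: float = 0.0
    ladder_offset: int = 100
    ladder_repeat: int = 2
    anc_dirichlet: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must lie in [0, 1)")
        if not 0.0 <= self.fis < 1.0 and self.fis != 1.0:
            raise ValueError("fis must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.admixture not in ("none", "two-cluster"):
            raise ValueError("admixture must be 'none' or 'two-cluster'")
        if len(self.sizes) != self.n_populations:
            raise ValueError("one size per population required")
        if any(s < 1 for s in self.sizes):
            raise ValueError("population sizes must be >= 1")
        if any(a < 2 for a in self.allele_counts):
            raise ValueError("allele counts must be >= 2")


@dataclass
class SimulationTruth:
    """Ground truth retained for parameter-recovery checks."""

    ancestral_freqs: list[np.ndarray]  # per locus
    population_freqs: list[np.ndarray]  # per locus: (k or 2 clusters) x alleles
    fst: float
    fis: float
    ancestry: np.ndarray | None  # (n, 2) q vectors in admixed mode

    def to_dict(self) -> dict:
        out = {
            "fst": self.fst,
            "fis": self.fis,
            "ancestral_freqs": [f.tolist() for f in self.ancestral_freqs],
            "population_freqs": [f.tolist() for f in self.population_freqs],
        }
        if self.ancestry is not None:
            out["ancestry"] = self.ancestry.tolist()
        return out


def _drifted(
    rng: np.random.Generator, p_anc: np.ndarray, fst: float, k: int
) -> np.ndarray:
    """k population frequency vectors drifted from p_anc at nominal Fst."""
    if fst == 0.0:
        return np.tile(p_anc, (k, 1))
    conc = p_anc * (1.0 - fst) / fst
    return rng.dirichlet(np.maximum(conc, 1e-6), size=k)


def simulate(spec: SimulationSpec) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Draw one genotype matrix (and its ground truth) from ``spec``."""
    rng = np.random.default_rng(spec.seed)
    k = spec.n_populations
    L = len(spec.allele_counts)
    n = int(sum(spec.sizes))
    n_sources = 2 if spec.admixture == "two-cluster" else k

    anc: list[np.ndarray] = []
    pop_freqs: list[np.ndarray] = []
    for n_alleles in spec.allele_counts:
        p_anc = rng.dirichlet(np.full(n_alleles, spec.anc_dirichlet))
        anc.append(p_anc)
        pop_freqs.append(_drifted(rng, p_anc, spec.fst, n_sources))

    ancestry: np.ndarray | None = None
    populations: list[str]
    if spec.admixture == "two-cluster":
        ancestry = rng.dirichlet(np.full(2, spec.admix_alpha), size=n)
        majority = ancestry.argmax(axis=1)
        populations = [f"Cluster{c + 1}" for c in majority]
        source_of_copy = None  # drawn per copy below
    else:
        populations = []
        for p_idx, size in enumerate(spec.sizes):
            populations += [f"Pop{p_idx + 1}"] * size
        src = np.repeat(np.arange(k), spec.sizes)
        source_of_copy = src

    calls = np.zeros((n, L, 2), dtype=np.int64)
    autozygous = rng.random((n, L)) < spec.fis
    for j in range(L):
        cum = np.cumsum(pop_freqs[j], axis=1)
        if ancestry is not None:
            src = (rng.random((n, 2)) >= ancestry[:, [0]]).astype(int)
        else:
            src = np.stack([source_of_copy, source_of_copy], axis=1)
        u = rng.random((n, 2))
        a = (u[:, :, None] > cum[src]).sum(axis=2)
        # autozygous call: one draw (allele and its source) duplicated
        a[:, 1] = np.where(autozygous[:, j], a[:, 0], a[:, 1])
        calls[:, j] = spec.ladder_offset + spec.ladder_repeat * a
    if spec.missing_rate > 0:
        mask = rng.random((n, L)) < spec.missing_rate
        calls[mask] = MISSING

    matrix = GenotypeMatrix(
        individuals=[f"ind{i + 1:03d}" for i in range(n)],
        loci=[f"SSR{j + 1:02d}" for j in range(L)],
        calls=calls,
        populations=populations,
    )
    truth = SimulationTruth(
        ancestral_freqs=anc,
        population_freqs=pop_freqs,
        fst=spec.fst,
        fis=spec.fis,
        ancestry=ancestry,
    )
    return matrix, truth
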
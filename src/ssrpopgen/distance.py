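"""Symmetric labelled distance matrices shared across analysis stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DistanceMatrix"]

KINDS = ("pairwise-fst", "nei-distance", "nm", "individual-squared", "shared-allele", "generic")


@dataclass
class DistanceMatrix:
    """A symmetric non-negative matrix with a zero diagonal.

    ``kind`` records what the entries measure (pairwise Fst, Nei distance,
    gene flow Nm, squared genotypic distance between individuals, ...).
    Undefined entries (e.g. populations sharing no genotyped locus) are NaN;
    infinite entries are legal sentinels (e.g. Nei distance with zero shared
    identity, Nm at Fst = 0).
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        finite = np.isfinite(self.values)
        if not np.allclose(
            self.values[finite], self.values.T[finite], atol=1e-9
        ):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("diagonal must be zero")

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy's condensed order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]
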
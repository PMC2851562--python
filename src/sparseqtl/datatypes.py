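"""Core containers for genotype, expression and marker-map data.

All containers are thin, validated wrappers around numpy arrays and pandas
DataFrames.  Strain order is the alignment contract: a GenotypePanel and an
ExpressionPanel used together must list strains in the same order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "GenotypePanel",
    "ExpressionPanel",
    "ModelIndicator",
]

#: founder allele codes: first founder (e.g. BN) / second founder (e.g. SHR)
FOUNDER_A = -0.5
FOUNDER_B = 0.5


class MarkerMap:
    """Genetic map: per-marker name, chromosome, cM and Mbp positions.

    Within each chromosome the stored order must be non-decreasing in cM.
    """

    REQUIRED = ("marker", "chr", "cm", "mbp")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"marker map missing columns: {missing}")
        table = table.reset_index(drop=True).copy()
        table["marker"] = table["marker"].astype(str)
        table["chr"] = table["chr"].astype(str)
        if table["marker"].duplicated().any():
            dups = table.loc[table["marker"].duplicated(), "marker"].tolist()
            raise ValueError(f"duplicate marker names: {dups}")
        if (table["cm"] < 0).any() or (table["mbp"] < 0).any():
            raise ValueError("cM and Mbp positions must be non-negative")
        for _, sub in table.groupby("chr", sort=False):
            if not np.all(np.diff(sub["cm"].to_numpy()) >= 0):
                raise ValueError(
                    f"cM positions not non-decreasing within chromosome "
                    f"{sub['chr'].iloc[0]!r}"
                )
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    @property
    def names(self) -> np.ndarray:
        return self.table["marker"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chr"].to_numpy()

    @property
    def cm(self) -> np.ndarray:
        return self.table["cm"].to_numpy(dtype=float)

    @property
    def mbp(self) -> np.ndarray:
        return self.table["mbp"].to_numpy(dtype=float)

    def index_of(self, name: str) -> int:
        hits = np.flatnonzero(self.names == name)
        if len(hits) == 0:
            raise KeyError(f"marker {name!r} not in map")
        return int(hits[0])


@dataclass
class GenotypePanel:
    """Strains x markers genotype codes for a two-founder inbred panel.

    Founder alleles are coded -0.5 / +0.5; fractional values in between are
    the output of flanking-marker imputation.  NaN marks missing calls.
    """

    codes: np.ndarray
    marker_map: MarkerMap
    strain_ids: Sequence[str] = field(default=None)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2:
            raise ValueError("genotype codes must be a 2-D array")
        n, p = self.codes.shape
        if p != len(self.marker_map):
            raise ValueError(
                f"{p} genotype columns but {len(self.marker_map)} mapped markers"
            )
        if self.strain_ids is None:
            self.strain_ids = [f"strain{i + 1}" for i in range(n)]
        self.strain_ids = list(map(str, self.strain_ids))
        if len(self.strain_ids) != n:
            raise ValueError("strain_ids length mismatch")
        finite = self.codes[np.isfinite(self.codes)]
        if finite.size and (finite.min() < FOUNDER_A or finite.max() > FOUNDER_B):
            raise ValueError(
                "genotype codes must lie in [-0.5, 0.5] (founder coding)"
            )

    @property
    def n_strains(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.codes).any())


@dataclass
class ExpressionPanel:
    """Strains x tissues expression values for a single probe set.

    q = 1 for single-tissue analysis, q >= 2 for joint multi-tissue
    analysis.  Columns are centered by ``center()`` before model fitting.
    """

    values: np.ndarray
    strain_ids: Sequence[str] = None
    tissue_ids: Sequence[str] = None
    probe_id: str = "probe"
    probe_chr: str | None = None
    probe_mbp: float | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if v.ndim != 2:
            raise ValueError("expression values must be 1- or 2-D")
        if v.shape[0] < 3:
            raise ValueError("need at least 3 strains")
        if not np.all(np.isfinite(v)):
            raise ValueError("expression values contain missing entries")
        self.values = v
        n, q = v.shape
        if self.strain_ids is None:
            self.strain_ids = [f"strain{i + 1}" for i in range(n)]
        if self.tissue_ids is None:
            self.tissue_ids = [f"tissue{i + 1}" for i in range(q)]
        self.strain_ids = list(map(str, self.strain_ids))
        self.tissue_ids = list(map(str, self.tissue_ids))
        if len(self.strain_ids) != n or len(self.tissue_ids) != q:
            raise ValueError("strain_ids/tissue_ids length mismatch")

    @property
    def n_strains(self) -> int:
        return self.values.shape[0]

    @property
    def n_tissues(self) -> int:
        return self.values.shape[1]

    def center(self) -> "ExpressionPanel":
        """Return a copy with each tissue column centered to mean zero."""
        return ExpressionPanel(
            self.values - self.values.mean(axis=0, keepdims=True),
            strain_ids=self.strain_ids,
            tissue_ids=self.tissue_ids,
            probe_id=self.probe_id,
            probe_chr=self.probe_chr,
            probe_mbp=self.probe_mbp,
        )

    @property
    def is_centered(self) -> bool:
        return bool(np.allclose(self.values.mean(axis=0), 0.0, atol=1e-9))


class ModelIndicator:
    """Latent binary inclusion vector gamma over p markers.

    Stored as a sorted tuple of included marker indices; hashable so model
    visit counts can live in a dict.
    """

    __slots__ = ("included", "p")

    def __init__(self, included, p: int):
        inc = tuple(sorted(int(j) for j in set(included)))
        if inc and (inc[0] < 0 or inc[-1] >= p):
            raise ValueError("marker index out of range")
        self.included = inc
        self.p = int(p)

    @classmethod
    def from_binary(cls, gamma) -> "ModelIndicator":
        gamma = np.asarray(gamma)
        return cls(np.flatnonzero(gamma), gamma.size)

    @classmethod
    def null(cls, p: int) -> "ModelIndicator":
        return cls((), p)

    @property
    def size(self) -> int:
        return len(self.included)

    @property
    def gamma(self) -> np.ndarray:
        g = np.zeros(self.p, dtype=int)
        g[list(self.included)] = 1
        return g

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ModelIndicator)
            and self.included == other.included
            and self.p == other.p
        )

    def __hash__(self) -> int:
        return hash((self.included, self.p))

    def __repr__(self) -> str:
        return f"ModelIndicator({list(self.included)}, p={self.p})"
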
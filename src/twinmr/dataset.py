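"""Twin-pair phenotype container.

A :class:`TwinPairDataset` stores one row per twin pair: the 2p-vector of
phenotype values (twin-1 block then twin-2 block, NaN for missing) and
the pair's zygosity.  Serializes as tab-separated text with
``<phenotype>_1`` / ``<phenotype>_2`` column pairs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TwinPairDataset"]

ZYGOSITIES = ("MZ", "DZ")


@dataclass
class TwinPairDataset:
    phenotypes: list[str]
    values: np.ndarray      # (n_pairs, 2p), NaN = missing
    zygosity: np.ndarray    # (n_pairs,) of "MZ"/"DZ"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.zygosity = np.asarray(self.zygosity, dtype=object)
        p = len(self.phenotypes)
        if self.values.ndim != 2 or self.values.shape[1] != 2 * p:
            raise ValueError(
                f"values must be (n_pairs, {2 * p}) for {p} phenotypes, "
                f"got {self.values.shape}"
            )
        if self.zygosity.shape != (self.values.shape[0],):
            raise ValueError("zygosity must have one entry per pair")
        bad = set(self.zygosity) - set(ZYGOSITIES)
        if bad:
            raise ValueError(f"unknown zygosity labels: {sorted(bad)}")

    @property
    def n_pairs(self) -> int:
        return self.values.shape[0]

    @property
    def n_observed_values(self) -> int:
        """Total count of non-missing data points."""
        return int(np.isfinite(self.values).sum())

    def subset(self, zygosity: str) -> np.ndarray:
        """Value rows for one zygosity group."""
        return self.values[self.zygosity == zygosity]

    def drop_empty(self) -> "TwinPairDataset":
        """Drop pairs with every value missing."""
        keep = np.isfinite(self.values).any(axis=1)
        return TwinPairDataset(self.phenotypes, self.values[keep],
                               self.zygosity[keep])

    def fingerprint(self) -> str:
        """Digest identifying the data, for guarding model comparisons."""
        h = hashlib.sha256()
        h.update(",".join(self.phenotypes).encode())
        h.update(np.ascontiguousarray(self.values).tobytes())
        h.update(",".join(self.zygosity).encode())
        return h.hexdigest()

    # -- interchange ---------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        cols = [f"{ph}_{t}" for t in (1, 2) for ph in self.phenotypes]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "zygosity", self.zygosity)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TwinPairDataset":
        if "zygosity" not in df.columns:
            raise ValueError("expected a 'zygosity' column")
        suffix1 = [c for c in df.columns if c.endswith("_1")]
        phenotypes = [c[:-2] for c in suffix1]
        cols = [f"{ph}_{t}" for t in (1, 2) for ph in phenotypes]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"missing twin columns: {missing}")
        return cls(phenotypes, df[cols].to_numpy(dtype=float),
                   df["zygosity"].to_numpy())

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TwinPairDataset":
        return cls.from_frame(pd.read_csv(path, sep="\t"))
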
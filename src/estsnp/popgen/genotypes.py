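"""Genotype container shared by the simulator and the popgen statistics.

Individuals x biallelic loci, coded as minor-allele dosage 0/1/2 with NaN for
missing calls, plus population labels and per-population coordinates (km).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix"]


@dataclass
class GenotypeMatrix:
    dosages: np.ndarray                  # (n_individuals, n_loci) float, NaN = missing
    individuals: list[str]
    populations: list[str]               # population label per individual
    loci: list[str]
    coords: pd.DataFrame = field(default_factory=pd.DataFrame)  # population, x_km, y_km

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.individuals) != n or len(self.populations) != n:
            raise ValueError("individual/population labels do not match dosage rows")
        if len(self.loci) != m:
            raise ValueError("locus ids do not match dosage columns")
        called = self.dosages[~np.isnan(self.dosages)]
        if called.size and not np.isin(called, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def population_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def population_mask(self, population: str) -> np.ndarray:
        return np.array([p == population for p in self.populations])

    def subset_loci(self, keep: np.ndarray | list) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            self.dosages[:, idx],
            list(self.individuals),
            list(self.populations),
            [self.loci[i] for i in idx],
            self.coords.copy(),
        )

    # ---- TSV round trip (row = individual: id, population, then dosages) ----

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.dosages, columns=self.loci)
        frame.insert(0, "population", self.populations)
        frame.insert(0, "individual", self.individuals)
        return frame

    def to_tsv(self, genotypes_path: str, coords_path: str | None = None) -> None:
        self.to_frame().to_csv(genotypes_path, sep="\t", index=False, na_rep="NA")
        if coords_path is not None:
            self.coords.to_csv(coords_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, genotypes_path: str, coords_path: str | None = None) -> "GenotypeMatrix":
        frame = pd.read_csv(genotypes_path, sep="\t", na_values=["NA"])
        coords = pd.DataFrame()
        if coords_path is not None:
            coords = pd.read_csv(coords_path, sep="\t")
        loci = [c for c in frame.columns if c not in ("individual", "population")]
        return cls(
            frame[loci].to_numpy(dtype=float),
            frame["individual"].astype(str).tolist(),
            frame["population"].astype(str).tolist(),
            loci,
            coords,
        )
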
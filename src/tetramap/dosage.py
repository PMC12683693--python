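"""Integer dosage matrix shared by the simulator, estimators and map builder.

A dosage matrix holds one row per SNP marker and one column per F1
individual, each entry an allele dosage in 0..4 or missing. The two
parental dosages accompany every marker because segregation-type
classification depends on them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import MISSING, DataError

__all__ = ["DosageMatrix", "MISSING"]


@dataclass
class DosageMatrix:
    markers: list[str]
    individuals: list[str]
    maternal: np.ndarray  # (n_markers,) int8, parental dosage 0..4
    paternal: np.ndarray  # (n_markers,) int8
    data: np.ndarray      # (n_markers, n_individuals) int8, MISSING = -1
    marker_chrom: np.ndarray | None = field(default=None)  # optional provenance
    marker_pos: np.ndarray | None = field(default=None)    # optional bp positions

    def __post_init__(self) -> None:
        self.maternal = np.asarray(self.maternal, dtype=np.int8)
        self.paternal = np.asarray(self.paternal, dtype=np.int8)
        self.data = np.asarray(self.data, dtype=np.int8)
        n_m, n_i = len(self.markers), len(self.individuals)
        if self.data.shape != (n_m, n_i):
            raise DataError(
                f"dosage data shape {self.data.shape} != ({n_m}, {n_i})")
        if len(set(self.markers)) != n_m:
            dupes = pd.Index(self.markers)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise DataError(f"duplicate marker ids: {dupes[:5]}")
        for name, arr in (("maternal", self.maternal), ("paternal", self.paternal)):
            if arr.shape != (n_m,):
                raise DataError(f"{name} dosages shape {arr.shape} != ({n_m},)")
            if ((arr < 0) | (arr > 4)).any():
                bad = np.where((arr < 0) | (arr > 4))[0][0]
                raise DataError(
                    f"{name} dosage out of 0..4 at marker {self.markers[bad]!r}")
        valid = (self.data == MISSING) | ((self.data >= 0) & (self.data <= 4))
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise DataError(
                f"dosage out of 0..4 at marker {self.markers[i]!r}, "
                f"individual {self.individuals[j]!r}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.data == MISSING

    def marker_missing_fraction(self) -> np.ndarray:
        return self.missing_mask.mean(axis=1)

    def individual_missing_fraction(self) -> np.ndarray:
        return self.missing_mask.mean(axis=0)

    def marker_index(self) -> dict[str, int]:
        return {m: i for i, m in enumerate(self.markers)}

    def subset(self, marker_idx=None, individual_idx=None) -> "DosageMatrix":
        marker_idx = (np.arange(self.n_markers) if marker_idx is None
                      else np.asarray(marker_idx))
        individual_idx = (np.arange(self.n_individuals) if individual_idx is None
                          else np.asarray(individual_idx))
        return DosageMatrix(
            markers=[self.markers[i] for i in marker_idx],
            individuals=[self.individuals[j] for j in individual_idx],
            maternal=self.maternal[marker_idx],
            paternal=self.paternal[marker_idx],
            data=self.data[np.ix_(marker_idx, individual_idx)],
            marker_chrom=None if self.marker_chrom is None
            else np.asarray(self.marker_chrom)[marker_idx],
            marker_pos=None if self.marker_pos is None
            else np.asarray(self.marker_pos)[marker_idx],
        )

    # -- frame conversion (TSV round trip lives in tetramap.io) ----------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data.astype(object), index=self.markers,
                          columns=self.individuals)
        df[df == MISSING] = pd.NA
        df.insert(0, "paternal", self.paternal)
        df.insert(0, "maternal", self.maternal)
        df.index.name = "marker"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DosageMatrix":
        if "maternal" not in df.columns or "paternal" not in df.columns:
            raise DataError("dosage frame needs 'maternal' and 'paternal' columns")
        body = df.drop(columns=["maternal", "paternal"])
        data = body.to_numpy(dtype=object)
        out = np.full(data.shape, MISSING, dtype=np.int8)
        for (i, j), v in np.ndenumerate(data):
            if v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NA:
                continue
            iv = int(v)
            if iv != v or not (0 <= iv <= 4):
                raise DataError(
                    f"non-integer or out-of-range dosage {v!r} at marker "
                    f"{df.index[i]!r}, column {body.columns[j]!r}")
            out[i, j] = iv
        return cls(markers=list(df.index.astype(str)),
                   individuals=list(body.columns.astype(str)),
                   maternal=df["maternal"].to_numpy(),
                   paternal=df["paternal"].to_numpy(),
                   data=out)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DosageMatrix):
            return NotImplemented
        return (self.markers == other.markers
                and self.individuals == other.individuals
                and np.array_equal(self.maternal, other.maternal)
                and np.array_equal(self.paternal, other.paternal)
                and np.array_equal(self.data, other.data))
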
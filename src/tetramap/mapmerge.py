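"""Consensus-map integration across two F1 populations.

Pairwise linkage data (recombination fraction and LOD per marker pair)
from the two populations are combined by averaging both quantities
weighted by the squares of the LOD scores; marker ordering is then
re-run on the combined data. A chromosome represented in only one
population is carried over from that population unchanged.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import DataError
from .mapbuild import GeneticMap, order_markers

__all__ = ["PairwiseLinkageSet", "merge_pairwise", "integrate_maps",
           "MissingGroupError"]


class MissingGroupError(DataError):
    pass


@dataclass
class PairwiseLinkageSet:
    """Pairwise linkage data of one population (or a merge of two)."""
    population: str
    pairs: pd.DataFrame  # marker1, marker2, r, lod [+ extra columns]

    REQUIRED = ("marker1", "marker2", "r", "lod")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.pairs.columns:
                raise DataError(f"pairwise table missing column {col!r}")
        p = self.pairs
        if ((p["r"] < 0) | (p["r"] > 0.5)).any():
            raise DataError("recombination fractions must lie in [0, 0.5]")
        if (p["lod"] < 0).any():
            raise DataError("LOD scores must be non-negative")
        key = self._keys(p)
        if key.duplicated().any():
            raise DataError("duplicate (unordered) marker pairs")

    @staticmethod
    def _keys(df: pd.DataFrame) -> pd.Series:
        a = df["marker1"].astype(str)
        b = df["marker2"].astype(str)
        lo = np.where(a <= b, a, b)
        hi = np.where(a <= b, b, a)
        return pd.Series(list(zip(lo, hi)), index=df.index)

    @property
    def weights(self) -> pd.Series:
        return self.pairs["lod"] ** 2


def merge_pairwise(a: PairwiseLinkageSet, b: PairwiseLinkageSet,
                   ) -> PairwiseLinkageSet:
    """LOD^2-weighted merge of two populations' pairwise linkage data.

    Shared pairs get r and LOD averaged with weights LOD^2; pairs present
    in only one set are copied unchanged. When both LODs of a shared
    pair are zero an unweighted mean is used (with a warning).
    """
    da = a.pairs.copy()
    db = b.pairs.copy()
    da["_key"] = PairwiseLinkageSet._keys(da)
    db["_key"] = PairwiseLinkageSet._keys(db)
    merged = da.merge(db, on="_key", how="outer", suffixes=("_a", "_b"))

    in_both = (merged["r_a"].notna() & merged["r_b"].notna()).to_numpy()
    wa = (merged["lod_a"] ** 2).fillna(0.0).to_numpy()
    wb = (merged["lod_b"] ** 2).fillna(0.0).to_numpy()
    zero = in_both & (wa + wb == 0)
    if zero.any():
        warnings.warn(f"{int(zero.sum())} shared pairs have zero LOD in both "
                      "populations; using unweighted means", stacklevel=2)
        wa = np.where(zero, 1.0, wa)
        wb = np.where(zero, 1.0, wb)
    wtot = np.where(in_both, wa + wb, 1.0)

    ra = merged["r_a"].to_numpy()
    rb = merged["r_b"].to_numpy()
    la = merged["lod_a"].to_numpy()
    lb = merged["lod_b"].to_numpy()
    out = pd.DataFrame({
        "marker1": [k[0] for k in merged["_key"]],
        "marker2": [k[1] for k in merged["_key"]],
        "r": np.where(in_both,
                      (np.nan_to_num(ra) * wa + np.nan_to_num(rb) * wb) / wtot,
                      np.where(np.isnan(ra), rb, ra)),
        "lod": np.where(in_both,
                        (np.nan_to_num(la) * wa + np.nan_to_num(lb) * wb) / wtot,
                        np.where(np.isnan(la), lb, la)),
    })
    if "n_a" in merged.columns and "n_b" in merged.columns:
        out["n"] = merged["n_a"].fillna(0).astype(int) + \
            merged["n_b"].fillna(0).astype(int)
    return PairwiseLinkageSet(population="combined", pairs=out)


@dataclass
class IntegrationResult:
    consensus: GeneticMap
    sources: dict = field(default_factory=dict)  # lg -> "combined" | population id


def integrate_maps(merged: PairwiseLinkageSet,
                   maps: dict[str, GeneticMap],
                   matrices: dict[str, "object"] | None = None,
                   expected_groups: int | None = None,
                   **order_kwargs) -> IntegrationResult:
    """Re-order each chromosome on the combined pairwise data.

    ``maps`` holds the per-population maps keyed by population id (their
    linkage-group labels must correspond). A chromosome with markers
    from both populations is re-ordered on the merged pairwise data; a
    chromosome represented in only one population is carried over from
    that population unchanged. ``matrices`` may supply the populations'
    dosage matrices to enable composite-likelihood ordering for groups
    whose markers all come from one population.
    """
    if not maps:
        raise MissingGroupError("no input maps")
    pops = list(maps)
    all_groups: set = set()
    for gmap in maps.values():
        all_groups |= set(gmap.entries["linkage_group"].unique())
    if expected_groups is not None and len(all_groups) < expected_groups:
        raise MissingGroupError(
            f"only {len(all_groups)} linkage groups present, expected "
            f"{expected_groups}")

    # each marker follows the first population that mapped it, so a
    # marker clustered differently in the two populations lands in one
    # group only
    group_of: dict[str, object] = {}
    for p in pops:
        for mk, lg in zip(maps[p].entries["marker"],
                          maps[p].entries["linkage_group"]):
            group_of.setdefault(mk, (p, lg))

    entries = []
    sources: dict = {}
    for lg in sorted(all_groups):
        members_by_pop = {
            p: {mk for mk in maps[p].group(lg)["marker"]
                if group_of[mk][1] == lg}
            for p in pops}
        present = [p for p in pops if members_by_pop[p]]
        if not present:
            raise MissingGroupError(f"linkage group {lg} absent from all maps")
        if len(present) == 1:
            src = present[0]
            carry = maps[src].group(lg)
            carry = carry[[group_of[mk][1] == lg for mk in carry["marker"]]]
            entries.append(carry.copy())
            sources[lg] = src
            continue
        members = sorted(set.union(*[members_by_pop[p] for p in present]))
        # composite-likelihood ordering pools the per-pair likelihood
        # profiles of every supplied population; the single-population
        # maps seed extra starting configurations so the consensus can
        # only improve on them
        matrix = None if matrices is None else [matrices[p] for p in present
                                                if p in matrices]
        init_maps = [dict(zip(maps[p].group(lg)["marker"],
                              maps[p].group(lg)["position_cM"]))
                     for p in present]
        res = order_markers(members, merged.pairs, matrix=matrix,
                            init_maps=init_maps, **order_kwargs)
        entries.append(res.entries(lg))
        sources[lg] = "combined"
    consensus = GeneticMap(pd.concat(entries, ignore_index=True)
                           [["marker", "linkage_group", "position_cM"]])
    return IntegrationResult(consensus=consensus, sources=sources)
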
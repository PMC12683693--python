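"""Linkage-map construction from pairwise linkage data.

Pipeline stages: missingness filtering and duplicate handling, LOD-ladder
clustering of simplex x nulliplex markers into linkage groups, homologue
assignment from coupling-phase subgraphs, cross-parent bridging through
simplex x simplex markers, 1-D weighted least-squares marker ordering
(weights LOD^2, Haldane distances) with local improvement, and iterative
elimination of ill-fitting markers.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from ._util import (MISSING, DataError, DomainError, TetramapError,
                    haldane_cm, inverse_haldane)
from .dosage import DosageMatrix
from . import tetrapoint

__all__ = [
    "MarkerBin", "GeneticMap", "FilterResult", "LinkageGroupResult",
    "HomologueAssignment", "OrderResult", "filter_and_bin",
    "cluster_linkage_groups", "assign_homologues", "order_markers",
    "build_map", "StructureError", "PhaseInconsistencyError", "OrderingError",
]


class StructureError(TetramapError):
    pass


class PhaseInconsistencyError(TetramapError):
    pass


class OrderingError(TetramapError):
    pass


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class MarkerBin:
    representative: str
    members: list[str]

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise DataError("bin representative must be a member")


@dataclass
class GeneticMap:
    """marker -> (linkage group, cM) with optional homologue annotation."""
    entries: pd.DataFrame  # marker, linkage_group, position_cM, [homologue_*...]

    REQUIRED = ("marker", "linkage_group", "position_cM")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.entries.columns:
                raise DataError(f"genetic map missing column {col!r}")
        if self.entries["marker"].duplicated().any():
            dup = self.entries.loc[self.entries["marker"].duplicated(), "marker"]
            raise DataError(f"duplicate map entries: {sorted(dup)[:5]}")
        if (self.entries["position_cM"] < 0).any():
            raise DataError("map positions must be non-negative")

    def summary(self) -> pd.DataFrame:
        """Per-linkage-group marker count and length (max position, cM)."""
        g = self.entries.groupby("linkage_group")
        out = pd.DataFrame({
            "markers": g["marker"].count(),
            "length_cM": g["position_cM"].max(),
        }).reset_index()
        return out.sort_values("linkage_group", ignore_index=True)

    def total_markers(self) -> int:
        return int(len(self.entries))

    def group(self, lg) -> pd.DataFrame:
        return self.entries[self.entries["linkage_group"] == lg]


# ---------------------------------------------------------------------------
# filtering and binning
# ---------------------------------------------------------------------------

@dataclass
class FilterResult:
    matrix: DosageMatrix
    bins: list[MarkerBin]
    merged_individuals: list[list[str]]
    ledger: dict[str, int] = field(default_factory=dict)

    def restore_bins(self, gmap: GeneticMap) -> GeneticMap:
        """Add binned duplicates back at their representative's position."""
        entries = gmap.entries
        extra = []
        for b in self.bins:
            rep_rows = entries[entries["marker"] == b.representative]
            if rep_rows.empty:
                continue
            rep = rep_rows.iloc[0]
            for m in b.members:
                if m == b.representative:
                    continue
                row = rep.to_dict()
                row["marker"] = m
                row["bin_representative"] = b.representative
                extra.append(row)
        if not extra:
            return gmap
        out = entries.copy()
        if "bin_representative" not in out.columns:
            out["bin_representative"] = pd.NA
        out = pd.concat([out, pd.DataFrame(extra)], ignore_index=True)
        return GeneticMap(out)


def filter_and_bin(matrix: DosageMatrix,
                   marker_missing_max: float = 0.1,
                   indiv_missing_max: float = 0.1,
                   duplicate_indiv_threshold: float = 0.98,
                   min_shared_calls: int = 10) -> FilterResult:
    """Missingness filters, duplicate-individual merging, marker binning.

    Individual pairs whose dosage identity over mutually non-missing
    calls reaches the threshold are merged into a consensus (conflicting
    calls become missing). Markers with byte-identical segregation
    vectors are binned behind one representative.
    """
    for name, v in (("marker_missing_max", marker_missing_max),
                    ("indiv_missing_max", indiv_missing_max),
                    ("duplicate_indiv_threshold", duplicate_indiv_threshold)):
        if not (0.0 <= v <= 1.0):
            raise DomainError(f"{name} must be in [0, 1]")
    ledger: dict[str, int] = {}

    keep_m = matrix.marker_missing_fraction() <= marker_missing_max
    ledger["markers_removed_missing"] = int((~keep_m).sum())
    m = matrix.subset(marker_idx=np.where(keep_m)[0])
    if m.n_markers == 0:
        raise DataError("all markers removed by the missingness filter")

    keep_i = m.individual_missing_fraction() <= indiv_missing_max
    ledger["individuals_removed_missing"] = int((~keep_i).sum())
    m = m.subset(individual_idx=np.where(keep_i)[0])

    # duplicate individuals: identity over shared non-missing calls
    data = m.data
    nonmiss = data != MISSING
    agree = np.zeros((m.n_individuals, m.n_individuals))
    for d in range(5):
        x = ((data == d) & nonmiss).astype(np.float32)
        agree += x.T @ x
    shared = nonmiss.astype(np.float32).T @ nonmiss.astype(np.float32)
    with np.errstate(invalid="ignore", divide="ignore"):
        identity = np.where(shared > 0, agree / shared, 0.0)
    dup_graph = nx.Graph()
    dup_graph.add_nodes_from(range(m.n_individuals))
    ii, jj = np.nonzero(np.triu(
        (identity >= duplicate_indiv_threshold) & (shared >= min_shared_calls), 1))
    dup_graph.add_edges_from(zip(ii.tolist(), jj.tolist()))
    merged_groups = [sorted(c) for c in nx.connected_components(dup_graph)
                     if len(c) > 1]
    merged_names: list[list[str]] = []
    if merged_groups:
        drop = set()
        new_data = data.copy()
        for grp in merged_groups:
            cols = data[:, grp]
            consensus = np.full(m.n_markers, MISSING, dtype=np.int8)
            for k in range(m.n_markers):
                vals = cols[k][cols[k] != MISSING]
                if len(vals) and (vals == vals[0]).all():
                    consensus[k] = vals[0]
                # conflicting duplicate calls -> missing
            new_data[:, grp[0]] = consensus
            drop.update(grp[1:])
            merged_names.append([m.individuals[g] for g in grp])
        keep = [j for j in range(m.n_individuals) if j not in drop]
        m = DosageMatrix(markers=m.markers,
                         individuals=[m.individuals[j] for j in keep],
                         maternal=m.maternal, paternal=m.paternal,
                         data=new_data[:, keep],
                         marker_chrom=m.marker_chrom, marker_pos=m.marker_pos)
    ledger["individuals_merged"] = sum(len(g) - 1 for g in merged_groups)

    # bin duplicate markers (identical dosage vectors incl. missing pattern)
    seen: dict[bytes, int] = {}
    bins_members: dict[int, list[str]] = {}
    keep_rows: list[int] = []
    for i in range(m.n_markers):
        key = m.data[i].tobytes() + bytes([max(0, m.maternal[i]),
                                           max(0, m.paternal[i])])
        if key in seen:
            bins_members[seen[key]].append(m.markers[i])
        else:
            seen[key] = i
            bins_members[i] = [m.markers[i]]
            keep_rows.append(i)
    bins = [MarkerBin(representative=m.markers[i], members=members)
            for i, members in bins_members.items() if len(members) > 1]
    ledger["markers_binned"] = sum(len(b.members) - 1 for b in bins)
    filtered = m.subset(marker_idx=np.array(keep_rows))
    return FilterResult(matrix=filtered, bins=bins,
                        merged_individuals=merged_names, ledger=ledger)


# ---------------------------------------------------------------------------
# linkage-group clustering
# ---------------------------------------------------------------------------

@dataclass
class LinkageGroupResult:
    groups: dict[str, int]          # marker -> 1..k (largest group first)
    unassigned: list[str]
    threshold: float
    n_components: int


DEFAULT_LOD_LADDER = (3.0, 4.0, 5.0, 6.0, 7.0, 10.0)


def cluster_linkage_groups(pairwise: pd.DataFrame, markers: list[str],
                           expected: int = 8,
                           lod_ladder=DEFAULT_LOD_LADDER) -> LinkageGroupResult:
    """Cluster markers into linkage groups by raising a LOD threshold.

    Edges connect pairs with LOD >= threshold; the threshold climbs the
    ladder until the number of connected components (markers with at
    least one edge) reaches the expected chromosome number. The largest
    ``expected`` components become groups; everything else is flagged
    unassigned.
    """
    marker_set = set(markers)
    pw = pairwise[pairwise["marker1"].isin(marker_set)
                  & pairwise["marker2"].isin(marker_set)]
    for t in lod_ladder:
        sub = pw[pw["lod"] >= t]
        g = nx.Graph()
        g.add_edges_from(zip(sub["marker1"], sub["marker2"]))
        comps = sorted(nx.connected_components(g),
                       key=lambda c: (-len(c), min(c)))
        if len(comps) >= expected:
            groups: dict[str, int] = {}
            for k, comp in enumerate(comps[:expected]):
                for m in comp:
                    groups[m] = k + 1
            unassigned = sorted(marker_set - set(groups))
            return LinkageGroupResult(groups=groups, unassigned=unassigned,
                                      threshold=float(t),
                                      n_components=len(comps))
    raise StructureError(
        f"could not reach {expected} linkage groups at max LOD "
        f"{lod_ladder[-1]}; achieved {len(comps)} components")


# ---------------------------------------------------------------------------
# homologue assignment
# ---------------------------------------------------------------------------

@dataclass
class HomologueAssignment:
    maternal: dict[str, int | None]   # marker -> homologue 1..4
    paternal: dict[str, int | None]
    cross_parent_matched: bool
    matching: dict[int, int] | None   # maternal homologue -> paternal homologue


def _coupling_clusters(markers: list[str], pw: pd.DataFrame, side: str,
                       lod_min: float, max_clusters: int,
                       strict: bool, r_max: float = 0.35) -> dict[str, int]:
    """Partition a parent's simplex markers by coupling-phase linkage.

    Edges additionally require r <= r_max: near r = 0.5 coupling and
    repulsion likelihoods converge, so distant pairs carry no reliable
    phase signal.
    """
    phase_idx = 0 if side == "maternal" else 1
    sub = pw[(pw["lod"] >= lod_min) & (pw["r"] <= r_max)
             & pw["marker1"].isin(markers) & pw["marker2"].isin(markers)]
    sub = sub[sub["phase"].str.split("x").str[phase_idx] == "C"]
    g = nx.Graph()
    g.add_nodes_from(markers)
    g.add_edges_from(zip(sub["marker1"], sub["marker2"]))
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    big = [c for c in comps if len(c) > 1]
    if strict and len(big) > max_clusters:
        raise PhaseInconsistencyError(
            f"{len(big)} {side} coupling clusters exceed {max_clusters}")
    labels: dict[str, int] = {}
    for k, comp in enumerate(c for c in comps if len(c) > 1):
        if k >= max_clusters:
            break
        for m in comp:
            labels[m] = k + 1
    # attach leftover singletons by their best coupling partner
    placed = set(labels)
    for m in markers:
        if m in labels:
            continue
        cand = sub[(sub["marker1"] == m) | (sub["marker2"] == m)]
        best, best_lod = None, 0.0
        for row in cand.itertuples():
            other = row.marker2 if row.marker1 == m else row.marker1
            if other in placed and row.lod > best_lod:
                best, best_lod = labels[other], row.lod
        labels[m] = best
    return labels


def assign_homologues(segtypes: dict[str, tuple[int, int]],
                      pairwise: pd.DataFrame, lod_min: float = 5.0,
                      strict: bool = True) -> HomologueAssignment:
    """Homologue labels 1..4 per parent for one linkage group.

    Simplex x nulliplex markers of each parent are partitioned by
    coupling-phase components; simplex x simplex markers (informative in
    both parents) bridge the two partitions; remaining segregating types
    are attached to the homologues with the strongest coupling evidence.
    """
    markers = list(segtypes)
    mat_sx = [m for m, (dm, dp) in segtypes.items() if dm == 1 and dp == 0]
    pat_sx = [m for m, (dm, dp) in segtypes.items() if dm == 0 and dp == 1]
    bridge = [m for m, (dm, dp) in segtypes.items() if dm == 1 and dp == 1]

    # clusters are seeded from simplex x nulliplex markers only; 1x1 pairs
    # leave the (C,R) vs (R,C) joint phases nearly indistinguishable and
    # would bridge unrelated homologues
    maternal = _coupling_clusters(mat_sx, pairwise, "maternal",
                                  lod_min, 4, strict)
    paternal = _coupling_clusters(pat_sx, pairwise, "paternal",
                                  lod_min, 4, strict)

    # attach every other segregating marker type (1x1 bridges included)
    # to the clusters by summed coupling LOD against the seed markers
    hom_m: dict[str, int | None] = dict(maternal)
    hom_p: dict[str, int | None] = dict(paternal)
    for side, labels, out in (("maternal", maternal, hom_m),
                              ("paternal", paternal, hom_p)):
        phase_idx = 0 if side == "maternal" else 1
        dose_idx = 0 if side == "maternal" else 1
        rest = [m for m in markers if m not in out
                and 1 <= segtypes[m][dose_idx] <= 3]
        if not rest:
            continue
        rest_set = set(rest)
        sub = pairwise[(pairwise["lod"] >= lod_min) & (pairwise["r"] <= 0.35)]
        sub = sub[sub["phase"].str.split("x").str[phase_idx] == "C"]
        by_marker: dict[str, dict[int, float]] = {}
        for m1, m2, lod in zip(sub["marker1"], sub["marker2"], sub["lod"]):
            for m, other in ((m1, m2), (m2, m1)):
                if m in rest_set and labels.get(other):
                    by_marker.setdefault(m, {}).setdefault(labels[other], 0.0)
                    by_marker[m][labels[other]] += lod
        for m in rest:
            sums = by_marker.get(m, {})
            out[m] = max(sums, key=sums.get) if sums else None

    votes = np.zeros((4, 4))
    for m in bridge:
        hm, hp = hom_m.get(m), hom_p.get(m)
        if hm and hp:
            votes[hm - 1, hp - 1] += 1
    matched = votes.sum() > 0
    matching = None
    if matched:
        rows, cols = linear_sum_assignment(-votes)
        matching = {int(r) + 1: int(c) + 1 for r, c in zip(rows, cols)
                    if votes[r, c] > 0}

    for m in markers:
        hom_m.setdefault(m, None)
        hom_p.setdefault(m, None)
    return HomologueAssignment(maternal=hom_m, paternal=hom_p,
                               cross_parent_matched=bool(matched),
                               matching=matching)


# ---------------------------------------------------------------------------
# marker ordering
# ---------------------------------------------------------------------------

@dataclass
class OrderResult:
    markers: list[str]            # in map order
    positions: np.ndarray         # cM, min = 0
    removed: list[str]
    stress: float

    def entries(self, linkage_group) -> pd.DataFrame:
        return pd.DataFrame({"marker": self.markers,
                             "linkage_group": linkage_group,
                             "position_cM": self.positions})


def _stress(x: np.ndarray, D: np.ndarray, W: np.ndarray) -> float:
    diff = np.abs(x[:, None] - x[None, :])
    return float((W * (diff - D) ** 2).sum() / 2.0)


def _smacof_1d(x: np.ndarray, D: np.ndarray, W: np.ndarray,
               n_iter: int = 200) -> np.ndarray:
    """1-D weighted least-squares embedding by majorization."""
    wsum = W.sum(axis=1)
    wsum[wsum == 0] = 1.0
    for _ in range(n_iter):
        diff = x[:, None] - x[None, :]
        s = np.sign(diff)
        s[s == 0] = 1.0
        np.fill_diagonal(s, 0.0)
        x = (W * (x[None, :] + D * s)).sum(axis=1) / wsum
    return x


def _classical_mds_1d(Dc: np.ndarray) -> np.ndarray:
    n = len(Dc)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (Dc ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    return vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))


def _swap_polish(x: np.ndarray, D: np.ndarray, W: np.ndarray,
                 max_passes: int = 30) -> np.ndarray:
    """Adjacent coordinate swaps until the stress stops decreasing."""
    cur = _stress(x, D, W)
    for _ in range(max_passes):
        improved = False
        order = np.argsort(x, kind="stable")
        for k in range(len(x) - 1):
            i, j = order[k], order[k + 1]
            x2 = x.copy()
            x2[i], x2[j] = x2[j], x2[i]
            s = _stress(x2, D, W)
            if s < cur - 1e-12:
                x, cur, improved = x2, s, True
        if not improved:
            break
    return x


def _profile_polish(x: np.ndarray, prof: np.ndarray, has: np.ndarray,
                    r_grid: np.ndarray, rng: np.random.Generator,
                    spans: np.ndarray, n_cand: int = 61) -> np.ndarray:
    """Coordinate-wise composite-likelihood ascent over marker positions.

    Each marker is moved to the candidate coordinate maximizing the sum
    of its pairwise log-likelihood profiles evaluated at the implied
    (inverse-Haldane) recombination fractions. Repulsion-type pairs have
    nearly flat profiles and so contribute little, instead of pulling
    with biased point estimates.
    """
    n = len(x)
    step = r_grid[1] - r_grid[0]
    G = len(r_grid)
    cols = np.arange(n)[None, :]
    for span in spans:
        moved = False
        offsets = np.linspace(-span, span, n_cand)
        for i in rng.permutation(n):
            cands = x[i] + offsets
            d = np.abs(cands[:, None] - x[None, :])
            r = 0.5 * (1.0 - np.exp(d * (-1.0 / 50.0)))  # inverse Haldane
            gi = ((r * (1.0 / step)).round().astype(np.int64)).clip(0, G - 1)
            ll = prof[i][cols, gi][:, has[i]].sum(axis=1)
            k = int(np.argmax(ll))
            if abs(cands[k] - x[i]) > 1e-9:
                x[i] = cands[k]
                moved = True
        if not moved:
            break
    return x


def _profile_total_ll(x: np.ndarray, prof: np.ndarray, has: np.ndarray,
                      r_grid: np.ndarray) -> float:
    step = r_grid[1] - r_grid[0]
    G = len(r_grid)
    d = np.abs(x[:, None] - x[None, :])
    gi = np.clip((inverse_haldane(d) / step).round().astype(int), 0, G - 1)
    n = len(x)
    ll = prof[np.arange(n)[:, None], np.arange(n)[None, :], gi]
    return float(ll[has].sum()) / 2.0


def order_markers(markers: list[str], pairwise: pd.DataFrame,
                  matrix=None, init_maps=None,
                  lod_min: float = 0.0, stress_multiple: float = 6.0,
                  max_removed_frac: float = 0.10, strong_lod: float = 5.0,
                  n_restarts: int = 3, profile_r_step: float = 0.002,
                  ) -> OrderResult:
    """Order one linkage group and assign cM positions.

    Haldane distances weighted by LOD^2 are embedded in 1-D by weighted
    least squares (SMACOF majorization seeded with classical MDS on
    shortest-path-completed strong-edge distances) and locally improved.
    When dosage data are supplied (one matrix, or a list of matrices
    from independent populations whose profiles are summed), local
    improvement maximizes the composite two-point likelihood
    (coordinate ascent over per-pair likelihood profiles, best restart
    kept); otherwise adjacent coordinate swaps reduce the stress until
    no decrease remains.
    Ill-fitting markers are then removed one at a time while the worst
    marker's normalized stress exceeds ``stress_multiple`` times the
    group median. Positions are shifted so the map starts at 0.
    """
    markers = list(markers)
    n = len(markers)
    if n < 2:
        raise DataError("ordering needs at least 2 markers")
    idx = {m: i for i, m in enumerate(markers)}
    D = np.zeros((n, n))
    W = np.zeros((n, n))
    sub = pairwise[pairwise["marker1"].isin(idx) & pairwise["marker2"].isin(idx)]
    for row in sub.itertuples():
        if row.lod < lod_min:
            continue
        i, j = idx[row.marker1], idx[row.marker2]
        w = row.lod ** 2
        if w > W[i, j]:
            D[i, j] = D[j, i] = haldane_cm(row.r)
            W[i, j] = W[j, i] = w

    from scipy.sparse.csgraph import connected_components
    n_comp, comp_labels = connected_components(csr_matrix((W > 0)), directed=False)
    if n_comp > 1:
        comps = [sorted(np.array(markers)[comp_labels == c]) for c in range(n_comp)]
        raise OrderingError(
            f"pairwise graph is disconnected into {n_comp} components: "
            f"{[c[:3] for c in comps]}")

    if n == 2:
        return OrderResult(markers=markers, positions=np.array([0.0, D[0, 1]]),
                           removed=[], stress=0.0)

    # shortest-path completion over confident edges for initialization
    strong = np.where(W >= strong_lod ** 2, D, 0.0)
    if connected_components(csr_matrix(strong > 0), directed=False)[0] > 1:
        strong = np.where(W > 0, D, 0.0)
    Dc = shortest_path(csr_matrix(strong), directed=False)
    finite = np.isfinite(Dc)
    if not finite.all():
        Dc[~finite] = np.nanmax(Dc[finite])
    np.fill_diagonal(Dc, 0.0)

    x = _smacof_1d(_classical_mds_1d(Dc), D, W)

    matrices = ([] if matrix is None
                else list(matrix) if isinstance(matrix, (list, tuple))
                else [matrix])
    if matrices:
        # composite likelihood: profiles from independent populations add
        r_step = profile_r_step if n <= 300 else 2.5 * profile_r_step
        r_grid = np.arange(0.0, 0.5 + r_step / 2, r_step)
        prof = np.zeros((n, n, len(r_grid)), dtype=np.float32)
        has = np.zeros((n, n), dtype=bool)
        for mat in matrices:
            known = set(mat.markers)
            present = [i for i, m in enumerate(markers) if m in known]
            if len(present) < 2:
                continue
            _, p_m, h_m = tetrapoint.pairwise_loglik_profiles(
                mat, [markers[i] for i in present], r_step=r_step)
            ix = np.ix_(present, present)
            prof[ix] += p_m
            has[ix] |= h_m

        # starting configurations: the stress embedding plus any supplied
        # candidate maps (e.g. the single-population maps during consensus
        # integration); markers absent from a candidate are first placed
        # by a global composite-likelihood scan
        inits = [x.copy()]
        for cand in (init_maps or []):
            pos_of = dict(cand)
            known = [i for i, m in enumerate(markers) if m in pos_of]
            if len(known) < max(3, n // 2):
                continue
            xi = np.empty(n)
            kvals = np.array([pos_of[markers[i]] for i in known])
            xi[known] = kvals
            missing = [i for i in range(n) if markers[i] not in pos_of]
            if missing:
                span = np.linspace(kvals.min() - 10.0, kvals.max() + 10.0, 151)
                step = r_grid[1] - r_grid[0]
                for i in missing:
                    d = np.abs(span[:, None] - xi[None, known])
                    r = 0.5 * (1.0 - np.exp(d * (-1.0 / 50.0)))
                    gi = ((r * (1.0 / step)).round().astype(np.int64)
                          ).clip(0, len(r_grid) - 1)
                    mask = has[i][known]
                    ll = prof[i][np.array(known)[None, :], gi][:, mask].sum(axis=1)
                    xi[i] = span[int(np.argmax(ll))]
            inits.append(xi)

        best_x, best_ll = None, -np.inf
        for k, x0 in enumerate(inits):
            for restart in range(max(1, n_restarts if k == 0 else 2)):
                rng = np.random.default_rng(100 * k + restart + 1)
                xx = _profile_polish(x0.copy(), prof, has, r_grid, rng,
                                     np.geomspace(15.0, 0.5, 30))
                ll = _profile_total_ll(xx, prof, has, r_grid)
                if ll > best_ll:
                    best_x, best_ll = xx, ll
        x = best_x
    else:
        x = _swap_polish(x, D, W)

    # iterative ill-fit elimination
    removed: list[str] = []
    active = np.arange(n)
    max_removed = int(max_removed_frac * n)
    while len(active) > 3 and len(removed) < max_removed:
        diff = np.abs(x[active][:, None] - x[active][None, :])
        Wa = W[np.ix_(active, active)]
        Da = D[np.ix_(active, active)]
        wsum = Wa.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_marker = np.where(wsum > 0,
                                  (Wa * (diff - Da) ** 2).sum(axis=1) / wsum, 0.0)
        med = float(np.median(per_marker))
        worst = int(np.argmax(per_marker))
        if med <= 0 or per_marker[worst] <= stress_multiple * med:
            break
        removed.append(markers[active[worst]])
        active = np.delete(active, worst)

    order = active[np.argsort(x[active], kind="stable")]
    pos = x[order] - x[order].min()
    final_stress = _stress(x[active], D[np.ix_(active, active)],
                           W[np.ix_(active, active)])
    return OrderResult(markers=[markers[i] for i in order], positions=pos,
                       removed=removed, stress=final_stress)


# ---------------------------------------------------------------------------
# full pipeline for one population
# ---------------------------------------------------------------------------

def build_map(matrix: DosageMatrix, expected_groups: int = 8,
              lod_ladder=DEFAULT_LOD_LADDER, hom_lod_min: float = 5.0,
              cluster_r_step: float = 0.01, order_r_step: float = 0.002,
              marker_missing_max: float = 0.1, indiv_missing_max: float = 0.1,
              duplicate_indiv_threshold: float = 0.98,
              stress_multiple: float = 6.0, strict_homologues: bool = False,
              ) -> tuple[GeneticMap, dict]:
    """Run the full single-population mapping pipeline.

    Returns the genetic map (binned duplicates restored) and a
    diagnostics dict with the intermediate artifacts, including the
    pairwise linkage table reused by consensus-map integration.
    """
    fr = filter_and_bin(matrix, marker_missing_max, indiv_missing_max,
                        duplicate_indiv_threshold)
    m = fr.matrix
    segtypes = {m.markers[i]: (int(m.maternal[i]), int(m.paternal[i]))
                for i in range(m.n_markers)}
    informative = [mk for mk, (dm, dp) in segtypes.items()
                   if tetrapoint.SegType(dm, dp).informative]
    pw = tetrapoint.pairwise_linkage(m, markers=informative,
                                     r_step=cluster_r_step)

    mat_sx = [mk for mk in informative if segtypes[mk] == (1, 0)]
    pat_sx = [mk for mk in informative if segtypes[mk] == (0, 1)]
    lg_m = cluster_linkage_groups(pw, mat_sx, expected_groups, lod_ladder)
    lg_p = cluster_linkage_groups(pw, pat_sx, expected_groups, lod_ladder)

    # bridge maternal and paternal groups through 1x1 markers
    bridge = set(mk for mk in informative if segtypes[mk] == (1, 1))
    votes = np.zeros((expected_groups, expected_groups))
    bridge_votes: dict[str, tuple[dict, dict]] = {mk: ({}, {}) for mk in bridge}
    strong = pw[pw["lod"] >= hom_lod_min]
    for m1, m2, lod in zip(strong["marker1"], strong["marker2"], strong["lod"]):
        for mk, other in ((m1, m2), (m2, m1)):
            if mk not in bridge:
                continue
            vm, vp = bridge_votes[mk]
            if other in lg_m.groups:
                vm[lg_m.groups[other]] = vm.get(lg_m.groups[other], 0) + lod
            if other in lg_p.groups:
                vp[lg_p.groups[other]] = vp.get(lg_p.groups[other], 0) + lod
    for mk, (vm, vp) in bridge_votes.items():
        if vm and vp:
            votes[max(vm, key=vm.get) - 1, max(vp, key=vp.get) - 1] += 1
    if votes.sum() > 0:
        rows, cols = linear_sum_assignment(-votes)
        match = {int(r) + 1: int(c) + 1 for r, c in zip(rows, cols)}
    else:
        match = {g: g for g in range(1, expected_groups + 1)}

    # final group membership
    group_of: dict[str, int] = dict(lg_m.groups)
    for mk, g in lg_p.groups.items():
        inv = {v: k for k, v in match.items()}
        group_of[mk] = inv.get(g, g)
    for mk, (vm, vp) in bridge_votes.items():
        votes_g: dict[int, float] = dict(vm)
        for g, v in vp.items():
            gg = {v2: k2 for k2, v2 in match.items()}.get(g, g)
            votes_g[gg] = votes_g.get(gg, 0) + v
        if votes_g:
            group_of[mk] = max(votes_g, key=votes_g.get)
    # remaining informative types by strongest linkage
    rest = set(mk for mk in informative if mk not in group_of)
    if rest:
        rest_votes: dict[str, dict[int, float]] = {mk: {} for mk in rest}
        for m1, m2, lod in zip(strong["marker1"], strong["marker2"],
                               strong["lod"]):
            for mk, other in ((m1, m2), (m2, m1)):
                if mk in rest and other in group_of:
                    g = group_of[other]
                    rest_votes[mk][g] = rest_votes[mk].get(g, 0) + lod
        for mk, votes_g in rest_votes.items():
            if votes_g:
                group_of[mk] = max(votes_g, key=votes_g.get)

    entries = []
    homologues: dict[str, HomologueAssignment] = {}
    group_pairwise: dict[int, pd.DataFrame] = {}
    for g in sorted(set(group_of.values())):
        members = [mk for mk, gg in group_of.items() if gg == g]
        if len(members) < 2:
            continue
        fine = tetrapoint.pairwise_linkage(m, markers=members,
                                           r_step=order_r_step)
        group_pairwise[g] = fine
        hom = assign_homologues({mk: segtypes[mk] for mk in members}, fine,
                                lod_min=hom_lod_min, strict=strict_homologues)
        homologues[g] = hom
        res = order_markers(members, fine, matrix=m,
                            stress_multiple=stress_multiple)
        df = res.entries(g)
        df["homologue_maternal"] = [hom.maternal.get(mk) for mk in res.markers]
        df["homologue_paternal"] = [hom.paternal.get(mk) for mk in res.markers]
        entries.append(df)
    if not entries:
        raise StructureError("no linkage group could be ordered")
    gmap = GeneticMap(pd.concat(entries, ignore_index=True))
    gmap = fr.restore_bins(gmap)
    diagnostics = {"filter": fr, "pairwise": pw, "groups": group_of,
                   "group_pairwise": group_pairwise,
                   "maternal_groups": lg_m, "paternal_groups": lg_p,
                   "homologues": homologues}
    return gmap, diagnostics
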
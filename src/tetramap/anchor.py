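"""Genetic-map-based scaffolding and recombination-landscape statistics.

Marker-to-contig alignments are filtered on coverage, identity and
mapping uniqueness; contigs are assigned to chromosomes by majority vote
of their markers' linkage groups, ordered by mean cM, oriented by the
rank correlation between within-contig bp and cM, and concatenated into
pseudomolecules (AGP v2.1 + FASTA, fixed-length N gaps). Marey-map
statistics summarize the recombination landscape; a run-based scan of
shared marker orders reports candidate inversions and translocations.

Coordinates are 1-based inclusive in AGP and alignment tables, 0-based
half-open internally.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.stats import spearmanr

from ._util import DataError, DomainError

__all__ = [
    "filter_alignments", "place_contigs", "build_pseudomolecules",
    "marey_stats", "synteny_compare", "marker_physical_positions",
    "AlignmentFilterResult", "PlacementResult", "LandscapeStats",
    "SyntenyReport",
]

ALIGNMENT_COLUMNS = ("marker", "contig", "start", "end", "strand",
                     "coverage", "identity", "n_hits")


# ---------------------------------------------------------------------------
# alignment filtering
# ---------------------------------------------------------------------------

@dataclass
class AlignmentFilterResult:
    retained: pd.DataFrame
    rejected: pd.DataFrame          # with a "reason" column
    ledger: dict[str, int] = field(default_factory=dict)


def _check_alignments(alignments: pd.DataFrame) -> None:
    for col in ALIGNMENT_COLUMNS:
        if col not in alignments.columns:
            raise DataError(f"alignment table missing column {col!r}")
    a = alignments
    if ((a["coverage"] < 0) | (a["coverage"] > 1)).any():
        raise DataError("coverage must lie in [0, 1]")
    if ((a["identity"] < 0) | (a["identity"] > 1)).any():
        raise DataError("identity must lie in [0, 1]")
    if (a["start"] > a["end"]).any():
        raise DataError("alignment start must be <= end")
    if (a["n_hits"] < 1).any():
        raise DataError("n_hits must be >= 1")


def filter_alignments(alignments: pd.DataFrame, min_coverage: float = 0.98,
                      min_identity: float = 0.95, require_unique: bool = True,
                      max_hits: int = 4, max_probes_per_contig: int = 350,
                      ) -> AlignmentFilterResult:
    """Apply the marker-alignment retention rules.

    Rejections are categorized in order: coverage, identity, ambiguity
    (more than one mapping position when uniqueness is required, or more
    hits than a tetraploid can explain), and the per-contig probe cap
    (keeping the highest-identity probes).
    """
    _check_alignments(alignments)
    df = alignments.copy()
    reasons = pd.Series(pd.NA, index=df.index, dtype="object")

    mask = df["coverage"] < min_coverage
    reasons[mask & reasons.isna()] = "coverage"
    mask = df["identity"] < min_identity
    reasons[mask & reasons.isna()] = "identity"
    if require_unique:
        mask = df["n_hits"] > 1
    else:
        mask = df["n_hits"] > max_hits
    reasons[mask & reasons.isna()] = "ambiguity"

    keep = reasons.isna()
    kept = df[keep]
    # per-contig cap keeps the highest-identity probes (name-stable order)
    capped_idx = []
    for contig, grp in kept.groupby("contig", sort=False):
        if len(grp) > max_probes_per_contig:
            order = grp.sort_values(["identity", "marker"],
                                    ascending=[False, True])
            capped_idx.extend(order.index[max_probes_per_contig:])
    reasons[capped_idx] = "contig_cap"

    keep = reasons.isna()
    retained = df[keep].reset_index(drop=True)
    rejected = df[~keep].copy()
    rejected["reason"] = reasons[~keep]
    ledger = {"input": int(len(df)), "retained": int(len(retained))}
    for cat in ("coverage", "identity", "ambiguity", "contig_cap"):
        ledger[f"rejected_{cat}"] = int((rejected["reason"] == cat).sum())
    if retained.empty:
        warnings.warn("no alignments retained after filtering", stacklevel=2)
    return AlignmentFilterResult(retained=retained,
                                 rejected=rejected.reset_index(drop=True),
                                 ledger=ledger)


# ---------------------------------------------------------------------------
# contig placement
# ---------------------------------------------------------------------------

@dataclass
class PlacementResult:
    placements: pd.DataFrame   # contig, chrom, order, orientation, n_markers, mean_cM
    conflicts: pd.DataFrame    # contig, reason / vote details
    unplaced: list[str]        # contigs without markers


def place_contigs(retained: pd.DataFrame, gmap,
                  contig_lengths: dict[str, int]) -> PlacementResult:
    """Assign, order and orient contigs along the genetic map.

    Chromosome by majority vote of marker linkage groups (ties drop the
    contig as a conflict); order by mean cM of supporting markers (ties
    broken by contig name); orientation from the sign of the Spearman
    correlation between within-contig bp and cM when at least two
    markers with distinct cM support it.
    """
    if retained.empty:
        raise DataError("no retained alignments to place")
    entries = gmap.entries.set_index("marker")
    merged = retained.merge(entries[["linkage_group", "position_cM"]],
                            left_on="marker", right_index=True, how="inner")
    skipped = set(retained["marker"]) - set(merged["marker"])

    rows, conflict_rows = [], []
    for contig, grp in merged.groupby("contig", sort=False):
        votes = grp["linkage_group"].value_counts()
        if len(votes) > 1 and votes.iloc[0] == votes.iloc[1]:
            conflict_rows.append({"contig": contig, "reason": "tied_vote",
                                  "votes": votes.to_dict()})
            continue
        lg = votes.index[0]
        on_lg = grp[grp["linkage_group"] == lg]
        if len(votes) > 1:
            conflict_rows.append({"contig": contig, "reason": "minority_markers",
                                  "votes": votes.to_dict()})
        mean_cm = float(on_lg["position_cM"].mean())
        distinct = on_lg.drop_duplicates("position_cM")
        if len(distinct) >= 2:
            rho = spearmanr(on_lg["start"], on_lg["position_cM"]).statistic
            if np.isnan(rho) or rho == 0:
                orient = "unoriented"
            else:
                orient = "+" if rho > 0 else "-"
        else:
            orient = "unoriented"
        rows.append({"contig": contig, "chrom": lg, "mean_cM": mean_cm,
                     "orientation": orient, "n_markers": int(len(on_lg))})
    placements = pd.DataFrame(rows)
    if not placements.empty:
        placements = placements.sort_values(
            ["chrom", "mean_cM", "contig"], ignore_index=True)
        placements["order"] = placements.groupby("chrom").cumcount()
        placements = placements[["contig", "chrom", "order", "orientation",
                                 "n_markers", "mean_cM"]]
    tied = {c["contig"] for c in conflict_rows if c["reason"] == "tied_vote"}
    unplaced = sorted(set(contig_lengths) - set(merged["contig"]) - tied)
    if skipped:
        warnings.warn(f"{len(skipped)} aligned markers absent from the map "
                      "were ignored", stacklevel=2)
    return PlacementResult(placements=placements,
                           conflicts=pd.DataFrame(conflict_rows),
                           unplaced=unplaced)


# ---------------------------------------------------------------------------
# pseudomolecules
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def build_pseudomolecules(placements: pd.DataFrame,
                          sequences: dict[str, str],
                          gap_length: int = 100,
                          object_prefix: str = "chr",
                          ) -> tuple[dict[str, str], pd.DataFrame]:
    """Concatenate placed contigs into chromosome sequences plus AGP.

    Contigs are joined in placement order with ``gap_length`` N
    characters at each junction; '-' contigs are reverse-complemented,
    unoriented contigs are inserted forward (AGP orientation '?').
    Returns (chromosome sequences, AGP v2.1 table).
    """
    if gap_length < 0:
        raise DomainError("gap_length must be >= 0")
    fasta: dict[str, str] = {}
    agp_rows = []
    for chrom, grp in placements.groupby("chrom", sort=True):
        grp = grp.sort_values("order")
        name = chrom if str(chrom).startswith(object_prefix) \
            else f"{object_prefix}{chrom}"
        parts: list[str] = []
        pos = 0
        part = 0
        for i, row in enumerate(grp.itertuples()):
            if row.contig not in sequences:
                raise DataError(f"missing sequence for contig {row.contig!r}")
            if i > 0 and gap_length > 0:
                part += 1
                agp_rows.append((name, pos + 1, pos + gap_length, part, "U",
                                 gap_length, "scaffold", "yes", "map"))
                parts.append("N" * gap_length)
                pos += gap_length
            seq = sequences[row.contig]
            emit = _revcomp(seq) if row.orientation == "-" else seq
            part += 1
            agp_orient = {"+": "+", "-": "-", "unoriented": "?"}[row.orientation]
            agp_rows.append((name, pos + 1, pos + len(seq), part, "W",
                             row.contig, 1, len(seq), agp_orient))
            parts.append(emit)
            pos += len(seq)
        fasta[name] = "".join(parts)
    agp = pd.DataFrame(agp_rows, columns=[
        "object", "object_beg", "object_end", "part_number", "component_type",
        "component_id", "component_beg", "component_end", "orientation"])
    return fasta, agp


# ---------------------------------------------------------------------------
# Marey-map statistics
# ---------------------------------------------------------------------------

@dataclass
class LandscapeStats:
    per_chromosome: pd.DataFrame  # chrom, n_markers, rho, central_fraction, class
    profiles: dict[str, pd.DataFrame] = field(default_factory=dict)


def marey_stats(marey: pd.DataFrame, chrom_lengths: dict | None = None,
                min_markers: int = 5, n_windows: int = 20,
                proximal_threshold: float = 0.5,
                distal_threshold: float = 0.25) -> LandscapeStats:
    """Recombination-landscape statistics from genetic vs physical positions.

    ``marey`` needs columns chrom, marker, bp, cM. Per chromosome:
    Spearman rho between the coordinates; a monotone (isotonic) Marey
    curve fitted after orienting the physical axis so rho >= 0; the
    central-tertile fraction C = (cM at 2L/3 - cM at L/3) / total cM;
    and a classification: proximal when C > 0.5, distal when C < 0.25,
    mixed otherwise. A windowed cM/Mb profile accompanies each chromosome.
    """
    for col in ("chrom", "bp", "cM"):
        if col not in marey.columns:
            raise DataError(f"marey table missing column {col!r}")
    rows = []
    profiles: dict[str, pd.DataFrame] = {}
    for chrom, grp in marey.groupby("chrom", sort=True):
        if len(grp) < min_markers:
            continue
        bp = grp["bp"].to_numpy(dtype=float)
        cm = grp["cM"].to_numpy(dtype=float)
        if np.unique(bp).size < 2:
            raise DataError(f"all markers of {chrom} share one physical position")
        L = float(chrom_lengths[chrom]) if chrom_lengths and chrom in chrom_lengths \
            else float(bp.max())
        rho = float(spearmanr(bp, cm).statistic)
        x = bp.copy()
        if rho < 0:
            x = L - x  # orient so the Marey curve rises
        order = np.argsort(x, kind="stable")
        x_s, cm_s = x[order], cm[order]
        fit = isotonic_regression(cm_s, increasing=True).x
        grid = np.array([L / 3.0, 2.0 * L / 3.0])
        cm_lo, cm_hi = np.interp(grid, x_s, fit)
        total = fit[-1] - fit[0]
        C = float((cm_hi - cm_lo) / total) if total > 0 else float("nan")
        if np.isnan(C):
            klass = "undefined"
        elif C > proximal_threshold:
            klass = "proximal"
        elif C < distal_threshold:
            klass = "distal"
        else:
            klass = "mixed"
        rows.append({"chrom": chrom, "n_markers": int(len(grp)),
                     "rho": abs(rho), "central_fraction": C, "class": klass})
        edges = np.linspace(0.0, L, n_windows + 1)
        cm_at = np.interp(edges, x_s, fit)
        profiles[str(chrom)] = pd.DataFrame({
            "window_start_bp": edges[:-1],
            "window_end_bp": edges[1:],
            "cM_per_Mb": np.diff(cm_at) / (np.diff(edges) / 1e6),
        })
    if not rows:
        raise DataError(f"no chromosome with >= {min_markers} markers")
    return LandscapeStats(per_chromosome=pd.DataFrame(rows), profiles=profiles)


def marker_physical_positions(agp: pd.DataFrame,
                              alignments: pd.DataFrame) -> pd.DataFrame:
    """Project marker alignment coordinates through an AGP onto
    pseudomolecule coordinates. Returns chrom, marker, bp."""
    comp = agp[agp["component_type"] == "W"]
    rows = []
    for row in comp.itertuples():
        sub = alignments[alignments["contig"] == row.component_id]
        for aln in sub.itertuples():
            clen = row.component_end - row.component_beg + 1
            if row.orientation == "-":
                bp = row.object_beg + (clen - aln.start)
            else:
                bp = row.object_beg + aln.start - 1
            rows.append({"chrom": row.object, "marker": aln.marker,
                         "bp": int(bp)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# marker-based synteny
# ---------------------------------------------------------------------------

@dataclass
class SyntenyReport:
    shared: pd.DataFrame          # per chromosome pair: n shared markers
    inversions: pd.DataFrame      # chrom_a, chrom_b, start/end markers, length
    translocations: pd.DataFrame  # markers on a non-majority chromosome


def synteny_compare(positions: pd.DataFrame, min_run: int = 5) -> SyntenyReport:
    """Compare marker orders between two assemblies.

    ``positions`` needs columns marker, chrom_a, pos_a, chrom_b, pos_b.
    Per chromosome of assembly A, the majority partner chromosome in B
    is determined; markers pointing elsewhere are translocation
    candidates. Among majority-partner markers sorted by A position
    (with the B axis flipped when the overall trend is decreasing),
    maximal strictly decreasing runs of length >= ``min_run`` are
    reported as candidate inversions.
    """
    for col in ("marker", "chrom_a", "pos_a", "chrom_b", "pos_b"):
        if col not in positions.columns:
            raise DataError(f"synteny table missing column {col!r}")
    shared_rows, inv_rows, trans_rows = [], [], []
    for chrom, grp in positions.groupby("chrom_a", sort=True):
        if len(grp) < min_run:
            warnings.warn(f"{chrom}: fewer than {min_run} shared markers",
                          stacklevel=2)
            continue
        partner_votes = grp["chrom_b"].value_counts()
        partner = partner_votes.index[0]
        shared_rows.append({"chrom_a": chrom, "chrom_b": partner,
                            "n_shared": int(partner_votes.iloc[0])})
        off = grp[grp["chrom_b"] != partner]
        for r in off.itertuples():
            trans_rows.append({"marker": r.marker, "chrom_a": chrom,
                               "chrom_b": r.chrom_b})
        on = grp[grp["chrom_b"] == partner].sort_values(
            ["pos_a", "marker"], ignore_index=True)
        if len(on) < min_run:
            continue
        b = on["pos_b"].to_numpy(dtype=float)
        rho = spearmanr(on["pos_a"], b).statistic
        if not np.isnan(rho) and rho < 0:
            b = -b
        # maximal strictly decreasing runs
        start = 0
        for k in range(1, len(b) + 1):
            if k == len(b) or b[k] >= b[k - 1]:
                if k - start >= min_run:
                    inv_rows.append({
                        "chrom_a": chrom, "chrom_b": partner,
                        "start_marker": on["marker"].iloc[start],
                        "end_marker": on["marker"].iloc[k - 1],
                        "n_markers": int(k - start)})
                start = k
    return SyntenyReport(
        shared=pd.DataFrame(shared_rows),
        inversions=pd.DataFrame(
            inv_rows, columns=["chrom_a", "chrom_b", "start_marker",
                               "end_marker", "n_markers"]),
        translocations=pd.DataFrame(
            trans_rows, columns=["marker", "chrom_a", "chrom_b"]))
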
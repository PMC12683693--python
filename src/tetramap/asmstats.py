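"""Assembly statistics, BUSCO summaries, duplication-minimizing contig
purging, and a coverage-peak genome-size estimate."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from ._util import DataError, DomainError, round_half_away

__all__ = [
    "AssemblyReport", "BuscoRecord", "BuscoSummary", "PurgeResult",
    "assembly_stats", "busco_summary", "purge_select", "genome_size_estimate",
]

COMPLETE_STATUSES = ("Complete", "Duplicated")
VALID_STATUSES = ("Complete", "Duplicated", "Fragmented", "Missing")


# ---------------------------------------------------------------------------
# assembly statistics
# ---------------------------------------------------------------------------

@dataclass
class AssemblyReport:
    total_size: int
    n_contigs: int
    n50: int
    l50: int
    gc_percent: float          # over non-N bases, one decimal
    max_contig: int
    n_gap_bases: int


def assembly_stats(sequences: dict[str, str] | None = None,
                   lengths: list[int] | None = None) -> AssemblyReport:
    """N50/L50 by the sorted cumulative half-total rule, plus GC and gap
    counts when sequences are given."""
    if sequences:
        lengths = [len(s) for s in sequences.values()]
    if not lengths:
        raise DomainError("assembly statistics need at least one contig")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    total = int(arr.sum())
    cum = np.cumsum(arr)
    i50 = int(np.searchsorted(cum, total / 2.0))
    n50 = int(arr[i50])
    l50 = i50 + 1
    gc = at = gaps = 0
    if sequences:
        for seq in sequences.values():
            up = seq.upper()
            gc += up.count("G") + up.count("C")
            at += up.count("A") + up.count("T")
            gaps += up.count("N")
    denom = gc + at
    gc_pct = round_half_away(100.0 * gc / denom, 1) if denom else float("nan")
    return AssemblyReport(total_size=total, n_contigs=len(arr), n50=n50,
                          l50=l50, gc_percent=gc_pct, max_contig=int(arr[0]),
                          n_gap_bases=gaps)


# ---------------------------------------------------------------------------
# BUSCO
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BuscoRecord:
    ortholog: str
    status: str                      # Complete | Duplicated | Fragmented | Missing
    contigs: tuple[str, ...] = ()    # contig hits

    def __post_init__(self) -> None:
        if self.status not in VALID_STATUSES:
            raise DataError(f"unknown BUSCO status {self.status!r}")
        if self.status == "Duplicated" and len(self.contigs) < 2:
            raise DataError(
                f"{self.ortholog}: Duplicated status needs >= 2 contig hits")
        if self.status == "Missing" and self.contigs:
            raise DataError(f"{self.ortholog}: Missing status with contig hits")


@dataclass
class BuscoSummary:
    total: int
    complete: int
    single: int
    duplicated: int
    fragmented: int
    missing: int
    percent: dict[str, float] = field(default_factory=dict)

    def line(self) -> str:
        p = self.percent
        return (f"C:{p['complete']}%[S:{p['single']}%,D:{p['duplicated']}%],"
                f"F:{p['fragmented']}%,M:{p['missing']}%,n:{self.total}")


def busco_summary(records: list[BuscoRecord]) -> BuscoSummary:
    """Counts and percentages (one decimal, ties away from zero);
    Complete = Single + Duplicated."""
    if not records:
        raise DataError("no BUSCO records")
    single = sum(r.status == "Complete" for r in records)
    dup = sum(r.status == "Duplicated" for r in records)
    frag = sum(r.status == "Fragmented" for r in records)
    miss = sum(r.status == "Missing" for r in records)
    total = len(records)
    pct = {k: round_half_away(100.0 * v / total, 1) for k, v in (
        ("complete", single + dup), ("single", single), ("duplicated", dup),
        ("fragmented", frag), ("missing", miss))}
    return BuscoSummary(total=total, complete=single + dup, single=single,
                        duplicated=dup, fragmented=frag, missing=miss,
                        percent=pct)


def _restrict(records: list[BuscoRecord], selected: set[str]
              ) -> list[BuscoRecord]:
    """Recompute statuses relative to a contig subset."""
    out = []
    for r in records:
        hits = tuple(c for c in r.contigs if c in selected)
        if r.status in COMPLETE_STATUSES:
            if len(hits) >= 2:
                out.append(BuscoRecord(r.ortholog, "Duplicated", hits))
            elif len(hits) == 1:
                out.append(BuscoRecord(r.ortholog, "Complete", hits))
            else:
                out.append(BuscoRecord(r.ortholog, "Missing", ()))
        elif r.status == "Fragmented":
            out.append(BuscoRecord(r.ortholog, "Fragmented" if hits else "Missing",
                                   hits))
        else:
            out.append(r)
    return out


@dataclass
class PurgeResult:
    selected: list[str]
    before: BuscoSummary
    after: BuscoSummary
    selection_order: list[tuple[str, int]]   # (contig, newly covered orthologs)
    uncovered: list[str]                     # coverable orthologs left uncovered


def purge_select(records: list[BuscoRecord],
                 contig_lengths: dict[str, int],
                 exact_limit: int = 16) -> PurgeResult:
    """Choose a minimal contig set that keeps every coverable complete
    ortholog while shedding duplication.

    Greedy max-coverage: repeatedly add the contig completing the most
    not-yet-covered complete orthologs (ties: fewer added duplicate hits,
    then larger contig, then name), stopping when nothing new can be
    covered. When the instance is small (<= ``exact_limit`` candidate
    contigs) the greedy result is checked against exhaustive subset
    enumeration and replaced by a provably minimum cover if smaller.
    """
    if not records:
        raise DataError("no BUSCO records")
    unknown = sorted({c for r in records for c in r.contigs}
                     - set(contig_lengths))
    if unknown:
        raise DataError(f"BUSCO hits reference unknown contigs: {unknown[:5]}")
    cover: dict[str, set[str]] = {}
    for r in records:
        if r.status in COMPLETE_STATUSES:
            for c in r.contigs:
                cover.setdefault(c, set()).add(r.ortholog)
    coverable = set().union(*cover.values()) if cover else set()
    if not coverable:
        warnings.warn("no complete BUSCO hits; empty selection", stacklevel=2)
        return PurgeResult(selected=[], before=busco_summary(records),
                           after=busco_summary(_restrict(records, set())),
                           selection_order=[], uncovered=[])

    selected: list[str] = []
    order: list[tuple[str, int]] = []
    covered: set[str] = set()
    candidates = set(cover)
    while True:
        best = None
        for c in sorted(candidates):
            new = len(cover[c] - covered)
            if new == 0:
                continue
            dup_added = len(cover[c] & covered)
            key = (-new, dup_added, -contig_lengths[c], c)
            if best is None or key < best[0]:
                best = (key, c, new)
        if best is None:
            break
        _, c, new = best
        selected.append(c)
        order.append((c, new))
        covered |= cover[c]
        candidates.discard(c)

    if len(cover) <= exact_limit and len(selected) > 1:
        exact = _minimum_cover(cover, coverable, contig_lengths)
        if exact is not None and len(exact) < len(selected):
            selected = exact
            order = [(c, len(cover[c])) for c in exact]  # gains not re-derived

    sel = set(selected)
    return PurgeResult(selected=selected, before=busco_summary(records),
                       after=busco_summary(_restrict(records, sel)),
                       selection_order=order,
                       uncovered=sorted(coverable
                                        - set().union(*(cover[c] for c in sel))))


def _minimum_cover(cover: dict[str, set[str]], universe: set[str],
                   contig_lengths: dict[str, int]) -> list[str] | None:
    contigs = sorted(cover)
    for k in range(1, len(contigs) + 1):
        best = None
        for combo in combinations(contigs, k):
            got = set().union(*(cover[c] for c in combo))
            if got >= universe:
                key = (-sum(contig_lengths[c] for c in combo), combo)
                if best is None or key < best[0]:
                    best = (key, list(combo))
        if best is not None:
            return best[1]
    return None


# ---------------------------------------------------------------------------
# genome size
# ---------------------------------------------------------------------------

def genome_size_estimate(total_bases: float, peak_coverage: float,
                         ploidy: int = 4) -> tuple[float, float]:
    """Coverage-peak genome size: (full-complement, per-copy) estimates.

    full = total sequenced bases / coverage of the first (single-copy)
    k-mer peak; per-copy divides by the ploidy.
    """
    if peak_coverage <= 0:
        raise DomainError("peak coverage must be > 0")
    if ploidy < 1:
        raise DomainError("ploidy must be >= 1")
    full = float(total_bases) / float(peak_coverage)
    return full, full / ploidy
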
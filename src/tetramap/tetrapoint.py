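"""Two-point linkage estimation for autotetraploid dosage data.

Gamete probabilities are computed by exhaustive enumeration of the three
equiprobable bivalent pairings of the four homologues, the chromatid
choice within each bivalent, and a recombination event with probability
``r`` between the two loci. Offspring joint-dosage class probabilities
are the convolution of the maternal and paternal gamete distributions;
the recombination fraction is estimated by bounded maximum likelihood
and reported with a LOD score against independence (r = 0.5).

Estimation assumes bivalent-only polysomic inheritance. Double reduction
is handled by a separate frequency estimator, mirroring how it is
treated as an independent observation in mapping practice.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from ._util import MISSING, DataError, DomainError

__all__ = [
    "SegType", "PairPhase", "JointCountTable", "TwoPointResult",
    "classify_segregation", "joint_gamete_distribution", "estimate_two_point",
    "estimate_double_reduction", "preferential_pairing_check",
    "pairwise_linkage", "pairwise_loglik_profiles",
]

PAIRINGS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))
COUPLING, REPULSION = "coupling", "repulsion"


# ---------------------------------------------------------------------------
# segregation types and phases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegType:
    maternal_dosage: int
    paternal_dosage: int

    def __post_init__(self) -> None:
        for d in (self.maternal_dosage, self.paternal_dosage):
            if not (0 <= int(d) <= 4):
                raise DomainError(f"parental dosage {d} outside 0..4")

    @property
    def label(self) -> str:
        return f"{self.maternal_dosage}x{self.paternal_dosage}"

    @property
    def informative(self) -> bool:
        # neither parent segregates when both dosages are 0 or 4
        return (self.maternal_dosage not in (0, 4)
                or self.paternal_dosage not in (0, 4))


@dataclass(frozen=True)
class PairPhase:
    """Phase relation per parent: coupling, repulsion, or None when the
    parent carries no joint linkage information for the pair."""
    maternal: str | None
    paternal: str | None

    def __str__(self) -> str:
        short = {COUPLING: "C", REPULSION: "R", None: "-"}
        return f"{short[self.maternal]}x{short[self.paternal]}"

    @classmethod
    def from_str(cls, s: str) -> "PairPhase":
        back = {"C": COUPLING, "R": REPULSION, "-": None}
        m, p = s.split("x")
        return cls(back[m], back[p])


@dataclass
class JointCountTable:
    """Offspring counts over joint dosage classes (d1, d2) in 0..4 x 0..4."""
    counts: np.ndarray  # (5, 5) int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (5, 5) or (self.counts < 0).any():
            raise DataError("counts must be a non-negative (5, 5) table")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_dosages(cls, d1: np.ndarray, d2: np.ndarray) -> "JointCountTable":
        d1 = np.asarray(d1)
        d2 = np.asarray(d2)
        ok = (d1 != MISSING) & (d2 != MISSING)
        counts = np.zeros((5, 5), dtype=np.int64)
        np.add.at(counts, (d1[ok], d2[ok]), 1)
        return cls(counts)


@dataclass
class TwoPointResult:
    r: float
    lod: float
    phase: PairPhase
    n_used: int


def classify_segregation(maternal_dosage: int, paternal_dosage: int) -> SegType:
    """Canonical segregation-type label for a marker, e.g. (1, 0) -> "1x0"."""
    return SegType(int(maternal_dosage), int(paternal_dosage))


# ---------------------------------------------------------------------------
# exact gamete probability engine
# ---------------------------------------------------------------------------

def _phase_options(d1: int, d2: int) -> list[str | None]:
    if d1 in (0, 4) or d2 in (0, 4):
        return [None]
    return [COUPLING, REPULSION]


def _allele_config(d1: int, d2: int, phase: str | None) -> np.ndarray:
    """(4, 2) binary matrix: allele of each homologue at the two loci.

    Coupling places the second marker's carriers with maximal overlap on
    the first marker's carrier homologues, repulsion with minimal overlap.
    Homologue identity within a parent is exchangeable, so these two
    canonical configurations cover all distinguishable phases for
    dosages up to duplex; higher mixed-overlap configurations are not
    enumerated (see module docstring).
    """
    a = np.zeros((4, 2), dtype=np.int8)
    a[:d1, 0] = 1
    if phase in (None, COUPLING):
        a[:d2, 1] = 1
    elif phase == REPULSION:
        idx = [(d1 + i) % 4 for i in range(d2)]
        a[idx, 1] = 1
    else:  # pragma: no cover
        raise DomainError(f"unknown phase {phase!r}")
    return a


def _gamete_table(a: np.ndarray, r: np.ndarray) -> np.ndarray:
    """P(gamete carries (g1, g2) copies), shape (len(r), 3, 3).

    Enumerates 3 pairings x per-bivalent chromatid outcomes. Within a
    bivalent of homologues (h, k), the transmitted chromatid carries the
    locus-1 allele of X and the locus-2 allele of Y with
    P(Y = X) = 1 - r (no recombination) and P(Y != X) = r.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if ((r < 0) | (r > 0.5)).any():
        raise DomainError("r must be in [0, 0.5]")
    out = np.zeros((len(r), 3, 3))
    half_nr = (1.0 - r) / 2.0
    half_r = r / 2.0
    for pairing in PAIRINGS:
        biv_outcomes = []
        for (h, k) in pairing:
            biv_outcomes.append([
                ((a[h, 0], a[h, 1]), half_nr),
                ((a[h, 0], a[k, 1]), half_r),
                ((a[k, 0], a[h, 1]), half_r),
                ((a[k, 0], a[k, 1]), half_nr),
            ])
        for (al1, p1), (al2, p2) in product(*biv_outcomes):
            g1 = al1[0] + al2[0]
            g2 = al1[1] + al2[1]
            out[:, g1, g2] += p1 * p2 / 3.0
    return out


def joint_gamete_distribution(seg1_dosage: int, seg2_dosage: int,
                              phase: str | None, r) -> np.ndarray:
    """Two-locus gamete class probabilities for one parent.

    Returns a (3, 3) table over gamete allele counts (0..2 per locus)
    for scalar ``r``, or (len(r), 3, 3) for an array.
    """
    scalar = np.isscalar(r)
    if phase not in (None, COUPLING, REPULSION):
        raise DomainError(f"unknown phase {phase!r}")
    a = _allele_config(int(seg1_dosage), int(seg2_dosage), phase)
    table = _gamete_table(a, r)
    return table[0] if scalar else table


def _offspring_table(seg1: SegType, seg2: SegType, phase: PairPhase,
                     r: np.ndarray) -> np.ndarray:
    """(len(r), 5, 5) offspring joint-dosage probabilities."""
    gm = _gamete_table(_allele_config(seg1.maternal_dosage,
                                      seg2.maternal_dosage, phase.maternal), r)
    gp = _gamete_table(_allele_config(seg1.paternal_dosage,
                                      seg2.paternal_dosage, phase.paternal), r)
    out = np.zeros((len(np.atleast_1d(r)), 5, 5))
    for i in range(3):
        for j in range(3):
            out[:, i:i + 3, j:j + 3] += gm[:, i, j, None, None] * gp
    return out


def candidate_phases(seg1: SegType, seg2: SegType) -> list[PairPhase]:
    """Phase candidates, coupling-first so likelihood ties resolve to
    coupling."""
    m_opts = _phase_options(seg1.maternal_dosage, seg2.maternal_dosage)
    p_opts = _phase_options(seg1.paternal_dosage, seg2.paternal_dosage)
    return [PairPhase(m, p) for m in m_opts for p in p_opts]


# ---------------------------------------------------------------------------
# maximum-likelihood two-point estimation
# ---------------------------------------------------------------------------

_LOG_FLOOR = 1e-300


def estimate_two_point(table: JointCountTable, seg1: SegType, seg2: SegType,
                       error_floor: float = 0.0,
                       xatol: float = 1e-7) -> TwoPointResult:
    """MLE of the recombination fraction with phase selection.

    For each candidate phase the multinomial likelihood over offspring
    joint-dosage classes is maximized over r in [0, 0.5] by bounded 1-D
    optimization; the best phase (ties toward coupling) is returned with
    LOD = log10 L(r_hat) - log10 L(0.5).

    ``error_floor`` mixes the class probabilities with a uniform
    component, which keeps the likelihood finite when a few miscalled
    dosages land in classes that are impossible under the exact model.
    """
    n = table.n
    if n < 1:
        raise DataError("no offspring counts")
    phases = candidate_phases(seg1, seg2)
    if all(ph.maternal is None and ph.paternal is None for ph in phases):
        raise DataError(
            f"no informative parent for pair {seg1.label} / {seg2.label}")
    counts = table.counts.astype(float)

    if error_floor == 0.0:
        # classes observed but impossible under every candidate phase/r
        possible = np.zeros((5, 5), dtype=bool)
        for ph in phases:
            probs = _offspring_table(seg1, seg2, ph, np.array([0.25]))[0]
            possible |= probs > 0
        bad = (counts > 0) & ~possible
        if bad.any():
            classes = [tuple(map(int, ij)) for ij in np.argwhere(bad)]
            raise DataError(
                f"counts in impossible dosage classes for "
                f"{seg1.label}/{seg2.label}: {classes}")

    best = None
    for ph in phases:
        def negll(r: float, ph=ph) -> float:
            probs = _offspring_table(seg1, seg2, ph, np.array([r]))[0]
            if error_floor > 0:
                probs = (1 - error_floor) * probs + error_floor / 25.0
            return -float((counts * np.log(np.clip(probs, _LOG_FLOOR, None))).sum())

        res = minimize_scalar(negll, bounds=(0.0, 0.5), method="bounded",
                              options={"xatol": xatol})
        # the bounded optimizer never evaluates the exact boundary; snap to
        # it when the boundary is at least as good
        cands = [(negll(0.0), 0.0), (negll(0.5), 0.5), (res.fun, float(res.x))]
        fun, r_hat = min(cands, key=lambda t: t[0])
        ll_half = -negll(0.5)
        lod = max(0.0, (-fun - ll_half) / np.log(10.0))
        # strict improvement only, so likelihood ties keep the earlier
        # (coupling-first) phase
        if best is None or -fun > best[0] + 1e-12:
            best = (-fun, r_hat, lod, ph)
    _, r_hat, lod, ph = best
    return TwoPointResult(r=r_hat, lod=lod, phase=ph, n_used=n)


# ---------------------------------------------------------------------------
# double reduction
# ---------------------------------------------------------------------------

@dataclass
class DoubleReductionEstimate:
    alpha: float
    ci_low: float
    ci_high: float
    n: int
    n_dosage2: int


def estimate_double_reduction(offspring_dosages: np.ndarray, seg: SegType,
                              confidence: float = 0.95) -> DoubleReductionEstimate:
    """DR rate from a simplex x nulliplex (or 0x1) marker.

    Under bivalent inheritance such a marker yields offspring dosages in
    {0, 1}; a dosage-2 offspring requires a gamete with two copies of the
    simplex allele, which happens with probability alpha / 4 (the
    duplicated homologue is the carrier in 1 of 4 cases). Hence
    alpha_hat = 4 * freq(dosage 2), with a Clopper-Pearson interval on
    the dosage-2 frequency scaled by 4 and clipped to [0, 1].
    """
    if {seg.maternal_dosage, seg.paternal_dosage} != {0, 1}:
        raise DomainError(
            f"DR estimation needs a 1x0 or 0x1 marker, got {seg.label}")
    d = np.asarray(offspring_dosages)
    d = d[d != MISSING]
    n = len(d)
    if n == 0:
        raise DataError("no non-missing offspring dosages")
    k = int((d == 2).sum())
    p_hat = k / n
    lo = 0.0 if k == 0 else float(beta_dist.ppf((1 - confidence) / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1 - (1 - confidence) / 2, k + 1, n - k))
    clip = lambda x: float(min(1.0, max(0.0, 4.0 * x)))
    return DoubleReductionEstimate(alpha=clip(p_hat), ci_low=clip(lo),
                                   ci_high=clip(hi), n=n, n_dosage2=k)


# ---------------------------------------------------------------------------
# preferential pairing
# ---------------------------------------------------------------------------

@dataclass
class PreferentialPairingTest:
    chi2: float
    p_value: float
    n: int
    underpowered: bool


def preferential_pairing_check(pairing_counts) -> PreferentialPairingTest:
    """Goodness of fit of observed bivalent-pairing counts against the
    uniform 1/3 expectation (chi-square, 2 df)."""
    counts = np.asarray(pairing_counts, dtype=float)
    if counts.shape != (3,) or (counts < 0).any():
        raise DomainError("need counts over the 3 pairing configurations")
    n = counts.sum()
    if n == 0:
        raise DataError("no pairing observations")
    expected = np.full(3, n / 3.0)
    stat = float(((counts - expected) ** 2 / expected).sum())
    p = float(chi2.sf(stat, df=2))
    return PreferentialPairingTest(chi2=stat, p_value=p, n=int(n),
                                   underpowered=n < 30)


# ---------------------------------------------------------------------------
# vectorized pairwise estimation over a dosage matrix
# ---------------------------------------------------------------------------

def _grid_tables(seg1: SegType, seg2: SegType, r_grid: np.ndarray,
                 error_floor: float) -> list[tuple[PairPhase, np.ndarray]]:
    out = []
    for ph in candidate_phases(seg1, seg2):
        probs = _offspring_table(seg1, seg2, ph, r_grid)  # (G, 5, 5)
        if error_floor > 0:
            probs = (1 - error_floor) * probs + error_floor / 25.0
        out.append((ph, np.log(np.clip(probs.reshape(len(r_grid), 25),
                                       _LOG_FLOOR, None))))
    return out


def pairwise_linkage(matrix, markers=None, r_step: float = 0.005,
                     error_floor: float = 1e-3, min_lod: float = 0.0,
                     chunk: int = 128):
    """All-pairs recombination fraction and LOD over a dosage matrix.

    Grid-based maximum likelihood (step ``r_step``), vectorized across
    marker pairs that share a segregation-type configuration; the exact
    same likelihood as :func:`estimate_two_point`, evaluated on a grid.
    Returns a DataFrame with columns marker1, marker2, r, lod, phase, n.
    Pairs with no informative parent in common are omitted.
    """
    import pandas as pd

    if markers is None:
        idx = np.arange(matrix.n_markers)
    else:
        lookup = matrix.marker_index()
        idx = np.array([lookup[m] if isinstance(m, str) else int(m)
                        for m in markers])
    r_grid = np.arange(0.0, 0.5 + r_step / 2, r_step)
    i_half = len(r_grid) - 1

    # group marker rows by segregation type
    groups: dict[tuple[int, int], list[int]] = {}
    for i in idx:
        seg = (int(matrix.maternal[i]), int(matrix.paternal[i]))
        if SegType(*seg).informative:
            groups.setdefault(seg, []).append(i)

    data = matrix.data
    nonmiss = (data != MISSING)
    rows: list[tuple] = []
    names = matrix.markers
    keys = sorted(groups)
    for a_i, ka in enumerate(keys):
        for kb in keys[a_i:]:
            seg1, seg2 = SegType(*ka), SegType(*kb)
            phases = candidate_phases(seg1, seg2)
            if all(ph.maternal is None and ph.paternal is None for ph in phases):
                continue
            tables = _grid_tables(seg1, seg2, r_grid, error_floor)
            ia = np.array(groups[ka])
            ib = np.array(groups[kb])
            same = ka == kb
            x2_by_class = [((data[ib] == d2) & nonmiss[ib]).astype(np.float32)
                           for d2 in range(5)]
            for lo in range(0, len(ia), chunk):
                ia_c = ia[lo:lo + chunk]
                # joint class counts via indicator matmuls
                counts = np.zeros((len(ia_c), len(ib), 25), dtype=np.float32)
                for d1 in range(5):
                    x1 = ((data[ia_c] == d1) & nonmiss[ia_c]).astype(np.float32)
                    for d2 in range(5):
                        counts[:, :, d1 * 5 + d2] = x1 @ x2_by_class[d2].T
                n_pair = counts.sum(axis=2)
                flat = counts.reshape(-1, 25)
                best_ll = np.full(flat.shape[0], -np.inf, dtype=np.float64)
                best_r = np.zeros(flat.shape[0])
                best_ph = np.zeros(flat.shape[0], dtype=np.int32)
                ll_half = None
                for p_i, (ph, logp) in enumerate(tables):
                    ll = flat @ logp.T.astype(np.float32)  # (pairs, G)
                    if ll_half is None:
                        ll_half = ll[:, i_half].astype(np.float64)
                    g_best = np.argmax(ll, axis=1)
                    ll_best = ll[np.arange(len(ll)), g_best]
                    improve = ll_best > best_ll + 1e-9
                    best_ll[improve] = ll_best[improve]
                    best_r[improve] = r_grid[g_best[improve]]
                    best_ph[improve] = p_i
                lod = np.maximum(0.0, (best_ll - ll_half) / np.log(10.0))
                lod_mat = lod.reshape(len(ia_c), len(ib))
                r_mat = best_r.reshape(len(ia_c), len(ib))
                ph_mat = best_ph.reshape(len(ia_c), len(ib))
                keep = (n_pair > 0) & (lod_mat >= min_lod)
                if same:
                    keep &= ib[None, :] > ia_c[:, None]
                ii, jj = np.nonzero(keep)
                phase_strs = [str(ph) for ph, _ in tables]
                for a, b in zip(ii, jj):
                    rows.append((names[ia_c[a]], names[ib[b]],
                                 float(r_mat[a, b]), float(lod_mat[a, b]),
                                 phase_strs[ph_mat[a, b]],
                                 int(n_pair[a, b])))
    return pd.DataFrame(rows, columns=["marker1", "marker2", "r", "lod",
                                       "phase", "n"])


def pairwise_loglik_profiles(matrix, markers, r_step: float = 0.002,
                             error_floor: float = 1e-3):
    """Per-pair log-likelihood profiles over an r grid (best phase
    pointwise).

    Returns ``(r_grid, prof, has)`` where ``prof[i, j]`` is the profile
    for markers i and j of ``markers`` and ``has`` flags pairs with a
    shared informative parent. Used by marker ordering: the full profile
    lets weakly informative (e.g. repulsion-phase) pairs speak with
    their actual, nearly flat likelihood instead of a biased point
    estimate.
    """
    lookup = matrix.marker_index()
    rows = np.array([lookup[m] for m in markers])
    data = matrix.data
    nonmiss = data != MISSING
    n = len(markers)
    r_grid = np.arange(0.0, 0.5 + r_step / 2, r_step)
    G = len(r_grid)
    prof = np.zeros((n, n, G), dtype=np.float32)
    has = np.zeros((n, n), dtype=bool)
    groups: dict[tuple[int, int], list[int]] = {}
    for k, i in enumerate(rows):
        seg = (int(matrix.maternal[i]), int(matrix.paternal[i]))
        if SegType(*seg).informative:
            groups.setdefault(seg, []).append(k)
    keys = sorted(groups)
    for a_i, ka in enumerate(keys):
        for kb in keys[a_i:]:
            seg1, seg2 = SegType(*ka), SegType(*kb)
            phases = candidate_phases(seg1, seg2)
            if all(ph.maternal is None and ph.paternal is None for ph in phases):
                continue
            tables = _grid_tables(seg1, seg2, r_grid, error_floor)
            ia = np.array(groups[ka])
            ib = np.array(groups[kb])
            counts = np.zeros((len(ia), len(ib), 25), dtype=np.float32)
            for d1 in range(5):
                x1 = ((data[rows[ia]] == d1) & nonmiss[rows[ia]]).astype(np.float32)
                for d2 in range(5):
                    x2 = ((data[rows[ib]] == d2) & nonmiss[rows[ib]]).astype(np.float32)
                    counts[:, :, d1 * 5 + d2] = x1 @ x2.T
            flat = counts.reshape(-1, 25)
            best = None
            for _, logp in tables:
                ll = flat @ logp.T.astype(np.float32)
                best = ll if best is None else np.maximum(best, ll)
            best = best.reshape(len(ia), len(ib), G)
            ixa, ixb = np.meshgrid(ia, ib, indexing="ij")
            prof[ixa, ixb] = best
            prof[ixb, ixa] = best
            has[ixa, ixb] = True
            has[ixb, ixa] = True
    np.fill_diagonal(has, False)
    return r_grid, prof, has
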
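"""Synthetic autotetraploid F1 crosses with known meiotic ground truth.

Simulates two tetraploid parents (4 homologues each, 2n = 4x), gamete
formation under polysomic bivalent pairing with an optional simplified
quadrivalent branch, and F1 offspring dosage matrices with genotyping
error and missingness. Every stochastic event (pairing, crossovers,
double reduction) is recorded so downstream estimators can be validated
by truth recovery instead of against external data.

The quadrivalent branch is deliberately minimal: a random
pairing-partner exchange at the centromere plus an explicit
double-reduction draw per chromosome arm. With double-reduction rate
``alpha`` and quadrivalent rate ``q``, the probability that a gamete
carries two sister-derived copies at a given telomere is ``q * alpha``,
and the expected dosage-2 frequency at a telomeric simplex x nulliplex
marker is ``q * alpha / 4`` (the duplicated homologue is the carrier
with probability 1/4).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from ._util import MISSING, InvalidConfigError, check_rate
from .dosage import DosageMatrix

__all__ = [
    "SimConfig", "ParentGenome", "MeiosisRecord", "SimTruth", "ContigTruth",
    "simulate_parents", "simulate_gamete", "simulate_f1", "simulate_contigs",
]

# the three ways four homologues can split into two bivalents
PAIRINGS: tuple[tuple[tuple[int, int], tuple[int, int]], ...] = (
    ((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)),
)

DEFAULT_SEG_MIX = {"1x0": 0.35, "0x1": 0.35, "1x1": 0.20, "2x0": 0.10}


@dataclass
class SimConfig:
    n_chromosomes: int = 8
    chrom_length_bp: int = 50_000_000
    centromere_pos: float = 0.5          # fraction of chromosome length
    n_markers_per_chrom: int = 100
    n_offspring: int = 187
    co_rate: float = 2.0                 # mean crossovers per bivalent (>=1 realized)
    co_density: str = "uniform"          # uniform | pericentromeric | distal
    co_concentration: float = 6.0        # Beta shape for non-uniform densities
    quadrivalent_rate: float = 0.0       # q
    double_reduction_rate: float = 0.0   # alpha, per arm, given a quadrivalent
    dosage_error_rate: float = 0.0       # epsilon
    missing_rate: float = 0.0            # mu
    seg_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEG_MIX))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "n_markers_per_chrom", "n_offspring"):
            if int(getattr(self, name)) < 1:
                raise InvalidConfigError(f"{name} must be >= 1")
        if self.chrom_length_bp < 2:
            raise InvalidConfigError("chrom_length_bp must be >= 2")
        if not (0.0 < self.centromere_pos < 1.0):
            raise InvalidConfigError("centromere_pos must be in (0, 1)")
        if self.co_rate < 0:
            raise InvalidConfigError("co_rate must be >= 0")
        if self.co_density not in ("uniform", "pericentromeric", "distal"):
            raise InvalidConfigError(f"unknown co_density {self.co_density!r}")
        if self.co_concentration < 1.0:
            raise InvalidConfigError("co_concentration must be >= 1")
        check_rate("quadrivalent_rate", self.quadrivalent_rate)
        check_rate("double_reduction_rate", self.double_reduction_rate)
        check_rate("dosage_error_rate", self.dosage_error_rate)
        check_rate("missing_rate", self.missing_rate)
        total = sum(self.seg_mix.values())
        if not self.seg_mix or abs(total - 1.0) > 1e-9:
            raise InvalidConfigError("seg_mix probabilities must sum to 1")
        for label in self.seg_mix:
            _parse_seg_label(label)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _parse_seg_label(label: str) -> tuple[int, int]:
    try:
        m, p = label.split("x")
        m, p = int(m), int(p)
    except ValueError as exc:
        raise InvalidConfigError(f"bad segregation label {label!r}") from exc
    if not (0 <= m <= 4 and 0 <= p <= 4):
        raise InvalidConfigError(f"bad segregation label {label!r}")
    return m, p


@dataclass
class ParentGenome:
    """One parent: marker positions and a 0/1 allele per homologue."""
    positions: list[np.ndarray]   # per chromosome, strictly increasing bp
    alleles: list[np.ndarray]     # per chromosome, (n_markers, 4) int8

    def __post_init__(self) -> None:
        for pos, al in zip(self.positions, self.alleles):
            if (np.diff(pos) <= 0).any():
                raise InvalidConfigError("marker positions must strictly increase")
            if al.shape != (len(pos), 4) or ((al != 0) & (al != 1)).any():
                raise InvalidConfigError("allele matrix must be (n_markers, 4) binary")

    def dosages(self, chrom: int) -> np.ndarray:
        return self.alleles[chrom].sum(axis=1).astype(np.int8)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParentGenome):
            return NotImplemented
        return (all(np.array_equal(a, b) for a, b in zip(self.positions, other.positions))
                and len(self.positions) == len(other.positions)
                and all(np.array_equal(a, b) for a, b in zip(self.alleles, other.alleles)))


@dataclass
class MeiosisRecord:
    """Ground truth for one chromosome of one gamete."""
    quadrivalent: bool
    pairing: int                       # index into PAIRINGS
    crossovers: list[float]            # bp positions, all bivalents pooled
    dr_events: list[dict]              # {"arm", "exchange_bp", "source_chromatid"}
    sources: np.ndarray                # (2, n_markers) int8 homologue ids 0..3


@dataclass
class SimTruth:
    config: SimConfig
    mother: ParentGenome
    father: ParentGenome
    marker_chrom: np.ndarray           # per marker, chromosome index
    marker_pos: np.ndarray             # per marker, bp
    true_dosage: np.ndarray            # (n_markers, n_offspring) pre-error
    maternal_gamete: np.ndarray        # (n_markers, n_offspring) int8 0..2
    paternal_gamete: np.ndarray
    meioses: list[dict]                # per offspring: {"maternal": [...], "paternal": [...]}

    def to_jsonable(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "marker_chrom": self.marker_chrom.tolist(),
            "marker_pos": self.marker_pos.tolist(),
            "true_dosage": self.true_dosage.tolist(),
            "meioses": [
                {side: [
                    {"quadrivalent": rec.quadrivalent,
                     "pairing": rec.pairing,
                     "crossovers": list(map(float, rec.crossovers)),
                     "dr_events": rec.dr_events}
                    for rec in recs]
                 for side, recs in off.items()}
                for off in self.meioses],
        }


# ---------------------------------------------------------------------------
# parents
# ---------------------------------------------------------------------------

def simulate_parents(config: SimConfig,
                     rng: np.random.Generator | None = None,
                     ) -> tuple[ParentGenome, ParentGenome]:
    """Draw marker positions and assign parental alleles to homologues.

    Each marker gets a segregation type from ``config.seg_mix``; the
    carrier homologues are chosen uniformly at random within each parent,
    so coupling/repulsion phases arise naturally.
    """
    if config.n_markers_per_chrom < 1:
        raise InvalidConfigError("n_markers_per_chrom must be >= 1")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    labels = sorted(config.seg_mix)
    probs = np.array([config.seg_mix[k] for k in labels])
    m_pos, m_alleles, f_alleles = [], [], []
    for _ in range(config.n_chromosomes):
        n = config.n_markers_per_chrom
        pos = np.sort(rng.choice(config.chrom_length_bp - 1, size=n, replace=False)) + 1
        seg = rng.choice(len(labels), size=n, p=probs)
        am = np.zeros((n, 4), dtype=np.int8)
        af = np.zeros((n, 4), dtype=np.int8)
        for i, s in enumerate(seg):
            dm, dp = _parse_seg_label(labels[s])
            if dm:
                am[i, rng.choice(4, size=dm, replace=False)] = 1
            if dp:
                af[i, rng.choice(4, size=dp, replace=False)] = 1
        m_pos.append(pos.astype(np.int64))
        m_alleles.append(am)
        f_alleles.append(af)
    mother = ParentGenome(positions=m_pos, alleles=m_alleles)
    father = ParentGenome(positions=[p.copy() for p in m_pos], alleles=f_alleles)
    return mother, father


# ---------------------------------------------------------------------------
# gametes
# ---------------------------------------------------------------------------

def _co_positions(rng: np.random.Generator, n: int, length: int,
                  centromere_frac: float, density: str, conc: float) -> np.ndarray:
    """Crossover positions in bp with the configured density along the arm."""
    if n == 0:
        return np.empty(0)
    cent = centromere_frac * length
    left = rng.random(n) < centromere_frac  # arm chosen in proportion to its length
    if density == "uniform":
        frac = rng.random(n)                # distance from centromere / arm length
    elif density == "pericentromeric":
        frac = rng.beta(1.0, conc, size=n)
    else:                                   # distal
        frac = rng.beta(conc, 1.0, size=n)
    arm_len = np.where(left, cent, length - cent)
    return np.where(left, cent - frac * arm_len, cent + frac * arm_len)


def _walk(positions: np.ndarray, start: int, partner_of: dict[int, int],
          co_pos: np.ndarray, switches: np.ndarray, left: bool) -> np.ndarray:
    """Source homologue per marker for one chromatid arm walked from the
    centromere outward; at each crossover the chromatid switches to the
    current partner with probability 1/2 (pre-drawn in `switches`)."""
    src = np.empty(len(positions), dtype=np.int8)
    order = np.argsort(co_pos)
    if left:                               # walk towards coordinate 0
        order = order[::-1]
    cur = start
    bounds = co_pos[order]
    # segment boundaries from centromere outwards
    seg_sources = []
    seg_bounds = []
    for b, sw in zip(bounds, switches[order]):
        seg_bounds.append(b)
        seg_sources.append(cur)
        if sw:
            cur = partner_of[cur]
    seg_sources.append(cur)
    # assign markers
    if left:
        # segments: (bound0 .. centromere] source0, (bound1..bound0] source1, ...
        edges = np.array(seg_bounds, dtype=float)
        idx = np.searchsorted(-edges, -positions.astype(float), side="left")
    else:
        edges = np.array(seg_bounds, dtype=float)
        idx = np.searchsorted(edges, positions.astype(float), side="right")
    src[:] = np.array(seg_sources, dtype=np.int8)[idx]
    return src


def _draw_n_co(rng: np.random.Generator, lam: float) -> int:
    # one obligate crossover per bivalent, extras Poisson(max(lam-1, 0))
    return 1 + int(rng.poisson(max(lam - 1.0, 0.0)))


def _bivalent_chromatid(rng, positions, length, pair, config) -> tuple[np.ndarray, list[float]]:
    n_co = _draw_n_co(rng, config.co_rate)
    co = _co_positions(rng, n_co, length, config.centromere_pos,
                       config.co_density, config.co_concentration)
    switches = rng.random(n_co) < 0.5
    order = np.argsort(co)
    cur = pair[int(rng.integers(2))]
    partner = {pair[0]: pair[1], pair[1]: pair[0]}
    seg_sources = []
    for sw in switches[order]:
        seg_sources.append(cur)
        if sw:
            cur = partner[cur]
    seg_sources.append(cur)
    idx = np.searchsorted(np.sort(co), positions.astype(float), side="right")
    src = np.array(seg_sources, dtype=np.int8)[idx]
    return src, [float(x) for x in co]


def _quadrivalent_sources(rng, positions, length, pairing, config
                          ) -> tuple[np.ndarray, list[float], list[dict]]:
    """Two chromatids under the simplified quadrivalent model.

    Proximal of the centromere each chromatid recombines within its
    original bivalent pair; distal of the centromere the two leftover
    homologues are re-dealt as new partners (the pairing-partner
    exchange). Chromatid partner sets stay disjoint, so dosage 2 at a
    simplex marker can only arise through an explicit DR event.
    """
    (p0, p1) = PAIRINGS[pairing]
    cent = config.centromere_pos * length
    cur = [p0[int(rng.integers(2))], p1[int(rng.integers(2))]]
    others = [h for h in range(4) if h not in cur]
    if rng.random() < 0.5:
        others = others[::-1]
    # proximal partners: original bivalent mate; distal partners: re-dealt
    proximal_partner = [
        {p0[0]: p0[1], p0[1]: p0[0]}, {p1[0]: p1[1], p1[1]: p1[0]}]
    all_co: list[float] = []
    sources = np.empty((2, len(positions)), dtype=np.int8)
    for c in range(2):
        n_co = _draw_n_co(rng, config.co_rate)
        co = _co_positions(rng, n_co, length, config.centromere_pos,
                           config.co_density, config.co_concentration)
        switches = rng.random(n_co) < 0.5
        all_co.extend(float(x) for x in co)
        distal_partner = {cur[c]: others[c], others[c]: cur[c]}
        is_left = co < cent
        src = np.empty(len(positions), dtype=np.int8)
        # right arm walk
        right_mask = positions >= cent
        rco = co[~is_left]
        rsw = switches[~is_left]
        # right of the centromere the chromatid recombines with its
        # re-dealt (exchanged) partner
        src[right_mask] = _walk(positions[right_mask], cur[c],
                                distal_partner, rco, rsw, left=False)
        # left arm walk (proximal pairing holds on the left side)
        left_mask = ~right_mask
        lco = co[is_left]
        lsw = switches[is_left]
        src[left_mask] = _walk(positions[left_mask], cur[c],
                               proximal_partner[c], lco, lsw, left=True)
        sources[c] = src
    # double reduction: per arm, duplicate one chromatid's distal segment
    dr_events: list[dict] = []
    for arm in ("left", "right"):
        if rng.random() >= config.double_reduction_rate:
            continue
        source_c = int(rng.integers(2))
        if arm == "left":
            exch = float(rng.random() * cent)
            mask = positions < exch
        else:
            exch = float(cent + rng.random() * (length - cent))
            mask = positions > exch
        sources[1 - source_c, mask] = sources[source_c, mask]
        dr_events.append({"arm": arm, "exchange_bp": exch,
                          "source_chromatid": source_c})
    return sources, all_co, dr_events


def simulate_gamete(parent: ParentGenome, config: SimConfig,
                    rng: np.random.Generator,
                    ) -> tuple[list[np.ndarray], list[MeiosisRecord]]:
    """One gamete: per-chromosome allele counts (0..2) plus truth records."""
    dosages: list[np.ndarray] = []
    records: list[MeiosisRecord] = []
    for c, (positions, alleles) in enumerate(zip(parent.positions, parent.alleles)):
        length = config.chrom_length_bp
        pairing = int(rng.integers(3))
        quad = rng.random() < config.quadrivalent_rate
        if quad:
            sources, co, dr = _quadrivalent_sources(
                rng, positions, length, pairing, config)
        else:
            s0, co0 = _bivalent_chromatid(rng, positions, length,
                                          PAIRINGS[pairing][0], config)
            s1, co1 = _bivalent_chromatid(rng, positions, length,
                                          PAIRINGS[pairing][1], config)
            sources = np.stack([s0, s1])
            co, dr = co0 + co1, []
        dose = (alleles[np.arange(len(positions)), sources[0]]
                + alleles[np.arange(len(positions)), sources[1]]).astype(np.int8)
        dosages.append(dose)
        records.append(MeiosisRecord(quadrivalent=quad, pairing=pairing,
                                     crossovers=co, dr_events=dr, sources=sources))
    return dosages, records


# ---------------------------------------------------------------------------
# F1
# ---------------------------------------------------------------------------

def simulate_f1(mother: ParentGenome, father: ParentGenome, config: SimConfig,
                rng: np.random.Generator | None = None,
                population_id: str = "pop",
                ) -> tuple[DosageMatrix, SimTruth]:
    """Full F1 population: gametes, dosage = maternal + paternal allele
    count, then +/-1 miscalls at rate epsilon (clipped to 0..4) and
    missingness at rate mu. Truth is retained pre-error."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_chrom = len(mother.positions)
    marker_names: list[str] = []
    marker_chrom: list[int] = []
    marker_pos: list[int] = []
    for c in range(n_chrom):
        for i, p in enumerate(mother.positions[c]):
            marker_names.append(f"C{c + 1:02d}M{i + 1:04d}")
            marker_chrom.append(c)
            marker_pos.append(int(p))
    n_markers = len(marker_names)
    n_off = config.n_offspring
    gm = np.zeros((n_markers, n_off), dtype=np.int8)
    gp = np.zeros((n_markers, n_off), dtype=np.int8)
    meioses: list[dict] = []
    offsets = np.cumsum([0] + [len(p) for p in mother.positions])
    for j in range(n_off):
        dm, rm = simulate_gamete(mother, config, rng)
        dp, rp = simulate_gamete(father, config, rng)
        for c in range(n_chrom):
            gm[offsets[c]:offsets[c + 1], j] = dm[c]
            gp[offsets[c]:offsets[c + 1], j] = dp[c]
        meioses.append({"maternal": rm, "paternal": rp})
    true_dosage = (gm + gp).astype(np.int8)

    observed = true_dosage.copy()
    if config.dosage_error_rate > 0:
        err = rng.random(observed.shape) < config.dosage_error_rate
        sign = np.where(rng.random(observed.shape) < 0.5, -1, 1).astype(np.int8)
        observed = np.clip(observed + err * sign, 0, 4).astype(np.int8)
    if config.missing_rate > 0:
        observed = np.where(rng.random(observed.shape) < config.missing_rate,
                            np.int8(MISSING), observed)

    maternal_dosage = np.concatenate(
        [mother.dosages(c) for c in range(n_chrom)])
    paternal_dosage = np.concatenate(
        [father.dosages(c) for c in range(n_chrom)])
    matrix = DosageMatrix(
        markers=marker_names,
        individuals=[f"{population_id}_{j + 1:04d}" for j in range(n_off)],
        maternal=maternal_dosage, paternal=paternal_dosage, data=observed,
        marker_chrom=np.asarray(marker_chrom),
        marker_pos=np.asarray(marker_pos, dtype=np.int64))
    truth = SimTruth(config=config, mother=mother, father=father,
                     marker_chrom=np.asarray(marker_chrom),
                     marker_pos=np.asarray(marker_pos, dtype=np.int64),
                     true_dosage=true_dosage, maternal_gamete=gm,
                     paternal_gamete=gp, meioses=meioses)
    return matrix, truth


# ---------------------------------------------------------------------------
# synthetic contigs for the anchoring stage
# ---------------------------------------------------------------------------

@dataclass
class ContigTruth:
    sequences: dict[str, str]          # contig id -> sequence (assembly orientation)
    placements: "object"               # pandas.DataFrame: contig, chrom, order, orientation
    alignments: "object"               # pandas.DataFrame marker alignment table
    contig_lengths: dict[str, int]


def simulate_contigs(truth: SimTruth, rng: np.random.Generator | None = None,
                     n_contigs_per_chrom: int = 8,
                     bp_per_marker_bp: float = 1e-3,
                     flip_fraction: float = 0.5) -> ContigTruth:
    """Cut each simulated chromosome into contigs and emit the marker ->
    contig alignment table plus the true placement (order/orientation).

    Sequences are random DNA whose lengths are the chromosome spans scaled
    by ``bp_per_marker_bp`` (keeps FASTA output small); marker coordinates
    are scaled consistently. A random subset of contigs is stored
    reverse-complemented so orientation recovery is non-trivial.
    """
    import pandas as pd

    rng = np.random.default_rng(truth.config.seed + 17) if rng is None else rng
    scale = bp_per_marker_bp
    seq_rows, place_rows, align_rows = [], [], []
    sequences: dict[str, str] = {}
    lengths: dict[str, int] = {}
    bases = np.frombuffer(b"ACGT", dtype="S1").astype(str)
    for c in range(truth.config.n_chromosomes):
        sel = truth.marker_chrom == c
        pos = truth.marker_pos[sel]
        names = [m for m, keep in zip(_marker_names(truth), sel) if keep]
        L = int(truth.config.chrom_length_bp * scale) + 1
        cuts = np.sort(rng.choice(np.arange(1, L), size=n_contigs_per_chrom - 1,
                                  replace=False))
        bounds = np.concatenate([[0], cuts, [L]])
        mpos = (pos * scale).astype(np.int64)
        for k in range(n_contigs_per_chrom):
            cid = f"ctg{c + 1:02d}_{k + 1:02d}"
            clen = int(bounds[k + 1] - bounds[k])
            if clen < 10:
                clen = 10
            seq = "".join(rng.choice(bases, size=clen))
            flipped = bool(rng.random() < flip_fraction)
            sequences[cid] = _revcomp(seq) if flipped else seq
            lengths[cid] = clen
            place_rows.append({"contig": cid, "chrom": f"chr{c + 1}",
                               "order": k, "orientation": "-" if flipped else "+"})
            inside = (mpos >= bounds[k]) & (mpos < bounds[k + 1])
            for m_name, m_bp in zip(np.array(names)[inside], mpos[inside]):
                off = int(m_bp - bounds[k]) + 1          # 1-based within contig
                if flipped:
                    start = clen - off + 1
                    strand = "-"
                else:
                    start = off
                    strand = "+"
                align_rows.append({"marker": m_name, "contig": cid,
                                   "start": start, "end": start,
                                   "strand": strand, "coverage": 1.0,
                                   "identity": 1.0, "n_hits": 1})
    placements = pd.DataFrame(place_rows)
    alignments = pd.DataFrame(align_rows)
    return ContigTruth(sequences=sequences, placements=placements,
                       alignments=alignments, contig_lengths=lengths)


def _marker_names(truth: SimTruth) -> list[str]:
    names = []
    counters: dict[int, int] = {}
    for c in truth.marker_chrom:
        counters[c] = counters.get(c, 0) + 1
        names.append(f"C{c + 1:02d}M{counters[c]:04d}")
    return names


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]
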
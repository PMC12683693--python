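"""End-to-end pipeline: simulate -> two-point -> map -> consensus ->
anchor -> Marey, with every stage's artifacts written to disk."""
from __future__ import annotations

import dataclasses
import inspect
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._util import InvalidConfigError
from . import anchor as anchor_mod
from . import asmstats, io, mapbuild, mapmerge, simdata, tetrapoint

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("tetramap")

_ANCHOR_KEYS = {"gap_length", "min_coverage", "min_identity", "require_unique",
                "max_hits", "max_probes_per_contig", "n_contigs_per_chrom"}
_STAGES = ("simulate", "twopoint", "buildmap", "mergemap", "contigs",
           "anchor", "marey", "stats")


@dataclass
class PipelineConfig:
    outdir: str = "tetramap_out"
    seed: int = 1
    log_level: str = "INFO"
    expected_groups: int = 8
    sim: dict = field(default_factory=dict)          # shared SimConfig overrides
    populations: list = field(default_factory=lambda: [
        {"n_offspring": 187}, {"n_offspring": 248}])
    mapping: dict = field(default_factory=dict)      # build_map overrides
    anchor: dict = field(default_factory=dict)
    stages: list = field(default_factory=lambda: list(_STAGES))

    def __post_init__(self) -> None:
        sim_fields = {f.name for f in dataclasses.fields(simdata.SimConfig)}
        for key in self.sim:
            if key not in sim_fields:
                raise InvalidConfigError(f"unknown sim key {key!r}")
        for pop in self.populations:
            for key in pop:
                if key not in sim_fields:
                    raise InvalidConfigError(f"unknown population key {key!r}")
        if not 1 <= len(self.populations) <= 2:
            raise InvalidConfigError("pipeline supports 1 or 2 populations")
        map_params = set(inspect.signature(mapbuild.build_map).parameters) - {
            "matrix"}
        for key in self.mapping:
            if key not in map_params:
                raise InvalidConfigError(f"unknown mapping key {key!r}")
        for key in self.anchor:
            if key not in _ANCHOR_KEYS:
                raise InvalidConfigError(f"unknown anchor key {key!r}")
        for s in self.stages:
            if s not in _STAGES:
                raise InvalidConfigError(f"unknown stage {s!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(io.read_yaml(path))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; deterministic under the
    configured seed. Returns a run report (also written as JSON)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}
    seeds = np.random.SeedSequence(config.seed).spawn(8)
    stage_rngs = {s: np.random.default_rng(ss)
                  for s, ss in zip(_STAGES, seeds)}
    want = set(config.stages)

    matrices: dict[str, object] = {}
    truths: dict[str, object] = {}
    maps: dict[str, mapbuild.GeneticMap] = {}
    diags: dict[str, dict] = {}
    consensus = None
    contigs = None
    placements = None
    agp = None
    pseudo = None
    try:
        if "simulate" in want:
            base = dict(config.sim)
            cfg0 = simdata.SimConfig(**{**base, "seed": config.seed})
            parents = simdata.simulate_parents(cfg0, stage_rngs["simulate"])
            for k, overrides in enumerate(config.populations):
                pop = f"pop{k + 1}"
                cfg = simdata.SimConfig(**{**base, **overrides,
                                           "seed": config.seed + k})
                mat, truth = simdata.simulate_f1(
                    parents[0], parents[1], cfg, stage_rngs["simulate"],
                    population_id=pop)
                matrices[pop] = mat
                truths[pop] = truth
                io.write_dosage_matrix(mat, out / f"dosage_{pop}.tsv")
                io.write_json(truth.to_jsonable(), out / f"truth_{pop}.json")
            report["stages"]["simulate"] = {
                "populations": {p: m.n_individuals for p, m in matrices.items()},
                "markers": next(iter(matrices.values())).n_markers}
            log.info("simulated %d populations", len(matrices))

        if "buildmap" in want:
            for pop, mat in matrices.items():
                gmap, diag = mapbuild.build_map(
                    mat, expected_groups=config.expected_groups,
                    **config.mapping)
                maps[pop] = gmap
                diags[pop] = diag
                io.write_genetic_map(gmap, out / f"map_{pop}.tsv")
                io.write_pairwise(diag["pairwise"], out / f"pairwise_{pop}.tsv")
                report["stages"].setdefault("buildmap", {})[pop] = {
                    "markers": gmap.total_markers(),
                    "filter": diag["filter"].ledger}
            log.info("built %d maps", len(maps))

        if "mergemap" in want and len(maps) == 2:
            pops = list(maps)
            sets = {p: mapmerge.PairwiseLinkageSet(p, diags[p]["pairwise"])
                    for p in pops}
            merged = mapmerge.merge_pairwise(sets[pops[0]], sets[pops[1]])
            # align group labels between populations by shared markers
            relabeled = _relabel_groups(maps[pops[0]], maps[pops[1]])
            integration = mapmerge.integrate_maps(
                merged, {pops[0]: maps[pops[0]], pops[1]: relabeled},
                matrices={p: matrices[p] for p in pops})
            consensus = integration.consensus
            io.write_genetic_map(consensus, out / "map_consensus.tsv")
            consensus.summary().to_csv(out / "map_summary.tsv", sep="\t",
                                       index=False, lineterminator="\n")
            report["stages"]["mergemap"] = {
                "markers": consensus.total_markers(),
                "sources": {str(k): v for k, v in integration.sources.items()}}
        elif maps:
            consensus = next(iter(maps.values()))

        if "contigs" in want and truths:
            truth = next(iter(truths.values()))
            contigs = simdata.simulate_contigs(
                truth, stage_rngs["contigs"],
                n_contigs_per_chrom=config.anchor.get("n_contigs_per_chrom", 8))
            io.write_fasta(contigs.sequences, out / "contigs.fasta")
            io.write_alignments(contigs.alignments, out / "alignments.tsv")
            report["stages"]["contigs"] = {"n_contigs": len(contigs.sequences)}

        if "anchor" in want and contigs is not None and consensus is not None:
            fkw = {k: v for k, v in config.anchor.items()
                   if k in {"min_coverage", "min_identity", "require_unique",
                            "max_hits", "max_probes_per_contig"}}
            filt = anchor_mod.filter_alignments(contigs.alignments, **fkw)
            placed = anchor_mod.place_contigs(filt.retained, consensus,
                                              contigs.contig_lengths)
            placements = placed.placements
            pseudo, agp = anchor_mod.build_pseudomolecules(
                placements, contigs.sequences,
                gap_length=config.anchor.get("gap_length", 100))
            io.write_fasta(pseudo, out / "pseudomolecules.fasta")
            io.write_agp(agp, out / "pseudomolecules.agp")
            placements.to_csv(out / "placements.tsv", sep="\t", index=False,
                              lineterminator="\n")
            report["stages"]["anchor"] = {
                "filter": filt.ledger,
                "placed": int(len(placements)),
                "unplaced": len(placed.unplaced),
                "conflicts": int(len(placed.conflicts))}

        if "marey" in want and agp is not None and consensus is not None:
            phys = anchor_mod.marker_physical_positions(
                agp, contigs.alignments)
            marey = phys.merge(consensus.entries, on="marker")
            marey = marey.rename(columns={"position_cM": "cM"})
            marey["chrom_lg"] = "chr" + marey["linkage_group"].astype(str)
            marey = marey[marey["chrom"] == marey["chrom_lg"]]
            stats = anchor_mod.marey_stats(marey[["chrom", "bp", "cM"]])
            stats.per_chromosome.to_csv(out / "landscape.tsv", sep="\t",
                                        index=False, lineterminator="\n")
            report["stages"]["marey"] = stats.per_chromosome.to_dict("records")

        if "stats" in want and pseudo is not None:
            rep = asmstats.assembly_stats(pseudo)
            io.write_json(dataclasses.asdict(rep), out / "assembly_stats.json")
            report["stages"]["stats"] = dataclasses.asdict(rep)
    except Exception as exc:
        report["failed_stage"] = _current_stage(report)
        io.write_json(report, out / "run_report.json")
        raise
    io.write_json(report, out / "run_report.json")
    return report


def _current_stage(report: dict) -> str:
    done = list(report["stages"])
    remaining = [s for s in _STAGES if s not in done]
    return remaining[0] if remaining else "unknown"


def _relabel_groups(ref: mapbuild.GeneticMap,
                    other: mapbuild.GeneticMap) -> mapbuild.GeneticMap:
    """Rename the second map's linkage groups to the first map's labels
    by maximum shared-marker overlap."""
    from scipy.optimize import linear_sum_assignment

    ref_groups = sorted(ref.entries["linkage_group"].unique())
    other_groups = sorted(other.entries["linkage_group"].unique())
    overlap = np.zeros((len(other_groups), len(ref_groups)))
    ref_of = dict(zip(ref.entries["marker"], ref.entries["linkage_group"]))
    for i, g in enumerate(other_groups):
        for mk in other.group(g)["marker"]:
            if mk in ref_of:
                overlap[i, ref_groups.index(ref_of[mk])] += 1
    rows, cols = linear_sum_assignment(-overlap)
    mapping = {other_groups[r]: ref_groups[c] for r, c in zip(rows, cols)}
    entries = other.entries.copy()
    entries["linkage_group"] = [mapping.get(g, g)
                                for g in entries["linkage_group"]]
    return mapbuild.GeneticMap(entries)
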
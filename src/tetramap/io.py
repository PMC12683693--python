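"""Readers and writers for the package's text formats.

TSV throughout (UTF-8, Unix newlines, "NA" as the sole missing token),
FASTA for sequences, AGP v2.1 for pseudomolecule layouts, JSON for truth
and reports, YAML for configuration.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import MISSING, DataError
from .dosage import DosageMatrix
from .mapbuild import GeneticMap
from .asmstats import BuscoRecord

__all__ = [
    "read_dosage_matrix", "write_dosage_matrix",
    "read_genetic_map", "write_genetic_map",
    "read_pairwise", "write_pairwise",
    "read_alignments", "write_alignments",
    "read_fasta", "write_fasta", "read_agp", "write_agp",
    "read_busco_full_table", "write_json",
]

NA = "NA"


# ---------------------------------------------------------------------------
# dosage matrices
# ---------------------------------------------------------------------------

def write_dosage_matrix(matrix: DosageMatrix, path) -> None:
    df = matrix.to_frame()
    df = df.where(df.notna(), NA)
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_dosage_matrix(path) -> DosageMatrix:
    """TSV with a marker index column, 'maternal'/'paternal' dosage
    columns, then one column per individual; "NA" marks missing calls."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False)
    if "maternal" not in df.columns or "paternal" not in df.columns:
        raise DataError(f"{path}: missing maternal/paternal columns")
    if df.index.duplicated().any():
        dup = sorted(df.index[df.index.duplicated()])
        raise DataError(f"{path}: duplicate marker ids {dup[:5]}")
    body = df.drop(columns=["maternal", "paternal"])
    data = np.full(body.shape, MISSING, dtype=np.int8)
    for j, col in enumerate(body.columns):
        raw = body[col].to_numpy()
        for i, v in enumerate(raw):
            if v == NA or v == "":
                continue
            try:
                iv = int(v)
            except ValueError as exc:
                raise DataError(
                    f"{path}: non-integer dosage {v!r} at marker "
                    f"{df.index[i]!r}, column {col!r}") from exc
            if not 0 <= iv <= 4:
                raise DataError(
                    f"{path}: dosage {iv} out of 0..4 at marker "
                    f"{df.index[i]!r}, column {col!r}")
            data[i, j] = iv

    def parental(col: str) -> np.ndarray:
        vals = []
        for i, v in enumerate(df[col]):
            try:
                iv = int(v)
            except ValueError as exc:
                raise DataError(f"{path}: bad {col} dosage {v!r} at marker "
                                f"{df.index[i]!r}") from exc
            vals.append(iv)
        return np.asarray(vals, dtype=np.int8)

    return DosageMatrix(markers=list(df.index.astype(str)),
                        individuals=list(body.columns.astype(str)),
                        maternal=parental("maternal"),
                        paternal=parental("paternal"), data=data)


# ---------------------------------------------------------------------------
# genetic maps / pairwise tables / alignments
# ---------------------------------------------------------------------------

MAP_COLUMNS = ("marker", "linkage_group", "position_cM",
               "homologue_maternal", "homologue_paternal",
               "bin_representative")


def write_genetic_map(gmap: GeneticMap, path) -> None:
    df = gmap.entries.copy()
    for col in MAP_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df = df[list(MAP_COLUMNS)]
    df.where(df.notna(), NA).to_csv(path, sep="\t", index=False,
                                    lineterminator="\n")


def read_genetic_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    df["position_cM"] = df["position_cM"].astype(float)
    return GeneticMap(df)


def write_pairwise(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_pairwise(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    for col in ("marker1", "marker2", "r", "lod"):
        if col not in df.columns:
            raise DataError(f"{path}: missing pairwise column {col!r}")
    return df


def write_alignments(alignments: pd.DataFrame, path) -> None:
    alignments.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_alignments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    from .anchor import ALIGNMENT_COLUMNS
    for col in ALIGNMENT_COLUMNS:
        if col not in df.columns:
            raise DataError(f"{path}: missing alignment column {col!r}")
    return df


# ---------------------------------------------------------------------------
# FASTA / AGP
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


AGP_COLUMNS = ("object", "object_beg", "object_end", "part_number",
               "component_type", "component_id", "component_beg",
               "component_end", "orientation")


def write_agp(agp: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        agp.to_csv(fh, sep="\t", index=False, header=False,
                   lineterminator="\n")


def read_agp(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=list(AGP_COLUMNS), keep_default_na=False)
    for col in ("object_beg", "object_end", "part_number"):
        df[col] = df[col].astype(int)
    return df


# ---------------------------------------------------------------------------
# BUSCO full table
# ---------------------------------------------------------------------------

def read_busco_full_table(path) -> list[BuscoRecord]:
    """Parse a BUSCO full_table TSV into per-ortholog records.

    Expected columns: busco id, status, sequence, ... (one row per hit;
    Missing rows carry no sequence). Hits of one ortholog are pooled.
    """
    hits: dict[str, list[str]] = {}
    status: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise DataError(f"{path}: malformed line {line!r}")
            ortholog, stat = parts[0], parts[1]
            status[ortholog] = stat
            if stat != "Missing" and len(parts) >= 3 and parts[2]:
                # strip any :start-end suffix from the sequence field
                contig = parts[2].split(":")[0]
                hits.setdefault(ortholog, []).append(contig)
    records = []
    for ortholog in sorted(status):
        records.append(BuscoRecord(ortholog=ortholog, status=status[ortholog],
                                   contigs=tuple(hits.get(ortholog, ()))))
    return records


# ---------------------------------------------------------------------------
# JSON / YAML helpers
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(data, path) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, default=_jsonable)
        fh.write("\n")


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_yaml(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
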
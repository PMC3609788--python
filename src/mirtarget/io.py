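"""Readers and writers for the pipeline's plain-text formats.

TSV matrices (counts, expression, screen panels with a ``#role`` header
line), FASTA 3'UTRs (via Biopython, tolerant of line wrapping), GMT gene-set
collections, RNK ranked lists, JSON sidecars (totals, ground truth,
reports) and YAML configuration. All writers use fixed number formatting
and sorted keys so that identical inputs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .screening import ScreenMatrix

FLOAT_FMT = "%.6g"


def write_fasta(utrs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=gid, description="") for gid, seq in utrs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_table(path: str | Path, index_col: int | str | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, comment=None)


def write_screen_matrix(sm: ScreenMatrix, path: str | Path) -> None:
    path = Path(path)
    cols = list(sm.values.columns)
    with open(path, "w") as fh:
        fh.write("#role\t" + "\t".join(sm.roles[c] for c in cols) + "\n")
    sm.values.to_csv(path, sep="\t", mode="a", float_format=FLOAT_FMT)


def read_screen_matrix(path: str | Path) -> ScreenMatrix:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#role\t"):
            raise ValueError(f"{path}: expected a '#role' header line")
        roles_row = first.split("\t")[1:]
        values = pd.read_csv(fh, sep="\t", index_col=0).astype(float)
    if len(roles_row) != len(values.columns):
        raise ValueError(f"{path}: role line does not match the sample columns")
    roles = dict(zip(values.columns, roles_row))
    return ScreenMatrix(values=values, roles=roles)


def write_gmt(gene_sets: Mapping[str, set[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            members = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(p for p in parts[2:] if p)
    return sets


def write_rnk(ranked, path: str | Path) -> None:
    pd.DataFrame({"gene_id": ranked.gene_ids, "metric": ranked.metric}).to_csv(
        path, sep="\t", index=False, header=False, float_format=FLOAT_FMT)


def read_rnk(path: str | Path):
    from .gsea import RankedGeneList

    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "metric"])
    return RankedGeneList.from_scores(df["gene_id"].astype(str), df["metric"])


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
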
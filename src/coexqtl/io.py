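"""Readers and writers for the plain-text formats used across the pipeline.

Expression, phenotype, dosage and annotation tables are tab-delimited;
gene sets use the GMT convention (set name, description, member genes);
genotype probabilities use the Oxford GEN layout (five leading columns,
then three probabilities per sample).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a transcripts x samples expression TSV (first column = transcript id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="transcript_id")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index_label="sample_id")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered mapping set name -> member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (needs >= 3 fields): {line[:80]!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Genotypes

def read_dosages(path: str | Path) -> pd.DataFrame:
    """Read a variants x samples dosage TSV; missing encoded as NA."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_dosages(dosages: pd.DataFrame, path: str | Path) -> None:
    dosages.to_csv(path, sep="\t", index_label="variant_id")


def read_variant_map(path: str | Path) -> pd.DataFrame:
    vm = pd.read_csv(path, sep="\t")
    required = {"variant_id", "chrom", "pos"}
    missing = required - set(vm.columns)
    if missing:
        raise ValueError(f"variant map missing columns: {sorted(missing)}")
    return vm


def write_variant_map(vm: pd.DataFrame, path: str | Path) -> None:
    vm.to_csv(path, sep="\t", index=False)


def read_gen(path: str | Path, sample_ids: Sequence[str] | None = None
             ) -> tuple[pd.DataFrame, np.ndarray]:
    """Read an Oxford GEN-style probability file.

    Each row: chrom variant_id pos ref alt p0_1 p1_1 p2_1 p0_2 ...
    Returns (variant map, probabilities array of shape (n_variants, n_samples, 3)).
    """
    rows = []
    probs = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            chrom, vid, pos, ref, alt = fields[:5]
            trip = np.asarray(fields[5:], dtype=float)
            if trip.size % 3 != 0:
                raise ValueError(f"GEN row for {vid} has {trip.size} probability fields")
            rows.append((vid, chrom, int(pos), ref, alt))
            probs.append(trip.reshape(-1, 3))
    vm = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "ref", "alt"])
    arr = np.stack(probs) if probs else np.empty((0, 0, 3))
    if sample_ids is not None and arr.size and arr.shape[1] != len(sample_ids):
        raise ValueError("sample id list does not match GEN column count")
    return vm, arr


def write_gen(vm: pd.DataFrame, probs: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, row in enumerate(vm.itertuples(index=False)):
            flat = " ".join(f"{p:.4f}" for p in probs[i].ravel())
            fh.write(f"{row.chrom} {row.variant_id} {row.pos} {row.ref} {row.alt} {flat}\n")


# ---------------------------------------------------------------------------
# Run metadata

def write_metadata(meta: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_metadata(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
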
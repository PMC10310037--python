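"""File-format helpers: well tables (CSV), expression (TSV), gene sets
(GMT), rankings (two-column TSV), multi-page TIFF well images with JSON
ground-truth sidecars, and YAML parameter files."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .expression import ExpressionStudy

CHANNEL_NAMES = ("spheroid", "muc5ac", "muc5b", "nuclear")


def write_well_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_well_table(path) -> pd.DataFrame:
    return pd.read_csv(
        path, dtype={"plate": str, "well": str, "compound": str}, keep_default_na=False,
        na_values=[""],
    ).assign(compound=lambda d: d["compound"].fillna(""))


def write_expression(study: ExpressionStudy, matrix_path, samples_path) -> None:
    study.expr.to_csv(matrix_path, sep="\t", index_label="gene")
    study.samples.to_csv(samples_path, sep="\t", index_label="sample")


def read_expression(matrix_path, samples_path) -> ExpressionStudy:
    expr = pd.read_csv(matrix_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return ExpressionStudy(expr=expr, samples=samples)


def write_gmt(gene_sets: dict, path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fields = [str(name), description or "na", *map(str, genes)]
            fh.write("\t".join(fields) + "\n")


def read_gmt(path) -> dict:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(parts[2:])
    return sets


def write_ranking(table: pd.DataFrame, path, gene_col="gene", stat_col="log2fc") -> None:
    table[[gene_col, stat_col]].to_csv(path, sep="\t", index=False, header=False)


def read_ranking(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["gene", "stat"])


def write_well_image(path, stack: np.ndarray, labels=None, mucin_masks=None) -> None:
    """Multi-page TIFF (one page per channel) + JSON ground-truth sidecar."""
    path = Path(path)
    tifffile.imwrite(
        path, np.asarray(stack, dtype=np.float32), photometric="minisblack"
    )
    if labels is not None:
        sidecar = {
            "channels": list(CHANNEL_NAMES[: stack.shape[0]]),
            "labels": np.asarray(labels).tolist(),
        }
        if mucin_masks is not None:
            sidecar["mucin_masks"] = np.asarray(mucin_masks, dtype=int).tolist()
        path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_well_image(path) -> np.ndarray:
    return tifffile.imread(path)


def load_params(path, cls):
    """Instantiate a params dataclass from a YAML mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown parameters for {cls.__name__}: {sorted(unknown)}")
    for f in dataclasses.fields(cls):
        if f.name in data and isinstance(data[f.name], list):
            data[f.name] = tuple(data[f.name])
    return cls(**data)
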
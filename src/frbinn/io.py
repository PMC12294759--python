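"""Readers and writers for the plain-text formats the toolkit exchanges.

Expression matrices and labels travel as TSV, gene sets as GMT, hierarchy
edges as a two-column TSV, the disease registry as TSV with empty cells for
absent statistics, and reports as CSV/JSON.  Numeric round-trips are
lossless to six significant digits.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .hierarchy import MaskStack
from .model import CLASSES, validate_expression
from .risk import DiseaseRegistry, DiseaseStats


class FormatError(ValueError):
    """Malformed input file."""


# -- expression ------------------------------------------------------------


def read_expression(path) -> pd.DataFrame:
    """TSV with sample IDs in the first column and gene IDs in the header."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.empty:
        raise FormatError(f"{path}: empty expression matrix")
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
    return validate_expression(frame)


def write_expression(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", float_format="%.6g", index_label="sample")


# -- labels ----------------------------------------------------------------


def read_labels(path) -> pd.Series:
    """Two-column TSV: sample ID, class string (one of the four classes)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.shape[1] != 1:
        raise FormatError(f"{path}: expected exactly two columns (sample, label)")
    labels = frame.iloc[:, 0].astype(str)
    bad = sorted(set(labels) - set(CLASSES))
    if bad:
        raise FormatError(
            f"{path}: unknown class labels {bad}; allowed classes: {list(CLASSES)}"
        )
    return labels.rename("label")


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("label").to_csv(path, sep="\t", index_label="sample")


# -- hierarchy files -------------------------------------------------------


def read_edges(path) -> list[tuple[str, str]]:
    """Two-column child/parent TSV with a header row."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] != 2:
        raise FormatError(f"{path}: expected two columns (child, parent)")
    if frame.isna().any().any():
        row = int(frame.isna().any(axis=1).idxmax()) + 2  # +1 header, +1 1-based
        raise FormatError(f"{path}: missing value at line {row}")
    return list(frame.itertuples(index=False, name=None))


def write_edges(edges: list[tuple[str, str]], path) -> None:
    pd.DataFrame(edges, columns=["child", "parent"]).to_csv(path, sep="\t", index=False)


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def write_masks(mask_stack: MaskStack, directory) -> list[Path]:
    """One TSV per layer-to-layer mask, 0/1 values with name headers."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for l, mask in enumerate(mask_stack.masks):
        p = directory / f"mask_layer{l}.tsv"
        mask.to_csv(p, sep="\t", index_label="entity")
        paths.append(p)
    return paths


# -- disease registry ------------------------------------------------------

_REGISTRY_COLUMNS = ["disease", "group", "RR", "HR", "SIR", "protective"]


def read_registry(path) -> DiseaseRegistry:
    frame = pd.read_csv(path, sep="\t", dtype={"disease": str, "group": str})
    missing = set(_REGISTRY_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing registry columns {sorted(missing)}")
    diseases = []
    for row in frame.itertuples(index=False):
        diseases.append(
            DiseaseStats(
                name=row.disease,
                rr=None if pd.isna(row.RR) else float(row.RR),
                hr=None if pd.isna(row.HR) else float(row.HR),
                sir=None if pd.isna(row.SIR) else float(row.SIR),
                protective=bool(row.protective) and str(row.protective).lower() not in ("0", "false", "nan"),
                group=row.group,
            )
        )
    return DiseaseRegistry(diseases=tuple(diseases))


def write_registry(registry: DiseaseRegistry, path) -> None:
    rows = [
        {
            "disease": d.name,
            "group": d.group,
            "RR": d.rr,
            "HR": d.hr,
            "SIR": d.sir,
            "protective": d.protective,
        }
        for d in registry.diseases
    ]
    pd.DataFrame(rows, columns=_REGISTRY_COLUMNS).to_csv(path, sep="\t", index=False)


# -- reports / manifests ---------------------------------------------------


def write_attribution_csv(result, path) -> None:
    """Entities as rows, samples as columns, plus a mean-|score| summary."""
    table = result.scores.T
    table["mean_abs"] = result.scores.abs().mean(axis=0)
    table.to_csv(path, float_format="%.6g", index_label="entity")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(paths: dict[str, Path], path, extra: dict | None = None) -> None:
    manifest = {
        "artifacts": {
            name: {"path": str(p), "sha256": file_sha256(p)}
            for name, p in paths.items()
            if Path(p).exists()
        }
    }
    if extra:
        manifest.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
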
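"""Readers and writers for every on-disk artifact.

All tables are TAB-delimited UTF-8 with '.' decimals; missing cells are
written empty and read from either an empty cell or "NA". Annotation sets
use the GMT dialect, networks export to SIF / GraphML / edge TSV.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from evcargo.datatypes import (
    AnnotationSets,
    ClinicalCohort,
    InteractionSnapshot,
    OmicsMatrix,
    PlasmaTable,
    SampleMeta,
)

log = logging.getLogger(__name__)

_NA_VALUES = ["", "NA"]


def _float_repr(v) -> str:
    """Shortest exact decimal so a write -> read round trip is bit-identical."""
    return repr(float(v))


def _parse_float_column(col: pd.Series) -> pd.Series:
    """Correctly-rounded string -> float64 (pandas' fast path is lossy)."""
    return col.map(lambda s: np.nan if pd.isna(s) else float(s))

NETWORK_FORMATS = ("sif", "graphml", "edge_tsv")


# ---------------------------------------------------------------- omics

def read_omics_matrix(
    path: str | Path,
    layer: str,
    design: dict[str, SampleMeta],
    log2_transform: bool = False,
) -> OmicsMatrix:
    """Read a feature x sample intensity TSV.

    ``design`` maps each sample id in the header to its metadata; a sample
    present in the file but absent from the design is a hard error. With
    ``log2_transform`` the file is taken to hold raw intensities: empty
    cells and non-positive values become missing and the rest are
    log2-transformed on read.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=_NA_VALUES,
                     keep_default_na=False, dtype=str)
    df = df.apply(_parse_float_column)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated feature ids in {path}: {dups}")
    missing = [c for c in df.columns if c not in design]
    if missing:
        raise ValueError(f"sample {missing[0]!r} in {path} is absent from the design")
    if log2_transform:
        vals = df.to_numpy(dtype=float)
        vals[~(vals > 0)] = np.nan  # raw zero/negative -> missing, never -inf
        df = pd.DataFrame(np.log2(vals), index=df.index, columns=df.columns)
    samples = [design[c] for c in df.columns]
    return OmicsMatrix(layer=layer, data=df, samples=samples)


def write_omics_matrix(m: OmicsMatrix, path: str | Path) -> None:
    df = m.data.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", na_rep="", float_format=_float_repr)


def read_design(path: str | Path) -> dict[str, SampleMeta]:
    """Sample-design JSON: sample_id -> {group, processing_replicate, technical_replicate}."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return {
        sid: SampleMeta(
            sample_id=sid,
            group=meta["group"],
            processing_replicate=int(meta.get("processing_replicate", 1)),
            technical_replicate=int(meta.get("technical_replicate", 1)),
        )
        for sid, meta in raw.items()
    }


def write_design(samples: list[SampleMeta], path: str | Path) -> None:
    out = {
        s.sample_id: {
            "group": s.group,
            "processing_replicate": s.processing_replicate,
            "technical_replicate": s.technical_replicate,
        }
        for s in samples
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------- interactions

def read_interaction_snapshot(
    path: str | Path, source_db: str = "", version: str = ""
) -> InteractionSnapshot:
    """Read a 3-column (source, target, type) edge-list TSV; deduplicates."""
    edges: list[tuple[str, str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts == ["source", "target", "type"]:
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            edges.append((parts[0], parts[1], parts[2]))
    snap = InteractionSnapshot(edges=edges, source_db=source_db, version=version)
    log.info("read %s: edges per type %s", path, snap.counts_by_type())
    return snap


def write_interaction_snapshot(snap: InteractionSnapshot, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\ttype\n")
        for src, tgt, etype in snap.edges:
            fh.write(f"{src}\t{tgt}\t{etype}\n")


# ------------------------------------------------------------------ GMT

def read_gmt(path: str | Path, background: set[str] | None = None) -> AnnotationSets:
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs term, description, >=1 member")
            tid, name, members = parts[0], parts[1], [p for p in parts[2:] if p]
            terms[tid] = (name, frozenset(members))
    return AnnotationSets(
        terms=terms, background=frozenset(background) if background is not None else None
    )


def write_gmt(sets: AnnotationSets, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tid in sorted(sets.terms):
            name, members = sets.terms[tid]
            fh.write("\t".join([tid, name, *sorted(members)]) + "\n")


# --------------------------------------------------------------- cohort

def read_cohort(path: str | Path, time_unit: str = "months") -> ClinicalCohort:
    """Cohort TSV: patient_id, time, event, then category and gene columns.

    Columns after the fixed three are classified by content: fully
    numeric-coercible columns are gene expression, the rest are clinical
    categories.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=_NA_VALUES, keep_default_na=False)
    for col in ("patient_id", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"cohort table {path} lacks required column {col!r}")
    df = df.set_index("patient_id")
    time = _parse_float_column(df.pop("time"))
    event = df.pop("event").map({"1": True, "0": False, "True": True, "False": False})
    gene_cols, cat_cols = [], []
    for col in df.columns:
        try:
            df[col] = _parse_float_column(df[col])
            gene_cols.append(col)
        except (ValueError, TypeError):
            cat_cols.append(col)
    return ClinicalCohort(
        expression=df[gene_cols].astype(float),
        categories=df[cat_cols],
        survival_time=time.astype(float),
        event=event.astype(bool),
        time_unit=time_unit,
    )


def write_cohort(cohort: ClinicalCohort, path: str | Path) -> None:
    out = pd.concat(
        [
            cohort.survival_time.rename("time"),
            cohort.event.astype(int).rename("event"),
            cohort.categories,
            cohort.expression,
        ],
        axis=1,
    )
    out.index.name = "patient_id"
    out.to_csv(path, sep="\t", na_rep="", float_format=_float_repr)


# --------------------------------------------------------------- plasma

def read_plasma_table(path: str | Path) -> PlasmaTable:
    """Plasma-concentration TSV: protein_id, concentration, unit (verbatim)."""
    conc: dict[str, tuple[float, str]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("protein_id"):
            raise ValueError(f"{path}: expected header starting with 'protein_id'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected protein_id, concentration, unit")
            conc[parts[0]] = (float(parts[1]), parts[2])
    return PlasmaTable(concentrations=conc)


def write_plasma_table(plasma: PlasmaTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\tconcentration\tunit\n")
        for pid in sorted(plasma.concentrations):
            value, unit = plasma.concentrations[pid]
            fh.write(f"{pid}\t{value!r}\t{unit}\n")


# -------------------------------------------------------------- network

def write_network(net: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Export the integrated network for external viewers (e.g. Cytoscape).

    Node attributes: layer, log2fc, direction, is_hub (plus
    lipid_associated for proteins); edge attribute: type. SIF uses the
    edge type as the relation token.
    """
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {fmt!r}; expected one of {NETWORK_FORMATS}")
    if fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for a, b, attrs in sorted(net.edges(data=True)):
                fh.write(f"{a}\t{attrs.get('type', 'interacts')}\t{b}\n")
            for node in sorted(net.nodes):
                if net.degree(node) == 0:
                    fh.write(f"{node}\n")
    elif fmt == "graphml":
        g = net.copy()
        for _, attrs in g.nodes(data=True):
            for k, v in list(attrs.items()):
                if isinstance(v, float) and math.isnan(v):
                    attrs[k] = ""
                elif isinstance(v, (bool, np.bool_)):
                    attrs[k] = bool(v)
                elif isinstance(v, np.floating):
                    attrs[k] = float(v)
        nx.write_graphml(g, path)
    else:  # edge_tsv
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\ttype\n")
            for a, b, attrs in sorted(net.edges(data=True)):
                fh.write(f"{a}\t{b}\t{attrs.get('type', '')}\n")


# --------------------------------------------------------------- config

def read_run_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_run_config(config: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(config, fh, indent=1, sort_keys=True)
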
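"""Core in-memory containers shared across the pipeline.

Intensity matrices are feature x sample pandas DataFrames of log2
intensities with NaN as the missing marker; sample metadata travels
alongside as a list of :class:`SampleMeta`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LAYERS = ("protein", "mirna", "metabolite", "lipid")
EDGE_TYPES = ("mirna_gene", "gene_metabolite", "protein_lipid_assoc")


@dataclass(frozen=True)
class SampleMeta:
    """One measured column: group label plus replicate coordinates.

    ``processing_replicate`` indexes independent sample preparations;
    ``technical_replicate`` indexes repeated measurements of the same
    preparation (only the protein layer uses values > 1).
    """

    sample_id: str
    group: str
    processing_replicate: int = 1
    technical_replicate: int = 1

    def __post_init__(self) -> None:
        if self.processing_replicate < 1 or self.technical_replicate < 1:
            raise ValueError(
                f"replicate indices must be >= 1 for sample {self.sample_id!r}"
            )


@dataclass
class OmicsMatrix:
    """One omics layer: feature x sample log2-intensity matrix.

    ``data`` rows are features (unique ids), columns are sample ids in the
    same order as ``samples``. NaN marks a missing (not quantified) cell;
    raw zero or negative intensities must be mapped to NaN upstream, never
    to -inf.
    """

    layer: str
    data: pd.DataFrame
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated feature ids: {dups}")
        if (self.data.index == "").any():
            raise ValueError("empty feature id")
        ids = [s.sample_id for s in self.samples]
        if list(self.data.columns) != ids:
            raise ValueError("data columns do not match sample metadata order")
        coords = {(s.group, s.processing_replicate, s.technical_replicate) for s in self.samples}
        if len(coords) != len(self.samples):
            raise ValueError("(group, processing_replicate, technical_replicate) not unique")
        groups = self.groups
        if len(groups) != 2:
            raise ValueError(f"expected a two-group design, found groups {groups}")
        vals = self.data.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("infinite intensity; raw non-positive values must map to missing")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        seen: list[str] = []
        for s in self.samples:
            if s.group not in seen:
                seen.append(s.group)
        return seen

    def group_columns(self, group: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.group == group]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class InteractionSnapshot:
    """Frozen local extract of a molecular-interaction resource.

    Edge semantics by type: ``mirna_gene`` source is a mature miRNA id and
    target a gene symbol; ``gene_metabolite`` links a gene symbol and a
    metabolite id through a shared reaction (undirected); for
    ``protein_lipid_assoc`` the source is a gene symbol listed as
    lipid-associated and the target names the association catalogue entry.
    """

    edges: list[tuple[str, str, str]]
    source_db: str = ""
    version: str = ""

    def __post_init__(self) -> None:
        cleaned: list[tuple[str, str, str]] = []
        seen: set[tuple[str, str, str]] = set()
        for src, tgt, etype in self.edges:
            if etype not in EDGE_TYPES:
                raise ValueError(f"unknown edge type {etype!r}; expected one of {EDGE_TYPES}")
            if src == tgt:
                continue
            key = (src, tgt, etype)
            if key in seen:
                continue
            seen.add(key)
            cleaned.append(key)
        self.edges = cleaned

    def counts_by_type(self) -> dict[str, int]:
        out = {t: 0 for t in EDGE_TYPES}
        for _, _, etype in self.edges:
            out[etype] += 1
        return out

    def lipid_associated_proteins(self) -> set[str]:
        return {src for src, _, etype in self.edges if etype == "protein_lipid_assoc"}


@dataclass
class AnnotationSets:
    """Named annotation terms (GO processes, pathways) for overrepresentation.

    ``terms`` maps term id -> (human-readable name, member id set). When a
    ``background`` is given every member set must be a subset of it.
    """

    terms: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for tid, (_, members) in self.terms.items():
            if not members:
                raise ValueError(f"term {tid!r} has an empty member set")
            if self.background is not None and not members <= self.background:
                extra = sorted(members - self.background)[:5]
                raise ValueError(f"term {tid!r} has members outside background: {extra}")


@dataclass
class ClinicalCohort:
    """Per-patient expression, clinical categories, and survival outcome."""

    expression: pd.DataFrame          # patients x genes, float
    categories: pd.DataFrame          # patients x clinical features, string or NaN
    survival_time: pd.Series          # >= 0
    event: pd.Series                  # bool: True = event observed
    time_unit: str = "months"

    def __post_init__(self) -> None:
        idx = self.expression.index
        if idx.duplicated().any():
            raise ValueError("duplicated patient ids")
        for other in (self.categories.index, self.survival_time.index, self.event.index):
            if not idx.equals(other):
                raise ValueError("patient index mismatch across cohort components")
        if (self.survival_time < 0).any():
            raise ValueError("negative survival time")
        if self.event.isna().any():
            raise ValueError("event indicator undefined for some patients with survival time")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.expression.index)

    @property
    def genes(self) -> list[str]:
        return list(self.expression.columns)


@dataclass
class PlasmaTable:
    """Protein -> estimated plasma concentration lookup (healthy donors)."""

    concentrations: dict[str, tuple[float, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, (value, _unit) in self.concentrations.items():
            if not value > 0:
                raise ValueError(f"non-positive plasma concentration for {pid!r}")

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.concentrations
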
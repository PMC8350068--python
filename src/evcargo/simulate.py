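"""Synthetic four-layer EV study generator with planted ground truth.

Emulates the study design: two conditions (primary-tumor "SCC9" vs
metastatic "LN1"), three processing replicates per group (five for the
metabolite layer), technical triplicates for the protein layer, log2-normal
baseline intensities, missing-at-random dropouts, a planted fraction of
differential features per layer, interaction snapshots that wire a chosen
set of differential proteins (the planted hubs) to differential miRNAs and
metabolites, and a clinical cohort with planted expression-survival and
expression-category effects.

The generator is the source of truth for downstream validation: every
planted effect is returned in a :class:`SimTruth` so recovery can be
scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from evcargo.datatypes import (
    ClinicalCohort,
    InteractionSnapshot,
    OmicsMatrix,
    SampleMeta,
)
from evcargo import io

GROUP1 = "SCC9_EV"   # primary-tumor-derived EVs (reference)
GROUP2 = "LN1_EV"    # metastatic-derived EVs (comparison)
CELL_GROUP1 = "SCC9_cell"
CELL_GROUP2 = "LN1_cell"

# fixed substream order so adding a layer never perturbs the others
_STREAMS = ("protein", "mirna", "metabolite", "lipid", "snapshot", "cohort", "cells")


@dataclass
class LayerSpec:
    """Per-layer simulation settings (log2-intensity scale)."""

    n_features: int
    n_processing_replicates: int = 3
    n_technical_replicates: int = 1
    fraction_differential: float = 0.4
    effect_size: float = 2.0          # mean log2 shift of planted features
    dropout_rate: float = 0.1         # missing-at-random cell probability
    noise_sd: float = 0.25            # within-group (processing) SD, log2 units
    technical_noise_sd: float = 0.1   # extra SD of a technical re-measurement
    baseline_mean: float = 20.0       # log2-normal baseline, LFQ-like
    baseline_sd: float = 2.0

    def validate(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.n_processing_replicates < 1 or self.n_technical_replicates < 1:
            raise ValueError("replicate counts must be >= 1")
        for name in ("fraction_differential", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0 or self.technical_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass
class CohortSpec:
    """Clinical-cohort simulation settings."""

    n_patients: int = 200
    n_prognostic_genes: int = 2       # planted survival-associated hub genes
    n_null_genes: int = 20            # extra genes with no planted effect
    hazard_ratio: float = 3.0         # hazard of low- vs high-expression arm
    component_separation: float = 5.0  # gap (in SDs) between expression modes
    baseline_hazard: float = 0.05     # events per time unit
    censoring_hazard: float = 0.02    # independent censoring rate
    # P(adverse level | low-expression mode). 0.85 implies a single-feature
    # ROC AUC of ~0.80 for the linked gene (AUC ~= p^2 + p(1-p)), i.e. a
    # marker that genuinely clears a 70% discrimination threshold.
    category_high_risk_prob: float = 0.85

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazards must be > 0")
        if not 0.0 <= self.category_high_risk_prob <= 1.0:
            raise ValueError("category_high_risk_prob must be in [0, 1]")


def default_layers() -> dict[str, LayerSpec]:
    """Layer sizes and replicate structure mirroring the study design."""
    return {
        "protein": LayerSpec(n_features=1722, n_technical_replicates=3),
        "mirna": LayerSpec(n_features=457),
        "metabolite": LayerSpec(n_features=33, n_processing_replicates=5,
                                fraction_differential=0.5),
        "lipid": LayerSpec(n_features=153),
    }


@dataclass
class SimSpec:
    """Full simulation specification; ``seed`` fixes every draw."""

    layers: dict[str, LayerSpec] = field(default_factory=default_layers)
    n_planted_hubs: int = 11
    n_decoy_edges: int = 60
    lipid_assoc_hub_fraction: float = 0.25  # fraction of hubs flagged lipid-associated
    cohort: CohortSpec = field(default_factory=CohortSpec)
    seed: int = 0

    def validate(self) -> None:
        for layer, ls in self.layers.items():
            if layer not in ("protein", "mirna", "metabolite", "lipid"):
                raise ValueError(f"unknown layer {layer!r}")
            ls.validate()
        if self.n_planted_hubs < 0 or self.n_decoy_edges < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.lipid_assoc_hub_fraction <= 1.0:
            raise ValueError("lipid_assoc_hub_fraction must be in [0, 1]")
        self.cohort.validate()


@dataclass
class SimTruth:
    """Planted ground truth: what a perfect analysis should recover."""

    differential: dict[str, dict[str, float]] = field(default_factory=dict)
    hubs: list[str] = field(default_factory=list)
    hub_edges: list[tuple[str, str, str]] = field(default_factory=list)
    lipid_associated_hubs: list[str] = field(default_factory=list)
    prognostic_genes: dict[str, float] = field(default_factory=dict)
    category_genes: list[str] = field(default_factory=list)

    def differential_ids(self, layer: str) -> set[str]:
        return set(self.differential.get(layer, {}))

    def to_json(self, path: str | Path) -> None:
        out = asdict(self)
        out["hub_edges"] = [list(e) for e in self.hub_edges]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(out, fh, indent=1, sort_keys=True)


def _substream(seed: int, name: str) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(name)])


_PREFIX = {"protein": "GENE", "mirna": "hsa-miR-sim", "metabolite": "MET", "lipid": "LIP"}


def feature_ids(layer: str, n: int) -> list[str]:
    if layer == "mirna":
        return [f"hsa-miR-sim-{i + 1:04d}" for i in range(n)]
    return [f"{_PREFIX[layer]}{i + 1:04d}" for i in range(n)]


def _simulate_matrix(
    ls: LayerSpec,
    ids: list[str],
    groups: tuple[str, str],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[SampleMeta], dict[str, float]]:
    n = ls.n_features
    baseline = rng.normal(ls.baseline_mean, ls.baseline_sd, size=n)
    n_diff = int(round(ls.fraction_differential * n)) if ls.effect_size != 0 else 0
    diff_idx = np.sort(rng.choice(n, size=n_diff, replace=False)) if n_diff else np.array([], int)
    signs = rng.choice([-1.0, 1.0], size=n_diff)
    effects = np.zeros(n)
    effects[diff_idx] = signs * ls.effect_size

    samples: list[SampleMeta] = []
    cols: list[np.ndarray] = []
    for gi, group in enumerate(groups):
        group_mean = baseline + effects if gi == 1 else baseline
        for pr in range(1, ls.n_processing_replicates + 1):
            proc = group_mean + rng.normal(0.0, ls.noise_sd, size=n)
            for tr in range(1, ls.n_technical_replicates + 1):
                col = proc.copy()
                if ls.n_technical_replicates > 1:
                    col = col + rng.normal(0.0, ls.technical_noise_sd, size=n)
                mask = rng.random(n) < ls.dropout_rate
                col[mask] = np.nan
                if ls.n_technical_replicates > 1:
                    sid = f"{group}_p{pr}_t{tr}"
                else:
                    sid = f"{group}_p{pr}"
                samples.append(SampleMeta(sid, group, pr, tr))
                cols.append(col)
    data = pd.DataFrame(np.column_stack(cols), index=ids,
                        columns=[s.sample_id for s in samples])
    truth = {ids[i]: float(effects[i]) for i in diff_idx}
    return data, samples, truth


def generate_omics_layer(
    spec: SimSpec, layer: str, rng: np.random.Generator | None = None
) -> tuple[OmicsMatrix, dict[str, float]]:
    """Generate one EV layer and its planted-differential truth fragment."""
    spec.validate()
    ls = spec.layers[layer]
    if rng is None:
        rng = _substream(spec.seed, layer)
    ids = feature_ids(layer, ls.n_features)
    data, samples, truth = _simulate_matrix(ls, ids, (GROUP1, GROUP2), rng)
    return OmicsMatrix(layer=layer, data=data, samples=samples), truth


def generate_cell_protein_layer(
    spec: SimSpec, rng: np.random.Generator | None = None
) -> OmicsMatrix:
    """Parental-cell proteome paired with the EV protein layer.

    Cells share the EV layer's per-protein baselines and differential
    effects (EV cargo mirrors the secreting cell) with an extra
    per-protein perturbation, so hub-protein mean intensities correlate
    strongly, but not perfectly, between cells and EVs.
    """
    spec.validate()
    ls = spec.layers["protein"]
    if rng is None:
        rng = _substream(spec.seed, "cells")
    # redraw the EV layer's deterministic quantities from its own stream
    ev_rng = _substream(spec.seed, "protein")
    n = ls.n_features
    baseline = ev_rng.normal(ls.baseline_mean, ls.baseline_sd, size=n)
    n_diff = int(round(ls.fraction_differential * n)) if ls.effect_size != 0 else 0
    diff_idx = np.sort(ev_rng.choice(n, size=n_diff, replace=False)) if n_diff else np.array([], int)
    signs = ev_rng.choice([-1.0, 1.0], size=n_diff)
    effects = np.zeros(n)
    effects[diff_idx] = signs * ls.effect_size

    ids = feature_ids("protein", n)
    cell_shift = rng.normal(0.0, 0.5, size=n)  # cell-vs-EV abundance offset
    samples: list[SampleMeta] = []
    cols: list[np.ndarray] = []
    for gi, group in enumerate((CELL_GROUP1, CELL_GROUP2)):
        group_mean = baseline + cell_shift + (effects if gi == 1 else 0.0)
        for pr in range(1, ls.n_processing_replicates + 1):
            col = group_mean + rng.normal(0.0, ls.noise_sd, size=n)
            mask = rng.random(n) < ls.dropout_rate
            col[mask] = np.nan
            samples.append(SampleMeta(f"{group}_p{pr}", group, pr, 1))
            cols.append(col)
    data = pd.DataFrame(np.column_stack(cols), index=ids,
                        columns=[s.sample_id for s in samples])
    return OmicsMatrix(layer="protein", data=data, samples=samples)


def generate_interaction_snapshot(
    spec: SimSpec,
    truth: SimTruth,
    rng: np.random.Generator | None = None,
) -> InteractionSnapshot:
    """Wire planted hubs to differential partners; add non-hub decoy edges.

    Each planted hub (a differential protein) receives at least one edge to
    a differential miRNA or metabolite. Decoy edges never join two
    differential molecules, so downstream both-ends filtering must recover
    exactly the planted hub set. Lipid-association flags go to a stated
    subset of hubs plus non-differential proteins only.
    """
    spec.validate()
    if rng is None:
        rng = _substream(spec.seed, "snapshot")
    diff_prot = sorted(truth.differential_ids("protein"))
    diff_mirna = sorted(truth.differential_ids("mirna"))
    diff_met = sorted(truth.differential_ids("metabolite"))
    if spec.n_planted_hubs > len(diff_prot):
        raise ValueError(
            f"n_planted_hubs={spec.n_planted_hubs} exceeds the "
            f"{len(diff_prot)} differential proteins"
        )
    hubs = sorted(rng.choice(diff_prot, size=spec.n_planted_hubs, replace=False).tolist())

    edges: list[tuple[str, str, str]] = []
    for hub in hubs:
        n_mir = int(rng.integers(0, 4)) if diff_mirna else 0
        n_met = int(rng.integers(0, 3)) if diff_met else 0
        if n_mir + n_met == 0:
            if diff_mirna:
                n_mir = 1
            elif diff_met:
                n_met = 1
            else:
                raise ValueError("no differential miRNAs or metabolites to wire hubs to")
        for mir in rng.choice(diff_mirna, size=min(n_mir, len(diff_mirna)), replace=False):
            edges.append((str(mir), hub, "mirna_gene"))
        for met in rng.choice(diff_met, size=min(n_met, len(diff_met)), replace=False):
            edges.append((hub, str(met), "gene_metabolite"))
    truth.hub_edges = list(edges)

    # lipid-association flags: a subset of hubs, plus non-differential proteins
    n_lipid_hubs = int(round(spec.lipid_assoc_hub_fraction * len(hubs)))
    lipid_hubs = sorted(rng.choice(hubs, size=n_lipid_hubs, replace=False).tolist()) if hubs else []
    all_prot = set(feature_ids("protein", spec.layers["protein"].n_features))
    nondiff_prot = sorted(all_prot - set(diff_prot))
    n_lipid_decoys = min(5, len(nondiff_prot))
    lipid_decoys = rng.choice(nondiff_prot, size=n_lipid_decoys, replace=False).tolist()
    for p in [*lipid_hubs, *lipid_decoys]:
        edges.append((str(p), "LMPD_sim", "protein_lipid_assoc"))

    # decoy interaction edges: both ends non-differential by plant
    all_mirna = set(feature_ids("mirna", spec.layers["mirna"].n_features))
    all_met = set(feature_ids("metabolite", spec.layers["metabolite"].n_features))
    nondiff_mirna = sorted(all_mirna - set(diff_mirna))
    nondiff_met = sorted(all_met - set(diff_met))
    pools = [
        (nondiff_mirna, nondiff_prot, "mirna_gene"),
        (nondiff_prot, nondiff_met, "gene_metabolite"),
    ]
    n_added = 0
    while n_added < spec.n_decoy_edges:
        src_pool, tgt_pool, etype = pools[n_added % len(pools)]
        if not src_pool or not tgt_pool:
            break
        src = str(src_pool[int(rng.integers(len(src_pool)))])
        tgt = str(tgt_pool[int(rng.integers(len(tgt_pool)))])
        edges.append((src, tgt, etype))
        n_added += 1

    truth.hubs = hubs
    truth.lipid_associated_hubs = lipid_hubs
    return InteractionSnapshot(edges=edges, source_db="synthetic", version=f"seed{spec.seed}")


def generate_cohort(
    spec: SimSpec,
    truth: SimTruth,
    rng: np.random.Generator | None = None,
) -> ClinicalCohort:
    """Cohort with planted expression-survival and expression-category effects.

    Planted prognostic genes (drawn from the hub set when available) are
    bimodal: each patient belongs to a low or high expression mode, and the
    low mode carries ``hazard_ratio``-fold the baseline hazard (low hub
    expression is the adverse state). Null genes are unimodal and
    outcome-independent. One clinical category ("node_status") is linked to
    the first planted gene's expression mode.
    """
    spec.validate()
    cs = spec.cohort
    if rng is None:
        rng = _substream(spec.seed, "cohort")
    n = cs.n_patients
    pids = [f"PAT{i + 1:04d}" for i in range(n)]

    candidates = truth.hubs if truth.hubs else feature_ids("protein", max(cs.n_prognostic_genes, 1))
    k = min(cs.n_prognostic_genes, len(candidates))
    prognostic = sorted(rng.choice(candidates, size=k, replace=False).tolist())
    null_genes = [f"NULLG{i + 1:04d}" for i in range(cs.n_null_genes)]

    expr: dict[str, np.ndarray] = {}
    low_mode: dict[str, np.ndarray] = {}
    for gene in prognostic:
        is_low = rng.random(n) < 0.5
        x = rng.normal(10.0, 1.0, size=n) + (~is_low) * cs.component_separation
        expr[gene] = x
        low_mode[gene] = is_low
    for gene in null_genes:
        expr[gene] = rng.normal(10.0, 1.5, size=n)

    hazard = np.full(n, cs.baseline_hazard)
    for gene in prognostic:
        hazard = hazard * np.where(low_mode[gene], cs.hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.exponential(1.0 / cs.censoring_hazard, size=n)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time

    categories = pd.DataFrame(index=pids)
    if prognostic:
        g0 = prognostic[0]
        p_adverse = np.where(low_mode[g0], cs.category_high_risk_prob,
                             1.0 - cs.category_high_risk_prob)
        categories["node_status"] = np.where(rng.random(n) < p_adverse, "N+", "N0")
        truth.category_genes = [g0]
    categories["site"] = rng.choice(["tongue", "floor_of_mouth", "buccal"], size=n)

    truth.prognostic_genes = {g: cs.hazard_ratio for g in prognostic}
    return ClinicalCohort(
        expression=pd.DataFrame(expr, index=pids),
        categories=categories,
        survival_time=pd.Series(time, index=pids),
        event=pd.Series(event, index=pids),
    )


@dataclass
class SimulatedStudy:
    """Everything one simulated study produces."""

    matrices: dict[str, OmicsMatrix]
    cell_protein: OmicsMatrix
    snapshot: InteractionSnapshot
    cohort: ClinicalCohort
    truth: SimTruth
    spec: SimSpec


def generate_study(spec: SimSpec) -> SimulatedStudy:
    """Generate all layers, the snapshot, the paired cell proteome and cohort."""
    spec.validate()
    truth = SimTruth()
    matrices: dict[str, OmicsMatrix] = {}
    for layer in ("protein", "mirna", "metabolite", "lipid"):
        m, frag = generate_omics_layer(spec, layer)
        matrices[layer] = m
        truth.differential[layer] = frag
    snapshot = generate_interaction_snapshot(spec, truth)
    cells = generate_cell_protein_layer(spec)
    cohort = generate_cohort(spec, truth)
    return SimulatedStudy(matrices, cells, snapshot, cohort, truth, spec)


def write_fixture_dir(study: SimulatedStudy, outdir: str | Path) -> dict[str, str]:
    """Write the full fixture directory; returns artifact name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for layer, m in study.matrices.items():
        p = outdir / f"{layer}_ev.tsv"
        io.write_omics_matrix(m, p)
        io.write_design(m.samples, outdir / f"{layer}_ev.design.json")
        paths[f"{layer}_ev"] = str(p)
    io.write_omics_matrix(study.cell_protein, outdir / "protein_cell.tsv")
    io.write_design(study.cell_protein.samples, outdir / "protein_cell.design.json")
    paths["protein_cell"] = str(outdir / "protein_cell.tsv")
    io.write_interaction_snapshot(study.snapshot, outdir / "interactions.tsv")
    paths["snapshot"] = str(outdir / "interactions.tsv")
    io.write_cohort(study.cohort, outdir / "cohort.tsv")
    paths["cohort"] = str(outdir / "cohort.tsv")
    study.truth.to_json(outdir / "truth.json")
    paths["truth"] = str(outdir / "truth.json")
    return paths
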
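"""End-to-end orchestration from one run-config, with a run manifest.

Stages run in dependency order: differential (per layer) -> multivariate
-> enrichment -> integration -> prognosis. A missing optional input
(snapshot, cohort, annotations, cells, plasma) skips the stages needing it
with a warning, never silently. The manifest records parameters, per-stage
outputs with content hashes, and headline counts; it contains no
timestamps so a fixed-seed rerun is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from evcargo import differential, enrichment, integration, io, multivariate, prognosis
from evcargo.datatypes import OmicsMatrix

log = logging.getLogger(__name__)

DEFAULTS = {
    "alpha": 0.05,
    "min_valid": 2,
    "hub_min_degree": 1,
    "auc_threshold": 0.70,
    "scaling": "unit_variance",
    "equal_var": True,
    "seed": 0,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def validate_config(config: dict) -> dict:
    """Fill defaults and check thresholds and referenced paths."""
    cfg = {**DEFAULTS, **config}
    if not 0 < cfg["alpha"] <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if cfg["min_valid"] < 1:
        raise ValueError("min_valid must be >= 1")
    if cfg["hub_min_degree"] < 1:
        raise ValueError("hub_min_degree must be >= 1")
    if not 0.5 <= cfg["auc_threshold"] <= 1:
        raise ValueError("auc_threshold must be in [0.5, 1]")
    if cfg["scaling"] not in ("center", "unit_variance"):
        raise ValueError("scaling must be 'center' or 'unit_variance'")
    for key in ("snapshot", "cohort", "plasma", "annotations"):
        if cfg.get(key) and not Path(cfg[key]).exists():
            raise FileNotFoundError(f"{key} path does not exist: {cfg[key]}")
    for layer, entry in cfg.get("layers", {}).items():
        for key in ("path", "design"):
            if not Path(entry[key]).exists():
                raise FileNotFoundError(f"layer {layer}: missing {key} {entry[key]}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_layer(entry: dict, layer: str) -> OmicsMatrix:
    design = io.read_design(entry["design"])
    return io.read_omics_matrix(
        entry["path"], layer, design, log2_transform=entry.get("log2_transform", False)
    )


def run_all(config: dict, output_dir: str | Path) -> dict:
    """Execute every stage the config enables; returns (and writes) the manifest."""
    cfg = validate_config(config)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {k: cfg[k] for k in DEFAULTS},
        "stages": {},
        "outputs": {},
        "counts": {},
        "warnings": [],
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    # ---- differential + multivariate, per layer
    matrices: dict[str, OmicsMatrix] = {}
    diff_tables: dict[str, object] = {}
    layer_cfg = cfg.get("layers", {})
    if not layer_cfg:
        manifest["warnings"].append("no layers configured; differential and downstream skipped")
    for layer in ("protein", "mirna", "metabolite", "lipid"):
        if layer not in layer_cfg:
            continue
        try:
            m = _load_layer(layer_cfg[layer], layer)
            matrices[layer] = m
            table, rejected = differential.differential_pipeline(
                m, min_valid=cfg["min_valid"], alpha=cfg["alpha"],
                equal_var=cfg["equal_var"],
            )
            diff_tables[layer] = table
            p = outdir / f"differential_{layer}.tsv"
            out = table.drop(columns=["p_bh"]).copy()
            out.index.name = "feature_id"
            out.to_csv(p, sep="\t", na_rep="NA")
            record(f"differential_{layer}", p)
            counts = differential.differential_counts(table)
            counts["n_rejected_by_filter"] = len(rejected)
            manifest["counts"][f"differential_{layer}"] = counts
        except Exception as exc:  # noqa: BLE001 - stage-named abort
            raise StageError(f"differential:{layer}", exc) from exc
    if matrices:
        manifest["stages"]["differential"] = "ok"
    for layer, m in matrices.items():
        try:
            averaged = differential.average_technical_replicates(m)
            pc = multivariate.pca(averaged, scaling=cfg["scaling"])
            p = outdir / f"pca_scores_{layer}.tsv"
            pc.scores.round(6).to_csv(p, sep="\t")
            record(f"pca_scores_{layer}", p)
            dend = multivariate.hierarchical_cluster(averaged, axis="samples")
            p = outdir / f"dendrogram_{layer}.nwk"
            p.write_text(dend.to_newick() + "\n", encoding="utf-8")
            record(f"dendrogram_{layer}", p)
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"multivariate:{layer}", exc) from exc
    if matrices:
        manifest["stages"]["multivariate"] = "ok"

    # ---- enrichment (protein layer)
    if cfg.get("annotations") and "protein" in diff_tables:
        try:
            table = diff_tables["protein"]
            background = set(table.index)
            sets = io.read_gmt(cfg["annotations"])
            sig = table.index[
                table["p_value"].notna() & (table["p_value"] <= cfg["alpha"])
            ]
            result = enrichment.overrepresentation(set(sig), sets, background)
            p = outdir / "enrichment_protein.tsv"
            result.to_csv(p, sep="\t", index=False)
            record("enrichment_protein", p)
            manifest["counts"]["enrichment_protein"] = {
                "n_terms_tested": int(len(result)),
                "n_significant_bonferroni": int((result["p_bonferroni"] <= 0.05).sum()),
            }
            manifest["stages"]["enrichment"] = "ok"
        except Exception as exc:  # noqa: BLE001
            raise StageError("enrichment", exc) from exc
    elif cfg.get("annotations"):
        manifest["stages"]["enrichment"] = "skipped"
        manifest["warnings"].append("enrichment skipped: protein layer missing")

    # ---- integration
    hub_ids: list[str] = []
    if cfg.get("snapshot") and "protein" in diff_tables:
        try:
            snap = io.read_interaction_snapshot(cfg["snapshot"])
            net = integration.build_network(diff_tables, snap, alpha=cfg["alpha"])
            report = integration.extract_hubs(net, hub_min_degree=cfg["hub_min_degree"])
            hub_ids = report.hub_ids
            for fmt, suffix in (("graphml", "graphml"), ("sif", "sif")):
                p = outdir / f"network.{suffix}"
                io.write_network(net, p, fmt=fmt)
                record(f"network_{fmt}", p)
            p = outdir / "hub_report.tsv"
            report.table.drop(columns=["mirnas", "metabolites"]).to_csv(p, sep="\t", index=False)
            record("hub_report", p)
            layers_in_net = [net.nodes[n]["layer"] for n in net.nodes]
            manifest["counts"]["integration"] = {
                "n_nodes": net.number_of_nodes(),
                "n_edges": net.number_of_edges(),
                "n_protein_nodes": layers_in_net.count("protein"),
                "n_mirna_nodes": layers_in_net.count("mirna"),
                "n_metabolite_nodes": layers_in_net.count("metabolite"),
                "n_hubs": len(hub_ids),
            }
            manifest["stages"]["integration"] = "ok"

            if cfg.get("cells"):
                cells = _load_layer(cfg["cells"], "protein")
                corrs = integration.cell_ev_correlation(cells, matrices["protein"], hub_ids)
                manifest["counts"]["cell_ev_correlation"] = {
                    c.group: {"r": round(c.r, 4), "n": c.n} for c in corrs
                }
            if cfg.get("plasma"):
                plasma = io.read_plasma_table(cfg["plasma"])
                lookup = integration.plasma_lookup(hub_ids, plasma)
                p = outdir / "plasma_lookup.tsv"
                lookup.to_csv(p, sep="\t", index=False)
                record("plasma_lookup", p)
                manifest["counts"]["plasma"] = {
                    "n_detected": lookup.attrs["n_detected"],
                    "n_total": lookup.attrs["n_total"],
                }
        except Exception as exc:  # noqa: BLE001
            raise StageError("integration", exc) from exc
    else:
        manifest["stages"]["integration"] = "skipped"
        if not cfg.get("snapshot"):
            manifest["warnings"].append("integration skipped: no interaction snapshot")
        else:
            manifest["warnings"].append("integration skipped: protein layer missing")

    # ---- prognosis
    if cfg.get("cohort"):
        try:
            cohort = io.read_cohort(cfg["cohort"])
            genes = [g for g in hub_ids if g in cohort.expression.columns] or cohort.genes
            screen = prognosis.screen_prognostic(
                cohort, genes=genes, auc_threshold=cfg["auc_threshold"]
            )
            p = outdir / "prognosis.tsv"
            screen.round(6).to_csv(p, sep="\t", index=False)
            record("prognosis", p)
            manifest["counts"]["prognosis"] = {
                "n_genes": int(len(screen)),
                "n_passing": int(screen["passes"].sum()),
            }
            manifest["stages"]["prognosis"] = "ok"
        except Exception as exc:  # noqa: BLE001
            raise StageError("prognosis", exc) from exc
    else:
        manifest["stages"]["prognosis"] = "skipped"
        manifest["warnings"].append("prognosis skipped: no cohort table")

    p = outdir / "manifest.json"
    with open(p, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
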
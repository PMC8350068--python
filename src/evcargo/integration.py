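"""Association-based multi-omics integration and hub-protein extraction.

Differentially abundant molecules from the protein, miRNA and metabolite
layers are fused into one heterogeneous graph using frozen interaction
snapshots: an edge survives only when BOTH endpoints are differential in
their layers. Lipids never form graph nodes; the lipid layer enters as a
boolean lipid-association annotation on differential proteins found in the
lipid-associated-protein list. Proteins connected to at least
``hub_min_degree`` differential molecules of other layers (lipid
association counts as one connection) are the "hub proteins".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from evcargo.datatypes import InteractionSnapshot, OmicsMatrix, PlasmaTable

log = logging.getLogger(__name__)


def _differential_ids(table: pd.DataFrame, alpha: float) -> set[str]:
    sig = table["p_value"].notna() & (table["p_value"] <= alpha)
    return set(table.index[sig])


def build_network(
    diff_tables: dict[str, pd.DataFrame],
    snapshot: InteractionSnapshot,
    alpha: float = 0.05,
) -> nx.Graph:
    """Build the heterogeneous differential-molecule network.

    ``diff_tables`` maps layer name -> differential table (as produced by
    :func:`evcargo.differential.differential_pipeline`) for at least the
    protein layer; miRNA and metabolite tables enable the corresponding
    edge types. Snapshot ids that belong to no supplied layer are logged
    and skipped. Isolated non-protein nodes are dropped; isolated proteins
    are retained only when lipid-associated.
    """
    layer_of: dict[str, str] = {}
    for layer in ("protein", "mirna", "metabolite"):
        table = diff_tables.get(layer)
        if table is None:
            continue
        for fid in table.index:
            layer_of[fid] = layer
    diff: dict[str, set[str]] = {
        layer: _differential_ids(t, alpha)
        for layer, t in diff_tables.items()
        if layer in ("protein", "mirna", "metabolite")
    }

    def is_diff(mol: str) -> bool:
        layer = layer_of.get(mol)
        return layer is not None and mol in diff.get(layer, set())

    net = nx.Graph(alpha=alpha, source_db=snapshot.source_db,
                   snapshot_version=snapshot.version)

    def add_node(mol: str) -> None:
        layer = layer_of[mol]
        row = diff_tables[layer].loc[mol]
        log2fc = float(row["log2fc"])
        if not np.isfinite(log2fc):
            raise ValueError(f"non-finite fold change for differential node {mol!r}")
        net.add_node(mol, layer=layer, log2fc=log2fc,
                     direction=str(row["direction"]), is_hub=False)
        if layer == "protein" and "lipid_associated" not in net.nodes[mol]:
            net.nodes[mol]["lipid_associated"] = False

    lipid_assoc = snapshot.lipid_associated_proteins()
    n_skipped = 0
    for src, tgt, etype in snapshot.edges:
        if etype == "protein_lipid_assoc":
            continue  # handled as node annotation below
        # orient: which end is the gene/protein?
        ends = (src, tgt)
        unknown = [m for m in ends if m not in layer_of]
        if unknown:
            n_skipped += 1
            log.debug("skipping edge %s-%s (%s): unknown id(s) %s", src, tgt, etype, unknown)
            continue
        if not (is_diff(src) and is_diff(tgt)):
            continue
        for mol in ends:
            if mol not in net:
                add_node(mol)
        net.add_edge(src, tgt, type=etype)
    if n_skipped:
        log.info("skipped %d snapshot edges with ids outside the supplied layers", n_skipped)

    # lipid-association annotation on differential proteins
    for prot in sorted(lipid_assoc):
        if layer_of.get(prot) == "protein" and is_diff(prot):
            if prot not in net:
                add_node(prot)
            net.nodes[prot]["lipid_associated"] = True

    # prune isolates: non-proteins always; proteins unless lipid-associated
    for node in [n for n in net.nodes if net.degree(n) == 0]:
        attrs = net.nodes[node]
        if attrs["layer"] != "protein" or not attrs.get("lipid_associated", False):
            net.remove_node(node)
    return net


@dataclass
class HubReport:
    """Hub proteins sorted by cross-layer degree (ties by id)."""

    table: pd.DataFrame  # hub_id, n_mirna, n_metabolite, lipid_associated, cross_layer_degree
    hub_min_degree: int = 1

    @property
    def hub_ids(self) -> list[str]:
        return list(self.table["hub_id"])

    def partners(self, hub_id: str) -> dict[str, list[str]]:
        row = self.table.set_index("hub_id").loc[hub_id]
        return {"mirna": list(row["mirnas"]), "metabolite": list(row["metabolites"])}


def extract_hubs(net: nx.Graph, hub_min_degree: int = 1) -> HubReport:
    """Extract hub proteins and mark them on the network.

    Cross-layer degree = #edges to non-protein differential nodes, plus one
    if the protein is lipid-associated. A protein is a hub when that degree
    reaches ``hub_min_degree``.
    """
    if hub_min_degree < 1:
        raise ValueError("hub_min_degree must be >= 1")
    rows = []
    for node, attrs in net.nodes(data=True):
        if attrs["layer"] != "protein":
            continue
        mirnas = sorted(nb for nb in net.neighbors(node)
                        if net.nodes[nb]["layer"] == "mirna")
        mets = sorted(nb for nb in net.neighbors(node)
                      if net.nodes[nb]["layer"] == "metabolite")
        lipid = bool(attrs.get("lipid_associated", False))
        degree = len(mirnas) + len(mets) + (1 if lipid else 0)
        attrs["is_hub"] = degree >= hub_min_degree
        if attrs["is_hub"]:
            rows.append({
                "hub_id": node, "n_mirna": len(mirnas), "n_metabolite": len(mets),
                "lipid_associated": lipid, "cross_layer_degree": degree,
                "mirnas": mirnas, "metabolites": mets,
                "direction": attrs["direction"], "log2fc": attrs["log2fc"],
            })
    table = pd.DataFrame(
        rows,
        columns=["hub_id", "n_mirna", "n_metabolite", "lipid_associated",
                 "cross_layer_degree", "mirnas", "metabolites", "direction", "log2fc"],
    )
    if len(table):
        table = table.sort_values(
            ["cross_layer_degree", "hub_id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return HubReport(table=table, hub_min_degree=hub_min_degree)


@dataclass
class CorrelationResult:
    """Pearson concordance between cell and EV hub-protein mean intensities."""

    group: str
    r: float
    n: int
    p_value: float = float("nan")


def cell_ev_correlation(
    cells: OmicsMatrix,
    evs: OmicsMatrix,
    hub_ids: list[str],
    group_pairs: dict[str, tuple[str, str]] | None = None,
) -> list[CorrelationResult]:
    """Per condition, Pearson r of hub-wise mean log2 intensities, cells vs EVs.

    ``group_pairs`` maps a label to (cell group, EV group); by default the
    i-th cell group is paired with the i-th EV group and labelled by their
    longest common prefix. Hubs absent from either matrix are logged and
    excluded; fewer than three common hubs is an error (r is unstable).
    """
    if group_pairs is None:
        group_pairs = {}
        for cg, eg in zip(cells.groups, evs.groups):
            prefix = ""
            for a, b in zip(cg, eg):
                if a != b:
                    break
                prefix += a
            group_pairs[prefix.rstrip("_") or cg] = (cg, eg)
    common = [h for h in hub_ids if h in cells.data.index and h in evs.data.index]
    dropped = sorted(set(hub_ids) - set(common))
    if dropped:
        log.info("hub proteins absent from cell or EV matrix, excluded: %s", dropped)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} hub proteins shared; need >= 3 for Pearson r")
    out = []
    for label, (cell_group, ev_group) in group_pairs.items():
        x = cells.data.loc[common, cells.group_columns(cell_group)].mean(axis=1, skipna=True)
        y = evs.data.loc[common, evs.group_columns(ev_group)].mean(axis=1, skipna=True)
        ok = x.notna() & y.notna()
        if ok.sum() < 3:
            raise ValueError(f"fewer than 3 hubs quantified in both matrices for {label!r}")
        r, p = stats.pearsonr(x[ok], y[ok])
        out.append(CorrelationResult(group=label, r=float(r), n=int(ok.sum()),
                                     p_value=float(p)))
    return out


def plasma_lookup(ids: list[str], plasma: PlasmaTable) -> pd.DataFrame:
    """Annotate proteins with detectability and concentration in plasma.

    Returns one row per input id: detected flag, concentration and the
    unit string preserved verbatim; summary counts live in ``df.attrs``.
    """
    rows = []
    for pid in ids:
        if pid in plasma:
            value, unit = plasma.concentrations[pid]
            rows.append({"protein_id": pid, "detected": True,
                         "concentration": value, "unit": unit})
        else:
            rows.append({"protein_id": pid, "detected": False,
                         "concentration": np.nan, "unit": ""})
    df = pd.DataFrame(rows, columns=["protein_id", "detected", "concentration", "unit"])
    df.attrs["n_detected"] = int(df["detected"].sum())
    df.attrs["n_total"] = len(df)
    return df
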
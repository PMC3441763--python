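"""Tripartite mimic-miRNA-target regulatory networks.

Nodes are miRNAs and transcripts; a transcript may carry the roles
{mimic}, {target} or both (one dual-role node). Directed edges are typed:
``mimicry`` runs mimic transcript -> miRNA (sequestration) and
``cleavage`` runs miRNA -> target transcript (slicing), composing the
"miRNA - mimic - miRNA - target" cascades. Export formats: GraphML, SIF
(with a node-attribute sidecar) and TSV edge/node lists.
"""
from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .models import TargetPair

EDGE_ATTRS = ["site_start", "site_end", "bulge_len", "nonmiddle_mismatches",
              "prediction_score", "peak_rpm"]


def build_network(
    mimic_table: Optional[pd.DataFrame],
    validated_pairs: Optional[Sequence[TargetPair] | pd.DataFrame],
) -> nx.DiGraph:
    """Assemble the typed regulatory graph from the two pipeline tables.

    Accepted mimic rows yield mimicry edges; validated target pairs yield
    cleavage edges. Parallel hits between the same mimic and miRNA at
    different sites collapse to one edge keeping the first site's
    coordinates and a ``n_sites`` multiplicity.
    """
    g = nx.DiGraph()
    if mimic_table is not None and not mimic_table.empty:
        accepted = mimic_table[mimic_table["accepted"]] if "accepted" in mimic_table \
            else mimic_table
        for row in accepted.itertuples(index=False):
            _ensure_node(g, row.mirna_id, "mirna")
            _ensure_node(g, row.transcript_id, "transcript", role="mimic")
            if g.has_edge(row.transcript_id, row.mirna_id):
                g[row.transcript_id][row.mirna_id]["n_sites"] += 1
            else:
                g.add_edge(
                    row.transcript_id,
                    row.mirna_id,
                    type="mimicry",
                    site_start=int(row.site_start),
                    site_end=int(row.site_end),
                    bulge_len=int(row.bulge_len),
                    nonmiddle_mismatches=int(row.nonmiddle_mismatches),
                    n_sites=1,
                )
    if validated_pairs is not None:
        if isinstance(validated_pairs, pd.DataFrame):
            iterator = (
                TargetPair(
                    mirna_id=r.mirna_id,
                    transcript_id=r.transcript_id,
                    binding_start=int(r.binding_start),
                    binding_end=int(r.binding_end),
                    expected_cleavage_position=int(r.expected_cleavage_position),
                    prediction_score=float(r.prediction_score),
                    validated=bool(r.validated),
                    peak_rpm=float(r.peak_rpm),
                )
                for r in validated_pairs.itertuples(index=False)
            )
        else:
            iterator = iter(validated_pairs)
        for pair in iterator:
            if not pair.validated:
                continue
            _ensure_node(g, pair.mirna_id, "mirna")
            _ensure_node(g, pair.transcript_id, "transcript", role="target")
            g.add_edge(
                pair.mirna_id,
                pair.transcript_id,
                type="cleavage",
                site_start=pair.binding_start,
                site_end=pair.binding_end,
                prediction_score=pair.prediction_score,
                peak_rpm=pair.peak_rpm,
                n_sites=1,
            )
    assert_type_discipline(g)
    return g


def _ensure_node(g: nx.DiGraph, node_id: str, kind: str, role: Optional[str] = None) -> None:
    if node_id in g:
        if g.nodes[node_id]["kind"] != kind:
            raise ValueError(
                f"id {node_id!r} used as both {g.nodes[node_id]['kind']} and {kind}"
            )
    else:
        g.add_node(node_id, kind=kind, roles="")
    if role:
        roles = set(filter(None, g.nodes[node_id]["roles"].split(",")))
        roles.add(role)
        g.nodes[node_id]["roles"] = ",".join(sorted(roles))


def assert_type_discipline(g: nx.DiGraph) -> None:
    """Every mimicry edge transcript->miRNA; every cleavage edge miRNA->transcript."""
    for u, v, data in g.edges(data=True):
        etype = data.get("type")
        kinds = (g.nodes[u]["kind"], g.nodes[v]["kind"])
        if etype == "mimicry" and kinds != ("transcript", "mirna"):
            raise ValueError(f"mimicry edge {u}->{v} violates type discipline")
        if etype == "cleavage" and kinds != ("mirna", "transcript"):
            raise ValueError(f"cleavage edge {u}->{v} violates type discipline")
        if etype not in ("mimicry", "cleavage"):
            raise ValueError(f"edge {u}->{v} has unknown type {etype!r}")


def network_stats(g: nx.DiGraph) -> dict:
    """Node/edge counts by type plus undirected connected components."""
    kinds = nx.get_node_attributes(g, "kind")
    roles = nx.get_node_attributes(g, "roles")
    mimics = sum(1 for n in g if "mimic" in roles.get(n, ""))
    targets = sum(1 for n in g if "target" in roles.get(n, ""))
    edge_types = [d["type"] for _, _, d in g.edges(data=True)]
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "n_mirnas": sum(1 for k in kinds.values() if k == "mirna"),
        "n_transcripts": sum(1 for k in kinds.values() if k == "transcript"),
        "n_mimic_transcripts": mimics,
        "n_target_transcripts": targets,
        "n_mimicry_edges": edge_types.count("mimicry"),
        "n_cleavage_edges": edge_types.count("cleavage"),
        "n_components": nx.number_connected_components(g.to_undirected())
        if g.number_of_nodes()
        else 0,
    }


def extract_subnetwork(g: nx.DiGraph, seed_ids: Iterable[str], radius: int) -> nx.DiGraph:
    """Induced subgraph of nodes within undirected distance <= radius of any seed."""
    seeds = list(seed_ids)
    unknown = [s for s in seeds if s not in g]
    if unknown:
        raise KeyError(f"seed id(s) not in the network: {unknown}")
    undirected = g.to_undirected(as_view=True)
    keep: set[str] = set()
    for seed in seeds:
        keep.update(
            nx.single_source_shortest_path_length(undirected, seed, cutoff=radius)
        )
    return g.subgraph(keep).copy()


def collapse_families(g: nx.DiGraph, family_of: dict[str, str]) -> nx.DiGraph:
    """Merge miRNA nodes sharing a family label (optional post-pass).

    Edges are re-attached to the family node; parallel edges merge with
    summed ``n_sites``.
    """
    mapping = {
        n: family_of.get(n, n) if g.nodes[n]["kind"] == "mirna" else n for n in g
    }
    merged = nx.DiGraph()
    for n, data in g.nodes(data=True):
        target = mapping[n]
        if target in merged:
            roles = set(filter(None, merged.nodes[target]["roles"].split(",")))
            roles |= set(filter(None, data["roles"].split(",")))
            merged.nodes[target]["roles"] = ",".join(sorted(roles))
        else:
            merged.add_node(target, **data)
    for u, v, data in g.edges(data=True):
        mu, mv = mapping[u], mapping[v]
        if merged.has_edge(mu, mv):
            merged[mu][mv]["n_sites"] += data.get("n_sites", 1)
        else:
            merged.add_edge(mu, mv, **data)
    assert_type_discipline(merged)
    return merged


# ---------------------------------------------------------------------------
# export / import

def export_network(g: nx.DiGraph, path: str | os.PathLike, format: str = "graphml") -> None:
    path = str(path)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "sif":
        _write_sif(g, path)
    elif format == "tsv-edgelist":
        _write_tsv(g, path)
    else:
        raise ValueError(f"unsupported network format {format!r}")


def import_network(path: str | os.PathLike, format: str = "graphml") -> nx.DiGraph:
    path = str(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        out = nx.DiGraph()
        out.add_nodes_from(g.nodes(data=True))
        out.add_edges_from(g.edges(data=True))
    elif format == "sif":
        out = _read_sif(path)
    elif format == "tsv-edgelist":
        out = _read_tsv(path)
    else:
        raise ValueError(f"unsupported network format {format!r}")
    assert_type_discipline(out)
    return out


def _sidecar(path: str) -> str:
    return path + ".nodes.tsv"


def _write_sif(g: nx.DiGraph, path: str) -> None:
    # SIF carries only typed edges; node kinds/roles go to a sidecar TSV
    with open(path, "w") as fh:
        connected = set()
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{data['type']}\t{v}\n")
            connected.update((u, v))
        for n in sorted(set(g) - connected):
            fh.write(f"{n}\n")
    _write_node_table(g, _sidecar(path))


def _read_sif(path: str) -> nx.DiGraph:
    g = nx.DiGraph()
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 1 and fields[0]:
                g.add_node(fields[0])
            elif len(fields) == 3:
                g.add_edge(fields[0], fields[2], type=fields[1])
    node_table = _sidecar(path)
    if os.path.exists(node_table):
        for row in pd.read_csv(node_table, sep="\t", keep_default_na=False).itertuples(
            index=False
        ):
            g.add_node(row.node_id, kind=row.kind, roles=row.roles)
    return g


def _write_node_table(g: nx.DiGraph, path: str) -> None:
    rows = [
        (n, d.get("kind", ""), d.get("roles", "")) for n, d in sorted(g.nodes(data=True))
    ]
    pd.DataFrame(rows, columns=["node_id", "kind", "roles"]).to_csv(
        path, sep="\t", index=False
    )


def _write_tsv(g: nx.DiGraph, path: str) -> None:
    rows = []
    for u, v, data in sorted(g.edges(data=True)):
        row = {"source": u, "target": v, "type": data["type"],
               "n_sites": data.get("n_sites", 1)}
        for attr in EDGE_ATTRS:
            row[attr] = data.get(attr, "")
        rows.append(row)
    pd.DataFrame(rows, columns=["source", "target", "type", "n_sites"] + EDGE_ATTRS).to_csv(
        path, sep="\t", index=False
    )
    _write_node_table(g, _sidecar(path))


def _read_tsv(path: str) -> nx.DiGraph:
    g = nx.DiGraph()
    for row in pd.read_csv(_sidecar(path), sep="\t", keep_default_na=False).itertuples(
        index=False
    ):
        g.add_node(row.node_id, kind=row.kind, roles=row.roles)
    edges = pd.read_csv(path, sep="\t", keep_default_na=False)
    for row in edges.itertuples(index=False):
        attrs = {"type": row.type, "n_sites": int(row.n_sites)}
        for attr in EDGE_ATTRS:
            value = getattr(row, attr)
            if value != "":
                attrs[attr] = float(value) if attr in ("prediction_score", "peak_rpm") \
                    else int(float(value))
        g.add_edge(row.source, row.target, **attrs)
    return g
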
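"""Assembly of the TF-family -> gene regulatory network.

An edge family F -> gene G exists in a condition when an occupied motif
occurrence of a family-F motif lies inside a DHS (or promoter bait
region) assigned to G through a significant promoter-capture interaction
in that condition, and G is differentially expressed (>= 2-fold,
p <= 0.01). Genes whose promoters or linked DHSs carry a RUNX1-ETO ChIP
peak summit are flagged as fusion-protein targets. Edges are grouped at
the family level; the motif-level evidence triples (dhs, interaction,
occurrence) are retained as edge attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .formats_io import (
    GenomicInterval,
    MotifOccurrence,
    PeakRecord,
    RestrictionFragment,
)
from .integration import DHSAssignment

__all__ = [
    "NetworkNode",
    "NetworkEdge",
    "RegulatoryNetwork",
    "build_network",
    "network_diff",
    "export_network",
    "read_network_graphml",
]


@dataclass(frozen=True)
class NetworkNode:
    node_id: str
    node_type: str  # tf_family | effector_gene
    direction: str = "unchanged"  # up | down | unchanged
    runx1_eto_target: bool = False


@dataclass
class NetworkEdge:
    source: str  # TF family
    target: str  # gene
    condition: str
    evidence: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("every edge needs >= 1 evidence triple")

    @property
    def key(self) -> tuple[str, str]:
        return (self.source, self.target)


@dataclass
class RegulatoryNetwork:
    condition: str
    nodes: dict[str, NetworkNode] = field(default_factory=dict)
    edges: dict[tuple[str, str], NetworkEdge] = field(default_factory=dict)

    def edge_keys(self) -> set[tuple[str, str]]:
        return set(self.edges)


def _dhs_id(dhs: PeakRecord) -> str:
    iv = dhs.interval
    return dhs.name or f"{iv.chrom}:{iv.start}-{iv.end}"


def _occ_id(occ: MotifOccurrence) -> str:
    iv = occ.interval
    return f"{occ.motif_id}@{iv.chrom}:{iv.start}:{occ.strand}"


def build_network(
    occupied_occurrences: list[MotifOccurrence],
    assignments: list[DHSAssignment],
    deg_up: set[str],
    deg_down: set[str],
    family_map: dict[str, str],
    runx1_eto_peaks: list[PeakRecord] | None = None,
    fragments: list[RestrictionFragment] | None = None,
    condition: str = "depleted",
    tf_family_genes: dict[str, str] | None = None,
) -> RegulatoryNetwork:
    """Assemble the regulatory network for one condition.

    ``family_map`` maps motif_id -> TF family and must cover every
    occupied motif. ``tf_family_genes`` optionally maps a family to its
    encoding gene so family nodes inherit that gene's DEG direction.
    """
    occupied = [o for o in occupied_occurrences if o.occupied]
    unmapped = sorted({o.motif_id for o in occupied} - set(family_map))
    if unmapped:
        raise ValueError(f"motifs without family mapping: {unmapped}")
    degs = deg_up | deg_down

    runx_summits: dict[str, list[int]] = {}
    for p in runx1_eto_peaks or []:
        runx_summits.setdefault(p.interval.chrom, []).append(p.summit)

    def has_runx_summit(iv: GenomicInterval) -> bool:
        return any(iv.start <= s < iv.end
                   for s in runx_summits.get(iv.chrom, []))

    bait_by_gene = {f.bait_gene: f for f in fragments or [] if f.is_bait}

    net = RegulatoryNetwork(condition=condition)
    tf_genes = tf_family_genes or {}
    family_gene_names = set(tf_genes.values()) | set(tf_genes)

    for assign in assignments:
        if not assign.assigned_genes:
            continue
        dhs_iv = assign.dhs.interval
        occs_here = [o for o in occupied if o.interval.overlaps(dhs_iv)]
        if not occs_here:
            continue
        for gene, interaction_id, _q in assign.assigned_genes:
            if gene not in degs:
                continue
            for occ in occs_here:
                family = family_map[occ.motif_id]
                key = (family, gene)
                triple = (_dhs_id(assign.dhs), interaction_id, _occ_id(occ))
                if key in net.edges:
                    if triple not in net.edges[key].evidence:
                        net.edges[key].evidence.append(triple)
                else:
                    net.edges[key] = NetworkEdge(
                        source=family, target=gene, condition=condition,
                        evidence=[triple])

    # nodes: targets plus every family that sourced an edge
    target_genes = sorted({g for _, g in net.edges})
    families = sorted({f for f, _ in net.edges})

    def gene_direction(gene: str) -> str:
        return "up" if gene in deg_up else ("down" if gene in deg_down
                                            else "unchanged")

    def is_runx_target(gene: str) -> bool:
        bait = bait_by_gene.get(gene)
        if bait is not None and has_runx_summit(bait.interval):
            return True
        for assign in assignments:
            if gene in assign.genes and has_runx_summit(assign.dhs.interval):
                return True
        return False

    for gene in target_genes:
        node_type = ("tf_family" if gene in family_gene_names
                     else "effector_gene")
        net.nodes[gene] = NetworkNode(
            node_id=gene, node_type=node_type,
            direction=gene_direction(gene),
            runx1_eto_target=is_runx_target(gene))
    for family in families:
        enc = tf_genes.get(family, family)
        net.nodes.setdefault(family, NetworkNode(
            node_id=family, node_type="tf_family",
            direction=gene_direction(enc),
            runx1_eto_target=False))

    # deterministic evidence ordering
    for edge in net.edges.values():
        edge.evidence.sort()
    return net


def network_diff(
    network_control: RegulatoryNetwork,
    network_depleted: RegulatoryNetwork,
) -> dict:
    """Edges gained/lost/shared between conditions, with per-family counts."""
    a, b = network_control.edge_keys(), network_depleted.edge_keys()
    gained, lost, shared = b - a, a - b, a & b
    per_family: dict[str, dict[str, int]] = {}
    for name, keys in (("gained", gained), ("lost", lost), ("shared", shared)):
        for fam, _ in keys:
            per_family.setdefault(fam, {"gained": 0, "lost": 0, "shared": 0})
            per_family[fam][name] += 1
    return {"gained": gained, "lost": lost, "shared": shared,
            "per_family": per_family}


def _to_nx(network: RegulatoryNetwork) -> nx.DiGraph:
    g = nx.DiGraph(condition=network.condition)
    for node in sorted(network.nodes.values(), key=lambda n: n.node_id):
        g.add_node(node.node_id, node_type=node.node_type,
                   direction=node.direction,
                   runx1_eto_target=str(node.runx1_eto_target))
    for key in sorted(network.edges):
        edge = network.edges[key]
        g.add_edge(edge.source, edge.target, condition=edge.condition,
                   n_evidence=len(edge.evidence),
                   evidence=";".join(",".join(t) for t in edge.evidence))
    return g


def export_network(network: RegulatoryNetwork, path, fmt: str = "graphml") -> None:
    """Write the network as graphml (lossless), edge_tsv (lossless), or dot."""
    path = str(path)
    if fmt == "graphml":
        nx.write_graphml(_to_nx(network), path)
    elif fmt == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tcondition\tsource_direction"
                     "\ttarget_direction\trunx1_eto_target\tn_evidence"
                     "\tevidence\n")
            for key in sorted(network.edges):
                e = network.edges[key]
                src = network.nodes[e.source]
                tgt = network.nodes[e.target]
                fh.write("\t".join([
                    e.source, e.target, e.condition, src.direction,
                    tgt.direction, str(tgt.runx1_eto_target),
                    str(len(e.evidence)),
                    ";".join(",".join(t) for t in e.evidence)]) + "\n")
    elif fmt == "dot":
        with open(path, "w") as fh:
            fh.write(f'digraph "{network.condition}" {{\n')
            for node in sorted(network.nodes.values(), key=lambda n: n.node_id):
                color = {"up": "red", "down": "blue"}.get(node.direction, "gray")
                shape = "box" if node.node_type == "tf_family" else "oval"
                fh.write(f'  "{node.node_id}" [color={color}, shape={shape}];\n')
            for key in sorted(network.edges):
                e = network.edges[key]
                fh.write(f'  "{e.source}" -> "{e.target}";\n')
            fh.write("}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_network_graphml(path) -> RegulatoryNetwork:
    """Re-import a graphml export (round-trips build_network output)."""
    g = nx.read_graphml(str(path))
    net = RegulatoryNetwork(condition=g.graph.get("condition", ""))
    for node_id, data in g.nodes(data=True):
        net.nodes[node_id] = NetworkNode(
            node_id=node_id, node_type=data["node_type"],
            direction=data["direction"],
            runx1_eto_target=data["runx1_eto_target"] == "True")
    for src, tgt, data in g.edges(data=True):
        evidence = [tuple(part.split(","))
                    for part in data["evidence"].split(";") if part]
        net.edges[(src, tgt)] = NetworkEdge(
            source=src, target=tgt, condition=data["condition"],
            evidence=evidence)
    return net
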
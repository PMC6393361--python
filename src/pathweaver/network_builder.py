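"""Integration of pathway collections into one unified interaction network.

Every biochemical interaction becomes its own *interaction node*, joined
by an edge to each of its participant nodes (gene products, metabolites,
complexes); the participant's role (source/target/participant) is stored
on the edge.  Interactions stated by several pathways — or several times
within one pathway — are merged into a single interaction node that
remembers the set of pathways it came from (*provenance*) and how many
raw records were merged (*occurrence_count*).  Ubiquitous currency
metabolites (ATP, H2O, H+, ...) are removed before the network is
assembled, because their promiscuity would create paths with no specific
biological meaning.

The resulting graph is bipartite: interaction nodes on one side,
molecular participants on the other.  A participant carrying two roles
in the same interaction yields two parallel edges, so the graph is a
:class:`networkx.MultiGraph` keyed by role.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

from .errors import ValidationError
from .pathway_model import InteractionRecord, PathwayCollection

INTERACTION_KIND = "interaction"
PARTICIPANT_KINDS = ("gene_product", "metabolite", "complex")


def canonical_interaction_key(record: InteractionRecord):
    """Deduplication key for interaction records.

    Two records receive the same key iff they share the interaction type
    and the same multiset of (entity_id, role) pairs; the pathway of
    origin and the record's local id are ignored.
    """
    pairs = Counter((p.entity_id, p.role) for p in record.participants)
    return (record.interaction_type, frozenset(pairs.items()))


def _interaction_node_id(key) -> str:
    digest = hashlib.sha1(repr(sorted(key[1])).encode() + key[0].encode())
    return "rx:" + digest.hexdigest()[:12]


@dataclass
class BuildReport:
    """Bookkeeping emitted by :func:`build_network`."""

    n_records: int = 0
    n_participant_refs_excluded: int = 0
    n_records_dropped_small: int = 0
    n_records_merged_away: int = 0
    n_interaction_nodes: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class UnifiedNetwork:
    """The unified bipartite network plus its build report.

    Node attributes: ``kind`` (interaction/gene_product/metabolite/
    complex) and ``label``; interaction nodes additionally carry
    ``interaction_type``, ``provenance`` (frozenset of pathway ids) and
    ``occurrence_count``.  Edge attribute: ``role``.
    """

    graph: nx.MultiGraph = field(default_factory=nx.MultiGraph)
    report: BuildReport = field(default_factory=BuildReport)

    # -- introspection ----------------------------------------------------
    def nodes_of_kind(self, kind: str) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["kind"] == kind
        )

    @property
    def interaction_node_ids(self) -> list[str]:
        return self.nodes_of_kind(INTERACTION_KIND)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def validate(self) -> None:
        g = self.graph
        for u, v in g.edges():
            ku = g.nodes[u]["kind"] == INTERACTION_KIND
            kv = g.nodes[v]["kind"] == INTERACTION_KIND
            if ku == kv:
                raise ValidationError(f"edge {u}–{v} violates bipartiteness")
        for n in self.interaction_node_ids:
            if len(set(g.neighbors(n))) < 2:
                raise ValidationError(
                    f"interaction node {n} has fewer than two distinct participants"
                )
            d = g.nodes[n]
            if not d.get("provenance"):
                raise ValidationError(f"interaction node {n} lacks provenance")
            if d.get("occurrence_count", 0) < len(d["provenance"]):
                raise ValidationError(
                    f"interaction node {n}: occurrence_count below |provenance|"
                )

    # -- exports ----------------------------------------------------------
    def to_graphml(self, path: str | Path) -> None:
        """Write GraphML with string-encoded provenance (';'-joined)."""
        g = nx.MultiGraph()
        for n, d in self.graph.nodes(data=True):
            attrs = dict(d)
            if "provenance" in attrs:
                attrs["provenance"] = ";".join(sorted(attrs["provenance"]))
            g.add_node(n, **attrs)
        for u, v, k, d in self.graph.edges(keys=True, data=True):
            g.add_edge(u, v, key=k, **d)
        nx.write_graphml(g, str(path))

    @classmethod
    def from_graphml(cls, path: str | Path) -> "UnifiedNetwork":
        raw = nx.read_graphml(str(path), force_multigraph=True)
        g = nx.MultiGraph()
        for n, d in raw.nodes(data=True):
            attrs = dict(d)
            if attrs.get("kind") == INTERACTION_KIND:
                prov = attrs.get("provenance", "")
                attrs["provenance"] = frozenset(p for p in prov.split(";") if p)
                attrs["occurrence_count"] = int(attrs.get("occurrence_count", 1))
            g.add_node(n, **attrs)
        for u, v, k, d in raw.edges(keys=True, data=True):
            g.add_edge(u, v, key=d.get("role", k), role=d.get("role", k))
        net = cls(graph=g)
        return net

    def write_sif(self, path: str | Path) -> None:
        """SIF export with the interaction node as the relation hub."""
        lines = []
        for u, v, d in sorted(
            self.graph.edges(data=True), key=lambda e: (e[0], e[1], e[2]["role"])
        ):
            if self.graph.nodes[u]["kind"] != INTERACTION_KIND:
                u, v = v, u
            lines.append(f"{u}\t{d['role']}\t{v}")
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))

    def write_node_table(self, path: str | Path) -> None:
        rows = ["node_id\tkind\tlabel\tprovenance\toccurrence_count"]
        for n in sorted(self.graph.nodes):
            d = self.graph.nodes[n]
            prov = ";".join(sorted(d.get("provenance", ()))) or "-"
            occ = d.get("occurrence_count", "-")
            rows.append(f"{n}\t{d['kind']}\t{d.get('label', n)}\t{prov}\t{occ}")
        Path(path).write_text("\n".join(rows) + "\n")

    def write_edge_table(self, path: str | Path) -> None:
        rows = ["interaction_node_id\tparticipant_node_id\trole"]
        for u, v, d in sorted(
            self.graph.edges(data=True), key=lambda e: (e[0], e[1], e[2]["role"])
        ):
            if self.graph.nodes[u]["kind"] != INTERACTION_KIND:
                u, v = v, u
            rows.append(f"{u}\t{v}\t{d['role']}")
        Path(path).write_text("\n".join(rows) + "\n")


def read_exclusion_list(path: str | Path) -> set[str]:
    """Read a currency-metabolite exclusion list: one entity id per line,
    ``#`` comments and blank lines ignored."""
    out: set[str] = set()
    for line in Path(path).read_text().splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            out.add(entry)
    return out


def build_network(
    collection: PathwayCollection, exclusion_list: Iterable[str] = ()
) -> UnifiedNetwork:
    """Build the unified interaction-as-node network from a collection.

    Participants whose entity id is on the exclusion list are dropped
    from every record first; records retaining at least two distinct
    participant entities become interaction nodes, merged across (and
    within) pathways by :func:`canonical_interaction_key`.  Records left
    with fewer than two distinct participants are discarded and counted
    in the build report.
    """
    collection.validate()
    excluded = set(exclusion_list)
    report = BuildReport(n_records=len(collection.interactions))
    g = nx.MultiGraph()
    entity_kind: dict[str, str] = {}
    # key -> dict(node_id, type, pairs, provenance set, occurrence)
    merged: dict = {}

    for rec in collection.interactions:
        kept = [p for p in rec.participants if p.entity_id not in excluded]
        report.n_participant_refs_excluded += len(rec.participants) - len(kept)
        if len({p.entity_id for p in kept}) < 2:
            report.n_records_dropped_small += 1
            continue
        core = InteractionRecord(rec.local_id, rec.interaction_type, kept, rec.pathway_id)
        key = canonical_interaction_key(core)
        entry = merged.get(key)
        if entry is None:
            merged[key] = entry = {
                "node_id": _interaction_node_id(key),
                "type": rec.interaction_type,
                "participants": kept,
                "provenance": set(),
                "occurrence": 0,
            }
        entry["provenance"].add(rec.pathway_id)
        entry["occurrence"] += 1
        for p in kept:
            prior = entity_kind.setdefault(p.entity_id, p.entity_kind)
            if prior != p.entity_kind:
                raise ValidationError(
                    f"entity {p.entity_id!r} appears both as {prior!r} and "
                    f"{p.entity_kind!r}"
                )

    for entry in merged.values():
        nid = entry["node_id"]
        g.add_node(
            nid,
            kind=INTERACTION_KIND,
            label=entry["type"],
            interaction_type=entry["type"],
            provenance=frozenset(entry["provenance"]),
            occurrence_count=entry["occurrence"],
        )
        seen_pairs = set()
        for p in entry["participants"]:
            pair = (p.entity_id, p.role)
            if pair in seen_pairs:
                continue
            seen_pairs.add(pair)
            if p.entity_id not in g:
                g.add_node(
                    p.entity_id,
                    kind=p.entity_kind,
                    label=p.entity_id,
                )
            g.add_edge(nid, p.entity_id, key=p.role, role=p.role)

    report.n_interaction_nodes = len(merged)
    report.n_records_merged_away = (
        report.n_records - report.n_records_dropped_small - len(merged)
    )
    net = UnifiedNetwork(graph=g, report=report)
    net.validate()
    return net


def connected_components(network: UnifiedNetwork) -> list[set[str]]:
    """Undirected components, largest first; ties broken by smallest
    member node id."""
    comps = [set(c) for c in nx.connected_components(network.graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    n_gene_products: int
    n_metabolites: int
    n_complexes: int
    n_interaction_nodes: int
    n_components: int
    component_sizes: list[int]
    interaction_type_census: dict[str, int]
    n_interactions_multi_occurrence: int
    n_interactions_multi_pathway: int

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["component_sizes"] = list(self.component_sizes)
        d["interaction_type_census"] = dict(self.interaction_type_census)
        return d

    def to_tsv(self, path: str | Path) -> None:
        rows = ["field\tvalue"]
        for k, v in self.as_dict().items():
            if isinstance(v, list):
                v = ";".join(str(x) for x in v)
            elif isinstance(v, dict):
                v = ";".join(f"{t}={c}" for t, c in sorted(v.items()))
            rows.append(f"{k}\t{v}")
        Path(path).write_text("\n".join(rows) + "\n")


def summarize(
    network: UnifiedNetwork, collection: PathwayCollection | None = None
) -> NetworkSummary:
    """Census of the unified network: node kinds, components, interaction
    types, and how often merged interactions recur within and across
    pathways."""
    g = network.graph
    kinds = Counter(d["kind"] for _, d in g.nodes(data=True))
    census: Counter = Counter()
    multi_occ = 0
    multi_path = 0
    for n in network.interaction_node_ids:
        d = g.nodes[n]
        census[d["interaction_type"]] += 1
        if d["occurrence_count"] > 1:
            multi_occ += 1
        if len(d["provenance"]) > 1:
            multi_path += 1
    comps = connected_components(network)
    summary = NetworkSummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        n_gene_products=kinds.get("gene_product", 0),
        n_metabolites=kinds.get("metabolite", 0),
        n_complexes=kinds.get("complex", 0),
        n_interaction_nodes=kinds.get(INTERACTION_KIND, 0),
        n_components=len(comps),
        component_sizes=[len(c) for c in comps],
        interaction_type_census=dict(census),
        n_interactions_multi_occurrence=multi_occ,
        n_interactions_multi_pathway=multi_path,
    )
    return summary
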
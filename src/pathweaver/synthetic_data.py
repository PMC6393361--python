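"""Synthetic pathway collections and expression tables with known truth.

The generator emulates the statistical structure of a curated
multi-pathway collection: a skewed interactions-per-pathway distribution
(log-normal, so the mean well exceeds the median), a fraction of
interactions shared verbatim across pathways, occasional duplicate
records within a pathway, a handful of promiscuous currency metabolites
attached to many interactions, and a participant mix dominated by gene
products.  On top of a built network it plants a connected set of gene
products with small p-values (p ~ Beta(alpha, 1)) against a uniform
background, fans genes out to multiple probes, and can permute gene
labels to produce a matched null dataset.

Every stochastic operation takes an explicit seed; the accompanying
:class:`GroundTruth` predicts — by pure bookkeeping, without running the
network builder — exactly what the unified network built from the
collection must look like.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .expression_mapping import GeneStatTable, ProbeStatRow
from .network_builder import UnifiedNetwork
from .pathway_model import (
    DIRECTED_TYPES,
    InteractionRecord,
    ParticipantRef,
    Pathway,
    PathwayCollection,
)

_DEFAULT_TYPE_WEIGHTS = {
    # proportions loosely matching the census of a curated human
    # pathway collection: directed interactions dominate, followed by
    # complex participation and catalysis
    "directed": 0.50,
    "complex_participation": 0.19,
    "catalysis": 0.17,
    "inhibition": 0.05,
    "conversion": 0.03,
    "undirected": 0.06,
}


@dataclass
class CollectionSpec:
    """Shape of a synthetic pathway collection.

    ``interactions_median``/``interactions_sigma`` parameterize a
    rounded log-normal (median 22, sigma 1 reproduces the skew of real
    collections: mean ~36 per pathway).  ``cross_pathway_share_rate`` is
    the fraction of interactions copied verbatim into a second pathway;
    ``within_pathway_duplicate_rate`` duplicates records inside their own
    pathway, which raises the occurrence count without widening
    provenance.
    """

    n_pathways: int = 30
    interactions_min: int = 1
    interactions_median: float = 22.0
    interactions_sigma: float = 1.0
    cross_pathway_share_rate: float = 0.08
    within_pathway_duplicate_rate: float = 0.04
    participant_kind_mix: tuple[float, float, float] = (0.70, 0.15, 0.15)
    extra_participants_mean: float = 0.6
    n_gene_products: int = 800
    n_metabolites: int = 250
    n_complexes: int = 250
    n_currency_metabolites: int = 10
    currency_attach_rate: float = 0.15
    type_weights: dict = field(default_factory=lambda: dict(_DEFAULT_TYPE_WEIGHTS))
    seed: int = 0

    def validate(self) -> None:
        if self.n_pathways < 1:
            raise ValidationError("n_pathways must be >= 1")
        if abs(sum(self.participant_kind_mix) - 1.0) > 1e-9:
            raise ValidationError("participant_kind_mix must sum to 1")
        for name in ("cross_pathway_share_rate", "within_pathway_duplicate_rate",
                     "currency_attach_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.cross_pathway_share_rate > 0 and self.n_pathways < 2:
            raise ValidationError(
                "cross-pathway sharing needs at least two pathways"
            )
        if self.n_currency_metabolites < 0:
            raise ValidationError("n_currency_metabolites must be >= 0")
        if self.currency_attach_rate > 0 and self.n_currency_metabolites == 0:
            raise ValidationError(
                "currency_attach_rate > 0 needs currency metabolites"
            )


@dataclass
class PlantSpec:
    """Planted differential-expression signal.

    Planted genes draw p ~ Beta(alpha, 1) (alpha = 1 degenerates to the
    uniform null) and |log2FC| ~ Normal(effect mean, sd) with a random
    sign; background genes draw p ~ Uniform(0,1) and
    log2FC ~ Normal(0, 0.2).  ``probes_per_gene`` is either a fixed int
    or an inclusive (lo, hi) range sampled uniformly.
    """

    planted_size: int = 15
    planted_p_alpha: float = 0.05
    effect_log2fc_mean: float = 1.0
    effect_log2fc_sd: float = 0.25
    probes_per_gene: int | tuple[int, int] = (1, 3)
    n_samples: int = 6
    undetected_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.planted_size < 2:
            raise ValidationError("planted_size must be >= 2")
        if not 0.0 < self.planted_p_alpha <= 1.0:
            raise ValidationError("planted_p_alpha must lie in (0, 1]")
        if not 0.0 <= self.undetected_rate <= 1.0:
            raise ValidationError("undetected_rate must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What the generated artifacts must look like downstream."""

    n_unique_interactions: int = 0
    interaction_records: list = field(default_factory=list)
    currency_ids: list = field(default_factory=list)
    expected_summary: dict = field(default_factory=dict)
    planted_genes: list = field(default_factory=list)
    n_probes: int = 0
    undetected_probes: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        p = self.parent.setdefault(x, x)
        while p != self.parent[p]:
            self.parent[p] = self.parent[self.parent[p]]
            p = self.parent[p]
        self.parent[x] = p
        return p

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _expected_summary(bases: list[dict]) -> dict:
    """Predict the unified-network summary from generator bookkeeping.

    ``bases`` holds one entry per unique interaction with its core
    (non-currency) participants, provenance and occurrence count.
    """
    kinds: dict[str, str] = {}
    census: Counter = Counter()
    n_edges = 0
    multi_occ = 0
    multi_path = 0
    uf = _UnionFind()
    for i, b in enumerate(bases):
        census[b["type"]] += 1
        n_edges += len(b["participants"])
        if b["occurrence"] > 1:
            multi_occ += 1
        if len(b["provenance"]) > 1:
            multi_path += 1
        inode = ("rx", i)
        for eid, kind, _role in b["participants"]:
            kinds[eid] = kind
            uf.union(inode, ("ent", eid))
    comp_sizes: Counter = Counter()
    for i in range(len(bases)):
        comp_sizes[uf.find(("rx", i))] += 1
    for eid in kinds:
        comp_sizes[uf.find(("ent", eid))] += 1
    sizes = sorted(comp_sizes.values(), reverse=True)
    kind_counts = Counter(kinds.values())
    return {
        "n_nodes": len(bases) + len(kinds),
        "n_edges": n_edges,
        "n_gene_products": kind_counts.get("gene_product", 0),
        "n_metabolites": kind_counts.get("metabolite", 0),
        "n_complexes": kind_counts.get("complex", 0),
        "n_interaction_nodes": len(bases),
        "n_components": len(sizes),
        "component_sizes": sizes,
        "interaction_type_census": dict(census),
        "n_interactions_multi_occurrence": multi_occ,
        "n_interactions_multi_pathway": multi_path,
    }


def generate_collection(spec: CollectionSpec) -> tuple[PathwayCollection, GroundTruth]:
    """Generate a pathway collection plus exact bookkeeping.

    Unique interactions are constructed with distinct core participant
    multisets, so the only merges the network builder will perform are
    the deliberate cross-pathway copies and within-pathway duplicates
    recorded in the ground truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = [f"ensembl:SYNG{i:06d}" for i in range(spec.n_gene_products)]
    metabolites = [f"chebi:SYNM{i:06d}" for i in range(spec.n_metabolites)]
    complexes = [f"reactome:R-SYN-{i:06d}" for i in range(spec.n_complexes)]
    currency = [f"chebi:SYNCUR{i:03d}" for i in range(spec.n_currency_metabolites)]
    pools = {"gene_product": genes, "metabolite": metabolites, "complex": complexes}

    pathways = [
        Pathway(f"SYNP{i:04d}", f"Synthetic pathway {i}", "synthetic")
        for i in range(spec.n_pathways)
    ]
    types = sorted(spec.type_weights)
    type_p = np.array([spec.type_weights[t] for t in types], dtype=float)
    type_p = type_p / type_p.sum()
    kind_names = ("gene_product", "metabolite", "complex")
    kind_p = np.array(spec.participant_kind_mix, dtype=float)

    used_keys: set = set()
    bases: list[dict] = []  # bookkeeping per unique interaction
    records: list[InteractionRecord] = []
    counters = {p.pathway_id: 0 for p in pathways}

    def fresh_local(pid: str) -> str:
        counters[pid] += 1
        return f"I{counters[pid]:05d}"

    for pw in pathways:
        mu = math.log(spec.interactions_median)
        n_i = max(
            spec.interactions_min,
            int(round(rng.lognormal(mu, spec.interactions_sigma))),
        )
        for _ in range(n_i):
            for _attempt in range(200):
                itype = types[int(rng.choice(len(types), p=type_p))]
                n_core = 2 + int(rng.poisson(spec.extra_participants_mean))
                kinds = [
                    kind_names[int(rng.choice(3, p=kind_p))] for _ in range(n_core)
                ]
                chosen: list[tuple[str, str]] = []
                taken: set[str] = set()
                ok = True
                for kind in kinds:
                    pool = pools[kind]
                    for _t in range(20):
                        eid = pool[int(rng.integers(len(pool)))]
                        if eid not in taken:
                            break
                    else:
                        ok = False
                        break
                    taken.add(eid)
                    chosen.append((eid, kind))
                if not ok:
                    continue
                directed = itype in DIRECTED_TYPES
                core = [
                    (eid, kind, ("source" if j == 0 else "target") if directed
                     else "participant")
                    for j, (eid, kind) in enumerate(chosen)
                ]
                key = (itype, frozenset((eid, role) for eid, _k, role in core))
                if key in used_keys:
                    continue
                used_keys.add(key)
                break
            else:
                raise ValidationError(
                    "could not construct a unique interaction; entity pools "
                    "too small for the requested collection size"
                )
            participants = [ParticipantRef(e, k, r) for e, k, r in core]
            if currency and rng.random() < spec.currency_attach_rate:
                n_cur = 1 + int(rng.random() < 0.3)
                cur_ids = rng.choice(
                    len(currency), size=min(n_cur, len(currency)), replace=False
                )
                for ci in sorted(int(c) for c in cur_ids):
                    role = "target" if directed else "participant"
                    participants.append(
                        ParticipantRef(currency[ci], "metabolite", role)
                    )
            records.append(
                InteractionRecord(
                    fresh_local(pw.pathway_id), itype, participants, pw.pathway_id
                )
            )
            bases.append(
                {
                    "type": itype,
                    "participants": core,
                    "provenance": {pw.pathway_id},
                    "occurrence": 1,
                    "record_participants": participants,
                }
            )

    n_base = len(bases)
    pw_ids = [p.pathway_id for p in pathways]
    # cross-pathway copies: verbatim re-statement in one other pathway
    n_cross = int(round(spec.cross_pathway_share_rate * n_base))
    if n_cross > 0:
        cross_idx = rng.choice(n_base, size=n_cross, replace=False)
        for bi in sorted(int(i) for i in cross_idx):
            origin = next(iter(bases[bi]["provenance"]))
            others = [p for p in pw_ids if p != origin]
            target = others[int(rng.integers(len(others)))]
            records.append(
                InteractionRecord(
                    fresh_local(target),
                    bases[bi]["type"],
                    bases[bi]["record_participants"],
                    target,
                )
            )
            bases[bi]["provenance"].add(target)
            bases[bi]["occurrence"] += 1
    # within-pathway duplicates: same pathway states the interaction twice
    n_dup = int(round(spec.within_pathway_duplicate_rate * n_base))
    if n_dup > 0:
        dup_idx = rng.choice(n_base, size=n_dup, replace=False)
        for bi in sorted(int(i) for i in dup_idx):
            origin = sorted(bases[bi]["provenance"])[
                int(rng.integers(len(bases[bi]["provenance"])))
            ]
            records.append(
                InteractionRecord(
                    fresh_local(origin),
                    bases[bi]["type"],
                    bases[bi]["record_participants"],
                    origin,
                )
            )
            bases[bi]["occurrence"] += 1

    collection = PathwayCollection(pathways, records)
    collection.validate()
    truth = GroundTruth(
        n_unique_interactions=n_base,
        interaction_records=[
            {
                "type": b["type"],
                "participants": [list(p) for p in b["participants"]],
                "provenance": sorted(b["provenance"]),
                "occurrence": b["occurrence"],
            }
            for b in bases
        ],
        currency_ids=list(currency),
        expected_summary=_expected_summary(bases),
    )
    return collection, truth


# ---------------------------------------------------------------------------
# Expression


def _gene_gene_adjacency(network: UnifiedNetwork) -> dict[str, set[str]]:
    g = network.graph
    adj: dict[str, set[str]] = {}
    for n, d in g.nodes(data=True):
        if d["kind"] != "interaction":
            continue
        members = [
            v for v in set(g.neighbors(n))
            if g.nodes[v]["kind"] == "gene_product"
        ]
        for u in members:
            adj.setdefault(u, set()).update(v for v in members if v != u)
    return adj


def _largest_gene_component(adj: dict[str, set[str]]) -> int:
    seen: set[str] = set()
    best = 0
    for start in adj:
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in comp:
                    comp.add(v)
                    stack.append(v)
        seen |= comp
        best = max(best, len(comp))
    return best


def generate_expression(
    network: UnifiedNetwork, plant: PlantSpec
) -> tuple[list[ProbeStatRow], dict[str, set[str]], GroundTruth]:
    """Plant a connected active module into an expression table.

    Returns (probe rows, probe->gene id map, ground truth).  The planted
    genes form a connected set in the gene-interaction-gene sense, so a
    depth-2 search can in principle recover them.
    """
    plant.validate()
    rng = np.random.default_rng(plant.seed)
    adj = _gene_gene_adjacency(network)
    genes = sorted(adj)
    isolated = sorted(
        set(network.nodes_of_kind("gene_product")) - set(genes)
    )
    all_genes = sorted(set(genes) | set(isolated))
    if not all_genes:
        raise ValidationError("network has no gene products")

    # snowball-sample a connected planted set
    planted: Optional[set[str]] = None
    order = list(rng.permutation(genes)) if genes else []
    for start in order[: min(50, len(order))]:
        current = {str(start)}
        frontier = set(adj[str(start)])
        while frontier and len(current) < plant.planted_size:
            pick = sorted(frontier)[int(rng.integers(len(frontier)))]
            current.add(pick)
            frontier |= adj[pick]
            frontier -= current
        if len(current) >= plant.planted_size:
            planted = current
            break
    if planted is None:
        raise ValidationError(
            "no connected gene set of size "
            f"{plant.planted_size} exists; largest available is "
            f"{_largest_gene_component(adj)}"
        )

    stats: dict[str, tuple[float, float]] = {}
    for gid in all_genes:
        if gid in planted:
            p = float(rng.random() ** (1.0 / plant.planted_p_alpha))
            fc = abs(rng.normal(plant.effect_log2fc_mean, plant.effect_log2fc_sd))
            fc *= -1.0 if rng.random() < 0.5 else 1.0
        else:
            p = float(rng.random())
            fc = float(rng.normal(0.0, 0.2))
        stats[gid] = (float(fc), min(max(p, 0.0), 1.0))

    probes: list[ProbeStatRow] = []
    idmap: dict[str, set[str]] = {}
    undetected: list[str] = []
    counter = 0
    for gid in all_genes:
        if isinstance(plant.probes_per_gene, int):
            n_probes = plant.probes_per_gene
        else:
            lo, hi = plant.probes_per_gene
            n_probes = int(rng.integers(lo, hi + 1))
        fc, p = stats[gid]
        for _ in range(max(1, n_probes)):
            counter += 1
            pid = f"PRB{counter:06d}"
            idmap[pid] = {gid}
            if gid not in planted and rng.random() < plant.undetected_rate:
                detected = tuple([False] * plant.n_samples)
                undetected.append(pid)
            else:
                flags = [bool(rng.random() < 0.9) for _ in range(plant.n_samples)]
                flags[0] = True
                detected = tuple(flags)
            probes.append(ProbeStatRow(pid, fc, p, detected))
    truth = GroundTruth(
        planted_genes=sorted(planted),
        n_probes=len(probes),
        undetected_probes=undetected,
    )
    return probes, idmap, truth


def permute_labels(table: GeneStatTable, seed: int = 0) -> GeneStatTable:
    """Reassign the (log2FC, p) pairs to a uniform random permutation of
    the gene ids, preserving the statistic multiset but destroying any
    network-localized signal."""
    genes = table.genes()
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(genes))
    values = [table.stats[g] for g in genes]
    return GeneStatTable(
        stats={genes[i]: values[int(perm[i])] for i in range(len(genes))},
        contrast_label=table.contrast_label,
    )


# ---------------------------------------------------------------------------
# Fixture bundles


def pathway_gene_sets(collection: PathwayCollection, exclude: Sequence[str] = ()):
    """Flat per-pathway gene sets (gene-product participants), the
    GMT-ready companion of a collection."""
    from .enrichment import GeneSet

    excluded = set(exclude)
    members: dict[str, set[str]] = {p.pathway_id: set() for p in collection.pathways}
    titles = {p.pathway_id: p.title for p in collection.pathways}
    for rec in collection.interactions:
        for q in rec.participants:
            if q.entity_kind == "gene_product" and q.entity_id not in excluded:
                members[rec.pathway_id].add(q.entity_id)
    return [
        GeneSet(pid, titles[pid], sorted(ms))
        for pid, ms in sorted(members.items())
        if ms
    ]


def write_fixture_bundle(
    out_dir: str | Path,
    collection_spec: CollectionSpec,
    plant_spec: PlantSpec,
) -> GroundTruth:
    """Emit a complete, self-consistent input bundle into ``out_dir``:
    collection.json, exclusion.txt, probes.tsv, idmap.tsv, genesets.gmt
    and truth.json."""
    from .enrichment import write_gmt
    from .expression_mapping import write_idmap, write_probe_table
    from .network_builder import build_network
    from .pathway_model import write_collection

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collection, truth = generate_collection(collection_spec)
    network = build_network(collection, truth.currency_ids)
    probes, idmap, expr_truth = generate_expression(network, plant_spec)
    truth.planted_genes = expr_truth.planted_genes
    truth.n_probes = expr_truth.n_probes
    truth.undetected_probes = expr_truth.undetected_probes

    write_collection(collection, out / "collection.json")
    (out / "exclusion.txt").write_text(
        "# currency metabolites excluded from the network\n"
        + "\n".join(truth.currency_ids)
        + ("\n" if truth.currency_ids else "")
    )
    write_probe_table(probes, out / "probes.tsv")
    write_idmap(idmap, out / "idmap.tsv")
    write_gmt(pathway_gene_sets(collection, truth.currency_ids), out / "genesets.gmt")
    truth.to_json(out / "truth.json")
    return truth
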
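"""Active-subnetwork discovery on the unified network.

A node's differential-expression p-value is converted to a z-score,
``z = Phi^-1(1 - p)``, and a candidate module aggregates its scored
members as ``zA = (sum z_i) / sqrt(k)``.  Because zA of random node sets
drifts with k, a Monte-Carlo background table of the mean and standard
deviation of zA over random size-k sets standardizes it:
``sA = (zA - mu_k) / sigma_k``.  Search proceeds by seeded greedy
expansion: starting from each scored node, the candidate within the
configured search depth whose adoption (together with the connector
nodes on its shortest path) most increases the corrected score is added,
until no addition helps.  Search depth is counted in biological steps —
one gene -> interaction -> gene hop per step — i.e. ``2 * depth`` edges
of the bipartite graph.  The ranked candidates are finally thinned by an
overlap filter so that at most ``n_modules`` sufficiently distinct
modules are reported.

Unscored nodes (interaction nodes, unmeasured genes, metabolites,
complexes) are traversable connectors: they can join a module to keep it
connected but contribute nothing to the score and are not counted in k.
"""

from __future__ import annotations

import math
from collections import Counter, deque
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError
from .expression_mapping import Criterion, GeneStatTable
from .network_builder import UnifiedNetwork

DEFAULT_CLAMP_EPSILON = 1e-12
DEFAULT_SIGMA_FLOOR = 1e-9


# ---------------------------------------------------------------------------
# Scoring primitives


def z_from_p(p, clamp_epsilon: float = DEFAULT_CLAMP_EPSILON):
    """Standard-normal quantile transform ``z = Phi^-1(1 - p)``.

    ``p`` is clamped into ``[eps, 1 - eps]`` first so that z stays
    finite at p = 0 or 1.  Accepts scalars or arrays.
    """
    if not 0.0 < clamp_epsilon < 0.5:
        raise ValidationError("clamp_epsilon must lie in (0, 0.5)")
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValidationError("p-values must lie in [0, 1]")
    clamped = np.clip(arr, clamp_epsilon, 1.0 - clamp_epsilon)
    z = sps.norm.isf(clamped)
    return float(z) if np.isscalar(p) or arr.ndim == 0 else z


def aggregate_score(zs: Sequence[float]) -> float:
    """Aggregate z-scores of k nodes: ``zA = (sum z_i) / sqrt(k)``."""
    zs = list(zs)
    if not zs:
        raise ValidationError("aggregate_score needs at least one z value")
    return float(sum(zs) / math.sqrt(len(zs)))


@dataclass
class NodeZScores:
    """Per-node z-scores; nodes without a p-value are simply absent."""

    z: dict[str, float] = field(default_factory=dict)

    @property
    def scored_set(self) -> set[str]:
        return set(self.z)

    def __len__(self) -> int:
        return len(self.z)


def node_z_scores(
    network: UnifiedNetwork,
    contrast_label: str,
    clamp_epsilon: float = DEFAULT_CLAMP_EPSILON,
) -> NodeZScores:
    """Collect z-scores from a network annotated for one contrast.

    Only nodes carrying a p-value for the contrast are scored; missing
    p-values are never imputed, since a neutral placeholder would dilute
    the module size k without adding evidence.
    """
    key = f"p__{contrast_label}"
    z: dict[str, float] = {}
    for n, d in network.graph.nodes(data=True):
        if key in d:
            z[n] = z_from_p(float(d[key]), clamp_epsilon)
    if not z:
        raise ValidationError(
            f"network carries no p-values for contrast {contrast_label!r}"
        )
    return NodeZScores(z=z)


def scores_from_table(
    table: GeneStatTable,
    node_ids: Iterable[str],
    clamp_epsilon: float = DEFAULT_CLAMP_EPSILON,
) -> NodeZScores:
    """z-scores for the gene nodes present in both the table and the
    given node-id universe."""
    universe = set(node_ids)
    z = {
        g: z_from_p(p, clamp_epsilon)
        for g, (_, p) in table.stats.items()
        if g in universe
    }
    return NodeZScores(z=z)


# ---------------------------------------------------------------------------
# Monte-Carlo background calibration


@dataclass
class CalibrationTable:
    """Per-size background mean and standard deviation of the aggregate
    score over uniformly random size-k subsets of the scored nodes."""

    mu: np.ndarray  # index k, entries 0..k_max (index 0 unused)
    sigma: np.ndarray
    n_draws: int
    seed: int
    k_max: int

    @classmethod
    def identity(cls, k_max: int) -> "CalibrationTable":
        """mu = 0, sigma = 1 for every k; corrected score equals zA.
        Useful for hand-checked examples and tests."""
        return cls(
            mu=np.zeros(k_max + 1),
            sigma=np.ones(k_max + 1),
            n_draws=0,
            seed=0,
            k_max=k_max,
        )


def calibrate(
    scores: NodeZScores,
    k_max: int,
    n_draws: int = 2000,
    seed: int = 0,
) -> CalibrationTable:
    """Estimate the background distribution of zA for k = 1..k_max.

    Subsets are drawn uniformly from the scored nodes without any
    connectivity requirement; the calibration answers "how large is zA
    for an arbitrary set of k measured genes", against which connected
    modules are standardized.
    """
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    if k_max > len(scores):
        raise ValidationError(
            f"k_max={k_max} exceeds the number of scored nodes ({len(scores)})"
        )
    if n_draws < 100:
        raise ValidationError("n_draws must be >= 100")
    zvals = np.array([scores.z[n] for n in sorted(scores.z)], dtype=float)
    n = zvals.size
    rng = np.random.default_rng(seed)
    mu = np.zeros(k_max + 1)
    sigma = np.zeros(k_max + 1)
    chunk = max(1, min(n_draws, 512))
    for k in range(1, k_max + 1):
        sums = np.empty(n_draws)
        done = 0
        while done < n_draws:
            m = min(chunk, n_draws - done)
            # uniform size-k subsets via partial argsort of random keys
            keys = rng.random((m, n))
            idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
            sums[done : done + m] = zvals[idx].sum(axis=1)
            done += m
        agg = sums / math.sqrt(k)
        mu[k] = agg.mean()
        sigma[k] = agg.std(ddof=1)
    return CalibrationTable(mu=mu, sigma=sigma, n_draws=n_draws, seed=seed, k_max=k_max)


def corrected_score(
    module_nodes: Iterable[str],
    scores: NodeZScores,
    calib: CalibrationTable,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
) -> float:
    """Background-corrected module score ``sA = (zA - mu_k) / sigma_k``
    over the module's scored members only."""
    zs = [scores.z[n] for n in module_nodes if n in scores.z]
    if not zs:
        raise ValidationError("module contains no scored nodes")
    k = len(zs)
    if k > calib.k_max:
        raise ValidationError(
            f"module has {k} scored nodes but calibration covers only "
            f"k <= {calib.k_max}"
        )
    za = aggregate_score(zs)
    return (za - calib.mu[k]) / max(calib.sigma[k], sigma_floor)


def _corr(total: float, k: int, calib: CalibrationTable, sigma_floor: float) -> float:
    return (total / math.sqrt(k) - calib.mu[k]) / max(calib.sigma[k], sigma_floor)


# ---------------------------------------------------------------------------
# Search


@dataclass
class SearchParams:
    """Knobs of the active-module search.

    Defaults follow the standard settings of the underlying method:
    five reported modules, overlap threshold 0.8, search depth 2.
    ``max_module_scored`` caps the number of scored genes per module;
    ``overlap_measure`` is ``|A&B| / min(|A|,|B|)`` by default, with
    Jaccard available.
    """

    n_modules: int = 5
    overlap_threshold: float = 0.8
    search_depth: int = 2
    max_module_scored: int = 20
    n_calibration_draws: int = 2000
    seed: int = 0
    overlap_measure: str = "min"  # or "jaccard"
    clamp_epsilon: float = DEFAULT_CLAMP_EPSILON
    sigma_floor: float = DEFAULT_SIGMA_FLOOR

    def validate(self) -> None:
        if self.n_modules < 1:
            raise ValidationError("n_modules must be >= 1")
        if self.search_depth < 1:
            raise ValidationError("search_depth must be >= 1")
        if not 0.0 <= self.overlap_threshold <= 1.0:
            raise ValidationError("overlap_threshold must lie in [0, 1]")
        if self.max_module_scored < 1:
            raise ValidationError("max_module_scored must be >= 1")
        if self.overlap_measure not in ("min", "jaccard"):
            raise ValidationError(f"unknown overlap_measure {self.overlap_measure!r}")


@dataclass
class ActiveModule:
    """A connected subnetwork with its activity scores."""

    member_node_ids: frozenset
    scored_k: int
    raw_score: float
    corrected: float
    seed_id: str
    pathway_contributions: dict[str, int] = field(default_factory=dict)
    n_significant: Optional[int] = None

    @property
    def corrected_score(self) -> float:
        return self.corrected


def _pathway_contributions(members: Iterable[str], network: UnifiedNetwork) -> dict:
    contrib: Counter = Counter()
    g = network.graph
    for n in members:
        d = g.nodes.get(n, {})
        if d.get("kind") == "interaction":
            for pid in d["provenance"]:
                contrib[pid] += 1
    return dict(contrib)


def _relax(sources, state, adj, radius, z, module):
    """Multi-source shortest-path relaxation from the module frontier.

    Each reached node carries a label ``(distance, scored-count,
    -scored-z-sum)`` describing its connecting path (counting/summing
    scored non-member nodes on the path, including the node itself);
    labels are minimized lexicographically, which makes the choice of
    "shortest connecting path" canonical: shortest first, then fewest
    scored intermediates, then the largest z-sum, independent of the
    order in which the module grew."""
    import heapq

    labels, parent, cand = state
    heap = []
    for s in sources:
        labels[s] = (0, 0, 0.0)
        parent[s] = None
        cand.discard(s)
        heapq.heappush(heap, ((0, 0, 0.0), s))
    while heap:
        lab, u = heapq.heappop(heap)
        if labels.get(u) != lab:
            continue  # stale entry
        du, cnt_u, negsum_u = lab
        if du == radius:
            continue
        for v in adj[u]:
            zv = z.get(v)
            if zv is not None and v not in module:
                new = (du + 1, cnt_u + 1, negsum_u - zv)
            else:
                new = (du + 1, cnt_u, negsum_u)
            if new < labels.get(v, (radius + 1, 0, 0.0)):
                labels[v] = new
                parent[v] = u
                if zv is not None and v not in module:
                    cand.add(v)
                heapq.heappush(heap, (new, v))


def _grow_from_seed(seed, adj, z, calib, params, k_cap):
    """Greedy expansion from one seed; returns (members, total_z, k,
    corrected score)."""
    sigma_floor = params.sigma_floor
    radius = 2 * params.search_depth
    module = {seed}
    total = z[seed]
    k = 1
    labels: dict = {}
    parent: dict = {}
    cand: set = set()
    state = (labels, parent, cand)
    _relax([seed], state, adj, radius, z, module)
    cur = _corr(total, k, calib, sigma_floor)
    while k < k_cap:
        best = None
        best_key = None
        for v in cand:
            dk = labels[v][1]
            if dk == 0 or k + dk > k_cap:
                continue
            s_new = _corr(total - labels[v][2], k + dk, calib, sigma_floor)
            key = (s_new, -dk)
            # prefer higher score, then fewer added scored nodes, then the
            # lexicographically smallest node id
            if best is None or key > best_key or (key == best_key and v < best):
                best = v
                best_key = key
        if best is None or best_key[0] <= cur + 1e-12:
            break
        # adopt the candidate plus its connecting path
        chain = []
        node = best
        while node is not None and node not in module:
            chain.append(node)
            node = parent[node]
        new_nodes = list(reversed(chain))
        module.update(new_nodes)
        total -= labels[best][2]
        k += labels[best][1]
        cur = best_key[0]
        _relax(new_nodes, state, adj, radius, z, module)
    return module, total, k, cur


def greedy_search(
    network: UnifiedNetwork,
    scores: NodeZScores,
    calib: CalibrationTable,
    params: SearchParams,
) -> list[ActiveModule]:
    """Seeded greedy search: one candidate module per scored seed node,
    returned sorted by corrected score (ties: fewer members, then the
    smallest seed id)."""
    params.validate()
    if not scores.z:
        raise ValidationError("no scored nodes: annotate the network first")
    k_cap = min(params.max_module_scored, calib.k_max, len(scores))
    g = network.graph
    adj = {n: sorted(set(g.neighbors(n))) for n in g.nodes}
    z = scores.z
    candidates: list[ActiveModule] = []
    for seed in sorted(z):
        if seed not in adj:
            continue
        module, total, k, cur = _grow_from_seed(seed, adj, z, calib, params, k_cap)
        candidates.append(
            ActiveModule(
                member_node_ids=frozenset(module),
                scored_k=k,
                raw_score=total / math.sqrt(k),
                corrected=cur,
                seed_id=seed,
                pathway_contributions=_pathway_contributions(module, network),
            )
        )
    candidates.sort(key=lambda m: (-m.corrected, len(m.member_node_ids), m.seed_id))
    return candidates


def module_overlap(a: frozenset, b: frozenset, measure: str = "min") -> float:
    inter = len(a & b)
    if measure == "min":
        denom = min(len(a), len(b))
    elif measure == "jaccard":
        denom = len(a | b)
    else:
        raise ValidationError(f"unknown overlap measure {measure!r}")
    return inter / denom if denom else 0.0


def select_modules(
    candidates: Sequence[ActiveModule], params: SearchParams
) -> list[ActiveModule]:
    """Accept candidates in rank order, rejecting any that overlaps an
    already-accepted module beyond the threshold; stop at n_modules."""
    params.validate()
    accepted: list[ActiveModule] = []
    for cand in candidates:
        if len(accepted) >= params.n_modules:
            break
        clash = any(
            module_overlap(
                cand.member_node_ids, acc.member_node_ids, params.overlap_measure
            )
            > params.overlap_threshold
            for acc in accepted
        )
        if not clash:
            accepted.append(cand)
    return accepted


# ---------------------------------------------------------------------------
# Exhaustive optimum for tiny instances


def scored_adjacency(
    network: UnifiedNetwork, scores: NodeZScores, radius: int
) -> dict[str, set[str]]:
    """Pairs of scored nodes joined by a path of length <= radius whose
    intermediate nodes are all unscored (connector-only paths)."""
    g = network.graph
    scored = scores.scored_set
    adj: dict[str, set[str]] = {n: set() for n in scored if n in g}
    for start in adj:
        dist = {start: 0}
        dq = deque([start])
        while dq:
            u = dq.popleft()
            du = dist[u]
            if du == radius:
                continue
            for v in g.neighbors(u):
                if v in dist:
                    continue
                dist[v] = du + 1
                if v in scored:
                    adj[start].add(v)
                    continue  # scored nodes terminate connector paths
                dq.append(v)
    return adj


def exhaustive_best(
    network: UnifiedNetwork,
    scores: NodeZScores,
    calib: CalibrationTable,
    params: SearchParams,
    max_scored: int = 12,
) -> tuple[float, frozenset]:
    """Brute-force optimum of the corrected score over all connected
    subsets of scored nodes (connectivity through connector-only paths
    within the search radius).  Only usable for tiny instances."""
    nodes = sorted(n for n in scores.scored_set if n in network.graph)
    if len(nodes) > max_scored:
        raise ValidationError(
            f"{len(nodes)} scored nodes exceed the exhaustive limit of {max_scored}"
        )
    adj = scored_adjacency(network, scores, 2 * params.search_depth)
    k_cap = min(params.max_module_scored, calib.k_max, len(nodes))
    best_score = -math.inf
    best_set: frozenset = frozenset()
    for k in range(1, k_cap + 1):
        for combo in combinations(nodes, k):
            cset = set(combo)
            # connectivity check via BFS on the scored-adjacency graph
            seen = {combo[0]}
            dq = deque([combo[0]])
            while dq:
                u = dq.popleft()
                for v in adj[u] & cset:
                    if v not in seen:
                        seen.add(v)
                        dq.append(v)
            if len(seen) != k:
                continue
            s = _corr(sum(scores.z[n] for n in combo), k, calib, params.sigma_floor)
            if s > best_score + 1e-15:
                best_score = s
                best_set = frozenset(combo)
    return best_score, best_set


# ---------------------------------------------------------------------------
# Reporting


@dataclass
class ModuleReport:
    rank: int
    n_members: int
    members_by_kind: dict[str, int]
    scored_k: int
    raw_score: float
    corrected: float
    pathway_contributions: dict[str, int]
    n_significant: int
    node_rows: list[dict]


def module_report(
    module: ActiveModule,
    network: UnifiedNetwork,
    criterion: Criterion | str,
    table: GeneStatTable,
    rank: int = 1,
    clamp_epsilon: float = DEFAULT_CLAMP_EPSILON,
) -> ModuleReport:
    """Per-module report: member counts by node kind, how many
    interactions each pathway contributed, the number of members passing
    the significance criterion, and a per-node attribute table."""
    if isinstance(criterion, str):
        criterion = Criterion.parse(criterion)
    g = network.graph
    kinds: Counter = Counter()
    rows = []
    n_sig = 0
    for n in sorted(module.member_node_ids):
        d = g.nodes[n]
        kinds[d["kind"]] += 1
        fc_p = table.stats.get(n) if d["kind"] == "gene_product" else None
        if fc_p is not None:
            fc, p = fc_p
            sig = criterion.evaluate(fc, p)
            n_sig += int(sig)
            rows.append(
                {
                    "node_id": n,
                    "kind": d["kind"],
                    "z": z_from_p(p, clamp_epsilon),
                    "log2fc": fc,
                    "pvalue": p,
                    "significant": sig,
                }
            )
        else:
            rows.append(
                {
                    "node_id": n,
                    "kind": d["kind"],
                    "z": None,
                    "log2fc": None,
                    "pvalue": None,
                    "significant": False,
                }
            )
    return ModuleReport(
        rank=rank,
        n_members=len(module.member_node_ids),
        members_by_kind=dict(kinds),
        scored_k=module.scored_k,
        raw_score=module.raw_score,
        corrected=module.corrected,
        pathway_contributions=_pathway_contributions(
            module.member_node_ids, network
        ),
        n_significant=n_sig,
        node_rows=rows,
    )


def write_module_tsv(report: ModuleReport, path: str | Path) -> None:
    lines = ["node_id\tkind\tz\tlog2fc\tpvalue\tsignificant"]
    for r in report.node_rows:
        fmt = lambda v: "-" if v is None else (repr(v) if isinstance(v, float) else str(v))
        lines.append(
            "\t".join(
                [r["node_id"], r["kind"], fmt(r["z"]), fmt(r["log2fc"]),
                 fmt(r["pvalue"]), str(int(r["significant"]))]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_modules_summary_tsv(
    reports: Sequence[ModuleReport], path: str | Path
) -> None:
    lines = [
        "rank\tcorrected_score\traw_score\tscored_k\tn_members\t"
        "n_gene_products\tn_interactions\tn_metabolites\tn_complexes\t"
        "n_significant\tn_pathways"
    ]
    for r in reports:
        kinds = r.members_by_kind
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    r.rank,
                    f"{r.corrected:.6f}",
                    f"{r.raw_score:.6f}",
                    r.scored_k,
                    r.n_members,
                    kinds.get("gene_product", 0),
                    kinds.get("interaction", 0),
                    kinds.get("metabolite", 0),
                    kinds.get("complex", 0),
                    r.n_significant,
                    len(r.pathway_contributions),
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_pathway_contributions_tsv(
    reports: Sequence[ModuleReport], path: str | Path
) -> None:
    lines = ["rank\tpathway_id\tn_interactions"]
    for r in reports:
        for pid in sorted(r.pathway_contributions):
            lines.append(f"{r.rank}\t{pid}\t{r.pathway_contributions[pid]}")
    Path(path).write_text("\n".join(lines) + "\n")
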
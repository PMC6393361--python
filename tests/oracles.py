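"""Independent reference implementations used as test oracles.

These deliberately favor clarity over speed and do not share code with
the package internals they check.
"""

from __future__ import annotations

import heapq
import math


def hypergeom_mean_var(N: int, R: int, n: int) -> tuple[float, float]:
    """Mean and variance of the changed count r by brute-force
    enumeration of the hypergeometric pmf (no closed forms)."""
    total = math.comb(N, n)
    mean = 0.0
    second = 0.0
    for r in range(max(0, n - (N - R)), min(n, R) + 1):
        p = math.comb(R, r) * math.comb(N - R, n - r) / total
        mean += r * p
        second += r * r * p
    return mean, second - mean * mean


def naive_module_labels(graph, module, z, radius):
    """From-scratch lexicographic shortest-path labels from a module:
    label(v) = (distance, #scored non-members on path incl. v, -z sum)."""
    labels = {}
    parent = {}
    heap = []
    for s in sorted(module):
        labels[s] = (0, 0, 0.0)
        parent[s] = None
        heapq.heappush(heap, ((0, 0, 0.0), s))
    while heap:
        lab, u = heapq.heappop(heap)
        if labels.get(u) != lab:
            continue
        d, cnt, negsum = lab
        if d == radius:
            continue
        for v in sorted(set(graph.neighbors(u))):
            if v in z and v not in module:
                new = (d + 1, cnt + 1, negsum - z[v])
            else:
                new = (d + 1, cnt, negsum)
            if new < labels.get(v, (radius + 1, 0, 0.0)):
                labels[v] = new
                parent[v] = u
                heapq.heappush(heap, (new, v))
    return labels, parent


def naive_greedy_from_seed(graph, z, mu, sigma, seed, radius, k_cap,
                           sigma_floor=1e-9):
    """Plain restatement of the greedy expansion: recompute all shortest
    labels from scratch at every step, evaluate every candidate, adopt
    the best jointly-scored addition while the corrected score rises."""

    def corr(total, k):
        return (total / math.sqrt(k) - mu[k]) / max(sigma[k], sigma_floor)

    module = {seed}
    total = z[seed]
    k = 1
    cur = corr(total, k)
    while k < k_cap:
        labels, parent = naive_module_labels(graph, module, z, radius)
        best, best_key = None, None
        for v in sorted(labels):
            if v in module or v not in z:
                continue
            dk = labels[v][1]
            if dk == 0 or k + dk > k_cap:
                continue
            key = (corr(total - labels[v][2], k + dk), -dk)
            if best is None or key > best_key or (key == best_key and v < best):
                best, best_key = v, key
        if best is None or best_key[0] <= cur + 1e-12:
            break
        node = best
        while node is not None and node not in module:
            module.add(node)
            node = parent[node]
        total -= labels[best][2]
        k += labels[best][1]
        cur = best_key[0]
    return module, total, k, cur


def naive_greedy_best(graph, z, mu, sigma, radius, k_cap, sigma_floor=1e-9):
    best = None
    for seed in sorted(z):
        if seed not in graph:
            continue
        module, total, k, cur = naive_greedy_from_seed(
            graph, z, mu, sigma, seed, radius, k_cap, sigma_floor
        )
        if best is None or cur > best[3]:
            best = (module, total, k, cur)
    return best
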
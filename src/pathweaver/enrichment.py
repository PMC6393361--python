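"""Gene-set overrepresentation analysis with a standardized-count
Z-score and label-permutation p-values.

For a background of N measured genes of which R are "changed" (per a
significance criterion), a set containing n measured genes with r of
them changed gets

    z = (r - n R / N) / sqrt( n (R/N) (1 - R/N) (1 - (n-1)/(N-1)) )

— the deviation of r from its hypergeometric expectation, in standard
deviations.  Significance is assessed empirically: the changed-gene
labels are redistributed uniformly over the background ``n_perm`` times
and the permutation p-value is the add-one-smoothed fraction of
permutations whose z reaches the observed one.  Each gene set draws its
own independent permutation stream so that p-values of different sets
are independent under the null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ParseError, ValidationError
from .expression_mapping import Criterion, GeneStatTable, evaluate_criterion


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: frozenset

    def __init__(self, set_id: str, name: str, members: Iterable[str]) -> None:
        object.__setattr__(self, "set_id", set_id)
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", frozenset(members))

    def validate(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.set_id!r} has no members")


@dataclass
class EnrichmentRow:
    set_id: str
    name: str
    N: int
    R: int
    n: int
    r: int
    z: Optional[float]
    perm_p: Optional[float]
    kept: bool = False

    @property
    def evaluable(self) -> bool:
        return self.z is not None


# ---------------------------------------------------------------------------
# GMT I/O


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Tab-separated gene-set file: set id, description, then members."""
    sets = []
    seen = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(
                f"{path}:{lineno}: GMT lines need id, description and at "
                "least one member"
            )
        set_id, name = parts[0], parts[1]
        if set_id in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate set id {set_id!r}")
        seen.add(set_id)
        gs = GeneSet(set_id, name, [m for m in parts[2:] if m])
        gs.validate()
        sets.append(gs)
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    lines = []
    for s in sets:
        lines.append("\t".join([s.set_id, s.name] + sorted(s.members)))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Statistic


def zscore(N: int, R: int, n: int, r: int) -> Optional[float]:
    """Overrepresentation Z-score; ``None`` when the variance is
    undefined (empty set in background, R = 0 or R = N, n = N)."""
    if not (0 <= R <= N and 0 <= n <= N and 0 <= r <= min(n, R)):
        raise ValidationError(f"invalid counts N={N} R={R} n={n} r={r}")
    if N < 2 or n == 0 or R == 0 or R == N:
        return None
    p = R / N
    var = n * p * (1.0 - p) * (1.0 - (n - 1) / (N - 1))
    if var <= 0.0:
        return None
    return (r - n * p) / math.sqrt(var)


def _perm_r_counts(
    member_mask: np.ndarray, R: int, n_perm: int, rng: np.random.Generator,
    chunk: int = 256,
) -> np.ndarray:
    """Changed-member counts of the set under n_perm uniform random
    R-subsets of the background (label permutations)."""
    N = member_mask.size
    if R == 0:
        return np.zeros(n_perm, dtype=np.int64)
    counts = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, N))
        idx = np.argpartition(keys, R - 1, axis=1)[:, :R]
        counts[done : done + m] = member_mask[idx].sum(axis=1)
        done += m
    return counts


def permutation_pvalue(
    gene_set: GeneSet,
    background: Sequence[str],
    changed: Iterable[str],
    n_perm: int = 2000,
    seed: int = 0,
) -> Optional[float]:
    """Add-one permutation p-value for one gene set.

    ``perm_p = (1 + #{permutations with z* >= observed z}) / (n_perm + 1)``.
    Because N, R and n are fixed across permutations, z* is a strictly
    increasing function of the permuted changed-member count r*, so the
    comparison is carried out on counts directly.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    bg = sorted(set(background))
    changed = set(changed) & set(bg)
    members = gene_set.members & set(bg)
    if not members:
        return None
    N, R = len(bg), len(changed)
    r_obs = len(members & changed)
    if zscore(N, R, len(members), r_obs) is None:
        return None
    mask = np.array([g in members for g in bg])
    rng = np.random.default_rng(seed)
    r_star = _perm_r_counts(mask, R, n_perm, rng)
    return float((1 + int((r_star >= r_obs).sum())) / (n_perm + 1))


def run_enrichment(
    sets: Sequence[GeneSet],
    table: GeneStatTable,
    criterion: Criterion | str,
    n_perm: int = 2000,
    seed: int = 0,
) -> list[EnrichmentRow]:
    """Overrepresentation analysis of every gene set against the measured
    background, sorted by z descending (non-evaluable sets last).

    The background is the full gene table; set members that were not
    measured are invisible to the statistic.
    """
    if len(table) == 0:
        raise ValidationError("gene table is empty")
    if isinstance(criterion, str):
        criterion = Criterion.parse(criterion)
    background = table.genes()
    bg_index = {g: i for i, g in enumerate(background)}
    changed = evaluate_criterion(criterion, table)
    N, R = len(background), len(changed)
    seeds = np.random.SeedSequence(seed).spawn(len(sets))
    rows: list[EnrichmentRow] = []
    for gs, ss in zip(sets, seeds):
        members = gs.members & bg_index.keys()
        n = len(members)
        r = len(members & changed)
        z = zscore(N, R, n, r)
        if z is None:
            rows.append(EnrichmentRow(gs.set_id, gs.name, N, R, n, r, None, None))
            continue
        mask = np.zeros(N, dtype=bool)
        mask[[bg_index[g] for g in members]] = True
        rng = np.random.default_rng(ss)
        r_star = _perm_r_counts(mask, R, n_perm, rng)
        perm_p = (1 + int((r_star >= r).sum())) / (n_perm + 1)
        rows.append(EnrichmentRow(gs.set_id, gs.name, N, R, n, r, z, perm_p))
    rows.sort(
        key=lambda row: (
            row.z is None,
            -(row.z if row.z is not None else 0.0),
            row.set_id,
        )
    )
    return rows


def filter_results(
    rows: Sequence[EnrichmentRow],
    z_min: float = 1.96,
    p_max: float = 0.05,
    min_changed: int = 5,
) -> list[EnrichmentRow]:
    """Keep rows with z > z_min, perm_p < p_max and at least
    ``min_changed`` changed genes; marks the ``kept`` flag on every row.
    ``min_changed=3`` gives the lenient variant used for exploratory
    heatmaps."""
    out = []
    for row in rows:
        row.kept = (
            row.z is not None
            and row.perm_p is not None
            and row.z > z_min
            and row.perm_p < p_max
            and row.r >= min_changed
        )
        if row.kept:
            out.append(row)
    return out


def write_enrichment_tsv(rows: Sequence[EnrichmentRow], path: str | Path) -> None:
    lines = ["set_id\tname\tN\tR\tn\tr\tz\tperm_p\tkept"]
    for row in rows:
        z = "-" if row.z is None else f"{row.z:.6f}"
        p = "-" if row.perm_p is None else f"{row.perm_p:.6f}"
        lines.append(
            f"{row.set_id}\t{row.name}\t{row.N}\t{row.R}\t{row.n}\t{row.r}\t"
            f"{z}\t{p}\t{int(row.kept)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
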
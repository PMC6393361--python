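"""Probe-level statistics: filtering, gene mapping/merging, significance
criteria, and network annotation.

The pipeline consumes the *output* of a differential-expression fit (one
log2 fold change and p-value per probe); model fitting itself happens
upstream.  Probes that were undetected in every sample are removed, the
remainder are mapped to gene identifiers, and multi-probe genes are
collapsed to a single statistic per gene.  Significance is expressed as
a boolean criterion over ``log2FC`` and ``pvalue`` — for example
``(log2FC < -0.58 OR log2FC > 0.58) AND pvalue < 0.05`` selects genes
with at least a 1.5-fold change at nominal significance.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import ParseError, ValidationError
from .network_builder import UnifiedNetwork

logger = logging.getLogger(__name__)

MERGE_RULES = ("min_p", "max_abs_fc")


@dataclass(frozen=True)
class ProbeStatRow:
    """One probe's differential-expression statistics.

    ``detected`` holds one boolean per sample (False encodes a detection
    p-value of 1, i.e. no evidence the probe was expressed); ``None``
    means no detection information is available for the probe.
    """

    probe_id: str
    log2_fold_change: float
    p_value: float
    detected: Optional[tuple[bool, ...]] = None

    def validate(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(
                f"probe {self.probe_id!r}: p_value {self.p_value} outside [0, 1]"
            )


@dataclass
class GeneStatTable:
    """Per-gene log2 fold change and p-value for one contrast."""

    stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    contrast_label: str = "contrast"

    def __len__(self) -> int:
        return len(self.stats)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.stats

    def genes(self) -> list[str]:
        return sorted(self.stats)

    def validate(self) -> None:
        for g, (_, p) in self.stats.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"gene {g!r}: p_value {p} outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g, fc, p) for g, (fc, p) in sorted(self.stats.items())],
            columns=["gene_id", "log2fc", "pvalue"],
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#contrast: {self.contrast_label}\n")
            fh.write("gene_id\tlog2fc\tpvalue\n")
            for g, (fc, p) in sorted(self.stats.items()):
                fh.write(f"{g}\t{fc!r}\t{p!r}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneStatTable":
        label = "contrast"
        stats: dict[str, tuple[float, float]] = {}
        for line in Path(path).read_text().splitlines():
            if line.startswith("#contrast:"):
                label = line.split(":", 1)[1].strip()
                continue
            if not line.strip() or line.startswith(("#", "gene_id\t")):
                continue
            g, fc, p = line.split("\t")
            stats[g] = (float(fc), float(p))
        table = cls(stats=stats, contrast_label=label)
        table.validate()
        return table


# ---------------------------------------------------------------------------
# Probe table / id map I/O


def read_probe_table(path: str | Path) -> list[ProbeStatRow]:
    """TSV columns: probe_id, log2fc, pvalue, then optional
    ``detected_<sample>`` boolean columns."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    required = {"probe_id", "log2fc", "pvalue"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: probe table must have columns {sorted(required)}"
        )
    det_cols = [c for c in df.columns if c.startswith("detected_")]
    rows = []
    for rec in df.itertuples(index=False):
        detected = None
        if det_cols:
            detected = tuple(
                bool(int(getattr(rec, c))) if not isinstance(getattr(rec, c), bool)
                else getattr(rec, c)
                for c in det_cols
            )
        row = ProbeStatRow(
            probe_id=rec.probe_id,
            log2_fold_change=float(rec.log2fc),
            p_value=float(rec.pvalue),
            detected=detected,
        )
        row.validate()
        rows.append(row)
    return rows


def write_probe_table(rows: Sequence[ProbeStatRow], path: str | Path) -> None:
    n_samples = 0
    for r in rows:
        if r.detected is not None:
            n_samples = max(n_samples, len(r.detected))
    header = ["probe_id", "log2fc", "pvalue"] + [
        f"detected_s{i+1}" for i in range(n_samples)
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            det = r.detected or ()
            flags = [str(int(det[i])) if i < len(det) else "1" for i in range(n_samples)]
            fh.write(
                "\t".join([r.probe_id, repr(r.log2_fold_change), repr(r.p_value)] + flags)
                + "\n"
            )


def read_idmap(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV ``probe_id<TAB>gene_id``; repeated probe rows encode
    multi-mapping probes."""
    idmap: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#") or line.startswith("probe_id\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        probe, gene = parts
        if not gene:
            raise ValidationError(f"{path}:{lineno}: empty gene id")
        idmap.setdefault(probe, set()).add(gene)
    return idmap


def write_idmap(idmap: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tgene_id\n")
        for probe in sorted(idmap):
            for gene in sorted(idmap[probe]):
                fh.write(f"{probe}\t{gene}\n")


# ---------------------------------------------------------------------------
# Filtering and merging


def filter_undetected(probes: Sequence[ProbeStatRow]) -> list[ProbeStatRow]:
    """Drop probes undetected in every sample (overall absence of
    expression).  If no probe carries detection flags the filter is a
    no-op and a warning is logged."""
    if all(r.detected is None for r in probes):
        if probes:
            logger.warning(
                "no detection flags present; undetected-probe filter skipped"
            )
        return list(probes)
    kept = [
        r for r in probes if r.detected is None or any(r.detected)
    ]
    removed = len(probes) - len(kept)
    logger.info("filter_undetected: removed %d of %d probes", removed, len(probes))
    return kept


def map_and_merge(
    probes: Sequence[ProbeStatRow],
    idmap: Mapping[str, set[str]],
    merge_rule: str = "min_p",
    contrast_label: str = "contrast",
) -> GeneStatTable:
    """Map probes to genes and collapse multi-probe genes to one row.

    A probe mapping to several genes contributes to each of them;
    unmapped probes are dropped.  ``min_p`` keeps the most significant
    probe per gene (ties: larger |log2FC|, then lexicographic probe id);
    ``max_abs_fc`` keeps the strongest fold change (ties: smaller p,
    then probe id).
    """
    if merge_rule not in MERGE_RULES:
        raise ValidationError(f"unknown merge_rule {merge_rule!r}")
    if not idmap:
        logger.warning("empty id map: gene table will be empty")
    per_gene: dict[str, ProbeStatRow] = {}

    def better(a: ProbeStatRow, b: ProbeStatRow) -> ProbeStatRow:
        if merge_rule == "min_p":
            ka = (a.p_value, -abs(a.log2_fold_change), a.probe_id)
            kb = (b.p_value, -abs(b.log2_fold_change), b.probe_id)
        else:
            ka = (-abs(a.log2_fold_change), a.p_value, a.probe_id)
            kb = (-abs(b.log2_fold_change), b.p_value, b.probe_id)
        return a if ka <= kb else b

    n_unmapped = 0
    for row in probes:
        genes = idmap.get(row.probe_id)
        if not genes:
            n_unmapped += 1
            continue
        for gene in genes:
            cur = per_gene.get(gene)
            per_gene[gene] = row if cur is None else better(cur, row)
    logger.info(
        "map_and_merge: %d probes unmapped, %d genes", n_unmapped, len(per_gene)
    )
    table = GeneStatTable(
        stats={
            g: (r.log2_fold_change, r.p_value) for g, r in sorted(per_gene.items())
        },
        contrast_label=contrast_label,
    )
    table.validate()
    return table


# ---------------------------------------------------------------------------
# Criterion language


_VARIABLES = {"log2fc": "log2FC", "pvalue": "pvalue"}

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<op><=|>=|==|<|>|=)"
    r"|(?P<num>[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)"
    r"|(?P<word>[A-Za-z_][A-Za-z0-9_]*))"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    # Normalize unicode dashes and the hyphenated 'p-value' spelling.
    text = text.replace("–", "-").replace("−", "-")
    text = re.sub(r"\bp-value\b", "pvalue", text, flags=re.IGNORECASE)
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ParseError(f"criterion syntax error at position {pos}: {text[pos:]!r}")
        pos = m.end()
        for kind in ("lpar", "rpar", "op", "num", "word"):
            val = m.group(kind)
            if val is not None:
                tokens.append((kind, val, m.start(kind)))
                break
    return tokens


class Criterion:
    """A boolean expression over per-gene statistics.

    Variables: ``log2FC`` and ``pvalue`` (the spelling ``p-value`` is
    accepted as an alias).  Operators: ``< > <= >= =`` combined with
    AND/OR/NOT and parentheses.  Comparisons are strict or non-strict
    exactly as written.
    """

    def __init__(self, text: str, ast) -> None:
        self.text = text
        self._ast = ast

    def __repr__(self) -> str:
        return f"Criterion({self.text!r})"

    @classmethod
    def parse(cls, text: str) -> "Criterion":
        tokens = _tokenize(text)
        idx = 0

        def peek():
            return tokens[idx] if idx < len(tokens) else (None, None, len(text))

        def advance():
            nonlocal idx
            tok = peek()
            idx += 1
            return tok

        def parse_or():
            node = parse_and()
            while peek()[0] == "word" and peek()[1].upper() == "OR":
                advance()
                node = ("or", node, parse_and())
            return node

        def parse_and():
            node = parse_not()
            while peek()[0] == "word" and peek()[1].upper() == "AND":
                advance()
                node = ("and", node, parse_not())
            return node

        def parse_not():
            if peek()[0] == "word" and peek()[1].upper() == "NOT":
                advance()
                return ("not", parse_not())
            return parse_atom()

        def parse_atom():
            kind, val, pos = peek()
            if kind == "lpar":
                advance()
                node = parse_or()
                if peek()[0] != "rpar":
                    raise ParseError(
                        f"criterion: expected ')' at position {peek()[2]}"
                    )
                advance()
                return node
            return parse_comparison()

        def parse_operand():
            kind, val, pos = advance()
            if kind == "num":
                return ("num", float(val))
            if kind == "word":
                canon = _VARIABLES.get(val.lower())
                if canon is None:
                    raise ValidationError(
                        f"criterion: unknown variable {val!r} at position {pos}"
                    )
                return ("var", canon)
            raise ParseError(
                f"criterion: expected variable or number at position {pos}"
            )

        def parse_comparison():
            left = parse_operand()
            kind, op, pos = advance()
            if kind != "op":
                raise ParseError(f"criterion: expected comparison at position {pos}")
            right = parse_operand()
            if left[0] == right[0]:
                raise ParseError(
                    "criterion: comparison must relate one variable to one "
                    f"number (position {pos})"
                )
            if left[0] == "num":
                flip = {"<": ">", ">": "<", "<=": ">=", ">=": "<="}
                op = flip.get(op, op)
                left, right = right, left
            return ("cmp", left[1], "=" if op == "==" else op, right[1])

        node = parse_or()
        if idx != len(tokens):
            raise ParseError(
                f"criterion: unexpected token {tokens[idx][1]!r} at position "
                f"{tokens[idx][2]}"
            )
        return cls(text, node)

    def evaluate(self, log2fc: float, pvalue: float) -> bool:
        """Evaluate for one gene; NaN statistics never satisfy anything."""
        if math.isnan(log2fc) or math.isnan(pvalue):
            return False
        env = {"log2FC": log2fc, "pvalue": pvalue}

        def ev(node) -> bool:
            tag = node[0]
            if tag == "cmp":
                _, var, op, num = node
                x = env[var]
                return {
                    "<": x < num,
                    ">": x > num,
                    "<=": x <= num,
                    ">=": x >= num,
                    "=": x == num,
                }[op]
            if tag == "and":
                return ev(node[1]) and ev(node[2])
            if tag == "or":
                return ev(node[1]) or ev(node[2])
            if tag == "not":
                return not ev(node[1])
            raise AssertionError(node)

        return ev(self._ast)


def evaluate_criterion(criterion: Criterion | str, table: GeneStatTable) -> set[str]:
    """Gene ids in the table whose statistics satisfy the criterion."""
    if isinstance(criterion, str):
        criterion = Criterion.parse(criterion)
    return {
        g for g, (fc, p) in table.stats.items() if criterion.evaluate(fc, p)
    }


# ---------------------------------------------------------------------------
# Network annotation


def annotate_network(
    network: UnifiedNetwork, table: GeneStatTable
) -> UnifiedNetwork:
    """Attach per-gene statistics to gene-product nodes as attributes
    labelled by contrast; every other node (and unmatched gene products)
    gets an explicit "not measured" marker for that contrast.  Several
    contrasts can be annotated in sequence."""
    label = table.contrast_label
    g = network.graph
    n_matched = 0
    for n, d in g.nodes(data=True):
        if d["kind"] == "gene_product" and n in table.stats:
            fc, p = table.stats[n]
            d[f"log2fc__{label}"] = float(fc)
            d[f"p__{label}"] = float(p)
            d[f"measured__{label}"] = True
            n_matched += 1
        else:
            d[f"measured__{label}"] = False
    if n_matched == 0 and len(table) > 0 and g.number_of_nodes() > 0:
        raise ValidationError(
            f"no gene-product node matched the {label!r} table: likely an "
            "identifier-namespace mismatch"
        )
    logger.info("annotate_network[%s]: %d nodes annotated", label, n_matched)
    return network
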
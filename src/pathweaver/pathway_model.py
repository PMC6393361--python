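"""Pathway-collection interchange format.

A pathway collection is a set of pathway models plus their interaction
records.  Each interaction record carries a type (directed, catalysis,
inhibition, conversion, complex participation, or undirected) and an
ordered list of typed, role-tagged participants.  Participants are
namespaced identifiers: gene products use Ensembl-style identifiers
(``ensembl:...``), metabolites ChEBI/Wikidata/HMDB-style identifiers
(``chebi:...``), and complexes Reactome-style identifiers
(``reactome:...``).  Namespace prefixes are treated as opaque strings;
no identifier resolution is performed.

Two on-disk dialects are supported:

* JSON (canonical): a single object with ``pathways`` and
  ``interactions`` arrays.
* TSV (flat): one row per (interaction, participant) with columns
  ``pathway_id, interaction_local_id, interaction_type, participant_id,
  participant_kind, role``.  Pathway metadata (title, source database)
  is carried on ``#pathway:`` comment lines so that the two dialects
  round-trip to equal collections; TSV files from other tools without
  those comments still parse, with the pathway id doubling as its title.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ParseError, ValidationError

DIRECTED_TYPES = frozenset({"directed", "catalysis", "inhibition", "conversion"})
UNDIRECTED_TYPES = frozenset({"complex_participation", "undirected"})
INTERACTION_TYPES = DIRECTED_TYPES | UNDIRECTED_TYPES

ENTITY_KINDS = ("gene_product", "metabolite", "complex")
ROLES = ("source", "target", "participant")
SOURCE_DBS = ("wikipathways", "reactome", "synthetic")

_TSV_COLUMNS = (
    "pathway_id",
    "interaction_local_id",
    "interaction_type",
    "participant_id",
    "participant_kind",
    "role",
)


@dataclass(frozen=True)
class ParticipantRef:
    """One participant of an interaction record."""

    entity_id: str
    entity_kind: str
    role: str

    def validate(self) -> None:
        if not self.entity_id:
            raise ValidationError("participant entity_id must be non-empty")
        prefix, sep, rest = self.entity_id.partition(":")
        if not sep or not prefix or not rest:
            raise ValidationError(
                f"entity_id {self.entity_id!r} must carry a namespace prefix "
                "separated by ':'"
            )
        if self.entity_kind not in ENTITY_KINDS:
            raise ValidationError(
                f"unknown entity_kind {self.entity_kind!r} for {self.entity_id!r}"
            )
        if self.role not in ROLES:
            raise ValidationError(
                f"unknown role {self.role!r} for {self.entity_id!r}"
            )


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    title: str
    source_db: str = "synthetic"

    def validate(self) -> None:
        if not self.pathway_id:
            raise ValidationError("pathway_id must be non-empty")
        if self.source_db not in SOURCE_DBS:
            raise ValidationError(
                f"pathway {self.pathway_id!r}: unknown source_db {self.source_db!r}"
            )


@dataclass(frozen=True)
class InteractionRecord:
    """A single raw interaction as stated by one pathway model.

    ``local_id`` is unique within its pathway only; deduplication across
    pathways happens at network-build time, not here.
    """

    local_id: str
    interaction_type: str
    participants: tuple[ParticipantRef, ...]
    pathway_id: str

    def __init__(
        self,
        local_id: str,
        interaction_type: str,
        participants: Sequence[ParticipantRef],
        pathway_id: str,
    ) -> None:
        object.__setattr__(self, "local_id", local_id)
        object.__setattr__(self, "interaction_type", interaction_type)
        object.__setattr__(self, "participants", tuple(participants))
        object.__setattr__(self, "pathway_id", pathway_id)

    def validate(self) -> None:
        if self.interaction_type not in INTERACTION_TYPES:
            raise ValidationError(
                f"interaction {self.pathway_id}/{self.local_id}: unknown "
                f"interaction_type {self.interaction_type!r}"
            )
        if len(self.participants) < 1:
            raise ValidationError(
                f"interaction {self.pathway_id}/{self.local_id}: needs at "
                "least one participant"
            )
        roles = Counter(p.role for p in self.participants)
        directed = self.interaction_type in DIRECTED_TYPES
        for p in self.participants:
            p.validate()
            if directed and p.role == "participant":
                raise ValidationError(
                    f"interaction {self.pathway_id}/{self.local_id}: role "
                    f"'participant' is not allowed in directed type "
                    f"{self.interaction_type!r}"
                )
            if not directed and p.role in ("source", "target"):
                raise ValidationError(
                    f"interaction {self.pathway_id}/{self.local_id}: role "
                    f"{p.role!r} is only allowed in directed interaction types"
                )
        if directed and (roles["source"] < 1 or roles["target"] < 1):
            raise ValidationError(
                f"interaction {self.pathway_id}/{self.local_id}: directed "
                "types need at least one source and one target participant"
            )


@dataclass
class PathwayCollection:
    """A set of pathway models with their interaction records."""

    pathways: list[Pathway] = field(default_factory=list)
    interactions: list[InteractionRecord] = field(default_factory=list)

    def validate(self) -> None:
        ids = [p.pathway_id for p in self.pathways]
        dup = [i for i, c in Counter(ids).items() if c > 1]
        if dup:
            raise ValidationError(f"duplicate pathway_id values: {sorted(dup)}")
        for p in self.pathways:
            p.validate()
        known = set(ids)
        seen_local: set[tuple[str, str]] = set()
        for rec in self.interactions:
            rec.validate()
            if rec.pathway_id not in known:
                raise ValidationError(
                    f"interaction {rec.local_id!r} references unknown pathway "
                    f"{rec.pathway_id!r}"
                )
            key = (rec.pathway_id, rec.local_id)
            if key in seen_local:
                raise ValidationError(
                    f"duplicate local_id {rec.local_id!r} in pathway "
                    f"{rec.pathway_id!r}"
                )
            seen_local.add(key)

    # -- order-insensitive equality -------------------------------------
    def _canonical(self):
        paths = frozenset(self.pathways)
        inter = Counter(
            (
                r.pathway_id,
                r.local_id,
                r.interaction_type,
                frozenset(Counter(r.participants).items()),
            )
            for r in self.interactions
        )
        return paths, frozenset(inter.items())

    def equivalent(self, other: "PathwayCollection") -> bool:
        """Structural equality up to ordering of pathways, records and
        participants."""
        return self._canonical() == other._canonical()

    @property
    def pathway_ids(self) -> list[str]:
        return [p.pathway_id for p in self.pathways]


# ---------------------------------------------------------------------------
# JSON dialect


def _collection_to_json_obj(collection: PathwayCollection) -> dict:
    return {
        "pathways": [
            {"id": p.pathway_id, "title": p.title, "source_db": p.source_db}
            for p in collection.pathways
        ],
        "interactions": [
            {
                "pathway": r.pathway_id,
                "local_id": r.local_id,
                "type": r.interaction_type,
                "participants": [
                    {"id": q.entity_id, "kind": q.entity_kind, "role": q.role}
                    for q in r.participants
                ],
            }
            for r in collection.interactions
        ],
    }


def _collection_from_json_obj(obj: dict) -> PathwayCollection:
    try:
        pathways = [
            Pathway(p["id"], p.get("title", p["id"]), p.get("source_db", "synthetic"))
            for p in obj["pathways"]
        ]
        interactions = [
            InteractionRecord(
                local_id=r["local_id"],
                interaction_type=r["type"],
                participants=[
                    ParticipantRef(q["id"], q["kind"], q["role"])
                    for q in r["participants"]
                ],
                pathway_id=r["pathway"],
            )
            for r in obj["interactions"]
        ]
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed collection JSON: missing field {exc}") from exc
    return PathwayCollection(pathways, interactions)


# ---------------------------------------------------------------------------
# TSV dialect


def _collection_to_tsv_lines(collection: PathwayCollection) -> Iterable[str]:
    for p in collection.pathways:
        yield f"#pathway:\t{p.pathway_id}\t{p.title}\t{p.source_db}"
    yield "\t".join(_TSV_COLUMNS)
    for r in collection.interactions:
        for q in r.participants:
            yield "\t".join(
                (
                    r.pathway_id,
                    r.local_id,
                    r.interaction_type,
                    q.entity_id,
                    q.entity_kind,
                    q.role,
                )
            )


def _collection_from_tsv_lines(lines: Iterable[str]) -> PathwayCollection:
    pathways: dict[str, Pathway] = {}
    # (pathway_id, local_id) -> (type, [participants]), insertion ordered
    records: dict[tuple[str, str], tuple[str, list[ParticipantRef]]] = {}
    header_seen = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#pathway:"):
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(
                    f"line {lineno}: malformed #pathway: comment (expected "
                    "4 tab-separated fields)"
                )
            _, pid, title, source_db = parts
            pathways[pid] = Pathway(pid, title, source_db)
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if not header_seen:
            if tuple(cols) != _TSV_COLUMNS:
                raise ParseError(
                    f"line {lineno}: expected header {_TSV_COLUMNS}, got {cols}"
                )
            header_seen = True
            continue
        if len(cols) != len(_TSV_COLUMNS):
            raise ParseError(
                f"line {lineno}: expected {len(_TSV_COLUMNS)} columns, got "
                f"{len(cols)}"
            )
        pid, local_id, itype, eid, kind, role = cols
        if pid not in pathways:
            pathways[pid] = Pathway(pid, pid, "synthetic")
        key = (pid, local_id)
        if key not in records:
            records[key] = (itype, [])
        elif records[key][0] != itype:
            raise ParseError(
                f"line {lineno}: interaction {pid}/{local_id} has conflicting "
                f"types {records[key][0]!r} and {itype!r}"
            )
        records[key][1].append(ParticipantRef(eid, kind, role))
    interactions = [
        InteractionRecord(local_id, itype, parts, pid)
        for (pid, local_id), (itype, parts) in records.items()
    ]
    return PathwayCollection(list(pathways.values()), interactions)


# ---------------------------------------------------------------------------
# Public I/O


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("json", "tsv"):
            raise ValidationError(f"unknown collection format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    raise ValidationError(
        f"cannot infer collection format from {path.name!r}; pass format="
    )


def read_collection(path: str | Path, format: str | None = None) -> PathwayCollection:
    """Read and validate a pathway collection from JSON or TSV."""
    path = Path(path)
    fmt = _infer_format(path, format)
    text = path.read_text()
    if fmt == "json":
        try:
            obj = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON: {exc}") from exc
        collection = _collection_from_json_obj(obj)
    else:
        collection = _collection_from_tsv_lines(text.splitlines())
    collection.validate()
    return collection


def write_collection(
    collection: PathwayCollection, path: str | Path, format: str | None = None
) -> None:
    """Write a validated collection; the emitted file re-reads to an
    equivalent collection in either dialect."""
    collection.validate()
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        path.write_text(json.dumps(_collection_to_json_obj(collection), indent=1) + "\n")
    else:
        path.write_text("\n".join(_collection_to_tsv_lines(collection)) + "\n")
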
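"""Entity model for a pathway/genome database (PGDB) and flat-file I/O.

A PGDB bundles the genes, proteins, reactions, compounds and pathways of one
metabolic pathway resource (e.g. an organism-specific BioCyc database).  The
on-disk representation is a minimal attribute-value dialect of the BioCyc
flat-file format:

* one ``SLOT - VALUE`` pair per line;
* records terminated by a line containing exactly ``//``;
* repeated slots accumulate into sets;
* continuation lines beginning with ``/`` are appended to the previous value.

Identifiers (frame IDs such as ``PWY-7115`` or ``RXN-13697``) are
case-sensitive and matched exactly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

GO_TERM_RE = re.compile(r"^GO:\d{7}$")
_EC_FIELD_RE = re.compile(r"^(\d+|-)$")

COMPOUND_KINDS = ("small-molecule", "macromolecule", "element")


class PgdbParseError(ValueError):
    """Raised on a malformed flat-file record (missing or duplicate UNIQUE-ID)."""


class InvalidECError(ValueError):
    """Raised when a string cannot be normalized to a four-field EC number."""


def normalize_ec(raw: str) -> str:
    """Normalize an Enzyme Commission number to the four-field form.

    Strips an optional ``EC-`` or ``EC `` prefix and pads missing trailing
    fields with ``-``.  Each field must be a positive integer or ``-``; the
    top-level class may be 1-7 (translocases, class 7, are accepted even
    though older resources predate them).

    >>> normalize_ec("EC-1.1.1.1")
    '1.1.1.1'
    >>> normalize_ec("3.4")
    '3.4.-.-'
    """
    if not raw or not raw.strip():
        raise InvalidECError("empty EC string")
    s = raw.strip()
    for prefix in ("EC-", "EC "):
        if s.startswith(prefix):
            s = s[len(prefix):].strip()
            break
    fields = s.split(".")
    if len(fields) > 4:
        raise InvalidECError(f"more than four fields in EC number: {raw!r}")
    for f in fields:
        if not _EC_FIELD_RE.match(f):
            raise InvalidECError(f"invalid EC field {f!r} in {raw!r}")
        if f != "-" and int(f) == 0:
            raise InvalidECError(f"EC fields are positive integers: {raw!r}")
    fields += ["-"] * (4 - len(fields))
    return ".".join(fields)


def ec_top_level_class(ec_number: str | None) -> int | None:
    """Top-level EC class (the integer before the first dot), or None."""
    if ec_number is None:
        return None
    head = ec_number.split(".", 1)[0]
    if head == "-":
        return None
    return int(head)


@dataclass
class Gene:
    gene_id: str
    protein_ids: set[str] = field(default_factory=set)
    go_terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        for term in self.go_terms:
            if not GO_TERM_RE.match(term):
                raise ValueError(f"malformed GO term {term!r} on gene {self.gene_id}")


@dataclass
class Protein:
    protein_id: str
    gene_id: str
    catalyzed_reaction_ids: set[str] = field(default_factory=set)


@dataclass
class Reaction:
    reaction_id: str
    ec_number: str | None = None
    substrate_ids: set[str] = field(default_factory=set)
    product_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.ec_number is not None:
            self.ec_number = normalize_ec(self.ec_number)


@dataclass
class Compound:
    compound_id: str
    kind: str = "small-molecule"

    def __post_init__(self) -> None:
        if self.kind not in COMPOUND_KINDS:
            raise ValueError(
                f"compound {self.compound_id}: kind must be one of {COMPOUND_KINDS}, "
                f"got {self.kind!r}"
            )


@dataclass
class Pathway:
    pathway_id: str
    reaction_ids: set[str] = field(default_factory=set)


@dataclass
class Pgdb:
    """One pathway/genome database: identifier-keyed entity collections.

    ``diagnostics`` records unresolved cross-references found at parse or
    validation time; it is empty iff the database is referentially intact.
    """

    name: str = ""
    genes: dict[str, Gene] = field(default_factory=dict)
    proteins: dict[str, Protein] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    compounds: dict[str, Compound] = field(default_factory=dict)
    pathways: dict[str, Pathway] = field(default_factory=dict)
    diagnostics: list[str] = field(default_factory=list)

    def referential_diagnostics(self) -> list[str]:
        """All unresolved cross-references, as human-readable strings."""
        out: list[str] = []
        for p in self.proteins.values():
            if p.gene_id not in self.genes:
                out.append(f"protein {p.protein_id}: unresolved gene {p.gene_id}")
            for rid in sorted(p.catalyzed_reaction_ids):
                if rid not in self.reactions:
                    out.append(f"protein {p.protein_id}: unresolved reaction {rid}")
        for g in self.genes.values():
            for pid in sorted(g.protein_ids):
                if pid not in self.proteins:
                    out.append(f"gene {g.gene_id}: unresolved protein {pid}")
        for r in self.reactions.values():
            for cid in sorted(r.substrate_ids | r.product_ids):
                if cid not in self.compounds:
                    out.append(f"reaction {r.reaction_id}: unresolved compound {cid}")
        for pw in self.pathways.values():
            for rid in sorted(pw.reaction_ids):
                if rid not in self.reactions:
                    out.append(f"pathway {pw.pathway_id}: unresolved reaction {rid}")
        return out

    def is_consistent(self) -> bool:
        return not self.referential_diagnostics()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pgdb):
            return NotImplemented
        return (
            self.genes == other.genes
            and self.proteins == other.proteins
            and self.reactions == other.reactions
            and self.compounds == other.compounds
            and self.pathways == other.pathways
        )


# ---------------------------------------------------------------------------
# flat-file dialect


def _parse_records(path: Path) -> list[dict[str, list[str]]]:
    """Parse one .dat file into a list of slot→values records."""
    records: list[dict[str, list[str]]] = []
    current: dict[str, list[str]] = {}
    last_slot: str | None = None
    seen_any = False
    with open(path, encoding="utf-8", newline=None) as fh:
        for raw_line in fh:
            line = raw_line.rstrip("\n").rstrip("\r")
            if line == "//":
                if seen_any:
                    records.append(current)
                current, last_slot, seen_any = {}, None, False
                continue
            if not line.strip():
                continue
            if line.startswith("/"):
                # continuation of the previous value
                if last_slot is None or not current.get(last_slot):
                    raise PgdbParseError(
                        f"{path.name}: continuation line with no preceding slot: {line!r}"
                    )
                current[last_slot][-1] += line[1:]
                continue
            if " - " not in line:
                raise PgdbParseError(f"{path.name}: malformed line {line!r}")
            slot, value = line.split(" - ", 1)
            slot = slot.strip()
            current.setdefault(slot, []).append(value.strip())
            last_slot = slot
            seen_any = True
    if seen_any:
        records.append(current)
    return records


def _unique_ids(records: list[dict[str, list[str]]], fname: str) -> list[str]:
    ids: list[str] = []
    seen: set[str] = set()
    for i, rec in enumerate(records):
        vals = rec.get("UNIQUE-ID", [])
        if not vals:
            raise PgdbParseError(f"{fname}: record {i} has no UNIQUE-ID")
        uid = vals[0]
        if uid in seen:
            raise PgdbParseError(f"{fname}: duplicate UNIQUE-ID {uid!r}")
        seen.add(uid)
        ids.append(uid)
    return ids


_KNOWN_SLOTS = {
    "genes.dat": {"UNIQUE-ID", "PRODUCT", "GO-TERMS"},
    "proteins.dat": {"UNIQUE-ID", "GENE", "CATALYZES"},
    "reactions.dat": {"UNIQUE-ID", "EC-NUMBER", "LEFT", "RIGHT"},
    "compounds.dat": {"UNIQUE-ID", "KIND"},
    "pathways.dat": {"UNIQUE-ID", "REACTION-LIST"},
}


def _warn_unknown(fname: str, rec: dict[str, list[str]]) -> None:
    for slot in rec:
        if slot not in _KNOWN_SLOTS[fname]:
            logger.warning("%s: ignoring unknown slot %s", fname, slot)


def parse_pgdb(directory: str | Path, name: str | None = None) -> Pgdb:
    """Read a PGDB from a directory of ``.dat`` flat files.

    Any of genes.dat, proteins.dat, reactions.dat, compounds.dat and
    pathways.dat may be absent.  Cross-references that do not resolve are
    collected into ``Pgdb.diagnostics`` rather than dropped.
    """
    directory = Path(directory)
    pgdb = Pgdb(name=name if name is not None else directory.name)

    path = directory / "genes.dat"
    if path.exists():
        records = _parse_records(path)
        for uid, rec in zip(_unique_ids(records, path.name), records):
            _warn_unknown(path.name, rec)
            pgdb.genes[uid] = Gene(
                gene_id=uid,
                protein_ids=set(rec.get("PRODUCT", [])),
                go_terms=set(rec.get("GO-TERMS", [])),
            )

    path = directory / "proteins.dat"
    if path.exists():
        records = _parse_records(path)
        for uid, rec in zip(_unique_ids(records, path.name), records):
            _warn_unknown(path.name, rec)
            gene_vals = rec.get("GENE", [""])
            pgdb.proteins[uid] = Protein(
                protein_id=uid,
                gene_id=gene_vals[0],
                catalyzed_reaction_ids=set(rec.get("CATALYZES", [])),
            )

    path = directory / "reactions.dat"
    if path.exists():
        records = _parse_records(path)
        for uid, rec in zip(_unique_ids(records, path.name), records):
            _warn_unknown(path.name, rec)
            ec_vals = rec.get("EC-NUMBER", [])
            pgdb.reactions[uid] = Reaction(
                reaction_id=uid,
                ec_number=ec_vals[0] if ec_vals else None,
                substrate_ids=set(rec.get("LEFT", [])),
                product_ids=set(rec.get("RIGHT", [])),
            )

    path = directory / "compounds.dat"
    if path.exists():
        records = _parse_records(path)
        for uid, rec in zip(_unique_ids(records, path.name), records):
            _warn_unknown(path.name, rec)
            kind_vals = rec.get("KIND", ["small-molecule"])
            pgdb.compounds[uid] = Compound(compound_id=uid, kind=kind_vals[0])

    path = directory / "pathways.dat"
    if path.exists():
        records = _parse_records(path)
        for uid, rec in zip(_unique_ids(records, path.name), records):
            _warn_unknown(path.name, rec)
            pgdb.pathways[uid] = Pathway(
                pathway_id=uid, reaction_ids=set(rec.get("REACTION-LIST", []))
            )

    pgdb.diagnostics = pgdb.referential_diagnostics()
    return pgdb


def _write_records(path: Path, rows: Iterable[list[tuple[str, str]]]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in rows:
            for slot, value in rec:
                fh.write(f"{slot} - {value}\n")
            fh.write("//\n")


def write_pgdb(pgdb: Pgdb, directory: str | Path) -> None:
    """Write a PGDB back to the flat-file dialect (deterministic ordering)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    _write_records(
        directory / "genes.dat",
        (
            [("UNIQUE-ID", g.gene_id)]
            + [("PRODUCT", p) for p in sorted(g.protein_ids)]
            + [("GO-TERMS", t) for t in sorted(g.go_terms)]
            for g in (pgdb.genes[k] for k in sorted(pgdb.genes))
        ),
    )
    _write_records(
        directory / "proteins.dat",
        (
            [("UNIQUE-ID", p.protein_id), ("GENE", p.gene_id)]
            + [("CATALYZES", r) for r in sorted(p.catalyzed_reaction_ids)]
            for p in (pgdb.proteins[k] for k in sorted(pgdb.proteins))
        ),
    )
    _write_records(
        directory / "reactions.dat",
        (
            [("UNIQUE-ID", r.reaction_id)]
            + ([("EC-NUMBER", r.ec_number)] if r.ec_number is not None else [])
            + [("LEFT", c) for c in sorted(r.substrate_ids)]
            + [("RIGHT", c) for c in sorted(r.product_ids)]
            for r in (pgdb.reactions[k] for k in sorted(pgdb.reactions))
        ),
    )
    _write_records(
        directory / "compounds.dat",
        (
            [("UNIQUE-ID", c.compound_id), ("KIND", c.kind)]
            for c in (pgdb.compounds[k] for k in sorted(pgdb.compounds))
        ),
    )
    _write_records(
        directory / "pathways.dat",
        (
            [("UNIQUE-ID", pw.pathway_id)]
            + [("REACTION-LIST", r) for r in sorted(pw.reaction_ids)]
            for pw in (pgdb.pathways[k] for k in sorted(pgdb.pathways))
        ),
    )
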
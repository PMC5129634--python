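"""Per-pathway gene–reaction pairing matrix comparing two resources.

For one pathway, the matrix records for every (gene, reaction) pair which of
the two resources asserts the catalytic link — the kind of display used to
contrast, e.g., the C4 photosynthesis pathway (PWY-7115) between two maize
databases, where one resource predicts enzymes for reactions the other
leaves orphaned.

A gene pairs with a reaction in resource X iff some protein (isoform) of that
gene in X catalyzes the reaction; isoform-level links are collapsed to the
gene.  Cells take one of four codes: ``absent``, ``a_only``, ``b_only``,
``both`` (TSV shorthand ``.``, ``c``, ``m``, ``cm``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .pgdb import Pgdb

CELL_CODES = ("absent", "a_only", "b_only", "both")
TSV_CODES = {"absent": ".", "a_only": "c", "b_only": "m", "both": "cm"}


class PathwayNotFoundError(KeyError):
    """The requested pathway exists in neither resource."""


@dataclass
class PairingMatrix:
    pathway_id: str
    reaction_ids: list[str]  # columns, sorted
    gene_ids: list[str]      # rows, sorted; only genes with ≥1 non-absent cell
    cells: dict[tuple[str, str], str]  # (gene_id, reaction_id) -> cell code

    def cell(self, gene_id: str, reaction_id: str) -> str:
        return self.cells[(gene_id, reaction_id)]

    def count(self, code: str) -> int:
        return sum(1 for v in self.cells.values() if v == code)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["gene_id\t" + "\t".join(self.reaction_ids)]
        for g in self.gene_ids:
            lines.append(
                g + "\t" + "\t".join(
                    TSV_CODES[self.cells[(g, r)]] for r in self.reaction_ids
                )
            )
        Path(path).write_text("".join(f"{l}\n" for l in lines), encoding="utf-8")

    def to_dict(self) -> dict:
        return {
            "pathway_id": self.pathway_id,
            "reaction_ids": self.reaction_ids,
            "gene_ids": self.gene_ids,
            "cells": {
                f"{g}\t{r}": v for (g, r), v in sorted(self.cells.items())
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8"
        )


def _gene_reaction_pairs(p: Pgdb, reaction_ids: set[str]) -> set[tuple[str, str]]:
    """(gene, reaction) pairs asserted by resource ``p``, restricted to the
    given reactions."""
    pairs: set[tuple[str, str]] = set()
    for prot in p.proteins.values():
        for rid in prot.catalyzed_reaction_ids & reaction_ids:
            pairs.add((prot.gene_id, rid))
    return pairs


def gene_reaction_matrix(pathway_id: str, a: Pgdb, b: Pgdb) -> PairingMatrix:
    """Build the pairing matrix for one pathway across two resources.

    Columns are the union of the pathway's reaction lists in the two
    resources; rows are the genes with at least one pairing in either.
    """
    pw_a = a.pathways.get(pathway_id)
    pw_b = b.pathways.get(pathway_id)
    if pw_a is None and pw_b is None:
        raise PathwayNotFoundError(
            f"pathway {pathway_id!r} not found in either resource"
        )
    reaction_ids = (pw_a.reaction_ids if pw_a else set()) | (
        pw_b.reaction_ids if pw_b else set()
    )

    pairs_a = _gene_reaction_pairs(a, reaction_ids)
    pairs_b = _gene_reaction_pairs(b, reaction_ids)

    gene_ids = sorted({g for g, _ in pairs_a | pairs_b})
    columns = sorted(reaction_ids)
    cells: dict[tuple[str, str], str] = {}
    for g in gene_ids:
        for r in columns:
            in_a = (g, r) in pairs_a
            in_b = (g, r) in pairs_b
            cells[(g, r)] = (
                "both" if in_a and in_b
                else "a_only" if in_a
                else "b_only" if in_b
                else "absent"
            )
    return PairingMatrix(
        pathway_id=pathway_id, reaction_ids=columns, gene_ids=gene_ids, cells=cells
    )
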
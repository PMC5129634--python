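"""Cross-resource content statistics for a pair of PGDBs.

Entity overlap between two resources is measured by exact shared identifier
(MetaCyc-style frame IDs), per entity class:

* genes — restricted to *annotated* genes (≥1 GO term, or ≥1 protein that
  catalyzes a reaction);
* proteins — restricted to reaction-mapped proteins (≥1 catalyzed reaction);
* compounds — restricted to small, non-elemental molecules;
* reactions and pathways — all.

Reactions are additionally broken down by top-level Enzyme Commission class
(1-7, plus an *unclassified* bin for reactions without an EC number) within
each partition (shared, unique-to-A, unique-to-B).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .pgdb import Pgdb, Reaction, ec_top_level_class

EC_CLASSES = (1, 2, 3, 4, 5, 6, 7)
UNCLASSIFIED = "unclassified"


@dataclass
class VennCounts:
    """The unique-to-A / shared / unique-to-B partition of two identifier sets."""

    set_a_only: set[str]
    set_shared: set[str]
    set_b_only: set[str]

    @property
    def unique_a(self) -> int:
        return len(self.set_a_only)

    @property
    def shared(self) -> int:
        return len(self.set_shared)

    @property
    def unique_b(self) -> int:
        return len(self.set_b_only)

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.unique_a, self.shared, self.unique_b)


def venn(ids_a: Iterable[str], ids_b: Iterable[str]) -> VennCounts:
    a, b = set(ids_a), set(ids_b)
    return VennCounts(set_a_only=a - b, set_shared=a & b, set_b_only=b - a)


@dataclass
class ECDistribution:
    """Reaction counts per top-level EC class (1-7) plus an unclassified bin."""

    counts: dict[int | str, int] = field(
        default_factory=lambda: {**{c: 0 for c in EC_CLASSES}, UNCLASSIFIED: 0}
    )

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def ec_distribution(reactions: Iterable[Reaction]) -> ECDistribution:
    """Count each reaction once, under its top-level EC class or unclassified.

    A reaction whose EC number has ``-`` in the first field also counts as
    unclassified.
    """
    dist = ECDistribution()
    tally: Counter = Counter()
    for r in reactions:
        cls = ec_top_level_class(r.ec_number)
        if cls is None:
            tally[UNCLASSIFIED] += 1
        elif cls in dist.counts:
            tally[cls] += 1
        else:
            raise ValueError(
                f"reaction {r.reaction_id}: top-level EC class {cls} outside 1-7"
            )
    dist.counts.update(tally)
    return dist


def annotated_genes(p: Pgdb) -> set[str]:
    """Genes with at least one GO term, or associated with a protein that
    catalyzes at least one reaction."""
    reaction_mapped = {
        prot.gene_id for prot in p.proteins.values() if prot.catalyzed_reaction_ids
    }
    return {
        g.gene_id
        for g in p.genes.values()
        if g.go_terms or g.gene_id in reaction_mapped
    }


def reaction_mapped_proteins(p: Pgdb) -> set[str]:
    return {
        prot.protein_id for prot in p.proteins.values() if prot.catalyzed_reaction_ids
    }


def small_molecule_compounds(p: Pgdb) -> set[str]:
    return {
        c.compound_id for c in p.compounds.values() if c.kind == "small-molecule"
    }


@dataclass
class OverlapReport:
    """Per-entity-class Venn partitions plus per-partition EC distributions."""

    name_a: str
    name_b: str
    genes: VennCounts
    proteins: VennCounts
    compounds: VennCounts
    reactions: VennCounts
    pathways: VennCounts
    ec_shared: ECDistribution
    ec_unique_a: ECDistribution
    ec_unique_b: ECDistribution

    ENTITY_CLASSES = ("genes", "proteins", "compounds", "reactions", "pathways")

    def venn_table(self) -> list[tuple[str, int, int, int]]:
        return [
            (cls, *getattr(self, cls).as_tuple()) for cls in self.ENTITY_CLASSES
        ]

    def to_tsv(self, path: str | Path) -> None:
        lines = ["entity_class\tunique_a\tshared\tunique_b"]
        lines += [
            f"{cls}\t{ua}\t{sh}\t{ub}" for cls, ua, sh, ub in self.venn_table()
        ]
        Path(path).write_text("".join(f"{l}\n" for l in lines), encoding="utf-8")

    def to_dict(self) -> dict:
        def venn_dict(v: VennCounts) -> dict:
            return {
                "unique_a": v.unique_a,
                "shared": v.shared,
                "unique_b": v.unique_b,
                "ids_unique_a": sorted(v.set_a_only),
                "ids_shared": sorted(v.set_shared),
                "ids_unique_b": sorted(v.set_b_only),
            }

        def ec_dict(d: ECDistribution) -> dict:
            return {str(k): v for k, v in d.counts.items()}

        return {
            "resource_a": self.name_a,
            "resource_b": self.name_b,
            "venn": {cls: venn_dict(getattr(self, cls)) for cls in self.ENTITY_CLASSES},
            "ec_distribution": {
                "shared": ec_dict(self.ec_shared),
                "unique_a": ec_dict(self.ec_unique_a),
                "unique_b": ec_dict(self.ec_unique_b),
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )


def compare_pgdbs(a: Pgdb, b: Pgdb) -> OverlapReport:
    """Full content comparison of two PGDBs (Venn partitions + EC classes)."""
    reaction_venn = venn(a.reactions, b.reactions)
    return OverlapReport(
        name_a=a.name,
        name_b=b.name,
        genes=venn(annotated_genes(a), annotated_genes(b)),
        proteins=venn(reaction_mapped_proteins(a), reaction_mapped_proteins(b)),
        compounds=venn(small_molecule_compounds(a), small_molecule_compounds(b)),
        reactions=reaction_venn,
        pathways=venn(a.pathways, b.pathways),
        ec_shared=ec_distribution(
            a.reactions[rid] for rid in reaction_venn.set_shared
        ),
        ec_unique_a=ec_distribution(
            a.reactions[rid] for rid in reaction_venn.set_a_only
        ),
        ec_unique_b=ec_distribution(
            b.reactions[rid] for rid in reaction_venn.set_b_only
        ),
    )
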
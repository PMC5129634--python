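"""Build a gene-level gold standard of enzyme (EC) annotations.

The gold standard merges two annotation sources — a manually *reviewed* set
(UniProt-style) and an *experimental* set (BRENDA-style) — unifying accessions
through database cross-links, maps the merged accessions onto a genome's
translated gene models via filtered alignment hits, and consolidates the
labels of alternate isoforms at the gene level.

The default alignment filters are a 96% sequence-identity cutoff and a 1e-20
e-value cutoff, both inclusive; for each query the top-scoring hit (highest
bitscore, ties broken by lowest e-value then smallest subject identifier) is
kept.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .pgdb import normalize_ec

PROVENANCES = ("reviewed", "experimental")

DEFAULT_MIN_IDENTITY = 96.0
DEFAULT_MAX_EVALUE = 1e-20


class AmbiguousCrossLinkError(ValueError):
    """An experimental accession carries cross-links to two reviewed accessions."""


class UnresolvedMappingError(KeyError):
    """A best-hit subject protein is missing from the protein→gene map."""


@dataclass(frozen=True)
class SourceAnnotation:
    accession: str
    ec_label: str
    provenance: str

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}")
        object.__setattr__(self, "ec_label", normalize_ec(self.ec_label))


@dataclass(frozen=True)
class CrossLink:
    experimental_accession: str
    reviewed_accession: str

    def __post_init__(self) -> None:
        if not self.experimental_accession or not self.reviewed_accession:
            raise ValueError("cross-link accessions must be non-empty")


@dataclass(frozen=True)
class AlignmentHit:
    query_accession: str
    subject_protein_id: str
    percent_identity: float
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity must lie in [0, 100]")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if self.bitscore <= 0:
            raise ValueError("bitscore must be positive")


@dataclass
class GoldStandard:
    """Gene-level truth: gene_id → set of EC labels, with per-label provenance."""

    annotations: dict[str, set[str]] = field(default_factory=dict)
    provenance: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    @property
    def annotation_count(self) -> int:
        return sum(len(labels) for labels in self.annotations.values())

    @property
    def gene_count(self) -> int:
        return len(self.annotations)


MergedAnnotations = dict[tuple[str, str], set[str]]  # (accession, ec) -> provenances


def merge_sources(
    reviewed: set[SourceAnnotation],
    experimental: set[SourceAnnotation],
    links: set[CrossLink],
) -> MergedAnnotations:
    """Union two annotation sources with duplicates removed.

    Experimental accessions with a cross-link are re-keyed to the linked
    reviewed accession before the union, so a label asserted by both sources
    collapses to a single (accession, label) pair with merged provenance.
    """
    link_map: dict[str, str] = {}
    for link in links:
        prev = link_map.get(link.experimental_accession)
        if prev is not None and prev != link.reviewed_accession:
            raise AmbiguousCrossLinkError(
                f"accession {link.experimental_accession!r} cross-links to both "
                f"{prev!r} and {link.reviewed_accession!r}"
            )
        link_map[link.experimental_accession] = link.reviewed_accession

    merged: MergedAnnotations = {}
    for ann in reviewed:
        merged.setdefault((ann.accession, ann.ec_label), set()).add(ann.provenance)
    for ann in experimental:
        accession = link_map.get(ann.accession, ann.accession)
        merged.setdefault((accession, ann.ec_label), set()).add(ann.provenance)
    return merged


def filter_hits(
    hits: set[AlignmentHit],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> set[AlignmentHit]:
    """Keep hits with identity ≥ cutoff and e-value ≤ cutoff (both inclusive)."""
    if not 0.0 <= min_identity <= 100.0:
        raise ValueError("min_identity must lie in [0, 100]")
    return {
        h
        for h in hits
        if h.percent_identity >= min_identity and h.evalue <= max_evalue
    }


def best_hit_per_query(hits: set[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Top-scoring hit per query: highest bitscore, then lowest e-value,
    then lexicographically smallest subject — fully deterministic."""
    best: dict[str, AlignmentHit] = {}
    for h in sorted(
        hits, key=lambda h: (h.query_accession, -h.bitscore, h.evalue, h.subject_protein_id)
    ):
        best.setdefault(h.query_accession, h)
    return best


def consolidate_to_genes(
    annotations: MergedAnnotations,
    best_hits: dict[str, AlignmentHit],
    protein_to_gene: dict[str, str],
) -> GoldStandard:
    """Attach each accession's labels to the gene of its best-hit subject and
    union labels across a gene's isoforms.  Accessions with no surviving hit
    are dropped."""
    gold = GoldStandard()
    for (accession, ec_label), provs in annotations.items():
        hit = best_hits.get(accession)
        if hit is None:
            continue
        try:
            gene_id = protein_to_gene[hit.subject_protein_id]
        except KeyError:
            raise UnresolvedMappingError(
                f"subject protein {hit.subject_protein_id!r} (best hit of "
                f"{accession!r}) is absent from the protein-to-gene map"
            ) from None
        gold.annotations.setdefault(gene_id, set()).add(ec_label)
        gold.provenance.setdefault((gene_id, ec_label), set()).update(provs)
    return gold


def build_gold_standard(
    reviewed: set[SourceAnnotation],
    experimental: set[SourceAnnotation],
    links: set[CrossLink],
    hits: set[AlignmentHit],
    protein_to_gene: dict[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> GoldStandard:
    """Full pipeline: merge → filter → best hit → gene-level consolidation."""
    merged = merge_sources(reviewed, experimental, links)
    surviving = filter_hits(hits, min_identity=min_identity, max_evalue=max_evalue)
    best = best_hit_per_query(surviving)
    return consolidate_to_genes(merged, best, protein_to_gene)


# ---------------------------------------------------------------------------
# tabular I/O


def read_annotation_table(path: str | Path) -> set[SourceAnnotation]:
    """TSV with header: accession, ec_label, provenance."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"accession", "ec_label", "provenance"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: annotation table needs columns {sorted(required)}")
    return {
        SourceAnnotation(row.accession, row.ec_label, row.provenance)
        for row in df.itertuples()
    }


def read_cross_links(path: str | Path) -> set[CrossLink]:
    """TSV with header: experimental_accession, reviewed_accession."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"experimental_accession", "reviewed_accession"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: cross-link table needs columns {sorted(required)}")
    return {
        CrossLink(row.experimental_accession, row.reviewed_accession)
        for row in df.itertuples()
    }


#: 12-column BLAST tabular (-outfmt 6) header; only qseqid, sseqid, pident,
#: evalue and bitscore are consumed.
BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tabular(path: str | Path) -> set[AlignmentHit]:
    df = pd.read_csv(
        path, sep="\t", header=None, names=BLAST_COLUMNS,
        float_precision="round_trip",
    )
    return {
        AlignmentHit(
            query_accession=str(row.qseqid),
            subject_protein_id=str(row.sseqid),
            percent_identity=float(row.pident),
            evalue=float(row.evalue),
            bitscore=float(row.bitscore),
        )
        for row in df.itertuples()
    }


def write_blast_tabular(hits: set[AlignmentHit], path: str | Path) -> None:
    """Write hits as 12-column BLAST tabular; unused columns are filled with
    plausible placeholders (deterministic ordering)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in sorted(
            hits, key=lambda h: (h.query_accession, h.subject_protein_id, h.bitscore)
        ):
            writer.writerow(
                [
                    h.query_accession, h.subject_protein_id,
                    f"{h.percent_identity:.2f}",
                    100, 0, 0, 1, 100, 1, 100,
                    f"{h.evalue:.3g}", f"{h.bitscore:.1f}",
                ]
            )


def write_gold_standard(gold: GoldStandard, path: str | Path) -> None:
    """TSV: gene_id, ec_label, comma-joined provenance list."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", "ec_label", "provenance"])
        for gene_id in sorted(gold.annotations):
            for ec in sorted(gold.annotations[gene_id]):
                provs = ",".join(sorted(gold.provenance.get((gene_id, ec), set())))
                writer.writerow([gene_id, ec, provs])


def read_gold_standard(path: str | Path) -> GoldStandard:
    df = pd.read_csv(path, sep="\t", dtype=str)
    gold = GoldStandard()
    for row in df.itertuples():
        gold.annotations.setdefault(row.gene_id, set()).add(row.ec_label)
        provs = set(str(row.provenance).split(",")) if pd.notna(row.provenance) else set()
        gold.provenance.setdefault((row.gene_id, row.ec_label), set()).update(
            p for p in provs if p
        )
    return gold
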
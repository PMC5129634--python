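"""Paired synthetic PGDBs with planted truth for end-to-end testing.

No public maize pathway database snapshot ships with this package, so every
pipeline stage is exercised on synthetic resources whose statistical shape
mirrors the real comparison setting:

* two resources built on one shared gene namespace, with controlled
  per-entity-class identifier overlap;
* resource A carries alternate splice isoforms (mean 1.6 transcripts per
  gene); resource B carries one canonical transcript per gene;
* strongly asymmetric GO-annotation and reaction-mapping coverage
  (A: ~0.1% GO / 99.1% reaction-mapped; B: 53.1% / 19.8%);
* a gold standard of 1,475 enzyme annotations across 1,450 genes, and
  per-resource prediction sets whose confusion counts (TP/FP/FN, including
  missing-gene false negatives) are planted by explicit construction rather
  than sampling, so downstream scoring must recover them exactly;
* alignment hits straddling the 96% identity / 1e-20 e-value filters in all
  four pass/fail quadrants.

``generate`` returns the resources plus an *expected ledger* — the planted
Venn counts, EC-class distributions and confusion counts, bookkept with
plain set arithmetic during construction — which downstream modules are
tested against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .evaluation import PredictionSet, write_prediction_set
from .gold_standard import AlignmentHit, GoldStandard, write_blast_tabular, write_gold_standard
from .pgdb import Compound, Gene, Pathway, Pgdb, Protein, Reaction, write_pgdb

ENTITY_CLASSES = ("gene", "reaction", "compound", "pathway")

#: Default EC top-level class mix, proportional to the shared-reaction column
#: of the real two-resource comparison (classes 1-6 plus unclassified).
DEFAULT_EC_CLASS_WEIGHTS = {
    1: 496 / 1856,
    2: 540 / 1856,
    3: 282 / 1856,
    4: 141 / 1856,
    5: 73 / 1856,
    6: 80 / 1856,
    "unclassified": 244 / 1856,
}


class ConfigError(ValueError):
    """The synthesis configuration is invalid or infeasible."""


def _default_overlap() -> dict[str, float]:
    # reaction/pathway overlap fractions follow the published resource pair
    # (1856 of 3537 reactions shared; 328 of 586 pathways shared)
    return {"gene": 0.5, "reaction": 0.525, "compound": 0.5, "pathway": 0.56}


@dataclass
class SynthesisConfig:
    """All knobs of the generator.  Defaults are the study conditions.

    The confusion-count plant is parameterized by per-resource precision and
    recall; the defaults are the exact ratios of the published Table-1-style
    counts (A: TP 1326 / FP 213 / FN 149; B: TP 1235 / FP 436 / FN 240
    against 1,475 gold annotations), including 86 and 2 missing-gene false
    negatives respectively.
    """

    seed: int = 0
    n_genes: int = 5000
    mean_isoforms_per_gene: float = 1.6
    go_fraction_a: float = 0.001
    go_fraction_b: float = 0.531
    reaction_map_fraction_a: float = 0.991
    reaction_map_fraction_b: float = 0.198
    entity_overlap: dict[str, float] = field(default_factory=_default_overlap)
    n_gold_genes: int = 1450
    n_gold_annotations: int = 1475
    missing_gold_genes_a: int = 86
    missing_gold_genes_b: int = 2
    planted_precision_a: float = 1326 / 1539
    planted_recall_a: float = 1326 / 1475
    planted_precision_b: float = 1235 / 1671
    planted_recall_b: float = 1235 / 1475
    ec_class_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_EC_CLASS_WEIGHTS)
    )
    n_reactions: int = 800
    n_compounds: int = 600
    n_pathways: int = 120
    n_background_predictions: int = 200

    # -- derived plant arithmetic ------------------------------------------

    def planted_counts(self, resource: str) -> tuple[int, int, int]:
        """(tp, fp, fn) implied by the planted precision/recall for 'a'/'b'."""
        recall = getattr(self, f"planted_recall_{resource}")
        precision = getattr(self, f"planted_precision_{resource}")
        n = self.n_gold_annotations
        tp = round(recall * n)
        fn = n - tp
        fp = round(tp * (1.0 - precision) / precision)
        return tp, fp, fn

    def validate(self) -> None:
        proportions = {
            "go_fraction_a": self.go_fraction_a,
            "go_fraction_b": self.go_fraction_b,
            "reaction_map_fraction_a": self.reaction_map_fraction_a,
            "reaction_map_fraction_b": self.reaction_map_fraction_b,
            "planted_precision_a": self.planted_precision_a,
            "planted_recall_a": self.planted_recall_a,
            "planted_precision_b": self.planted_precision_b,
            "planted_recall_b": self.planted_recall_b,
            **{f"entity_overlap[{k}]": v for k, v in self.entity_overlap.items()},
        }
        for name, v in proportions.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} = {v} outside [0, 1]")
        for name in ("planted_precision_a", "planted_precision_b"):
            if getattr(self, name) == 0.0:
                raise ConfigError(f"{name} must be positive")
        if set(self.entity_overlap) - set(ENTITY_CLASSES):
            raise ConfigError(
                f"unknown entity classes in entity_overlap: "
                f"{sorted(set(self.entity_overlap) - set(ENTITY_CLASSES))}"
            )
        if abs(sum(self.ec_class_weights.values()) - 1.0) > 1e-9:
            raise ConfigError("ec_class_weights must sum to 1")
        if self.n_gold_genes <= 0 or self.n_genes <= 0:
            raise ConfigError("n_genes and n_gold_genes must be positive")
        if self.n_gold_genes > self.n_genes:
            raise ConfigError("n_gold_genes exceeds n_genes")
        if self.n_gold_annotations < self.n_gold_genes:
            raise ConfigError("every gold gene needs at least one annotation")
        if self.mean_isoforms_per_gene < 1.0:
            raise ConfigError("mean_isoforms_per_gene must be >= 1")

        shared, a_only, b_only = self._gene_partition_sizes()
        if self.missing_gold_genes_a > b_only:
            raise ConfigError(
                f"missing_gold_genes_a = {self.missing_gold_genes_a} exceeds the "
                f"{b_only} genes unique to resource B"
            )
        if self.missing_gold_genes_b > a_only:
            raise ConfigError(
                f"missing_gold_genes_b = {self.missing_gold_genes_b} exceeds the "
                f"{a_only} genes unique to resource A"
            )
        n_shared_gold = (
            self.n_gold_genes - self.missing_gold_genes_a - self.missing_gold_genes_b
        )
        if n_shared_gold < 0 or n_shared_gold > shared:
            raise ConfigError("gold genes do not fit the gene overlap partition")
        n_second = self.n_gold_annotations - self.n_gold_genes
        if n_second > n_shared_gold:
            raise ConfigError(
                "n_gold_annotations requires more two-label genes than there are "
                "gold genes present in both resources"
            )
        for res in ("a", "b"):
            tp, fp, fn = self.planted_counts(res)
            missing = getattr(self, f"missing_gold_genes_{res}")
            if fn < missing:
                raise ConfigError(
                    f"resource {res}: planted recall implies {fn} false negatives, "
                    f"fewer than the {missing} forced by missing genes"
                )
        for res in ("a", "b"):
            frac = getattr(self, f"reaction_map_fraction_{res}")
            if frac > 0 and self.n_reactions == 0:
                raise ConfigError(
                    f"reaction_map_fraction_{res} > 0 but n_reactions = 0"
                )

    def _gene_partition_sizes(self) -> tuple[int, int, int]:
        shared = round(self.entity_overlap.get("gene", 0.5) * self.n_genes)
        rest = self.n_genes - shared
        a_only = (rest + 1) // 2
        return shared, a_only, rest - a_only

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ec_class_weights"] = {str(k): v for k, v in self.ec_class_weights.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthesisConfig":
        d = dict(d)
        if "ec_class_weights" in d:
            d["ec_class_weights"] = {
                (int(k) if str(k).isdigit() else str(k)): float(v)
                for k, v in d["ec_class_weights"].items()
            }
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "SynthesisConfig":
        text = Path(path).read_text(encoding="utf-8")
        return cls.from_dict(yaml.safe_load(text) or {})


@dataclass
class ExpectedLedger:
    """Planted truth, bookkept with plain set arithmetic at generation time."""

    venn: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    ec_distribution: dict[str, dict] = field(default_factory=dict)
    confusion: dict[str, dict[str, int]] = field(default_factory=dict)
    gold_annotation_count: int = 0
    gold_gene_count: int = 0
    missing_gene_fn: dict[str, int] = field(default_factory=dict)
    mean_isoforms_a: float = 0.0
    hit_quadrants: dict[str, int] = field(default_factory=dict)
    n_pass_hits: int = 0

    def validate(self) -> None:
        for res, c in self.confusion.items():
            if c["tp"] + c["fn"] != self.gold_annotation_count:
                raise AssertionError(
                    f"ledger inconsistent: resource {res} tp+fn != gold count"
                )
        for part, dist in self.ec_distribution.items():
            idx = {"shared": 1, "unique_a": 0, "unique_b": 2}[part]
            if sum(dist.values()) != self.venn["reaction"][idx]:
                raise AssertionError(
                    f"ledger inconsistent: EC distribution total for {part}"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ec_distribution"] = {
            part: {str(k): v for k, v in dist.items()}
            for part, dist in self.ec_distribution.items()
        }
        return d


@dataclass
class SyntheticHits:
    hits: set[AlignmentHit]
    expected_pass: set[AlignmentHit]


@dataclass
class SynthesisOutput:
    config: SynthesisConfig
    pgdb_a: Pgdb
    pgdb_b: Pgdb
    gold: GoldStandard
    predictions_a: PredictionSet
    predictions_b: PredictionSet
    hits: SyntheticHits
    expected: ExpectedLedger

    def write(self, directory: str | Path) -> None:
        """Write flat files, TSVs and the expected ledger (deterministic)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_pgdb(self.pgdb_a, directory / "pgdb_a")
        write_pgdb(self.pgdb_b, directory / "pgdb_b")
        write_gold_standard(self.gold, directory / "gold_standard.tsv")
        write_prediction_set(
            self.predictions_a,
            directory / "predictions_a.tsv",
            directory / "universe_a.txt",
        )
        write_prediction_set(
            self.predictions_b,
            directory / "predictions_b.tsv",
            directory / "universe_b.txt",
        )
        write_blast_tabular(self.hits.hits, directory / "hits.tsv")
        (directory / "expected.json").write_text(
            json.dumps(self.expected.to_dict(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        (directory / "config.yaml").write_text(
            yaml.safe_dump(self.config.to_dict(), sort_keys=True), encoding="utf-8"
        )


# ---------------------------------------------------------------------------
# generation


def _partition(rng: np.random.Generator, ids: list[str], overlap: float
               ) -> tuple[list[str], list[str], list[str]]:
    """Split identifiers into (shared, a_only, b_only) with the given shared
    fraction; the unique remainder splits evenly (A gets the odd one)."""
    ids = list(ids)
    rng.shuffle(ids)
    n = len(ids)
    n_shared = round(overlap * n)
    rest = n - n_shared
    n_a = (rest + 1) // 2
    return ids[:n_shared], ids[n_shared:n_shared + n_a], ids[n_shared + n_a:]


def _random_ec(rng: np.random.Generator, cls: int, lo: int = 1, hi: int = 99) -> str:
    a, b, c = rng.integers(lo, hi + 1, size=3)
    return f"{cls}.{a}.{b}.{c}"


def _draw_ec_class(rng: np.random.Generator, weights: dict) -> int | None:
    keys = sorted(weights, key=str)
    probs = np.array([weights[k] for k in keys], dtype=float)
    probs /= probs.sum()
    k = keys[int(rng.choice(len(keys), p=probs))]
    return None if k == "unclassified" else int(k)


def generate_hits(config: SynthesisConfig, n_per_quadrant: int = 3) -> SyntheticHits:
    """Alignment hits covering all four (identity, e-value) filter quadrants.

    One passing hit sits exactly on both cutoffs (96.0, 1e-20) to pin the
    inclusive-boundary semantics.  Expected pass/fail labels are returned
    alongside the hits.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 7])
    hits: set[AlignmentHit] = set()
    expected_pass: set[AlignmentHit] = set()
    counter = 0
    for id_pass in (True, False):
        for ev_pass in (True, False):
            for j in range(n_per_quadrant):
                counter += 1
                if id_pass and ev_pass and j == 0:
                    pident, evalue = 96.0, 1e-20  # exact boundary
                else:
                    pident = (
                        float(rng.uniform(96.0, 100.0))
                        if id_pass
                        else float(rng.uniform(60.0, 95.9))
                    )
                    evalue = (
                        10.0 ** -float(rng.uniform(20.5, 60.0))
                        if ev_pass
                        else 10.0 ** -float(rng.uniform(0.0, 19.5))
                    )
                hit = AlignmentHit(
                    query_accession=f"ACC-H{counter:04d}",
                    subject_protein_id=f"PROT-H{counter:04d}",
                    percent_identity=round(pident, 2),
                    evalue=evalue,
                    bitscore=float(round(rng.uniform(50.0, 500.0), 1)),
                )
                hits.add(hit)
                if id_pass and ev_pass:
                    expected_pass.add(hit)
    return SyntheticHits(hits=hits, expected_pass=expected_pass)


def generate(config: SynthesisConfig) -> SynthesisOutput:
    """Generate the full paired-resource scenario with its expected ledger.

    Structure (which identifiers exist, isoform counts, GO coverage,
    reaction chemistry) is sampled; planted *counts* (confusion counts, Venn
    partitions) are fixed by construction so that downstream recovery is an
    exact check, not a statistical one.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])

    # ---- gene namespace and per-resource universes
    gene_ids = [f"GENE-{i:05d}" for i in range(config.n_genes)]
    g_shared, g_a_only, g_b_only = _partition(
        rng, gene_ids, config.entity_overlap.get("gene", 0.5)
    )
    universe_a = set(g_shared) | set(g_a_only)
    universe_b = set(g_shared) | set(g_b_only)

    # ---- compounds (small molecules partitioned; extras exercise the filter)
    cpd_ids = [f"CPD-{i:05d}" for i in range(config.n_compounds)]
    c_shared, c_a_only, c_b_only = _partition(
        rng, cpd_ids, config.entity_overlap.get("compound", 0.5)
    )

    def make_compounds(small: list[str], tag: str) -> dict[str, Compound]:
        out = {cid: Compound(cid, "small-molecule") for cid in small}
        out[f"MACRO-{tag}"] = Compound(f"MACRO-{tag}", "macromolecule")
        out["ELEM-FE"] = Compound("ELEM-FE", "element")  # shared, never counted
        return out

    compounds_a = make_compounds(sorted(c_shared + c_a_only), "A")
    compounds_b = make_compounds(sorted(c_shared + c_b_only), "B")

    # ---- reactions with EC classes drawn from the configured mix
    rxn_ids = [f"RXN-{i:05d}" for i in range(config.n_reactions)]
    r_shared, r_a_only, r_b_only = _partition(
        rng, rxn_ids, config.entity_overlap.get("reaction", 0.5)
    )
    ec_tallies = {
        part: {**{c: 0 for c in range(1, 8)}, "unclassified": 0}
        for part in ("shared", "unique_a", "unique_b")
    }

    def make_reaction(rid: str, pool: list[str], part: str) -> Reaction:
        cls = _draw_ec_class(rng, config.ec_class_weights)
        ec_tallies[part][cls if cls is not None else "unclassified"] += 1
        ec = _random_ec(rng, cls) if cls is not None else None
        subs: set[str] = set()
        prods: set[str] = set()
        if pool:
            n_sub = int(rng.integers(1, 3))
            n_prod = int(rng.integers(1, 3))
            subs = set(rng.choice(pool, size=min(n_sub, len(pool)), replace=False))
            prods = set(rng.choice(pool, size=min(n_prod, len(pool)), replace=False))
        return Reaction(rid, ec_number=ec, substrate_ids=subs, product_ids=prods)

    shared_pool = sorted(c_shared)
    pool_a = sorted(c_shared + c_a_only)
    pool_b = sorted(c_shared + c_b_only)
    reactions_shared = {rid: make_reaction(rid, shared_pool, "shared")
                        for rid in sorted(r_shared)}
    reactions_a = dict(reactions_shared)
    reactions_a.update(
        (rid, make_reaction(rid, pool_a, "unique_a")) for rid in sorted(r_a_only)
    )
    reactions_b = dict(reactions_shared)
    reactions_b.update(
        (rid, make_reaction(rid, pool_b, "unique_b")) for rid in sorted(r_b_only)
    )

    # ---- pathways draw their member reactions from what each resource holds
    pwy_ids = [f"PWY-{i:04d}" for i in range(config.n_pathways)]
    p_shared, p_a_only, p_b_only = _partition(
        rng, pwy_ids, config.entity_overlap.get("pathway", 0.5)
    )

    def make_pathway(pid: str, pool: list[str]) -> Pathway:
        if not pool:
            return Pathway(pid, set())
        size = int(rng.integers(3, 9))
        members = set(rng.choice(pool, size=min(size, len(pool)), replace=False))
        return Pathway(pid, members)

    pathways_shared = {
        pid: make_pathway(pid, sorted(r_shared)) for pid in sorted(p_shared)
    }
    pathways_a = dict(pathways_shared)
    pathways_a.update(
        (pid, make_pathway(pid, sorted(r_shared + r_a_only)))
        for pid in sorted(p_a_only)
    )
    pathways_b = dict(pathways_shared)
    pathways_b.update(
        (pid, make_pathway(pid, sorted(r_shared + r_b_only)))
        for pid in sorted(p_b_only)
    )

    # ---- proteins: resource A has isoforms (shifted-geometric counts with
    # the configured mean); resource B is canonical-transcript only
    def make_proteins(universe: set[str], with_isoforms: bool
                      ) -> tuple[dict[str, Protein], dict[str, Gene]]:
        proteins: dict[str, Protein] = {}
        genes: dict[str, Gene] = {}
        for gid in sorted(universe):
            if with_isoforms and config.mean_isoforms_per_gene > 1.0:
                k = int(rng.geometric(1.0 / config.mean_isoforms_per_gene))
            else:
                k = 1
            pids = {f"{gid}-P{j}" for j in range(1, k + 1)}
            genes[gid] = Gene(gid, protein_ids=pids)
            for pid in sorted(pids):
                proteins[pid] = Protein(pid, gid)
        return proteins, genes

    proteins_a, genes_a = make_proteins(universe_a, with_isoforms=True)
    proteins_b, genes_b = make_proteins(universe_b, with_isoforms=False)
    mean_isoforms_a = len(proteins_a) / max(len(genes_a), 1)

    # ---- reaction mapping and GO coverage per resource
    def apply_coverage(
        genes: dict[str, Gene],
        proteins: dict[str, Protein],
        reactions: dict[str, Reaction],
        rmap_fraction: float,
        go_fraction: float,
    ) -> tuple[set[str], set[str], set[str]]:
        ordered = sorted(genes)
        n_rmap = round(rmap_fraction * len(ordered))
        n_go = round(go_fraction * len(ordered))
        rmap_genes = set(
            rng.choice(ordered, size=n_rmap, replace=False)
        ) if n_rmap else set()
        go_genes = set(
            rng.choice(ordered, size=n_go, replace=False)
        ) if n_go else set()
        rxn_pool = sorted(reactions)
        rm_proteins: set[str] = set()
        for gid in sorted(rmap_genes):
            for pid in sorted(genes[gid].protein_ids):
                n_cat = int(rng.integers(1, 3))
                proteins[pid].catalyzed_reaction_ids = set(
                    rng.choice(rxn_pool, size=min(n_cat, len(rxn_pool)), replace=False)
                )
                rm_proteins.add(pid)
        for gid in sorted(go_genes):
            n_terms = int(rng.integers(1, 4))
            genes[gid].go_terms = {
                f"GO:{int(t):07d}" for t in rng.integers(1, 9_999_999, size=n_terms)
            }
        return rmap_genes, go_genes, rm_proteins

    rmap_a, go_a, rm_prot_a = apply_coverage(
        genes_a, proteins_a, reactions_a,
        config.reaction_map_fraction_a, config.go_fraction_a,
    )
    rmap_b, go_b, rm_prot_b = apply_coverage(
        genes_b, proteins_b, reactions_b,
        config.reaction_map_fraction_b, config.go_fraction_b,
    )

    pgdb_a = Pgdb(
        name="synthetic_a", genes=genes_a, proteins=proteins_a,
        reactions=reactions_a, compounds=compounds_a, pathways=pathways_a,
    )
    pgdb_b = Pgdb(
        name="synthetic_b", genes=genes_b, proteins=proteins_b,
        reactions=reactions_b, compounds=compounds_b, pathways=pathways_b,
    )

    # ---- gold standard: place missing genes in the other resource's unique
    # partition so the missing-gene FN counts are exact by construction
    miss_a = sorted(
        rng.choice(sorted(g_b_only), size=config.missing_gold_genes_a, replace=False)
    ) if config.missing_gold_genes_a else []
    miss_b = sorted(
        rng.choice(sorted(g_a_only), size=config.missing_gold_genes_b, replace=False)
    ) if config.missing_gold_genes_b else []
    n_shared_gold = (
        config.n_gold_genes - config.missing_gold_genes_a - config.missing_gold_genes_b
    )
    shared_gold = sorted(
        rng.choice(sorted(g_shared), size=n_shared_gold, replace=False)
    ) if n_shared_gold else []
    gold_genes = sorted(miss_a) + sorted(miss_b) + list(shared_gold)

    gold = GoldStandard()
    used_labels: set[tuple[str, str]] = set()
    for gid in gold_genes:
        ec = _random_ec(rng, int(rng.integers(1, 7)))
        while (gid, ec) in used_labels:
            ec = _random_ec(rng, int(rng.integers(1, 7)))
        used_labels.add((gid, ec))
        gold.annotations[gid] = {ec}
        gold.provenance[(gid, ec)] = {
            "reviewed" if rng.random() < 0.7 else "experimental"
        }
    # second labels only on genes present in both resources
    n_second = config.n_gold_annotations - config.n_gold_genes
    for gid in (
        rng.choice(shared_gold, size=n_second, replace=False) if n_second else []
    ):
        ec = _random_ec(rng, int(rng.integers(1, 7)))
        while (gid, ec) in used_labels:
            ec = _random_ec(rng, int(rng.integers(1, 7)))
        used_labels.add((gid, ec))
        gold.annotations[gid].add(ec)
        gold.provenance[(gid, ec)] = {"experimental"}

    # ---- predictions with planted confusion counts
    def make_predictions(
        resource: str, universe: set[str], non_gold_pool: list[str]
    ) -> PredictionSet:
        tp_target, fp_target, fn_target = config.planted_counts(resource)
        pairs_in = [
            (gid, ec)
            for gid in sorted(gold.annotations)
            if gid in universe
            for ec in sorted(gold.annotations[gid])
        ]
        forced_fn = config.n_gold_annotations - len(pairs_in)  # missing genes
        n_miss_in_universe = fn_target - forced_fn
        miss_idx = set(
            rng.choice(len(pairs_in), size=n_miss_in_universe, replace=False)
        ) if n_miss_in_universe else set()
        predictions: dict[str, set[str]] = {}
        for i, (gid, ec) in enumerate(pairs_in):
            if i not in miss_idx:
                predictions.setdefault(gid, set()).add(ec)
        # false positives: noise labels (field range disjoint from gold's)
        # on gold genes inside the universe
        gold_in_universe = sorted({gid for gid, _ in pairs_in})
        planted_fp = 0
        while planted_fp < fp_target:
            gid = gold_in_universe[int(rng.integers(0, len(gold_in_universe)))]
            ec = _random_ec(rng, int(rng.integers(1, 7)), lo=100, hi=999)
            if ec in predictions.get(gid, set()):
                continue
            predictions.setdefault(gid, set()).add(ec)
            planted_fp += 1
        # unscored background predictions on non-gold genes
        if config.n_background_predictions and non_gold_pool:
            picks = rng.choice(
                non_gold_pool,
                size=min(config.n_background_predictions, len(non_gold_pool)),
                replace=False,
            )
            for gid in picks:
                predictions.setdefault(gid, set()).add(
                    _random_ec(rng, int(rng.integers(1, 7)), lo=100, hi=999)
                )
        return PredictionSet(
            name=f"synthetic_{resource}",
            predictions=predictions,
            gene_universe=set(universe),
        )

    gold_set = set(gold.annotations)
    predictions_a = make_predictions(
        "a", universe_a, sorted(universe_a - gold_set)
    )
    predictions_b = make_predictions(
        "b", universe_b, sorted(universe_b - gold_set)
    )

    hits = generate_hits(config)

    # ---- expected ledger (direct set arithmetic, independent of the
    # overlap/evaluation modules)
    ann_a = go_a | rmap_a
    ann_b = go_b | rmap_b
    small_a = set(c_shared) | set(c_a_only)
    small_b = set(c_shared) | set(c_b_only)

    def venn3(a: set, b: set) -> tuple[int, int, int]:
        return (len(a - b), len(a & b), len(b - a))

    tp_a, fp_a, fn_a = config.planted_counts("a")
    tp_b, fp_b, fn_b = config.planted_counts("b")
    ledger = ExpectedLedger(
        venn={
            "gene": venn3(ann_a, ann_b),
            "protein": venn3(rm_prot_a, rm_prot_b),
            "compound": venn3(small_a, small_b),
            "reaction": venn3(set(reactions_a), set(reactions_b)),
            "pathway": venn3(set(pathways_a), set(pathways_b)),
        },
        ec_distribution=ec_tallies,
        confusion={
            "a": {"tp": tp_a, "fp": fp_a, "fn": fn_a},
            "b": {"tp": tp_b, "fp": fp_b, "fn": fn_b},
        },
        gold_annotation_count=config.n_gold_annotations,
        gold_gene_count=config.n_gold_genes,
        missing_gene_fn={
            "a": config.missing_gold_genes_a,
            "b": config.missing_gold_genes_b,
        },
        mean_isoforms_a=mean_isoforms_a,
        hit_quadrants={"pass": len(hits.expected_pass),
                       "fail": len(hits.hits) - len(hits.expected_pass)},
        n_pass_hits=len(hits.expected_pass),
    )
    ledger.validate()

    return SynthesisOutput(
        config=config,
        pgdb_a=pgdb_a,
        pgdb_b=pgdb_b,
        gold=gold,
        predictions_a=predictions_a,
        predictions_b=predictions_b,
        hits=hits,
        expected=ledger,
    )
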
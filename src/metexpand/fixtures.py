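"""Packaged, download-free inputs reproducing the noscapine study system.

Everything ships as small text tables under ``metexpand/data``:

* ``compounds.tsv`` — name -> structure for every fixture compound,
* ``noscapine_pathway.json`` — the 17-metabolite / 17-reaction seed
  pathway with its 11 generalized rule classes,
* ``rules.yaml`` — the mini rule collection,
* ``catalogs.tsv`` — biological / bioactive / chemical membership,
* ``annotations.tsv`` — citation and patent counts of the candidate
  derivatives (as printed, including one internally inconsistent reported
  total that the loader flags rather than repairs),
* ``reference_reactions.tsv`` — a miniature enzyme-annotated reference
  reaction DB,
* ``validation_pathways.tsv`` — known external biosynthesis routes used
  for the network-recovery check.

Structures are constitutional reconstructions of the published compounds
(stereo stripped).  Structures of reference-reaction participants that are
too large to embed faithfully (coenzyme A, polyprenyl tails, the
tabersonine scaffold) are truncated synthetic stand-ins; they serve as
fingerprint carriers, not as literature structures.  EC sub-numbers of the
CYP719 methylenedioxy synthases other than 1.14.19.73 are likewise
reconstructions.
"""

from __future__ import annotations

import csv
import io
import json
import random
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .catalogs import (
    AnnotationRecord,
    CompoundCatalog,
    annotation_inconsistencies,
    catalogs_from_tsv,
)
from .chem import FilterSpec, Molecule, parse_structure
from .errors import ValidationError
from .rules import (
    CompoundEntry,
    Network,
    ReactionEdge,
    ReactionRule,
    apply_rule,
    load_rules,
)
from .enzymes import ReferenceReaction, reference_db_from_tsv


DATA_FILES = (
    "compounds.tsv",
    "noscapine_pathway.json",
    "rules.yaml",
    "catalogs.tsv",
    "annotations.tsv",
    "reference_reactions.tsv",
    "validation_pathways.tsv",
)


def _read(name: str) -> str:
    return resources.files("metexpand.data").joinpath(name).read_text()


# --- text-level loaders (shared by the packaged fixtures and the CLI) ------


def load_compounds_tsv(text: str) -> dict[str, Molecule]:
    out: dict[str, Molecule] = {}
    for row in csv.DictReader(io.StringIO(text), delimiter="\t"):
        out[row["name"]] = parse_structure(row["smiles"], "smiles", name=row["name"])
    return out


def load_catalogs_tsv(text: str, registry: dict[str, Molecule]) -> list[CompoundCatalog]:
    rows = ["\t".join(CompoundCatalog.HEADER)]
    for row in csv.DictReader(io.StringIO(text), delimiter="\t"):
        rows.append(
            "\t".join(
                [
                    registry[row["name"]].canonical_key,
                    row["catalog_class"],
                    row["database"],
                    row["identifier"],
                ]
            )
        )
    return catalogs_from_tsv("\n".join(rows) + "\n")


def load_annotations_tsv(text: str, registry: dict[str, Molecule]) -> str:
    """Rewrite a name-keyed annotation table into a canonical-key-keyed one."""
    out = ["canonical_key\tname\tcitations\tpatents\treported_total"]
    for row in csv.DictReader(io.StringIO(text), delimiter="\t"):
        out.append(
            "\t".join(
                [
                    registry[row["name"]].canonical_key,
                    row["name"],
                    row["citations"],
                    row["patents"],
                    row.get("reported_total", ""),
                ]
            )
        )
    return "\n".join(out) + "\n"


def load_validation_tsv(text: str, registry: dict[str, Molecule]) -> dict[str, tuple[str, ...]]:
    out: dict[str, tuple[str, ...]] = {}
    for row in csv.DictReader(io.StringIO(text), delimiter="\t"):
        chain = [c.strip() for c in row["compounds"].split(">")]
        out[row["pathway"]] = tuple(registry[c].canonical_key for c in chain)
    return out


@lru_cache(maxsize=None)
def compound_registry() -> dict[str, Molecule]:
    """All fixture compounds, name -> parsed Molecule."""
    return load_compounds_tsv(_read("compounds.tsv"))


def molecule(name: str) -> Molecule:
    try:
        return compound_registry()[name]
    except KeyError:
        raise KeyError(f"no fixture compound named {name!r}") from None


def key_of(name: str) -> str:
    return molecule(name).canonical_key


@lru_cache(maxsize=None)
def compound_names() -> dict[str, str]:
    """canonical key -> fixture name (for readable reports)."""
    return {m.canonical_key: n for n, m in compound_registry().items()}


# ---------------------------------------------------------------------------
# seed pathway


@dataclass(frozen=True)
class PathwayReaction:
    substrate_key: str
    product_key: str
    rule_id: str
    enzyme: str
    substrate_name: str
    product_name: str


@dataclass(frozen=True)
class PathwayDefinition:
    name: str
    metabolites: tuple[Molecule, ...]
    reactions: tuple[PathwayReaction, ...]

    @property
    def rule_classes(self) -> frozenset[str]:
        return frozenset(r.rule_id for r in self.reactions)

    def metabolite_keys(self) -> list[str]:
        return [m.canonical_key for m in self.metabolites]

    def seed_edges(self, rules: tuple[ReactionRule, ...] = ()) -> list[ReactionEdge]:
        """The pathway's reactions as known network edges (generation 1).

        When the loaded rule set reproduces a step, the recorded reactive
        site is taken from the rule application; steps outside the rule
        set (or whose product is stored as a ring-chain tautomer) carry an
        empty site.
        """
        by_id = {r.rule_id: r for r in rules}
        by_key = {m.canonical_key: m for m in self.metabolites}
        edges = []
        for rxn in self.reactions:
            site: frozenset[int] = frozenset()
            rule = by_id.get(rxn.rule_id)
            if rule is not None:
                for app in apply_rule(rule, by_key[rxn.substrate_key], "forward"):
                    if app.product.canonical_key == rxn.product_key:
                        site = app.site_atoms
                        break
            edges.append(
                ReactionEdge(
                    substrate_key=rxn.substrate_key,
                    product_key=rxn.product_key,
                    rule_id=rxn.rule_id,
                    site_atoms=site,
                    status="known",
                    generation=1,
                )
            )
        return edges


def load_pathway_json(text: str, registry: dict[str, Molecule]) -> PathwayDefinition:
    doc = json.loads(text)
    mets = tuple(registry[n] for n in doc["metabolites"])
    rxns = tuple(
        PathwayReaction(
            substrate_key=registry[r["substrate"]].canonical_key,
            product_key=registry[r["product"]].canonical_key,
            rule_id=r["rule"],
            enzyme=r["enzyme"],
            substrate_name=r["substrate"],
            product_name=r["product"],
        )
        for r in doc["reactions"]
    )
    return PathwayDefinition(name=doc["name"], metabolites=mets, reactions=rxns)


@lru_cache(maxsize=None)
def noscapine_pathway() -> PathwayDefinition:
    """The packaged noscapine seed pathway (17 metabolites, 17 reactions,
    11 distinct generalized rule classes)."""
    return load_pathway_json(_read("noscapine_pathway.json"), compound_registry())


# ---------------------------------------------------------------------------
# rules / catalogs / annotations / reference DB


def mini_rules() -> list[ReactionRule]:
    return load_rules(_read("rules.yaml"))


@lru_cache(maxsize=None)
def _catalogs_cached() -> tuple[CompoundCatalog, ...]:
    return tuple(load_catalogs_tsv(_read("catalogs.tsv"), compound_registry()))


def mini_catalogs() -> list[CompoundCatalog]:
    """Catalogs keyed by canonical structure key (classes: biological,
    bioactive, chemical).  The registry's decoy compound
    ('4'-O-methyl-N-methylcoclaurine') is deliberately absent everywhere."""
    return list(_catalogs_cached())


def decoy_compound() -> Molecule:
    """A parseable fixture compound present in no catalog."""
    return molecule("4'-O-methyl-N-methylcoclaurine")


def _annotations_text_with_keys() -> str:
    return load_annotations_tsv(_read("annotations.tsv"), compound_registry())


@lru_cache(maxsize=None)
def annotation_table() -> dict[str, AnnotationRecord]:
    """Citation/patent counts of the candidate derivatives, keyed by
    canonical structure key.  Popularity is definitional (the sum), even
    where the printed total disagrees (see
    :func:`annotation_inconsistency_report`)."""
    out: dict[str, AnnotationRecord] = {}
    for row in csv.DictReader(io.StringIO(_annotations_text_with_keys()), delimiter="\t"):
        out[row["canonical_key"]] = AnnotationRecord(
            compound_key=row["canonical_key"],
            citations=int(row["citations"]),
            patents=int(row["patents"]),
        )
    return out


def annotation_inconsistency_report() -> list[dict]:
    """Annotation rows whose reported total is not citations + patents."""
    return annotation_inconsistencies(_annotations_text_with_keys())


@lru_cache(maxsize=None)
def mini_reference_db() -> tuple[ReferenceReaction, ...]:
    return tuple(reference_db_from_tsv(_read("reference_reactions.tsv")))


@lru_cache(maxsize=None)
def validation_pathways() -> dict[str, tuple[str, ...]]:
    """Known external biosynthesis routes, name -> ordered canonical keys."""
    return load_validation_tsv(_read("validation_pathways.tsv"), compound_registry())


# ---------------------------------------------------------------------------
# random networks for stress tests


def random_network(
    seed: int,
    n_nodes: int = 12,
    n_edges: int = 16,
    n_seeds: int = 2,
    rule_ids: tuple[str, ...] = ("syn-a", "syn-b"),
) -> Network:
    """A reproducible synthetic Network satisfying the structural
    invariants (generations are BFS distances from the seed set).

    Node "structures" are linear alkanes — stand-ins that give distinct
    canonical keys, not chemistry the rules ever see.
    """
    if n_seeds < 1 or n_seeds > n_nodes:
        raise ValidationError("need 1 <= n_seeds <= n_nodes")
    min_edges = n_nodes - n_seeds
    max_edges = n_nodes * (n_nodes - 1) * len(rule_ids) // 2
    if not min_edges <= n_edges <= max_edges:
        raise ValidationError(
            f"n_edges={n_edges} infeasible for {n_nodes} nodes (needs {min_edges}..{max_edges})"
        )
    rng = random.Random(seed)
    mols = [parse_structure("C" * (i + 1), "smiles", name=f"syn-{i}") for i in range(n_nodes)]
    keys = [m.canonical_key for m in mols]
    pairs: list[tuple[int, int]] = []
    reached = list(range(n_seeds))
    for i in range(n_seeds, n_nodes):
        pairs.append((rng.choice(reached), i))
        reached.append(i)
    seen_edges = set()
    edges: list[ReactionEdge] = []

    def add(u: int, v: int) -> bool:
        if u == v:
            return False
        rid = rng.choice(rule_ids)
        if rng.random() < 0.5:
            u, v = v, u
        ekey = (keys[u], keys[v], rid)
        if ekey in seen_edges or (keys[v], keys[u], rid) in seen_edges:
            return False
        seen_edges.add(ekey)
        edges.append(
            ReactionEdge(
                substrate_key=keys[u], product_key=keys[v], rule_id=rid,
                site_atoms=frozenset({0}), generation=1,
            )
        )
        return True

    for u, v in pairs:
        add(u, v)
    attempts = 0
    while len(edges) < n_edges and attempts < 50 * n_edges:
        add(rng.randrange(n_nodes), rng.randrange(n_nodes))
        attempts += 1

    # generations = undirected BFS distance from the seed set
    adj: dict[str, set[str]] = {k: set() for k in keys}
    for e in edges:
        adj[e.substrate_key].add(e.product_key)
        adj[e.product_key].add(e.substrate_key)
    gen = {keys[i]: 0 for i in range(n_seeds)}
    frontier = list(gen)
    d = 0
    while frontier:
        d += 1
        nxt = []
        for k in frontier:
            for n2 in adj[k]:
                if n2 not in gen:
                    gen[n2] = d
                    nxt.append(n2)
        frontier = nxt
    net = Network(
        compounds={
            keys[i]: CompoundEntry(mols[i], gen[keys[i]]) for i in range(n_nodes)
        },
        edges={},
        config={"synthetic": True, "seed": seed},
    )
    for e in edges:
        g = max(
            1,
            max(net.compounds[e.substrate_key].generation, net.compounds[e.product_key].generation),
        )
        net.edges[e.key] = ReactionEdge(
            substrate_key=e.substrate_key, product_key=e.product_key, rule_id=e.rule_id,
            site_atoms=e.site_atoms, generation=g,
        )
    return net


# ---------------------------------------------------------------------------
# convenience: the fully expanded fixture network


def expanded_network(generations: int = 4, known_only: bool = True) -> Network:
    """Expand the packaged pathway with the mini rules and catalogs."""
    from .rules import ExpansionConfig, expand

    pathway = noscapine_pathway()
    rules = mini_rules()
    return expand(
        pathway.metabolites,
        rules,
        mini_catalogs(),
        ExpansionConfig(generations=generations, known_only=known_only),
        seed_reactions=pathway.seed_edges(tuple(rules)),
    )


def default_filter() -> FilterSpec:
    return FilterSpec()
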
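"""Generalized bidirectional reaction rules and network expansion.

A rule abstracts an enzymatic reaction class as a pair of subgraph-rewrite
patterns (one per direction) plus bookkeeping the rest of the workflow
needs: a third-level EC class tag, the co-substrate/co-product context
(SAM->SAH for methylations, O2/NADPH for oxygenations, ...) and the
element-count change of the main substrate.  Cofactors are rule metadata
only — they are never instantiated as network nodes, so the network shows
just the main scaffold lineage.

Expansion is breadth-first by generation: at iteration g every rule is
applied in both directions to every compound of generation <= g-1, products
are canonicalized, and — under the default known-compound restriction —
kept only when they occur in at least one compound catalog.  Reactions
discovered by applying a rule in reverse are normalized to the rule's
forward orientation before deduplication, so an edge is stored once per
(substrate, product, rule) triple.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field, replace
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import yaml
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import FilterSpec, Molecule, element_counts, from_rdkit, passes_filter
from .errors import ConfigError, RuleLoadError

logger = logging.getLogger(__name__)

DIRECTIONS = ("forward", "reverse")

#: hard guard on the number of expansion iterations
MAX_GENERATIONS = 10


def _negate(delta: Mapping[str, int]) -> dict[str, int]:
    return {k: -v for k, v in delta.items() if v != 0}


def _norm_delta(delta: Mapping[str, int]) -> dict[str, int]:
    return {k: int(v) for k, v in sorted(delta.items()) if int(v) != 0}


@dataclass(frozen=True)
class ReactionRule:
    """A bidirectional generalized enzymatic reaction rule."""

    rule_id: str
    name: str
    ec_prefix: str
    smarts_forward: str
    smarts_reverse: str
    cofactors_forward: tuple[tuple[str, ...], tuple[str, ...]]  # (consumes, produces)
    delta_forward: dict[str, int]

    @cached_property
    def _rxns(self) -> dict[str, AllChem.ChemicalReaction]:
        return {
            "forward": AllChem.ReactionFromSmarts(self.smarts_forward),
            "reverse": AllChem.ReactionFromSmarts(self.smarts_reverse),
        }

    def rxn(self, direction: str) -> AllChem.ChemicalReaction:
        return self._rxns[direction]

    def cofactors(self, direction: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """(consumed, produced) cofactor names for the travelled direction."""
        consumes, produces = self.cofactors_forward
        return (consumes, produces) if direction == "forward" else (produces, consumes)

    def delta(self, direction: str) -> dict[str, int]:
        return dict(self.delta_forward) if direction == "forward" else _negate(self.delta_forward)


_REQUIRED_FIELDS = ("id", "ec_prefix", "smarts_forward", "smarts_reverse", "delta_forward")


def _validate_rule(raw: Mapping) -> ReactionRule:
    rid = raw.get("id")
    for f in _REQUIRED_FIELDS:
        if f not in raw:
            raise RuleLoadError("missing required field", rule_id=rid, field=f)
    for f in ("smarts_forward", "smarts_reverse"):
        try:
            rxn = AllChem.ReactionFromSmarts(raw[f])
        except Exception as exc:  # RDKit raises bare ValueError
            raise RuleLoadError(f"invalid reaction SMARTS: {exc}", rule_id=rid, field=f)
        if rxn.GetNumReactantTemplates() != 1 or rxn.GetNumProductTemplates() != 1:
            raise RuleLoadError(
                "rules rewrite a single main substrate into a single main product",
                rule_id=rid, field=f,
            )
        reactant_maps = {
            a.GetAtomMapNum() for a in rxn.GetReactantTemplate(0).GetAtoms() if a.GetAtomMapNum()
        }
        product_maps = {
            a.GetAtomMapNum() for a in rxn.GetProductTemplate(0).GetAtoms() if a.GetAtomMapNum()
        }
        if not product_maps <= reactant_maps:
            raise RuleLoadError(
                "every mapped atom in the rewrite must appear in the match pattern",
                rule_id=rid, field=f,
            )
    delta_f = _norm_delta(raw["delta_forward"] or {})
    delta_r = _norm_delta(raw.get("delta_reverse") or _negate(delta_f))
    if delta_r != _norm_delta(_negate(delta_f)):
        raise RuleLoadError(
            f"reverse delta {delta_r} is not the negation of forward delta {delta_f}",
            rule_id=rid, field="delta_reverse",
        )
    cof = raw.get("cofactors_forward") or {}
    return ReactionRule(
        rule_id=str(rid),
        name=str(raw.get("name", rid)),
        ec_prefix=str(raw["ec_prefix"]),
        smarts_forward=str(raw["smarts_forward"]),
        smarts_reverse=str(raw["smarts_reverse"]),
        cofactors_forward=(
            tuple(cof.get("consumes") or ()),
            tuple(cof.get("produces") or ()),
        ),
        delta_forward=delta_f,
    )


def load_rules(source: str | Path) -> list[ReactionRule]:
    """Load and validate a YAML rule collection.

    *source* may be a path or a YAML string.  An empty document yields an
    empty collection with a logged warning; schema violations raise
    :class:`RuleLoadError` naming the rule and field.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif source.strip() and "\n" not in source and Path(source).is_file():
        text = Path(source).read_text()
    else:
        text = source
    doc = yaml.safe_load(text)
    if not doc:
        logger.warning("rule document is empty; returning an empty collection")
        return []
    if isinstance(doc, str):
        raise RuleLoadError("document is not a rule collection")
    raw_rules = doc.get("rules", []) if isinstance(doc, Mapping) else doc
    if not raw_rules:
        logger.warning("rule document contains no rules")
        return []
    rules = [_validate_rule(r) for r in raw_rules]
    seen: set[str] = set()
    for r in rules:
        if r.rule_id in seen:
            raise RuleLoadError("duplicate rule id", rule_id=r.rule_id, field="id")
        seen.add(r.rule_id)
    return rules


# ---------------------------------------------------------------------------
# rule application


@dataclass(frozen=True)
class RuleApplication:
    """One product of applying a rule at one reactive site."""

    product: Molecule
    site_atoms: frozenset[int]          # substrate-side atoms, canonical indices
    product_site_atoms: frozenset[int]  # product-side atoms, canonical indices


def _canonical_product(pmol: Chem.Mol) -> tuple[Molecule, dict[int, int]] | None:
    """Sanitize and canonicalize a raw RunReactants product.

    Returns the product Molecule plus a map raw-index -> canonical-index,
    or None when the product cannot be sanitized (impossible chemistry at
    that match site).
    """
    try:
        Chem.SanitizeMol(pmol)
    except Exception:
        return None
    flat = Chem.Mol(pmol)
    Chem.RemoveStereochemistry(flat)
    smi = Chem.MolToSmiles(flat)
    order = json.loads(flat.GetProp("_smilesAtomOutputOrder"))
    remap = {orig: pos for pos, orig in enumerate(order)}
    product = Molecule(name="", canonical_key=smi, element_counts=element_counts(flat), source=smi)
    return product, remap


def apply_rule(
    rule: ReactionRule, m: Molecule, direction: str = "forward"
) -> list[RuleApplication]:
    """Apply *rule* to *m*, one outcome per distinct product.

    Products are canonicalized; symmetric matches yielding the same product
    are deduplicated (the site with the smallest atom-index tuple is kept).
    Products whose element counts disagree with the rule's declared delta
    are discarded with a warning — they indicate a pattern matching outside
    its intended chemistry.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    mol = m.mol  # built from canonical SMILES: atom indices are canonical
    expected = dict(m.element_counts)
    for k, v in rule.delta(direction).items():
        expected[k] = expected.get(k, 0) + v
    template = rule.rxn(direction).GetReactantTemplate(0)
    matches = mol.GetSubstructMatches(template, uniquify=False)
    outcomes: dict[str, RuleApplication] = {}
    for prods in rule.rxn(direction).RunReactants((mol,)):
        pmol = prods[0]
        got = _canonical_product(pmol)
        if got is None:
            continue
        product, remap = got
        if product.canonical_key == m.canonical_key:
            continue
        elements = set(expected) | set(product.element_counts)
        bad = any(
            product.element_counts.get(k, 0) != expected.get(k, 0) for k in elements
        )
        if bad:
            logger.warning(
                "rule %s (%s) on %s produced %s violating its element delta; discarded",
                rule.rule_id, direction, m.canonical_key, product.canonical_key,
            )
            continue
        mapped_sub = {
            a.GetIntProp("react_atom_idx")
            for a in pmol.GetAtoms()
            if a.HasProp("old_mapno") and a.HasProp("react_atom_idx")
        }
        site = _full_match_site(matches, mapped_sub)
        prod_site = frozenset(
            remap[a.GetIdx()]
            for a in pmol.GetAtoms()
            if a.HasProp("old_mapno") or not a.HasProp("react_atom_idx")
        )
        app = RuleApplication(product=product, site_atoms=site, product_site_atoms=prod_site)
        prev = outcomes.get(product.canonical_key)
        if prev is None or sorted(app.site_atoms) < sorted(prev.site_atoms):
            outcomes[product.canonical_key] = app
    return [outcomes[k] for k in sorted(outcomes)]


def _full_match_site(matches: Sequence[Sequence[int]], mapped_sub: set[int]) -> frozenset[int]:
    """The template match (full reactive site) consistent with the mapped atoms."""
    candidates = [frozenset(t) for t in matches if mapped_sub <= set(t)]
    if not candidates:
        return frozenset(mapped_sub)
    return min(candidates, key=lambda s: sorted(s))


# ---------------------------------------------------------------------------
# network types


@dataclass(frozen=True)
class ReactionEdge:
    """A rule-labelled reactant->product pair, stored in the rule's forward
    orientation regardless of the direction in which it was discovered."""

    substrate_key: str
    product_key: str
    rule_id: str
    direction: str = "forward"
    site_atoms: frozenset[int] = frozenset()
    status: str = "novel"  # "known" | "novel"
    generation: int = 1

    def __post_init__(self) -> None:
        if self.substrate_key == self.product_key:
            raise ValueError("substrate and product of an edge must differ")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.substrate_key, self.product_key, self.rule_id)


@dataclass
class CompoundEntry:
    molecule: Molecule
    generation: int
    catalog_class: str | None = None  # "biological" | "bioactive" | "chemical" | None


@dataclass(frozen=True)
class ExpansionConfig:
    generations: int = 4
    known_only: bool = True

    def __post_init__(self) -> None:
        if self.generations < 0:
            raise ConfigError("generations must be >= 0")
        if self.generations > MAX_GENERATIONS:
            raise ConfigError(f"generations guard exceeded ({self.generations} > {MAX_GENERATIONS})")


@dataclass
class Network:
    """Generation-indexed compounds plus rule-labelled reaction edges."""

    compounds: dict[str, CompoundEntry] = field(default_factory=dict)
    edges: dict[tuple[str, str, str], ReactionEdge] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def edge_list(self) -> list[ReactionEdge]:
        return [self.edges[k] for k in sorted(self.edges)]

    def compounds_at(self, generation: int) -> list[str]:
        return sorted(k for k, e in self.compounds.items() if e.generation == generation)

    def neighbors(self, key: str) -> set[str]:
        out: set[str] = set()
        for e in self.edges.values():
            if e.substrate_key == key:
                out.add(e.product_key)
            elif e.product_key == key:
                out.add(e.substrate_key)
        return out

    def has_pair(self, a: str, b: str) -> bool:
        """True when some edge (any rule, either orientation) links a and b."""
        return any(
            (e.substrate_key == a and e.product_key == b)
            or (e.substrate_key == b and e.product_key == a)
            for e in self.edges.values()
        )

    def validate(self) -> None:
        """Assert the structural invariants; raises AssertionError."""
        for e in self.edges.values():
            assert e.substrate_key in self.compounds, f"dangling substrate {e.substrate_key}"
            assert e.product_key in self.compounds, f"dangling product {e.product_key}"
        for key, entry in self.compounds.items():
            if entry.generation == 0:
                continue
            gens = [
                self.compounds[n].generation for n in self.neighbors(key) if n in self.compounds
            ]
            if gens:
                assert entry.generation == 1 + min(gens), (
                    f"{key}: generation {entry.generation} != 1 + min neighbor {min(gens)}"
                )


# ---------------------------------------------------------------------------
# expansion


def _catalog_lookup(catalogs) -> "callable":
    from .catalogs import classify_compound  # local import to avoid cycle

    def lookup(key: str) -> str | None:
        return classify_compound(key, catalogs)

    return lookup


def expand(
    seeds: Sequence[Molecule],
    rules: Sequence[ReactionRule],
    catalogs,
    config: ExpansionConfig | None = None,
    seed_reactions: Iterable[ReactionEdge] = (),
) -> Network:
    """Breadth-first rule expansion around *seeds*.

    ``seed_reactions`` (typically the input pathway's own reactions) are
    injected as edges so the original pathway is part of the network even
    where a step's chemistry is not covered by the loaded rule set.
    """
    config = config or ExpansionConfig()
    if not seeds:
        raise ValueError("seeds must be non-empty")
    lookup = _catalog_lookup(catalogs)
    net = Network(
        config={
            "generations": config.generations,
            "known_only": config.known_only,
            "rule_set": sorted(r.rule_id for r in rules),
        }
    )
    for m in seeds:
        net.compounds.setdefault(m.canonical_key, CompoundEntry(m, 0, lookup(m.canonical_key)))
    for e in seed_reactions:
        if e.substrate_key in net.compounds and e.product_key in net.compounds:
            net.edges.setdefault(e.key, e)
        else:
            logger.warning("seed reaction %s has endpoints outside the seed set; skipped", e.key)

    rules_sorted = sorted(rules, key=lambda r: r.rule_id)
    cache: dict[tuple[str, str, str], list[RuleApplication]] = {}
    for g in range(1, config.generations + 1):
        substrates = sorted(k for k, e in net.compounds.items() if e.generation <= g - 1)
        for key in substrates:
            m = net.compounds[key].molecule
            for rule in rules_sorted:
                for direction in DIRECTIONS:
                    ck = (key, rule.rule_id, direction)
                    if ck not in cache:
                        cache[ck] = apply_rule(rule, m, direction)
                    for app in cache[ck]:
                        pk = app.product.canonical_key
                        klass = lookup(pk)
                        if pk not in net.compounds:
                            if config.known_only and klass is None:
                                continue
                            net.compounds[pk] = CompoundEntry(app.product, g, klass)
                        if direction == "forward":
                            edge = ReactionEdge(
                                substrate_key=key, product_key=pk, rule_id=rule.rule_id,
                                site_atoms=app.site_atoms, generation=g,
                            )
                        else:  # normalize to the rule's forward orientation
                            edge = ReactionEdge(
                                substrate_key=pk, product_key=key, rule_id=rule.rule_id,
                                site_atoms=app.product_site_atoms, generation=g,
                            )
                        net.edges.setdefault(edge.key, edge)
    return net


def trim_network(n: Network, spec: FilterSpec | None = None) -> Network:
    """Keep exactly the compounds passing *spec* and the edges whose both
    endpoints survive.  Idempotent."""
    spec = spec or FilterSpec()
    kept = {k: e for k, e in n.compounds.items() if passes_filter(e.molecule, spec)}
    edges = {
        key: e for key, e in n.edges.items()
        if e.substrate_key in kept and e.product_key in kept
    }
    return Network(compounds=kept, edges=edges, config={**n.config, "trimmed": True})


def classify_reaction(edge: ReactionEdge, reference, seed_pathway) -> str:
    """'known' iff the (substrate, product, rule) triple occurs in the
    reference reaction DB or among the seed pathway's reactions (either
    orientation — reference reactions are direction-agnostic); else 'novel'.
    """
    pairs = {(edge.substrate_key, edge.product_key), (edge.product_key, edge.substrate_key)}
    for ref in reference:
        if (ref.substrate_key, ref.product_key) in pairs and (
            ref.rule_id is None or ref.rule_id == edge.rule_id
        ):
            return "known"
    for rxn in getattr(seed_pathway, "reactions", seed_pathway or ()):
        if (rxn.substrate_key, rxn.product_key) in pairs and rxn.rule_id == edge.rule_id:
            return "known"
    return "novel"


def classify_network(n: Network, reference, seed_pathway) -> Network:
    """Return a copy of *n* with every edge's status recomputed."""
    out = Network(compounds=dict(n.compounds), edges={}, config=dict(n.config))
    for key, e in n.edges.items():
        out.edges[key] = replace(e, status=classify_reaction(e, reference, seed_pathway))
    return out


# ---------------------------------------------------------------------------
# export


def network_to_json(n: Network) -> str:
    doc = {
        "config": n.config,
        "compounds": [
            {
                "key": k,
                "name": e.molecule.name,
                "generation": e.generation,
                "catalog_class": e.catalog_class,
            }
            for k, e in sorted(n.compounds.items())
        ],
        "reactions": [
            {
                "substrate": e.substrate_key,
                "product": e.product_key,
                "rule": e.rule_id,
                "status": e.status,
                "generation": e.generation,
                "site_atoms": sorted(e.site_atoms),
            }
            for e in n.edge_list()
        ],
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def network_to_graphml(n: Network, path: str | Path) -> None:
    """GraphML export with generation/status attributes (Gephi-ready)."""
    g = nx.MultiDiGraph()
    for k, e in sorted(n.compounds.items()):
        g.add_node(
            k,
            name=e.molecule.name or k,
            generation=e.generation,
            catalog_class=e.catalog_class or "none",
        )
    for e in n.edge_list():
        g.add_edge(
            e.substrate_key,
            e.product_key,
            rule=e.rule_id,
            status=e.status,
            generation=e.generation,
        )
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wb") as fh:
        nx.write_graphml(g, fh)
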
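"""Directed reactant-product graph and linear pathway enumeration.

Every network edge can in principle be travelled in both directions; the
pathway search removes directions that are thermodynamically or
catalytically implausible using the rule's cofactor context:

* directions that release molecular oxygen (reverse oxygenations),
* directions that bind CO2 to the substrate (reverse decarboxylations),
* demethylations whose cofactor context converts S-adenosylhomocysteine
  back to S-adenosylmethionine (other demethylations stay allowed).

Pathways are simple (vertex-disjoint) directed edge paths of bounded
length from any seed intermediate to a target.  Enumeration is exhaustive
within the step cap, which is exact at the scale this package works at;
zero-length pathways (the target already is an intermediate) are not
returned.  Pathways that share the compound chain but differ in rule
assignment are kept distinct, because the enzyme-ranking stage depends on
the rule's reactive site.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import ConfigError
from .rules import Network, ReactionEdge, ReactionRule

logger = logging.getLogger(__name__)

#: hard guard on the pathway step cap
MAX_STEPS_GUARD = 8

EXCLUSIONS = frozenset(
    {"produces_O2", "fixes_CO2_reverse_decarboxylation", "demethylation_SAH_to_SAM"}
)


@dataclass(frozen=True)
class SearchConfig:
    max_steps: int = 4
    exclusions: frozenset[str] = EXCLUSIONS

    def __post_init__(self) -> None:
        if self.max_steps < 1:
            raise ConfigError("max_steps must be >= 1")
        if self.max_steps > MAX_STEPS_GUARD:
            raise ConfigError(f"max_steps guard exceeded ({self.max_steps} > {MAX_STEPS_GUARD})")
        unknown = set(self.exclusions) - EXCLUSIONS
        if unknown:
            raise ConfigError(f"unknown exclusions: {sorted(unknown)}")


@dataclass(frozen=True)
class Step:
    """One travelled arc of a pathway."""

    substrate_key: str
    product_key: str
    rule_id: str
    direction: str  # direction of the underlying rule when travelled this way
    status: str = "novel"

    @property
    def arc_id(self) -> str:
        return f"{self.substrate_key}>{self.product_key}:{self.rule_id}:{self.direction}"


@dataclass(frozen=True)
class Pathway:
    source: str
    target: str
    steps: tuple[Step, ...]

    def __post_init__(self) -> None:
        assert self.steps, "a pathway has at least one step"
        assert self.steps[0].substrate_key == self.source
        assert self.steps[-1].product_key == self.target
        visited = [self.source] + [s.product_key for s in self.steps]
        for a, b in zip(self.steps, self.steps[1:]):
            assert a.product_key == b.substrate_key, "steps must chain"
        assert len(set(visited)) == len(visited), "pathways are acyclic"

    @property
    def length(self) -> int:
        return len(self.steps)

    def compounds(self) -> list[str]:
        return [self.source] + [s.product_key for s in self.steps]

    def sort_key(self) -> tuple:
        return (self.length, tuple(s.arc_id for s in self.steps))


def is_excluded_direction(
    edge: ReactionEdge,
    rule: ReactionRule,
    travel: str,
    exclusions: Iterable[str] = EXCLUSIONS,
) -> bool:
    """Whether travelling *edge* in direction *travel* is excluded.

    *travel* is relative to the stored (rule-forward) orientation:
    ``forward`` means substrate -> product.  The decision looks only at the
    rule's cofactor context for the travelled direction.
    """
    exclusions = set(exclusions)
    consumed, produced = rule.cofactors(travel)
    if "produces_O2" in exclusions and "O2" in produced:
        return True
    if "fixes_CO2_reverse_decarboxylation" in exclusions and "CO2" in consumed:
        return True
    if (
        "demethylation_SAH_to_SAM" in exclusions
        and "SAH" in consumed
        and "SAM" in produced
    ):
        return True
    return False


def build_pair_graph(
    n: Network,
    rules: Sequence[ReactionRule],
    config: SearchConfig | None = None,
) -> nx.MultiDiGraph:
    """One arc per allowed (edge, direction); arcs carry rule and status.

    Edges whose rule is not in *rules* (e.g. seed-pathway steps outside the
    loaded rule set) are treated as having an empty cofactor context, hence
    both directions allowed.
    """
    config = config or SearchConfig()
    by_id = {r.rule_id: r for r in rules}
    g = nx.MultiDiGraph()
    g.add_nodes_from(sorted(n.compounds))
    for e in n.edge_list():
        rule = by_id.get(e.rule_id)
        for travel, (u, v) in (
            ("forward", (e.substrate_key, e.product_key)),
            ("reverse", (e.product_key, e.substrate_key)),
        ):
            if rule is not None and is_excluded_direction(e, rule, travel, config.exclusions):
                continue
            g.add_edge(u, v, rule_id=e.rule_id, direction=travel, status=e.status)
    return g


def enumerate_pathways(
    graph: nx.MultiDiGraph,
    sources: Iterable[str],
    target: str,
    config: SearchConfig | None = None,
) -> list[Pathway]:
    """Every simple directed path of length 1..max_steps from any source to
    *target*, in deterministic order (length, then lexicographic arc ids).
    """
    config = config or SearchConfig()
    sources = sorted(set(sources))
    if target not in graph:
        logger.warning("pathway target %s is not in the graph", target)
        return []
    found: list[Pathway] = []
    for src in sources:
        if src == target or src not in graph:
            continue
        _dfs(graph, src, target, config.max_steps, [src], [], found)
    found.sort(key=Pathway.sort_key)
    return found


def _dfs(graph, node, target, budget, visited, steps, found) -> None:
    if budget == 0:
        return
    for _, nxt, data in sorted(
        graph.out_edges(node, data=True),
        key=lambda t: (t[1], t[2]["rule_id"], t[2]["direction"]),
    ):
        if nxt in visited:
            continue
        step = Step(
            substrate_key=node, product_key=nxt,
            rule_id=data["rule_id"], direction=data["direction"],
            status=data.get("status", "novel"),
        )
        if nxt == target:
            found.append(Pathway(source=visited[0], target=target, steps=tuple(steps + [step])))
            continue
        _dfs(graph, nxt, target, budget - 1, visited + [nxt], steps + [step], found)


def contains_pathway(n: Network, reference: Sequence) -> bool:
    """True iff every consecutive compound pair of *reference* is linked by
    some network edge (any rule, either orientation).

    *reference* is an ordered list of canonical keys or objects with a
    ``canonical_key`` attribute; it must name at least two compounds.
    """
    keys = [getattr(c, "canonical_key", c) for c in reference]
    if len(keys) < 2:
        raise ValueError("a reference pathway needs at least two compounds")
    return all(n.has_pair(a, b) for a, b in zip(keys, keys[1:]))


def recovered_fraction(n: Network, references: Mapping[str, Sequence]) -> dict:
    """Per-pathway recovery of a set of named reference pathways."""
    results = {name: contains_pathway(n, chain) for name, chain in references.items()}
    found = sum(results.values())
    return {
        "per_pathway": results,
        "recovered": found,
        "total": len(results),
        "fraction": found / len(results) if results else 0.0,
    }


# ---------------------------------------------------------------------------
# serialization


def pathways_to_json(paths: Sequence[Pathway]) -> str:
    doc = [
        {
            "source": p.source,
            "target": p.target,
            "length": p.length,
            "steps": [
                {
                    "substrate": s.substrate_key,
                    "product": s.product_key,
                    "rule": s.rule_id,
                    "direction": s.direction,
                    "status": s.status,
                }
                for s in p.steps
            ],
        }
        for p in paths
    ]
    return json.dumps(doc, indent=2)


def pathways_to_tsv(paths: Sequence[Pathway], names: Mapping[str, str] | None = None) -> str:
    names = names or {}
    buf = io.StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(["pathway", "length", "step", "substrate", "product", "rule", "direction", "status"])
    for i, p in enumerate(paths, start=1):
        for j, s in enumerate(p.steps, start=1):
            w.writerow([
                i, p.length, j,
                names.get(s.substrate_key, s.substrate_key),
                names.get(s.product_key, s.product_key),
                s.rule_id, s.direction, s.status,
            ])
    return buf.getvalue()
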
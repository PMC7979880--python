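# metexpand

Tools for exploring the **biochemical vicinity of a heterologous
biosynthetic pathway**: given the ordered intermediates of a pathway
reconstituted in a microbial host, which catalogued natural products could
be reached by derivatizing those intermediates with one or a few enzymatic
steps — and which known enzymes are the best candidates to catalyze each
new step?

The package targets metabolic engineers working on plant natural products
(the packaged study system is the 17-metabolite noscapine pathway of the
benzylisoquinoline alkaloids, BIAs) but every stage takes ordinary files —
structures, rule sets, catalogs, annotation tables — so any linear pathway
can be analyzed.

## The method

1. **Rule-based network expansion.** Enzymatic reaction classes are
   abstracted as *generalized bidirectional rules*: a reactive-site
   subgraph pattern plus a rewrite (aromatic *O*-methylation,
   *N*-methylation, methylenedioxy-bridge formation, berberine-bridge
   cyclization, hydroxylations, acetyl transfer, ...). Every rule is
   applied in both directions to every compound, breadth-first by
   *generation* (reaction steps from the seed pathway). Only structures
   found in a biological / bioactive / chemical compound catalog are kept
   ("known-compound" restriction), so the network stays interpretable.
   Stereochemistry is ignored throughout: compounds are deduplicated by a
   stereo-stripped canonical SMILES key.
2. **Scaffold trim.** Substrates and products must contain the minimal
   elemental composition of the 1-benzylisoquinoline scaffold — at least
   C16, H13 and N1 (configurable).
3. **Popularity ranking.** Candidate derivatives are ranked by
   *popularity* = citations + patents; compounds without a single
   annotation are dropped; seed metabolites are excluded.
4. **Pathway enumeration.** All simple directed pathways (≤ 4 steps by
   default) from any pathway intermediate to a target are extracted from
   the reactant–product graph. Directions that release O₂, fix CO₂
   (reverse decarboxylations) or run a demethylation that converts SAH
   back to SAM are excluded as thermodynamically/catalytically implausible.
5. **Enzyme candidate ranking.** Each novel reaction is fingerprinted by
   the canonical atom environments at bond radii 1..7 around its reactive
   site (substrate and product side) and compared against a reference DB
   of enzyme-annotated reactions; similarity is the mean per-depth Jaccard
   overlap in [0, 1] (1.0 = identical up to 7 bonds around the site;
   > 0.3 counts as significant). Orphan reactions (no protein sequence)
   are removed. A pathway's feasibility is the mean of its steps' top
   scores.

## Worked example

The packaged fixture reproduces the noscapine study system offline:
17 metabolites, 17 reactions, 11 rule classes, a 12-rule mini rule set,
catalogs, a citation/patent table and a miniature reference reaction DB.

```bash
metexpand --seed 1 --out out rank --one-step
```

prints the one-step candidate table (popularity-ranked compounds one
reaction from a pathway intermediate):

```
rank  name                 popularity  citations  patents  distance  best_score  predicted_ec
1     berberine            12181       5430       6751     1         1.0         1.3.3.8
2     tetrahydropalmatine  885         530        355      1         0.79        2.1.1.291
3     columbamine          366         131        235      1         0.6         1.3.3.8
4     norlaudanosoline     321         144        177      1         0.74        1.14.14.102
5     laudanine            135         23         112      1         1.0         2.1.1.291
...
```

Reading it: berberine is the most-studied compound reachable in one step
(its producing reaction is identical to a reference reaction, score 1.0,
EC 1.3.3.8 — tetrahydroprotoberberine oxidase); tetrahydropalmatine, the
second-ranked candidate, needs a novel aromatic *O*-methylation whose
closest sequence-annotated reference is reticuline 7-*O*-methyltransferase
(EC 2.1.1.291, score 0.79). Note berberine's popularity is the
definitional sum 5430 + 6751 = 12181; the upstream table's printed total
(12154) is internally inconsistent and is flagged, not repaired.

Other subcommands: `expand` (network JSON + Gephi-ready GraphML), `trim`,
`annotate`, `pathways --target tetrahydropalmatine` (11 routes ≤ 4 steps,
with feasibility scores), `enzymes --target ...` (reference-ranked enzyme
table), `validate` (recovers 12 of 13 known external BIA biosynthesis
routes; the papaverine route needs chemistry outside the mini rule set),
and `fixtures` (materialize all packaged inputs as TSV/YAML/JSON/SDF/
molfiles).

Everything is also available as a library:

```python
from metexpand import fixtures as fx
from metexpand.rules import trim_network

net = trim_network(fx.expanded_network(generations=4))
print(len(net.compounds), len(net.edges))   # 31 compounds, 39 reactions
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full workflow from the packaged inputs — expansion (4
generations), trim, candidate ranking with enzyme annotation, pathway
enumeration to tetrahydropalmatine, enzyme ranking for the target
methylation, and the external-pathway recovery check — and writes the
results JSON to `--out`.

## Layout

- `src/metexpand/` — `chem`, `rules`, `catalogs`, `pathways`, `enzymes`,
  `fixtures`, `cli`
- `src/metexpand/data/` — packaged fixture tables (plain text)
- `docs/methods.md` — the model, its assumptions and numerical choices
- `tests/` — unit, property and acceptance suites
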
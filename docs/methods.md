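# Methods

## Scope and model

`metexpand` models the *chemical neighborhood* of a linear biosynthetic
pathway as a generation-indexed reaction network. The unit of chemistry is
the **generalized bidirectional reaction rule**: a SMARTS reactive-site
pattern plus a rewrite, tagged with a third-level EC class, a cofactor
context (co-substrate/co-product names such as SAM→SAH or O₂/NADPH→H₂O)
and the element-count change of the main substrate. Cofactors are
metadata only — they are never nodes of the network, so the network shows
the main scaffold lineage.

Assumptions inherited by every stage:

- **No stereochemistry.** All stereo descriptors are stripped before the
  canonical key (RDKit canonical SMILES under RDKit's default aromaticity
  model) is computed. Stereoisomers are one compound; fixture names keep
  their literature `(S)-` prefixes as labels only.
- **No tautomer merging.** Distinct tautomers get distinct keys. The one
  place this matters in the packaged pathway — the ring-chain pair of the
  deacetylated papaveroxine/narcotine-hemiacetal intermediate — is stored
  in the cyclic hemiacetal form, and the seed reaction producing it is
  injected rather than re-derived by the esterase rule.
- **Single fragment, charges allowed.** Multi-fragment input (salts,
  mixtures) is rejected rather than split. Intramolecular charges are
  accepted: the quaternary protoberberinium intermediates of the noscapine
  pathway (N-methylcanadine onward) and the aromatized alkaloids
  (berberine, columbamine, palmatine) are single-fragment cations.

## Network expansion

Expansion is breadth-first and closed-world. Seeds are generation 0; at
iteration *g* every rule is applied in both directions to every compound
of generation ≤ *g*−1. Products are canonicalized, and under the default
`known_only` policy kept only when they occur in at least one compound
catalog (classes *biological* > *bioactive* > *chemical*, a compound
counted once at the highest precedence). A reaction discovered by a
reverse application is normalized to the rule's forward orientation, so
edges are unique per (substrate, product, rule); two rules linking the
same pair give two edges, because enzyme ranking depends on the rule's
reactive site. The seed pathway's own reactions are injected as known
edges (generation 1 — the edge type's floor) so the original pathway is
always contained in its network, including the two steps outside the
executable rule set (the spontaneous carbinolamine ring opening, and the
tautomer-folded deacetylation above).

A compound's generation equals its undirected BFS distance from the seed
set (the "produced-by" formulation is vacuous for compounds first reached
by a reverse application); `Network.validate()` asserts exactly this, and
the test suite cross-checks it against networkx shortest paths. Guards:
≤ 10 generations, ≤ 8 pathway steps.

Reactions are classified **known** when the (substrate, product) pair —
either orientation, reference reactions being direction-agnostic — occurs
in the reference reaction DB or among the seed pathway's reactions, and
the rule matches where the reference records one; everything else is
**novel**.

## The mini rule set

Twelve expert-written rules ship with the package: aromatic
*O*-methylation, secondary-amine and quaternizing *N*-methylation (all
2.1.1.-, SAM→SAH; their reverses are SAH→SAM demethylations),
methylenedioxy-bridge formation (CYP719-type, 1.14.19.-), aromatic and
benzylic hydroxylation, the berberine-bridge cyclization (1.21.3.-),
tetrahydroprotoberberine oxidase ring-C aromatization (1.3.3.-),
*O*-acetylation, acetyl-ester hydrolysis, alcohol/hemiacetal oxidation
and aromatic (de)carboxylation. This exercises every code path — including
directions that must be excluded in pathway search — without claiming
parity with any full published rule collection. Rule files are open YAML;
the loader checks that reverse deltas negate forward deltas and that every
mapped product atom appears in the match pattern. Products whose element
counts disagree with the declared delta (a pattern matching outside its
intended chemistry) are discarded with a warning.

## Candidate ranking

Popularity is definitional: citations + patents, nothing else. Compounds
with zero annotations are dropped (the "at least one annotation" filter),
seed metabolites are excluded, ties break by compound name ascending (the
digit-leading name `1,2-dehydroreticuline` therefore sorts before letters;
the packaged network never surfaces this tie). Where an annotation table
carries a `reported_total` column disagreeing with the sum — the packaged
table reproduces one such row (berberine: printed 12154 vs 5430 + 6751 =
12181) — the row is *flagged* in a validation report and the sum is used.

`distance` in candidate reports is the compound's generation; the
one-step table keeps generation-1 rows. The `best_score`/`predicted_ec`
columns take, over all edges linking the candidate to a lower-generation
neighbor, the best enzyme candidate of the reaction travelled
neighbor→candidate.

## Pathway search

The reactant–product graph carries one arc per allowed (edge, direction).
A direction is excluded when its cofactor context (of the travelled
direction) produces O₂, consumes CO₂ (reverse decarboxylation — detected
via the declared cofactors, the criterion being "binding CO₂ to the
substrate"), or consumes SAH while producing SAM (methyl-transfer
demethylation; oxidative demethylations would remain allowed). Pathway
enumeration is an exhaustive DFS over simple (vertex-disjoint) directed
paths of 1..`max_steps` arcs — exact at this scale, no reactant-pair
weighting — returned in deterministic order (length, then lexicographic
arc ids). Zero-length pathways are not returned. Pathways identical as
compound chains but differing in rule assignment are kept distinct.

## Reactive-site fingerprints and enzyme ranking

The reactive site of a reaction is the atom set matched by its rule
(substrate side) and the mapped/new atoms of the rewrite (product side);
for stored reactions it is recomputed by re-matching the rule and
selecting the application that reproduces the recorded product — failure
to re-match raises a consistency error.

The fingerprint enumerates, for depths d = 1..7 (bond radius — "seven
atoms around the reactive site" is *interpreted* as bond radius 7), the
canonical SMILES fragments within d bonds of each site atom, tagged by
side (S/P) and depth. Multi-site reactions contribute by feature union.
Similarity of two fingerprints is the unweighted mean over depths of the
Jaccard overlap of the depth-d feature sets (a depth empty on both sides
counts as identical; equal weights mean deeper shells never outweigh
shallower ones). Consequences worth knowing: identity within 7 bonds of
the site ⇒ 1.0; different rule classes share no depth-1 feature ⇒ 0.0;
same-rule reactions on unrelated scaffolds score near the significance
threshold (≈ 0.3–0.4), because only the shallow shells agree. Scores are
**not** numerically comparable to any previously published reaction-
similarity tool; only the qualitative contract (bounds, identity,
symmetry, sensible ordering) is claimed. Significance is strict:
score > 0.3.

Ranking removes orphan references (`has_sequence = false`), sorts by
descending score with ties by EC then reference id, and reports one best
row per EC class. Pathway feasibility is the arithmetic mean of each
step's top candidate score; steps classified *known* score 1.0 by
convention — an enzyme is already assigned, so they pose no discovery
problem.

## The packaged study system

The fixture reconstructs the noscapine pathway: 17 metabolites from
norcoclaurine to noscapine, 17 reactions, 11 distinct rule classes. The
upstream half (norcoclaurine → canadine) follows the canonical BIA route;
downstream intermediates carry their standard pathway names with
reconstructed constitutions. Because the literature does not print the
exact rule-class assignment over the 17 reactions, the fixture's
assignment is a documented reconstruction; the 17th reaction is the
esterase's promiscuous deacetylation of the 13-*O*-acetyl intermediate (a
futile-cycle edge), included to complete the stated 17/17/11 counts.
Catalogs cover all fixture compounds except one deliberate decoy
(4'-*O*-methyl-*N*-methylcoclaurine) that tests the known-compound
restriction. The annotation table reproduces the printed citation/patent
counts of the 15 one-step candidates. The reference reaction DB holds 29
enzyme-annotated reactions spanning the 18 *O*-methyltransferase classes
of the published enzyme table plus the CYP719, CNMT, TNMT, BBE, STOX and
NMCH classes, and one orphan entry (the tetrahydrocolumbamine
2-*O*-methylation, EC 2.1.1.89, sequence-less — the reaction whose
enzyme-discovery problem motivates the whole workflow). Structures of
participants too large to embed faithfully (coenzyme A, polyprenyl
tails, the tabersonine scaffold) are truncated synthetic stand-ins, and
CYP719 EC sub-numbers other than 1.14.19.73 are reconstructions.

What a green test therefore establishes: the *mechanics* — expansion,
trimming, ranking, enumeration, fingerprinting — reproduce the published
worked examples (one-step candidates and their order, popularity sums,
directionality exclusions, 12/13 external-pathway recovery with the
papaverine route honestly unreachable). What it does not establish:
network-scale figures (thousands of compounds/reactions) or printed
similarity scores, which depend on a 442-rule collection and 2018–2019
database snapshots that are out of scope.

`random_network(seed, ...)` generates invariant-satisfying synthetic
networks (alkane stand-in nodes, BFS-consistent generations) for stress
tests; it emulates graph shape only, not chemistry.

## Numerical and engineering choices

- Canonicalization is RDKit canonical SMILES (stereo stripped); rule
  matching operates on molecules rebuilt from that SMILES, so recorded
  site-atom indices are stable across runs.
- Products that fail sanitization at a match site are skipped (no partial
  products); symmetric matches yielding one product keep the
  smallest-index site.
- GraphML export (Gephi-ready) is verified by networkx read round-trip;
  no offline XSD validation.
- All reports are pure functions of (inputs, config, seed); TSV bodies are
  byte-stable and carry a header naming the tool version and a hash of the
  scientific configuration (output paths and log level excluded).
- Reaction fingerprints are cached process-wide by (substrate key,
  product key, rule, direction, depth).

## Known limitations

- The esterase/acetylation pair makes ester hydrolysis reachable in two
  rule guises (reverse acetylation and forward hydrolysis); both edges are
  kept by design, which slightly inflates edge counts.
- Aromatic hydroxylation is deliberately promiscuous (any aromatic C–H);
  the known-compound restriction is what keeps it in check, so running
  with `known_only=false` on large seeds grows quickly.
- The live citation/patent annotation adapter is not implemented; the
  offline tables are canonical.
- Quaternizing N-methylation assigns the +1 charge to the product with no
  counterion model; pKa/charge equilibria are out of scope.
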
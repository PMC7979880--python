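"""Reactive-site fingerprints, similarity scoring and enzyme ranking."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from metexpand import fixtures as fx
from metexpand.chem import parse_structure
from metexpand.errors import ConfigError, ConsistencyError, ValidationError
from metexpand.enzymes import (
    EnzymeCandidate,
    NovelReaction,
    PathwayScore,
    ReactionFingerprint,
    ReferenceReaction,
    SimilarityConfig,
    ec_is_valid,
    fingerprint,
    pathway_feasibility,
    rank_enzymes,
    reactive_site,
    significant,
    similarity,
)
from metexpand.pathways import Step


@pytest.fixture(scope="module")
def omt(rules_by_id):
    return rules_by_id["omt-aromatic"]


@pytest.fixture(scope="module")
def thc_to_thp(omt):
    return NovelReaction(fx.molecule("tetrahydrocolumbamine"),
                         fx.molecule("tetrahydropalmatine"), omt)


# ---------------------------------------------------------------------------
# EC formats and config guards


@pytest.mark.parametrize("ec,ok", [
    ("2.1.1.291", True), ("1.14.19.-", True), ("2.1.-.-", True),
    ("2.1.1", False), ("x.1.1.1", False), ("2.1.1.291.5", False),
])
def test_ec_wellformedness(ec, ok):
    assert ec_is_valid(ec) is ok


def test_reference_reaction_rejects_bad_ec():
    m = parse_structure("Oc1ccccc1", "smiles")
    with pytest.raises(ValidationError):
        ReferenceReaction("r", "banana", m, m, "x", "t", "o", True)


def test_similarity_config_guards():
    with pytest.raises(ConfigError):
        SimilarityConfig(max_depth=0)
    with pytest.raises(ConfigError):
        SimilarityConfig(max_depth=8)
    with pytest.raises(ConfigError):
        SimilarityConfig(threshold=1.5)


# ---------------------------------------------------------------------------
# reactive site


def test_reactive_site_of_thc_methylation(thc_to_thp):
    sub_sites, prod_sites = reactive_site(thc_to_thp.substrate, thc_to_thp.product,
                                          thc_to_thp.rule)
    mol = thc_to_thp.substrate.mol
    symbols = {mol.GetAtomWithIdx(i).GetSymbol() for i in sub_sites}
    assert "O" in symbols and "C" in symbols   # phenolic oxygen + ring carbon
    aromatic = [i for i in sub_sites if mol.GetAtomWithIdx(i).GetIsAromatic()]
    assert aromatic
    assert sub_sites <= set(range(mol.GetNumAtoms()))
    pmol = thc_to_thp.product.mol
    assert prod_sites <= set(range(pmol.GetNumAtoms()))


def test_reactive_site_round_trips_recorded_edges(network, rules_by_id):
    """Re-matching the rule on a stored edge reproduces its recorded site."""
    checked = 0
    for e in network.edge_list():
        rule = rules_by_id.get(e.rule_id)
        if rule is None or not e.site_atoms:
            continue
        sub = network.compounds[e.substrate_key].molecule
        prod = network.compounds[e.product_key].molecule
        sub_sites, _ = reactive_site(sub, prod, rule)
        assert sub_sites == e.site_atoms, (e.rule_id, e.substrate_key)
        checked += 1
        if checked >= 10:
            break
    assert checked >= 10


def test_reactive_site_inconsistency_error(omt):
    with pytest.raises(ConsistencyError):
        reactive_site(fx.molecule("tetrahydrocolumbamine"), fx.molecule("berberine"), omt)


# ---------------------------------------------------------------------------
# fingerprints


def test_identical_reactions_have_identical_fingerprints(thc_to_thp, omt):
    again = NovelReaction(fx.molecule("tetrahydrocolumbamine"),
                          fx.molecule("tetrahydropalmatine"), omt)
    assert fingerprint(thc_to_thp) == fingerprint(again)


def test_depth1_phenol_methylation_features_are_substrate_independent(omt):
    """The depth-1 shell sees only the O/ipso-carbon/methyl environment,
    which is the same for any para-substituted phenol O-methylation."""
    pairs = [
        ("CC=Cc1ccc(O)cc1", "CC=Cc1ccc(OC)cc1"),            # anol
        ("CCCCc1ccc(O)cc1", "CCCCc1ccc(OC)cc1"),            # butylphenol
        ("OCc1ccc(O)cc1", "OCc1ccc(OC)cc1"),                # hydroxymethyl
    ]
    fps = []
    for sub, prod in pairs:
        fps.append(fingerprint(NovelReaction(parse_structure(sub, "smiles"),
                                             parse_structure(prod, "smiles"), omt)))
    assert fps[0].at_depth(1) == fps[1].at_depth(1) == fps[2].at_depth(1)


def test_fingerprint_blind_beyond_max_depth(omt):
    """Two methylations identical within 7 bonds of the site but differing
    farther out get identical fingerprints."""
    short = NovelReaction(parse_structure("CCCCCCCCc1ccc(O)cc1", "smiles"),
                          parse_structure("CCCCCCCCc1ccc(OC)cc1", "smiles"), omt)
    longer = NovelReaction(parse_structure("CCCCCCCCCCCCc1ccc(O)cc1", "smiles"),
                           parse_structure("CCCCCCCCCCCCc1ccc(OC)cc1", "smiles"), omt)
    f1, f2 = fingerprint(short), fingerprint(longer)
    assert f1 == f2
    assert similarity(f1, f2) == 1.0


# ---------------------------------------------------------------------------
# similarity


def _naive_similarity(a, b):
    """Brute-force overlap oracle: plain mean of per-depth Jaccards."""
    vals = []
    for d in range(1, 8):
        fa, fb = a.at_depth(d), b.at_depth(d)
        vals.append(1.0 if not (fa | fb) else len(fa & fb) / len(fa | fb))
    return sum(vals) / 7


def test_similarity_matches_naive_overlap_oracle(rules_by_id, reference_db):
    by_id = rules_by_id
    fps = []
    for ref in reference_db[:12]:
        rule = by_id[ref.rule_id]
        fps.append(fingerprint(NovelReaction(ref.substrate, ref.product, rule)))
    rng = random.Random(0)
    for _ in range(10):
        a, b = rng.sample(fps, 2)
        assert similarity(a, b) == pytest.approx(_naive_similarity(a, b), abs=1e-12)


def test_similarity_self_identity_symmetry_bounds(rules_by_id, reference_db):
    fps = []
    for ref in reference_db[:8]:
        rule = rules_by_id[ref.rule_id]
        fps.append(fingerprint(NovelReaction(ref.substrate, ref.product, rule)))
    for a in fps:
        assert similarity(a, a) == 1.0
    for a in fps:
        for b in fps:
            s = similarity(a, b)
            assert 0.0 <= s <= 1.0
            assert s == similarity(b, a)


def test_different_rule_classes_share_nothing(rules_by_id):
    omt_rxn = NovelReaction(fx.molecule("tetrahydrocolumbamine"),
                            fx.molecule("tetrahydropalmatine"),
                            rules_by_id["omt-aromatic"])
    nmt_rxn = NovelReaction(fx.molecule("coclaurine"),
                            fx.molecule("N-methylcoclaurine"),
                            rules_by_id["nmt-secondary"])
    assert similarity(fingerprint(omt_rxn), fingerprint(nmt_rxn)) == 0.0


def test_similarity_config_mismatch_is_an_error(thc_to_thp):
    a = fingerprint(thc_to_thp, SimilarityConfig(max_depth=7))
    b = fingerprint(thc_to_thp, SimilarityConfig(max_depth=3))
    with pytest.raises(ConfigError):
        similarity(a, b)


_feature = st.text(alphabet="abcxyz|123", min_size=1, max_size=6)


@given(st.lists(st.frozensets(_feature, max_size=5), min_size=3, max_size=3),
       st.lists(st.frozensets(_feature, max_size=5), min_size=3, max_size=3))
@settings(max_examples=60, deadline=None)
def test_similarity_properties_on_arbitrary_feature_sets(la, lb):
    fa = ReactionFingerprint(3, tuple(la))
    fb = ReactionFingerprint(3, tuple(lb))
    s = similarity(fa, fb)
    assert 0.0 <= s <= 1.0
    assert s == similarity(fb, fa)
    assert similarity(fa, fa) == 1.0
    if all(not (x & y) for x, y in zip(la, lb)) and any(x | y for x, y in zip(la, lb)):
        assert s < 1.0


# ---------------------------------------------------------------------------
# ranking


def test_db_containing_the_novel_reaction_ranks_it_first(rules_by_id, reference_db):
    novel = NovelReaction(fx.molecule("scoulerine"), fx.molecule("nandinine"),
                          rules_by_id["methylenedioxy"])
    ranked = rank_enzymes(novel, reference_db, list(rules_by_id.values()))
    assert ranked[0].score == 1.0
    perfect = {c.ec for c in ranked if c.score == 1.0}
    assert "1.14.19.73" in perfect  # the identical reference reaction's EC


def test_orphan_references_are_removed(thc_to_thp, reference_db, rules):
    ranked = rank_enzymes(thc_to_thp, reference_db, rules)
    assert "2.1.1.89" not in {c.ec for c in ranked}  # the orphan entry
    assert ranked[0].ec == "2.1.1.291"
    assert ranked == sorted(ranked, key=lambda c: (-c.score, c.ec, c.reference_id))


def test_orphan_filter_preserves_relative_order_of_survivors(thc_to_thp, reference_db, rules):
    with_orphans = [r for r in reference_db]
    without = [r for r in reference_db if r.has_sequence]
    a = rank_enzymes(thc_to_thp, with_orphans, rules)
    b = rank_enzymes(thc_to_thp, without, rules)
    assert a == b


def test_ranking_deterministic_under_db_permutation(thc_to_thp, reference_db, rules):
    shuffled = list(reference_db)
    random.Random(3).shuffle(shuffled)
    assert rank_enzymes(thc_to_thp, shuffled, rules) == rank_enzymes(
        thc_to_thp, reference_db, rules
    )


def test_one_best_row_per_ec(thc_to_thp, reference_db, rules):
    ranked = rank_enzymes(thc_to_thp, reference_db, rules)
    ecs = [c.ec for c in ranked]
    assert len(ecs) == len(set(ecs))


def test_empty_db_warns_and_returns_empty(thc_to_thp, rules, caplog):
    with caplog.at_level("WARNING"):
        assert rank_enzymes(thc_to_thp, [], rules) == []


def _cand(score, ec="2.1.1.1"):
    return EnzymeCandidate(ec=ec, score=score, reference_id="r",
                           native_substrate="s", substrate_type="t", organism="o")


def test_significance_threshold_is_strict():
    cands = [_cand(0.31), _cand(0.30), _cand(0.299), _cand(1.0)]
    kept = significant(cands)
    assert [c.score for c in kept] == [0.31, 1.0]
    assert significant([]) == []


# ---------------------------------------------------------------------------
# pathway feasibility


def test_known_steps_score_one(network, reference_db, rules):
    step = Step(substrate_key=fx.key_of("tetrahydrocolumbamine"),
                product_key=fx.key_of("tetrahydropalmatine"),
                rule_id="omt-aromatic", direction="forward", status="known")
    ps = pathway_feasibility([step], network, reference_db, rules)
    assert ps.step_top_scores == (1.0,)
    assert ps.mean_top_score == 1.0


def test_mean_is_the_arithmetic_mean_of_step_tops(network, reference_db, rules, rules_by_id):
    novel_step = Step(substrate_key=fx.key_of("scoulerine"),
                      product_key=fx.key_of("tetrahydropalmatrubine"),
                      rule_id="omt-aromatic", direction="forward", status="novel")
    known_step = Step(substrate_key=fx.key_of("reticuline"),
                      product_key=fx.key_of("scoulerine"),
                      rule_id="bbe-bridge", direction="forward", status="known")
    alone = pathway_feasibility([novel_step], network, reference_db, rules)
    s = alone.mean_top_score
    assert alone.step_top_scores == (s,)
    both = pathway_feasibility([known_step, novel_step], network, reference_db, rules)
    assert both.mean_top_score == pytest.approx((1.0 + s) / 2)
    assert min(both.step_top_scores) <= both.mean_top_score <= max(both.step_top_scores)


def test_empty_pathway_is_an_error(network, reference_db, rules):
    with pytest.raises(ValueError):
        pathway_feasibility([], network, reference_db, rules)
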
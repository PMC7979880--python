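# Generalized bidirectional enzymatic reaction rules (mini collection).
#
# Each rule rewrites a single main substrate; cofactors are context only
# and never become network nodes.  delta_forward is the element-count
# change of the main substrate in the forward direction; the reverse delta
# must be (and is checked to be) its negation.  SMARTS patterns are written
# against RDKit's default aromaticity model.
rules:
  - id: omt-aromatic
    name: aromatic O-methylation (reverse = SAH-dependent O-demethylation)
    ec_prefix: 2.1.1.-
    smarts_forward: "[c:1][OX2H1:2]>>[c:1][OX2:2][CH3]"
    smarts_reverse: "[c:1][OX2:2][CH3:3]>>[c:1][OX2H1:2]"
    cofactors_forward: {consumes: [SAM], produces: [SAH]}
    delta_forward: {C: 1, H: 2}
    delta_reverse: {C: -1, H: -2}

  - id: nmt-secondary
    name: N-methylation of a secondary amine
    ec_prefix: 2.1.1.-
    smarts_forward: "[NX3;H1;+0:1]>>[NX3;H0:1][CH3]"
    smarts_reverse: "[NX3;H0;+0:1][CH3:2]>>[NX3;H1:1]"
    cofactors_forward: {consumes: [SAM], produces: [SAH]}
    delta_forward: {C: 1, H: 2}
    delta_reverse: {C: -1, H: -2}

  - id: nmt-quaternary
    name: quaternizing N-methylation of a tertiary amine
    ec_prefix: 2.1.1.-
    smarts_forward: "[NX3;H0;+0:1]>>[N+:1][CH3]"
    smarts_reverse: "[N+;X4;H0:1][CH3:2]>>[NX3;+0:1]"
    cofactors_forward: {consumes: [SAM], produces: [SAH]}
    delta_forward: {C: 1, H: 3}
    delta_reverse: {C: -1, H: -3}

  - id: methylenedioxy
    name: methylenedioxy-bridge formation from vicinal hydroxyl/methoxyl
    ec_prefix: 1.14.19.-
    smarts_forward: "[OX2H1:1][c:2]:[c:3][OX2:4][CH3:5]>>[O:1]1[c:2]:[c:3][O:4][CH2:5]1"
    smarts_reverse: "[OX2:1]1[c:2]:[c:3][OX2:4][CH2:5]1>>[OX2H1:1][c:2]:[c:3][O:4][CH3:5]"
    cofactors_forward: {consumes: [O2, NADPH], produces: [H2O, NADP+]}
    delta_forward: {H: -2}
    delta_reverse: {H: 2}

  - id: arom-hydroxylation
    name: aromatic ring hydroxylation
    ec_prefix: 1.14.14.-
    smarts_forward: "[cH:1]>>[c:1][OX2H1]"
    smarts_reverse: "[c:1][OX2H1:2]>>[cH:1]"
    cofactors_forward: {consumes: [O2, NADPH], produces: [H2O, NADP+]}
    delta_forward: {O: 1}
    delta_reverse: {O: -1}

  - id: aliph-hydroxylation
    name: benzylic (aliphatic) hydroxylation
    ec_prefix: 1.14.13.-
    smarts_forward: "[CH2;$(Cc):1]>>[CH1:1][OX2H1]"
    smarts_reverse: "[CH1;$(Cc):1][OX2H1:2]>>[CH2:1]"
    cofactors_forward: {consumes: [O2, NADPH], produces: [H2O, NADP+]}
    delta_forward: {O: 1}
    delta_reverse: {O: -1}

  - id: bbe-bridge
    name: berberine-bridge oxidative C-C cyclization of an N-methyl group
    ec_prefix: 1.21.3.-
    smarts_forward: "[CH3:1][NX3;+0:2][CX4H1:3][CH2:4][c:5]:[cH:6]>>[N:2]1[C:3][C:4][c:5]:[c:6][CH2:1]1"
    smarts_reverse: "[NX3;+0:2]1[CX4H1:3][CH2:4][c:5]:[c:6][CH2:1]1>>[CH3:1][N:2][C:3][C:4][c:5]:[cH:6]"
    cofactors_forward: {consumes: [O2], produces: [H2O2]}
    delta_forward: {H: -2}
    delta_reverse: {H: 2}

  - id: thb-oxidase
    name: tetrahydroprotoberberine oxidase (ring-C aromatization)
    ec_prefix: 1.3.3.-
    smarts_forward: "[c:1]1[c:2][CH2:3][NX3;+0:4][CX4H1:5][CH2:6]1>>[c:1]1[c:2][cH:3][n+:4][c:5][cH:6]1"
    smarts_reverse: "[c:1]1[c:2][cH:3][n+:4][c:5][cH:6]1>>[c:1]1[c:2][CH2:3][N+0:4][CH1:5][CH2:6]1"
    cofactors_forward: {consumes: [O2], produces: [H2O2]}
    delta_forward: {H: -3}
    delta_reverse: {H: 3}

  - id: oat-acetyl
    name: O-acetylation of an aliphatic hydroxyl
    ec_prefix: 2.3.1.-
    smarts_forward: "[CX4:1][OX2H1:2]>>[C:1][O:2]C(C)=O"
    smarts_reverse: "[CX4:1][OX2:2][CX3](=[OX1])[CH3]>>[C:1][OX2H1:2]"
    cofactors_forward: {consumes: [acetyl-CoA], produces: [CoA]}
    delta_forward: {C: 2, H: 2, O: 1}
    delta_reverse: {C: -2, H: -2, O: -1}

  - id: est-hydrolysis
    name: acetyl-ester hydrolysis (carboxylesterase)
    ec_prefix: 3.1.1.-
    smarts_forward: "[CX4:1][OX2:2][CX3](=[OX1])[CH3]>>[C:1][OX2H1:2]"
    smarts_reverse: "[CX4:1][OX2H1:2]>>[C:1][O:2]C(C)=O"
    cofactors_forward: {consumes: [H2O], produces: [acetate]}
    delta_forward: {C: -2, H: -2, O: -1}
    delta_reverse: {C: 2, H: 2, O: 1}

  - id: alc-oxidation
    name: alcohol/hemiacetal oxidation to carbonyl
    ec_prefix: 1.1.1.-
    smarts_forward: "[CX4;H1,H2:1][OX2H1:2]>>[C:1]=[O:2]"
    smarts_reverse: "[CX3;$([CX3]([#6])[#6]),$([CX3H1][#6]),$([CX3]([OX2])[#6]):1]=[OX1:2]>>[C:1][OX2H1:2]"
    cofactors_forward: {consumes: [NADP+], produces: [NADPH]}
    delta_forward: {H: -2}
    delta_reverse: {H: 2}

  - id: decarboxylation
    name: aromatic decarboxylation (reverse = carboxylation, CO2-fixing)
    ec_prefix: 4.1.1.-
    smarts_forward: "[c:1][CX3](=[OX1])[OX2H1]>>[cH:1]"
    smarts_reverse: "[cH:1]>>[c:1]C(=O)O"
    cofactors_forward: {consumes: [], produces: [CO2]}
    delta_forward: {C: -1, O: -2}
    delta_reverse: {C: 1, O: 2}
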
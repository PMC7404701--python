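# Default enzyme-specificity ruleset ("biopep_2020").
#
# Each enzyme carries one or more cleavage rules. A rule constrains residues
# at relative positions P4..P1 (N-terminal side of the scissile bond) and
# P1'..P4' (C-terminal side); a bond is cut when ANY rule of ANY selected
# enzyme is satisfied on the intact sequence. Constraints are either
# "allow: <residues>" (the residue at that position must be one of these) or
# "deny: <residues>" (it must not be). Positions falling off the sequence
# ends fail allow-constraints and satisfy deny-constraints.
#
# Trypsin, pepsin (pH 1.3 form, cutting after Phe/Leu) and chymotrypsin
# follow the standard specificity descriptions used by in silico proteolysis
# services. The plant cysteine proteases (stem bromelain, ficin, papain) have
# broad, incompletely standardised specificities; the P1 sets below are
# transcribed from published qualitative summaries and are deliberately kept
# as editable data — replace this file to match any other specificity table.
ruleset: biopep_2020
enzymes:
  - name: stem_bromelain
    ec: 3.4.22.32
    rules:
      - P1: {allow: KAYG}
  - name: ficin
    ec: 3.4.22.3
    rules:
      - P1: {allow: GAY}
  - name: papain
    ec: 3.4.22.2
    rules:
      - P1: {allow: RKLG}
  - name: pepsin
    ec: 3.4.23.1
    rules:
      - P1: {allow: FL}
  - name: trypsin
    ec: 3.4.21.4
    rules:
      - P1: {allow: KR}
        P1': {deny: P}
  - name: chymotrypsin
    ec: 3.4.21.1
    rules:
      - P1: {allow: FYWL}
        P1': {deny: P}
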
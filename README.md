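# colpep

In silico proteolysis of collagen (and other protein) chains, quantitative
screening for bioactive peptides, and downstream peptide cheminformatics.

`colpep` is aimed at food-science and peptidomics groups who evaluate
proteins as *sources* of bioactive peptides before going to the bench: which
activities are encrypted in a chain, which proteases would actually release
them under idealised complete digestion, and whether the released peptides
look drug-like.

## The model

For a protein of `N` residues and a peptide–activity database (peptide
sequences annotated with activity codes such as `ah` = ACE inhibitor,
`dpp` = DPP-IV inhibitor):

- **A = a / N** — *frequency of occurrence*: `a` counts all (possibly
  overlapping) occurrences of database peptides with a given activity in the
  intact chain. A values are binned **major** (A ≥ 0.500), **moderate**
  (0.100 ≤ A < 0.500) and **minor** (A < 0.100).
- **A_E = d / N** — *frequency of release*: `d` counts digest fragments whose
  full sequence equals a database peptide with the activity.
- **W = A_E / A** — *relative frequency of release*, the released share of
  the encrypted potential (undefined when A = 0).
- **DH_t = 100 · |cut sites| / (N − 1)** — *theoretical degree of
  hydrolysis*.

Digestion is simulated as **complete, simultaneous hydrolysis**: an enzyme is
a set of cleavage rules over a P4…P1↓P1'…P4' window (e.g. trypsin: P1 ∈
{K, R}, P1' ∉ {P}); every bond of the intact sequence satisfying any rule of
any selected enzyme is cut, so multi-enzyme digestion is the union of the
single-enzyme cut-site sets. Kinetics, partial digestion and structural
accessibility are deliberately out of scope. The bundled `biopep_2020`
ruleset covers stem bromelain, ficin, papain, pepsin, trypsin and
chymotrypsin and is plain YAML data — replace it to match any other
specificity table (see `docs/methods.md` for its provenance and caveats).

Released peptides can be converted to SMILES (neutral and neutral-pH ionized
forms, L-stereocentres encoded) and screened with the Lipinski Rule of 5
(MW ≤ 500 Da, logP ≤ 5, H-bond donors ≤ 5, acceptors ≤ 10).

A synthetic-data module generates collagen-like G-X-Y repeat chains with
planted motifs whose expected A/A_E/W/DH_t are computed by an independent
brute-force oracle, giving every pipeline stage analytically known answers.

## Worked example

```
$ printf ">toy\nGKGFRL\n" > toy.fasta
$ colpep digest -p toy.fasta -e pepsin -e trypsin -e pepsin,trypsin
protein_id  enzymes         n_bonds  n_cuts  DH_t
toy         pepsin          5        1       20.00
toy         trypsin         5        2       40.00
toy         pepsin+trypsin  5        3       60.00
```

Pepsin (cutting after F/L) hydrolyses 1 of the 5 bonds of GKGFRL
(DH_t = 20%), producing fragments GKGF and RL; trypsin (after K/R, not
before P) cuts 2 bonds; together they cut the union, 3 bonds (60%).

```
$ colpep release -p toy.fasta -e pepsin
protein_id  enzymes  activity_code  d_count  A_E    W
toy         pepsin   ah             1        0.167  0.500
toy         pepsin   dpp            1        0.167  0.500
```

The bundled database knows GF and RL as dual ACE/DPP-IV inhibitors; the toy
chain contains both (a = 2, A = 2/6 = 0.333, a *moderate* source), and the
peptic digest releases exactly RL (d = 1, A_E = 1/6 = 0.167), i.e. half of
the encrypted potential (W = 0.5).

```
$ colpep chem RL PGL        # columns abridged
peptide  mw      logp    hba  rule_of_5
RL       287.36  -0.808  8    +
PGL      285.34  -0.530  7    +
```

Both released peptides are well inside the Rule-of-5 box: small (≪500 Da),
hydrophilic (logP < 5) and within the donor/acceptor limits.

The same run is available end-to-end (`colpep run`), writing occurrence,
release, digest, fragment, released-peptide and chemistry tables plus a
manifest with a config hash and database fingerprint; repeated runs are
byte-identical.

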
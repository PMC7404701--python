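# Methods

## Digestion model

An enzyme's specificity is a list of cleavage rules. Each rule constrains
residues at relative positions P4…P1 (N-terminal side of the scissile bond)
and P1'…P4' (C-terminal side) with either an *allow* set (the residue must be
one of these) or a *deny* set (it must not be). A bond `i` — joining residues
`i` and `i+1`, 0-based — is susceptible iff every constrained position of
some rule, mapped onto the **intact** sequence, is satisfied. Window
positions that fall off the chain fail allow-constraints and satisfy
deny-constraints: a bond near a terminus simply lacks the required context
residue. Windows wider than P4–P4' are not representable; no published
specificity used here needs more.

Digestion is *complete and simultaneous*: all susceptible bonds of the intact
chain are cut at once, so a multi-enzyme digest cuts exactly the union of the
single-enzyme cut-site sets and the result is independent of enzyme order.
This mirrors how in silico proteolysis services behave (their combination
DH_t values are near-additive) and is intentionally *not* an iterative
re-digestion of fragments: bond susceptibility depends only on the original
sequence context. Kinetics, pH/temperature optima, enzyme:substrate ratio,
partial digestion and missed-cleavage enumeration are out of scope, as is
any structural accessibility modelling.

`DH_t = 100 · |cut sites| / (N − 1)`. A single-residue chain has no bonds;
DH_t is defined as 0 and the digest is the chain itself.

## The bundled ruleset (`biopep_2020`)

Shipped as editable YAML data, not code. Trypsin (P1 ∈ {K,R}, P1' ∉ {P}),
pepsin in its pH ≈ 1–2 form (P1 ∈ {F,L}) and chymotrypsin (P1 ∈ {F,Y,W,L},
P1' ∉ {P}) follow the standard specificity descriptions used by rule-based
digestion tools. The plant cysteine proteases are broad-specificity enzymes
whose machine-readable rules are not standardised; the shipped sets — stem
bromelain P1 ∈ {K,A,Y,G}, ficin P1 ∈ {G,A,Y}, papain P1 ∈ {R,K,L,G} — are
transcriptions of published qualitative summaries and are the dominant
uncertainty in any absolute DH_t this package prints for real proteins. They
reproduce the expected *regime* on collagen-like chains (plant proteases
≈ 40–60% DH_t because glycine alone is a third of the chain; pepsin/trypsin
in single digits) but two-decimal agreement with any particular database
snapshot is a property of that snapshot's enzyme tables; users comparing
against one should transcribe its tables into the YAML schema verbatim. The
suite's published-value DH_t check (live UniProt retrieval) is the intended
verification surface for such a transcription.

## Occurrence, release, binning

- `a` counts **overlapping** occurrences with multiplicity per start
  position, summed over all database peptides carrying the activity code; a
  peptide listed under k codes contributes to all k profiles. Whether the
  original web tools count overlaps is not documented; this convention is
  the simplest deterministic one and is stated here because it matters for
  self-similar sequences.
- `d` counts digest fragments whose **full sequence** equals a database
  peptide (substring containment is not release), with multiplicity across
  fragment positions.
- `A = a/N`, `A_E = d/N`, `W = A_E/A` (undefined when A = 0; a released
  fragment implies an occurrence, so d > 0 ⟹ A > 0 and W is never
  "undefined but positive").
- Bins: major A ≥ 0.500, moderate 0.100 ≤ A < 0.500, minor 0 < A < 0.100,
  none at exactly 0. The boundaries are applied to the exact value, not the
  printed rounding.
- All frequencies are exact `Fraction`s internally. Reports print A/A_E/W to
  three decimals and DH_t to two; a value rounding to 0.000 is left blank in
  tables (machine-readable JSON keeps full precision and an explicit null
  for undefined W). A release row can therefore show W without A_E — one
  released copy from a long chain has A_E < 0.001 while W stays large.
- Table rows sort by descending parameter, then activity code, so output is
  deterministic.

## Sequences

Chains are plain strings over the 20 standard amino acids. Hydroxyproline
and other post-translational modifications are not representable —
collagen's Hyp is modelled as the unmodified residue the database uses, a
known limitation of sequence-level digestion tools. Canonicalization
uppercases, strips whitespace/gap characters and either rejects (`strict`)
or drops with a positional warning (`drop_unknown`) non-standard letters.
Mature-chain trimming takes an explicit 1-based inclusive range (UniProt
convention) from user config or UniProt feature annotation; nothing is
predicted. Whether propeptides besides the signal peptide should be excluded
is a study-design question the package does not answer — it trims exactly
the range it is given. Internal fragment coordinates are 0-based half-open.

## Peptide chemistry

SMILES are built by condensing per-residue templates through amide bonds;
L-stereocentres are encoded (Cα CIP *S*, except cysteine *R*; Thr 2S,3R;
Ile 2S,3S — verified in the suite via RDKit CIP assignment). The ionized
form is the dominant species at pH 7: N-terminal ammonium, C-terminal
carboxylate, Asp/Glu carboxylates, Lys ammonium, Arg guanidinium; His and
Cys stay neutral. Equivalence is defined up to RDKit canonicalization, not
byte identity.

Rule-of-5 descriptors: molecular weight is the average (not monoisotopic)
mass, residue masses plus one water (pyteomics). Hydrogen-bond donors are
counted as donor N/O atoms and acceptors as N + O atoms **on the ionized
species** — the species the screen is actually applied to when ionized
structures are the input, under which a carboxylate stops donating while an
ammonium still does. On the neutral form, hydrogen-counting conventions push
any arginine dipeptide past 5 donors and would fail peptides that
drug-likeness tools (fed ionized input) report as passing; the ionized
atom-count convention reproduces those verdicts and is the package's
default. logP is Wildman–Crippen (RDKit `MolLogP`) on the neutral form,
since logP is defined for the neutral species; the method name is recorded
in the output. All four thresholds (500 Da, 5, 5, 10) are applied as ≤.

## Synthetic fixtures

`generate_collagen_like` emits `n_triplets` G-X-Y triplets with X/Y drawn
from a weighted composition; the default is proline-dominated with minor
A/E/S/Q/R/K/D/L/F, so glycine is one third of residues and pepsin/trypsin
site densities land in the low-DH_t regime characteristic of collagen. The
default deliberately omits Y/W/M and the rare residues, so chymotrypsin adds
nothing beyond pepsin on default chains — a property of the emulation, not
of the engine. What the generator does *not* emulate: hydroxyproline
chemistry, the triple helix and its accessibility effects, telopeptides,
real composition gradients. Passing fixture tests therefore demonstrates
arithmetic correctness of the pipeline, not biological fidelity of any
DH_t for real collagen.

`plant_motifs` overwrites non-overlapping triplet-aligned segments at
seeded positions (retry with a cap, then a hard error). `cuttable` mode
engineers the flank before each copy from a P1 allow-set of the first
enzyme set, requires the motif's own last residue to be cleavable, and
verifies with the oracle that every copy is released — motifs whose
interior the enzymes would cut are rejected rather than silently
under-released. `inert` mode places flanks outside every P1 set so the
motif's N-terminal boundary is never cut and the exact motif cannot be
released. Glycine-only motifs are rejected (they self-overlap with the
G-X-Y frame). Expected A/A_E/DH_t are computed at generation time by a
naive per-bond, per-rule scan and naive substring counting implemented
independently of the engine modules, and kept as exact rationals so
pipeline comparisons are equality checks, with no tolerance. Seeds are
mandatory; no global random state is touched.

## Problem sizes

The suite and the acceptance script use a 1014-residue reference chain
(338 triplets, a realistic α-chain length), 1000 random sequences of length
≤ 50 for the engine-vs-brute-force comparison, 100 seeded planted-motif
fixtures of 40–80 triplets, and the full 20 × 20 dipeptide space for the
ionization checks; the whole run takes a few seconds on one CPU.

## Known limitations

- Absolute DH_t and release values for real proteins inherit the
  approximate plant-protease rules (above).
- The bundled activity database is the nine-peptide ACE/DPP-IV set with
  literature IC50 metadata, a deliberately small stand-in: occurrence
  profiles of real proteins against a full bioactive-peptide database
  require the user to supply that database as TSV.
- Bioactivity-likelihood scores are joined from a user-supplied table only;
  the package never computes them, nor any ADMET or target-prediction
  quantity.
- UniProt retrieval is an optional, network-gated convenience; all core
  functionality is offline.
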
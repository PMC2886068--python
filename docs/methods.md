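# Methods

## Structural model of a bile salt

A bile salt is represented by its skeleton carbon count (23, 24 or 27 in
this model; 22 is accepted for bisnor acids), the side-chain terminal group
(primary alcohol vs carboxylic acid), the A/B ring-junction stereochemistry
(5α "allo" = trans, 5β = cis, or unknown when the source name omits it), a
set of (position, orientation) hydroxyls, a set of oxo positions, a set of
double-bond positions, and a conjugation state (none, glycine, taurine,
sulfate). Orientations are `a`/`b` for nuclear positions and `R`/`S` for
side-chain stereocentres, with `""` for unspecified — matching how source
tables actually print them. Validation enforces position ranges and forbids
a hydroxyl and an oxo at the same carbon.

The nomenclature parser accepts Greek letters (`α/β`), ASCII (`a/b`) and
spelled-out (`alpha/beta`) forms, `glyco-`/`tauro-` prefixes with or without
the hyphen, a trailing `sulfate`, `24-nor`/`23,24-bisnor` skeleton
contractions, and `-en`/`-dien` unsaturation infixes. Canonical rendered
names use ASCII `a/b` (and `R/S`), and `parse(render(d)) == d` is a tested
invariant for both the trivial-name registry and randomized descriptors.
For bile alcohols the terminal side-chain hydroxyl is implicit in the
terminal group: the parser removes the highest unoriented position ≥24 from
an `-ol` suffix list and the renderer reinstates it (26 by default on a C27
skeleton, 24 on shorter ones). A descriptor that has an unoriented hydroxyl
on every available side-chain terminus cannot be rendered and raises an
error; such structures do not occur in practice.

## Mass arithmetic

Molecular formulas are built by scaffold arithmetic: CnH(2n−8)O2 for a
saturated unsubstituted bile acid, CnH(2n−6)O for a bile alcohol (the
terminal hydroxyl is part of the base); each hydroxyl +O, each oxo +O −2H,
each double bond −2H, glycine amide +C2H3NO, taurine amide +C2H5NO2S,
sulfate ester +SO3. Whether an oxo replaced a hydroxyl or arose de novo is
irrelevant — only the final substituent multiset affects composition.
Monoisotopic masses come from one embedded six-decimal table (C 12.000000,
H 1.007825, N 14.003074, O 15.994915, S 31.972071) and the proton mass is
fixed at 1.007276 Da, so [M−H]⁻ values are bit-reproducible. The tests
check these against an independent hand-counted-formula oracle with its own
higher-precision mass table.

Peak annotation enumerates a bounded space of structural *equivalence
classes* — scaffold ∈ {C23 acid, C24 acid, C27 acid, C27 alcohol},
0–4 hydroxyls, 0–2 oxo, 0–2 double bonds, 4 conjugation states — because
unit-resolution m/z cannot localize substituents; a candidate is reported
whenever |Δm/z| ≤ tolerance, sorted by |Δm/z| with a deterministic label
tiebreak. The default tolerance is 0.5 Da, appropriate for unit-resolution
quadrupole data; pass a smaller window for high-resolution spectra. The
instrument tolerance behind published "consistent with" assignments is not
documented anywhere we know of, so this default is a package decision, not
a literature value.

## Profile classification

Per species, component percentages are aggregated by compound type on the
aglycone (conjugation ignored); types reaching the 10% threshold define the
class: alcohols only → I, alcohols + C27 acids → II, alcohols + C24 acids →
III, C27 acids only → IV, C27 acids + C24 acids → V, C24 acids only → VI.
All three types at threshold is reported distinctly as `mixed` rather than
forced into the six-class scheme; no type at threshold is a classification
error naming the species. Threshold conventions: "10% or greater" is
inclusive for classification and complexity; "more than 50%" is strict for
the major label; minor is the interval (10, 50], which makes the
major/minor/trace partition exhaustive while keeping each boundary faithful
to its own source convention. Percentages are used as reported — no
renormalization against unidentified material, since the thresholds are
phrased against total biliary bile salts. `~`-prefixed values parse to the
bare number with an approximate flag, and profile percent sums may exceed
100 by up to 5 points to accommodate such entries.

Complexity: a profile is complex iff ≥2 types each aggregate ≥10%, and/or
≥3 individual components each reach ≥10%.

The diet cross-tab reports per diet group (carnivore >90% meat, herbivore
>90% plant, omnivore otherwise; boundaries strict): n, % complex, % with
CA / CDCA / another C24 acid as the single >50% major compound, and %
"primarily C27 bile acids". *Primarily* has no formal definition in the
comparative literature; here it means the C27-acid aggregate exceeds 50% of
the pool, and every report carries that definition in a header line.
Percentages are rounded half-up to one decimal, matching printed-table
conventions; numerators and denominators are kept alongside.

## Parsimony ancestral reconstruction

Minimum-change reconstruction is computed by the unit-cost Sankoff
recursion: an up-pass gives `up[v][s]` (minimal changes in v's subtree with
v in state s), and a down-pass gives the complementary cost, so
`up[v][s] + down[v][s]` is the best total with v fixed to s. Per node the
reported set is every state attaining the global minimum — the full
most-parsimonious set, never one arbitrary member; ties are information.
On binary trees this reduces to classic Fitch set intersection/union. The
common shortcut of merging polytomy children sequentially with
intersection/union was deliberately not used: it undercounts (four children
in states A, A, B, B require two changes whichever state the node takes,
but sequential merging reports one). Exactness is property-tested against
brute-force enumeration of all internal labelings on random polytomous
trees (≤6 tips, ≤3 states).

Tips without a state are pruned by default (`missing_policy="error"`
refuses instead). Characters for node-level inference are presence/absence
binaries per compound type at the 10% rule, not the seven-level class
character, because ancestral reasoning concerns type gains and losses.

The amniote fixture (`bilesalts/data/amniote_*_synthetic.*`) is a
group-level summary tree (Testudines sister to Crocodylia + Aves; labelled
nodes A/B/C) with tip codings assembled from the comparative literature —
it is a synthetic, editable stand-in, not a transcribed published data
table.

Pairwise protein identity uses Biopython's global aligner with BLOSUM62,
gap open 10 and extend 0.5, and divides identical positions by *all*
alignment columns including gaps. Published cross-species identity figures
rarely state their alignment method, so identities computed here should be
treated as approximations to any particular published number; the scoring
choices are fixed and documented precisely so comparisons are reproducible.

## Synthetic survey generator

The generator emulates the statistical structure of real comparative
tables: (1) a Yule backbone over families (default 120 when driven by the
analysis scripts, 40 in the config default), rescaled to unit height;
(2) a profile-class character evolved by a continuous-time Mk process
(total leaving rate = expected changes per unit length; default 0.05, so
class changes are rare across the backbone); (3) species grafted under each
family tip (subtree height 0.1) copying the family state with flip
probability 0.005 — about half a percent of species deviate, so only a few
percent of 10-species families are heterogeneous, mirroring surveys in
which a handful of families out of dozens mix classes; (4) compositions
drawn from a Dirichlet (total concentration 50) over class-specific
compound menus; (5) diets drawn per family; (6) a per-diet complexity coin
(defaults 0.398 / 0.705 / 0.500 for carnivores/herbivores/omnivores, the
complex-profile fractions reported for a large mammalian survey) choosing
between a dominant-compound draw (weights 0.97/0.03) and a three-component
draw (weights 0.45/0.33/0.22, each component ≥10% with high probability).

Two consequences worth knowing: for single-type classes (I, IV, VI) the
complexity coin is the only source of complex profiles, so the observed
complex fraction per diet group estimates the configured q directly — this
is the calibration the acceptance checks exercise at ~400 species per
group against exact 99% binomial intervals. Two-type classes (II, III, V)
are complex by construction, so runs mixing them will exceed q. The default
class alphabet is ("I", "IV", "VI"); the full six-class alphabet is
available via configuration. Diet is independent of the class character by
construction, matching the empirical finding that bile-salt profiles do not
track diet.

Everything derives from one seeded `numpy.random.Generator`; identical
seed + config yields byte-identical tables. Configs serialize to a flat
`key=value` file.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: measurement noise and non-closure in reported
percentages, unidentified material, secondary (microbial) modification
dynamics, realistic mass-spectral noise or isotope patterns, and any
diet–profile correlation.

## Problem sizes and numerics

The shipped analysis runs use 1,200 species (120 families × 10), 1,000
random trees for the parsimony-exactness check, 500 replicates of 64-tip
trees for root-state recovery, and 100 random structures for the
conjugation-delta check; the whole acceptance script completes in a few
seconds on one CPU. Rounding of reported percentages is decimal half-up
(not banker's). m/z values print to 4 decimals. The Dirichlet degenerate
limit (concentration → ∞) concentrates on the menu weights exactly; a
concentration of 0 is rejected. All thresholds (10%, 50%, 90% diet rule)
are module constants, not scattered literals.

## Known limitations

The parser covers the nomenclature patterns that occur in comparative
bile-salt tables (hydroxy/oxo prefixes, nor contractions, en/dien
unsaturation, ol/oic-acid suffixes, conjugation prefixes); it is not a
general steroid-nomenclature engine (no ring-letter locants, epoxides, or
esters other than sulfate). C24 bile alcohols classify as `other`, which is
faithful to the three-type scheme but means rare short-chain alcohols never
define a class. The Mk simulator assumes equal transition rates among
states. Fitch/Sankoff parsimony weights all changes equally — no Dollo or
step-matrix variants — and reconstructs each character independently.
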
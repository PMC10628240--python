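# Methods

This note records the models, numerical conventions and design choices
behind fvgraft, and what the synthetic test data does and does not show.

## Kabat numbering engine

Numbering is assignment of each residue of a VH or VL sequence to a Kabat
position, by global alignment against one packaged position-annotated
consensus template per chain type (113 columns heavy, 107 light). The
aligner is a bespoke dynamic program rather than a generic affine aligner
because the scheme's gap structure is position-specific:

* insertions relative to the template are only permitted immediately after
  the canonical Kabat insertion sites (heavy 35, 52, 82, 100; light 27,
  95, 106) and receive alphabetic codes (82 → 82A, 82B, …);
* deletions simply skip Kabat numbers; leading/trailing template columns
  are free so truncated chains (e.g. V-gene records without FR4) number
  cleanly;
* framework columns score BLOSUM62; CDR columns score flat (0). CDR loops
  are hypervariable, so their content carries no information about
  placement — letting it influence the alignment would occasionally drag
  insertions to the wrong site. Only the framework anchors decide.

Costs: −8 per internal deleted column; −4.5 per inserted residue. The
insertion cost sits strictly below the worst BLOSUM62 mismatch (−4) so a
terminal residue can never be "explained away" as an insertion followed by
a free end deletion. Tie-breaks in the traceback prefer match > deletion >
insertion, making the result deterministic. Sequences whose framework
identity to the template falls below 50% are rejected as not-an-Fv;
lengths outside 90–140 and non-canonical letters (except X) are input
errors. Exotic indel patterns outside the canonical sites are deliberately
rejected rather than guessed at.

CDR boundaries (heavy 31–35/50–65/95–102, light 24–34/50–56/89–97) follow
the standard Kabat definitions; insertion codes inherit the region of
their base number, so 82A is framework and 100A is CDR-H3.

## Germline selection

Candidates are compared position-by-position over framework columns
present in both chains; CDR columns never enter the score since they are
replaced by the donor loops anyway. Ranking: upper-core positions
preserved (descending), framework identity (descending), an optional
per-allele numeric prior (descending, default 0 — a hook for
considerations such as expression track record that the method does not
quantify), allele name (ascending). The upper-core sets default to heavy
{2, 4, 24, 27, 29, 47, 48, 49, 69, 71, 78, 94} and light {2, 4, 64, 66,
71} and are configurable. FR4 comes from a J segment, not the V gene, so
it is scored separately against a small packaged J-segment set and
reported rather than folded into the V-gene ranking.

The packaged germline and J libraries are synthetic stand-ins (flagged in
their filenames): realistic consensus-style sequences carrying IMGT-style
allele names, sufficient for testing and for the bundled worked example,
not authoritative IMGT records. Users point the library arguments at their
own FASTA for real work.

## Grafting and back-mutation

Grafting takes CDR positions (with any donor insertion codes) from the
donor and framework positions from the acceptor; acceptor CDR content and
length are discarded — that is the definition of a wholesale graft.
Framework positions the acceptor lacks (typically FR4 against a V-gene
record) are filled from the donor with an explicit warning. Every product
residue carries a provenance tag (donor_CDR / acceptor_FR / back_mutated).
Applying a back-mutation plan changes exactly the planned positions
(Hamming distance equals plan length), and reverting every framework
difference reproduces the donor sequence exactly — both identities are
enforced by tests.

## Contact analysis and the recommendation cascade

All structural reasoning is distance-based over heavy atoms; hydrogens are
ignored (predicted models rarely place them reliably), and no angle terms
or donor/acceptor chemistry tables are used. Windows, inclusive at both
ends: hydrogen bond = any N/O–N/O pair in 2.7–3.3 Å; hydrophobic = any
C–C pair in 3.3–4.0 Å; framework–CDR analysis window 4.2 Å; beyond 10 Å no
interaction is possible. Pairs between 4.2 and 10 Å fall in a band the
distance rules do not define; they are labelled `none` and excluded from
the support map. When a pair satisfies both windows the tighter class
(hydrogen bond) wins.

Per differing framework position the recommender applies, first match
wins: (1) upper-core → back-mutate; (2) no contacts in the window → keep
human (exposed, distant from the CDRs); (3) conservative substitution →
keep human, with classes {K,R,H}, {D,E}, {S,T}, {N,Q}, {L,I,V,M},
{F,Y,W}, {A,G}, {C}, {P}; (4) contacts without a hydrogen bond and count ≤
1 (configurable `contact_weight_threshold`) → keep human; (5) otherwise
back-mutate. Rule 2 uses "no contacts within 4.2 Å" as the operative
criterion for "surface-exposed and distant"; solvent exposure is not
computed for this rule. The cascade is total and deterministic: every
differing framework position receives exactly one decision.

Support maps can come from coordinates (`find_fr_cdr_contacts`) or from a
transcribed text table (`support_map_from_rows`) when no structure is
available; the bundled worked case uses the latter.

## Interface profiling and the affinity model

Interfacial contacts: cross-side residue pairs with min heavy-atom
distance ≤ 5.5 Å, bucketed by the unordered pair of polarity classes,
with charged = {D,E,K,R}, polar = {C,H,N,Q,S,T,W,Y}, apolar =
{A,F,G,I,L,M,P,V}. Class membership of H, C, W, Y varies between
conventions, so the table is configurable.

SASA is Shrake–Rupley with a fixed deterministic golden-spiral point set
(960 points/atom), probe 1.4 Å, van-der-Waals radii C 1.70, N 1.55,
O 1.52, S 1.80, default 1.80 Å. Relative SASA divides by per-residue
reference maxima computed once from the same isolated pseudo-residue
geometry the synthetic generator emits (so an isolated residue sits at
≈ 1.0), clipped to [0, 1.2]. Literature Gly-X-Gly tripeptide areas would
be systematically wrong for 3–5-atom pseudo-residues, which is why the
reference is internal. NIS residues are those with relative SASA ≥ 5%
outside every interfacial pair; a complex whose every exposed residue is
interfacial has no NIS and is reported as an error rather than a silent 0.

ΔG is the linear IC/NIS model with coefficients (kcal/mol): −0.09459 per
charged–charged contact, −0.10007 per charged–apolar, +0.19577 per
polar–polar, −0.22671 per polar–apolar, +0.18681 per %NIS apolar,
+0.13810 per %NIS charged, intercept −15.9433. Charged–polar and
apolar–apolar contacts are counted in the profile but carry no weight —
that is a property of the model, not an omission. Coefficients live in the
configuration, not in operation logic, and are swappable.
K<sub>d</sub> = exp(ΔG/RT) with R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹, default
T = 298.15 K. Note a rounding subtlety the tests pin down: a printed
ΔG = −14.5 corresponds to 2.4×10⁻¹¹ M, while the unrounded −14.54 behind
it gives the reported 2.2×10⁻¹¹ M.

## Synthetic data: what it emulates and what it does not

The bundled anti-PD-L1 worked case has no public coordinates or
sequences, so every structural stage is validated against planted
synthetic ground truth instead of experimental regression data.

* `make_fv_sequence` builds sequences directly on the numbering template:
  randomized CDRs of chosen lengths (length changes realized as insertions
  at the canonical CDR sites; supported ranges H1 5–7, H2 16–19, H3 8–19,
  L1 11–17, L2 fixed 7, L3 9–15), optional framework insertions (heavy 82,
  light 106, up to 3), and an optional randomized framework (default
  mutation rate 0.1 per position — murine-vs-template divergence scale).
  The two framework columns flanking each CDR and insertion region are
  excluded from mutation: these anchors (W36, W103, the Cys pair, …) are
  near-invariant in real repertoires, and mutating them can make the
  planted numbering of an adjacent insertion unidentifiable in principle.
* `make_fv_structure` lays framework and CDR residues on two rails 30 Å
  apart (12 Å spacing) and relocates each planted CDR residue so the
  designated atom pair (O···N, CB···CB, or CA···CA) meets its target
  distance exactly, all other atoms held ≥ 2 Å behind the apex atoms.
  Residues are 3–5 pseudo-atoms (N, CA, C, O, CB except glycine): the
  distance rules depend only on interatomic distances and elements. Every
  emitted structure is re-measured brute-force before being returned;
  targets hold to 0.01 Å and unplanted framework–CDR pairs stay > 6 Å, or
  generation fails as over-constrained. At most two plants may share a
  framework residue (the second is tilted 35° off the vertical) and they
  must designate the same framework atom.
* `make_complex` plants a two-chain interface of chosen residue-class
  composition: in-range pairs at a controlled distance ≤ 5.5 Å, excluded
  pairs and extra NIS residues ≥ 30 Å across the interface, with the same
  brute-force self-check. Ground-truth IC counts derive from the spec
  alone.

All generators take a mandatory integer seed and are byte-reproducible;
there is no hidden global random state.

Passing against this data shows the *rules* are implemented exactly — the
distance windows, the cascade, the counting, the numbering conventions.
It does not show robustness to real structural noise: toy geometry has no
packing, no rotamers, no crystallographic artifacts, and toy sequences
have no somatic-hypermutation structure beyond i.i.d. framework mutations.
Contact maps from real predicted models inherit whatever error the
structure predictor makes.

## Problem sizes and numerics

The shipped test suite and the acceptance script use 1000 fuzzed sequences
for numbering recovery, 100 planted structures for contact equivalence and
100 planted complexes for IC equivalence — sizes at which the brute-force
oracles are exact and the whole suite runs in well under a minute on one
core. Distance comparisons against PDB text allow 2×10⁻³ Å for coordinate
rounding (three decimals in the format). Contact detection uses a
bounding-sphere prefilter per residue pair but is asserted equal to the
naive all-pairs scan. Alternate conformations in PDB input collapse to the
first-listed location (PDB convention orders altlocs by occupancy);
waters and hydrogens are dropped on reading.

## Known limitations

* Kabat only; Chothia/IMGT/Martin numbering and lambda-specific templates
  are out of scope (the kappa template covers packaged light chains).
* CDR loops shorter than the template cannot be generated or numbered
  without a deletion convention; such inputs are rejected, not guessed.
* Hydrogen-bond detection is purely geometric (no angles, no chemistry
  table), matching the distance-only analysis conventions it implements.
* The affinity model is a fixed linear function; it is not re-fit here and
  carries the accuracy of its published coefficients.
* Back-mutation recommendations consider contacts and residue classes
  only — no immunogenicity scoring, expression prediction or energetics.
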
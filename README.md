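# fvgraft

Structure-guided antibody humanization as a reusable pipeline: Kabat
numbering, human germline acceptor selection with upper-hydrophobic-core
checks, CDR grafting, distance-based framework–CDR contact analysis that
drives back-mutation recommendations, and a contact-classified
interface/affinity predictor (ΔG and K<sub>d</sub>) for antibody–antigen
complexes.

It is written for antibody engineers who humanize murine monoclonals
against predicted (e.g. AlphaFold2) structures: the tool takes VH/VL amino
acid sequences (FASTA) and model coordinates (PDB) and produces the
humanized sequences plus the structural evidence behind every framework
decision.

## The method

**Humanization.** A murine Fv is numbered in the Kabat scheme (CDR-H1
31–35, H2 50–65, H3 95–102; CDR-L1 24–34, L2 50–56, L3 89–97, with
insertion codes such as 82A at the canonical insertion sites). For each
chain a human germline V-gene acceptor is ranked by (1) how many
*upper hydrophobic core* positions it preserves — the platform of framework
residues directly beneath the CDRs (heavy Kabat 2, 4, 24, 27, 29, 47–49,
69, 71, 78, 94; light 2, 4, 64, 66, 71) — then (2) framework identity. The
donor CDRs are grafted wholesale onto the acceptor framework, and each
remaining framework difference gets one decision from a fixed cascade:

1. upper-core position → **back-mutate** (restore the donor residue);
2. no CDR contact within 4.2 Å → keep human;
3. substitution within one physicochemical class (K↔R, S↔T, …) → keep human;
4. contacts but no hydrogen bond and at most one contact → keep human;
5. otherwise → **back-mutate**.

Contacts are read off the model with purely distance-based rules:
hydrogen bond if any N/O–N/O pair lies in 2.7–3.3 Å, hydrophobic if any
C–C pair lies in 3.3–4.0 Å, and no interaction possible beyond 10 Å.

**Affinity.** For an antibody–antigen complex, every cross-side residue
pair within 5.5 Å is an interfacial contact (IC), bucketed by the polarity
classes (charged/polar/apolar) of its residues. Solvent-exposed residues
(relative Shrake–Rupley SASA ≥ 5%) outside the interface form the
non-interacting surface (NIS). Binding free energy follows the linear
IC/NIS model

    ΔG = −0.09459·IC(cc) − 0.10007·IC(ca) + 0.19577·IC(pp)
         − 0.22671·IC(pa) + 0.18681·%NIS(apolar) + 0.13810·%NIS(charged)
         − 15.9433   [kcal/mol]

and K<sub>d</sub> = exp(ΔG / RT) at 25 °C with R = 1.9872×10⁻³
kcal·mol⁻¹·K⁻¹. For scale: ΔG = −12.1 kcal/mol corresponds to
K<sub>d</sub> = 1.4×10⁻⁹ M, and ΔG ≈ −14.54 to 2.2×10⁻¹¹ M.

## Worked example

The package bundles a synthetic murine anti-PD-L1 Fv together with a
transcribed framework–CDR contact summary (`fvgraft.examples`; the
sequences are labelled synthetic stand-ins). Ranking its heavy chain
against the packaged germline library and running the recommender:

```python
from fvgraft import germline, grafting, kabat, structure
from fvgraft.examples import load_example_case

case = load_example_case()["heavy"]
lib = germline.default_library("heavy")
core = kabat.upper_core_positions("heavy")
best = germline.select_germline(case.donor, lib, core)[0]
acceptor = next(r for r in lib if r.allele_name == best.allele_name)
recs = structure.recommend_back_mutations(case.donor, acceptor, case.support, core)
```

prints (via the pipeline's report writer):

```
heavy: acceptor IGHV1-46*01 (identity 0.86, core 7/12)
    38  K->R  KEEP_HUMAN  CONSERVATIVE_SWAP
    40  R->A  KEEP_HUMAN  MINOR_CONTACT
    48  V->M  BACK_MUTATE UPPER_CORE
    66  K->R  KEEP_HUMAN  CONSERVATIVE_SWAP
    67  A->V  BACK_MUTATE CONTACT_DISRUPTING
    69  L->I  BACK_MUTATE UPPER_CORE
    71  A->R  BACK_MUTATE UPPER_CORE
    78  A->V  BACK_MUTATE UPPER_CORE
   82A  R->S  KEEP_HUMAN  MINOR_CONTACT
    94  G->R  BACK_MUTATE UPPER_CORE
```

IGHV1-46\*01 wins the ranking but preserves only 7 of 12 upper-core
positions, so those five core positions (48, 69, 71, 78, 94) are restored
to the donor residue, and position 67 is additionally reverted because its
two CDR contacts would be disrupted by the A→V swap. Lys66→Arg66 is kept
human: K and R are both basic and the contacts to CDR-H2 survive the swap.
The light chain selects IGKV1-5\*01 (identity 0.94, core 5/5 — fully
preserving) and needs no back-mutations at all. Grafting plus the planned
reversions yields the humanized sequences
(`grafting.apply_back_mutations`), e.g. the heavy chain
`QVQLVQSGAEVKKPGASVKVSCKASGYTFTTYGMSWVRQAPGQGLEWVG…`.

The same flow runs from the shell:

```sh
fvgraft run-all donor.fasta --outdir out/           # chain=heavy/light tags
fvgraft affinity complex.pdb --side-a A,B --side-b C
```

`fvgraft affinity` prints the interface profile in the standard column
layout — ΔG (kcal mol-1), Kd (M) at 25 °C, then the six IC class counts.
On a small synthetic complex with a planted interface (one R·D, one S·L
and one L·L pair in range) it reports ΔG −5.0 kcal/mol, K<sub>d</sub>
2.1×10⁻⁴ M, ICs 1/0/0/0/1/1 — exactly the planted composition.

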
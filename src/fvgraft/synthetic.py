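"""Synthetic inputs with exact ground truth for every pipeline stage.

Three generators:

* :func:`make_fv_sequence` — an Fv amino-acid sequence built directly from
  the numbering template, with randomized CDRs of chosen lengths and
  optional framework insertions, so its Kabat numbering is known by
  construction;
* :func:`make_fv_structure` — a toy one-chain 3D model of a numbered Fv in
  which chosen framework-CDR atom pairs are planted at controlled distances
  (realized to better than 0.01 Å) while every unplanted framework-CDR pair
  stays beyond 6 Å;
* :func:`make_complex` — a toy two-chain complex with a planted interface of
  known residue-class composition at the 5.5 Å contact cutoff.

Residues are simplified to 3-5 pseudo-atoms (backbone N, CA, C, O plus a CB
carbon except for glycine): the distance rules downstream depend only on
interatomic distances and elements, not on real side-chain geometry.  All
randomness flows through an explicit integer seed; identical calls are
byte-identical.  Each structure generator re-measures its own output with an
independent brute-force pass and raises :class:`GenerationError` if the
requested geometry could not be realized (over-constrained plants).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import GenerationError
from .kabat import (
    AMINO_ACIDS,
    CDR_BOUNDS,
    HEAVY,
    LIGHT,
    INSERTION_SITES,
    TEMPLATES,
    NumberedChain,
    NumberedResidue,
    region_of,
)
from .structure import ONE_TO_THREE, Atom, Residue, StructureModel

# Supported CDR length ranges (template length .. template + insertion codes
# used in practice).  Shorter-than-template loops would need deletion
# conventions the numbering engine does not model, so they are rejected.
CDR_LENGTH_RANGES = {
    HEAVY: {"CDR1": (5, 7), "CDR2": (16, 19), "CDR3": (8, 19)},
    LIGHT: {"CDR1": (11, 17), "CDR2": (7, 7), "CDR3": (9, 15)},
}
# Canonical insertion site inside each CDR (extra residues gain codes there).
CDR_INSERTION_SITE = {
    HEAVY: {"CDR1": 35, "CDR2": 52, "CDR3": 100},
    LIGHT: {"CDR1": 27, "CDR3": 95},
}
# Framework insertion sites (outside the CDRs).
FRAMEWORK_INSERTION_SITES = {HEAVY: (82,), LIGHT: (106,)}

# Framework anchor positions excluded from the randomized-framework mutation
# model: the two framework columns flanking each CDR and each framework
# insertion region on either side.  These are near-invariant in real
# repertoires (the conserved tryptophans at heavy 36/103, the cysteines at
# heavy 92 / light 88 and their neighbours), and mutating them can make the
# planted numbering of an adjacent insertion unidentifiable.
FRAMEWORK_ANCHORS = {
    HEAVY: frozenset({29, 30, 36, 37, 48, 49, 66, 67, 81, 82, 83, 84, 93, 94, 103, 104}),
    LIGHT: frozenset({22, 23, 35, 36, 48, 49, 57, 58, 87, 88, 98, 99, 105, 106, 107}),
}

NO_PAIR = "no_pair"        # plant an O...N donor/acceptor pair
CC_PAIR = "cc_pair"        # plant a carbon-carbon pair
GENERIC = "generic"        # plant a CA...CA pair
ATOM_KINDS = (NO_PAIR, CC_PAIR, GENERIC)

_MIN_PLANT_DISTANCE = 2.0
_UNPLANTED_MIN_SEPARATION = 6.0
_PLANT_TOLERANCE = 0.01

# Local atom offsets of an ordinary (unplanted) residue; extent < 1.4 Å.
_BASE_OFFSETS = {
    "N": (-1.2, 0.9, 0.0),
    "CA": (0.0, 0.0, 0.0),
    "C": (1.3, 0.7, 0.0),
    "O": (1.3, 1.3, 1.0),
    "CB": (0.0, -1.1, 1.0),
}
# Offsets of the non-apex atoms of a planted residue, relative to its apex
# and pointing away from the partner (gap >= 2.0 Å behind the apex).
_BEHIND_OFFSETS = (
    (0.4, -2.0, 0.2),
    (-1.0, -2.3, 0.4),
    (0.9, -2.6, -0.4),
    (0.1, -2.9, 0.8),
)


@dataclass(frozen=True)
class FvSpec:
    """Recipe for a synthetic Fv sequence with known Kabat structure."""

    chain_type: str
    cdr_lengths: tuple[int, int, int] | None = None  # None -> template lengths
    insertions: tuple[tuple[int, int], ...] = ()     # (framework site, count)
    framework_source: str = "template"               # or "randomized"
    framework_mutation_rate: float = 0.1


@dataclass(frozen=True)
class PlantedContactSpec:
    fr_kabat_position: str
    cdr_kabat_position: str
    target_distance: float
    atom_kinds: str = GENERIC


@dataclass(frozen=True)
class PlantedInterfaceSpec:
    """Planted two-chain interface: (residue A, residue B, within cutoff?)."""

    pairs: tuple[tuple[str, str, bool], ...]
    in_range_distance: float = 4.5
    out_of_range_distance: float = 30.0
    extra_a: str = ""   # additional chain-A residues (one-letter), never in range
    extra_b: str = ""


def _template_cdr_lengths(chain_type: str) -> dict[str, int]:
    return {
        cdr: hi - lo + 1 for cdr, (lo, hi) in CDR_BOUNDS[chain_type].items()
    }


def _check_fv_spec(spec: FvSpec) -> dict[str, int]:
    if spec.chain_type not in TEMPLATES:
        raise GenerationError(f"unknown chain type {spec.chain_type!r}")
    base = _template_cdr_lengths(spec.chain_type)
    lengths = dict(base)
    if spec.cdr_lengths is not None:
        if len(spec.cdr_lengths) != 3:
            raise GenerationError("cdr_lengths must have exactly three entries")
        for cdr, length in zip(("CDR1", "CDR2", "CDR3"), spec.cdr_lengths):
            lo, hi = CDR_LENGTH_RANGES[spec.chain_type][cdr]
            if not lo <= length <= hi:
                raise GenerationError(
                    f"{spec.chain_type} {cdr} length {length} outside supported [{lo}, {hi}]"
                )
            lengths[cdr] = length
    legal_sites = FRAMEWORK_INSERTION_SITES[spec.chain_type]
    seen = set()
    for site, count in spec.insertions:
        if site not in legal_sites:
            raise GenerationError(
                f"framework insertion site {site} illegal for {spec.chain_type} "
                f"(legal: {legal_sites})"
            )
        if site in seen:
            raise GenerationError(f"duplicate insertion site {site}")
        if not 1 <= count <= 3:
            raise GenerationError("framework insertion count must be 1-3")
        seen.add(site)
    if spec.framework_source not in ("template", "randomized"):
        raise GenerationError(f"unknown framework_source {spec.framework_source!r}")
    return lengths


def make_fv_sequence(spec: FvSpec, seed: int) -> tuple[str, NumberedChain]:
    """Generate a sequence and its ground-truth Kabat numbering."""
    lengths = _check_fv_spec(spec)
    rng = np.random.default_rng(seed)
    aas = list(AMINO_ACIDS)
    template = TEMPLATES[spec.chain_type]
    cdr_sites = CDR_INSERTION_SITE[spec.chain_type]
    fr_ins = dict(spec.insertions)
    base_lengths = _template_cdr_lengths(spec.chain_type)

    def random_aa() -> str:
        return aas[int(rng.integers(len(aas)))]

    residues: list[NumberedResidue] = []
    for j, template_aa in enumerate(template):
        number = j + 1
        region = region_of(spec.chain_type, number)
        if region.startswith("CDR"):
            aa = random_aa()
        elif (
            spec.framework_source == "randomized"
            and number not in FRAMEWORK_ANCHORS[spec.chain_type]
            and rng.random() < spec.framework_mutation_rate
        ):
            choices = [a for a in aas if a != template_aa]
            aa = choices[int(rng.integers(len(choices)))]
        else:
            aa = template_aa
        residues.append(NumberedResidue(aa, number, "", region))
        extra = 0
        if region.startswith("CDR") and cdr_sites.get(region) == number:
            extra = lengths[region] - base_lengths[region]
        elif number in fr_ins:
            extra = fr_ins[number]
        for k in range(extra):
            residues.append(
                NumberedResidue(random_aa(), number, chr(ord("A") + k), region)
            )
    chain = NumberedChain(spec.chain_type, tuple(residues), source_id=f"synthetic-{spec.chain_type}-{seed}")
    return chain.sequence, chain


def isolated_residue(one_letter: str, name_hint: str | None = None) -> Residue:
    """A single toy residue at the origin (reference geometry for SASA)."""
    atom_names = ["N", "CA", "C", "O"] + ([] if one_letter == "G" else ["CB"])
    atoms = tuple(
        Atom(n, "N" if n == "N" else ("O" if n == "O" else "C"), _BASE_OFFSETS[n])
        for n in atom_names
    )
    return Residue("A", 1, "", name_hint or ONE_TO_THREE.get(one_letter, "UNK"), atoms)


def _residue_atoms(one_letter: str) -> list[str]:
    return ["N", "CA", "C", "O"] + ([] if one_letter == "G" else ["CB"])


def _element_of(atom_name: str) -> str:
    return {"N": "N", "O": "O"}.get(atom_name, "C")


def _plain_cluster(one_letter: str, origin: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    return [
        (n, _element_of(n), origin + np.array(_BASE_OFFSETS[n]))
        for n in _residue_atoms(one_letter)
    ]


def _apex_atom(one_letter: str, kind: str, side: str) -> str:
    if kind == NO_PAIR:
        return "O" if side == "fr" else "N"
    if kind == CC_PAIR:
        return "CA" if one_letter == "G" else "CB"
    return "CA"


def _planted_cluster(
    one_letter: str, apex_name: str, apex_pos: np.ndarray, direction: float
) -> list[tuple[str, str, np.ndarray]]:
    """Apex atom at ``apex_pos``; remaining atoms >= 2 Å behind it along y."""
    atoms = [(apex_name, _element_of(apex_name), apex_pos.copy())]
    others = [n for n in _residue_atoms(one_letter) if n != apex_name]
    for atom_name, (dx, dy, dz) in zip(others, _BEHIND_OFFSETS):
        atoms.append(
            (atom_name, _element_of(atom_name), apex_pos + np.array((dx, direction * -dy, dz)))
        )
    # keep PDB atom order canonical (N, CA, C, O, CB)
    order = {n: i for i, n in enumerate(_residue_atoms(one_letter))}
    atoms.sort(key=lambda t: order[t[0]])
    return atoms


def _format_pdb(chains: dict[str, list[tuple[str, str, list[tuple[str, str, np.ndarray]]]]]) -> str:
    """chains: chain id -> list of (resname3, icode-free resnum implied, atoms)."""
    lines = []
    serial = 1
    for chain_id in chains:
        for resnum, (resname, _one, atoms) in enumerate(chains[chain_id], start=1):
            for atom_name, element, pos in atoms:
                name_field = f" {atom_name:<3s}" if len(atom_name) < 4 else atom_name
                lines.append(
                    f"ATOM  {serial:5d} {name_field:<4s} {resname:<3s} {chain_id}{resnum:4d}    "
                    f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _check_contact_specs(chain: NumberedChain, contacts: Sequence[PlantedContactSpec]) -> None:
    pmap = chain.position_map
    seen_cdr: set[str] = set()
    per_fr: dict[str, str] = {}
    seen_pairs = set()
    for c in contacts:
        fr = pmap.get(c.fr_kabat_position)
        cdr = pmap.get(c.cdr_kabat_position)
        if fr is None or cdr is None:
            raise GenerationError(
                f"planted positions {c.fr_kabat_position}/{c.cdr_kabat_position} not in chain"
            )
        if not fr.region.startswith("FR") or not cdr.region.startswith("CDR"):
            raise GenerationError(
                f"plant must pair a framework with a CDR position, got "
                f"{fr.region}/{cdr.region}"
            )
        if c.atom_kinds not in ATOM_KINDS:
            raise GenerationError(f"unknown atom kind {c.atom_kinds!r}")
        if c.target_distance < _MIN_PLANT_DISTANCE:
            raise GenerationError(
                f"target distance {c.target_distance} below the steric floor "
                f"{_MIN_PLANT_DISTANCE} Å"
            )
        pair = (c.fr_kabat_position, c.cdr_kabat_position)
        if pair in seen_pairs:
            raise GenerationError(f"contradictory duplicate plant for pair {pair}")
        seen_pairs.add(pair)
        if c.cdr_kabat_position in seen_cdr:
            raise GenerationError(
                f"CDR position {c.cdr_kabat_position} planted against two framework "
                "positions: over-constrained"
            )
        seen_cdr.add(c.cdr_kabat_position)
        apex = _apex_atom(fr.one_letter_code, c.atom_kinds, "fr")
        prev = per_fr.get(c.fr_kabat_position)
        if prev is not None and prev != apex:
            raise GenerationError(
                f"plants on framework position {c.fr_kabat_position} designate "
                "different framework atoms: over-constrained"
            )
        if prev is not None and sum(
            1 for s in contacts if s.fr_kabat_position == c.fr_kabat_position
        ) > 2:
            raise GenerationError(
                f"more than two plants on framework position {c.fr_kabat_position}: "
                "over-constrained"
            )
        per_fr[c.fr_kabat_position] = apex


def make_fv_structure(
    chain: NumberedChain, contacts: Sequence[PlantedContactSpec], seed: int
) -> str:
    """PDB text for a toy Fv with planted framework-CDR contacts.

    Framework residues sit on one rail, CDR residues on a far parallel rail;
    each planted CDR residue is relocated so that the designated atom pair
    meets its target distance exactly, with all other atoms of both residues
    kept behind the apex atoms.  The emitted coordinates are re-measured
    brute-force before returning.
    """
    _check_contact_specs(chain, contacts)
    del seed  # geometry is fully deterministic; kept for interface symmetry
    fr_keys = [r.key for r in chain.residues if r.region.startswith("FR")]
    fr_slot = {k: i for i, k in enumerate(fr_keys)}
    cdr_keys = [r.key for r in chain.residues if r.region.startswith("CDR")]
    cdr_slot = {k: i for i, k in enumerate(cdr_keys)}
    pmap = chain.position_map

    spacing, cdr_rail_y = 12.0, 30.0
    plants_by_fr: dict[str, list[PlantedContactSpec]] = {}
    for c in contacts:
        plants_by_fr.setdefault(c.fr_kabat_position, []).append(c)
    planted_cdr = {c.cdr_kabat_position: c for c in contacts}

    placements: dict[str, list[tuple[str, str, np.ndarray]]] = {}
    for fr_key, plist in plants_by_fr.items():
        x0 = fr_slot[fr_key] * spacing
        fr_aa = pmap[fr_key].one_letter_code
        for idx, c in enumerate(plist):
            apex_f_name = _apex_atom(fr_aa, c.atom_kinds, "fr")
            if idx == 0:
                apex_f = np.array((x0, 2.0, 0.0))
                placements[fr_key] = _planted_cluster(fr_aa, apex_f_name, apex_f, direction=-1.0)
            else:
                # second plant shares the framework apex atom; its partner is
                # tilted off the vertical so both target distances hold
                apex_f = next(p for n, _, p in placements[fr_key] if n == apex_f_name)
            tilt = 0.0 if idx == 0 else math.radians(35.0)
            offset = np.array(
                (c.target_distance * math.sin(tilt), c.target_distance * math.cos(tilt), 0.0)
            )
            cdr_aa = pmap[c.cdr_kabat_position].one_letter_code
            apex_c_name = _apex_atom(cdr_aa, c.atom_kinds, "cdr")
            placements[c.cdr_kabat_position] = _planted_cluster(
                cdr_aa, apex_c_name, apex_f + offset, direction=+1.0
            )

    residues_out: list[tuple[str, str, list[tuple[str, str, np.ndarray]]]] = []
    for res in chain.residues:
        if res.key in placements:
            atoms = placements[res.key]
        elif res.region.startswith("FR"):
            atoms = _plain_cluster(
                res.one_letter_code, np.array((fr_slot[res.key] * spacing, 0.0, 0.0))
            )
        else:
            atoms = _plain_cluster(
                res.one_letter_code, np.array((cdr_slot[res.key] * spacing, cdr_rail_y, 0.0))
            )
        residues_out.append((ONE_TO_THREE.get(res.one_letter_code, "UNK"), res.one_letter_code, atoms))

    _verify_fv_geometry(chain, contacts, residues_out)
    return _format_pdb({"A": residues_out})


def _min_pair_distance(atoms_a, atoms_b) -> float:
    pa = np.array([p for _, _, p in atoms_a])
    pb = np.array([p for _, _, p in atoms_b])
    return float(np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1).min())


def _verify_fv_geometry(chain, contacts, residues_out) -> None:
    atoms_by_key = {res.key: residues_out[i][2] for i, res in enumerate(chain.residues)}
    planted = {(c.fr_kabat_position, c.cdr_kabat_position): c for c in contacts}
    fr = [r.key for r in chain.residues if r.region.startswith("FR")]
    cdr = [r.key for r in chain.residues if r.region.startswith("CDR")]
    for f in fr:
        for c in cdr:
            d = _min_pair_distance(atoms_by_key[f], atoms_by_key[c])
            spec = planted.get((f, c))
            if spec is not None:
                if abs(d - spec.target_distance) > _PLANT_TOLERANCE:
                    raise GenerationError(
                        f"planted pair {f}-{c}: realized {d:.3f} Å, wanted "
                        f"{spec.target_distance:.3f} Å (over-constrained geometry)"
                    )
            elif d <= _UNPLANTED_MIN_SEPARATION:
                raise GenerationError(
                    f"unplanted pair {f}-{c} at {d:.2f} Å violates the "
                    f">{_UNPLANTED_MIN_SEPARATION} Å separation guarantee"
                )


def make_complex(spec: PlantedInterfaceSpec, seed: int) -> tuple[str, dict[str, int]]:
    """PDB text for a toy two-chain complex plus ground-truth IC counts.

    Ground truth counts use the default polarity classes and are derived
    from the spec alone; the emitted geometry is re-measured before return.
    """
    from .affinity import IC_KEYS, _pair_key, residue_class

    del seed  # deterministic layout; kept for interface symmetry
    if not spec.pairs and not (spec.extra_a or spec.extra_b):
        raise GenerationError("empty interface spec")
    if not 2.0 <= spec.in_range_distance <= 5.5:
        raise GenerationError("in_range_distance must lie in [2.0, 5.5] Å")
    if spec.out_of_range_distance <= 6.5:
        raise GenerationError("out_of_range_distance must exceed 6.5 Å")

    spacing = 14.0
    chain_a: list[tuple[str, str, list[tuple[str, str, np.ndarray]]]] = []
    chain_b: list[tuple[str, str, list[tuple[str, str, np.ndarray]]]] = []
    counts = {k: 0 for k in IC_KEYS}
    for i, (aa_a, aa_b, in_range) in enumerate(spec.pairs):
        x0 = i * spacing
        if in_range:
            apex_a = np.array((x0, 2.0, 0.0))
            atoms_a = _planted_cluster(aa_a, _apex_atom(aa_a, GENERIC, "fr"), apex_a, direction=-1.0)
            apex_b = apex_a + np.array((0.0, spec.in_range_distance, 0.0))
            atoms_b = _planted_cluster(aa_b, _apex_atom(aa_b, GENERIC, "cdr"), apex_b, direction=+1.0)
            counts[_pair_key(residue_class(aa_a), residue_class(aa_b))] += 1
        else:
            atoms_a = _plain_cluster(aa_a, np.array((x0, 0.0, 0.0)))
            atoms_b = _plain_cluster(aa_b, np.array((x0, spec.out_of_range_distance, 0.0)))
        chain_a.append((ONE_TO_THREE[aa_a], aa_a, atoms_a))
        chain_b.append((ONE_TO_THREE[aa_b], aa_b, atoms_b))
    x_extra = len(spec.pairs) * spacing
    for j, aa in enumerate(spec.extra_a):
        chain_a.append((ONE_TO_THREE[aa], aa, _plain_cluster(aa, np.array((x_extra + j * spacing, 0.0, 0.0)))))
    for j, aa in enumerate(spec.extra_b):
        chain_b.append(
            (ONE_TO_THREE[aa], aa, _plain_cluster(aa, np.array((x_extra + j * spacing, spec.out_of_range_distance, 0.0))))
        )

    # independent re-measurement: every planted in-range pair within the IC
    # cutoff, everything else across the interface beyond 6 Å
    for i, ra in enumerate(chain_a):
        for j, rb in enumerate(chain_b):
            d = _min_pair_distance(ra[2], rb[2])
            if i == j and j < len(spec.pairs) and spec.pairs[i][2]:
                if abs(d - spec.in_range_distance) > _PLANT_TOLERANCE:
                    raise GenerationError(f"planted interface pair {i}: {d:.3f} Å off target")
            elif d <= _UNPLANTED_MIN_SEPARATION:
                raise GenerationError(
                    f"cross-chain pair A{i+1}-B{j+1} at {d:.2f} Å violates separation"
                )
    return _format_pdb({"A": chain_a, "B": chain_b}), counts
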
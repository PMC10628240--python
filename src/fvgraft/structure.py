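"""Structure reading, framework-CDR contact analysis and back-mutation logic.

The structural questions asked here are purely distance-based, matching how a
modeller inspects a predicted Fv in a viewer: which framework residues sit
within 4.2 Å of a CDR residue, is any N/O-N/O atom pair in hydrogen-bond
range (2.7-3.3 Å), is any C-C pair in van-der-Waals range (3.3-4.0 Å), and
is the residue pair beyond 10 Å (no interaction possible).  Hydrogens are
ignored throughout — predicted models rarely have reliable ones — and no
angle terms or donor/acceptor chemistry tables are applied.

The back-mutation recommender turns a per-framework-position contact summary
(:class:`SupportMap`) plus the parent/germline residue pair into one decision
per differing framework position, via a fixed rule cascade (see
:func:`recommend_back_mutations`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from Bio import Align

from .errors import InputError, MappingError
from .kabat import NumberedChain, UpperCoreSet

ANALYSIS_CUTOFF = 4.2       # Å, framework-CDR contact window
HBOND_RANGE = (2.7, 3.3)    # Å, donor-acceptor N/O pair
HYDROPHOBIC_RANGE = (3.3, 4.0)  # Å, carbon-carbon pair
NO_INTERACTION_BEYOND = 10.0    # Å, residue pairs past this cannot interact

HYDROGEN_BOND = "hydrogen_bond"
HYDROPHOBIC = "hydrophobic"
PROXIMAL = "proximal"
NONE = "none"

BACK_MUTATE = "BACK_MUTATE"
KEEP_HUMAN = "KEEP_HUMAN"
UPPER_CORE = "UPPER_CORE"
CONSERVATIVE_SWAP = "CONSERVATIVE_SWAP"
NO_CDR_CONTACT = "NO_CDR_CONTACT"
MINOR_CONTACT = "MINOR_CONTACT"
CONTACT_DISRUPTING = "CONTACT_DISRUPTING"

# Physicochemical classes under which a framework substitution is considered
# conservative (e.g. K<->R both positively charged basic; S<->T both small
# hydroxyl).  Configurable via PipelineConfig.
DEFAULT_SWAP_CLASSES: tuple[frozenset[str], ...] = tuple(
    frozenset(s)
    for s in ("KRH", "DE", "ST", "NQ", "LIVM", "FYW", "AG", "C", "P")
)
DEFAULT_CONTACT_WEIGHT_THRESHOLD = 1

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass(frozen=True)
class Residue:
    chain_id: str
    seqid: int
    icode: str
    name: str
    atoms: tuple[Atom, ...]

    @property
    def author_key(self) -> str:
        return f"{self.seqid}{self.icode}"

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class StructureModel:
    chains: dict[str, tuple[Residue, ...]]
    source: str = ""

    def chain(self, chain_id: str) -> tuple[Residue, ...]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise InputError(f"chain {chain_id!r} not in structure (has {sorted(self.chains)})")

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.chain(chain_id))


@dataclass(frozen=True)
class ContactRecord:
    fr_position: str
    cdr_position: str
    min_distance: float
    closest_atom_pair: tuple[str, str]
    interaction_class: str


@dataclass(frozen=True)
class PositionSupport:
    contacts: tuple[ContactRecord, ...]

    @property
    def contact_count(self) -> int:
        return len(self.contacts)

    @property
    def has_hydrogen_bond(self) -> bool:
        return any(c.interaction_class == HYDROGEN_BOND for c in self.contacts)


@dataclass(frozen=True)
class SupportMap:
    """Per-framework-position summary of CDR contacts within the 4.2 Å window."""

    positions: dict[str, PositionSupport]

    def support(self, kabat_key: str) -> PositionSupport:
        return self.positions.get(kabat_key, PositionSupport(()))


@dataclass(frozen=True)
class BackMutationRecommendation:
    kabat_position: str
    parent_residue: str
    germline_residue: str
    decision: str
    rationale: str


def read_structure(path: str | Path) -> StructureModel:
    """Read a PDB file into a light-weight model.

    Waters and hydrogens are dropped; alternate conformations collapse to the
    highest-occupancy (first on tie) location; chains with no standard amino
    acid are rejected.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise InputError(f"cannot read PDB file {path}: {exc}") from None
    if len(st) == 0:
        raise InputError(f"no models in {path}")
    st.remove_alternative_conformations()
    st.remove_hydrogens()
    st.remove_waters()
    model = st[0]
    chains: dict[str, tuple[Residue, ...]] = {}
    for ch in model:
        residues = []
        for res in ch:
            if res.is_water():
                continue
            atoms = tuple(
                Atom(a.name, a.element.name.upper(), (a.pos.x, a.pos.y, a.pos.z))
                for a in res
                if a.element.name.upper() not in ("H", "D")
            )
            if atoms:
                residues.append(
                    Residue(ch.name, res.seqid.num, res.seqid.icode.strip(), res.name, atoms)
                )
        if residues:
            if not any(r.name in THREE_TO_ONE for r in residues):
                raise InputError(f"chain {ch.name} in {path} has no standard residues")
            chains[ch.name] = tuple(residues)
    if not chains:
        raise InputError(f"no protein chains in {path}")
    return StructureModel(chains, source=str(path))


def map_structure_to_kabat(
    model: StructureModel,
    chain: NumberedChain,
    chain_id: str,
    min_identity: float = 0.9,
) -> dict[str, str]:
    """Align a structure chain onto a numbered sequence.

    Returns an injective mapping author residue key -> Kabat position key.
    Residues that do not align (gaps, mismatched tails) are left out; an
    overall aligned identity below ``min_identity`` raises MappingError.
    """
    residues = model.chain(chain_id)
    struct_seq = "".join(r.one_letter for r in residues)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    aln = aligner.align(chain.sequence, struct_seq)[0]
    mapping: dict[str, str] = {}
    matches = aligned_cols = 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for k in range(t1 - t0):
            ti, qi = t0 + k, q0 + k
            aligned_cols += 1
            matches += chain.sequence[ti] == struct_seq[qi]
            mapping[residues[qi].author_key] = chain.residues[ti].key
    if aligned_cols == 0 or matches / aligned_cols < min_identity:
        got = matches / aligned_cols if aligned_cols else 0.0
        raise MappingError(
            f"structure chain {chain_id} aligns to the numbered sequence at "
            f"{got:.0%} identity (< {min_identity:.0%})"
        )
    return mapping


def _min_distance(a: np.ndarray, b: np.ndarray) -> tuple[float, int, int]:
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    idx = int(np.argmin(d))
    i, j = divmod(idx, d.shape[1])
    return float(d[i, j]), i, j


def classify_interaction(
    res_a: Residue,
    res_b: Residue,
    hbond_range: tuple[float, float] = HBOND_RANGE,
    hydrophobic_range: tuple[float, float] = HYDROPHOBIC_RANGE,
    proximal_cutoff: float = ANALYSIS_CUTOFF,
) -> str:
    """Distance-only interaction class of a residue pair.

    hydrogen_bond if any N/O-N/O pair lies in the donor-acceptor window
    (inclusive at both ends); else hydrophobic if any C-C pair lies in the
    van-der-Waals window; else proximal if the residues approach within the
    analysis cutoff; otherwise none (including the undefined 4.2-10 Å band
    and pairs beyond 10 Å).
    """
    pa, pb = res_a.coords(), res_b.coords()
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    ea = np.array([a.element for a in res_a.atoms])
    eb = np.array([b.element for b in res_b.atoms])
    no_a = np.isin(ea, ("N", "O"))
    no_b = np.isin(eb, ("N", "O"))
    if no_a.any() and no_b.any():
        dd = d[np.ix_(no_a, no_b)]
        if ((dd >= hbond_range[0]) & (dd <= hbond_range[1])).any():
            return HYDROGEN_BOND
    c_a = ea == "C"
    c_b = eb == "C"
    if c_a.any() and c_b.any():
        dd = d[np.ix_(c_a, c_b)]
        if ((dd >= hydrophobic_range[0]) & (dd <= hydrophobic_range[1])).any():
            return HYDROPHOBIC
    if d.min() <= proximal_cutoff:
        return PROXIMAL
    return NONE


def find_fr_cdr_contacts(
    model: StructureModel,
    mapping: Mapping[str, str],
    annotation: NumberedChain,
    chain_id: str | None = None,
    cutoff: float = ANALYSIS_CUTOFF,
) -> SupportMap:
    """All framework-CDR residue pairs within ``cutoff`` Å (heavy atoms).

    Every mapped framework position appears in the result, with an empty
    contact list when nothing lies within the window.
    """
    if chain_id is None:
        if len(model.chains) != 1:
            raise InputError("chain_id required for multi-chain structures")
        chain_id = next(iter(model.chains))
    pos_map = annotation.position_map
    by_key = {r.author_key: r for r in model.chain(chain_id)}
    fr: list[tuple[str, Residue]] = []
    cdr: list[tuple[str, Residue]] = []
    for author_key, kabat_key in mapping.items():
        res = by_key.get(author_key)
        numbered = pos_map.get(kabat_key)
        if res is None or numbered is None:
            continue
        if numbered.region.startswith("FR"):
            fr.append((kabat_key, res))
        else:
            cdr.append((kabat_key, res))
    positions: dict[str, PositionSupport] = {}
    for fr_key, fr_res in fr:
        records = []
        for cdr_key, cdr_res in cdr:
            dist, i, j = _min_distance(fr_res.coords(), cdr_res.coords())
            if dist <= cutoff:
                records.append(
                    ContactRecord(
                        fr_position=fr_key,
                        cdr_position=cdr_key,
                        min_distance=dist,
                        closest_atom_pair=(fr_res.atoms[i].name, cdr_res.atoms[j].name),
                        interaction_class=classify_interaction(fr_res, cdr_res, proximal_cutoff=cutoff),
                    )
                )
        positions[fr_key] = PositionSupport(tuple(records))
    return SupportMap(positions)


def interface_residues(
    model: StructureModel,
    side_a: Sequence[str],
    side_b: Sequence[str],
    cutoff: float,
) -> list[tuple[Residue, Residue, float]]:
    """Cross-side residue pairs with min heavy-atom distance <= cutoff."""
    sa, sb = set(side_a), set(side_b)
    if not sa or not sb:
        raise InputError("both interface sides must be non-empty")
    if sa & sb:
        raise InputError(f"interface sides overlap: {sorted(sa & sb)}")
    res_a = [r for cid in sorted(sa) for r in model.chain(cid)]
    res_b = [r for cid in sorted(sb) for r in model.chain(cid)]
    pairs = []
    coords_b = [r.coords() for r in res_b]
    centers_b = np.array([c.mean(axis=0) for c in coords_b])
    radii_b = np.array([np.linalg.norm(c - m, axis=1).max() for c, m in zip(coords_b, centers_b)])
    for ra in res_a:
        ca = ra.coords()
        center_a = ca.mean(axis=0)
        radius_a = np.linalg.norm(ca - center_a, axis=1).max()
        # bounding-sphere prefilter; exact distances for survivors
        lower = np.linalg.norm(centers_b - center_a, axis=1) - radii_b - radius_a
        for j in np.nonzero(lower <= cutoff)[0]:
            dist, _, _ = _min_distance(ca, coords_b[j])
            if dist <= cutoff:
                pairs.append((ra, res_b[j], dist))
    return pairs


def recommend_back_mutations(
    parent: NumberedChain,
    germline,
    support: SupportMap,
    core: UpperCoreSet,
    swap_classes: Sequence[frozenset[str]] = DEFAULT_SWAP_CLASSES,
    contact_weight_threshold: int = DEFAULT_CONTACT_WEIGHT_THRESHOLD,
) -> list[BackMutationRecommendation]:
    """One decision per framework position where parent and germline differ.

    Rule cascade, first match wins:

    1. position in the upper hydrophobic core -> BACK_MUTATE (UPPER_CORE):
       the platform beneath the CDRs must stay donor-like;
    2. no CDR contacts within the analysis window -> KEEP_HUMAN
       (NO_CDR_CONTACT): surface residues distant from the CDRs do not
       affect antigen binding;
    3. substitution within one physicochemical class -> KEEP_HUMAN
       (CONSERVATIVE_SWAP): the human residue can maintain the same
       interactions (e.g. K->R, T->S);
    4. contacts exist but carry no hydrogen bond and number at most
       ``contact_weight_threshold`` -> KEEP_HUMAN (MINOR_CONTACT);
    5. otherwise -> BACK_MUTATE (CONTACT_DISRUPTING).
    """
    gchain = germline.numbered_sequence if hasattr(germline, "numbered_sequence") else germline
    if parent.chain_type != gchain.chain_type:
        raise InputError("parent and germline chain types differ")
    gmap = gchain.position_map
    out: list[BackMutationRecommendation] = []
    for res in parent.residues:
        if not res.region.startswith("FR"):
            continue
        other = gmap.get(res.key)
        if other is None or other.one_letter_code == res.one_letter_code:
            continue
        p, g = res.one_letter_code, other.one_letter_code
        sup = support.support(res.key)
        if res.insertion_code == "" and res.kabat_number in core:
            decision, rationale = BACK_MUTATE, UPPER_CORE
        elif sup.contact_count == 0:
            decision, rationale = KEEP_HUMAN, NO_CDR_CONTACT
        elif any(p in cls and g in cls for cls in swap_classes):
            decision, rationale = KEEP_HUMAN, CONSERVATIVE_SWAP
        elif not sup.has_hydrogen_bond and sup.contact_count <= contact_weight_threshold:
            decision, rationale = KEEP_HUMAN, MINOR_CONTACT
        else:
            decision, rationale = BACK_MUTATE, CONTACT_DISRUPTING
        out.append(BackMutationRecommendation(res.key, p, g, decision, rationale))
    return out


def support_map_from_rows(rows: Iterable[Mapping[str, object]]) -> SupportMap:
    """Build a SupportMap from tabulated contact summaries.

    Each row: fr_position, cdr_position, min_distance, interaction_class and
    optionally the closest atom pair — the text form used for transcribed
    (non-coordinate) contact narratives and for the contacts TSV.
    """
    positions: dict[str, list[ContactRecord]] = {}
    for row in rows:
        fr = str(row["fr_position"])
        rec = ContactRecord(
            fr_position=fr,
            cdr_position=str(row.get("cdr_position", "")),
            min_distance=float(row.get("min_distance", 0.0)),
            closest_atom_pair=tuple(row.get("closest_atom_pair", ("", ""))),  # type: ignore[arg-type]
            interaction_class=str(row.get("interaction_class", PROXIMAL)),
        )
        positions.setdefault(fr, []).append(rec)
    return SupportMap({k: PositionSupport(tuple(v)) for k, v in positions.items()})


def write_contacts_tsv(support: SupportMap, handle) -> None:
    handle.write("fr_position\tcdr_position\tmin_distance\tclass\tfr_atom\tcdr_atom\n")
    for fr_key in sorted(support.positions, key=_kabat_sort_key):
        for c in support.positions[fr_key].contacts:
            handle.write(
                f"{c.fr_position}\t{c.cdr_position}\t{c.min_distance:.3f}\t"
                f"{c.interaction_class}\t{c.closest_atom_pair[0]}\t{c.closest_atom_pair[1]}\n"
            )


def write_recommendations_tsv(recs: Iterable[BackMutationRecommendation], handle) -> None:
    handle.write("kabat_position\tparent\tgermline\tdecision\trationale\n")
    for r in recs:
        handle.write(
            f"{r.kabat_position}\t{r.parent_residue}\t{r.germline_residue}\t"
            f"{r.decision}\t{r.rationale}\n"
        )


def _kabat_sort_key(key: str) -> tuple[int, str]:
    num = "".join(ch for ch in key if ch.isdigit())
    return (int(num), key[len(num):])
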
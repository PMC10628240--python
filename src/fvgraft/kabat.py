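"""Kabat numbering and region annotation for antibody variable domains.

An Fv sequence (VH or VL) is numbered by global alignment against a packaged
position-annotated consensus template, one per chain type.  Insertions
relative to the template are only permitted at the canonical Kabat insertion
sites (heavy: after 35, 52, 82, 100; light: after 27, 95, 106) and receive
alphabetic insertion codes (82 -> 82A, 82B, ...).  Deletions relative to the
template simply skip Kabat numbers.  The alignment is a bespoke dynamic
program because the site-restricted gap rule is the point: a generic affine
aligner would happily open insertions anywhere.

Region labels follow the standard Kabat CDR boundaries:

    heavy: CDR1 31-35(B), CDR2 50-65, CDR3 95-102
    light: CDR1 24-34,    CDR2 50-56, CDR3 89-97

so that e.g. heavy 63 and 65 fall in CDR-H2, heavy 66 in FR3, and light 26 in
CDR-L1.  Framework regions are the complements; FR4 may be absent on
truncated (V-gene-only) input.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio.Align import substitution_matrices

from .errors import InputError, NotAnFvError

HEAVY = "heavy"
LIGHT = "light"
CHAIN_TYPES = (HEAVY, LIGHT)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"

REGIONS = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")

# Consensus numbering templates.  Plain positions 1..N; real antibodies with
# occupied 82A-C / long CDRs acquire insertion codes via alignment.
HEAVY_TEMPLATE = (
    "QVQLVQSGAEVKKPGASVKVSCKASGYTFT"  # FR1   1-30
    "SYYMH"                           # CDR1 31-35
    "WVRQAPGQGLEWMG"                  # FR2  36-49
    "IINPSGGSTSYAQKFQ"                # CDR2 50-65
    "RVTITRDTSTSTVYMELSSLRSEDTACAR"   # FR3  66-94
    "DGGYYFDY"                        # CDR3 95-102
    "WGQGTLVTVSS"                     # FR4 103-113
)
LIGHT_TEMPLATE = (
    "DIQMTQSPSSLSASVGDRVTITC"          # FR1   1-23
    "RASQSISSYLN"                      # CDR1 24-34
    "WYQQKPGKAPKLLIY"                  # FR2  35-49
    "AASSLQS"                          # CDR2 50-56
    "GVPSRFSGSGSGTDFTLTISSLQPEDFATYYC"  # FR3 57-88
    "QQSYSTPLT"                        # CDR3 89-97
    "FGQGTKVEIK"                       # FR4 98-107
)
TEMPLATES = {HEAVY: HEAVY_TEMPLATE, LIGHT: LIGHT_TEMPLATE}

# Canonical insertion sites: an inserted residue is numbered <site><code>.
INSERTION_SITES = {HEAVY: (35, 52, 82, 100), LIGHT: (27, 95, 106)}

# CDR boundaries as (first, last) Kabat numbers; insertion codes inherit the
# region of their base number.
CDR_BOUNDS = {
    HEAVY: {"CDR1": (31, 35), "CDR2": (50, 65), "CDR3": (95, 102)},
    LIGHT: {"CDR1": (24, 34), "CDR2": (50, 56), "CDR3": (89, 97)},
}

DEFAULT_UPPER_CORE = {
    HEAVY: frozenset({2, 4, 24, 27, 29, 47, 48, 49, 69, 71, 78, 94}),
    LIGHT: frozenset({2, 4, 64, 66, 71}),
}

MIN_LENGTH, MAX_LENGTH = 90, 140
FRAMEWORK_IDENTITY_FLOOR = 0.5

_BLOSUM = substitution_matrices.load("BLOSUM62")
_SCORE = {
    (a, b): float(_BLOSUM[a, b])
    for a in _BLOSUM.alphabet
    for b in _BLOSUM.alphabet
}

_GAP_DELETE = -8.0       # skip one template column internally
# One inserted query residue at a canonical insertion site.  Strictly worse
# than the worst BLOSUM62 mismatch (-4) so a terminal residue can never dodge
# a bad match by becoming an insertion followed by a free end deletion.
_GAP_INSERT = -4.5
_FORBIDDEN = -1.0e9      # insertion anywhere else


def _check_chain_type(chain_type: str) -> str:
    if chain_type not in CHAIN_TYPES:
        raise InputError(f"unknown chain type {chain_type!r}; expected one of {CHAIN_TYPES}")
    return chain_type


def region_of(chain_type: str, kabat_number: int) -> str:
    """Kabat region label for a position number (insertion codes inherit it)."""
    _check_chain_type(chain_type)
    bounds = CDR_BOUNDS[chain_type]
    for cdr, (lo, hi) in bounds.items():
        if lo <= kabat_number <= hi:
            return cdr
    if kabat_number < bounds["CDR1"][0]:
        return "FR1"
    if kabat_number < bounds["CDR2"][0]:
        return "FR2"
    if kabat_number < bounds["CDR3"][0]:
        return "FR3"
    return "FR4"


@dataclass(frozen=True)
class NumberedResidue:
    one_letter_code: str
    kabat_number: int
    insertion_code: str = ""
    region: str = ""

    @property
    def key(self) -> str:
        """Position label, e.g. ``"82A"``."""
        return f"{self.kabat_number}{self.insertion_code}"

    @property
    def sort_key(self) -> tuple[int, str]:
        return (self.kabat_number, self.insertion_code)


@dataclass(frozen=True)
class NumberedChain:
    chain_type: str
    residues: tuple[NumberedResidue, ...]
    source_id: str = ""

    def __post_init__(self) -> None:
        _check_chain_type(self.chain_type)
        keys = [r.sort_key for r in self.residues]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise InputError("residue positions are not strictly increasing")

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter_code for r in self.residues)

    @property
    def position_map(self) -> dict[str, NumberedResidue]:
        return {r.key: r for r in self.residues}

    def residue_at(self, key: str) -> NumberedResidue | None:
        return self.position_map.get(key)

    def framework_keys(self) -> list[str]:
        return [r.key for r in self.residues if r.region.startswith("FR")]

    def cdr_keys(self) -> list[str]:
        return [r.key for r in self.residues if r.region.startswith("CDR")]

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class UpperCoreSet:
    """Framework positions forming the platform directly beneath the CDRs.

    These "upper hydrophobic core" residues support CDR loop conformation;
    a grafted framework must preserve them (or have them back-mutated).
    """

    chain_type: str
    positions: frozenset[int] = field(default_factory=frozenset)

    def __contains__(self, kabat_number: int) -> bool:
        return kabat_number in self.positions


def upper_core_positions(chain_type: str, extra: Iterable[int] = ()) -> UpperCoreSet:
    """Default upper-hydrophobic-core position set for a chain type.

    Heavy: 2, 4, 24, 27, 29 (FR1), 47-49 (FR2), 69, 71, 78, 94 (FR3).
    Light: 2, 4 (FR1), 64, 66, 71 (FR3).
    """
    _check_chain_type(chain_type)
    return UpperCoreSet(chain_type, DEFAULT_UPPER_CORE[chain_type] | frozenset(extra))


def _validate_sequence(sequence: str) -> str:
    seq = sequence.strip().upper()
    bad = sorted(set(seq) - set(ALPHABET))
    if bad:
        raise InputError(f"illegal sequence characters: {''.join(bad)}")
    if not MIN_LENGTH <= len(seq) <= MAX_LENGTH:
        raise InputError(
            f"sequence length {len(seq)} outside the supported Fv range "
            f"[{MIN_LENGTH}, {MAX_LENGTH}]"
        )
    return seq


def _align_to_template(seq: str, chain_type: str) -> list[tuple[int, int]]:
    """Site-restricted global alignment of ``seq`` against the template.

    Returns traceback moves as (di, dj) per step: (1,1) match/mismatch,
    (0,1) template column skipped, (1,0) query residue inserted.  End
    deletions (leading/trailing template columns) are free so truncated
    chains align cleanly; insertions are only affordable after canonical
    insertion-site columns.  Tie-break order: diagonal > delete > insert,
    applied during traceback for determinism.
    """
    template = TEMPLATES[chain_type]
    sites = set(INSERTION_SITES[chain_type])
    n, m = len(seq), len(template)
    NEG = float("-inf")
    score = [[NEG] * (m + 1) for _ in range(n + 1)]
    score[0][0] = 0.0
    ins_ok = [False] + [(j in sites) for j in range(1, m + 1)]  # after column j
    # CDR columns score flat: hypervariable content must not pull the
    # alignment around; only framework anchors determine the placement.
    is_cdr = [False] + [
        region_of(chain_type, j).startswith("CDR") for j in range(1, m + 1)
    ]

    for j in range(1, m + 1):
        score[0][j] = 0.0  # free leading deletions
    for i in range(1, n + 1):
        qi = seq[i - 1]
        row, prev = score[i], score[i - 1]
        for j in range(m + 1):
            best = NEG
            if j > 0:
                d = prev[j - 1] + (0.0 if is_cdr[j] else _SCORE[qi, template[j - 1]])
                if d > best:
                    best = d
                s = row[j - 1] + (0.0 if i == n else _GAP_DELETE)
                if s > best:
                    best = s
            g = prev[j] + (_GAP_INSERT if ins_ok[j] else _FORBIDDEN)
            if g > best:
                best = g
            row[j] = best

    if score[n][m] <= _FORBIDDEN / 2:
        raise NotAnFvError("sequence cannot be aligned to the Fv template")

    moves: list[tuple[int, int]] = []
    i, j = n, m
    eps = 1e-9
    while i > 0 or j > 0:
        s = score[i][j]
        diag = 0.0 if (j > 0 and is_cdr[j]) else (_SCORE[seq[i - 1], template[j - 1]] if i > 0 and j > 0 else NEG)
        if i > 0 and j > 0 and abs(score[i - 1][j - 1] + diag - s) < eps:
            moves.append((1, 1)); i -= 1; j -= 1
        elif j > 0 and abs(score[i][j - 1] + (0.0 if i in (0, n) else _GAP_DELETE) - s) < eps:
            moves.append((0, 1)); j -= 1
        elif i > 0 and ins_ok[j] and abs(score[i - 1][j] + _GAP_INSERT - s) < eps:
            moves.append((1, 0)); i -= 1
        else:  # pragma: no cover - defensive
            raise NotAnFvError("alignment traceback failed")
    moves.reverse()
    return moves


def assign_kabat_numbering(sequence: str, chain_type: str, source_id: str = "") -> NumberedChain:
    """Number an Fv amino-acid sequence in the Kabat scheme.

    Raises :class:`NotAnFvError` when the best alignment leaves framework
    identity to the template below 50% (non-antibody input), and
    :class:`InputError` for illegal characters or lengths.
    """
    _check_chain_type(chain_type)
    seq = _validate_sequence(sequence)
    moves = _align_to_template(seq, chain_type)
    template = TEMPLATES[chain_type]

    residues: list[NumberedResidue] = []
    i = j = 0
    fr_match = fr_total = 0
    pending_code = 0
    for di, dj in moves:
        if di == 1 and dj == 1:
            number = j + 1
            region = region_of(chain_type, number)
            residues.append(NumberedResidue(seq[i], number, "", region))
            if region.startswith("FR"):
                fr_total += 1
                fr_match += seq[i] == template[j]
            pending_code = 0
            i += 1
            j += 1
        elif dj == 1:  # template column skipped
            pending_code = 0
            j += 1
        else:  # insertion after column j
            number = j  # 1-based number of the preceding column
            if pending_code >= len(string.ascii_uppercase):
                raise InputError(f"more than 26 insertions after position {number}")
            code = string.ascii_uppercase[pending_code]
            pending_code += 1
            residues.append(
                NumberedResidue(seq[i], number, code, region_of(chain_type, number))
            )
            i += 1

    if fr_total == 0 or fr_match / fr_total < FRAMEWORK_IDENTITY_FLOOR:
        raise NotAnFvError(
            "framework identity to the numbering template is below "
            f"{FRAMEWORK_IDENTITY_FLOOR:.0%}: not an Fv {chain_type} chain"
        )
    chain = NumberedChain(chain_type, tuple(residues), source_id)
    if chain.sequence != seq:
        raise InputError("numbering failed to cover the input sequence")  # pragma: no cover
    return chain


def annotate_regions(chain: NumberedChain) -> NumberedChain:
    """(Re-)label every residue with its Kabat region.

    The region of each residue depends only on its Kabat number, so this is a
    pure relabeling; it is idempotent and preserves the sequence.
    """
    residues = tuple(
        replace(r, region=region_of(chain.chain_type, r.kabat_number))
        for r in chain.residues
    )
    return replace(chain, residues=residues)


def numbering_table(chain: NumberedChain) -> list[dict[str, object]]:
    """Rows for the numbering TSV: seq_index, kabat_number, insertion_code, residue, region."""
    return [
        {
            "seq_index": idx,
            "kabat_number": r.kabat_number,
            "insertion_code": r.insertion_code,
            "residue": r.one_letter_code,
            "region": r.region,
        }
        for idx, r in enumerate(chain.residues)
    ]


def write_numbering_tsv(chain: NumberedChain, handle) -> None:
    cols = ("seq_index", "kabat_number", "insertion_code", "residue", "region")
    handle.write("\t".join(cols) + "\n")
    for row in numbering_table(chain):
        handle.write("\t".join(str(row[c]) for c in cols) + "\n")
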
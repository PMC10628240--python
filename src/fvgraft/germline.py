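"""Human germline acceptor selection for humanization.

A parental (murine) chain is compared position-by-position against a library
of numbered human germline V-gene frameworks.  Candidates are ranked by how
many upper-hydrophobic-core positions they preserve, then by overall
framework identity — the acceptor of choice is one that keeps the entire
platform of residues beneath the CDRs intact, so no core back-mutations are
needed.  CDR columns never enter the score: they will be replaced by the
donor loops anyway.

FR4 comes from a J segment, not the V gene, and is scored separately against
a small packaged J-segment set rather than folded into the V ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .errors import ChainTypeMismatchError, InputError
from .kabat import NumberedChain, UpperCoreSet, assign_kabat_numbering

HEAVY_LIBRARY = "germline_heavy_synthetic.fasta"
LIGHT_LIBRARY = "germline_light_synthetic.fasta"
J_LIBRARY = "j_segments_synthetic.fasta"


@dataclass(frozen=True)
class GermlineRecord:
    """A numbered germline acceptor candidate (e.g. IGHV1-46*01)."""

    allele_name: str
    chain_type: str
    numbered_sequence: NumberedChain

    def __post_init__(self) -> None:
        if self.chain_type != self.numbered_sequence.chain_type:
            raise ChainTypeMismatchError(
                f"{self.allele_name}: record chain type {self.chain_type} does not "
                f"match its numbering ({self.numbered_sequence.chain_type})"
            )


@dataclass(frozen=True)
class PositionComparison:
    kabat_key: str
    parent_residue: str
    germline_residue: str
    is_upper_core: bool
    identical: bool


@dataclass(frozen=True)
class GermlineMatch:
    allele_name: str
    framework_identity: float
    upper_core_preserved: int
    upper_core_total: int
    per_position_report: tuple[PositionComparison, ...]
    fully_preserving: bool = False
    prior: float = 0.0


def load_library(path_or_name: str | Path, chain_type: str) -> list[GermlineRecord]:
    """Load a germline library from a FASTA file (allele names in headers).

    Bare names of the packaged synthetic fixture libraries are also accepted.
    """
    path = Path(path_or_name)
    if not path.exists():
        pkg_file = resources.files("fvgraft.data") / str(path_or_name)
        if pkg_file.is_file():
            path = Path(str(pkg_file))
        else:
            raise InputError(f"germline library not found: {path_or_name}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        chain = assign_kabat_numbering(str(rec.seq), chain_type, source_id=rec.id)
        records.append(GermlineRecord(rec.id, chain_type, chain))
    if not records:
        raise InputError(f"no sequences in germline library {path}")
    return records


def default_library(chain_type: str) -> list[GermlineRecord]:
    name = HEAVY_LIBRARY if chain_type == "heavy" else LIGHT_LIBRARY
    return load_library(name, chain_type)


def score_germline(
    parent: NumberedChain, germline: GermlineRecord, core: UpperCoreSet
) -> GermlineMatch:
    """Per-position framework comparison of a parent chain to one candidate.

    Identity is matches / compared over framework positions present in both
    chains; upper-core tallies count only core positions the parent actually
    occupies.
    """
    if parent.chain_type != germline.chain_type:
        raise ChainTypeMismatchError(
            f"parent is {parent.chain_type} but {germline.allele_name} is {germline.chain_type}"
        )
    gmap = germline.numbered_sequence.position_map
    report: list[PositionComparison] = []
    matches = compared = 0
    core_kept = core_total = 0
    for res in parent.residues:
        if not res.region.startswith("FR"):
            continue
        other = gmap.get(res.key)
        if other is None:
            continue
        same = res.one_letter_code == other.one_letter_code
        in_core = res.insertion_code == "" and res.kabat_number in core
        report.append(
            PositionComparison(res.key, res.one_letter_code, other.one_letter_code, in_core, same)
        )
        compared += 1
        matches += same
        if in_core:
            core_total += 1
            core_kept += same
    if compared == 0:
        raise InputError(f"no shared framework positions with {germline.allele_name}")
    return GermlineMatch(
        allele_name=germline.allele_name,
        framework_identity=matches / compared,
        upper_core_preserved=core_kept,
        upper_core_total=core_total,
        per_position_report=tuple(report),
        fully_preserving=core_kept == core_total,
    )


def select_germline(
    parent: NumberedChain,
    library: Iterable[GermlineRecord],
    core: UpperCoreSet,
    priors: Mapping[str, float] | None = None,
) -> list[GermlineMatch]:
    """Rank germline candidates as humanization acceptors.

    Order: upper-core positions preserved (desc), framework identity (desc),
    optional per-allele prior (desc; default 0 — a hook for non-sequence
    considerations such as expression track record), allele name (asc).
    """
    library = list(library)
    if not library:
        raise InputError("empty germline library")
    priors = priors or {}
    matches = []
    for record in library:
        m = score_germline(parent, record, core)
        prior = float(priors.get(record.allele_name, 0.0))
        matches.append(
            GermlineMatch(
                m.allele_name, m.framework_identity, m.upper_core_preserved,
                m.upper_core_total, m.per_position_report, m.fully_preserving, prior,
            )
        )
    matches.sort(
        key=lambda m: (-m.upper_core_preserved, -m.framework_identity, -m.prior, m.allele_name)
    )
    return matches


def score_fr4(parent: NumberedChain, j_library: str | Path = J_LIBRARY) -> list[tuple[str, float]]:
    """Identity of the parent FR4 against each packaged J-segment framework.

    Reported separately from V-gene ranking; returns (name, identity) sorted
    by identity desc then name.  Empty when the parent FR4 is absent.
    """
    fr4 = {r.key: r.one_letter_code for r in parent.residues if r.region == "FR4"}
    if not fr4:
        return []
    path = Path(j_library)
    if not path.exists():
        path = Path(str(resources.files("fvgraft.data") / str(j_library)))
    prefix = "J_HEAVY_" if parent.chain_type == "heavy" else "J_LIGHT_"
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id.startswith(prefix):
            continue
        # J fixture headers carry the Kabat number of their first FR4 column.
        start = int(rec.description.split("start=")[1].split()[0])
        jmap = {str(start + i): aa for i, aa in enumerate(str(rec.seq))}
        shared = [k for k in fr4 if k in jmap]
        if not shared:
            continue
        ident = sum(fr4[k] == jmap[k] for k in shared) / len(shared)
        out.append((rec.id, ident))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def write_ranking_tsv(matches: Iterable[GermlineMatch], handle) -> None:
    handle.write("allele\tframework_identity\tcore_preserved\tcore_total\tfully_preserving\n")
    for m in matches:
        handle.write(
            f"{m.allele_name}\t{m.framework_identity:.4f}\t{m.upper_core_preserved}\t"
            f"{m.upper_core_total}\t{str(m.fully_preserving).lower()}\n"
        )


def write_position_report_tsv(match: GermlineMatch, handle) -> None:
    handle.write("kabat_position\tparent\tgermline\tis_upper_core\tidentical\n")
    for row in match.per_position_report:
        handle.write(
            f"{row.kabat_key}\t{row.parent_residue}\t{row.germline_residue}\t"
            f"{str(row.is_upper_core).lower()}\t{str(row.identical).lower()}\n"
        )
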
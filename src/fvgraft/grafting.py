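"""CDR grafting and framework back-mutation.

``graft_cdrs`` transplants the donor (murine) CDR loops wholesale onto the
acceptor (human germline) framework — the preliminary humanized chain, before
any reversion.  ``apply_back_mutations`` then restores selected framework
positions to the donor residue.  Every residue of the product carries a
provenance tag (donor_CDR / acceptor_FR / back_mutated) so downstream reports
can show exactly where each amino acid came from.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

from .errors import ChainTypeMismatchError, InputError
from .germline import GermlineRecord
from .kabat import NumberedChain, NumberedResidue, annotate_regions

DONOR_CDR = "donor_CDR"
ACCEPTOR_FR = "acceptor_FR"
BACK_MUTATED = "back_mutated"


@dataclass(frozen=True)
class BackMutation:
    """Restore ``human_residue`` at ``kabat_key`` to the donor's ``donor_residue``."""

    kabat_key: str
    human_residue: str
    donor_residue: str


@dataclass(frozen=True)
class GraftPlan:
    donor: NumberedChain
    acceptor: GermlineRecord
    back_mutations: tuple[BackMutation, ...] = ()

    def __post_init__(self) -> None:
        keys = [bm.kabat_key for bm in self.back_mutations]
        if len(keys) != len(set(keys)):
            raise InputError("duplicate back-mutation positions in plan")
        dmap = self.donor.position_map
        for bm in self.back_mutations:
            res = dmap.get(bm.kabat_key)
            if res is not None and res.one_letter_code != bm.donor_residue:
                raise InputError(
                    f"back-mutation at {bm.kabat_key} restores {bm.donor_residue!r} "
                    f"but the donor carries {res.one_letter_code!r}"
                )


@dataclass(frozen=True)
class HumanizedChain:
    chain: NumberedChain
    provenance: tuple[str, ...]  # one tag per residue, aligned with chain.residues
    warnings: tuple[str, ...] = ()

    @property
    def sequence(self) -> str:
        return self.chain.sequence

    def provenance_of(self, kabat_key: str) -> str | None:
        for res, tag in zip(self.chain.residues, self.provenance):
            if res.key == kabat_key:
                return tag
        return None


def graft_cdrs(donor: NumberedChain, acceptor: GermlineRecord) -> HumanizedChain:
    """Transplant donor CDRs onto the acceptor framework.

    CDR positions (with any donor insertion codes) come from the donor;
    framework positions come from the acceptor.  Acceptor CDR content and
    length are discarded.  Framework positions present in the donor but
    missing from the acceptor are filled from the donor with a warning.
    """
    if donor.chain_type != acceptor.chain_type:
        raise ChainTypeMismatchError(
            f"donor is {donor.chain_type}, acceptor {acceptor.allele_name} is {acceptor.chain_type}"
        )
    acc = acceptor.numbered_sequence
    residues: list[NumberedResidue] = []
    tags: list[str] = []
    warnings: list[str] = []

    merged: dict[tuple[int, str], tuple[NumberedResidue, str]] = {}
    for res in acc.residues:
        if res.region.startswith("FR"):
            merged[res.sort_key] = (res, ACCEPTOR_FR)
    for res in donor.residues:
        if res.region.startswith("CDR"):
            merged[res.sort_key] = (res, DONOR_CDR)
        elif res.sort_key not in merged:
            merged[res.sort_key] = (res, ACCEPTOR_FR)
            warnings.append(
                f"framework position {res.key} missing from acceptor "
                f"{acceptor.allele_name}; filled from donor"
            )
    for key in sorted(merged):
        res, tag = merged[key]
        residues.append(res)
        tags.append(tag)

    chain = annotate_regions(
        NumberedChain(donor.chain_type, tuple(residues), source_id=f"{donor.source_id}|{acceptor.allele_name}")
    )
    return HumanizedChain(chain, tuple(tags), tuple(warnings))


def apply_back_mutations(grafted: HumanizedChain, plan: GraftPlan) -> HumanizedChain:
    """Apply the plan's reversions; exactly those positions change."""
    pmap = grafted.chain.position_map
    for bm in plan.back_mutations:
        res = pmap.get(bm.kabat_key)
        if res is None:
            raise InputError(f"back-mutation position {bm.kabat_key} absent from grafted chain")
        if res.region.startswith("CDR"):
            raise InputError(
                f"back-mutation at {bm.kabat_key} falls inside {res.region}; "
                "CDR residues are already donor-derived"
            )
    wanted = {bm.kabat_key: bm for bm in plan.back_mutations}
    residues: list[NumberedResidue] = []
    tags: list[str] = []
    for res, tag in zip(grafted.chain.residues, grafted.provenance):
        bm = wanted.get(res.key)
        if bm is not None:
            residues.append(replace(res, one_letter_code=bm.donor_residue))
            tags.append(BACK_MUTATED)
        else:
            residues.append(res)
            tags.append(tag)
    chain = replace(grafted.chain, residues=tuple(residues))
    return HumanizedChain(chain, tuple(tags), grafted.warnings)


def plan_from_recommendations(
    donor: NumberedChain, acceptor: GermlineRecord, keys: Iterable[str]
) -> GraftPlan:
    """Build a GraftPlan restoring the donor residue at each given position."""
    dmap = donor.position_map
    amap = acceptor.numbered_sequence.position_map
    bms = []
    for key in keys:
        d, a = dmap.get(key), amap.get(key)
        if d is None or a is None:
            raise InputError(f"position {key} absent from donor or acceptor")
        bms.append(BackMutation(key, a.one_letter_code, d.one_letter_code))
    return GraftPlan(donor, acceptor, tuple(bms))


def write_provenance_tsv(humanized: HumanizedChain, handle) -> None:
    handle.write("kabat_position\tresidue\tregion\torigin\n")
    for res, tag in zip(humanized.chain.residues, humanized.provenance):
        handle.write(f"{res.key}\t{res.one_letter_code}\t{res.region}\t{tag}\n")
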
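"""Bundled worked example: humanizing a murine anti-PD-L1 Fv.

The sequences and the transcribed framework-CDR contact summary are
synthetic stand-ins (see ``data/example_case_synthetic.yaml``): they
reproduce the decision structure of a real humanization campaign — an
IGHV1-46*01-style acceptor that preserves 7 of 12 heavy upper-core
positions, an IGKV1-5*01-style acceptor that preserves all 5 light ones,
and ten heavy / four light differing framework positions feeding the
back-mutation recommender — without claiming to be measured data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .kabat import NumberedChain, assign_kabat_numbering
from .structure import SupportMap, support_map_from_rows

EXAMPLE_FILE = "example_case_synthetic.yaml"


@dataclass(frozen=True)
class ExampleChainCase:
    donor: NumberedChain
    acceptor_allele: str
    support: SupportMap


def load_example_case() -> dict[str, ExampleChainCase]:
    """The packaged murine anti-PD-L1 humanization case, keyed by chain type."""
    text = (resources.files("fvgraft.data") / EXAMPLE_FILE).read_text()
    raw = yaml.safe_load(text)
    out: dict[str, ExampleChainCase] = {}
    for chain_type in ("heavy", "light"):
        entry = raw[chain_type]
        donor = assign_kabat_numbering(
            entry["donor_sequence"], chain_type, source_id=entry["donor_id"]
        )
        out[chain_type] = ExampleChainCase(
            donor=donor,
            acceptor_allele=entry["acceptor"],
            support=support_map_from_rows(entry["support"]),
        )
    return out
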
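"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's production code paths:
PDB text is parsed by fixed-column slicing, distances are computed by naive
all-pairs loops, and Kabat insertion placement is found by exhaustive
enumeration, so that agreement with the package is meaningful.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict

from fvgraft.kabat import CDR_BOUNDS, INSERTION_SITES, TEMPLATES, region_of


def parse_pdb_text(text: str):
    """chain id -> list of residues [(resname, [(atom, element, x, y, z)])]."""
    chains: dict[str, dict[int, tuple[str, list]]] = defaultdict(dict)
    for line in text.splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21]
        resseq = int(line[22:26])
        x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
        element = line[76:78].strip() or name[0]
        entry = chains[chain].setdefault(resseq, (resname, []))
        entry[1].append((name, element, x, y, z))
    return {
        cid: [chains[cid][k] for k in sorted(chains[cid])] for cid in sorted(chains)
    }


def min_residue_distance(atoms_a, atoms_b) -> float:
    best = math.inf
    for _, _, xa, ya, za in atoms_a:
        for _, _, xb, yb, zb in atoms_b:
            d = math.sqrt((xa - xb) ** 2 + (ya - yb) ** 2 + (za - zb) ** 2)
            best = min(best, d)
    return best


def brute_force_cross_pairs(res_a, res_b, cutoff: float):
    """Indices (i, j) of residue pairs within cutoff, by naive all-pairs."""
    out = []
    for i, (_, atoms_a) in enumerate(res_a):
        for j, (_, atoms_b) in enumerate(res_b):
            if min_residue_distance(atoms_a, atoms_b) <= cutoff:
                out.append((i, j))
    return out


def brute_force_numbering(sequence: str, chain_type: str):
    """Exhaustive insertion-placement oracle for Kabat numbering.

    Tries every distribution of the length surplus over the canonical
    insertion sites and keeps the placement with the highest framework
    identity to the template (first in site-order on ties).  Only supports
    insertion-only divergence (sequence at least as long as the template).
    """
    template = TEMPLATES[chain_type]
    sites = INSERTION_SITES[chain_type]
    surplus = len(sequence) - len(template)
    assert surplus >= 0, "oracle only handles insertion-only cases"

    best = None
    for counts in _compositions(surplus, len(sites)):
        keys = []
        extra = dict(zip(sites, counts))
        for j in range(1, len(template) + 1):
            keys.append((j, ""))
            for k in range(extra.get(j, 0)):
                keys.append((j, chr(ord("A") + k)))
        identity = matched = 0
        for (num, icode), aa in zip(keys, sequence):
            if icode == "" and not region_of(chain_type, num).startswith("CDR"):
                matched += 1
                identity += aa == template[num - 1]
        score = identity / matched
        if best is None or score > best[0]:
            best = (score, keys)
    return [
        (f"{num}{icode}", aa) for (num, icode), aa in zip(best[1], sequence)
    ]


def _compositions(total: int, bins: int):
    if bins == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, bins - 1):
            yield (first,) + rest


def cdr_keys(chain_type: str):
    out = set()
    for lo, hi in CDR_BOUNDS[chain_type].values():
        out.update(range(lo, hi + 1))
    return out
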
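"""Minimal independent PDB parsing and distance measurement.

Used by the acceptance script to re-measure generated structures without
touching the package's own readers: fixed-column text slicing and naive
all-pairs distances only.
"""

from __future__ import annotations

import math
from collections import defaultdict


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
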
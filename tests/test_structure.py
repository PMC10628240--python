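"""Structure IO, contact detection, interaction classification, interface mapping."""

import numpy as np
import pytest

from fvgraft import synthetic
from fvgraft.errors import InputError, MappingError
from fvgraft.kabat import assign_kabat_numbering
from fvgraft.structure import (
    HYDROGEN_BOND,
    HYDROPHOBIC,
    NONE,
    PROXIMAL,
    Atom,
    Residue,
    classify_interaction,
    find_fr_cdr_contacts,
    interface_residues,
    map_structure_to_kabat,
    read_structure,
)

from oracles import brute_force_cross_pairs, min_residue_distance, parse_pdb_text


@pytest.fixture(scope="module")
def toy_fv(tmp_path_factory):
    seq, chain = synthetic.make_fv_sequence(synthetic.FvSpec("heavy"), seed=5)
    plants = [
        synthetic.PlantedContactSpec("66", "63", 3.0, synthetic.NO_PAIR),
        synthetic.PlantedContactSpec("71", "52", 3.6, synthetic.CC_PAIR),
        synthetic.PlantedContactSpec("94", "100", 4.1, synthetic.GENERIC),
        synthetic.PlantedContactSpec("38", "95", 4.3, synthetic.GENERIC),
    ]
    text = synthetic.make_fv_structure(chain, plants, seed=5)
    path = tmp_path_factory.mktemp("fv") / "fv.pdb"
    path.write_text(text)
    return path, text, chain


def test_reader_round_trips_writer_coordinates(toy_fv):
    path, text, chain = toy_fv
    model = read_structure(path)
    parsed = parse_pdb_text(text)["A"]
    residues = model.chain("A")
    assert len(residues) == len(parsed) == len(chain)
    for res, (resname, atoms) in zip(residues, parsed):
        assert res.name == resname
        got = {a.name: a.xyz for a in res.atoms}
        for name, _el, x, y, z in atoms:
            assert got[name] == pytest.approx((x, y, z), abs=1e-3)


def test_waters_and_hydrogens_dropped(tmp_path):
    pdb = "\n".join([
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N",
        "ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C",
        "ATOM      3  H   ALA A   1       1.800   1.000   0.000  1.00  0.00           H",
        "HETATM    4  O   HOH A   2       9.000   9.000   9.000  1.00  0.00           O",
        "END",
    ]) + "\n"
    path = tmp_path / "w.pdb"
    path.write_text(pdb)
    model = read_structure(path)
    residues = model.chain("A")
    assert [r.name for r in residues] == ["ALA"]
    assert sorted(a.name for a in residues[0].atoms) == ["CA", "N"]


def test_altloc_collapses_to_single_conformer(tmp_path):
    pdb = "\n".join([
        "ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N",
        "ATOM      2  CA ASER A   1       1.500   0.000   0.000  0.50  0.00           C",
        "ATOM      3  CA BSER A   1       1.600   0.100   0.000  0.50  0.00           C",
        "ATOM      4  OG  SER A   1       2.500   1.000   0.000  1.00  0.00           O",
        "END",
    ]) + "\n"
    path = tmp_path / "alt.pdb"
    path.write_text(pdb)
    model = read_structure(path)
    atoms = model.chain("A")[0].atoms
    # text-scan oracle: one atom per distinct name
    names = {line[12:16].strip() for line in pdb.splitlines() if line.startswith("ATOM")}
    assert len(atoms) == len(names)
    assert sum(a.name == "CA" for a in atoms) == 1


def test_structure_maps_onto_numbering_exactly_and_truncated(toy_fv):
    path, _text, chain = toy_fv
    model = read_structure(path)
    mapping = map_structure_to_kabat(model, chain, "A")
    residues = model.chain("A")
    assert len(mapping) == len(chain)
    assert [mapping[r.author_key] for r in residues] == [r.key for r in chain.residues]
    # truncated structure: drop 2 N-terminal residues -> mapping starts at 3
    truncated_keys = [r.author_key for r in residues[2:]]
    assert mapping[truncated_keys[0]] == "3"


def test_mapping_is_injective_under_truncation_fuzz(toy_fv, tmp_path):
    path, text, chain = toy_fv
    lines = text.splitlines()
    rng = np.random.default_rng(3)
    for _ in range(10):
        drop_head = int(rng.integers(0, 6))
        drop_tail = int(rng.integers(0, 6))
        keep = set(range(1 + drop_head, len(chain) + 1 - drop_tail))
        body = [
            ln for ln in lines
            if not ln.startswith("ATOM") or int(ln[22:26]) in keep
        ]
        p = tmp_path / "trunc.pdb"
        p.write_text("\n".join(body) + "\n")
        model = read_structure(p)
        mapping = map_structure_to_kabat(model, chain, "A")
        assert len(set(mapping.values())) == len(mapping)  # injective


def test_low_identity_mapping_rejected(toy_fv):
    """A heavy-chain structure cannot be mapped onto an unrelated light chain."""
    path, _, _chain = toy_fv
    model = read_structure(path)
    unrelated = assign_kabat_numbering(
        synthetic.make_fv_sequence(synthetic.FvSpec("light"), seed=1)[0], "light"
    )
    with pytest.raises(MappingError):
        map_structure_to_kabat(model, unrelated, "A")


def test_contact_window_is_inclusive_at_cutoff(toy_fv):
    path, _, chain = toy_fv
    model = read_structure(path)
    mapping = map_structure_to_kabat(model, chain, "A")
    support = find_fr_cdr_contacts(model, mapping, chain, "A", cutoff=4.2)
    contacts = {
        (c.fr_position, c.cdr_position): c
        for pos in support.positions.values()
        for c in pos.contacts
    }
    assert set(contacts) == {("66", "63"), ("71", "52"), ("94", "100")}
    assert contacts[("66", "63")].min_distance == pytest.approx(3.0, abs=0.01)
    assert contacts[("66", "63")].interaction_class == HYDROGEN_BOND
    assert contacts[("71", "52")].interaction_class == HYDROPHOBIC
    assert contacts[("94", "100")].interaction_class == PROXIMAL
    # the 4.3 Å plant is outside the inclusive 4.2 Å window
    assert support.support("38").contact_count == 0
    # every mapped framework position is recorded, even without contacts
    fr_keys = {r.key for r in chain.residues if r.region.startswith("FR")}
    assert set(support.positions) == fr_keys


def _mk_residue(name, atoms):
    return Residue("A", 1, "", name, tuple(Atom(n, e, xyz) for n, e, xyz in atoms))


def test_classification_rules():
    backbone_o = _mk_residue("SER", [("O", "O", (0.0, 0.0, 0.0)), ("C", "C", (0.0, -1.4, 0.0))])
    amide_n = _mk_residue("GLN", [("N", "N", (0.0, 3.0, 0.0)), ("CA", "C", (0.0, 4.5, 0.0))])
    assert classify_interaction(backbone_o, amide_n) == HYDROGEN_BOND

    cb = _mk_residue("LEU", [("CB", "C", (0.0, 0.0, 0.0))])
    cg = _mk_residue("VAL", [("CG", "C", (0.0, 3.6, 0.0))])
    assert classify_interaction(cb, cg) == HYDROPHOBIC

    near = _mk_residue("ALA", [("CA", "C", (0.0, 0.0, 0.0)), ("N", "N", (0.0, -1.4, 0.0))])
    mid = _mk_residue("GLY", [("CA", "C", (0.0, 4.1, 0.0))])
    assert classify_interaction(near, mid) == PROXIMAL

    far = _mk_residue("GLY", [("CA", "C", (0.0, 12.0, 0.0))])
    assert classify_interaction(near, far) == NONE
    between = _mk_residue("GLY", [("CA", "C", (0.0, 7.0, 0.0))])
    assert classify_interaction(near, between) == NONE  # undefined 4.2-10 Å band


def test_hydrogen_bond_outranks_hydrophobic_at_boundary():
    """A 3.3 Å N/O pair classifies as hydrogen bond even though 3.3 Å also
    opens the carbon-carbon window."""
    a = _mk_residue("SER", [("O", "O", (0.0, 0.0, 0.0)), ("CB", "C", (0.0, -0.1, 0.0))])
    b = _mk_residue("THR", [("N", "N", (0.0, 3.3, 0.0)), ("CB", "C", (0.0, 3.4, 0.0))])
    assert classify_interaction(a, b) == HYDROGEN_BOND


def test_classification_invariant_under_rigid_motion():
    rng = np.random.default_rng(17)
    a = _mk_residue("SER", [("O", "O", (0.0, 0.0, 0.0)), ("C", "C", (0.5, -1.3, 0.2))])
    b = _mk_residue("GLN", [("N", "N", (0.0, 3.0, 0.0)), ("CA", "C", (0.3, 4.4, -0.2))])
    base = classify_interaction(a, b)
    for _ in range(5):
        theta, phi = rng.uniform(0, 2 * np.pi, size=2)
        rz = np.array([
            [np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]
        ])
        rx = np.array([
            [1, 0, 0], [0, np.cos(phi), -np.sin(phi)], [0, np.sin(phi), np.cos(phi)]
        ])
        rot = rz @ rx
        shift = rng.uniform(-50, 50, size=3)

        def move(res):
            return Residue(
                res.chain_id, res.seqid, res.icode, res.name,
                tuple(
                    Atom(at.name, at.element, tuple(rot @ np.array(at.xyz) + shift))
                    for at in res.atoms
                ),
            )

        assert classify_interaction(move(a), move(b)) == base


def test_interface_residues_symmetry_and_planted_pairs(tmp_path):
    spec = synthetic.PlantedInterfaceSpec(
        pairs=(("R", "D", True), ("S", "L", True), ("L", "L", True),
               ("K", "E", True), ("N", "Q", True), ("A", "G", False)),
        extra_a="AG", extra_b="KD",
    )
    text, _counts = synthetic.make_complex(spec, seed=2)
    path = tmp_path / "cx.pdb"
    path.write_text(text)
    model = read_structure(path)
    pairs = interface_residues(model, ["A"], ["B"], cutoff=5.5)
    assert len(pairs) == 5
    swapped = interface_residues(model, ["B"], ["A"], cutoff=5.5)
    assert {(a.seqid, b.seqid) for a, b, _ in pairs} == {
        (b.seqid, a.seqid) for a, b, _ in swapped
    }
    # brute-force oracle over independently parsed text
    parsed = parse_pdb_text(text)
    oracle = brute_force_cross_pairs(parsed["A"], parsed["B"], 5.5)
    assert {(a.seqid - 1, b.seqid - 1) for a, b, _ in pairs} == set(oracle)


def test_separated_chains_have_empty_interface(tmp_path):
    spec = synthetic.PlantedInterfaceSpec(pairs=(("A", "G", False), ("L", "V", False)))
    text, _ = synthetic.make_complex(spec, seed=0)
    path = tmp_path / "far.pdb"
    path.write_text(text)
    model = read_structure(path)
    assert interface_residues(model, ["A"], ["B"], cutoff=5.5) == []
    with pytest.raises(InputError):
        interface_residues(model, ["A"], ["A"], cutoff=5.5)


def test_contact_detection_equals_bruteforce_on_fuzzed_structures():
    """Production contact detection agrees with naive all-pairs measurement
    on randomized planted geometries."""
    rng = np.random.default_rng(23)
    for trial in range(15):
        seed = int(rng.integers(0, 10_000))
        seq, chain = synthetic.make_fv_sequence(synthetic.FvSpec("heavy"), seed)
        fr = [r.key for r in chain.residues if r.region.startswith("FR")]
        cdr = [r.key for r in chain.residues if r.region.startswith("CDR")]
        picks = rng.choice(len(fr), size=3, replace=False)
        plants = [
            synthetic.PlantedContactSpec(
                fr[int(f)], cdr[int(rng.integers(len(cdr)))],
                float(rng.uniform(2.2, 5.0)), synthetic.GENERIC,
            )
            for f in picks
        ]
        # distinct CDR partners required; retry collisions by shifting
        seen = set()
        uniq = []
        for p in plants:
            if p.cdr_kabat_position not in seen:
                uniq.append(p)
                seen.add(p.cdr_kabat_position)
        text = synthetic.make_fv_structure(chain, uniq, seed)
        parsed = parse_pdb_text(text)["A"]
        keys = [r.key for r in chain.residues]
        regions = {r.key: r.region for r in chain.residues}
        expected = set()
        for i, ki in enumerate(keys):
            for j, kj in enumerate(keys):
                if regions[ki].startswith("FR") and regions[kj].startswith("CDR"):
                    if min_residue_distance(parsed[i][1], parsed[j][1]) <= 4.2:
                        expected.add((ki, kj))
        import os
        import tempfile
        with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as fh:
            fh.write(text)
            tmp = fh.name
        try:
            model = read_structure(tmp)
        finally:
            os.unlink(tmp)
        mapping = map_structure_to_kabat(model, chain, "A")
        support = find_fr_cdr_contacts(model, mapping, chain, "A")
        got = {
            (c.fr_position, c.cdr_position)
            for pos in support.positions.values()
            for c in pos.contacts
        }
        assert got == expected
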
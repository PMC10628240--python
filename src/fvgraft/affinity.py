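"""Contact-classified interface profiling and binding-affinity prediction.

Implements the linear interfacial-contacts + non-interacting-surface (NIS)
binding-energy model for a two-sided protein complex:

    dG = c1*IC(charged-charged) + c2*IC(charged-apolar) + c3*IC(polar-polar)
       + c4*IC(polar-apolar) + c5*%NIS(apolar) + c6*%NIS(charged) + c0

where an interfacial contact (IC) is any cross-side residue pair with a
heavy-atom distance within 5.5 Å, bucketed by the polarity classes of its two
residues, and NIS percentages are computed over solvent-exposed residues
(relative SASA >= 5%) that are not part of any interfacial pair.  Kd follows
from dG at the stated temperature via dG = RT ln Kd.

SASA is deterministic Shrake-Rupley: 960 golden-spiral sphere points per
heavy atom, probe 1.4 Å, fixed van-der-Waals radii (C 1.70, N 1.55, O 1.52,
S 1.80, default 1.80 Å).  Relative SASA is taken against per-residue
reference maxima computed from the same isolated residue geometry the
synthetic generator emits, so an isolated residue sits at ~1.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import FvGraftError, InputError
from .structure import Residue, StructureModel, interface_residues

GAS_CONSTANT_KCAL = 1.9872e-3  # kcal / (mol K)
DEFAULT_TEMPERATURE = 298.15   # K (25 C)

IC_CUTOFF = 5.5                # Å
NIS_RELATIVE_SASA_THRESHOLD = 0.05
SASA_PROBE_RADIUS = 1.4        # Å
SASA_N_POINTS = 960
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
VDW_DEFAULT = 1.80
RELATIVE_SASA_CLIP = 1.2

CHARGED, POLAR, APOLAR = "charged", "polar", "apolar"
DEFAULT_RESIDUE_CLASSES: dict[str, str] = {
    **{aa: CHARGED for aa in "DEKR"},
    **{aa: POLAR for aa in "CHNQSTWY"},
    **{aa: APOLAR for aa in "AFGILMPV"},
}

IC_KEYS = (
    "charged-charged", "charged-polar", "charged-apolar",
    "polar-polar", "polar-apolar", "apolar-apolar",
)

# Linear-model coefficients (kcal/mol per contact or per %NIS) keyed by term.
DEFAULT_DG_COEFFICIENTS: dict[str, float] = {
    "ic_charged_charged": -0.09459,
    "ic_charged_apolar": -0.10007,
    "ic_polar_polar": 0.19577,
    "ic_polar_apolar": -0.22671,
    "nis_apolar_pct": 0.18681,
    "nis_charged_pct": 0.13810,
    "intercept": -15.9433,
}


@dataclass(frozen=True)
class SasaResult:
    absolute: dict[tuple[str, str], float]  # (chain id, author key) -> Å²
    relative: dict[tuple[str, str], float]  # same keys, clipped to [0, 1.2]


@dataclass(frozen=True)
class InterfaceProfile:
    ic_counts: dict[str, int]
    nis_apolar_pct: float
    nis_charged_pct: float
    delta_g: float  # kcal/mol
    kd: float       # molar
    temperature: float = DEFAULT_TEMPERATURE


def residue_class(residue_one_letter: str, classes: Mapping[str, str] | None = None) -> str:
    classes = classes or DEFAULT_RESIDUE_CLASSES
    try:
        return classes[residue_one_letter]
    except KeyError:
        raise InputError(f"no polarity class for residue {residue_one_letter!r}")


def _pair_key(class_a: str, class_b: str) -> str:
    order = (CHARGED, POLAR, APOLAR)
    a, b = sorted((class_a, class_b), key=order.index)
    return f"{a}-{b}"


def count_interfacial_contacts(
    model: StructureModel,
    side_a: Sequence[str],
    side_b: Sequence[str],
    classes: Mapping[str, str] | None = None,
    cutoff: float = IC_CUTOFF,
) -> dict[str, int]:
    """Bucket every in-range cross-side residue pair by polarity class pair."""
    counts = {k: 0 for k in IC_KEYS}
    for ra, rb, _dist in interface_residues(model, side_a, side_b, cutoff):
        key = _pair_key(residue_class(ra.one_letter, classes), residue_class(rb.one_letter, classes))
        counts[key] += 1
    return counts


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


_UNIT_SPHERE = _sphere_points(SASA_N_POINTS)


def _atom_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), VDW_DEFAULT)


def compute_absolute_sasa(residues: Sequence[Residue]) -> dict[int, float]:
    """Shrake-Rupley accessible surface per residue (indices into input)."""
    atoms = [(i, a) for i, r in enumerate(residues) for a in r.atoms]
    if not atoms:
        raise InputError("no heavy atoms for SASA")
    coords = np.array([a.xyz for _, a in atoms])
    radii = np.array([_atom_radius(a.element) + SASA_PROBE_RADIUS for _, a in atoms])
    tree = cKDTree(coords)
    max_r = radii.max()
    out = {i: 0.0 for i in range(len(residues))}
    for idx, (res_i, _atom) in enumerate(atoms):
        r = radii[idx]
        pts = coords[idx] + r * _UNIT_SPHERE
        neighbors = [j for j in tree.query_ball_point(coords[idx], r + max_r) if j != idx]
        if neighbors:
            nb_coords = coords[neighbors]
            nb_radii = radii[neighbors]
            d2 = ((pts[:, None, :] - nb_coords[None, :, :]) ** 2).sum(axis=-1)
            buried = (d2 < (nb_radii**2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[res_i] += 4.0 * math.pi * r * r * frac
    return out


_REFERENCE_MAX_CACHE: dict[str, float] = {}


def reference_max_sasa(one_letter: str) -> float:
    """SASA of the isolated toy residue — the denominator for relative SASA."""
    if one_letter not in _REFERENCE_MAX_CACHE:
        from .synthetic import isolated_residue

        res = isolated_residue(one_letter)
        _REFERENCE_MAX_CACHE[one_letter] = compute_absolute_sasa([res])[0]
    return _REFERENCE_MAX_CACHE[one_letter]


def compute_sasa(model: StructureModel) -> SasaResult:
    """Per-residue absolute and relative SASA for a whole model."""
    residues = [r for cid in sorted(model.chains) for r in model.chains[cid]]
    absolute_by_idx = compute_absolute_sasa(residues)
    absolute: dict[tuple[str, str], float] = {}
    relative: dict[tuple[str, str], float] = {}
    for i, res in enumerate(residues):
        key = (res.chain_id, res.author_key)
        area = absolute_by_idx[i]
        absolute[key] = area
        ref = reference_max_sasa(res.one_letter) if res.one_letter != "X" else area or 1.0
        relative[key] = min(area / ref, RELATIVE_SASA_CLIP) if ref > 0 else 0.0
    return SasaResult(absolute, relative)


def nis_percentages(
    model: StructureModel,
    side_a: Sequence[str],
    side_b: Sequence[str],
    sasa: SasaResult,
    classes: Mapping[str, str] | None = None,
    interface: Sequence[tuple[Residue, Residue, float]] | None = None,
    cutoff: float = IC_CUTOFF,
    threshold: float = NIS_RELATIVE_SASA_THRESHOLD,
) -> tuple[float, float]:
    """Apolar and charged percentages of the non-interacting surface.

    NIS residues are those of the whole complex with relative SASA >= the
    threshold that belong to no interfacial pair.  Raises when the complex
    has no NIS residues at all (degenerate toy dimers).
    """
    if interface is None:
        interface = interface_residues(model, side_a, side_b, cutoff)
    interfacial = {(r.chain_id, r.author_key) for pair in interface for r in pair[:2]}
    tallies = {CHARGED: 0, POLAR: 0, APOLAR: 0}
    for cid in sorted(model.chains):
        for res in model.chains[cid]:
            key = (cid, res.author_key)
            if key in interfacial or sasa.relative.get(key, 0.0) < threshold:
                continue
            tallies[residue_class(res.one_letter, classes)] += 1
    total = sum(tallies.values())
    if total == 0:
        raise FvGraftError("no NIS residues: every exposed residue is interfacial")
    return 100.0 * tallies[APOLAR] / total, 100.0 * tallies[CHARGED] / total


def predict_dG(
    ic_counts: Mapping[str, int],
    nis_apolar_pct: float,
    nis_charged_pct: float,
    coefficients: Mapping[str, float] | None = None,
) -> float:
    """Linear binding-free-energy model (kcal/mol).

    Only four of the six IC buckets carry weight; charged-polar and
    apolar-apolar contacts are counted in the profile but do not enter dG.
    """
    c = dict(DEFAULT_DG_COEFFICIENTS if coefficients is None else coefficients)
    missing = set(DEFAULT_DG_COEFFICIENTS) - set(c)
    if missing:
        raise InputError(f"missing dG coefficients: {sorted(missing)}")
    if not (0.0 <= nis_apolar_pct <= 100.0 and 0.0 <= nis_charged_pct <= 100.0):
        raise InputError("NIS percentages must lie in [0, 100]")
    return (
        c["ic_charged_charged"] * ic_counts.get("charged-charged", 0)
        + c["ic_charged_apolar"] * ic_counts.get("charged-apolar", 0)
        + c["ic_polar_polar"] * ic_counts.get("polar-polar", 0)
        + c["ic_polar_apolar"] * ic_counts.get("polar-apolar", 0)
        + c["nis_apolar_pct"] * nis_apolar_pct
        + c["nis_charged_pct"] * nis_charged_pct
        + c["intercept"]
    )


def dG_to_Kd(delta_g: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Dissociation constant (M) from binding free energy: Kd = exp(dG / RT)."""
    if temperature <= 0:
        raise InputError("temperature must be positive (kelvin)")
    return math.exp(delta_g / (GAS_CONSTANT_KCAL * temperature))


def Kd_to_dG(kd: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse of :func:`dG_to_Kd`: dG = RT ln Kd (kcal/mol)."""
    if kd <= 0:
        raise InputError("Kd must be positive")
    return GAS_CONSTANT_KCAL * temperature * math.log(kd)


def fold_change(weaker: float, stronger: float) -> float:
    """Ratio of two measured constants (e.g. KD or EC50), weaker / stronger."""
    if weaker <= 0 or stronger <= 0:
        raise InputError("constants must be positive")
    return weaker / stronger


def profile_complex(
    model: StructureModel,
    side_a: Sequence[str],
    side_b: Sequence[str],
    classes: Mapping[str, str] | None = None,
    coefficients: Mapping[str, float] | None = None,
    cutoff: float = IC_CUTOFF,
    temperature: float = DEFAULT_TEMPERATURE,
) -> InterfaceProfile:
    """Full interface profile: IC counts, %NIS, dG and Kd for one complex."""
    interface = interface_residues(model, side_a, side_b, cutoff)
    counts = {k: 0 for k in IC_KEYS}
    for ra, rb, _ in interface:
        counts[_pair_key(residue_class(ra.one_letter, classes), residue_class(rb.one_letter, classes))] += 1
    sasa = compute_sasa(model)
    nis_apolar, nis_charged = nis_percentages(
        model, side_a, side_b, sasa, classes, interface=interface, cutoff=cutoff
    )
    dg = predict_dG(counts, nis_apolar, nis_charged, coefficients)
    return InterfaceProfile(counts, nis_apolar, nis_charged, dg, dG_to_Kd(dg, temperature), temperature)


PROFILE_COLUMNS = (
    "dG (kcal mol-1)", "Kd (M) at 25 °C",
    "ICs charged-charged", "ICs charged-polar", "ICs charged-apolar",
    "ICs polar-polar", "ICs polar-apolar", "ICs apolar-apolar",
)


def profile_row(profile: InterfaceProfile) -> dict[str, object]:
    return {
        "dG (kcal mol-1)": round(profile.delta_g, 1),
        "Kd (M) at 25 °C": f"{profile.kd:.1e}",
        "ICs charged-charged": profile.ic_counts["charged-charged"],
        "ICs charged-polar": profile.ic_counts["charged-polar"],
        "ICs charged-apolar": profile.ic_counts["charged-apolar"],
        "ICs polar-polar": profile.ic_counts["polar-polar"],
        "ICs polar-apolar": profile.ic_counts["polar-apolar"],
        "ICs apolar-apolar": profile.ic_counts["apolar-apolar"],
    }


def write_profile_tsv(profiles: Mapping[str, InterfaceProfile], handle) -> None:
    handle.write("complex\t" + "\t".join(PROFILE_COLUMNS) + "\n")
    for name, profile in profiles.items():
        row = profile_row(profile)
        handle.write(name + "\t" + "\t".join(str(row[c]) for c in PROFILE_COLUMNS) + "\n")


def format_profile_text(name: str, profile: InterfaceProfile) -> str:
    row = profile_row(profile)
    lines = [f"Interface profile: {name}"]
    lines += [f"  {col:<22s} {row[col]}" for col in PROFILE_COLUMNS]
    lines.append(f"  {'%NIS apolar':<22s} {profile.nis_apolar_pct:.1f}")
    lines.append(f"  {'%NIS charged':<22s} {profile.nis_charged_pct:.1f}")
    return "\n".join(lines)
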
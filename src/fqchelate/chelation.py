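"""Fluoroquinolone-metal chelate construction and binding-energy bookkeeping.

The modelled reaction is the 1:1 bidentate chelation of the N-protonated
fluoroquinolone cation by an octahedral metal hexahydrate, displacing two
of the six coordinated waters:

    FQH+  +  M(H2O)6^n+   ->   [FQH.M(H2O)4]^(n+1)+  +  2 H2O

with M in {Mg2+, Ca2+, Al3+}.  The drug binds through its 3-carboxyl and
4-keto oxygens, which with four retained waters completes the metal's
octahedron.  The number of displaced waters is a parameter so alternative
reference states can be tested.

Electronic structure is delegated: this module builds starting
geometries, emits engine-agnostic staged job descriptions (gas-phase
optimization and 310 K frequencies in a double-zeta polarized basis, then
a diffuse-augmented implicit-water single point), and combines parsed
energy ledgers into binding energies:

    dE_bind = [E(complex) + 2 E(water) - E(FQH+) - E(M(H2O)6)] * 627.5095
    dG_bind = same combination on (E_solvated_sp + G_thermal_corr)

with energies in hartree and results in kcal/mol
(1 hartree = 627.5095 kcal/mol).
"""

from __future__ import annotations

import itertools
import json
import math
import re
from collections import Counter
from dataclasses import asdict, dataclass
from typing import Callable, Iterable, Literal, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolTransforms

from .errors import (
    AdapterError,
    DomainError,
    GeometryError,
    LedgerError,
    StoichiometryError,
    SubstructureError,
)

__all__ = [
    "HARTREE_TO_KCAL",
    "METALS",
    "Species",
    "BindingReaction",
    "QMJobSpec",
    "TorsionRule",
    "hartree_to_kcal",
    "kcal_to_hartree",
    "protonated_fq_cation",
    "metal_hexahydrate",
    "water_species",
    "build_chelate_geometry",
    "enumerate_conformer_starts",
    "emit_qm_jobspec",
    "parse_qm_jobspec",
    "binding_energy",
    "make_binding_reaction",
    "donor_bond_lengths",
    "load_energy_ledger",
    "write_xyz",
    "read_xyz",
]

#: CODATA-style conversion used for all reported energies
HARTREE_TO_KCAL = 627.5095

#: metal -> (formal charge, initial metal-oxygen distance in Angstroms)
METALS = {"Al": (3, 1.9), "Mg": (2, 2.1), "Ca": (2, 2.4)}

#: minimum allowed non-bonded contact in a constructed geometry (Angstroms)
CLASH_DISTANCE = 0.7

Role = Literal["fq_cation", "metal_hexahydrate", "chelate_complex", "water"]
Stage = Literal["optimize", "frequencies", "single_point"]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def hartree_to_kcal(e_hartree: float) -> float:
    return e_hartree * HARTREE_TO_KCAL


def kcal_to_hartree(e_kcal: float) -> float:
    return e_kcal / HARTREE_TO_KCAL


def _parse_formula(formula: str) -> Counter:
    counts: Counter = Counter()
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise DomainError(f"malformed formula {formula!r}")
        pos = match.end()
        counts[match.group(1)] += int(match.group(2) or 1)
    if pos != len(formula):
        raise DomainError(f"malformed formula {formula!r}")
    return counts


Atom = tuple[str, float, float, float]


@dataclass
class Species:
    """One chemical species with optional geometry and energy components.

    Energy fields are in hartree: ``e_opt`` at the optimization level,
    ``g_thermal_corr`` the 310 K Gibbs thermal correction, ``e_pcm_sp``
    the implicit-water single point.  Charge bookkeeping per role is
    validated at construction.
    """

    label: str
    role: Role
    charge: int
    multiplicity: int = 1
    geometry: Optional[list[Atom]] = None
    formula: Optional[str] = None
    e_opt: Optional[float] = None
    g_thermal_corr: Optional[float] = None
    e_pcm_sp: Optional[float] = None
    donor_indices: Optional[tuple[int, int]] = None  # (carboxyl O, keto O)

    _ROLE_CHARGES = {
        "fq_cation": {1},
        "metal_hexahydrate": {2, 3},
        "water": {0},
    }

    def __post_init__(self) -> None:
        allowed = self._ROLE_CHARGES.get(self.role)
        if allowed is not None and self.charge not in allowed:
            raise DomainError(
                f"{self.label}: charge {self.charge} inconsistent with role {self.role}"
            )
        if self.multiplicity != 1:
            raise DomainError(
                f"{self.label}: only closed-shell singlets are modelled here"
            )

    def composition(self) -> Counter:
        """Element counts from the geometry, or the formula if no geometry."""
        if self.geometry is not None:
            return Counter(elem for elem, *_ in self.geometry)
        if self.formula:
            return _parse_formula(self.formula)
        raise LedgerError(f"{self.label}: no geometry or formula to count atoms from")

    def coords(self) -> np.ndarray:
        if self.geometry is None:
            raise LedgerError(f"{self.label}: no geometry present")
        return np.array([[x, y, z] for _, x, y, z in self.geometry], dtype=float)

    def energy(self, energy_field: Literal["e_pcm_sp", "gibbs"]) -> float:
        """The energy used in binding sums, in hartree."""
        if self.e_pcm_sp is None:
            raise LedgerError(f"{self.label}: missing e_pcm_sp")
        if energy_field == "e_pcm_sp":
            return self.e_pcm_sp
        if energy_field == "gibbs":
            if self.g_thermal_corr is None:
                raise LedgerError(f"{self.label}: missing g_thermal_corr")
            return self.e_pcm_sp + self.g_thermal_corr
        raise DomainError(f"unknown energy_field {energy_field!r}")


@dataclass
class BindingReaction:
    """A stoichiometric reaction with computed binding energies in kcal/mol."""

    reactants: list[tuple[Species, int]]
    products: list[tuple[Species, int]]
    delta_e_bind: float
    delta_g_bind: float

    def __post_init__(self) -> None:
        _check_balance(self.reactants, self.products)


def _side_totals(side: Iterable[tuple[Species, int]]) -> tuple[Counter, int]:
    atoms: Counter = Counter()
    charge = 0
    for species, count in side:
        if count <= 0:
            raise StoichiometryError(f"{species.label}: stoichiometric count must be > 0")
        comp = species.composition()
        for elem, n in comp.items():
            atoms[elem] += n * count
        charge += species.charge * count
    return atoms, charge


def _check_balance(
    reactants: Iterable[tuple[Species, int]], products: Iterable[tuple[Species, int]]
) -> None:
    r_atoms, r_charge = _side_totals(reactants)
    p_atoms, p_charge = _side_totals(products)
    residual = Counter(r_atoms)
    residual.subtract(p_atoms)
    residual = {elem: n for elem, n in residual.items() if n != 0}
    if residual or r_charge != p_charge:
        raise StoichiometryError(
            f"unbalanced reaction: element residual {residual}, "
            f"charge {r_charge} -> {p_charge}"
        )


# ---------------------------------------------------------------------------
# Geometry construction
# ---------------------------------------------------------------------------

# terminal amine nitrogen of the R7 ring system (piperazine NH or primary
# amine on a pyrrolidine), the site protonated under gastric pH
_BASIC_N_SMARTS = (
    "[NX3;H1;R;!$(N-c);!$(N-C=O)]",   # secondary ring amine (piperazine NH)
    "[NX3;H2;!R;$(N-[C;R])]",         # primary amine on a ring carbon
    "[NX3;H0;R;!$(N-c);!$(N-C=O)]",   # tertiary ring amine (N-methylpiperazine)
)

_CARBOXYL_SMARTS = Chem.MolFromSmarts("[CX3](=[OX1])[OX2H1]")
_KETO_SMARTS = Chem.MolFromSmarts("[OX1]=[#6;R]")


def _find_donor_oxygens(mol: Chem.Mol) -> tuple[int, int]:
    """Atom indices of (carboxyl carbonyl O, ring keto O) of the pocket."""
    carboxyls = mol.GetSubstructMatches(_CARBOXYL_SMARTS)
    if not carboxyls:
        raise SubstructureError("no carboxylic acid group found")
    carboxyl_carbons = {m[0] for m in carboxyls}
    ketos = [
        m
        for m in mol.GetSubstructMatches(_KETO_SMARTS)
        if m[1] not in carboxyl_carbons
    ]
    if not ketos:
        raise SubstructureError("no ring keto oxygen found")
    # the 3-carboxyl carbon is bonded to the ring carbon adjacent to the
    # 4-keto carbon; pick the carboxyl/keto pair satisfying that topology
    for (c_cbx, o_cbx, _o_h) in carboxyls:
        for (o_keto, c_keto) in ketos:
            ring_c = [
                n.GetIdx()
                for n in mol.GetAtomWithIdx(c_cbx).GetNeighbors()
                if n.GetIdx() != o_cbx and n.GetSymbol() == "C"
            ]
            for rc in ring_c:
                if mol.GetBondBetweenAtoms(rc, c_keto) is not None:
                    return o_cbx, o_keto
    raise SubstructureError("carboxyl and keto groups are not adjacent (no pocket)")


def protonated_fq_cation(
    smiles: str, label: str = "fq_cation", seed: int = 2021
) -> Species:
    """Build the 3D N-protonated fluoroquinolone cation.

    The terminal amine of the R7 ring is protonated (+1), the carboxylic
    acid stays neutral, a conformer is embedded deterministically and
    relaxed with MMFF94, and the carboxyl is rotated so its carbonyl
    oxygen faces the keto oxygen (the open chelation pocket).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SubstructureError(f"unparseable SMILES: {smiles!r}")
    for smarts in _BASIC_N_SMARTS:
        matches = mol.GetSubstructMatches(Chem.MolFromSmarts(smarts))
        if matches:
            n_idx = matches[-1][0]
            break
    else:
        raise SubstructureError("no protonatable amine nitrogen found")
    atom = mol.GetAtomWithIdx(n_idx)
    atom.SetFormalCharge(1)
    atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
    Chem.SanitizeMol(mol)
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise GeometryError("3D embedding failed")
    AllChem.MMFFOptimizeMolecule(mol)

    o_cbx, o_keto = _find_donor_oxygens(mol)
    conf = mol.GetConformer()
    # orient the carboxyl so the carbonyl O is syn to the keto O
    c_cbx = next(
        n.GetIdx()
        for n in mol.GetAtomWithIdx(o_cbx).GetNeighbors()
    )
    ring_c = next(
        n.GetIdx()
        for n in mol.GetAtomWithIdx(c_cbx).GetNeighbors()
        if n.GetSymbol() == "C"
    )
    ring_n = next(
        n.GetIdx()
        for n in mol.GetAtomWithIdx(ring_c).GetNeighbors()
        if n.GetIdx() != c_cbx
    )
    best = None
    for angle in (0.0, 180.0):
        try:
            rdMolTransforms.SetDihedralDeg(conf, ring_n, ring_c, c_cbx, o_cbx, angle)
        except ValueError:
            continue
        d = np.linalg.norm(
            np.array(conf.GetAtomPosition(o_cbx)) - np.array(conf.GetAtomPosition(o_keto))
        )
        if best is None or d < best[0]:
            best = (d, angle)
    if best is not None:
        rdMolTransforms.SetDihedralDeg(conf, ring_n, ring_c, c_cbx, o_cbx, best[1])

    geometry = [
        (a.GetSymbol(), *map(float, conf.GetAtomPosition(a.GetIdx())))
        for a in mol.GetAtoms()
    ]
    return Species(
        label=label,
        role="fq_cation",
        charge=1,
        geometry=geometry,
        donor_indices=(o_cbx, o_keto),
    )


_WATER_GEOM = [
    ("O", 0.0, 0.0, 0.0),
    ("H", 0.9572, 0.0, 0.0),
    ("H", -0.2400, 0.9266, 0.0),
]


def water_species(label: str = "water") -> Species:
    return Species(label=label, role="water", charge=0, geometry=list(_WATER_GEOM))


def _water_at(origin: np.ndarray, outward: np.ndarray) -> list[Atom]:
    """A water molecule with its O at *origin* and H's pointing outward."""
    u = outward / np.linalg.norm(outward)
    # any vector orthogonal to u
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, u)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, ref)
    v /= np.linalg.norm(v)
    d_oh, half_angle = 0.9572, math.radians(104.52 / 2)
    h1 = origin + d_oh * (math.cos(half_angle) * u + math.sin(half_angle) * v)
    h2 = origin + d_oh * (math.cos(half_angle) * u - math.sin(half_angle) * v)
    return [
        ("O", *map(float, origin)),
        ("H", *map(float, h1)),
        ("H", *map(float, h2)),
    ]


def metal_hexahydrate(metal: str, label: Optional[str] = None) -> Species:
    """Octahedral M(H2O)6 starting geometry for Mg, Ca or Al."""
    if metal not in METALS:
        raise DomainError(f"unsupported metal {metal!r}; choose from {sorted(METALS)}")
    charge, d = METALS[metal]
    geometry: list[Atom] = [(metal, 0.0, 0.0, 0.0)]
    for axis in np.vstack([np.eye(3), -np.eye(3)]):
        geometry.extend(_water_at(d * axis, axis))
    return Species(
        label=label or f"{metal.lower()}_hexahydrate",
        role="metal_hexahydrate",
        charge=charge,
        geometry=geometry,
    )


def build_chelate_geometry(
    fq: Species,
    metal: str,
    n_waters: int = 4,
    label: Optional[str] = None,
) -> Species:
    """Starting geometry of the octahedral 1:1 bidentate chelate.

    The metal is placed equidistant from the two donor oxygens (at the
    element-dependent bond distance) on the open side of the pocket, and
    waters complete the six-coordinate shell.  Raises
    :class:`GeometryError` on steric clashes (< 0.7 A contacts) or if the
    donor separation exceeds twice the target bond length.
    """
    if metal not in METALS:
        raise DomainError(f"unsupported metal {metal!r}; choose from {sorted(METALS)}")
    if fq.role != "fq_cation":
        raise DomainError("chelate construction expects the protonated FQ cation")
    metal_charge, d_bond = METALS[metal]
    coords = fq.coords()
    if fq.donor_indices is not None:
        i_cbx, i_keto = fq.donor_indices
    else:
        i_cbx, i_keto = _donors_by_geometry(fq)
    o1, o2 = coords[i_cbx], coords[i_keto]
    half_sep = np.linalg.norm(o2 - o1) / 2.0
    if half_sep >= d_bond:
        raise GeometryError(
            f"donor oxygens {2 * half_sep:.2f} A apart; cannot place {metal} at "
            f"{d_bond} A from both"
        )
    center = (o1 + o2) / 2.0
    axis = (o2 - o1) / np.linalg.norm(o2 - o1)
    away = center - coords.mean(axis=0)
    away -= np.dot(away, axis) * axis
    if np.linalg.norm(away) < 1e-8:
        raise GeometryError("degenerate pocket geometry; cannot orient metal")
    away /= np.linalg.norm(away)
    height = math.sqrt(d_bond**2 - half_sep**2)
    m_pos = center + height * away

    # octahedral frame at the metal: two sites point at the donors, the
    # remaining four hold waters
    e1 = (o1 - m_pos) / np.linalg.norm(o1 - m_pos)
    u2 = (o2 - m_pos) / np.linalg.norm(o2 - m_pos)
    e2 = u2 - np.dot(u2, e1) * e1
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    water_dirs = [-e1, -e2, e3, -e3][:n_waters]

    geometry: list[Atom] = [(elem, float(x), float(y), float(z)) for (elem, _, _, _), (x, y, z) in zip(fq.geometry, coords)]
    geometry.append((metal, *map(float, m_pos)))
    for direction in water_dirs:
        geometry.extend(_water_at(m_pos + d_bond * direction, direction))

    _check_clashes(geometry, fq_atoms=len(fq.geometry))
    return Species(
        label=label or f"{fq.label}_{metal.lower()}_chelate",
        role="chelate_complex",
        charge=fq.charge + metal_charge,
        geometry=geometry,
        donor_indices=(i_cbx, i_keto),
    )


def _donors_by_geometry(fq: Species) -> tuple[int, int]:
    """Fallback donor identification: closest O-O pair in the pocket window."""
    coords = fq.coords()
    oxygens = [i for i, (elem, *_xyz) in enumerate(fq.geometry) if elem == "O"]
    candidates = [
        (np.linalg.norm(coords[i] - coords[j]), i, j)
        for i, j in itertools.combinations(oxygens, 2)
        if 2.0 <= np.linalg.norm(coords[i] - coords[j]) <= 3.6
    ]
    if not candidates:
        raise SubstructureError("no donor oxygen pair found in the 2.0-3.6 A window")
    _, i, j = min(candidates)
    return i, j


def _check_clashes(geometry: Sequence[Atom], fq_atoms: int) -> None:
    """Reject < 0.7 A contacts between the new fragment and the ligand."""
    coords = np.array([[x, y, z] for _, x, y, z in geometry])
    new = coords[fq_atoms:]
    old = coords[:fq_atoms]
    if new.size and old.size:
        d = np.linalg.norm(new[:, None, :] - old[None, :, :], axis=-1)
        if d.min() < CLASH_DISTANCE:
            raise GeometryError(
                f"steric clash: {d.min():.2f} A contact between placed fragment "
                "and ligand"
            )


def donor_bond_lengths(complex_species: Species) -> tuple[float, float]:
    """Metal-donor oxygen distances (carboxyl O, keto O) in Angstroms."""
    if complex_species.role != "chelate_complex":
        raise DomainError("donor_bond_lengths expects a chelate complex")
    metals = [
        i for i, (elem, *_xyz) in enumerate(complex_species.geometry) if elem in METALS
    ]
    if len(metals) != 1:
        raise SubstructureError(f"expected exactly one metal atom, found {len(metals)}")
    coords = complex_species.coords()
    m = coords[metals[0]]
    if complex_species.donor_indices is not None:
        i_cbx, i_keto = complex_species.donor_indices
    else:
        # nearest two ligand oxygens to the metal, tie-broken by distance
        oxygens = sorted(
            (
                (np.linalg.norm(coords[i] - m), i)
                for i, (elem, *_xyz) in enumerate(complex_species.geometry)
                if elem == "O"
            )
        )
        if len(oxygens) < 2:
            raise SubstructureError("fewer than two oxygens near the metal")
        i_cbx, i_keto = oxygens[0][1], oxygens[1][1]
    return (
        float(np.linalg.norm(coords[i_cbx] - m)),
        float(np.linalg.norm(coords[i_keto] - m)),
    )


# ---------------------------------------------------------------------------
# Conformer start enumeration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TorsionRule:
    """One rotatable torsion: dihedral atoms, grid angles, moving atoms."""

    atoms: tuple[int, int, int, int]
    angles_deg: tuple[float, ...]
    moving: frozenset[int]


def _set_torsion(coords: np.ndarray, rule: TorsionRule, angle_deg: float) -> np.ndarray:
    i, j, k, l = rule.atoms
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    current = math.degrees(math.atan2(np.dot(m1, n2), np.dot(n1, n2)))
    delta = math.radians(angle_deg - current)
    axis = b2 / np.linalg.norm(b2)
    rot = _rotation_matrix(axis, delta)
    out = coords.copy()
    pivot = coords[k]
    for idx in rule.moving:
        out[idx] = pivot + rot @ (coords[idx] - pivot)
    return out


def _rotation_matrix(axis: np.ndarray, theta: float) -> np.ndarray:
    a = math.cos(theta / 2.0)
    b, c, d = -axis * math.sin(theta / 2.0)
    return np.array(
        [
            [a * a + b * b - c * c - d * d, 2 * (b * c + a * d), 2 * (b * d - a * c)],
            [2 * (b * c - a * d), a * a + c * c - b * b - d * d, 2 * (c * d + a * b)],
            [2 * (b * d + a * c), 2 * (c * d - a * b), a * a + d * d - b * b - c * c],
        ]
    )


def _aligned_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Least RMSD after optimal superposition (Kabsch)."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, _s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, sign]) @ u.T
    diff = ac @ rot.T - bc
    return float(np.sqrt((diff**2).sum() / len(a)))


def enumerate_conformer_starts(
    species: Species,
    torsion_rules: Sequence[TorsionRule],
    adapter: Optional[Callable[[list[Atom]], float]] = None,
    rmsd_threshold: float = 0.05,
) -> list[Species]:
    """Deterministic grid of torsional starting geometries.

    Enumerates every combination of grid angles over the supplied torsion
    rules, removes duplicates (aligned RMSD below *rmsd_threshold*), and,
    when a force-field *adapter* is supplied, returns the starts sorted
    ascending by adapter energy (stable sort; enumeration order otherwise).
    """
    coords0 = species.coords()
    seen: list[np.ndarray] = []
    starts: list[Species] = []
    grids = [rule.angles_deg for rule in torsion_rules]
    for combo in itertools.product(*grids):
        coords = coords0
        for rule, angle in zip(torsion_rules, combo):
            coords = _set_torsion(coords, rule, angle)
        if any(_aligned_rmsd(coords, prev) < rmsd_threshold for prev in seen):
            continue
        seen.append(coords)
        geometry = [
            (elem, float(x), float(y), float(z))
            for (elem, *_xyz), (x, y, z) in zip(species.geometry, coords)
        ]
        starts.append(
            Species(
                label=f"{species.label}_start{len(starts)}",
                role=species.role,
                charge=species.charge,
                geometry=geometry,
                donor_indices=species.donor_indices,
            )
        )
    if adapter is not None:
        scored = []
        for s in starts:
            try:
                scored.append((float(adapter(s.geometry)), s))
            except Exception as exc:  # adapter contract: propagate with geometry
                raise AdapterError(
                    f"adapter failed on {s.label}:\n{_xyz_text(s)}"
                ) from exc
        scored.sort(key=lambda pair: pair[0])
        starts = [s for _, s in scored]
    return starts


# ---------------------------------------------------------------------------
# QM job specifications
# ---------------------------------------------------------------------------

_STAGE_DEFAULTS = {
    "optimize": {"basis": "6-31G(d)", "solvent_model": "none", "temperature": None},
    "frequencies": {"basis": "6-31G(d)", "solvent_model": "none", "temperature": 310.0},
    "single_point": {
        "basis": "6-31+G(d,p)",
        "solvent_model": "pcm_water",
        "temperature": None,
    },
}


@dataclass
class QMJobSpec:
    """Engine-agnostic description of one electronic-structure job."""

    stage: Stage
    method: str
    basis: str
    solvent_model: Literal["none", "pcm_water"]
    temperature: Optional[float]
    charge: int
    multiplicity: int
    geometry: list[Atom]
    label: str = ""

    def __post_init__(self) -> None:
        defaults = _STAGE_DEFAULTS.get(self.stage)
        if defaults is None:
            raise DomainError(f"unknown stage {self.stage!r}")
        if self.stage == "frequencies" and self.temperature != 310.0:
            raise DomainError("frequency jobs carry the 310 K thermal condition")
        if self.stage == "single_point" and self.solvent_model != "pcm_water":
            raise DomainError("single-point jobs use implicit water (pcm_water)")
        if self.stage in ("optimize", "frequencies") and self.basis != "6-31G(d)":
            raise DomainError("optimization and frequencies share the 6-31G(d) basis")


def emit_qm_jobspec(species: Species, stage: Stage, method: str = "PBE-D3BJ") -> str:
    """Serialize a staged job description as canonical JSON.

    The serialization is canonical (sorted keys, fixed separators) so that
    emit -> parse -> emit is byte-identical.
    """
    if species.geometry is None:
        raise DomainError(f"{species.label}: cannot emit a job without a geometry")
    defaults = _STAGE_DEFAULTS.get(stage)
    if defaults is None:
        raise DomainError(f"unknown stage {stage!r}")
    spec = QMJobSpec(
        stage=stage,
        method=method,
        basis=defaults["basis"],
        solvent_model=defaults["solvent_model"],  # type: ignore[arg-type]
        temperature=defaults["temperature"],
        charge=species.charge,
        multiplicity=species.multiplicity,
        geometry=list(species.geometry),
        label=species.label,
    )
    return _jobspec_json(spec)


def _jobspec_json(spec: QMJobSpec) -> str:
    payload = asdict(spec)
    payload["geometry"] = [[e, x, y, z] for e, x, y, z in spec.geometry]
    return json.dumps(payload, sort_keys=True, separators=(",", ":"))


def parse_qm_jobspec(text: str) -> QMJobSpec:
    """Inverse of :func:`emit_qm_jobspec`; round-trips losslessly."""
    payload = json.loads(text)
    payload["geometry"] = [tuple(atom) for atom in payload["geometry"]]
    return QMJobSpec(**payload)


def serialize_qm_jobspec(spec: QMJobSpec) -> str:
    return _jobspec_json(spec)


# ---------------------------------------------------------------------------
# Binding energies
# ---------------------------------------------------------------------------


def binding_energy(
    complex_species: Species,
    fq: Species,
    hexahydrate: Species,
    water: Species,
    energy_field: Literal["e_pcm_sp", "gibbs"] = "e_pcm_sp",
    displaced_waters: int = 2,
) -> float:
    """Binding energy of FQH+ + M(H2O)6 -> complex + n H2O, in kcal/mol."""
    _check_balance(
        [(fq, 1), (hexahydrate, 1)],
        [(complex_species, 1), (water, displaced_waters)],
    )
    delta_hartree = (
        complex_species.energy(energy_field)
        + displaced_waters * water.energy(energy_field)
        - fq.energy(energy_field)
        - hexahydrate.energy(energy_field)
    )
    return hartree_to_kcal(delta_hartree)


def make_binding_reaction(
    complex_species: Species,
    fq: Species,
    hexahydrate: Species,
    water: Species,
    displaced_waters: int = 2,
) -> BindingReaction:
    """Both binding energies (electronic and Gibbs) as a checked reaction."""
    return BindingReaction(
        reactants=[(fq, 1), (hexahydrate, 1)],
        products=[(complex_species, 1), (water, displaced_waters)],
        delta_e_bind=binding_energy(
            complex_species, fq, hexahydrate, water, "e_pcm_sp", displaced_waters
        ),
        delta_g_bind=binding_energy(
            complex_species, fq, hexahydrate, water, "gibbs", displaced_waters
        ),
    )


def load_energy_ledger(path) -> tuple[dict[str, Species], list[dict]]:
    """Read an energy ledger JSON.

    Returns the species keyed by label plus the raw reaction descriptors
    (dicts naming complex/fq/metal_hexahydrate/water labels).
    """
    with open(path) as fh:
        payload = json.load(fh)
    species = {}
    for entry in payload.get("species", []):
        sp = Species(
            label=entry["label"],
            role=entry["role"],
            charge=entry["charge"],
            multiplicity=entry.get("multiplicity", 1),
            formula=entry.get("formula"),
            e_opt=entry.get("e_opt"),
            g_thermal_corr=entry.get("g_thermal_corr"),
            e_pcm_sp=entry.get("e_pcm_sp"),
        )
        species[sp.label] = sp
    return species, list(payload.get("reactions", []))


def ledger_binding_energies(path) -> list[dict]:
    """Evaluate every reaction in a ledger; returns rows of kcal/mol results."""
    species, reactions = load_energy_ledger(path)
    rows = []
    for rxn in reactions:
        try:
            cplx = species[rxn["complex"]]
            fq = species[rxn["fq"]]
            hexa = species[rxn["metal_hexahydrate"]]
            water = species[rxn["water"]]
        except KeyError as exc:
            raise LedgerError(f"reaction {rxn.get('label')}: missing species {exc}")
        reaction = make_binding_reaction(
            cplx, fq, hexa, water, displaced_waters=rxn.get("displaced_waters", 2)
        )
        rows.append(
            {
                "label": rxn.get("label", cplx.label),
                "delta_e_bind_kcal": reaction.delta_e_bind,
                "delta_g_bind_kcal": reaction.delta_g_bind,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# XYZ I/O
# ---------------------------------------------------------------------------


def _xyz_text(species: Species) -> str:
    lines = [str(len(species.geometry)), species.label]
    for elem, x, y, z in species.geometry:
        lines.append(f"{elem} {x:.6f} {y:.6f} {z:.6f}")
    return "\n".join(lines) + "\n"


def write_xyz(species: Species, path) -> None:
    """Write one species as a standard XYZ file (element, x, y, z in A)."""
    if species.geometry is None:
        raise DomainError(f"{species.label}: no geometry to write")
    with open(path, "w") as fh:
        fh.write(_xyz_text(species))


def read_xyz(path, role: Role, charge: int, label: Optional[str] = None) -> Species:
    """Read an XYZ file into a species (role and charge supplied by caller)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    n = int(lines[0])
    comment = lines[1] if len(lines) > 1 else ""
    geometry = []
    for line in lines[2 : 2 + n]:
        elem, x, y, z = line.split()
        geometry.append((elem, float(x), float(y), float(z)))
    return Species(
        label=label or comment or "species", role=role, charge=charge, geometry=geometry
    )
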
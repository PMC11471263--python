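"""Structure parsing and geometric annotation of Fab-like assemblies.

Parsing (via gemmi) keeps the two sequence views apart: the deposited
polymer sequence (SEQRES / entity_poly_seq) and the ATOM-record sequence of
residues that actually have coordinates -- the difference is the
structural coverage.  On top of the parsed coordinates this module
computes Calpha contact matrices indexed by IMGT labels, Fab packing
angles (elbow and CH1-CL) via pseudo-twofold superposition axes,
Shrake-Rupley solvent accessibility with delta-SASA chain interfaces, and
disulfide bonds.

The elbow angle is operationalised as the angle between the rotation axes
of the least-squares VL->VH and CL->CH1 superpositions (each a pseudo-dyad
of the Fab module); the CH1-CL packing angle is the rotation angle of the
CL->CH1 superposition itself.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

import biotite.structure as bstruc

from .errors import (ArgumentError, DataInconsistencyError, GeometryError,
                     InsufficientCorrespondenceError, ParseError)
from .numbering import NumberedDomain, DomainHit, label_sort_key

DEFAULT_CONTACT_CUTOFF = 8.0      # Angstrom, Calpha-Calpha
DEFAULT_DISULFIDE_CUTOFF = 2.5    # Angstrom, Sgamma-Sgamma
DEFAULT_PROBE_RADIUS = 1.4        # Angstrom, water probe
DEFAULT_SASA_POINTS = 960
DEFAULT_DSASA_THRESHOLD = 1.0     # Angstrom^2 per residue

#: Van-der-Waals radii used for SASA; unknown elements fall back to carbon.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_VDW_RADIUS = 1.70


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass
class Residue:
    seqres_index: int  # 1-based position in the deposited polymer sequence
    amino_acid: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> np.ndarray | None:
        a = self.atom("CA")
        return np.asarray(a.xyz, dtype=float) if a else None


@dataclass
class ChainCoordinates:
    chain_id: str
    seqres_seq: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def atom_seq(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    @property
    def resolved_mask(self) -> list[bool]:
        resolved = {r.seqres_index for r in self.residues}
        return [i + 1 in resolved for i in range(len(self.seqres_seq))]

    def residue_at(self, seqres_index: int) -> Residue | None:
        for r in self.residues:
            if r.seqres_index == seqres_index:
                return r
        return None


@dataclass
class ParsedStructure:
    entry_id: str
    chains: dict[str, ChainCoordinates] = field(default_factory=dict)


def _pick_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """One atom per atom name: highest occupancy wins, ties alphabetical."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for atom in residue:
        by_name.setdefault(atom.name, []).append(atom)
    picked = []
    for name in by_name:
        cands = by_name[name]
        cands.sort(key=lambda a: (-a.occ, a.altloc if a.altloc != "\x00" else ""))
        picked.append(cands[0])
    picked.sort(key=lambda a: a.serial)
    return picked


def read_structure(path: str | Path, format: str | None = None) -> ParsedStructure:
    """Parse an mmCIF or legacy PDB file into per-chain sequence+coordinates.

    The deposited polymer sequence comes from the entity description
    (entity_poly_seq / SEQRES); the per-residue list holds only residues
    with coordinates, ordered and indexed by their position in that
    sequence.  Alternate locations are resolved to the highest-occupancy
    conformer (ties alphabetically).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"structure file not found: {path}")
    if format is None:
        format = "pdb" if path.suffix.lower() in (".pdb", ".ent") else "mmcif"
    if format not in ("mmcif", "pdb"):
        raise ValueError(f"unknown structure format {format!r}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path} as {format}: {exc}") from exc
    st.setup_entities()
    if format == "pdb":
        st.assign_label_seq_id()
    entry_id = st.name.strip() or path.stem
    parsed = ParsedStructure(entry_id=entry_id)
    if len(st) == 0:
        raise ParseError(f"{path}: no models in structure")
    model = st[0]
    seq_by_subchain: dict[str, str] = {}
    for ent in st.entities:
        if ent.entity_type != gemmi.EntityType.Polymer or not ent.full_sequence:
            continue
        one = gemmi.one_letter_code(ent.full_sequence).upper()
        for sub in ent.subchains:
            seq_by_subchain[sub] = one
    for chain in model:
        residues: list[Residue] = []
        seqres = ""
        bad: list[str] = []
        for res in chain:
            if res.label_seq is None:
                continue  # waters / ligands outside the polymer
            aa = gemmi.find_tabulated_residue(res.name)
            one = aa.one_letter_code.upper() if aa else "X"
            if not one.isalpha():
                one = "X"
            atoms = [Atom(a.name, a.element.name.upper() or "C",
                          (a.pos.x, a.pos.y, a.pos.z))
                     for a in _pick_altlocs(res)]
            for a in atoms:
                if not all(math.isfinite(v) for v in a.xyz):
                    raise ParseError(f"{path}: non-finite coordinates in "
                                     f"{chain.name}/{res.seqid.num}")
            residues.append(Residue(seqres_index=int(res.label_seq),
                                    amino_acid=one, atoms=atoms))
            sub = res.subchain
            if sub in seq_by_subchain:
                seqres = seq_by_subchain[sub]
            if seqres and int(res.label_seq) <= len(seqres):
                if seqres[int(res.label_seq) - 1] != one:
                    bad.append(f"{chain.name}/{res.seqid.num} {res.name}")
        if not residues:
            continue
        if bad:
            raise DataInconsistencyError(
                f"{path}: coordinate residues disagree with the polymer "
                f"sequence: {', '.join(bad)}")
        if not seqres:
            seqres = "".join(r.amino_acid for r in residues)
        residues.sort(key=lambda r: r.seqres_index)
        parsed.chains[chain.name] = ChainCoordinates(
            chain_id=chain.name, seqres_seq=seqres, residues=residues)
    if not parsed.chains:
        raise ParseError(f"{path}: no polymer chains with coordinates")
    return parsed


# ---------------------------------------------------------------------------
# labelled Calpha sets

LabeledCA = dict[str, np.ndarray]


def labeled_ca(chain: ChainCoordinates, hit: DomainHit,
               numbered: NumberedDomain, atom_space: bool = True) -> LabeledCA:
    """Map IMGT labels of one numbered domain to Calpha coordinates.

    ``hit``/``numbered`` must come from detection on this chain's ATOM
    sequence (``atom_space=True``) or on the SEQRES sequence; residues
    without a Calpha are skipped (reported via a warning).
    """
    out: LabeledCA = {}
    skipped = []
    for offset, (label, aa) in enumerate(numbered.residues):
        pos = hit.query_start + offset  # 1-based index into the search space
        if atom_space:
            if pos - 1 >= len(chain.residues):
                continue
            res = chain.residues[pos - 1]
        else:
            res = chain.residue_at(pos)
            if res is None:
                continue
        ca = res.ca
        if ca is None:
            skipped.append(label)
            continue
        out[label] = ca
    if skipped:
        warnings.warn(f"{len(skipped)} residue(s) lack a Calpha and were "
                      f"excluded: {skipped[:5]}...", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# contact matrices

@dataclass
class ContactMatrix:
    row_labels: list[str]
    col_labels: list[str]
    distances: np.ndarray  # (n_rows, n_cols), NaN where a position is unresolved
    cutoff: float = DEFAULT_CONTACT_CUTOFF

    @property
    def contacts(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.distances, nan=np.inf) <= self.cutoff

    def contact_pairs(self) -> set[tuple[str, str]]:
        rows, cols = np.nonzero(self.contacts)
        return {(self.row_labels[i], self.col_labels[j]) for i, j in zip(rows, cols)}


def contact_matrix(domain_a: LabeledCA, domain_b: LabeledCA,
                   cutoff: float = DEFAULT_CONTACT_CUTOFF) -> ContactMatrix:
    """Calpha-Calpha distance/contact matrix between two labelled domains.

    Labels mapped to ``None`` (unresolved) yield NaN distances, which never
    count as contacts.
    """
    rows = sorted(domain_a, key=label_sort_key)
    cols = sorted(domain_b, key=label_sort_key)
    if not any(domain_a[k] is not None for k in rows) or \
       not any(domain_b[k] is not None for k in cols):
        raise ArgumentError("contact_matrix requires at least one resolved Calpha per domain")
    dist = np.full((len(rows), len(cols)), np.nan)
    a = np.array([domain_a[r] if domain_a[r] is not None else [np.nan] * 3 for r in rows],
                 dtype=float)
    b = np.array([domain_b[c] if domain_b[c] is not None else [np.nan] * 3 for c in cols],
                 dtype=float)
    diff = a[:, None, :] - b[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    return ContactMatrix(row_labels=rows, col_labels=cols, distances=dist, cutoff=cutoff)


# ---------------------------------------------------------------------------
# packing angles

@dataclass(frozen=True)
class DyadAxis:
    axis: np.ndarray  # unit vector; sign fixed so the angle is in (0, 180]
    angle_deg: float


@dataclass(frozen=True)
class PackingAngles:
    elbow_deg: float
    ch1_cl_deg: float


def pseudo_dyad_axis(domain_1: LabeledCA, domain_2: LabeledCA,
                     min_common: int = 3) -> DyadAxis:
    """Axis and angle of the least-squares superposition of domain_2 onto domain_1.

    Correspondence is by shared IMGT label (insertion-lettered labels
    participate if present in both).  Raises for < ``min_common`` shared
    labels, for collinear point sets, and for a pure translation (rotation
    angle ~ 0, where the axis is undefined).
    """
    shared = sorted(set(domain_1) & set(domain_2), key=label_sort_key)
    shared = [s for s in shared if domain_1[s] is not None and domain_2[s] is not None]
    if len(shared) < min_common:
        raise InsufficientCorrespondenceError(
            f"only {len(shared)} shared labelled Calpha position(s); "
            f"need >= {min_common}")
    p1 = np.array([domain_1[s] for s in shared], dtype=float)
    p2 = np.array([domain_2[s] for s in shared], dtype=float)
    p1c = p1 - p1.mean(axis=0)
    p2c = p2 - p2.mean(axis=0)
    if np.linalg.matrix_rank(p1c, tol=1e-8) < 2 or np.linalg.matrix_rank(p2c, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) point set; dyad axis undefined")
    rot, _ = Rotation.align_vectors(p1c, p2c)
    rotvec = rot.as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    if angle < 1e-9:
        raise GeometryError("pure translation between domains: rotation angle 0, "
                            "dyad axis undefined")
    return DyadAxis(axis=rotvec / angle, angle_deg=math.degrees(angle))


def ch1_cl_angle(ch1: LabeledCA, cl: LabeledCA) -> float:
    """Rotation angle (degrees, in (0, 180]) of the CL->CH1 superposition."""
    return pseudo_dyad_axis(ch1, cl).angle_deg


def elbow_angle(vh: LabeledCA, vl: LabeledCA, ch1: LabeledCA, cl: LabeledCA,
                convention: str = "raw") -> float:
    """Angle between the V-module and C-module pseudo-dyad axes.

    ``convention="raw"`` folds into [0, 180] (arccos of the axis dot
    product).  ``convention="literature"`` unfolds values below 90 degrees
    to 360 - theta, matching the (90, 270) range elbow angles are commonly
    reported in; the fold ambiguity is intrinsic to comparing two
    sign-conventioned axes.
    """
    v_axis = pseudo_dyad_axis(vh, vl).axis
    c_axis = pseudo_dyad_axis(ch1, cl).axis
    cosang = float(np.clip(np.dot(v_axis, c_axis), -1.0, 1.0))
    theta = math.degrees(math.acos(cosang))
    if convention == "raw":
        return theta
    if convention == "literature":
        return theta if theta >= 90.0 else 360.0 - theta
    raise ValueError(f"unknown angle convention {convention!r}")


def packing_angles(vh: LabeledCA, vl: LabeledCA, ch1: LabeledCA, cl: LabeledCA,
                   convention: str = "raw") -> PackingAngles:
    return PackingAngles(elbow_deg=elbow_angle(vh, vl, ch1, cl, convention),
                         ch1_cl_deg=ch1_cl_angle(ch1, cl))


# ---------------------------------------------------------------------------
# solvent accessibility and the H-L interface

def sasa(atoms: list[Atom], probe: float = DEFAULT_PROBE_RADIUS,
         n_points: int = DEFAULT_SASA_POINTS) -> np.ndarray:
    """Per-atom Shrake-Rupley solvent-accessible surface areas (A^2).

    Deterministic for a given ``n_points`` (fixed sphere point set).
    Unknown elements trigger a warning and use the carbon radius.  Exactly
    coincident atoms of equal radius share one sphere: the first carries
    the area, duplicates report 0 (the coincident limit of two spheres
    approaching each other).
    """
    if not atoms:
        raise ArgumentError("sasa requires at least one atom")
    n = len(atoms)
    arr = bstruc.AtomArray(n)
    arr.coord = np.array([a.xyz for a in atoms], dtype=np.float32)
    arr.element = np.array([a.element for a in atoms])
    arr.atom_name = np.array([a.name for a in atoms])
    arr.res_id = np.arange(n)
    arr.res_name = np.array(["UNK"] * n)
    arr.chain_id = np.array(["A"] * n)
    radii = np.empty(n)
    for i, a in enumerate(atoms):
        r = VDW_RADII.get(a.element)
        if r is None:
            warnings.warn(f"no van-der-Waals radius for element {a.element!r}; "
                          f"using {DEFAULT_VDW_RADIUS} A", stacklevel=2)
            r = DEFAULT_VDW_RADIUS
        radii[i] = r
    # collapse exact duplicates (same centre and radius) onto one sphere
    keys = {}
    rep = np.arange(n)
    for i, a in enumerate(atoms):
        key = (round(a.xyz[0], 6), round(a.xyz[1], 6), round(a.xyz[2], 6),
               round(radii[i], 6))
        rep[i] = keys.setdefault(key, i)
    unique = np.nonzero(rep == np.arange(n))[0]
    areas_u = np.asarray(bstruc.sasa(arr[unique], probe_radius=probe,
                                     point_number=n_points,
                                     vdw_radii=radii[unique]), dtype=float)
    out = np.zeros(n)
    out[unique] = areas_u
    return out


def _chain_atoms(chain: ChainCoordinates) -> tuple[list[Atom], list[int]]:
    atoms: list[Atom] = []
    owner: list[int] = []
    for res in chain.residues:
        for a in res.atoms:
            atoms.append(a)
            owner.append(res.seqres_index)
    return atoms, owner


@dataclass
class InterfaceAnnotation:
    delta_sasa: dict[tuple[str, int], float]  # (chain_id, seqres_index) -> A^2
    interface_residues: list[tuple[str, int]]
    buried_area: float


def hl_interface(h_chain: ChainCoordinates, l_chain: ChainCoordinates,
                 delta_threshold: float = DEFAULT_DSASA_THRESHOLD,
                 probe: float = DEFAULT_PROBE_RADIUS,
                 n_points: int = DEFAULT_SASA_POINTS) -> InterfaceAnnotation:
    """Delta-SASA interface between a heavy and a light chain.

    Per residue: SASA of the chain in isolation minus SASA in the two-chain
    complex.  Residues losing more than ``delta_threshold`` A^2 are
    interface residues; the buried area is the summed loss over both
    chains divided by two.
    """
    h_atoms, h_owner = _chain_atoms(h_chain)
    l_atoms, l_owner = _chain_atoms(l_chain)
    if not h_atoms or not l_atoms:
        raise ArgumentError("hl_interface: both chains need atoms ('insufficient atoms')")
    h_alone = sasa(h_atoms, probe, n_points)
    l_alone = sasa(l_atoms, probe, n_points)
    both = sasa(h_atoms + l_atoms, probe, n_points)
    h_complex, l_complex = both[:len(h_atoms)], both[len(h_atoms):]
    delta: dict[tuple[str, int], float] = {}
    for chain, owner, alone, complexed in (
            (h_chain, h_owner, h_alone, h_complex),
            (l_chain, l_owner, l_alone, l_complex)):
        per_res: dict[int, float] = {}
        for idx, da in zip(owner, alone - complexed):
            per_res[idx] = per_res.get(idx, 0.0) + float(da)
        for idx, val in per_res.items():
            delta[(chain.chain_id, idx)] = val
    interface = sorted(k for k, v in delta.items() if v > delta_threshold)
    buried = sum(max(v, 0.0) for v in delta.values()) / 2.0
    return InterfaceAnnotation(delta_sasa=delta, interface_residues=interface,
                               buried_area=buried)


# ---------------------------------------------------------------------------
# disulfide bonds

@dataclass(frozen=True)
class DisulfideBond:
    chain_a: str
    res_a: int
    chain_b: str
    res_b: int
    distance: float
    kind: str  # "intra" or "inter"


def disulfide_bonds(structure: ParsedStructure,
                    cutoff: float = DEFAULT_DISULFIDE_CUTOFF) -> list[DisulfideBond]:
    """Cysteine pairs with Sgamma-Sgamma distance <= ``cutoff`` (A)."""
    sgs: list[tuple[str, int, np.ndarray]] = []
    for chain in structure.chains.values():
        for res in chain.residues:
            if res.amino_acid != "C":
                continue
            sg = res.atom("SG")
            if sg is not None:
                sgs.append((chain.chain_id, res.seqres_index,
                            np.asarray(sg.xyz, dtype=float)))
    bonds: list[DisulfideBond] = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            ca, ra, pa = sgs[i]
            cb, rb, pb = sgs[j]
            d = float(np.linalg.norm(pa - pb))
            if d <= cutoff:
                bonds.append(DisulfideBond(ca, ra, cb, rb, d,
                                           "intra" if ca == cb else "inter"))
    return bonds
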
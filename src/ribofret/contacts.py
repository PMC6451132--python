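"""Contact geometry for ligand/ribosome structures.

Measures the quantities used to characterize an E-site-bound inhibitor:
halogen-pi contacts (halogen to aromatic-ring-centroid distance plus the
angle to the ring normal, "face-on" below an angle threshold), short polar
contacts between ligand halogens/oxygens and N/O partners, and least-squares
rigid superposition RMSD between paired coordinate sets.

File I/O (mmCIF and PDB, first model, alternate locations resolved by
occupancy) goes through biotite; everything downstream operates on plain
numpy arrays so the geometry is easy to test against brute-force oracles.
Coordinates are Angstroms with as-deposited numbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Structure",
    "RingSpec",
    "HalogenPiContact",
    "PolarContact",
    "AtomRef",
    "load_structure",
    "write_structure_pdb",
    "ring_centroid_normal",
    "ring_choice_distances",
    "find_halogen_pi",
    "find_polar_contacts",
    "superpose_rmsd",
    "parse_selection",
]

HALOGEN_ELEMENTS = ("F", "CL", "BR", "I")

# aromatic ring member atoms per nucleobase family (standard PDB names)
PURINE_RESIDUES = {"A", "G", "DA", "DG", "1MA", "2MG", "7MG", "M2G", "OMG"}
PYRIMIDINE_RESIDUES = {"C", "U", "T", "DC", "DT", "DU", "5MC", "5MU", "OMC", "OMU", "PSU"}
PURINE_SIX_RING = ("N1", "C2", "N3", "C4", "C5", "C6")
PURINE_FIVE_RING = ("C4", "C5", "N7", "C8", "N9")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")


@dataclass(frozen=True)
class AtomRef:
    chain_id: str
    res_name: str
    res_id: int
    atom_name: str

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.res_name}{self.res_id}:{self.atom_name}"


@dataclass
class Structure:
    """Flat atom table of one model of a macromolecular structure."""

    chain_id: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coord: np.ndarray
    occupancy: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.coord)

    def select(self, chain_id=None, res_id=None, res_name=None, atom_name=None) -> np.ndarray:
        """Boolean mask over atoms matching all given (scalar or set) fields."""
        mask = np.ones(len(self), dtype=bool)
        for values, field in ((chain_id, self.chain_id), (res_id, self.res_id),
                              (res_name, self.res_name), (atom_name, self.atom_name)):
            if values is None:
                continue
            if np.isscalar(values):
                values = {values}
            mask &= np.isin(field, list(values))
        return mask

    def atom_ref(self, i: int) -> AtomRef:
        return AtomRef(str(self.chain_id[i]), str(self.res_name[i]),
                       int(self.res_id[i]), str(self.atom_name[i]))

    @classmethod
    def from_atom_array(cls, atoms: struc.AtomArray, source: str = "") -> "Structure":
        element = np.char.upper(atoms.element.astype(str))
        missing = element == ""
        if np.any(missing):
            inferred = np.asarray(struc.infer_elements(atoms), dtype=str)
            element = np.where(missing, np.char.upper(inferred), element)
        occupancy = (atoms.occupancy if "occupancy" in atoms.get_annotation_categories()
                     else np.ones(atoms.array_length()))
        return cls(chain_id=atoms.chain_id.astype(str),
                   res_name=atoms.res_name.astype(str),
                   res_id=atoms.res_id.astype(int),
                   atom_name=atoms.atom_name.astype(str),
                   element=element,
                   coord=np.asarray(atoms.coord, dtype=float),
                   occupancy=np.asarray(occupancy, dtype=float),
                   source=source)

    def to_atom_array(self) -> struc.AtomArray:
        atoms = struc.AtomArray(len(self))
        atoms.chain_id = self.chain_id
        atoms.res_name = self.res_name
        atoms.res_id = self.res_id
        atoms.atom_name = self.atom_name
        atoms.element = self.element
        atoms.coord = self.coord
        atoms.set_annotation("occupancy", self.occupancy)
        return atoms


def parse_selection(text: str) -> dict:
    """Parse ``chain:resnum[:atom]`` selection syntax into select() kwargs."""
    parts = text.split(":")
    if len(parts) not in (2, 3):
        raise ValueError("selection must look like chain:resnum[:atom]")
    sel = {"chain_id": parts[0], "res_id": int(parts[1])}
    if len(parts) == 3:
        sel["atom_name"] = parts[2]
    return sel


def load_structure(path: str | Path, fmt: str | None = None) -> Structure:
    """Read an mmCIF or PDB file (first model; altlocs by highest occupancy)."""
    path = Path(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    kwargs = dict(model=1, altloc="occupancy", extra_fields=["occupancy"])
    if fmt == "mmcif":
        import biotite.structure.io.pdbx as pdbx
        atoms = pdbx.get_structure(pdbx.CIFFile.read(str(path)), **kwargs)
    elif fmt == "pdb":
        atoms = PDBFile.read(str(path)).get_structure(**kwargs)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return Structure.from_atom_array(atoms, source=str(path))


def write_structure_pdb(structure: Structure, path: str | Path) -> None:
    f = PDBFile()
    f.set_structure(structure.to_atom_array())
    f.write(str(path))


# ---------------------------------------------------------------------------
# Ring geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RingSpec:
    """Selects one aromatic ring of one residue.

    ``ring`` is "six" (pyrimidine-like / purine six-membered ring, the
    default for guanine centroid measurements), "five" (purine imidazole
    ring) or "fused" (all purine ring atoms together).
    """

    chain_id: str
    res_id: int
    ring: str = "six"

    def member_atoms(self, res_name: str) -> tuple[str, ...]:
        if res_name in PURINE_RESIDUES:
            return {"six": PURINE_SIX_RING, "five": PURINE_FIVE_RING,
                    "fused": tuple(dict.fromkeys(PURINE_SIX_RING + PURINE_FIVE_RING))
                    }[self.ring]
        if res_name in PYRIMIDINE_RESIDUES:
            return PYRIMIDINE_RING
        raise ValueError(f"no aromatic ring table for residue {res_name!r}")


def _plane_normal(coords: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane (smallest principal direction).

    Sign convention: the component of largest magnitude is made positive.
    """
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    normal = vt[-1]
    pivot = int(np.argmax(np.abs(normal)))
    if normal[pivot] < 0:
        normal = -normal
    return normal


def ring_centroid_normal(
    structure: Structure, ring: RingSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of an aromatic ring.

    The centroid is the mean of the ring-atom coordinates; the normal is the
    least-squares plane normal (smallest principal moment of the centered
    ring atoms).  Raises if any ring atom is missing, naming it.
    """
    res_mask = structure.select(chain_id=ring.chain_id, res_id=ring.res_id)
    if not np.any(res_mask):
        raise ValueError(f"residue {ring.chain_id}:{ring.res_id} not found")
    res_name = str(structure.res_name[res_mask][0])
    names = ring.member_atoms(res_name)
    coords = []
    for name in names:
        m = res_mask & (structure.atom_name == name)
        if not np.any(m):
            raise ValueError(
                f"ring atom {name} missing in {ring.chain_id}:{res_name}{ring.res_id}")
        coords.append(structure.coord[m][0])
    coords = np.asarray(coords)
    return coords.mean(axis=0), _plane_normal(coords)


def ring_choice_distances(
    structure: Structure, chain_id: str, res_id: int, point: np.ndarray,
    spread_threshold: float = 0.2,
) -> dict:
    """Distance from ``point`` to each available ring-centroid choice.

    For purines the six-membered/five-membered/fused centroids can differ;
    returns {"six": d, ...} plus "ambiguous": True when the choices spread
    by more than ``spread_threshold`` Angstrom (so all of them should be
    reported alongside any headline distance).
    """
    res_mask = structure.select(chain_id=chain_id, res_id=res_id)
    if not np.any(res_mask):
        raise ValueError(f"residue {chain_id}:{res_id} not found")
    res_name = str(structure.res_name[res_mask][0])
    choices = (("six", "five", "fused") if res_name in PURINE_RESIDUES
               else ("six",))
    out = {}
    for choice in choices:
        centroid, _ = ring_centroid_normal(
            structure, RingSpec(chain_id, res_id, choice))
        out[choice] = float(np.linalg.norm(np.asarray(point) - centroid))
    vals = list(out.values())
    out["ambiguous"] = bool(max(vals) - min(vals) > spread_threshold)
    return out


# ---------------------------------------------------------------------------
# Contact detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HalogenPiContact:
    halogen: AtomRef
    ring_residue: AtomRef      # atom_name holds the ring choice
    distance: float            # halogen to ring centroid, Angstrom
    angle: float               # to the ring normal, degrees in [0, 90]
    face_on: bool

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if not (0.0 <= self.angle <= 90.0):
            raise ValueError("angle must lie in [0, 90] degrees")

    @property
    def geometry(self) -> str:
        return "face-on" if self.face_on else "edge-on"


@dataclass(frozen=True)
class PolarContact:
    ligand_atom: AtomRef
    partner_atom: AtomRef
    distance: float
    contact_class: str         # "Cl...base", "O...H-N" or "O...H-O"

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("distance must be positive")


def _aromatic_residues(structure: Structure, exclude_mask: np.ndarray) -> list[tuple[str, int, str]]:
    keys = set()
    out = []
    aromatic = PURINE_RESIDUES | PYRIMIDINE_RESIDUES
    for i in np.flatnonzero(~exclude_mask):
        rn = str(structure.res_name[i])
        if rn not in aromatic:
            continue
        key = (str(structure.chain_id[i]), int(structure.res_id[i]), rn)
        if key not in keys:
            keys.add(key)
            out.append(key)
    return out


def find_halogen_pi(
    structure: Structure,
    ligand: dict | str,
    halogen_elements: tuple[str, ...] = HALOGEN_ELEMENTS,
    max_distance: float = 4.5,
    max_face_angle: float = 40.0,
    ring: str = "six",
) -> list[HalogenPiContact]:
    """All halogen-to-aromatic-ring contacts within a centroid distance cutoff.

    ``ligand`` selects the inhibitor (``select()`` kwargs or
    ``chain:resnum`` text).  Rings are taken from nucleobase residues
    outside the ligand (choice per :class:`RingSpec`).  Contacts with the
    halogen-centroid vector within ``max_face_angle`` of the ring normal are
    labelled face-on.  Results are sorted by distance.
    """
    if isinstance(ligand, str):
        ligand = parse_selection(ligand)
    lig_mask = structure.select(**ligand)
    if not np.any(lig_mask):
        raise ValueError("ligand selection matches no atoms")
    elements = np.char.upper(structure.element.astype(str))
    hal_idx = np.flatnonzero(lig_mask & np.isin(elements, list(halogen_elements)))
    if len(hal_idx) == 0:
        warnings.warn("ligand contains no halogen atoms", stacklevel=2)
        return []

    contacts = []
    for chain, res_id, res_name in _aromatic_residues(structure, lig_mask):
        ring_choice = ring if res_name in PURINE_RESIDUES else "six"
        try:
            centroid, normal = ring_centroid_normal(
                structure, RingSpec(chain, res_id, ring_choice))
        except ValueError:
            continue  # incomplete ring
        for i in hal_idx:
            v = structure.coord[i] - centroid
            dist = float(np.linalg.norm(v))
            if dist == 0.0 or dist > max_distance:
                continue
            cosang = abs(float(np.dot(v / dist, normal)))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            contacts.append(HalogenPiContact(
                halogen=structure.atom_ref(int(i)),
                ring_residue=AtomRef(chain, res_name, res_id, ring_choice),
                distance=dist, angle=angle,
                face_on=angle <= max_face_angle))
    contacts.sort(key=lambda c: c.distance)
    return contacts


def find_polar_contacts(
    structure: Structure,
    ligand: dict | str,
    max_distance: float = 3.6,
) -> list[PolarContact]:
    """Short heavy-atom contacts from ligand halogens/oxygens to N/O partners.

    A plain distance screen (hydrogens are not required): ligand halogen to
    any N/O gives class "Cl...base"; ligand oxygen to N gives "O...H-N" and
    to O gives "O...H-O".  Results are sorted by distance.
    """
    if isinstance(ligand, str):
        ligand = parse_selection(ligand)
    lig_mask = structure.select(**ligand)
    if not np.any(lig_mask):
        raise ValueError("ligand selection matches no atoms")
    elements = np.char.upper(structure.element.astype(str))

    donor_idx = np.flatnonzero(
        lig_mask & np.isin(elements, list(HALOGEN_ELEMENTS) + ["O"]))
    partner_idx = np.flatnonzero(~lig_mask & np.isin(elements, ["N", "O"]))
    if len(donor_idx) == 0 or len(partner_idx) == 0:
        return []

    tree = cKDTree(structure.coord[partner_idx])
    contacts = []
    for i in donor_idx:
        for j_local in tree.query_ball_point(structure.coord[i], max_distance):
            j = int(partner_idx[j_local])
            dist = float(np.linalg.norm(structure.coord[i] - structure.coord[j]))
            if dist == 0.0 or dist > max_distance:
                continue
            if elements[i] in HALOGEN_ELEMENTS:
                cls = "Cl...base"
            else:
                cls = "O...H-N" if elements[j] == "N" else "O...H-O"
            contacts.append(PolarContact(
                ligand_atom=structure.atom_ref(int(i)),
                partner_atom=structure.atom_ref(j),
                distance=dist, contact_class=cls))
    contacts.sort(key=lambda c: c.distance)
    return contacts


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def superpose_rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    pairing: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of B onto A (Kabsch).

    ``pairing`` optionally holds (index_in_a, index_in_b) rows; by default
    the sets are paired positionally and must have equal length.  Returns
    ``(rmsd, rotation, translation)`` with ``rotation @ b + translation``
    the superposed copy of B.  The SVD construction includes the usual
    reflection guard; collinear point sets raise.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if pairing is not None:
        pairing = np.asarray(pairing, dtype=int)
        A, B = A[pairing[:, 0]], B[pairing[:, 1]]
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("need equal-length paired (n, 3) coordinate sets")
    if len(A) < 3:
        raise ValueError("need at least 3 paired points")

    ca, cb = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - ca, B - cb
    for M in (Ac, Bc):
        s = np.linalg.svd(M, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise ValueError("degenerate (collinear) coordinate set")

    H = Bc.T @ Ac
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    rmsd = float(np.sqrt(np.mean(np.sum((Bc @ R.T - Ac) ** 2, axis=1))))
    t = ca - R @ cb
    return rmsd, R, t
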
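"""Crystal data model, CIF reading/writing, supercells and rigid-unit detection.

A :class:`Crystal` is a P1 cell: a 3x3 lattice matrix (rows are the cell
vectors, Å), an ordered atom list with fractional coordinates wrapped to
[0, 1), and a partition of the atoms into rigid units (whole molecules).
Molecules are the dynamical objects of the rigid-body lattice-dynamics model;
each is characterised by its centre of mass, inertia tensor and orientation.

CIF files are handled through gemmi's CIF document layer.  Symmetry operations
present in a file are applied and the cell expanded to P1 on read; the writer
always emits P1.  Atomic point charges and force-field type labels travel in
two custom atom_site-loop tags, ``_polyphonon_charge`` and
``_polyphonon_ff_type`` (both optional on read; the force-field file can
supply them instead).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "RigidUnit",
    "Crystal",
    "FormatError",
    "PolymerError",
    "read_cif",
    "write_cif",
    "make_supercell",
    "identify_rigid_units",
    "COVALENT_RADII",
]


class FormatError(ValueError):
    """Raised for malformed or incomplete CIF input."""


class PolymerError(ValueError):
    """Raised when a bonded network spans the lattice (no finite molecule)."""


# Covalent radii (Å), Cordero et al. single-bond values, for bond perception.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Br": 1.20, "Kr": 1.16, "I": 1.39, "Xe": 1.40,
    "Cs": 2.44,
}


@dataclass
class Atom:
    """One atom: element, mass (amu), fractional position, charge (e), ff type."""

    element: str
    mass: float
    frac_pos: np.ndarray
    charge: float = 0.0
    ff_type: str = ""

    def __post_init__(self):
        self.frac_pos = np.asarray(self.frac_pos, dtype=float) % 1.0
        if self.mass <= 0:
            raise ValueError(f"atom {self.element}: mass must be positive")
        if not self.ff_type:
            self.ff_type = self.element


@dataclass
class RigidUnit:
    """A rigid molecule: member atoms, COM (Å), inertia tensor (amu Å²)."""

    atom_indices: list[int]
    com: np.ndarray
    inertia_tensor: np.ndarray
    orientation: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0])
    )

    @property
    def mass(self) -> float:  # set by Crystal.rigid_unit
        return self._mass

    def __post_init__(self):
        n = float(np.linalg.norm(self.orientation))
        if abs(n - 1.0) > 1e-12:
            raise ValueError("orientation quaternion must be normalised")


@dataclass
class Crystal:
    """A P1 molecular crystal.

    Parameters
    ----------
    lattice_vectors : (3, 3) array
        Rows are the cell vectors a, b, c in Å.  Must be right-handed
        (positive scalar triple product).
    atoms : list of Atom
    rigid_units : list of list of int
        Partition of atom indices into molecules.  Defaults to one unit per
        atom if omitted.
    """

    lattice_vectors: np.ndarray
    atoms: list[Atom]
    rigid_units: list[list[int]] = field(default_factory=list)

    def __post_init__(self):
        self.lattice_vectors = np.asarray(self.lattice_vectors, dtype=float)
        if self.lattice_vectors.shape != (3, 3):
            raise ValueError("lattice_vectors must be 3x3")
        if np.linalg.det(self.lattice_vectors) <= 0:
            raise ValueError("cell must be right-handed with positive volume")
        if not self.rigid_units:
            self.rigid_units = [[i] for i in range(len(self.atoms))]
        idx = sorted(i for unit in self.rigid_units for i in unit)
        if idx != list(range(len(self.atoms))):
            raise ValueError("rigid_units must partition the atom indices")

    # -- geometry -----------------------------------------------------------

    @property
    def volume(self) -> float:
        """Cell volume in Å³ (scalar triple product)."""
        return float(np.linalg.det(self.lattice_vectors))

    @property
    def n_molecules(self) -> int:
        return len(self.rigid_units)

    @property
    def frac_coords(self) -> np.ndarray:
        return np.array([a.frac_pos for a in self.atoms])

    @property
    def cart_coords(self) -> np.ndarray:
        return self.frac_coords @ self.lattice_vectors

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    def unit_positions(self, u: int) -> np.ndarray:
        """Cartesian positions of unit ``u``, unwrapped to a contiguous molecule.

        Atoms are shifted by lattice vectors so that each sits in the periodic
        image closest to the first atom of the unit (molecules are assumed
        smaller than half the cell, which holds for whole-molecule P1 cells).
        """
        idx = self.rigid_units[u]
        frac = self.frac_coords[idx]
        d = frac - frac[0]
        d -= np.round(d)
        return (frac[0] + d) @ self.lattice_vectors

    def rigid_unit(self, u: int) -> RigidUnit:
        """COM, inertia tensor and member list of unit ``u``."""
        idx = self.rigid_units[u]
        pos = self.unit_positions(u)
        m = self.masses[idx]
        com = m @ pos / m.sum()
        d = pos - com
        inertia = np.einsum("a,ai,aj->ij", m, d, d)
        inertia = np.trace(inertia) * np.eye(3) - inertia
        unit = RigidUnit(list(idx), com, inertia)
        unit._mass = float(m.sum())
        return unit

    def replace_geometry(
        self, lattice_vectors: np.ndarray, cart_coords: np.ndarray
    ) -> "Crystal":
        """New Crystal with the same topology but new cell and positions."""
        lat = np.asarray(lattice_vectors, dtype=float)
        frac = np.asarray(cart_coords, dtype=float) @ np.linalg.inv(lat)
        atoms = [replace(a, frac_pos=f % 1.0) for a, f in zip(self.atoms, frac)]
        return Crystal(lat, atoms, [list(u) for u in self.rigid_units])

    def scaled(self, volume_factor: float) -> "Crystal":
        """Isotropically scale the cell, keeping rigid-unit geometry fixed.

        COMs move affinely with the cell; intramolecular distances are
        preserved (the rigid-body constraint).
        """
        s = volume_factor ** (1.0 / 3.0)
        new_lat = self.lattice_vectors * s
        new_cart = np.empty((len(self.atoms), 3))
        for u in range(self.n_molecules):
            idx = self.rigid_units[u]
            pos = self.unit_positions(u)
            m = self.masses[idx]
            com = m @ pos / m.sum()
            new_cart[idx] = com * s + (pos - com)
        return self.replace_geometry(new_lat, new_cart)


# -- CIF input/output -------------------------------------------------------


def _atom_mass(element: str) -> float:
    el = gemmi.Element(element)
    if el.name == "X" or el.weight <= 0:
        raise FormatError(f"unknown element symbol {element!r}")
    return float(el.weight)


def read_cif(path, bond_scale: float | None = 1.2) -> Crystal:
    """Read a CIF file into a P1 :class:`Crystal`.

    Symmetry operations in the file are applied and duplicate sites merged, so
    the returned cell is always P1.  Rigid units are identified from the bond
    graph with ``bond_scale`` (pass ``None`` to leave every atom in its own
    unit).
    """
    path = Path(path)
    try:
        doc = gemmi.cif.read(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse CIF {path}: {exc}") from exc
    block = doc.sole_block()

    def cell_par(tag):
        v = block.find_value(tag)
        if v is None:
            raise FormatError(f"{path}: missing {tag}")
        return float(gemmi.cif.as_number(v))

    a, b, c = (cell_par(f"_cell_length_{x}") for x in "abc")
    al, be, ga = (cell_par(f"_cell_angle_{x}") for x in ("alpha", "beta", "gamma"))
    cell = gemmi.UnitCell(a, b, c, al, be, ga)
    lat = np.array(cell.orth.mat.tolist())
    # gemmi's orthogonalisation matrix has cell vectors as columns
    lat = lat.T

    tags = [
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
    ]
    table = block.find(tags)
    if len(table) == 0:
        raise FormatError(f"{path}: no atom_site loop with {tags}")
    extra = block.find(["_atom_site_type_symbol", "_polyphonon_charge",
                        "_polyphonon_ff_type"])
    charges = [float(gemmi.cif.as_number(r[1])) for r in extra] or None
    fftypes = [gemmi.cif.as_string(r[2]) for r in extra] or None

    ops = []
    for tag in ("_symmetry_equiv_pos_as_xyz", "_space_group_symop_operation_xyz"):
        col = block.find_loop(tag)
        ops += [gemmi.Op(gemmi.cif.as_string(v)) for v in col]
    if not ops:
        ops = [gemmi.Op("x,y,z")]

    atoms: list[Atom] = []
    seen: list[np.ndarray] = []
    for i, row in enumerate(table):
        el = gemmi.cif.as_string(row[0])
        frac = np.array([gemmi.cif.as_number(row[j]) for j in (1, 2, 3)])
        q = charges[i] if charges else 0.0
        ft = fftypes[i] if fftypes else el
        for op in ops:
            f = np.array(op.apply_to_xyz(list(frac))) % 1.0
            if any(np.linalg.norm((f - s + 0.5) % 1.0 - 0.5) < 1e-4 for s in seen):
                continue
            seen.append(f)
            atoms.append(Atom(el, _atom_mass(el), f, q, ft))
    if not atoms:
        raise FormatError(f"{path}: empty atom list")

    crystal = Crystal(lat, atoms)
    if bond_scale is not None:
        crystal.rigid_units = identify_rigid_units(crystal, bond_scale)
    return crystal


def write_cif(crystal: Crystal, path) -> None:
    """Write ``crystal`` as a P1 CIF (cell and coordinates to 6 decimals)."""
    if not crystal.atoms:
        raise ValueError("refusing to write a crystal with no atoms")
    lat = crystal.lattice_vectors
    a, b, c = (float(np.linalg.norm(v)) for v in lat)
    cosang = lambda u, v: float(np.dot(lat[u], lat[v])
                                / (np.linalg.norm(lat[u]) * np.linalg.norm(lat[v])))
    alpha, beta, gamma = (math.degrees(math.acos(cosang(*p)))
                          for p in ((1, 2), (0, 2), (0, 1)))
    lines = [
        "data_polyphonon",
        "_symmetry_space_group_name_H-M   'P 1'",
        "_symmetry_Int_Tables_number      1",
        f"_cell_length_a     {a:.6f}",
        f"_cell_length_b     {b:.6f}",
        f"_cell_length_c     {c:.6f}",
        f"_cell_angle_alpha  {alpha:.6f}",
        f"_cell_angle_beta   {beta:.6f}",
        f"_cell_angle_gamma  {gamma:.6f}",
        "loop_",
        "_symmetry_equiv_pos_as_xyz",
        "  'x,y,z'",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
        "_polyphonon_charge",
        "_polyphonon_ff_type",
    ]
    # reconstruct fractional coordinates from the possibly non-orthogonal cell
    for i, at in enumerate(crystal.atoms):
        f = at.frac_pos % 1.0
        lines.append(
            f"  {at.element}{i+1} {at.element} {f[0]:.6f} {f[1]:.6f} {f[2]:.6f} "
            f"{at.charge:.6f} {at.ff_type}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# -- supercells -------------------------------------------------------------


def make_supercell(crystal: Crystal, n1: int, n2: int, n3: int) -> Crystal:
    """Replicate the cell ``n1 x n2 x n3`` times (rigid units replicated too)."""
    if min(n1, n2, n3) < 1:
        raise ValueError("supercell factors must be >= 1")
    reps = (n1, n2, n3)
    lat = crystal.lattice_vectors * np.array(reps)[:, None]
    atoms: list[Atom] = []
    units: list[list[int]] = []
    frac = crystal.frac_coords
    for i in range(n1):
        for j in range(n2):
            for k in range(n3):
                off = len(atoms)
                shift = np.array([i, j, k], dtype=float)
                for at, f in zip(crystal.atoms, frac):
                    atoms.append(replace(at, frac_pos=(f + shift) / reps))
                units += [[idx + off for idx in u] for u in crystal.rigid_units]
    return Crystal(lat, atoms, units)


# -- rigid-unit identification ----------------------------------------------


def identify_rigid_units(crystal: Crystal, bond_scale: float = 1.2) -> list[list[int]]:
    """Partition atoms into molecules by bond-graph connected components.

    Two atoms are bonded when their minimum-image distance is below
    ``bond_scale`` times the sum of their covalent radii.  A component that
    bonds to its own periodic image is an infinite polymer, for which the
    rigid-body model does not apply.
    """
    n = len(crystal.atoms)
    frac = crystal.frac_coords
    lat = crystal.lattice_vectors
    radii = []
    for at in crystal.atoms:
        r = COVALENT_RADII.get(at.element)
        if r is None:
            raise ValueError(f"no covalent radius tabulated for {at.element}")
        radii.append(r)

    shifts = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                       for k in (-1, 0, 1)], dtype=float)
    # bonds[(i, j)] -> list of integer image shifts of j relative to i
    bonds: dict[int, list[tuple[int, np.ndarray]]] = {i: [] for i in range(n)}
    for i in range(n):
        for j in range(i, n):
            cut = bond_scale * (radii[i] + radii[j])
            if cut <= 0:
                continue
            d = frac[j] + shifts - frac[i]
            dist = np.linalg.norm(d @ lat, axis=1)
            for s, r in zip(shifts, dist):
                if 1e-6 < r < cut:
                    bonds[i].append((j, s))
                    bonds[j].append((i, -s))

    units: list[list[int]] = []
    assigned: dict[int, np.ndarray] = {}
    for start in range(n):
        if start in assigned:
            continue
        comp = [start]
        assigned[start] = np.zeros(3)
        stack = [start]
        while stack:
            i = stack.pop()
            for j, s in bonds[i]:
                shift = assigned[i] + s
                if j in assigned:
                    if not np.allclose(assigned[j], shift):
                        raise PolymerError(
                            "bond network spans the lattice: rigid-body model "
                            "inapplicable (polymeric structure)"
                        )
                else:
                    assigned[j] = shift
                    comp.append(j)
                    stack.append(j)
        units.append(sorted(comp))
    return units
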
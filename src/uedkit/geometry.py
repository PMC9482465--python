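"""Molecular geometries and packed liquid droplet configurations.

A :class:`MolecularGeometry` is the unit of gas-phase diffraction: an ordered
list of atoms with Cartesian coordinates in ångströms.  A
:class:`LiquidConfiguration` is a droplet of rigid copies of one molecule,
randomly oriented and packed to a target mass density with a hard heavy-atom
contact distance; flattening it yields the atom set over which the pairwise
(Debye) interference sum of the liquid is evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "MolecularGeometry",
    "LiquidConfiguration",
    "PackingError",
    "XYZParseError",
    "read_xyz",
    "write_xyz",
    "build_glycerol",
    "pair_distances",
    "pack_droplet",
]

#: elements with tabulated electron scattering factors (see scattering.py);
#: geometry validation checks membership here so an untabulated element fails
#: early rather than deep inside a simulation.
KNOWN_ELEMENTS = {"H", "C", "N", "O"}

#: atomic masses in u, enough for the molecules this package simulates.
ATOMIC_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}

# Avogadro constant folded into the g/cm^3 <-> molecules/Å^3 conversion:
# number density [Å^-3] = density [g/cm^3] * _DENS2NUM / molar mass [g/mol]
_DENS2NUM = 0.602214076


class XYZParseError(ValueError):
    """Raised when an XYZ file violates the count/record layout."""


class PackingError(RuntimeError):
    """Raised when droplet packing cannot satisfy density and contact."""


@dataclass(frozen=True)
class Atom:
    """One atom: chemical symbol plus Cartesian position in Å."""

    element: str
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.element not in KNOWN_ELEMENTS:
            raise ValueError(
                f"element {self.element!r} has no tabulated scattering factor"
            )
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        object.__setattr__(self, "position", tuple(float(x) for x in pos))


class MolecularGeometry:
    """Ordered collection of atoms; coordinates in Å.

    Parameters
    ----------
    atoms:
        Non-empty sequence of :class:`Atom`.
    name:
        Free-text label, preserved in XYZ comment lines.
    """

    def __init__(self, atoms, name: str = ""):
        atoms = list(atoms)
        if len(atoms) < 1:
            raise ValueError("a geometry needs at least one atom")
        self.atoms = atoms
        self.name = name
        self._coords = np.array([a.position for a in atoms], dtype=float)
        self._symbols = np.array([a.element for a in atoms])
        if len(atoms) > 1:
            tree = cKDTree(self._coords)
            close = tree.query_pairs(0.5)
            if close:
                i, j = sorted(close)[0]
                raise ValueError(
                    f"atoms {i} and {j} are closer than 0.5 Å; not a physical geometry"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) array of positions, Å. A copy; mutating it is safe."""
        return self._coords.copy()

    @property
    def symbols(self) -> np.ndarray:
        return self._symbols.copy()

    @property
    def molar_mass(self) -> float:
        """Molar mass in g/mol."""
        return float(sum(ATOMIC_MASS[s] for s in self._symbols))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "MolecularGeometry":
        """Rigid-body copy: ``x -> rotation @ x + translation``."""
        new = np.asarray(self._coords) @ np.asarray(rotation).T + np.asarray(translation)
        return MolecularGeometry(
            [Atom(s, tuple(p)) for s, p in zip(self._symbols, new)], name=self.name
        )

    def __repr__(self) -> str:
        return f"MolecularGeometry({self.name!r}, N={self.n_atoms})"


@dataclass
class LiquidConfiguration:
    """Packed droplet of rigid molecular copies.

    ``droplet_radius`` bounds the molecular centres of mass, chosen so that
    ``n`` molecules of the template's molar mass realize ``target_density``.
    """

    molecules: list[MolecularGeometry]
    droplet_radius: float
    target_density: float
    contact_distance: float
    seed: int

    def flatten(self, name: str = "droplet") -> MolecularGeometry:
        """Single geometry containing every atom of every molecule."""
        atoms = [a for mol in self.molecules for a in mol.atoms]
        return MolecularGeometry(atoms, name=name)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def realized_density(self) -> float:
        """Mass inside the droplet sphere divided by its volume, g/cm³."""
        mass = sum(m.molar_mass for m in self.molecules)
        volume = 4.0 / 3.0 * np.pi * self.droplet_radius**3
        return mass / (volume * _DENS2NUM)


def read_xyz(path) -> MolecularGeometry:
    """Read a standard XYZ file (count line, comment line, element x y z).

    Atom order and the comment line (as ``name``) are preserved.  Malformed
    counts, unknown elements and non-numeric coordinates raise
    :class:`XYZParseError` naming the offending line.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    try:
        count = int(lines[0].strip())
    except ValueError:
        raise XYZParseError(f"{path}, line 1: expected an atom count") from None
    if count < 1:
        raise XYZParseError(f"{path}, line 1: atom count must be >= 1")
    comment = lines[1] if len(lines) > 1 else ""
    records = [ln for ln in lines[2:] if ln.strip()]
    if len(records) < count:
        raise XYZParseError(
            f"{path}: count line says {count} atoms but only {len(records)} records follow"
        )
    atoms = []
    for k in range(count):
        lineno = k + 3
        parts = records[k].split()
        if len(parts) < 4:
            raise XYZParseError(f"{path}, line {lineno}: expected 'element x y z'")
        el = parts[0]
        if el not in KNOWN_ELEMENTS:
            raise XYZParseError(f"{path}, line {lineno}: unknown element {el!r}")
        try:
            xyz = tuple(float(v) for v in parts[1:4])
        except ValueError:
            raise XYZParseError(
                f"{path}, line {lineno}: non-numeric coordinate"
            ) from None
        atoms.append(Atom(el, xyz))
    return MolecularGeometry(atoms, name=comment)


def write_xyz(geom: MolecularGeometry, path) -> None:
    """Write ``geom`` in standard XYZ layout; round-trips to 1e-6 Å."""
    with open(path, "w") as fh:
        fh.write(f"{geom.n_atoms}\n")
        fh.write((geom.name or "") + "\n")
        for atom in geom.atoms:
            x, y, z = atom.position
            fh.write(f"{atom.element} {x:.8f} {y:.8f} {z:.8f}\n")


# Glycerol (propane-1,2,3-triol, C3H8O3) reference conformer.  Coordinates are
# a fixed MMFF94-optimized geometry at standard bond lengths: bonded C-O
# 1.42-1.44 Å, C-C 1.53 Å, O-H 0.97 Å, C-H 1.10 Å; the 1-3 (geminal)
# heavy-atom distances cluster near 2.4 Å.  Frozen here so every simulation in
# the package refers to one and the same conformer.
_GLYCEROL_XYZ = [
    ("O", -1.828475, -0.538196, 1.131648),
    ("C", -1.302730, 0.380275, 0.184216),
    ("C", 0.038140, -0.088766, -0.384152),
    ("O", 0.489425, 0.805138, -1.412330),
    ("C", 1.122204, -0.152554, 0.695872),
    ("O", 2.353115, -0.567384, 0.098242),
    ("H", -2.030884, -1.369083, 0.667278),
    ("H", -1.194416, 1.356146, 0.670103),
    ("H", -2.036170, 0.512568, -0.618881),
    ("H", -0.063050, -1.081448, -0.838346),
    ("H", -0.161518, 0.771111, -2.135412),
    ("H", 1.293556, 0.831683, 1.143968),
    ("H", 0.867029, -0.864434, 1.485923),
    ("H", 2.453774, 0.004943, -0.688130),
]


def build_glycerol() -> MolecularGeometry:
    """Embedded glycerol reference conformer (14 atoms: 3 C, 3 O, 8 H)."""
    return MolecularGeometry(
        [Atom(el, (x, y, z)) for el, x, y, z in _GLYCEROL_XYZ], name="glycerol C3H8O3"
    )


def pair_distances(geom: MolecularGeometry):
    """All N(N-1)/2 unordered pairs as ``(element_i, element_j, r_ij)``."""
    coords = geom.coords
    syms = geom.symbols
    out = []
    for i in range(len(syms)):
        d = np.linalg.norm(coords[i + 1 :] - coords[i], axis=1)
        for j, r in enumerate(d, start=i + 1):
            out.append((str(syms[i]), str(syms[j]), float(r)))
    return out


# ---------------------------------------------------------------------------
# droplet packing
# ---------------------------------------------------------------------------

def _rotation_from_quaternion(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _axis_rotations(v: np.ndarray, max_angle: float) -> np.ndarray:
    """Rotation matrices for rotation vectors ``v``, angles capped."""
    theta = np.linalg.norm(v, axis=1)
    angle = np.minimum(theta, max_angle)
    k = np.where(theta[:, None] > 1e-12, v / np.maximum(theta, 1e-12)[:, None], 0.0)
    K = np.zeros((len(v), 3, 3))
    K[:, 0, 1] = -k[:, 2]
    K[:, 0, 2] = k[:, 1]
    K[:, 1, 0] = k[:, 2]
    K[:, 1, 2] = -k[:, 0]
    K[:, 2, 0] = -k[:, 1]
    K[:, 2, 1] = k[:, 0]
    eye = np.eye(3)
    return (
        eye
        + np.sin(angle)[:, None, None] * K
        + (1 - np.cos(angle))[:, None, None] * (K @ K)
    )


def droplet_radius_for(template: MolecularGeometry, n_molecules: int, density: float) -> float:
    """Sphere radius (Å) holding ``n_molecules`` at ``density`` g/cm³."""
    number_density = density * _DENS2NUM / template.molar_mass
    volume = n_molecules / number_density
    return float((3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0))


def pack_droplet(
    template: MolecularGeometry,
    n_molecules: int,
    density: float = 1.26,
    contact_distance: float = 3.2,
    seed: int = 0,
    max_iter: int = 200_000,
) -> LiquidConfiguration:
    """Pack rigid copies of ``template`` into a spherical droplet.

    Molecules receive uniformly random orientations and start at random
    positions in an inflated sphere; pairwise heavy-atom overlaps shallower
    than ``contact_distance`` are then relaxed by rigid-body moves (forces and
    torques from a linear-ramp repulsion, with capped step sizes) while the
    droplet is gradually compressed to the radius that realizes ``density``.
    The result is deterministic for a fixed seed.

    Raises
    ------
    PackingError
        If the overlap relaxation has not produced a contact-free packing at
        the target radius within ``max_iter`` total iterations; the error
        message reports the iterations spent and the radius reached.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if density <= 0 or contact_distance <= 0:
        raise ValueError("density and contact_distance must be positive")

    rng = np.random.default_rng(seed)
    target_r = droplet_radius_for(template, n_molecules, density)

    base = template.coords
    base -= base.mean(axis=0)
    heavy_mask = template.symbols != "H"
    base_heavy = base[heavy_mask]
    n_heavy = base_heavy.shape[0]

    quats = rng.normal(size=(n_molecules, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    rots = np.stack([_rotation_from_quaternion(q) for q in quats])

    if n_molecules == 1:
        mols = [template.transformed(rots[0], np.zeros(3))]
        return LiquidConfiguration(mols, target_r, density, contact_distance, seed)

    radius = target_r * 1.35
    centers = rng.normal(size=(n_molecules, 3))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    centers *= radius * rng.uniform(0.0, 1.0, (n_molecules, 1)) ** (1.0 / 3.0)

    skin = 0.02  # relax slightly beyond the hard limit so the final check is strict
    iterations = 0
    while iterations < max_iter:
        converged = False
        while iterations < max_iter:
            iterations += 1
            heavy = np.einsum("kij,aj->kai", rots, base_heavy) + centers[:, None, :]
            flat = heavy.reshape(-1, 3)
            tree = cKDTree(flat)
            pairs = tree.query_pairs(contact_distance + skin, output_type="ndarray")
            if len(pairs):
                mol_i = pairs[:, 0] // n_heavy
                mol_j = pairs[:, 1] // n_heavy
                keep = mol_i != mol_j
                pairs, mol_i, mol_j = pairs[keep], mol_i[keep], mol_j[keep]
            if len(pairs) == 0:
                strict = tree.query_pairs(contact_distance, output_type="ndarray")
                if len(strict) == 0 or np.all(
                    strict[:, 0] // n_heavy == strict[:, 1] // n_heavy
                ):
                    converged = True
                    break
            delta = flat[pairs[:, 0]] - flat[pairs[:, 1]]
            dist = np.linalg.norm(delta, axis=1)
            force = ((contact_distance + skin - dist) / dist)[:, None] * delta
            net_force = np.zeros_like(centers)
            net_torque = np.zeros_like(centers)
            arm_i = flat[pairs[:, 0]] - centers[mol_i]
            arm_j = flat[pairs[:, 1]] - centers[mol_j]
            np.add.at(net_force, mol_i, force)
            np.add.at(net_force, mol_j, -force)
            np.add.at(net_torque, mol_i, np.cross(arm_i, force))
            np.add.at(net_torque, mol_j, np.cross(arm_j, -force))
            norm = np.linalg.norm(net_force, axis=1, keepdims=True)
            step = np.where(norm > 0.4, 0.4 * net_force / np.maximum(norm, 1e-12), net_force)
            centers = centers + step
            rots = _axis_rotations(0.5 * net_torque, 0.15) @ rots
            r_c = np.linalg.norm(centers, axis=1)
            outside = r_c > radius
            if np.any(outside):
                centers[outside] *= (radius / r_c[outside])[:, None]
        if not converged:
            break
        if radius <= target_r:
            mols = [
                template.transformed(rots[k], centers[k]) for k in range(n_molecules)
            ]
            return LiquidConfiguration(mols, target_r, density, contact_distance, seed)
        radius = max(target_r, radius * 0.985)
        r_c = np.linalg.norm(centers, axis=1)
        outside = r_c > radius
        if np.any(outside):
            centers[outside] *= (radius / r_c[outside])[:, None]

    raise PackingError(
        f"could not pack {n_molecules} molecules at {density} g/cm³ with "
        f"{contact_distance} Å contact: stalled at radius {radius:.2f} Å "
        f"(target {target_r:.2f} Å) after {iterations} relaxation iterations"
    )
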
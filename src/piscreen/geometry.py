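"""Molecular geometries, bond perception and pi-system identification.

The screening method treats only the pi electrons of a conjugated molecule:
every sp2/sp heavy atom contributes one p orbital, and lone-pair donors
(pyrrole-type N, ether O, thioether S) contribute two electrons to the pi
count instead of one.  Everything downstream (parameter assembly, SCF, CIS)
works on the :class:`PiSystem` produced here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import COVALENT_RADII
from .exceptions import (
    OddElectronError,
    ParseError,
    UnsupportedCenterError,
    UnsupportedElementError,
)

# Elements accepted in input files.  H and the halogens are sigma-framework
# atoms only; the pi-parameterized subset lives in the valence-state table.
KNOWN_ELEMENTS = frozenset(
    "H He B C N O F Ne Si P S Cl Ar Se Br Kr I".split()
)

#: default scale applied to the sum of covalent radii in bond perception
DEFAULT_CUTOFF_SCALE = 1.15


@dataclass
class Geometry:
    """Element symbols and cartesian coordinates (angstrom) of one molecule.

    ``bonds`` is an optional explicit bond list (pairs of 0-based atom
    indices, e.g. from an SDF bond block); when present it always overrides
    distance-based perception.
    """

    symbols: list[str]
    coords: np.ndarray  # (n_atoms, 3) angstrom
    bonds: list[tuple[int, int]] | None = None
    identifier: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.symbols) < 1:
            raise ParseError("geometry needs at least one atom")
        if self.coords.shape != (len(self.symbols), 3):
            raise ParseError("coordinate array must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ParseError("non-finite coordinate encountered")
        for i, sym in enumerate(self.symbols):
            if sym not in KNOWN_ELEMENTS:
                raise UnsupportedElementError(
                    f"element {sym!r} (atom {i}) is not supported; "
                    f"known elements: {sorted(KNOWN_ELEMENTS)}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def heavy_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.symbols) if s != "H"]


def load_geometry(path: str | Path, fmt: str | None = None) -> Geometry:
    """Read a structure from an XYZ or MDL MOL/SDF (V2000) file.

    The format is inferred from the suffix unless ``fmt`` ("xyz" or "sdf")
    is given.  Coordinates are kept exactly as printed; an SDF bond block is
    retained on the returned :class:`Geometry`.
    """
    path = Path(path)
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() in {".sdf", ".mol"} else "xyz"
    text = path.read_text()
    if fmt == "xyz":
        geom = parse_xyz(text)
    elif fmt == "sdf":
        geom = parse_sdf(text)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not geom.identifier:
        geom.identifier = path.stem
    return geom


def parse_xyz(text: str) -> Geometry:
    lines = text.splitlines()
    if not lines:
        raise ParseError("empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line 1: expected atom count, got {lines[0]!r}") from exc
    if len(lines) < n + 2:
        raise ParseError(f"XYZ header announces {n} atoms but file has fewer lines")
    comment = lines[1].strip() if len(lines) > 1 else ""
    symbols: list[str] = []
    coords: list[list[float]] = []
    for ln in range(2, 2 + n):
        parts = lines[ln].split()
        if len(parts) < 4:
            raise ParseError(f"line {ln + 1}: expected 'element x y z'")
        sym = parts[0].capitalize() if len(parts[0]) > 1 else parts[0].upper()
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError as exc:
            raise ParseError(f"line {ln + 1}: bad coordinate field") from exc
        symbols.append(sym)
        coords.append(xyz)
    return Geometry(symbols, np.array(coords), identifier=comment)


def parse_sdf(text: str) -> Geometry:
    """Parse the first molecule of an MDL V2000 MOL/SDF block (via RDKit).

    Sanitization is disabled so that exotic conjugated species survive
    unchanged; coordinates and the explicit bond block are kept as printed.
    """
    from rdkit import Chem

    mol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
    if mol is None:
        raise ParseError("RDKit could not parse the MOL/SDF block")
    if mol.GetNumConformers() == 0:
        raise ParseError("MOL/SDF block carries no coordinates")
    conf = mol.GetConformer()
    symbols = [atom.GetSymbol() for atom in mol.GetAtoms()]
    coords = np.array([[conf.GetAtomPosition(i).x,
                        conf.GetAtomPosition(i).y,
                        conf.GetAtomPosition(i).z]
                       for i in range(mol.GetNumAtoms())])
    bonds = sorted(
        (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
         max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
    )
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    return Geometry(symbols, coords, bonds=bonds, identifier=name)


def geometry_from_smiles(smiles: str, seed: int = 42,
                         optimize: bool = True) -> Geometry:
    """Optional adapter: 3D-embed a SMILES string with RDKit.

    Convenience only; screening-quality work should start from optimized
    geometries.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"RDKit could not parse SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    if AllChem.EmbedMolecule(mol, randomSeed=seed) != 0:
        raise ParseError(f"3D embedding failed for {smiles!r}")
    if optimize:
        AllChem.MMFFOptimizeMolecule(mol)
    conf = mol.GetConformer()
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    coords = np.array([[conf.GetAtomPosition(i).x,
                        conf.GetAtomPosition(i).y,
                        conf.GetAtomPosition(i).z]
                       for i in range(mol.GetNumAtoms())])
    bonds = sorted(
        (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
         max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
    )
    return Geometry(symbols, coords, bonds=bonds, identifier=smiles)


def write_xyz(geom: Geometry, path: str | Path, precision: int = 8) -> None:
    lines = [str(geom.n_atoms), geom.identifier]
    for sym, (x, y, z) in zip(geom.symbols, geom.coords):
        lines.append(f"{sym:<3s} {x:.{precision}f} {y:.{precision}f} {z:.{precision}f}")
    Path(path).write_text("\n".join(lines) + "\n")


def perceive_connectivity(
    geom: Geometry, cutoff_scale: float = DEFAULT_CUTOFF_SCALE
) -> list[tuple[int, int]]:
    """Distance-based bond perception.

    Two atoms are bonded when their distance is below ``cutoff_scale`` times
    the sum of their covalent radii.  Explicit bonds on the geometry win.
    """
    if geom.bonds is not None:
        return list(geom.bonds)
    bonds = []
    for i in range(geom.n_atoms):
        ri = COVALENT_RADII.get(geom.symbols[i], 0.75)
        for j in range(i + 1, geom.n_atoms):
            rj = COVALENT_RADII.get(geom.symbols[j], 0.75)
            d = float(np.linalg.norm(geom.coords[i] - geom.coords[j]))
            if d < cutoff_scale * (ri + rj):
                bonds.append((i, j))
    return bonds


# Valence-type classification: (element, number of sigma neighbors) -> (key, n_pi)
# sp2 carbon always donates 1 electron; divalent N (pyridine-like) donates 1,
# trivalent N (pyrrole/amine-like) donates its lone pair (2); monovalent O
# (carbonyl) 1, divalent O (ether/hydroxyl/furan) 2; the S rules mirror O.
_PI_RULES: dict[tuple[str, int], tuple[str, int]] = {
    ("C", 1): ("C", 1),
    ("C", 2): ("C", 1),
    ("C", 3): ("C", 1),
    ("N", 1): ("N1", 1),
    ("N", 2): ("N1", 1),
    ("N", 3): ("N2", 2),
    ("O", 1): ("O1", 1),
    ("O", 2): ("O2", 2),
    ("S", 1): ("S1", 1),
    ("S", 2): ("S2", 2),
}

#: elements that never join a pi system and never raise (sigma substituents)
_SIGMA_ONLY = frozenset({"H", "F", "Cl", "Br", "I"})


@dataclass
class PiSystem:
    """The pi network extracted from a geometry.

    ``centers`` indexes into the parent geometry; ``valence_types`` are keys
    into the valence-state table; ``n_pi`` are per-center electron counts
    (1 for ordinary sp2 atoms, 2 for lone-pair donors); ``adjacency`` is a
    symmetric 0/1 matrix over centers and ``twist`` the per-bond twist angle
    theta_rs in degrees, folded to [0, 90].
    """

    centers: list[int]
    valence_types: list[str]
    n_pi: list[int]
    adjacency: np.ndarray
    twist: np.ndarray  # degrees, same shape as adjacency
    geometry: Geometry
    warnings: list[str] = field(default_factory=list)

    @property
    def n_centers(self) -> int:
        return len(self.centers)

    @property
    def n_electrons(self) -> int:
        return int(sum(self.n_pi))

    @property
    def coords(self) -> np.ndarray:
        return self.geometry.coords[self.centers]

    def bonded_pairs(self) -> list[tuple[int, int]]:
        n = self.n_centers
        return [(r, s) for r in range(n) for s in range(r + 1, n)
                if self.adjacency[r, s]]


def perceive_pi_system(
    geom: Geometry,
    bonds: list[tuple[int, int]] | None = None,
    cutoff_scale: float = DEFAULT_CUTOFF_SCALE,
) -> PiSystem:
    """Identify the pi centers of a geometry and their electron counts.

    Raises :class:`UnsupportedCenterError` when an atom without PPP
    parameters (for example four-coordinate P) is wired into the conjugated
    network, and :class:`OddElectronError` when the perceived pi-electron
    count is odd (the closed-shell SCF downstream would be meaningless).
    """
    if bonds is None:
        bonds = perceive_connectivity(geom, cutoff_scale)
    nbrs: dict[int, list[int]] = {i: [] for i in range(geom.n_atoms)}
    for a, b in bonds:
        nbrs[a].append(b)
        nbrs[b].append(a)

    candidates: dict[int, tuple[str, int]] = {}
    for i in geom.heavy_indices():
        sym = geom.symbols[i]
        if sym in _SIGMA_ONLY:
            continue
        degree = len(nbrs[i])
        rule = _PI_RULES.get((sym, degree))
        if rule is not None:
            candidates[i] = rule
    # sp3 / hypervalent atoms: silently sigma for C, fatal for anything that
    # would bridge two or more pi centers without parameters (e.g. PR4)
    warnings: list[str] = []
    for i in geom.heavy_indices():
        if i in candidates or geom.symbols[i] in _SIGMA_ONLY:
            continue
        sym = geom.symbols[i]
        n_pi_nbrs = sum(1 for j in nbrs[i] if j in candidates)
        if sym != "C" and n_pi_nbrs >= 2:
            raise UnsupportedCenterError(
                f"atom {i} ({sym}, {len(nbrs[i])}-coordinate) bridges the pi "
                "system but has no PPP parameters"
            )

    # keep only candidates wired into a conjugated fragment
    centers = [i for i in sorted(candidates)
               if any(j in candidates for j in nbrs[i])]
    dropped = sorted(set(candidates) - set(centers))
    if dropped:
        warnings.append(f"isolated pi candidates dropped: {dropped}")
    if len(centers) < 2:
        raise UnsupportedCenterError("no conjugated pi system found")

    index_of = {atom: k for k, atom in enumerate(centers)}
    n = len(centers)
    adjacency = np.zeros((n, n), dtype=int)
    for a, b in bonds:
        if a in index_of and b in index_of:
            adjacency[index_of[a], index_of[b]] = 1
            adjacency[index_of[b], index_of[a]] = 1

    # connectivity check over pi centers
    n_components = _count_components(adjacency)
    if n_components > 1:
        warnings.append(f"pi system has {n_components} disconnected components")

    valence_types = [candidates[i][0] for i in centers]
    n_pi = [candidates[i][1] for i in centers]
    total = sum(n_pi)
    if total % 2 != 0:
        raise OddElectronError(
            f"pi system carries {total} electrons; closed-shell treatment "
            "requires an even count"
        )

    ps = PiSystem(centers, valence_types, n_pi, adjacency,
                  np.zeros((n, n)), geom, warnings)
    ps.twist = twist_angles(ps)
    return ps


def _count_components(adjacency: np.ndarray) -> int:
    n = len(adjacency)
    seen: set[int] = set()
    comps = 0
    for start in range(n):
        if start in seen:
            continue
        comps += 1
        stack = [start]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            stack.extend(int(w) for w in np.nonzero(adjacency[v])[0])
    return comps


def dihedral_deg(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                 p3: np.ndarray) -> float:
    """Dihedral angle p0-p1-p2-p3 in degrees, in [0, 180]."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    denom = np.linalg.norm(n1) * np.linalg.norm(n2)
    if denom < 1e-12:
        return 0.0
    cosang = float(np.clip(np.dot(n1, n2) / denom, -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def twist_angles(ps: PiSystem) -> np.ndarray:
    """Per-bond p-orbital twist angles theta_rs (degrees).

    theta_rs is the average over all dihedrals a-r-s-b with a, b pi
    neighbors of r and s, each folded to [0, 90] (only |cos theta| is
    physical).  Bonds without any flanking pi neighbor (ethylene-like) get
    theta = 0 by convention.
    """
    n = ps.n_centers
    coords = ps.coords
    theta = np.zeros((n, n))
    for r, s in ps.bonded_pairs():
        folded = []
        for a in np.nonzero(ps.adjacency[r])[0]:
            if a == s:
                continue
            for b in np.nonzero(ps.adjacency[s])[0]:
                if b == r or b == a:
                    continue
                d = dihedral_deg(coords[a], coords[r], coords[s], coords[b])
                folded.append(min(d, 180.0 - d))
        if folded:
            theta[r, s] = theta[s, r] = float(np.mean(folded))
    return theta
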
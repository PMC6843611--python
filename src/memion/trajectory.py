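"""Data model and I/O for membrane trajectories and the atom-role map.

The in-memory :class:`Trajectory` is deliberately small: a flat atom table
(species, role, partial charge per atom) plus coordinate/time/box arrays in
nm and ns, with the membrane normal fixed along the third axis (Oz).  File
I/O (GRO, PDB, XTC) is delegated to MDAnalysis; this module only converts
units (A -> nm, ps -> ns) and attaches the role annotations that every
downstream geometric analysis relies on.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import yaml

from .errors import FormatError, ValidationError


class Species(str, Enum):
    DOPC = "DOPC"
    CHOL = "CHOL"
    KOR105 = "KOR105"
    BAC = "BAC"
    SDS = "SDS"
    WATER = "WATER"
    ION = "ION"
    OTHER = "OTHER"


class Role(str, Enum):
    N_PLUS = "N_PLUS"          # quaternary nitrogen of a cationic surfactant
    PARA_C = "PARA_C"          # para carbon of the aromatic ring
    TERM_C = "TERM_C"          # terminal carbon of the alkyl tail
    SULFATE_S = "SULFATE_S"    # sulfur of the SDS sulfate group
    LIPID_P = "LIPID_P"        # phosphorus of the lipid headgroup
    LIPID_N = "LIPID_N"        # choline nitrogen of the lipid headgroup
    CHOL_O = "CHOL_O"          # hydroxyl oxygen of cholesterol
    NONE = "NONE"


#: residue-name synonyms recognised when reading coordinate files
_RESNAME_TO_SPECIES = {
    "DOPC": Species.DOPC,
    "CHOL": Species.CHOL,
    "CHL1": Species.CHOL,
    "KOR105": Species.KOR105,
    "KOR": Species.KOR105,
    "BAC": Species.BAC,
    "SDS": Species.SDS,
    "SOL": Species.WATER,
    "WAT": Species.WATER,
    "TIP3": Species.WATER,
    "HOH": Species.WATER,
    "K": Species.ION,
    "CL": Species.ION,
    "NA": Species.ION,
    "ION": Species.ION,
}

#: roles each analysed species must carry after :func:`assign_roles`
REQUIRED_ROLES: Mapping[Species, tuple[Role, ...]] = {
    Species.KOR105: (Role.N_PLUS, Role.PARA_C, Role.TERM_C),
    Species.BAC: (Role.N_PLUS, Role.PARA_C, Role.TERM_C),
    Species.SDS: (Role.SULFATE_S, Role.TERM_C),
    Species.DOPC: (Role.LIPID_P, Role.LIPID_N),
    Species.CHOL: (Role.CHOL_O,),
}

#: atom used to decide which leaflet a molecule belongs to
LEAFLET_REFERENCE_ROLES = (Role.N_PLUS, Role.SULFATE_S, Role.CHOL_O, Role.LIPID_P)


@dataclass
class AtomRecord:
    """One atom of the topology, annotated with its analysis role."""

    atom_id: int
    molecule_id: int
    species: Species
    atom_name: str
    role: Role = Role.NONE
    partial_charge: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.partial_charge):
            raise ValidationError(
                f"atom {self.atom_id}: partial charge must be finite"
            )


@dataclass
class Frame:
    """A single snapshot: time (ns), orthorhombic box edges (nm), coords (nm)."""

    time: float
    box: np.ndarray            # (3,) edge lengths
    coords: np.ndarray         # (n_atoms, 3)


@dataclass
class Trajectory:
    """Topology plus frames; the membrane normal is the third axis (Oz)."""

    atoms: list[AtomRecord]
    coords: np.ndarray         # (n_frames, n_atoms, 3) nm
    times: np.ndarray          # (n_frames,) ns
    boxes: np.ndarray          # (n_frames, 3) nm

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise FormatError("a trajectory needs at least one frame")
        if self.coords.shape[1] != len(self.atoms):
            raise FormatError(
                f"coordinate count ({self.coords.shape[1]}) does not match "
                f"topology atom count ({len(self.atoms)})"
            )
        if np.any(np.diff(self.times) <= 0):
            raise FormatError("frame times must be strictly increasing")
        if np.any(self.boxes <= 0):
            raise FormatError("box edge lengths must be positive")

    # -- convenience views ------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Frame:
        return Frame(time=self.times[i], box=self.boxes[i], coords=self.coords[i])

    def iter_frames(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def atom_index(
        self,
        species: Optional[Sequence[Species | str]] = None,
        roles: Optional[Sequence[Role | str]] = None,
        atom_names: Optional[Sequence[str]] = None,
    ) -> np.ndarray:
        """Indices of atoms matching all given criteria (criteria are ANDed)."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if species is not None:
            wanted = {Species(s) for s in species}
            mask &= np.array([a.species in wanted for a in self.atoms])
        if roles is not None:
            wanted_r = {Role(r) for r in roles}
            mask &= np.array([a.role in wanted_r for a in self.atoms])
        if atom_names is not None:
            names = set(atom_names)
            mask &= np.array([a.atom_name in names for a in self.atoms])
        return np.flatnonzero(mask)

    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms])

    def molecule_ids(self) -> np.ndarray:
        return np.array([a.molecule_id for a in self.atoms])

    def window_frames(self, window: Optional[tuple] = None) -> np.ndarray:
        """Frame indices inside an analysis window.

        ``window`` is ``None`` (all frames), ``(t0, t1)`` in ns, or
        ``("last", n_ns)`` mirroring the usual "last N ns" convention.
        """
        if window is None:
            return np.arange(self.n_frames)
        if len(window) == 2 and window[0] == "last":
            t1 = self.times[-1]
            t0 = t1 - float(window[1])
        else:
            t0, t1 = float(window[0]), float(window[1])
        idx = np.flatnonzero((self.times >= t0) & (self.times <= t1))
        return idx


# ---------------------------------------------------------------------------
# File I/O (via MDAnalysis)
# ---------------------------------------------------------------------------

def _species_from_resname(resname: str) -> Species:
    return _RESNAME_TO_SPECIES.get(resname.strip().upper(), Species.OTHER)


def read_trajectory(topology_path, trajectory_path=None) -> Trajectory:
    """Read a GRO/PDB topology and optional XTC/multi-model-PDB trajectory.

    Coordinates are returned in nm and times in ns.  A single coordinate
    file yields a one-frame trajectory.  Triclinic boxes are rejected:
    every analysis here assumes a flat bilayer in an orthorhombic cell.
    """
    import MDAnalysis as mda

    topology_path = Path(topology_path)
    if not topology_path.exists():
        raise FormatError(f"topology file not found: {topology_path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if trajectory_path is None:
                u = mda.Universe(str(topology_path))
            else:
                u = mda.Universe(str(topology_path), str(trajectory_path))
    except ValueError as exc:
        # MDAnalysis raises ValueError on atom-count mismatch
        msg = str(exc)
        raise FormatError(
            f"topology/trajectory mismatch or unreadable input: {msg}"
        ) from exc
    except OSError as exc:
        raise FormatError(f"cannot read input: {exc}") from exc

    atoms: list[AtomRecord] = []
    # molecule_id from residue index; GRO/PDB residues are the molecules here
    for i, a in enumerate(u.atoms):
        atoms.append(
            AtomRecord(
                atom_id=i,
                molecule_id=int(a.resindex),
                species=_species_from_resname(a.resname),
                atom_name=str(a.name).strip(),
            )
        )

    coords, times, boxes = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            if ts.dimensions is None or np.any(np.asarray(ts.dimensions[:3]) <= 0):
                raise FormatError("input has no box information")
            angles = np.asarray(ts.dimensions[3:6], dtype=float)
            if not np.allclose(angles, 90.0, atol=1e-3):
                raise FormatError(
                    f"triclinic box (angles {angles}) not supported; "
                    "analyses assume an orthorhombic cell"
                )
            coords.append(ts.positions / 10.0)          # A -> nm
            boxes.append(np.asarray(ts.dimensions[:3], dtype=float) / 10.0)
            times.append(float(ts.time) / 1000.0)       # ps -> ns

    times_arr = np.asarray(times)
    if len(times_arr) > 1 and np.any(np.diff(times_arr) <= 0):
        # PDB MODELs (and GRO without time stamps) carry no usable clock;
        # fall back to the frame index in ns
        times_arr = np.arange(len(times_arr), dtype=float)

    return Trajectory(atoms=atoms, coords=np.asarray(coords),
                      times=times_arr, boxes=np.asarray(boxes))


def _as_universe(traj: Trajectory):
    """Build an MDAnalysis Universe mirroring this trajectory (A, ps)."""
    import MDAnalysis as mda

    n = traj.n_atoms
    mol_ids = traj.molecule_ids()
    _, resindices = np.unique(mol_ids, return_inverse=True)
    n_res = resindices.max() + 1 if n else 0
    resnames = [""] * n_res
    for a, ri in zip(traj.atoms, resindices):
        name = a.species.value if a.species != Species.KOR105 else "KOR"
        resnames[ri] = name
    u = mda.Universe.empty(
        n_atoms=n,
        n_residues=n_res,
        atom_resindex=resindices,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.atom_name for a in traj.atoms])
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", np.arange(1, n_res + 1))
    return u


def write_gro(traj: Trajectory, path, frame: int = 0) -> None:
    """Write one frame as a GRO file (3-decimal nm precision)."""
    import MDAnalysis as mda

    u = _as_universe(traj)
    u.atoms.positions = traj.coords[frame] * 10.0
    u.dimensions = np.concatenate([traj.boxes[frame] * 10.0, [90.0, 90.0, 90.0]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.n_atoms) as w:
            w.write(u.atoms)


def write_xtc(traj: Trajectory, path) -> None:
    """Write all frames as an XTC trajectory."""
    import MDAnalysis as mda

    u = _as_universe(traj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.n_atoms) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.coords[i] * 10.0
                u.dimensions = np.concatenate(
                    [traj.boxes[i] * 10.0, [90.0, 90.0, 90.0]]
                )
                u.trajectory.ts.time = traj.times[i] * 1000.0
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# Role maps
# ---------------------------------------------------------------------------

def load_role_map(path) -> dict:
    """Load a YAML role map: species -> {atom_name: {role, charge}}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    role_map: dict = {}
    for species, entries in (raw or {}).items():
        sp = Species(species)
        role_map[sp] = {}
        for atom_name, cfg in entries.items():
            role_map[sp][str(atom_name)] = {
                "role": Role(cfg["role"]),
                "charge": float(cfg.get("charge", 0.0)),
            }
    return role_map


def _normalise_role_map(role_map: Mapping) -> dict:
    out: dict = {}
    for species, entries in role_map.items():
        sp = Species(species)
        out[sp] = {}
        for atom_name, cfg in entries.items():
            if isinstance(cfg, Mapping):
                role = Role(cfg["role"])
                charge = float(cfg.get("charge", 0.0))
            else:  # bare role, zero charge
                role, charge = Role(cfg), 0.0
            out[sp][str(atom_name)] = {"role": role, "charge": charge}
    return out


def assign_roles(
    traj: Trajectory,
    role_map: Mapping,
    require: Optional[Mapping[Species, tuple[Role, ...]]] = None,
) -> Trajectory:
    """Tag atoms with roles and partial charges from a (species, atom_name) map.

    Returns a new Trajectory sharing coordinate arrays.  Assignment is
    idempotent.  Every molecule of an analysed species must end up with
    exactly its required roles (``require`` defaults to the standard table);
    violations raise :class:`ValidationError` naming the molecule.
    """
    rm = _normalise_role_map(role_map)
    if require is None:
        require = REQUIRED_ROLES

    new_atoms = []
    for a in traj.atoms:
        entry = rm.get(a.species, {}).get(a.atom_name)
        if entry is not None:
            new_atoms.append(
                replace(a, role=entry["role"], partial_charge=entry["charge"])
            )
        else:
            new_atoms.append(copy.copy(a))

    # validate per-molecule role coverage
    per_mol: dict[int, list[Role]] = {}
    mol_species: dict[int, Species] = {}
    for a in new_atoms:
        mol_species[a.molecule_id] = a.species
        if a.role != Role.NONE:
            per_mol.setdefault(a.molecule_id, []).append(a.role)
    problems = []
    for mol_id, sp in mol_species.items():
        needed = require.get(sp)
        if not needed:
            continue
        have = per_mol.get(mol_id, [])
        for role in needed:
            count = sum(1 for r in have if r == role)
            if count != 1:
                problems.append((mol_id, sp.value, role.value, count))
    if problems:
        lines = ", ".join(
            f"molecule {m} ({s}): role {r} occurs {c} times (need 1)"
            for m, s, r, c in problems[:10]
        )
        more = "" if len(problems) <= 10 else f" (+{len(problems) - 10} more)"
        raise ValidationError(f"role map incomplete: {lines}{more}")

    return Trajectory(
        atoms=new_atoms, coords=traj.coords, times=traj.times, boxes=traj.boxes
    )
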
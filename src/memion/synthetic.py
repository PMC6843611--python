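"""Synthetic membrane systems and measurement curves with known ground truth.

The generator does not integrate any dynamics; it emulates the *statistical
structure* of an equilibrated bilayer so every analysis stage can be tested
against a manifest of known parameters:

* lipids sit on jittered lattices at z = +/- leaflet_z, carrying a -1 e
  point charge at the phosphorus depth and +1 e at the choline depth
  0.1 nm further out;
* surfactants are anchor triplets (N+/S, para-ring C, terminal tail C)
  whose head and tail polar angles are independent von Mises draws about
  prescribed modes (eta0, theta0) with concentration kappa, measured from
  the outward normal of their leaflet;
* cholesterol hydroxyl oxygens follow a Thomas clustered point process
  (Poisson parents, Gaussian offspring) per leaflet;
* frames add i.i.d. Gaussian positional jitter (roughness) per frame;
* boundary-potential curves and IFC capacitance scans come from the
  electrostatics model plus seeded Gaussian noise.

Every draw goes through one ``numpy.random.Generator`` seeded from the
spec, so the same seed reproduces the same system bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .electrostatics import (
    AdsorptionParams,
    BoundaryPotentialCurve,
    ElectrolyteConditions,
    IFCScan,
    adsorption_curve,
)
from .errors import GenerationError
from .trajectory import AtomRecord, Role, Species, Trajectory

# anchor-triplet geometry (nm): head vector N+ -> para C, tail vector -> terminal C
H_LENGTH = 0.45
T_LENGTH = 1.30
LIPID_N_OFFSET = 0.1       # choline sits 0.1 nm outside the phosphorus plane
CHOL_O_DEPTH_OFFSET = 0.3  # cholesterol O sits 0.3 nm inside the phosphorus plane

DEFAULT_CHARGES = {
    Role.LIPID_P: -1.0,
    Role.LIPID_N: +1.0,
    Role.N_PLUS: +1.0,
    Role.SULFATE_S: -1.0,
    Role.PARA_C: 0.0,
    Role.TERM_C: 0.0,
    Role.CHOL_O: 0.0,
}


@dataclass
class SurfactantSpec:
    species: str = "KOR105"        # KOR105 | BAC | SDS
    count: int = 0
    eta0_deg: float = 130.0        # head-vector mode (ignored for SDS)
    theta0_deg: float = 150.0      # tail-vector mode
    kappa: float = 8.0             # von Mises concentration
    nplus_depth_z: float = 2.5     # |z| of the charged anchor, nm


@dataclass
class CholesterolSpec:
    count: int = 0
    thomas_parent_rate: float = 0.05   # parents per nm^2 of leaflet
    offspring_sigma: float = 0.3       # nm, Gaussian spread around a parent


@dataclass
class SyntheticSpec:
    n_lipids_per_leaflet: int = 100
    leaflet_z: float = 1.8             # nm, half-distance between P planes
    roughness_sigma: float = 0.05      # nm, per-frame positional jitter
    area_per_lipid: float = 0.7        # nm^2
    surfactants: list = field(default_factory=list)
    cholesterol: CholesterolSpec = field(default_factory=CholesterolSpec)
    charges: dict = field(default_factory=lambda: dict(DEFAULT_CHARGES))
    n_frames: int = 10
    frame_dt: float = 1.0              # ns
    seed: int = 0
    box_edge_xy: Optional[float] = None  # nm; None = sized from molecule count

    def __post_init__(self) -> None:
        if self.n_lipids_per_leaflet < 0 or self.cholesterol.count < 0:
            raise GenerationError("counts must be non-negative")
        for s in self.surfactants:
            if s.count < 0 or s.kappa < 0:
                raise GenerationError("surfactant counts and kappa must be >= 0")
        if self.n_frames < 1 or self.frame_dt <= 0:
            raise GenerationError("need n_frames >= 1 and frame_dt > 0")


@dataclass
class GroundTruthManifest:
    """The spec plus every realized draw that determined the trajectory."""

    spec: SyntheticSpec
    box: np.ndarray
    lipids: list                 # dicts: molecule_id, leaflet, x, y
    surfactants: list            # dicts incl. realized eta/theta draws (deg)
    cholesterol: list            # dicts incl. parent index and position

    def to_json(self, path) -> None:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, Role):
                return o.value
            raise TypeError(f"cannot serialise {type(o)}")

        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, default=default, indent=1)


def _fold_polar(draws: np.ndarray) -> np.ndarray:
    """Wrap circular draws into (-pi, pi] and reflect into the polar range [0, pi]."""
    wrapped = np.mod(draws + np.pi, 2 * np.pi) - np.pi
    return np.abs(wrapped)


def _folded_vonmises_mean(mu: float, kappa: float) -> float:
    """Mean of |vM(mu, kappa)| folded into [0, pi] (numerical quadrature)."""
    x = np.linspace(0.0, np.pi, 2001)
    # folded density: contributions from +x and -x on the circle
    dens = np.exp(kappa * np.cos(x - mu)) + np.exp(kappa * np.cos(x + mu))
    dens /= np.trapezoid(dens, x)
    return float(np.trapezoid(x * dens, x))


def _mean_corrected_mu(target: float, kappa: float) -> float:
    """Draw centre whose folded von Mises mean equals the prescribed angle.

    Reflection at the poles skews the mean of a folded von Mises draw
    slightly toward 90 deg; the generator's contract is that realized polar
    angles have mean equal to the prescribed eta0/theta0, so the circular
    mean is offset to compensate.  For kappa = 0 the fold is uniform and no
    centre reproduces an arbitrary mean; the target itself is returned.
    """
    if kappa <= 0:
        return target
    from scipy.optimize import brentq

    lo, hi = max(target - 0.5, 0.0), min(target + 0.5, np.pi + 0.5)
    f = lambda m: _folded_vonmises_mean(m, kappa) - target
    if f(lo) * f(hi) > 0:
        return target
    return float(brentq(f, lo, hi, xtol=1e-10))


def _unit_from_polar(polar: np.ndarray, azimuth: np.ndarray, sign: float) -> np.ndarray:
    """Unit vectors at polar angle from the outward normal sign * +Oz."""
    st = np.sin(polar)
    return np.stack(
        [st * np.cos(azimuth), st * np.sin(azimuth), sign * np.cos(polar)], axis=-1
    )


def generate_system(spec: SyntheticSpec):
    """Build a synthetic bilayer trajectory and its ground-truth manifest.

    Returns ``(Trajectory, GroundTruthManifest)``.  Atoms come with roles
    and partial charges pre-assigned; writing to GRO/XTC and re-reading
    with :func:`default_role_map` reproduces the same annotations.
    """
    rng = np.random.default_rng(spec.seed)
    spacing = math.sqrt(spec.area_per_lipid)

    surf_split = []  # per surfactant spec: (upper_count, lower_count)
    for s in spec.surfactants:
        up = (s.count + 1) // 2
        surf_split.append((up, s.count - up))
    sites_needed = spec.n_lipids_per_leaflet + max(
        (sum(u for u, _ in surf_split), sum(l for _, l in surf_split)), default=0
    )

    if spec.box_edge_xy is None:
        nx = max(1, math.ceil(math.sqrt(max(sites_needed, 1))))
        box_xy = nx * spacing
    else:
        box_xy = spec.box_edge_xy
        nx = int(box_xy / spacing)
        if nx * nx < sites_needed:
            raise GenerationError(
                f"lattice capacity {nx * nx} sites per leaflet cannot hold "
                f"{sites_needed} molecules (box {box_xy} nm, spacing {spacing:.2f} nm)"
            )

    max_depth = spec.leaflet_z + LIPID_N_OFFSET
    for s in spec.surfactants:
        max_depth = max(max_depth, s.nplus_depth_z)
    box_z = max(7.6, 2.0 * (max_depth + 1.5))
    box = np.array([box_xy, box_xy, box_z])

    atoms: list[AtomRecord] = []
    base: list = []
    lipid_rows, surf_rows, chol_rows = [], [], []
    mol_id = 0
    atom_id = 0
    q = spec.charges

    def add_atom(species, name, role, pos):
        nonlocal atom_id
        atoms.append(
            AtomRecord(
                atom_id=atom_id,
                molecule_id=mol_id,
                species=species,
                atom_name=name,
                role=role,
                partial_charge=float(q.get(role, 0.0)),
            )
        )
        base.append(pos)
        atom_id += 1

    for leaflet_i, sign in enumerate((+1.0, -1.0)):
        leaflet = "UPPER" if sign > 0 else "LOWER"
        # jittered lattice sites, randomly partitioned between lipids and surfactants
        ii, jj = np.meshgrid(np.arange(nx), np.arange(nx), indexing="ij")
        sites = np.stack([(ii.ravel() + 0.5), (jj.ravel() + 0.5)], axis=1) * spacing
        sites = sites + rng.uniform(-0.15, 0.15, size=sites.shape) * spacing
        order = rng.permutation(len(sites))
        cursor = 0

        for _ in range(spec.n_lipids_per_leaflet):
            x, y = sites[order[cursor]]
            cursor += 1
            add_atom(Species.DOPC, "P", Role.LIPID_P,
                     (x, y, sign * spec.leaflet_z))
            add_atom(Species.DOPC, "N", Role.LIPID_N,
                     (x, y, sign * (spec.leaflet_z + LIPID_N_OFFSET)))
            lipid_rows.append(
                {"molecule_id": mol_id, "leaflet": leaflet, "x": x, "y": y}
            )
            mol_id += 1

        for s, (up, lo) in zip(spec.surfactants, surf_split):
            count = up if sign > 0 else lo
            species = Species(s.species)
            mu_eta = _mean_corrected_mu(math.radians(s.eta0_deg), s.kappa)
            mu_theta = _mean_corrected_mu(math.radians(s.theta0_deg), s.kappa)
            for _ in range(count):
                x, y = sites[order[cursor]]
                cursor += 1
                anchor = np.array([x, y, sign * s.nplus_depth_z])
                theta = float(_fold_polar(rng.vonmises(mu_theta, s.kappa, 1))[0])
                phi_t = float(rng.uniform(0, 2 * np.pi))
                t_dir = _unit_from_polar(np.array(theta), np.array(phi_t), sign)
                row = {
                    "molecule_id": mol_id,
                    "species": species.value,
                    "leaflet": leaflet,
                    "theta_deg": math.degrees(theta),
                    "eta_deg": None,
                    "x": x,
                    "y": y,
                }
                if species == Species.SDS:
                    add_atom(species, "S", Role.SULFATE_S, anchor)
                else:
                    eta = float(_fold_polar(rng.vonmises(mu_eta, s.kappa, 1))[0])
                    phi_h = float(rng.uniform(0, 2 * np.pi))
                    h_dir = _unit_from_polar(np.array(eta), np.array(phi_h), sign)
                    add_atom(species, "N", Role.N_PLUS, anchor)
                    add_atom(species, "CP", Role.PARA_C, anchor + H_LENGTH * h_dir)
                    row["eta_deg"] = math.degrees(eta)
                add_atom(species, "CT", Role.TERM_C, anchor + T_LENGTH * t_dir)
                surf_rows.append(row)
                mol_id += 1

        # cholesterol by a Thomas clustered point process in the leaflet plane
        n_chol = (spec.cholesterol.count + (1 if sign > 0 else 0)) // 2
        if n_chol > 0:
            area = box_xy * box_xy
            n_parents = max(
                1, int(rng.poisson(spec.cholesterol.thomas_parent_rate * area))
            )
            parents = rng.uniform(0, box_xy, size=(n_parents, 2))
            assign = rng.integers(0, n_parents, size=n_chol)
            offsets = rng.normal(
                0.0, spec.cholesterol.offspring_sigma, size=(n_chol, 2)
            )
            xy = np.mod(parents[assign] + offsets, box_xy)
            z = sign * (spec.leaflet_z - CHOL_O_DEPTH_OFFSET)
            for k in range(n_chol):
                add_atom(Species.CHOL, "O", Role.CHOL_O, (xy[k, 0], xy[k, 1], z))
                chol_rows.append(
                    {
                        "molecule_id": mol_id,
                        "leaflet": leaflet,
                        "parent": int(assign[k]),
                        "x": float(xy[k, 0]),
                        "y": float(xy[k, 1]),
                    }
                )
                mol_id += 1

    base_arr = np.asarray(base, dtype=float)
    jitter = rng.normal(
        0.0, spec.roughness_sigma, size=(spec.n_frames,) + base_arr.shape
    )
    coords = base_arr[None, :, :] + jitter
    times = np.arange(spec.n_frames, dtype=float) * spec.frame_dt
    boxes = np.tile(box, (spec.n_frames, 1))

    traj = Trajectory(atoms=atoms, coords=coords, times=times, boxes=boxes)
    manifest = GroundTruthManifest(
        spec=spec, box=box, lipids=lipid_rows,
        surfactants=surf_rows, cholesterol=chol_rows,
    )
    return traj, manifest


def default_role_map() -> dict:
    """Role map matching the atom names emitted by :func:`generate_system`."""
    c = DEFAULT_CHARGES
    return {
        Species.DOPC: {
            "P": {"role": Role.LIPID_P, "charge": c[Role.LIPID_P]},
            "N": {"role": Role.LIPID_N, "charge": c[Role.LIPID_N]},
        },
        Species.CHOL: {"O": {"role": Role.CHOL_O, "charge": 0.0}},
        Species.KOR105: {
            "N": {"role": Role.N_PLUS, "charge": c[Role.N_PLUS]},
            "CP": {"role": Role.PARA_C, "charge": 0.0},
            "CT": {"role": Role.TERM_C, "charge": 0.0},
        },
        Species.BAC: {
            "N": {"role": Role.N_PLUS, "charge": c[Role.N_PLUS]},
            "CP": {"role": Role.PARA_C, "charge": 0.0},
            "CT": {"role": Role.TERM_C, "charge": 0.0},
        },
        Species.SDS: {
            "S": {"role": Role.SULFATE_S, "charge": c[Role.SULFATE_S]},
            "CT": {"role": Role.TERM_C, "charge": 0.0},
        },
    }


# ---------------------------------------------------------------------------
# Synthetic measurement curves
# ---------------------------------------------------------------------------

@dataclass
class IFCSettings:
    c0: float = 1.0                    # capacitance at zero inner field (a.u.)
    alpha: float = 2e-5                # 1/mV^2
    voltage_halfspan: float = 80.0     # scan +/- this around the vertex, mV
    n_points: int = 33
    noise_sd: float = 0.01             # relative (multiplicative) noise


def generate_measurements(
    params: AdsorptionParams,
    cond: ElectrolyteConditions,
    concentrations_uM: Sequence[float],
    noise_sd_mV: float = 2.0,
    ifc: Optional[IFCSettings] = None,
    seed: int = 0,
):
    """Noisy boundary-potential curve plus one IFC scan per concentration.

    The curve is the adsorption model plus i.i.d. Gaussian noise
    (``noise_sd_mV``); each IFC scan is an electrostriction parabola whose
    vertex sits at that concentration's *noisy* potential, sampled on a
    symmetric voltage grid around the vertex with multiplicative noise.
    Returns ``(BoundaryPotentialCurve, list_of_IFCScan, true_curve)``.
    """
    if noise_sd_mV < 0:
        raise ValueError("noise_sd_mV must be >= 0")
    if ifc is None:
        ifc = IFCSettings()
    rng = np.random.default_rng(seed)

    true_curve = adsorption_curve(params, cond, concentrations_uM)
    noisy_phi = true_curve.delta_phi_mV + rng.normal(
        0.0, noise_sd_mV, size=len(true_curve.delta_phi_mV)
    ) if noise_sd_mV > 0 else true_curve.delta_phi_mV.copy()
    noisy_curve = BoundaryPotentialCurve(
        concentrations_uM=true_curve.concentrations_uM,
        delta_phi_mV=noisy_phi,
        method="IFC",
    )

    scans = []
    for phi in noisy_phi:
        u = phi + np.linspace(-ifc.voltage_halfspan, ifc.voltage_halfspan,
                              ifc.n_points)
        c = ifc.c0 * (1.0 + ifc.alpha * (u - phi) ** 2)
        if ifc.noise_sd > 0:
            c = c * (1.0 + rng.normal(0.0, ifc.noise_sd, size=len(c)))
        scans.append(IFCScan(applied_voltage_mV=u, capacitance=c))
    return noisy_curve, scans, true_curve
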
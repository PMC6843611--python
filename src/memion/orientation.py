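"""Surfactant orientation angles relative to the membrane normal.

Two angles characterise a hydrophobic ion in the bilayer: eta, between the
outward leaflet normal n and the head vector h (N+ -> para-ring carbon),
and theta, between n and the tail vector t (N+ or S -> terminal tail
carbon).  The normal is taken *outward* per leaflet (+Oz for the upper
monolayer, -Oz for the lower), so both monolayers pool into a single
distribution.  Anchor pairs straddling a periodic boundary are unwrapped by
minimum image relative to the charged anchor before the vectors are built.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .trajectory import (
    LEAFLET_REFERENCE_ROLES,
    Frame,
    Role,
    Species,
    Trajectory,
)

logger = logging.getLogger(__name__)

UPPER = "UPPER"
LOWER = "LOWER"


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention."""
    return d - box * np.round(d / box)


def membrane_frame_geometry(frame: Frame, traj: Trajectory):
    """Membrane centre (mean z of lipid phosphorus) and per-molecule leaflets.

    Returns ``(center_z, leaflets)`` where ``leaflets`` maps molecule_id ->
    "UPPER"/"LOWER" decided by the z of the molecule's reference atom
    (N+, sulfate S, cholesterol O, or lipid P).
    """
    p_idx = traj.atom_index(roles=[Role.LIPID_P])
    if len(p_idx) == 0:
        raise AnalysisError("no LIPID_P atoms: cannot locate the membrane centre")
    center_z = float(frame.coords[p_idx, 2].mean())

    leaflets: dict[int, str] = {}
    for role in LEAFLET_REFERENCE_ROLES:
        for i in traj.atom_index(roles=[role]):
            mol = traj.atoms[i].molecule_id
            if mol not in leaflets:
                z = frame.coords[i, 2]
                leaflets[mol] = UPPER if z > center_z else LOWER
    return center_z, leaflets


def _anchor_table(traj: Trajectory) -> pd.DataFrame:
    """One row per surfactant molecule with its anchor atom indices."""
    rows: dict[int, dict] = {}
    for i, a in enumerate(traj.atoms):
        if a.species not in (Species.KOR105, Species.BAC, Species.SDS):
            continue
        row = rows.setdefault(
            a.molecule_id, {"molecule_id": a.molecule_id, "species": a.species.value}
        )
        if a.role == Role.N_PLUS:
            row["anchor"] = i
        elif a.role == Role.SULFATE_S:
            row["anchor"] = i
        elif a.role == Role.PARA_C:
            row["para"] = i
        elif a.role == Role.TERM_C:
            row["term"] = i
    table = pd.DataFrame(list(rows.values()))
    if table.empty:
        raise AnalysisError("no surfactant molecules with assigned roles")
    return table


def _angles_to_normal(vec: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """Angle (deg) between vectors and the outward normal sign * +Oz."""
    norm = np.linalg.norm(vec, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = sign * vec[:, 2] / norm
    cosang = np.clip(cosang, -1.0, 1.0)
    out = np.degrees(np.arccos(cosang))
    out[norm == 0] = np.nan
    return out


def compute_orientation_angles(
    traj: Trajectory, window: Optional[tuple] = None
) -> pd.DataFrame:
    """Per-molecule, per-frame eta/theta angles inside an analysis window.

    Returns a DataFrame with columns ``time_ns, molecule_id, species,
    leaflet, eta_deg, theta_deg``; ``eta_deg`` is NaN for species without a
    ring (SDS).  Records with coincident anchors (zero-length vector) are
    skipped with a logged warning.
    """
    frames = traj.window_frames(window)
    if len(frames) == 0:
        raise AnalysisError("analysis window does not overlap the trajectory")
    table = _anchor_table(traj)
    has_para = table["para"].notna() if "para" in table else pd.Series(False, index=table.index)

    anchor_idx = table["anchor"].to_numpy(dtype=int)
    term_idx = table["term"].to_numpy(dtype=int)
    para_idx = np.where(has_para, table.get("para", np.nan), -1)
    para_idx = np.nan_to_num(para_idx, nan=-1).astype(int)

    chunks = []
    n_skipped = 0
    for fi in frames:
        frame = traj.frame(fi)
        box = frame.box
        center_z, leaflets = membrane_frame_geometry(frame, traj)
        mol_leaflet = np.array(
            [leaflets[m] for m in table["molecule_id"]], dtype=object
        )
        sign = np.where(mol_leaflet == UPPER, 1.0, -1.0)

        anchors = frame.coords[anchor_idx]
        t_vec = minimum_image(frame.coords[term_idx] - anchors, box)
        theta = _angles_to_normal(t_vec, sign)

        eta = np.full(len(table), np.nan)
        hp = has_para.to_numpy()
        if hp.any():
            h_vec = minimum_image(
                frame.coords[para_idx[hp]] - anchors[hp], box
            )
            eta[hp] = _angles_to_normal(h_vec, sign[hp])

        bad = np.isnan(theta) | (hp & np.isnan(eta))
        n_skipped += int(bad.sum())
        keep = ~bad
        chunks.append(
            pd.DataFrame(
                {
                    "time_ns": frame.time,
                    "molecule_id": table["molecule_id"].to_numpy()[keep],
                    "species": table["species"].to_numpy()[keep],
                    "leaflet": mol_leaflet[keep],
                    "eta_deg": eta[keep],
                    "theta_deg": theta[keep],
                }
            )
        )
    if n_skipped:
        logger.warning(
            "skipped %d records with coincident anchor atoms", n_skipped
        )
    return pd.concat(chunks, ignore_index=True)


@dataclass
class AngleDensity:
    """Normalised per-degree histogram density of an orientation angle."""

    bin_centers: np.ndarray
    density: np.ndarray
    angle_name: str            # "ETA" or "THETA"
    n_samples: int

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])

    @property
    def mode_deg(self) -> float:
        """Bin centre of maximal density."""
        return float(self.bin_centers[int(np.argmax(self.density))])


def angle_density(
    records: pd.DataFrame, angle_name: str, bin_width_deg: float = 2.0
) -> AngleDensity:
    """Histogram density on [0, 180] deg of eta or theta over all records."""
    name = angle_name.upper()
    col = {"ETA": "eta_deg", "THETA": "theta_deg"}[name]
    values = records[col].dropna().to_numpy()
    if len(values) == 0:
        raise AnalysisError(f"no records carry the angle {name}")
    n_bins = int(round(180.0 / bin_width_deg))
    density, edges = np.histogram(
        values, bins=n_bins, range=(0.0, 180.0), density=True
    )
    centers = 0.5 * (edges[:-1] + edges[1:])
    return AngleDensity(
        bin_centers=centers, density=density, angle_name=name,
        n_samples=len(values),
    )
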
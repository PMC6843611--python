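"""Cholesterol cluster statistics and midplane plunge (flip-flop attempt) events.

Two cholesterols belong to the same cluster when the minimum-image distance
between their hydroxyl oxygens is below a cutoff (0.7 nm by default);
cluster sizes are the connected-component sizes of that contact graph,
counted at every analysed frame.  A plunge event opens when a cholesterol
oxygen enters a band around the bilayer midplane and closes when it leaves;
short excursions below a dwell threshold are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import AnalysisError
from .orientation import minimum_image
from .trajectory import Frame, Role, Trajectory


def _chol_o_indices(traj: Trajectory) -> np.ndarray:
    return traj.atom_index(roles=[Role.CHOL_O])


def cluster_sizes_frame(
    frame: Frame, traj: Trajectory, cutoff: float = 0.7
) -> list[int]:
    """Connected-component sizes of the cholesterol O contact graph (one frame).

    Singletons are included.  Distances use the minimum-image convention in
    all three axes; the cutoff must be below half the smallest box edge so
    the convention is unambiguous.
    """
    if cutoff >= min(frame.box) / 2:
        raise AnalysisError(
            f"cutoff {cutoff} nm >= half the smallest box edge "
            f"({min(frame.box) / 2:.3f} nm)"
        )
    idx = _chol_o_indices(traj)
    n = len(idx)
    if n == 0:
        return []
    pos = frame.coords[idx]
    d = pos[:, None, :] - pos[None, :, :]
    d = minimum_image(d, frame.box)
    dist = np.sqrt((d ** 2).sum(axis=-1))
    adj = (dist < cutoff) & ~np.eye(n, dtype=bool)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    return np.bincount(labels, minlength=n_comp).tolist()


@dataclass
class ClusterSizeDistribution:
    """Mean number of clusters of each size per frame."""

    mean_counts: dict          # size -> mean count per frame
    window: Optional[tuple]
    cutoff: float
    n_frames: int
    n_chol: int

    def mean_counts_excluding_singletons(self) -> dict:
        return {s: c for s, c in self.mean_counts.items() if s > 1}

    @property
    def mean_cluster_size(self) -> float:
        tot_mol = sum(s * c for s, c in self.mean_counts.items())
        tot_clusters = sum(self.mean_counts.values())
        return tot_mol / tot_clusters if tot_clusters else float("nan")


def cluster_size_distribution(
    traj: Trajectory, window: Optional[tuple] = None, cutoff: float = 0.7
) -> ClusterSizeDistribution:
    """Per-size mean cluster counts over the frames of an analysis window."""
    frames = traj.window_frames(window)
    if len(frames) == 0:
        raise AnalysisError("analysis window does not overlap the trajectory")
    n_chol = len(_chol_o_indices(traj))
    counts: dict[int, int] = {}
    for fi in frames:
        sizes = cluster_sizes_frame(traj.frame(fi), traj, cutoff=cutoff)
        assert sum(sizes) == n_chol  # conservation: every molecule in one cluster
        for s in sizes:
            counts[s] = counts.get(s, 0) + 1
    nf = len(frames)
    return ClusterSizeDistribution(
        mean_counts={s: c / nf for s, c in sorted(counts.items())},
        window=window,
        cutoff=cutoff,
        n_frames=nf,
        n_chol=n_chol,
    )


@dataclass
class PlungeEvent:
    molecule_id: int
    t_start: float                         # ns, first frame inside the band
    dwell: float                           # ns spent inside the band
    returned_to_same_leaflet: Optional[bool]   # None if truncated by the window
    reached_interface: bool                # crossed within band/2 of the centre


def detect_plunges(
    traj: Trajectory,
    band_halfwidth: float = 0.3,
    min_dwell: float = 1.0,
) -> list[PlungeEvent]:
    """Detect cholesterol excursions into the bilayer midplane band.

    ``reached_interface`` flags events whose oxygen came within half the
    band width of the membrane centre.  ``returned_to_same_leaflet``
    compares the leaflet just before entry and just after exit; it is None
    when the event touches the start or end of the trajectory.
    """
    idx = _chol_o_indices(traj)
    if len(idx) == 0:
        return []
    p_idx = traj.atom_index(roles=[Role.LIPID_P])
    if len(p_idx) == 0:
        raise AnalysisError("no LIPID_P atoms: cannot locate the membrane centre")

    centers = traj.coords[:, p_idx, 2].mean(axis=1)           # (n_frames,)
    z_rel = traj.coords[:, idx, 2] - centers[:, None]          # (n_frames, n_chol)
    inside = np.abs(z_rel) < band_halfwidth
    times = traj.times

    events: list[PlungeEvent] = []
    for j, atom_i in enumerate(idx):
        mol = traj.atoms[atom_i].molecule_id
        col = inside[:, j]
        # contiguous runs of inside frames
        edges = np.flatnonzero(np.diff(col.astype(int)))
        starts = [0] if col[0] else []
        starts += [e + 1 for e in edges if col[e + 1]]
        ends = [e + 1 for e in edges if col[e]]       # first outside frame
        open_at_end = col[-1]
        if open_at_end:
            ends.append(len(col))
        for s, e in zip(starts, ends):
            t_start = times[s]
            t_end = times[e] if e < len(col) else times[-1]
            dwell = float(t_end - t_start)
            if dwell < min_dwell:
                continue
            reached = bool(np.min(np.abs(z_rel[s:e, j])) < band_halfwidth / 2)
            if s > 0 and e < len(col):
                same = bool(np.sign(z_rel[s - 1, j]) == np.sign(z_rel[e, j]))
            else:
                same = None
            events.append(
                PlungeEvent(
                    molecule_id=mol,
                    t_start=float(t_start),
                    dwell=dwell,
                    returned_to_same_leaflet=same,
                    reached_interface=reached,
                )
            )
    events.sort(key=lambda ev: ev.t_start)
    return events
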
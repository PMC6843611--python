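#!/usr/bin/env python
"""Generate the synthetic membrane scenarios used by the downstream analyses.

Two bilayer scenarios mirror the study design: a pure-DOPC-like membrane
(phosphorus planes at +/-1.8 nm, broader surfactant orientations) and a
cholesterol-rich one (planes at +/-2.2 nm, narrower orientations, the
cationic ion partly unbent and its charged nitrogen at the same absolute
depth).  Trajectories are written under scratch/ (they are regenerable from
the seed); the scenario table goes to results/.
"""

from pathlib import Path

import pandas as pd

from memion.synthetic import (
    CholesterolSpec,
    SurfactantSpec,
    SyntheticSpec,
    generate_system,
)
from memion.trajectory import write_gro, write_xtc

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "systems"
RESULTS = ROOT / "results"

SEED = 2026


def scenario_specs() -> dict[str, SyntheticSpec]:
    ion = dict(species="KOR105", count=86, kappa=8.0, nplus_depth_z=2.5)
    return {
        # 202 DOPC + 86 cations, no sterol: bent ion, broad angles
        "dopc": SyntheticSpec(
            n_lipids_per_leaflet=101, leaflet_z=1.8,
            surfactants=[SurfactantSpec(eta0_deg=130.0, theta0_deg=150.0, **ion)],
            n_frames=50, seed=SEED,
        ),
        # 122 DOPC + 80 Chol + 86 cations: thicker membrane, ion unbends
        "dopc_chol": SyntheticSpec(
            n_lipids_per_leaflet=61, leaflet_z=2.2,
            surfactants=[SurfactantSpec(eta0_deg=122.0, theta0_deg=158.0, **ion)],
            cholesterol=CholesterolSpec(count=80, thomas_parent_rate=0.02,
                                        offspring_sigma=0.25),
            n_frames=50, seed=SEED + 1,
        ),
    }


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, spec in scenario_specs().items():
        traj, manifest = generate_system(spec)
        write_gro(traj, SCRATCH / f"{name}.gro")
        write_xtc(traj, SCRATCH / f"{name}.xtc")
        manifest.to_json(SCRATCH / f"{name}_manifest.json")
        rows.append({
            "scenario": name,
            "n_atoms": traj.n_atoms,
            "n_frames": traj.n_frames,
            "leaflet_z_nm": spec.leaflet_z,
            "n_surfactants": sum(s.count for s in spec.surfactants),
            "n_cholesterol": spec.cholesterol.count,
            "box_x_nm": round(float(traj.boxes[0][0]), 3),
        })
        print(f"{name}: {traj.n_atoms} atoms, {traj.n_frames} frames, "
              f"P planes at +/-{spec.leaflet_z} nm")
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "systems.tsv", sep="\t", index=False)
    print(f"\nwrote {RESULTS / 'systems.tsv'}")


if __name__ == "__main__":
    main()
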
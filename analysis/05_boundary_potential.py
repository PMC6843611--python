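#!/usr/bin/env python
"""Boundary-potential measurement model: simulate, re-measure, re-fit.

For each surfactant scenario a boundary-potential curve is generated from
known Langmuir/Gouy-Chapman parameters (20 mM 1:1 electrolyte, 295 K), an
inner-field-compensation capacitance scan is simulated at every
concentration, the capacitance minima are re-fitted to recover the
potentials, and the adsorption parameters are re-estimated from the
recovered curve.  Cationic ions give positive potentials, SDS the
sign-mirrored negative branch; a cholesterol-enhanced binding constant
emulates the stronger adsorption of the rigid cation on sterol-rich
membranes.
"""

import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from memion.electrostatics import (
    AdsorptionParams,
    BoundaryPotentialCurve,
    ElectrolyteConditions,
    estimate_phi_in,
    fit_adsorption,
)
from memion.synthetic import IFCSettings, generate_measurements

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

COND = ElectrolyteConditions()          # 20 mM KCl-like, 295 K
CONC_UM = np.geomspace(1.0, 100.0, 8)

SCENARIOS = {
    # (K 1/M, Gamma_max nm^-2, valence)
    "kor105_dopc": (4e4, 0.05, +1),     # weaker adsorption without sterol
    "kor105_chol": (1.5e5, 0.05, +1),   # cholesterol enhances adsorption
    "bac_dopc": (1e5, 0.05, +1),
    "bac_chol": (1e5, 0.05, +1),        # sterol-insensitive
    "sds_dopc": (1e5, 0.05, -1),        # anionic: sign-mirrored potentials
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for name, (k, gmax, z) in SCENARIOS.items():
        params = AdsorptionParams(binding_constant=k, max_site_density=gmax,
                                  surfactant_valence=z)
        curve, scans, true_curve = generate_measurements(
            params, COND, CONC_UM, noise_sd_mV=1.0,
            ifc=IFCSettings(noise_sd=0.002), seed=zlib.crc32(name.encode()) % 2**31,
        )
        rephi = np.array([estimate_phi_in(s).phi_in_mV for s in scans])
        refit = fit_adsorption(BoundaryPotentialCurve(CONC_UM, rephi, "IFC"),
                               COND, valence=z)
        rows.append({
            "scenario": name,
            "K_true_per_M": k,
            "K_refit_per_M": round(refit.params.binding_constant, 1),
            "K_rel_err": round(abs(refit.params.binding_constant / k - 1), 3),
            "gamma_refit_per_nm2": round(refit.params.max_site_density, 4),
            "dphi_at_100uM_mV": round(float(true_curve.delta_phi_mV[-1]), 2),
            "residual_norm_mV": round(refit.residual_norm, 2),
        })
        print(f"{name}: dPhi(100 uM) = {rows[-1]['dphi_at_100uM_mV']:+.1f} mV, "
              f"K recovered to {100 * rows[-1]['K_rel_err']:.1f}%")
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "adsorption_fits.tsv", sep="\t", index=False)
    d = table.set_index("scenario")
    print("\ncholesterol raises the Kor105-like potential:",
          d.loc["kor105_chol", "dphi_at_100uM_mV"]
          > d.loc["kor105_dopc", "dphi_at_100uM_mV"])
    print("SDS branch is negative:", d.loc["sds_dopc", "dphi_at_100uM_mV"] < 0)
    print(f"wrote {RESULTS / 'adsorption_fits.tsv'}")


if __name__ == "__main__":
    main()
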
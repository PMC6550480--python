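"""MWCO characterization of synthetic membrane variants.

Generates sigmoidal rejection-vs-Stokes-radius profiles for three membrane
variants differing in effective pore size (cutoff midpoint) and applies the
90%-rejection rule to each: a loose membrane cuts off at PEG 1000, a
tightened one at PEG 600, and an aquaporin-sealed one rejects everything
tested (cutoff at or below the lightest solute).

Writes results/mwco_characterization.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from aqpflux.characterization import (STANDARD_SOLUTES, RejectionRecord,
                                      determine_mwco)
from aqpflux.synthetic import SyntheticStudySpec, generate_rejection_profile

OUT = Path(__file__).resolve().parents[1] / "results"

# variant -> rejection sigmoid midpoint (nm); tighter pores = smaller radius
VARIANT_MIDPOINTS = {"pbi_unmodified": 0.85, "pva_alkyl": 0.60,
                     "aqp_sealed": 0.30}


def main() -> None:
    rows = []
    for variant, midpoint in VARIANT_MIDPOINTS.items():
        spec = SyntheticStudySpec(rejection_midpoint_nm=midpoint,
                                  rejection_steepness=0.03,
                                  rejection_noise_sd_pct=1.0, seed=42)
        table = generate_rejection_profile(spec)
        recs = [RejectionRecord(solute=s, rejection_pct=r)
                for s, r in zip(STANDARD_SOLUTES, table.rejection_pct)]
        res = determine_mwco(recs, threshold=90.0)
        rows.append({"variant": variant, "midpoint_nm": midpoint,
                     "mwco_gmol": res.mwco,
                     "defining_solute": res.defining_solute.name
                     if res.defining_solute else None,
                     "status": res.status.value})
        print(f"{variant:15s} (cutoff midpoint {midpoint:.2f} nm): "
              f"MWCO {res.mwco} g/mol [{res.status.value}]")
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "mwco_characterization.csv",
                              index=False, float_format="%.10g")
    print("\nSmaller effective pores push the 90%-rejection cutoff to "
          "lighter solutes; full aquaporin sealing rejects the whole "
          "tested series.")


if __name__ == "__main__":
    sys.exit(main())
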
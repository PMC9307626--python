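#!/usr/bin/env python
"""Folding free energies and their modulation by the tunnel-loop variants.

From the measured populations: dG_F-U = -RT ln(P_F/P_U) per variant and
length, ddG vs the wild type, the 1 % detection cap for variants with no
folded signal, and the attenuation of |ddG| from L=31 to L=34.  Writes
results/folding_energetics.csv.
"""

import pandas as pd
from common import ATTENUATION_VARIANTS, PF_L31, PF_L34, RESULTS

from tunnelfold.energetics import ThermoConfig, ddg, delta_g_folding, length_attenuation
from tunnelfold.lineshape_fit import StatePopulations

CFG = ThermoConfig()  # 298.15 K, as recorded


def energy(p_pct, linker_l, variant):
    if p_pct is None:
        pop = StatePopulations(p_f=0.01, p_u=0.99, sd_pf=0.0, bounded=True)
    else:
        pop = StatePopulations(p_f=p_pct / 100, p_u=1 - p_pct / 100, sd_pf=0.0)
    return delta_g_folding(pop, CFG, variant=variant, linker_l=linker_l)


def main() -> None:
    rows = []
    energies = {}
    for linker_l, table in ((31, PF_L31), (34, PF_L34)):
        for variant, pf in table.items():
            fe = energy(pf, linker_l, variant)
            energies[(variant, linker_l)] = fe
            rows.append({"variant": variant, "linker_l": linker_l,
                         "quantity": "dG_F-U", "value": fe.dg, "bounded": fe.bounded})
    for (variant, linker_l), fe in list(energies.items()):
        if variant == "WT":
            continue
        d = ddg(fe, energies[("WT", linker_l)])
        rows.append({"variant": variant, "linker_l": linker_l,
                     "quantity": "ddG_F-U", "value": d.dg, "bounded": d.bounded})
        print(f"{variant} L={linker_l}: ddG_F-U = {d.dg:+.2f} kcal/mol"
              + (" (bound)" if d.bounded else ""))

    dd31 = [ddg(energies[(v, 31)], energies[("WT", 31)]) for v in ATTENUATION_VARIANTS]
    dd34 = [ddg(energies[(v, 34)], energies[("WT", 34)]) for v in ATTENUATION_VARIANTS]
    mean, sd, per_variant = length_attenuation(dd31, dd34)
    print(f"\n|ddG| attenuation L=31 -> L=34 over {per_variant.size} variants: "
          f"{mean:.0f} +/- {sd:.0f} % (per variant: "
          + ", ".join(f"{v}={a:.0f}%" for v, a in zip(ATTENUATION_VARIANTS, per_variant)) + ")")
    rows.append({"variant": "mean", "linker_l": 0, "quantity": "attenuation_pct",
                 "value": mean, "bounded": False})
    pd.DataFrame(rows).to_csv(RESULTS / "folding_energetics.csv", index=False)
    print(f"wrote {RESULTS / 'folding_energetics.csv'}")


if __name__ == "__main__":
    main()
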
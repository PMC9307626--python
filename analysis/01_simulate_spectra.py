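#!/usr/bin/env python
"""Generate the synthetic 19F spectra used by the downstream fits.

One two-resonance spectrum per (variant, linker length) with the folded
fraction set to the measured population, SNR ~ 20 on the dominant peak,
0.8 ppm U/F separation.  Writes FID + spectrum files under
scratch/inputs/ in the package's text dialect (bulky, regenerable).
"""

from common import PF_L31, PF_L34, SCRATCH

from tunnelfold.nmr_core import AcquisitionParams, fourier_transform, write_fid, write_spectrum
from tunnelfold.synthetic_data import GroundTruthSpectrum, simulate_fid

SEED = 20260923
N_POINTS = 2048


def main() -> None:
    out = SCRATCH / "inputs"
    out.mkdir(parents=True, exist_ok=True)
    acq = AcquisitionParams(n_points=N_POINTS, dwell=0.350 / N_POINTS)
    n = 0
    for linker_l, table in ((31, PF_L31), (34, PF_L34)):
        for i, (variant, pf) in enumerate(sorted(table.items())):
            if pf is None:
                continue  # no folded signal: detection-bound workflow, no fit
            truth = GroundTruthSpectrum.two_state(pf / 100, snr=20.0,
                                                 seed=SEED + 100 * linker_l + i)
            fid = simulate_fid(truth, acq)
            stem = out / f"{variant}_L{linker_l}"
            write_fid(fid, f"{stem}.fid.csv")
            write_spectrum(fourier_transform(fid, zero_fill_factor=1), f"{stem}.spec.csv")
            n += 1
    print(f"wrote {n} spectra (plus FIDs) to {out}")
    print(f"conditions: {N_POINTS} complex points, 350 ms acquisition, "
          "SNR ~ 20, 0.8 ppm separation")


if __name__ == "__main__":
    main()
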
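"""Shared study constants for the analysis drivers.

Folded-state populations (%) measured by 19F lineshape deconvolution for
each ribosome variant at the two sensitive linker lengths.  ``None`` marks
variants with no detectable folded signal, which enter the energetics
through the 1 % detection cap.
"""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"
#: bulky generated inputs (FIDs, spectra, ensembles) live outside results
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

PF_L31 = {"WT": 8, "23dL": 11, "24dL": 16, "23dL24dL": 42, "23+L": 34,
          "24+L": None, "23+L24+L": None, "23+L24dL": 37}
PF_L34 = {"WT": 59, "23dL": 67, "24dL": 64, "23dL24dL": 72, "23+L": 66,
          "24+L": 47, "23+L24+L": 47, "22dL": 58, "22dL23dL24dL": 78}

#: the six uL23/uL24 variants quantified at both lengths
ATTENUATION_VARIANTS = ["23dL", "24dL", "23dL24dL", "23+L", "24+L", "23+L24+L"]

#: printed binding free-energy penalties (kcal/mol) for the truncations
DDG_BINDING = {"23dL": 0.46, "24dL": 0.31, "23dL24dL": 0.77}
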
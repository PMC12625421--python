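#!/usr/bin/env python
"""Document the choice of the extraction simulator's default constants.

Stage-level rate and partition constants are not identifiable from endpoint
residue measurements alone, so the shipped defaults are tuned once against
the observed compliant residue band for the standard protocol (5 g seed,
40 % oil, 50 degC / 30 min, four fresh 20 mL washes): total THC in the
residue between 1.5 and 3.3 mg/kg.

This script scans the first-order rate constant k (with the other defaults
fixed) and prints the simulated residue concentration, marking the band.
The shipped default k = 0.13 /min sits mid-band (~3.1 mg/kg).

Usage:  python scripts/tune_extraction.py
"""

from __future__ import annotations

import numpy as np

from huskmodel.extraction import ExtractionExperiment, run_protocol

BAND = (1.5, 3.3)


def main() -> None:
    print(f"{'k (1/min)':>10} {'residue (mg/kg)':>16}  in band {BAND}?")
    for k in np.round(np.arange(0.02, 0.32, 0.01), 3):
        exp = ExtractionExperiment(rate_constant_k=float(k))
        residue = run_protocol(exp)[-1].residue_concentration
        mark = "  <-- " if BAND[0] <= residue <= BAND[1] else ""
        default = " (shipped default)" if abs(k - 0.13) < 1e-9 else ""
        print(f"{k:>10.2f} {residue:>16.3f}{mark}{default}")


if __name__ == "__main__":
    main()
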
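"""Packaged reference data.

Two small CSVs ship with the package:

* the assigned 750 MHz 1H/13C shift table of 12S-deoxynortryptoquivaline
  in methanol-d4;
* a *synthetic* reconstruction of that compound's experimental ECD
  spectrum — two Gaussian bands (sigma 5 nm) placed at the reported Cotton
  effects, 208 nm (Δε +18.04) and 230 nm (Δε −15.78). The measured curve
  itself is not available as digital data, so this fixture reproduces only
  the band positions, amplitudes and signs, which is all the sign-pattern
  comparison uses.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .ecd import Spectrum, read_spectrum_csv

_DATA = files("stereonmr") / "data"


def deoxynortryptoquivaline_shifts() -> pd.DataFrame:
    """Assigned 13C/1H chemical shifts (ppm) of 12S-deoxynortryptoquivaline."""
    with (_DATA / "deoxynortryptoquivaline_nmr.csv").open() as fh:
        return pd.read_csv(fh)


def deoxynortryptoquivaline_ecd() -> Spectrum:
    """Synthetic reconstruction of the experimental ECD spectrum (see module
    docstring); positive band at 208 nm, negative band at 230 nm."""
    return read_spectrum_csv(str(_DATA / "ecd_synthetic_reference.csv"))
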
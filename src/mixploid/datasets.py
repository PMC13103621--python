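"""Small built-in reference datasets.

``piper_cytometry`` returns the published flow-cytometry peak
measurements for *Piper nigrum* cultivars (Kuching, Panniyur) and the
Sri Lankan species *P. trineuron*, *P. zeylanicum* and *P. walkeri*.
*Solanum pseudocapsicum* (1C = 1.3 pg) is the primary standard;
*P. zeylanicum*, whose genome size is too close to the Solanum standard
for the peaks to separate, was measured against *P. walkeri* as an
intermediate standard.
"""

from __future__ import annotations

import pandas as pd

SOLANUM_STANDARD_1C = 1.3  # pg, Solanum pseudocapsicum

PIPER_STANDARDS: dict[str, float] = {"Solanum pseudocapsicum": SOLANUM_STANDARD_1C}

_ROWS = [
    # sample, peak_sample, peak_standard, standard
    ("P. nigrum (Kuching)", 1.0, 1.506, "Solanum pseudocapsicum"),
    ("P. nigrum (Kuching)", 1.0, 1.504, "Solanum pseudocapsicum"),
    ("P. nigrum (Panniyur)", 1.0, 1.508, "Solanum pseudocapsicum"),
    ("P. nigrum (Panniyur)", 1.0, 1.508, "Solanum pseudocapsicum"),
    ("P. trineuron", 1.0, 1.546, "Solanum pseudocapsicum"),
    ("P. trineuron", 1.0, 1.550, "Solanum pseudocapsicum"),
    ("P. zeylanicum", 1.885, 1.0, "P. walkeri"),
    ("P. zeylanicum", 1.891, 1.0, "P. walkeri"),
    ("P. walkeri", 1.0, 1.942, "Solanum pseudocapsicum"),
    ("P. walkeri", 1.0, 1.945, "Solanum pseudocapsicum"),
]


def piper_cytometry() -> pd.DataFrame:
    """Published peak measurements, one row per replicate run."""
    return pd.DataFrame(
        _ROWS, columns=["sample", "peak_sample", "peak_standard", "standard"]
    )
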
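"""Flow-cytometry genome sizes for Piper from the built-in peak data.

Each replicate 1C value is peak_sample / peak_standard x 1C_standard
(Solanum pseudocapsicum, 1.3 pg).  P. zeylanicum is measured against the
chained P. walkeri intermediate standard because its genome size is too
close to the Solanum standard for separate peaks.
"""

from mixploid.cytometry import genome_size_table
from mixploid.datasets import PIPER_STANDARDS, piper_cytometry

table = genome_size_table(piper_cytometry(), PIPER_STANDARDS)
print(table.to_string(index=False))
print(
    "\nc_sample: per-replicate 1C (pg, 3 decimals); mean_1c: per-sample "
    "mean (2 decimals).  Cultivated P. nigrum averages 0.86 pg."
)
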
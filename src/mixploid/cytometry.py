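"""Flow-cytometry genome-size (1C) estimation with chained standards.

A sample's 1C DNA content in picograms is the ratio of its G1 peak
fluorescence to that of a co-chopped internal standard of known 1C:

    1C_sample = peak_sample / peak_standard * 1C_standard

When a sample's genome size is too close to the primary standard's for
the peaks to separate, it is measured against an *intermediate* standard
-- a sample whose own 1C was first estimated against the primary standard;
the intermediate's value is the mean of its replicate 1C estimates.

All rounding is decimal half-up: per-replicate 1C to 3 decimals,
per-sample means to 2 decimals, intermediate-standard values to
3 decimals.  These conventions reproduce published flow-cytometry tables
cell for cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = [
    "CytometryMeasurement",
    "round_half_up",
    "compute_1c",
    "chain_standard",
    "summarize_sample",
    "genome_size_table",
]


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (0.6685 -> 0.669 at 3 digits).

    Python's built-in ``round`` is banker's rounding; published tables
    virtually always use half-up.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def compute_1c(peak_sample: float, peak_standard: float, c_standard: float) -> float:
    """1C in pg from peak positions and the standard's 1C, 3-decimal half-up."""
    if peak_sample <= 0 or peak_standard <= 0 or c_standard <= 0:
        raise ValueError("peaks and standard 1C must be positive")
    return round_half_up(peak_sample / peak_standard * c_standard, 3)


def chain_standard(replicate_1c: list[float]) -> float:
    """Intermediate-standard 1C: mean of replicate estimates, 3-decimal half-up."""
    if not replicate_1c:
        raise ValueError("no replicate measurements for the intermediate standard")
    return round_half_up(sum(replicate_1c) / len(replicate_1c), 3)


def summarize_sample(replicate_1c: list[float]) -> float:
    """Mean 1C over replicates, 2-decimal half-up (the reported value)."""
    if not replicate_1c:
        raise ValueError("no replicate measurements")
    return round_half_up(sum(replicate_1c) / len(replicate_1c), 2)


@dataclass
class CytometryMeasurement:
    """One flow-cytometry run of one sample against one standard."""

    sample_name: str
    peak_sample: float
    peak_standard: float
    standard_name: str
    c_standard: float

    @property
    def c_sample(self) -> float:
        return compute_1c(self.peak_sample, self.peak_standard, self.c_standard)


def genome_size_table(
    measurements: pd.DataFrame, standards: dict[str, float]
) -> pd.DataFrame:
    """Per-replicate and per-sample 1C report from a measurement table.

    ``measurements`` needs columns ``sample``, ``peak_sample``,
    ``peak_standard``, ``standard``; replicates are consecutive rows of
    one sample.  ``standards`` maps primary-standard names to their 1C in
    pg.  A measurement may name another *sample* as its standard; that
    sample's chained value (3-decimal mean of its replicate 1Cs against a
    resolvable standard) is then used, whatever the row order.

    Returns one row per replicate with ``c_sample`` (3 dp) and, on each
    sample's first row, ``mean_1c`` (2 dp) — the shape of a published
    genome-size table.
    """
    required = {"sample", "peak_sample", "peak_standard", "standard"}
    if not required.issubset(measurements.columns):
        raise ValueError(f"measurement table needs columns {sorted(required)}")

    known = dict(standards)
    by_sample = {name: grp for name, grp in measurements.groupby("sample", sort=False)}
    replicate_values: dict[str, list[float]] = {}

    # resolve samples whose standard is known; chained standards may need
    # several passes but never more than the number of samples
    pending = list(by_sample)
    for _ in range(len(pending) + 1):
        still = []
        for name in pending:
            grp = by_sample[name]
            std_names = set(grp["standard"])
            if std_names.issubset(known):
                vals = [
                    compute_1c(r.peak_sample, r.peak_standard, known[r.standard])
                    for r in grp.itertuples()
                ]
                replicate_values[name] = vals
                known.setdefault(name, chain_standard(vals))
            else:
                still.append(name)
        pending = still
        if not pending:
            break
    if pending:
        raise ValueError(f"unresolvable standards for samples: {pending}")

    rows = []
    for name, grp in by_sample.items():
        vals = replicate_values[name]
        mean = summarize_sample(vals)
        for i, (r, v) in enumerate(zip(grp.itertuples(), vals)):
            rows.append(
                {
                    "sample": name,
                    "peak_sample": r.peak_sample,
                    "peak_standard": r.peak_standard,
                    "standard": r.standard,
                    "c_sample": v,
                    "mean_1c": mean if i == 0 else float("nan"),
                }
            )
    return pd.DataFrame(rows)
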
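"""Post-calling site-selection cascade for mixed-ploidy SNP panels.

Stages, with their default thresholds (all settable):

1. :func:`hard_filter`          -- drop QD < 2.0, FS > 60, MQ < 40
   (strict inequalities; boundary values survive; records missing an
   annotation are retained unless ``drop_unannotated=True``).
2. :func:`intersect_ploidy_callsets` -- keep (chrom, pos, ref, alt)
   present in both a diploid-called and a tetraploid-called dataset,
   taking each sample's genotype from the callset matching its ploidy.
3. :func:`presence_biallelic_filter` -- biallelic SNPs called in >= 80%
   of samples (inclusive).
4. :func:`singleton_missingness_filter` -- drop singletons (total
   minor-allele dosage == 1) and sites with > 20% missing (strict).
5. :func:`thin_by_distance`     -- greedy per-chromosome scan keeping
   sites >= 10,000 bp apart.
6. :func:`select_least_missing` -- the n sites with fewest missing
   genotypes (ties broken by chrom, pos).

Every stage is idempotent and accounts for its removals in a
:class:`FilterReport` whose counts telescope across the cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix


@dataclass
class FilterReport:
    """Ordered per-stage bookkeeping: input, removed, survivors."""

    stages: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in or n_out < 0:
            raise ValueError("survivors must be between 0 and the input count")
        if self.stages and self.stages[-1][3] != n_in:
            raise ValueError(
                f"stage {name!r} input {n_in} != previous survivors "
                f"{self.stages[-1][3]}"
            )
        self.stages.append((name, n_in, n_in - n_out, n_out))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages, columns=["stage", "n_in", "n_removed", "n_out"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @property
    def survivors(self) -> int:
        return self.stages[-1][3] if self.stages else 0


def _report(report: FilterReport | None) -> FilterReport:
    return report if report is not None else FilterReport()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def hard_filter(
    gm: GenotypeMatrix,
    *,
    min_qd: float = 2.0,
    max_fs: float = 60.0,
    min_mq: float = 40.0,
    drop_unannotated: bool = False,
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """GATK-style hard filter: remove QD < min_qd OR FS > max_fs OR MQ < min_mq.

    Inequalities are strict, so a site exactly at a threshold is retained.
    Sites lacking an annotation pass that criterion by default.
    """
    report = _report(report)
    s = gm.sites
    qd = s["qd"].to_numpy(dtype=float)
    fs = s["fs"].to_numpy(dtype=float)
    mq = s["mq"].to_numpy(dtype=float)

    def _fails(values: np.ndarray, bad: np.ndarray) -> np.ndarray:
        missing = np.isnan(values)
        return np.where(missing, drop_unannotated, bad)

    fail = (
        _fails(qd, qd < min_qd)
        | _fails(fs, fs > max_fs)
        | _fails(mq, mq < min_mq)
    )
    out = gm.mask_sites(~fail)
    report.add("hard_filter", gm.n_sites, out.n_sites)
    return out, report


def intersect_ploidy_callsets(
    diploid: GenotypeMatrix,
    tetraploid: GenotypeMatrix,
    *,
    position_only: bool = False,
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep sites present in both the diploid- and tetraploid-called sets.

    Matching is on (chrom, pos, ref, alt) by default (``position_only``
    relaxes it to (chrom, pos), the bcftools isec behaviour).  The merged
    genotypes come from the tetraploid callset for samples the sheet calls
    tetraploid and from the diploid callset otherwise; both inputs must be
    coordinate-sorted and carry the same samples.
    """
    report = _report(report)
    for name, part in (("diploid", diploid), ("tetraploid", tetraploid)):
        if not part.is_sorted():
            raise ValueError(f"{name} callset is not coordinate-sorted")
    if diploid.samples != tetraploid.samples:
        raise ValueError("callsets carry different samples")

    def _keys(g: GenotypeMatrix) -> list[tuple]:
        if position_only:
            return [(c, p) for c, p, _, _ in g.site_keys()]
        return g.site_keys()

    dip_keys = _keys(diploid)
    tet_keys = _keys(tetraploid)
    dip_index = {k: j for j, k in enumerate(dip_keys)}
    keep_tet = [j for j, k in enumerate(tet_keys) if k in dip_index]

    merged = tetraploid.take_sites(keep_tet)
    dip_cols = [dip_index[tet_keys[j]] for j in keep_tet]
    is_dip = merged.ploidy == 2
    if is_dip.any():
        merged.dosage[is_dip, :] = diploid.dosage[np.ix_(is_dip, np.array(dip_cols, dtype=int))]
    report.add("intersect_ploidy_callsets", tetraploid.n_sites, merged.n_sites)
    return merged, report


def presence_biallelic_filter(
    gm: GenotypeMatrix,
    *,
    min_presence: float = 0.80,
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep biallelic SNPs called in at least ``min_presence`` of samples (inclusive)."""
    if not 0.0 < min_presence <= 1.0:
        raise ValueError("min_presence must be in (0, 1]")
    report = _report(report)
    n_alt = gm.sites["alt"].astype(str).str.count(",") + 1
    biallelic = (n_alt == 1).to_numpy()
    keep = biallelic & (gm.call_fraction() >= min_presence)
    out = gm.mask_sites(keep)
    report.add("presence_biallelic", gm.n_sites, out.n_sites)
    return out, report


def singleton_missingness_filter(
    gm: GenotypeMatrix,
    *,
    max_missing: float = 0.20,
    mode: str = "dosage",
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop singletons and sites with more than ``max_missing`` missing data.

    A singleton has total minor-allele dosage 1 across the panel
    (``mode="dosage"``, the default, the natural unit for mixed ploidy) or
    exactly one carrier of the minor allele (``mode="carriers"``).
    The missingness inequality is strict: exactly 20% missing survives.
    """
    if mode not in ("dosage", "carriers"):
        raise ValueError("mode must be 'dosage' or 'carriers'")
    report = _report(report)
    called = gm.called
    alt_sum = np.where(called, gm.dosage, 0).sum(axis=0)
    tot = (called * gm.ploidy[:, None]).sum(axis=0)
    ref_sum = tot - alt_sum
    minor_is_alt = alt_sum <= ref_sum
    if mode == "dosage":
        minor = np.minimum(alt_sum, ref_sum)
        singleton = minor == 1
    else:
        alt_carriers = (called & (gm.dosage > 0)).sum(axis=0)
        ref_carriers = (called & (gm.dosage < gm.ploidy[:, None])).sum(axis=0)
        singleton = np.where(minor_is_alt, alt_carriers, ref_carriers) == 1
        # a 'carrier singleton' must also be the minor allele
        singleton &= np.minimum(alt_sum, ref_sum) > 0
    missing_frac = 1.0 - gm.call_fraction()
    keep = ~singleton & ~(missing_frac > max_missing)
    out = gm.mask_sites(keep)
    report.add("singleton_missingness", gm.n_sites, out.n_sites)
    return out, report


def thin_by_distance(
    gm: GenotypeMatrix,
    *,
    min_gap_bp: int = 10_000,
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Greedy LD thinning: per chromosome keep the first site, then every
    site at least ``min_gap_bp`` beyond the last kept one."""
    report = _report(report)
    if not gm.is_sorted():
        raise ValueError("sites must be coordinate-sorted before thinning")
    keep = np.zeros(gm.n_sites, dtype=bool)
    last_chrom, last_pos = None, None
    for j, (chrom, pos) in enumerate(zip(gm.sites["chrom"], gm.sites["pos"])):
        chrom, pos = str(chrom), int(pos)
        if chrom != last_chrom or pos - last_pos >= min_gap_bp:
            keep[j] = True
            last_chrom, last_pos = chrom, pos
    out = gm.mask_sites(keep)
    # contract check: surviving successive gaps within a chromosome
    s = out.sites
    for c, grp in s.groupby("chrom", sort=False):
        gaps = np.diff(grp["pos"].to_numpy())
        assert (gaps >= min_gap_bp).all(), "thinning postcondition violated"
    report.add("thin_by_distance", gm.n_sites, out.n_sites)
    return out, report


def select_least_missing(
    gm: GenotypeMatrix,
    *,
    n: int = 50_000,
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """The ``n`` sites with fewest missing genotypes, stable under ties.

    Ties are broken by ascending (chrom, pos); the selection is returned
    in original coordinate order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    report = _report(report)
    order = pd.DataFrame(
        {
            "missing": gm.missing_counts(),
            "chrom": gm.sites["chrom"].astype(str),
            "pos": gm.sites["pos"].astype(int),
            "idx": np.arange(gm.n_sites),
        }
    ).sort_values(["missing", "chrom", "pos"], kind="mergesort")
    chosen = np.sort(order["idx"].to_numpy()[:n])
    out = gm.take_sites(chosen)
    report.add("select_least_missing", gm.n_sites, out.n_sites)
    return out, report
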
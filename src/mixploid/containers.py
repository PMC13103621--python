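"""Core in-memory containers for mixed-ploidy genotype data.

The central object is :class:`GenotypeMatrix`: a samples x sites matrix of
alternate-allele dosages (0..ploidy, -1 for missing) together with a
per-sample ploidy vector and a per-site annotation table.  Dosage is the
natural genotype encoding when diploids and tetraploids are analysed
jointly, because every downstream statistic here (allele frequencies,
genotype-class spectra, Ritland coancestry) is a function of dosage and
ploidy only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: columns every site annotation table carries
SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "qd", "fs", "mq"]


@dataclass
class SiteRecord:
    """One biallelic (or multiallelic) variant and its per-sample genotypes.

    ``genotypes`` holds alternate-allele dosages, ``MISSING`` (-1) where the
    call is absent.  ``qd``/``fs``/``mq`` are the GATK-style site
    annotations (quality by depth, Phred-scaled strand-bias Fisher p,
    RMS mapping quality); ``None`` when the annotation was absent.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: np.ndarray
    qd: float | None = None
    fs: float | None = None
    mq: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"positions are 1-based; got {self.pos}")

    @property
    def n_alt_alleles(self) -> int:
        return self.alt.count(",") + 1

    @property
    def is_biallelic(self) -> bool:
        return self.n_alt_alleles == 1


@dataclass
class GenotypeMatrix:
    """Samples x sites dosage matrix with per-sample ploidy.

    Parameters
    ----------
    samples
        Ordered sample identifiers.
    ploidy
        Per-sample ploidy (2 or 4), aligned with ``samples``.
    dosage
        ``(n_samples, n_sites)`` integer array of alternate-allele dosages;
        ``MISSING`` (-1) marks uncalled genotypes.
    sites
        Per-site annotation frame with at least the columns in
        :data:`SITE_COLUMNS`; ``qd``/``fs``/``mq`` may be NaN.
    groups
        Optional sample -> group label mapping (variety / species).
    """

    samples: list[str]
    ploidy: np.ndarray
    dosage: np.ndarray
    sites: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ploidy = np.asarray(self.ploidy, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int64)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        if not np.isin(self.ploidy, (2, 4)).all():
            raise ValueError("ploidy must be 2 or 4 for every sample")
        if self.dosage.size and (self.dosage.max(axis=1, initial=MISSING) > self.ploidy).any():
            raise ValueError("dosage exceeds sample ploidy")
        self.sites = self.sites.reset_index(drop=True)

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample {exc}") from None

    # -- derived per-site quantities ------------------------------------
    @property
    def called(self) -> np.ndarray:
        """Boolean mask of called genotypes, samples x sites."""
        return self.dosage != MISSING

    def call_fraction(self) -> np.ndarray:
        """Fraction of samples with a called genotype, per site."""
        return self.called.mean(axis=0)

    def missing_counts(self) -> np.ndarray:
        return (~self.called).sum(axis=0)

    def allele_frequencies(self) -> np.ndarray:
        """Dosage-weighted alternate-allele frequency per site.

        p = sum_i d_i / sum_i k_i over called genotypes; NaN where no
        genotype is called.
        """
        called = self.called
        alt = np.where(called, self.dosage, 0).sum(axis=0).astype(float)
        tot = (called * self.ploidy[:, None]).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / tot, np.nan)

    def site_keys(self) -> list[tuple]:
        """(chrom, pos, ref, alt) tuple per site."""
        s = self.sites
        return list(zip(s["chrom"], s["pos"], s["ref"], s["alt"]))

    # -- subsetting -----------------------------------------------------
    def take_sites(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=np.int64)
        return GenotypeMatrix(
            samples=list(self.samples),
            ploidy=self.ploidy.copy(),
            dosage=self.dosage[:, index],
            sites=self.sites.iloc[index].reset_index(drop=True),
            groups=dict(self.groups),
        )

    def mask_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        return self.take_sites(np.flatnonzero(np.asarray(keep, dtype=bool)))

    def take_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_index(ids)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            ploidy=self.ploidy[idx],
            dosage=self.dosage[idx, :],
            sites=self.sites.copy(),
            groups={s: g for s, g in self.groups.items() if s in set(ids)},
        )

    def site_record(self, j: int) -> SiteRecord:
        row = self.sites.iloc[j]
        def _opt(v):
            return None if pd.isna(v) else float(v)
        return SiteRecord(
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            ref=str(row["ref"]),
            alt=str(row["alt"]),
            genotypes=self.dosage[:, j].copy(),
            qd=_opt(row.get("qd", np.nan)),
            fs=_opt(row.get("fs", np.nan)),
            mq=_opt(row.get("mq", np.nan)),
        )

    def is_sorted(self) -> bool:
        """True when chromosomes form contiguous blocks with ascending positions."""
        s = self.sites
        seen: set[str] = set()
        prev_chrom: str | None = None
        prev_pos = -1
        for chrom, pos in zip(s["chrom"], s["pos"]):
            chrom = str(chrom)
            if chrom != prev_chrom:
                if chrom in seen:
                    return False  # chromosome block split apart
                seen.add(chrom)
                prev_chrom, prev_pos = chrom, -1
            if int(pos) < prev_pos:
                return False
            prev_pos = int(pos)
        return True
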
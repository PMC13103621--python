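"""Deterministic format exporters for downstream phylogenetic and
population-structure tools.

* :func:`export_phylip` writes a relaxed-PHYLIP nucleotide alignment:
  hom-ref -> ref base, hom-alt -> alt base, any mixed dosage -> the IUPAC
  ambiguity code of {ref, alt} (dosage is not representable in a
  nucleotide alignment), missing -> N.  Invariant columns are pruned so
  the alignment is valid input for Lewis-corrected ascertainment-bias
  models, which require variable sites only: a column is invariant when
  a single base is consistent with every non-N character (ambiguity
  codes resolve to their base sets).
* :func:`export_structure` writes the structure genotype file at the
  cohort's maximum ploidy: one row per allele copy, alleles coded 0/1 in
  sorted order, lower-ploidy samples padded with the missing code -9.
  The row multiset per tetraploid sample is a bijection of dosage, so the
  encoding is lossless.  A ``mainparams`` template records the run
  settings used in the original workflow (burn-in 200,000; 1,000,000
  MCMC repetitions).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .containers import MISSING, GenotypeMatrix

IUPAC = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}

_RESOLVE = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"},
    "W": {"A", "T"}, "K": {"G", "T"}, "M": {"A", "C"},
}


def genotype_to_base(dosage: int, ploidy: int, ref: str, alt: str) -> str:
    """One alignment character for a dosage call (N when missing)."""
    if dosage == MISSING:
        return "N"
    if dosage == 0:
        return ref
    if dosage == ploidy:
        return alt
    try:
        return IUPAC[frozenset((ref, alt))]
    except KeyError:
        raise ValueError(f"no ambiguity code for alleles {ref}/{alt}") from None


def invariant_columns(matrix: np.ndarray) -> np.ndarray:
    """Mask of columns resolvable to a single state (to be pruned).

    A column is invariant when the intersection of the possible-base sets
    of all its non-N characters is non-empty — e.g. all 'A', 'A' plus
    'N', or entirely 'N'.
    """
    n_sites = matrix.shape[1]
    mask = np.zeros(n_sites, dtype=bool)
    for j in range(n_sites):
        possible: set[str] | None = None
        for ch in matrix[:, j]:
            if ch == "N":
                continue
            sets = _RESOLVE[ch]
            possible = set(sets) if possible is None else possible & sets
            if not possible:
                break
        mask[j] = possible is None or bool(possible)
    return mask


def _char_matrix(gm: GenotypeMatrix) -> np.ndarray:
    for j, (ref, alt) in enumerate(zip(gm.sites["ref"], gm.sites["alt"])):
        if len(str(ref)) != 1 or len(str(alt)) != 1 or "," in str(alt):
            raise ValueError(
                f"site {j}: only biallelic SNPs can be exported ({ref}/{alt})"
            )
    chars = np.empty((gm.n_samples, gm.n_sites), dtype="<U1")
    refs = gm.sites["ref"].astype(str).to_numpy()
    alts = gm.sites["alt"].astype(str).to_numpy()
    for i in range(gm.n_samples):
        k = int(gm.ploidy[i])
        for j in range(gm.n_sites):
            chars[i, j] = genotype_to_base(int(gm.dosage[i, j]), k, refs[j], alts[j])
    return chars


def export_phylip(gm: GenotypeMatrix, path: str | Path) -> tuple[int, int]:
    """Write a relaxed-PHYLIP alignment with invariant columns pruned.

    Returns (n_samples, n_sites_written); the header always matches the
    written column count.
    """
    path = Path(path)
    chars = _char_matrix(gm)
    keep = ~invariant_columns(chars)
    chars = chars[:, keep]
    n, m = chars.shape
    with open(path, "w") as fh:
        fh.write(f"{n} {m}\n")
        for i, sample in enumerate(gm.samples):
            fh.write(f"{sample}  {''.join(chars[i])}\n")
    return n, m


def export_structure(
    gm: GenotypeMatrix, path: str | Path, *, missing_code: int = -9
) -> Path:
    """Write the structure genotype file (one row per allele copy).

    Every sample occupies ``max_ploidy`` rows.  Tetraploids contribute
    their four 0/1 alleles in sorted order; diploids contribute two
    alleles followed by padding rows of the missing code; missing
    genotypes are entirely missing-coded.
    """
    path = Path(path)
    kmax = int(gm.ploidy.max())
    with open(path, "w") as fh:
        for i, sample in enumerate(gm.samples):
            k = int(gm.ploidy[i])
            rows = np.full((kmax, gm.n_sites), missing_code, dtype=np.int64)
            for j in range(gm.n_sites):
                d = int(gm.dosage[i, j])
                if d == MISSING:
                    continue
                rows[:k, j] = [0] * (k - d) + [1] * d
            for r in range(kmax):
                fh.write(sample + "\t" + "\t".join(map(str, rows[r])) + "\n")
    return path


def structure_rows_to_dosage(
    rows: np.ndarray, *, missing_code: int = -9
) -> np.ndarray:
    """Invert :func:`export_structure` for one sample's row block.

    Returns the dosage vector; MISSING where every allele row is the
    missing code.
    """
    rows = np.asarray(rows)
    valid = rows != missing_code
    dosage = np.where(valid, rows, 0).sum(axis=0)
    return np.where(valid.any(axis=0), dosage, MISSING)


MAINPARAMS_TEMPLATE = """\
#define BURNIN     200000
#define NUMREPS    1000000
#define PLOIDY     {ploidy}
#define MISSING    {missing}
#define NUMINDS    {n_individuals}
#define NUMLOCI    {n_loci}
#define ONEROWPERIND 0
#define LABEL      1
#define POPDATA    0
#define POPFLAG    0
#define LOCDATA    0
#define PHENOTYPE  0
#define EXTRACOLS  0
#define MARKERNAMES 0
#define RECESSIVEALLELES 0
#define MAPDISTANCES 0
"""


def export_structure_params(
    path: str | Path, *, n_individuals: int, n_loci: int, ploidy: int = 4,
    missing_code: int = -9,
) -> Path:
    """Write a mainparams template matching the exported genotype file."""
    path = Path(path)
    path.write_text(
        MAINPARAMS_TEMPLATE.format(
            ploidy=ploidy, missing=missing_code,
            n_individuals=n_individuals, n_loci=n_loci,
        )
    )
    return path
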
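"""Reading and writing VCF 4.2 and sample sheets for mixed-ploidy cohorts.

Genotypes are written unphased at each sample's ploidy (``0/0/1/1`` for a
duplex tetraploid, ``./././.`` when missing).  The same dosage matrix can
also be rendered "diploid-called" (dosage collapsed to 0/0, 0/1, 1/1 by
presence of each allele), which emulates a caller run at ploidy 2 on
tetraploid material and lets the dual-ploidy position intersection be
exercised on one simulated truth set.

Reading goes through :mod:`pysam`, which handles per-sample ploidy
differences within one record.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .containers import MISSING, GenotypeMatrix

_HEADER = """\
##fileformat=VCFv4.2
##source=mixploid-simulator
##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">
##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled p-value, Fisher strand bias">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def dosage_to_gt(dosage: int, ploidy: int) -> str:
    """Unphased GT string for an alternate-allele dosage, e.g. 3,4 -> 0/1/1/1."""
    if dosage == MISSING:
        return "/".join(["."] * ploidy)
    if not 0 <= dosage <= ploidy:
        raise ValueError(f"dosage {dosage} out of range for ploidy {ploidy}")
    return "/".join(["0"] * (ploidy - dosage) + ["1"] * dosage)


def collapse_to_diploid(dosage: int, ploidy: int) -> int:
    """Diploid-called rendering: 0 if hom ref, ploidy-agnostic het if mixed, 2 if hom alt."""
    if dosage == MISSING:
        return MISSING
    if dosage == 0:
        return 0
    if dosage == ploidy:
        return 2
    return 1


def write_vcf(
    gm: GenotypeMatrix, path: str | Path, *, diploid_called: bool = False
) -> Path:
    """Write the matrix as VCF 4.2.

    With ``diploid_called=True`` every genotype is collapsed to ploidy 2 by
    allele presence, regardless of the sample's true ploidy.
    """
    path = Path(path)
    contigs = list(dict.fromkeys(gm.sites["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write(_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        sites = gm.sites
        for j in range(gm.n_sites):
            row = sites.iloc[j]
            info_parts = []
            for key in ("qd", "fs", "mq"):
                v = row[key]
                if not pd.isna(v):
                    info_parts.append(f"{key.upper()}={float(v):.2f}")
            info = ";".join(info_parts) or "."
            gts = []
            for i in range(gm.n_samples):
                d, k = int(gm.dosage[i, j]), int(gm.ploidy[i])
                if diploid_called:
                    gts.append(dosage_to_gt(collapse_to_diploid(d, k), 2))
                else:
                    gts.append(dosage_to_gt(d, k))
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t{info}\tGT\t" + "\t".join(gts) + "\n"
            )
    return path


def read_vcf(
    path: str | Path,
    sample_sheet: pd.DataFrame | None = None,
    *,
    check_ploidy: bool = True,
) -> GenotypeMatrix:
    """Load a VCF into a :class:`GenotypeMatrix`.

    Per-sample ploidy is taken from the GT tuples themselves; a genotype
    with any missing allele is treated as a missing call.  If a sample
    sheet (columns ``sample_id``, ``group``, ``ploidy``) is given, group
    labels are attached and the sheet's ploidy is cross-checked against
    the GT arity (disable ``check_ploidy`` for diploid-called renderings
    of tetraploid samples, where the arity is deliberately 2).
    """
    path = Path(path)
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        chroms, positions, refs, alts = [], [], [], []
        qd, fs, mq = [], [], []
        dosage_cols = []
        ploidy = np.zeros(len(samples), dtype=np.int64)
        for rec in vf:
            chroms.append(rec.chrom)
            positions.append(rec.pos)
            refs.append(rec.ref)
            alts.append(",".join(rec.alts) if rec.alts else ".")
            qd.append(rec.info.get("QD", np.nan))
            fs.append(rec.info.get("FS", np.nan))
            mq.append(rec.info.get("MQ", np.nan))
            col = np.empty(len(samples), dtype=np.int64)
            for i, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                if gt is None:
                    gt = ()
                k = len(gt)
                if k > ploidy[i]:
                    ploidy[i] = k
                if k == 0 or any(a is None for a in gt):
                    col[i] = MISSING
                else:
                    col[i] = sum(1 for a in gt if a != 0)
            dosage_cols.append(col)

    sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "ref": refs,
            "alt": alts,
            "qd": np.array(qd, dtype=float),
            "fs": np.array(fs, dtype=float),
            "mq": np.array(mq, dtype=float),
        }
    )
    dosage = (
        np.stack(dosage_cols, axis=1)
        if dosage_cols
        else np.zeros((len(samples), 0), dtype=np.int64)
    )
    groups: dict[str, str] = {}
    if sample_sheet is not None:
        sheet = sample_sheet.set_index("sample_id")
        for i, s in enumerate(samples):
            if s in sheet.index:
                groups[s] = str(sheet.loc[s, "group"])
                declared = int(sheet.loc[s, "ploidy"])
                if check_ploidy and ploidy[i] and declared != ploidy[i]:
                    raise ValueError(
                        f"sample {s}: sheet ploidy {declared} != GT arity {ploidy[i]}"
                    )
    ploidy[ploidy == 0] = 2  # samples missing everywhere default to diploid
    return GenotypeMatrix(
        samples=samples, ploidy=ploidy, dosage=dosage, sites=sites, groups=groups
    )


def write_sample_sheet(gm: GenotypeMatrix, path: str | Path) -> Path:
    """Tab-separated sheet: sample_id, group, ploidy."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "sample_id": gm.samples,
            "group": [gm.groups.get(s, "NA") for s in gm.samples],
            "ploidy": gm.ploidy,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    required = {"sample_id", "group", "ploidy"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    return df
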
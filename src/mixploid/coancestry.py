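"""Ritland method-of-moments coancestry for mixed-ploidy SNP panels.

For a biallelic locus with panel alternate-allele frequency p, write each
individual's within-individual allele frequencies as x_alt = d / k and
x_ref = 1 - x_alt (dosage d, ploidy k).  The per-locus moment estimator of
the coancestry (kinship) coefficient between individuals x and y is

    r_l = x_ref * y_ref / p_ref + x_alt * y_alt / p_alt - 1

with locus weight w_l = A - 1 = 1 for biallelic sites.  The multi-locus
estimate is the weighted average over loci called in both individuals.
Because only dosage and ploidy enter, diploid x tetraploid pairs are
handled exactly like same-ploidy pairs.  For non-inbred individuals the
expected self-coancestry is 1/k (0.5 diploid, 0.25 tetraploid), a
parent-offspring diploid pair has expectation 0.25, and unrelated pairs
0; moment estimates go negative and are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import GenotypeMatrix


@dataclass
class CoancestryMatrix:
    """Symmetric pairwise coancestry estimates with per-pair locus counts.

    ``values[i, j]`` is NaN for pairs sharing no called polymorphic locus
    (flagged, never silently 0); the diagonal holds self-coancestry.
    """

    sample_ids: list[str]
    values: np.ndarray
    n_loci_used: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.values.shape != (n, n) or self.n_loci_used.shape != (n, n):
            raise ValueError("matrix shapes do not match sample count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def to_tsv(self, path, counts_path=None) -> None:
        self.to_frame().to_csv(path, sep="\t")
        if counts_path is not None:
            pd.DataFrame(
                self.n_loci_used, index=self.sample_ids, columns=self.sample_ids
            ).to_csv(counts_path, sep="\t")

    def off_diagonal(self) -> np.ndarray:
        mask = ~np.eye(len(self.sample_ids), dtype=bool)
        return self.values[mask]


def ritland_locus(d_x: int, k_x: int, d_y: int, k_y: int, p: float) -> float:
    """Per-locus Ritland moment coancestry for one pair of genotypes.

    Raises ValueError at monomorphic frequencies (p = 0 or 1): such loci
    carry no information and must be skipped, not scored.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"monomorphic locus (p={p}); skip it")
    x_alt, y_alt = d_x / k_x, d_y / k_y
    x_ref, y_ref = 1.0 - x_alt, 1.0 - y_alt
    return x_ref * y_ref / (1.0 - p) + x_alt * y_alt / p - 1.0


def coancestry_matrix(
    gm: GenotypeMatrix, *, leave_pair_out: bool = False
) -> CoancestryMatrix:
    """All-pairs (and self) Ritland coancestry over the matrix's loci.

    Panel allele frequencies are dosage-weighted over every called
    genotype, focal pair included (``leave_pair_out=True`` recomputes p
    per pair excluding the two focal individuals, a sensitivity check).
    Loci monomorphic in the panel are excluded throughout.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least two samples")
    called = gm.called
    dos = np.where(called, gm.dosage, 0).astype(float)
    kk = called * gm.ploidy[:, None].astype(float)

    alt_tot = dos.sum(axis=0)
    cop_tot = kk.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_all = np.where(cop_tot > 0, alt_tot / cop_tot, np.nan)
    poly = (p_all > 0) & (p_all < 1)

    n = gm.n_samples
    x = np.where(called, gm.dosage / gm.ploidy[:, None], np.nan)
    values = np.full((n, n), np.nan)
    counts = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i, n):
            shared = called[i] & called[j] & poly
            if leave_pair_out:
                if i == j:
                    a = alt_tot - dos[i]
                    c = cop_tot - kk[i]
                else:
                    a = alt_tot - dos[i] - dos[j]
                    c = cop_tot - kk[i] - kk[j]
                with np.errstate(invalid="ignore", divide="ignore"):
                    p = np.where(c > 0, a / c, np.nan)
                shared = shared & (p > 0) & (p < 1)
            else:
                p = p_all
            m = int(shared.sum())
            counts[i, j] = counts[j, i] = m
            if m == 0:
                continue
            pi, xi, xj = p[shared], x[i, shared], x[j, shared]
            r = (1 - xi) * (1 - xj) / (1 - pi) + xi * xj / pi - 1.0
            values[i, j] = values[j, i] = float(r.mean())
    return CoancestryMatrix(list(gm.samples), values, counts)


def order_for_heatmap(cm: CoancestryMatrix) -> np.ndarray:
    """Leaf order from average-linkage clustering on 1 - r (rescaled).

    Coancestries are affinely rescaled so the most related pair is at
    distance 0 and the least related at 1; missing pairs are imputed to
    the panel mean for ordering only.  Ties are broken deterministically
    by clustering in lexicographic sample order; the returned permutation
    indexes the original sample order and is always a bijection.
    """
    n = len(cm.sample_ids)
    if n == 1:
        return np.array([0])
    r = cm.values.copy()
    off = ~np.eye(n, dtype=bool)
    finite_off = r[off][np.isfinite(r[off])]
    fill = float(finite_off.mean()) if finite_off.size else 0.0
    r[~np.isfinite(r)] = fill

    # lexicographic pre-sort makes scipy's tie handling label-deterministic
    lex = np.argsort(np.array(cm.sample_ids, dtype=object), kind="mergesort")
    rs = r[np.ix_(lex, lex)]
    rs = (rs + rs.T) / 2.0
    lo, hi = rs[off].min(), rs[off].max()
    span = hi - lo if hi > lo else 1.0
    dist = (hi - rs) / span
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = hierarchy.leaves_list(link)
    return lex[leaves]
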
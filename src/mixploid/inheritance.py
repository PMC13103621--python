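"""Mode-of-inheritance analysis for tetraploids: tetrasomic vs disomic.

Under Hardy-Weinberg equilibrium an autotetraploid with random pairing of
all four homologs (tetrasomic inheritance) has dosage-class frequencies
Binomial(4, p) at allele frequency p, so near p = 0.5 all five classes
(nulliplex .. quadruplex) are populated.  An allotetraploid with strictly
disomic inheritance behaves as two independent diploid subgenomes; in the
maximal-divergence case all segregation sits in one subgenome
(p1 = min(1, 2p), p2 = max(0, 2p - 1)), and at p = 0.5 every individual
is a fixed dosage-2 heterozygote — the two hypotheses are maximally
distinguishable in the allele-frequency / genotype-frequency plane.

The classifier computes the observed spectrum per sample group, the RMSE
of each candidate expectation surface over (site, class) cells, and a
"five-class score": the fraction of sites near p = 0.5 showing all five
dosage classes, the diagnostic signature of tetrasomic inheritance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import GenotypeMatrix

__all__ = [
    "GenotypeSpectrum",
    "ModelFit",
    "InsufficientDataError",
    "genotype_spectrum",
    "allele_frequencies",
    "tetrasomic_expectation",
    "disomic_expectation",
    "diploid_expectation",
    "collapse_tetraploid_expectation",
    "classify_inheritance",
    "plot_spectrum",
]


class InsufficientDataError(ValueError):
    """Raised when a group has too few usable sites for a verdict."""


@dataclass
class GenotypeSpectrum:
    """Per-site allele frequency and observed dosage-class frequencies.

    ``class_freqs[j, c]`` is the fraction of called genotypes in the group
    with dosage c at site j; rows sum to 1.  ``ploidy`` is the group's
    shared called ploidy, so there are ``ploidy + 1`` classes.
    """

    group: str
    ploidy: int
    site_freqs: np.ndarray        # (n_sites,)
    class_freqs: np.ndarray       # (n_sites, ploidy + 1)
    n_called: np.ndarray          # (n_sites,)

    @property
    def n_sites(self) -> int:
        return self.site_freqs.size

    def polymorphic(self) -> np.ndarray:
        """Mask of sites segregating within the group (0 < p < 1)."""
        return (self.site_freqs > 0) & (self.site_freqs < 1)


@dataclass
class ModelFit:
    model: str                     # tetrasomic | disomic | diploid
    rmse: float
    five_class_score: float | None = None
    n_sites: int = 0


# ---------------------------------------------------------------------------
# observed spectra
# ---------------------------------------------------------------------------

def allele_frequencies(gm: GenotypeMatrix, samples: list[str]) -> np.ndarray:
    """Dosage-weighted allele frequency per site for a sample subset.

    Supports mixed ploidy: p = sum_i d_i / sum_i k_i over called genotypes.
    """
    return gm.take_samples(samples).allele_frequencies()


def genotype_spectrum(
    gm: GenotypeMatrix, samples: list[str], *, group: str = "", min_called: int = 2
) -> GenotypeSpectrum:
    """Observed allele/genotype-frequency spectrum for one sample group.

    All samples must share one called ploidy (the dosage classes are
    ploidy-specific); sites with fewer than ``min_called`` called
    genotypes in the group are skipped.  Frequencies are group-internal.
    """
    if not samples:
        raise ValueError("empty sample group")
    sub = gm.take_samples(samples)
    ploidies = set(sub.ploidy.tolist())
    if len(ploidies) != 1:
        raise ValueError(
            f"group {group or samples!r} mixes ploidies {sorted(ploidies)}; "
            "genotype classes require a shared ploidy"
        )
    k = ploidies.pop()
    called = sub.called
    n_called = called.sum(axis=0)
    keep = n_called >= min_called
    dosage = sub.dosage[:, keep]
    called = called[:, keep]
    n_called = n_called[keep]

    p = np.where(called, dosage, 0).sum(axis=0) / (k * n_called)
    counts = np.zeros((dosage.shape[1], k + 1), dtype=float)
    for c in range(k + 1):
        counts[:, c] = (called & (dosage == c)).sum(axis=0)
    class_freqs = counts / n_called[:, None]
    return GenotypeSpectrum(
        group=group,
        ploidy=k,
        site_freqs=p,
        class_freqs=class_freqs,
        n_called=n_called,
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg expectation surfaces
# ---------------------------------------------------------------------------

def _check_p(p) -> tuple[np.ndarray, bool]:
    scalar = np.ndim(p) == 0
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if (p < 0).any() or (p > 1).any():
        raise ValueError("allele frequency outside [0, 1]")
    return p, scalar


def tetrasomic_expectation(p) -> np.ndarray:
    """Expected dosage-class frequencies under tetrasomic HW: Binomial(4, p).

    Returns shape (..., 5); scalar input gives a length-5 vector.
    """
    p, scalar = _check_p(p)
    out = stats.binom.pmf(np.arange(5), 4, p[..., None])
    return out[0] if scalar else out


def disomic_expectation(p, *, p1=None, p2=None) -> np.ndarray:
    """Expected dosage-class frequencies under disomic HW (two subgenomes).

    By default the maximal-divergence parametrization is used:
    p1 = min(1, 2p), p2 = max(0, 2p - 1); explicit subgenome frequencies
    may be supplied instead.  Dosage is the independent sum of two
    Binomial(2, p_i) draws; the exact convolution is returned, shape
    (..., 5).
    """
    p, scalar = _check_p(p)
    if p1 is None:
        p1 = np.minimum(1.0, 2.0 * p)
    else:
        p1 = _check_p(p1)[0]
    if p2 is None:
        p2 = np.maximum(0.0, 2.0 * p - 1.0)
    else:
        p2 = _check_p(p2)[0]
    c = np.arange(3)
    b1 = stats.binom.pmf(c, 2, np.asarray(p1)[..., None])  # (..., 3)
    b2 = stats.binom.pmf(c, 2, np.asarray(p2)[..., None])
    out = np.zeros(np.broadcast_shapes(b1.shape[:-1], b2.shape[:-1]) + (5,))
    for i in range(3):
        for j in range(3):
            out[..., i + j] += b1[..., i] * b2[..., j]
    return out[0] if scalar else out


def diploid_expectation(p) -> np.ndarray:
    """Expected genotype-class frequencies for HW diploids: Binomial(2, p)."""
    p, scalar = _check_p(p)
    out = stats.binom.pmf(np.arange(3), 2, p[..., None])
    return out[0] if scalar else out


def collapse_tetraploid_expectation(expected: np.ndarray) -> np.ndarray:
    """Collapse a 5-class tetraploid expectation to diploid-called classes.

    A caller run at ploidy 2 maps dosage 0 -> hom ref, 1..3 -> het,
    4 -> hom alt.
    """
    expected = np.asarray(expected)
    return np.stack(
        [
            expected[..., 0],
            expected[..., 1] + expected[..., 2] + expected[..., 3],
            expected[..., 4],
        ],
        axis=-1,
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _rmse(observed: np.ndarray, expected: np.ndarray) -> float:
    return float(np.sqrt(np.mean((observed - expected) ** 2)))


def five_class_score(
    spectrum: GenotypeSpectrum, *, p_window: tuple[float, float] = (0.45, 0.55)
) -> float:
    """Fraction of sites with p in the window showing all five dosage classes.

    The presence of all five classes near p = 0.5 is the diagnostic
    signature of tetrasomic inheritance; a strictly disomic tetraploid
    shows only the dosage-2 class there.  Returns 0.0 when no site falls
    in the window.
    """
    if spectrum.ploidy != 4:
        raise ValueError("five-class score is defined for tetraploid spectra")
    lo, hi = p_window
    in_window = (spectrum.site_freqs >= lo) & (spectrum.site_freqs <= hi)
    if not in_window.any():
        return 0.0
    all_five = (spectrum.class_freqs[in_window] > 0).all(axis=1)
    return float(all_five.mean())


def classify_inheritance(
    spectrum: GenotypeSpectrum,
    *,
    min_sites: int = 10,
    p_window: tuple[float, float] = (0.45, 0.55),
    strong_score: float = 0.5,
) -> tuple[str, list[ModelFit]]:
    """Classify a group's inheritance mode from its genotype spectrum.

    Tetraploid-called groups are fitted against the tetrasomic and disomic
    expectation surfaces; diploid-called groups against Binomial(2, p) and
    the two tetraploid surfaces collapsed to diploid-called classes.
    Monomorphic sites are excluded (all models coincide there).  The
    verdict is the smallest-RMSE model; a tetrasomic verdict is upgraded
    to ``"tetrasomic (strong)"`` when the five-class score exceeds
    ``strong_score``.

    Raises :class:`InsufficientDataError` below ``min_sites`` polymorphic
    sites rather than returning a silent verdict.
    """
    poly = spectrum.polymorphic()
    n_poly = int(poly.sum())
    if n_poly < min_sites:
        raise InsufficientDataError(
            f"group {spectrum.group!r}: {n_poly} polymorphic sites "
            f"(need >= {min_sites})"
        )
    p = spectrum.site_freqs[poly]
    obs = spectrum.class_freqs[poly]

    fits: list[ModelFit] = []
    if spectrum.ploidy == 4:
        score = five_class_score(spectrum, p_window=p_window)
        fits.append(
            ModelFit("tetrasomic", _rmse(obs, tetrasomic_expectation(p)), score, n_poly)
        )
        fits.append(
            ModelFit("disomic", _rmse(obs, disomic_expectation(p)), score, n_poly)
        )
    else:
        fits.append(ModelFit("diploid", _rmse(obs, diploid_expectation(p)), None, n_poly))
        fits.append(
            ModelFit(
                "tetrasomic",
                _rmse(obs, collapse_tetraploid_expectation(tetrasomic_expectation(p))),
                None,
                n_poly,
            )
        )
        fits.append(
            ModelFit(
                "disomic",
                _rmse(obs, collapse_tetraploid_expectation(disomic_expectation(p))),
                None,
                n_poly,
            )
        )

    best = min(fits, key=lambda f: f.rmse)
    verdict = best.model
    if (
        spectrum.ploidy == 4
        and verdict == "tetrasomic"
        and best.five_class_score is not None
        and best.five_class_score > strong_score
    ):
        verdict = "tetrasomic (strong)"
    return verdict, fits


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def plot_spectrum(spectrum: GenotypeSpectrum, fits, path) -> None:
    """Allele-frequency vs genotype-frequency scatter with model overlays.

    One colour per dosage class; each model in ``fits`` contributes its
    expectation curves on a fine p grid.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = spectrum.ploidy
    fig, ax = plt.subplots(figsize=(7, 5))
    cmap = plt.get_cmap("viridis", k + 1)
    for c in range(k + 1):
        ax.scatter(
            spectrum.site_freqs,
            spectrum.class_freqs[:, c],
            s=6,
            alpha=0.4,
            color=cmap(c),
            label=f"dosage {c}",
        )
    grid = np.linspace(0, 1, 201)
    surfaces = {
        "tetrasomic": tetrasomic_expectation,
        "disomic": disomic_expectation,
        "diploid": diploid_expectation,
    }
    styles = {"tetrasomic": "-", "disomic": "--", "diploid": ":"}
    for fit in fits:
        exp = surfaces[fit.model](grid)
        if k == 2 and exp.shape[-1] == 5:
            exp = collapse_tetraploid_expectation(exp)
        if k == 4 and exp.shape[-1] == 3:
            continue  # diploid surface not drawable on 5 classes
        for c in range(exp.shape[-1]):
            ax.plot(grid, exp[:, c], styles[fit.model], color=cmap(c), lw=1)
    ax.set_xlabel("alternate-allele frequency p")
    ax.set_ylabel("genotype-class frequency")
    ax.set_title(spectrum.group or "genotype spectrum")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
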
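"""Synthetic mixed-ploidy genotype data with known segregation structure.

The generator produces exactly the genotype patterns the downstream
analyses discriminate between:

* ``diploid_hw``    -- Hardy-Weinberg diploids, dosage ~ Binomial(2, p);
* ``tetrasomic``    -- autotetraploids with random pairing of all four
  homologs, dosage ~ Binomial(4, p);
* ``disomic``       -- allotetraploids with two diploid subgenomes.  A
  fraction ``subgenome_divergence`` of sites is differentially fixed
  (one subgenome 1/1, the other 0/0, so every individual has dosage 2);
  at the remaining sites all segregation is placed in one subgenome at
  frequency min(1, 2p) while the other is fixed for the reference,
  which maximises the contrast with the tetrasomic pattern.

Clonal populations replicate a single founder genotype; simple pedigrees
(parent pairs and their offspring) are supported for relatedness
calibration.  Output is a :class:`~mixploid.containers.GenotypeMatrix`
plus QD/FS/MQ site annotations with planted fractions of
filter-failing sites, writable as VCF 4.2 via :mod:`mixploid.vcfio`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix

INHERITANCE_MODES = ("diploid_hw", "tetrasomic", "disomic")

_BASES = np.array(list("ACGT"))


@dataclass
class PopulationSpec:
    """One simulated population and its segregation model.

    ``subgenome_divergence`` is the probability that a site is
    differentially fixed between the two subgenomes; it only applies to
    ``inheritance="disomic"``.  ``founder_beta`` parametrises the
    Beta(a, b) distribution the per-site alternate-allele frequency p is
    drawn from; the default Beta(0.8, 0.8) gives the U-shaped site
    frequency spectrum typical of SNP panels.
    """

    name: str
    n_individuals: int
    inheritance: str
    ploidy: int | None = None
    subgenome_divergence: float = 0.0
    clonal: bool = False
    founder_beta: tuple[float, float] = (0.8, 0.8)

    def __post_init__(self) -> None:
        if self.inheritance not in INHERITANCE_MODES:
            raise ValueError(f"unknown inheritance mode {self.inheritance!r}")
        expected = 2 if self.inheritance == "diploid_hw" else 4
        if self.ploidy is None:
            self.ploidy = expected
        elif self.ploidy != expected:
            raise ValueError(
                f"{self.inheritance} forces ploidy {expected}, got {self.ploidy}"
            )
        if self.n_individuals < 1:
            raise ValueError(f"population {self.name!r} has no individuals")
        if not 0.0 <= self.subgenome_divergence <= 1.0:
            raise ValueError("subgenome_divergence must be in [0, 1]")


@dataclass
class InfoFieldModel:
    """Distributions for the QD / FS / MQ site annotations.

    Disjoint fractions of sites are planted below/above the GATK hard
    thresholds (QD < 2, FS > 60, MQ < 40) so that the filter cascade has
    analytically known survivor counts; the exact planted count for each
    annotation is ``round(fraction * n_sites)``.
    """

    fail_qd_fraction: float = 0.0
    fail_fs_fraction: float = 0.0
    fail_mq_fraction: float = 0.0
    qd_pass: tuple[float, float] = (10.0, 35.0)
    qd_fail: tuple[float, float] = (0.1, 1.9)
    fs_pass: tuple[float, float] = (0.0, 20.0)
    fs_fail: tuple[float, float] = (61.0, 150.0)
    mq_pass: tuple[float, float] = (45.0, 60.0)
    mq_fail: tuple[float, float] = (10.0, 39.0)

    def __post_init__(self) -> None:
        total = self.fail_qd_fraction + self.fail_fs_fraction + self.fail_mq_fraction
        if total > 1.0:
            raise ValueError("failing fractions exceed 1")

    def planted_counts(self, n_sites: int) -> tuple[int, int, int]:
        return (
            round(self.fail_qd_fraction * n_sites),
            round(self.fail_fs_fraction * n_sites),
            round(self.fail_mq_fraction * n_sites),
        )


@dataclass
class SimulationConfig:
    populations: list[PopulationSpec]
    n_sites: int
    seed: int
    missing_rate: float = 0.0
    info: InfoFieldModel = field(default_factory=InfoFieldModel)
    pedigree_pairs: list[tuple[str, int]] = field(default_factory=list)
    n_chromosomes: int = 2
    chrom_length: int = 10_000_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")


# ---------------------------------------------------------------------------
# dosage generation
# ---------------------------------------------------------------------------

def _population_subgenomes(
    pop: PopulationSpec, p: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Dosage per subgenome copy-pair: array (n_individuals, 2, n_sites).

    For non-disomic modes the "subgenomes" are just a bookkeeping split of
    the homolog set (diploid: one Binomial(2,p) pair + an empty pair;
    tetrasomic: dosage split uniformly over the two pairs), which keeps
    pedigree gamete drawing uniform across modes.
    """
    n, L = pop.n_individuals, p.size
    n_draw = 1 if pop.clonal else n
    if pop.inheritance == "diploid_hw":
        sub = np.zeros((n_draw, 2, L), dtype=np.int64)
        sub[:, 0, :] = rng.binomial(2, p, size=(n_draw, L))
    elif pop.inheritance == "tetrasomic":
        total = rng.binomial(4, p, size=(n_draw, L))
        # random assignment of the 4 homologs into two pairs: first-pair
        # dosage is hypergeometric (2 of the 4 slots carry the pair)
        first = rng.hypergeometric(total, 4 - total, 2)
        sub = np.stack([first, total - first], axis=1)
    else:  # disomic
        fixed = rng.random(L) < pop.subgenome_divergence
        p1 = np.where(fixed, 1.0, np.minimum(1.0, 2.0 * p))
        p2 = np.where(fixed, 0.0, 0.0)
        sub = np.stack(
            [
                rng.binomial(2, p1, size=(n_draw, L)),
                rng.binomial(2, p2, size=(n_draw, L)),
            ],
            axis=1,
        )
    if pop.clonal:
        sub = np.repeat(sub, n, axis=0)
    return sub


def _gamete(sub: np.ndarray, inheritance: str, rng: np.random.Generator) -> np.ndarray:
    """Draw one gamete's subgenome dosages from a parent's (2, L) subgenomes.

    tetrasomic: 2 homologs sampled without replacement from the parent's 4
    (pairing is random, so the pair split is irrelevant and the draw is
    hypergeometric on total dosage); disomic: 1 homolog per subgenome;
    diploid: 1 of the 2 homologs.  Returns (2, L) gamete subgenome dosages.
    """
    L = sub.shape[1]
    out = np.zeros((2, L), dtype=np.int64)
    if inheritance == "tetrasomic":
        total = sub.sum(axis=0)
        drawn = rng.hypergeometric(total, 4 - total, 2)
        half = rng.hypergeometric(drawn, 2 - drawn, 1)
        out[0], out[1] = half, drawn - half
    elif inheritance == "disomic":
        out[0] = rng.hypergeometric(sub[0], 2 - sub[0], 1)
        out[1] = rng.hypergeometric(sub[1], 2 - sub[1], 1)
    else:  # diploid_hw
        out[0] = rng.hypergeometric(sub[0], 2 - sub[0], 1)
    return out


def simulate_pedigree_offspring(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    inheritance: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Offspring subgenome dosages (2, L) from two parents' (2, L) arrays.

    Each parent contributes one gamete according to the inheritance mode;
    the offspring genotype is the union of the two gametes.
    """
    if inheritance not in INHERITANCE_MODES:
        raise ValueError(f"unknown inheritance mode {inheritance!r}")
    if parent_a.shape != parent_b.shape:
        raise ValueError("parent genotype arrays differ in shape")
    return _gamete(parent_a, inheritance, rng) + _gamete(parent_b, inheritance, rng)


# ---------------------------------------------------------------------------
# site annotations
# ---------------------------------------------------------------------------

def _site_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    L = config.n_sites
    per = np.full(config.n_chromosomes, L // config.n_chromosomes)
    per[: L % config.n_chromosomes] += 1
    chroms, positions = [], []
    for c, n in enumerate(per, start=1):
        pos = np.sort(rng.choice(np.arange(1, config.chrom_length + 1), size=n, replace=False))
        chroms.extend([f"chr{c}"] * n)
        positions.extend(pos.tolist())
    ref_idx = rng.integers(0, 4, size=L)
    alt_idx = (ref_idx + rng.integers(1, 4, size=L)) % 4

    info = config.info
    n_qd, n_fs, n_mq = info.planted_counts(L)
    fail_idx = rng.choice(L, size=n_qd + n_fs + n_mq, replace=False)
    qd = rng.uniform(*info.qd_pass, size=L)
    fs = rng.uniform(*info.fs_pass, size=L)
    mq = rng.uniform(*info.mq_pass, size=L)
    qd[fail_idx[:n_qd]] = rng.uniform(*info.qd_fail, size=n_qd)
    fs[fail_idx[n_qd : n_qd + n_fs]] = rng.uniform(*info.fs_fail, size=n_fs)
    mq[fail_idx[n_qd + n_fs :]] = rng.uniform(*info.mq_fail, size=n_mq)

    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "qd": np.round(qd, 2),
            "fs": np.round(fs, 2),
            "mq": np.round(mq, 2),
        }
    )


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Simulate the full cohort described by ``config``.

    Per site a shared alternate-allele frequency p is drawn per population
    from its founder Beta distribution; dosages follow the population's
    segregation model.  Pedigree offspring are appended after their parent
    population with sample names ``<pop>_off<i>``.  Missingness is applied
    i.i.d. per genotype call at ``missing_rate`` as the final step.

    Identical config and seed produce identical output (and hence
    byte-identical VCF through :func:`mixploid.vcfio.write_vcf`).
    """
    rng = np.random.default_rng(config.seed)
    sites = _site_table(config, rng)
    L = config.n_sites

    samples: list[str] = []
    ploidies: list[int] = []
    groups: dict[str, str] = {}
    rows: list[np.ndarray] = []

    pedigree = dict(config.pedigree_pairs)
    for pop in config.populations:
        p = rng.beta(*pop.founder_beta, size=L)
        sub = _population_subgenomes(pop, p, rng)
        for i in range(pop.n_individuals):
            samples.append(f"{pop.name}_{i + 1}")
            ploidies.append(pop.ploidy)
            groups[samples[-1]] = pop.name
            rows.append(sub[i].sum(axis=0))
        n_off = pedigree.get(pop.name, 0)
        if n_off:
            if pop.n_individuals < 2:
                raise ValueError(
                    f"pedigree for {pop.name!r} needs at least 2 parents"
                )
            a, b = rng.choice(pop.n_individuals, size=2, replace=False)
            for j in range(n_off):
                child = simulate_pedigree_offspring(
                    sub[a], sub[b], pop.inheritance, rng
                )
                name = f"{pop.name}_off{j + 1}"
                samples.append(name)
                ploidies.append(pop.ploidy)
                groups[name] = pop.name
                rows.append(child.sum(axis=0))

    dosage = np.stack(rows, axis=0)
    if config.missing_rate > 0:
        drop = rng.random(dosage.shape) < config.missing_rate
        dosage = np.where(drop, MISSING, dosage)

    return GenotypeMatrix(
        samples=samples,
        ploidy=np.array(ploidies),
        dosage=dosage,
        sites=sites,
        groups=groups,
    )
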
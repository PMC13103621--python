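"""Filter cascade: thresholds, boundaries, idempotence, bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mixploid import filtering
from mixploid.containers import MISSING
from mixploid.simulate import InfoFieldModel, PopulationSpec, SimulationConfig, simulate_genotypes


def _full(n, L):
    return np.ones((n, L), dtype=int)


class TestHardFilter:
    def test_failing_site_removed(self, matrix_factory):
        gm = matrix_factory(_full(2, 1) * 1, [2, 2], qd=[1.9], fs=[10.0], mq=[50.0])
        out, report = filtering.hard_filter(gm)
        assert out.n_sites == 0
        assert report.stages == [("hard_filter", 1, 1, 0)]

    def test_boundary_values_retained(self, matrix_factory):
        # printed thresholds are strict inequalities
        gm = matrix_factory(_full(2, 1), [2, 2], qd=[2.0], fs=[60.0], mq=[40.0])
        out, _ = filtering.hard_filter(gm)
        assert out.n_sites == 1

    @pytest.mark.parametrize(
        "qd,fs,mq,kept",
        [
            (1.99, 0.0, 50.0, False),
            (2.01, 0.0, 50.0, True),
            (20.0, 60.01, 50.0, False),
            (20.0, 59.99, 50.0, True),
            (20.0, 0.0, 39.99, False),
            (20.0, 0.0, 40.01, True),
        ],
    )
    def test_each_criterion(self, matrix_factory, qd, fs, mq, kept):
        gm = matrix_factory(_full(2, 1), [2, 2], qd=[qd], fs=[fs], mq=[mq])
        out, _ = filtering.hard_filter(gm)
        assert (out.n_sites == 1) is kept

    def test_unannotated_sites_retained_by_default(self, matrix_factory):
        gm = matrix_factory(_full(2, 1), [2, 2], qd=[np.nan], fs=[np.nan], mq=[np.nan])
        assert filtering.hard_filter(gm)[0].n_sites == 1
        assert filtering.hard_filter(gm, drop_unannotated=True)[0].n_sites == 0

    def test_planted_disjoint_failures_leave_seventy_of_hundred(self):
        cfg = SimulationConfig(
            populations=[PopulationSpec("p", 5, "tetrasomic")],
            n_sites=100,
            seed=17,
            info=InfoFieldModel(0.1, 0.1, 0.1),
        )
        out, report = filtering.hard_filter(simulate_genotypes(cfg))
        assert out.n_sites == 70
        assert report.stages[-1] == ("hard_filter", 100, 30, 70)


class TestIntersect:
    def _pair(self, matrix_factory, dip_pos, tet_pos, dip_alt=None, tet_alt=None):
        dip = matrix_factory(
            np.array([[1] * len(dip_pos), [1] * len(dip_pos)]),
            [2, 2],
            positions=dip_pos,
            alt=dip_alt or ["G"] * len(dip_pos),
        )
        tet = matrix_factory(
            np.array([[2] * len(tet_pos), [3] * len(tet_pos)]),
            [4, 4],
            positions=tet_pos,
            alt=tet_alt or ["G"] * len(tet_pos),
        )
        return dip, tet

    def test_position_set_intersection(self, matrix_factory):
        dip, tet = self._pair(matrix_factory, [10, 20, 30], [20, 30, 40])
        out, _ = filtering.intersect_ploidy_callsets(dip, tet)
        assert out.sites["pos"].tolist() == [20, 30]

    def test_same_position_different_alt_excluded(self, matrix_factory):
        dip, tet = self._pair(matrix_factory, [10], [10], dip_alt=["G"], tet_alt=["T"])
        assert filtering.intersect_ploidy_callsets(dip, tet)[0].n_sites == 0
        out, _ = filtering.intersect_ploidy_callsets(dip, tet, position_only=True)
        assert out.n_sites == 1

    def test_genotypes_taken_per_sample_ploidy(self, matrix_factory):
        dip = matrix_factory(np.array([[1], [2]]), [2, 2], positions=[10])
        tet = matrix_factory(np.array([[3], [4]]), [4, 4], positions=[10])
        tet.ploidy = np.array([2, 4])  # first sample is truly diploid
        tet.dosage[0, 0] = 2
        out, _ = filtering.intersect_ploidy_callsets(dip, tet)
        assert out.dosage[:, 0].tolist() == [1, 4]  # dip payload, tet payload

    def test_dual_rendering_of_one_dataset_intersects_fully(self, tmp_path):
        from mixploid import vcfio

        cfg = SimulationConfig(
            populations=[PopulationSpec("p", 6, "tetrasomic")], n_sites=40, seed=23
        )
        gm = simulate_genotypes(cfg)
        vcfio.write_vcf(gm, tmp_path / "t.vcf")
        vcfio.write_vcf(gm, tmp_path / "d.vcf", diploid_called=True)
        tet = vcfio.read_vcf(tmp_path / "t.vcf")
        dip = vcfio.read_vcf(tmp_path / "d.vcf")
        out, _ = filtering.intersect_ploidy_callsets(dip, tet)
        assert out.n_sites == 40

    def test_unsorted_input_rejected(self, matrix_factory):
        dip, tet = self._pair(matrix_factory, [20, 10], [10, 20])
        with pytest.raises(ValueError, match="sorted"):
            filtering.intersect_ploidy_callsets(dip, tet)


class TestPresenceBiallelic:
    def test_inclusive_eighty_percent_boundary(self, matrix_factory):
        dosage = np.ones((10, 1), dtype=int)
        dosage[:2, 0] = MISSING  # 8 of 10 called
        gm = matrix_factory(dosage, [2] * 10)
        assert filtering.presence_biallelic_filter(gm, min_presence=0.80)[0].n_sites == 1
        dosage[2, 0] = MISSING  # 7 of 10
        gm = matrix_factory(dosage, [2] * 10)
        assert filtering.presence_biallelic_filter(gm, min_presence=0.80)[0].n_sites == 0

    def test_multiallelic_removed_despite_full_presence(self, matrix_factory):
        gm = matrix_factory(_full(4, 1), [2] * 4, alt=["G,T"])
        assert filtering.presence_biallelic_filter(gm)[0].n_sites == 0

    def test_min_presence_validation(self, matrix_factory):
        gm = matrix_factory(_full(2, 1), [2, 2])
        with pytest.raises(ValueError):
            filtering.presence_biallelic_filter(gm, min_presence=0.0)

    def test_survivors_match_enumeration(self, matrix_factory):
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, size=(10, 50))
        dosage[rng.random((10, 50)) < 0.3] = MISSING
        gm = matrix_factory(dosage, [2] * 10)
        out, _ = filtering.presence_biallelic_filter(gm, min_presence=0.8)
        expected = sum(
            1 for j in range(50) if (dosage[:, j] != MISSING).sum() >= 8
        )
        assert out.n_sites == expected


class TestSingletonMissingness:
    def test_total_dosage_one_is_singleton(self, matrix_factory):
        dosage = np.zeros((5, 1), dtype=int)
        dosage[0, 0] = 1  # one tetraploid simplex 0/0/0/1, rest hom ref
        gm = matrix_factory(dosage, [4] * 5)
        assert filtering.singleton_missingness_filter(gm)[0].n_sites == 0

    def test_dosage_two_across_two_carriers_retained(self, matrix_factory):
        dosage = np.zeros((5, 1), dtype=int)
        dosage[0, 0] = dosage[1, 0] = 1
        gm = matrix_factory(dosage, [4] * 5)
        assert filtering.singleton_missingness_filter(gm)[0].n_sites == 1

    def test_carrier_mode_differs_on_duplex_singleton(self, matrix_factory):
        dosage = np.zeros((5, 1), dtype=int)
        dosage[0, 0] = 2  # one duplex carrier: dosage 2 but 1 carrier
        gm = matrix_factory(dosage, [4] * 5)
        assert filtering.singleton_missingness_filter(gm, mode="dosage")[0].n_sites == 1
        assert filtering.singleton_missingness_filter(gm, mode="carriers")[0].n_sites == 0

    def test_minor_allele_can_be_reference(self, matrix_factory):
        dosage = np.full((5, 1), 4, dtype=int)
        dosage[0, 0] = 3  # one ref copy in the whole panel
        gm = matrix_factory(dosage, [4] * 5)
        assert filtering.singleton_missingness_filter(gm)[0].n_sites == 0

    def test_missingness_boundary_is_strict(self, matrix_factory):
        dosage = np.ones((10, 2), dtype=int)
        dosage[:2, 0] = MISSING  # exactly 20% -> retained
        dosage[:3, 1] = MISSING  # 30% -> removed
        gm = matrix_factory(dosage, [2] * 10)
        out, _ = filtering.singleton_missingness_filter(gm, max_missing=0.20)
        assert out.sites["pos"].tolist() == [1]


class TestThinning:
    def test_greedy_hand_trace(self, matrix_factory):
        gm = matrix_factory(_full(2, 4), [2, 2], positions=[1, 5000, 10001, 20001])
        out, _ = filtering.thin_by_distance(gm, min_gap_bp=10_000)
        assert out.sites["pos"].tolist() == [1, 10001, 20001]

    def test_resets_per_chromosome(self, matrix_factory):
        gm = matrix_factory(
            _full(2, 4),
            [2, 2],
            chrom=["chr1", "chr1", "chr2", "chr2"],
            positions=[1, 2, 1, 2],
        )
        out, _ = filtering.thin_by_distance(gm, min_gap_bp=10_000)
        assert out.sites["chrom"].tolist() == ["chr1", "chr2"]

    def test_dense_chromosome_keeps_exactly_one(self, matrix_factory):
        gm = matrix_factory(_full(2, 5), [2, 2], positions=[1, 2, 3, 4, 5])
        assert filtering.thin_by_distance(gm)[0].n_sites == 1

    def test_unsorted_rejected(self, matrix_factory):
        gm = matrix_factory(_full(2, 2), [2, 2], positions=[100, 1])
        with pytest.raises(ValueError, match="sorted"):
            filtering.thin_by_distance(gm)

    def test_surviving_gaps_respect_minimum(self, matrix_factory):
        rng = np.random.default_rng(1)
        pos = np.sort(rng.choice(200_000, size=120, replace=False)) + 1
        gm = matrix_factory(_full(2, 120), [2, 2], positions=pos)
        out, _ = filtering.thin_by_distance(gm, min_gap_bp=10_000)
        assert (np.diff(out.sites["pos"].to_numpy()) >= 10_000).all()


class TestLeastMissing:
    def test_ranking_example(self, matrix_factory):
        dosage = np.ones((3, 3), dtype=int)
        dosage[:2, 0] = MISSING  # missing counts per site: 2, 0, 1
        dosage[0, 2] = MISSING
        gm = matrix_factory(dosage, [2] * 3)
        out, _ = filtering.select_least_missing(gm, n=2)
        assert out.sites["pos"].tolist() == [2, 3]

    def test_n_larger_than_panel_is_identity(self, matrix_factory):
        gm = matrix_factory(_full(2, 5), [2, 2])
        out, _ = filtering.select_least_missing(gm, n=50)
        assert out.n_sites == 5

    def test_matches_brute_force_sort(self, matrix_factory):
        rng = np.random.default_rng(3)
        dosage = rng.integers(0, 3, size=(8, 60))
        dosage[rng.random((8, 60)) < 0.25] = MISSING
        gm = matrix_factory(dosage, [2] * 8)
        out, _ = filtering.select_least_missing(gm, n=20)
        oracle = sorted(
            range(60),
            key=lambda j: ((dosage[:, j] == MISSING).sum(), "chr1", j + 1),
        )[:20]
        assert sorted(out.sites["pos"].tolist()) == sorted(j + 1 for j in oracle)


class TestCascadeAccounting:
    @pytest.mark.parametrize(
        "stage",
        [
            filtering.hard_filter,
            filtering.presence_biallelic_filter,
            filtering.singleton_missingness_filter,
            filtering.thin_by_distance,
            lambda gm, **kw: filtering.select_least_missing(gm, n=30, **kw),
        ],
    )
    def test_every_stage_is_idempotent(self, stage):
        cfg = SimulationConfig(
            populations=[PopulationSpec("p", 10, "tetrasomic")],
            n_sites=120,
            seed=31,
            missing_rate=0.1,
            info=InfoFieldModel(0.1, 0.1, 0.1),
        )
        gm = simulate_genotypes(cfg)
        once, _ = stage(gm)
        twice, _ = stage(once)
        assert once.sites["pos"].tolist() == twice.sites["pos"].tolist()
        assert (once.dosage == twice.dosage).all()

    def test_report_counts_telescope(self):
        cfg = SimulationConfig(
            populations=[PopulationSpec("p", 10, "tetrasomic")],
            n_sites=150,
            seed=37,
            missing_rate=0.15,
            info=InfoFieldModel(0.1, 0.1, 0.1),
        )
        gm = simulate_genotypes(cfg)
        report = filtering.FilterReport()
        gm, report = filtering.hard_filter(gm, report=report)
        gm, report = filtering.presence_biallelic_filter(gm, report=report)
        gm, report = filtering.singleton_missingness_filter(gm, report=report)
        gm, report = filtering.thin_by_distance(gm, report=report)
        for (_, n_in, n_rm, n_out), (_, next_in, *_rest) in zip(
            report.stages, report.stages[1:]
        ):
            assert n_in - n_rm == n_out == next_in
        assert report.survivors == gm.n_sites

    def test_inconsistent_chain_rejected(self):
        report = filtering.FilterReport()
        report.add("a", 100, 60)
        with pytest.raises(ValueError, match="input"):
            report.add("b", 99, 50)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_idempotence_of_hard_filter_on_random_annotations(self, seed):
        rng = np.random.default_rng(seed)
        import pandas as pd

        from mixploid.containers import GenotypeMatrix

        L = 30
        sites = pd.DataFrame(
            {
                "chrom": ["chr1"] * L,
                "pos": np.arange(1, L + 1),
                "ref": ["A"] * L,
                "alt": ["G"] * L,
                "qd": rng.uniform(0, 5, L),
                "fs": rng.uniform(0, 120, L),
                "mq": rng.uniform(0, 80, L),
            }
        )
        gm = GenotypeMatrix(["a", "b"], np.array([2, 2]), np.ones((2, L), int), sites)
        once, _ = filtering.hard_filter(gm)
        twice, _ = filtering.hard_filter(once)
        assert once.n_sites == twice.n_sites
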
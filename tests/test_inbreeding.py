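import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from equusage.config import FilterConfig, ROHConfig
from equusage.inbreeding import (
    detect_roh,
    f_moments,
    froh,
    hard_filter,
    imputation_metrics,
    inbreeding_estimates,
    mendelian_error_rate,
)
from equusage.simulate import gen_genotypes
from equusage.types import GenotypeTable, ROHSegment, ValidationError

from oracles import mendel_allowed, roh_oracle


def make_table(dosages, pos=None, chrom="chr1", info=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n_ind, n_sites = dosages.shape
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos if pos is not None else np.arange(1, n_sites + 1) * 10,
            "ref": "A",
            "alt": "G",
        }
    )
    if info:
        for key, values in info.items():
            sites[key] = values
    return GenotypeTable([f"i{k}" for k in range(n_ind)], sites, dosages)


class TestHardFilter:
    def test_single_criterion_violation_attributed(self):
        info = {
            "QD": [1.9, 5.0],
            "FS": [10.0, 10.0],
            "SOR": [1.0, 1.0],
            "MQ": [50.0, 50.0],
            "MQRankSum": [0.0, 0.0],
            "ReadPosRankSum": [0.0, 0.0],
        }
        table = make_table(np.array([[0, 1], [1, 2], [0, 1], [1, 0]]), info=info)
        kept, report = hard_filter(table)
        assert kept.n_sites == 1
        assert report.removed_by["QD"] == 1
        assert sum(v for k, v in report.removed_by.items() if k != "QD") == 0

    def test_maf_boundary_is_strict(self):
        # 50 individuals, alt allele count 1 -> MAF 0.01 exactly: retained
        dosages = np.zeros((50, 2), dtype=np.int8)
        dosages[0, 0] = 1  # site 0: MAF exactly 0.01
        dosages[:, 1] = [1] * 25 + [0] * 25  # site 1: common
        table = make_table(dosages)
        kept, report = hard_filter(table, FilterConfig())
        assert kept.n_sites == 2
        dosages2 = dosages.copy()
        dosages2[0, 0] = 0  # site 0 now monomorphic: MAF 0 < 0.01
        kept2, report2 = hard_filter(make_table(dosages2))
        assert kept2.n_sites == 1 and report2.removed_by["MAF"] == 1

    def test_missing_info_field_passes_criterion(self):
        table = make_table(np.array([[0, 1], [1, 2], [1, 0], [2, 1]]))
        kept, report = hard_filter(table)
        assert kept.n_sites == 2  # no INFO at all: only MAF applies

    def test_mac_filter_drops_singletons_and_doubletons(self):
        dosages = np.zeros((30, 3), dtype=np.int8)
        dosages[0, 0] = 1  # singleton
        dosages[0, 1] = 2  # private doubleton
        dosages[:3, 2] = 1  # MAC 3: kept
        kept, report = hard_filter(
            make_table(dosages), FilterConfig(maf_min=0.0, min_mac=3)
        )
        assert kept.n_sites == 1 and report.removed_by["MAC"] == 2

    def test_ten_site_fixture_matches_per_site_oracle(self):
        rng = np.random.default_rng(0)
        info = {
            "QD": rng.uniform(0, 10, 10),
            "FS": rng.uniform(0, 100, 10),
            "SOR": rng.uniform(0, 5, 10),
            "MQ": rng.uniform(20, 60, 10),
            "MQRankSum": rng.uniform(-20, 5, 10),
            "ReadPosRankSum": rng.uniform(-12, 4, 10),
        }
        dosages = rng.integers(0, 3, size=(20, 10)).astype(np.int8)
        table = make_table(dosages, info=info)
        kept, _ = hard_filter(table)
        survive = []
        for j in range(10):
            p = np.mean(dosages[:, j]) / 2
            ok = (
                info["QD"][j] >= 2
                and info["FS"][j] <= 60
                and info["SOR"][j] <= 3
                and info["MQ"][j] >= 40
                and info["MQRankSum"][j] >= -12.5
                and info["ReadPosRankSum"][j] >= -8
                and min(p, 1 - p) >= 0.01
            )
            if ok:
                survive.append(j)
        assert kept.sites["pos"].tolist() == [(j + 1) * 10 for j in survive]

    def test_empty_table_rejected(self):
        table = make_table(np.zeros((2, 1), dtype=np.int8)).subset_sites([False])
        with pytest.raises(ValidationError):
            hard_filter(table)


class TestFMoments:
    def test_fully_homozygous_individual_is_one(self):
        # p = 0.5 at every locus, every individual homozygous
        dosages = np.array([[0, 2, 0, 2], [2, 0, 2, 0]], dtype=np.int8)
        f = f_moments(make_table(dosages))
        assert f["i0"] == pytest.approx(1.0)
        assert f["i1"] == pytest.approx(1.0)

    def test_hwe_proportions_give_zero(self):
        # individual i0: 4 loci at p=0.5, half het half hom -> O = E -> F = 0
        dosages = np.array(
            [
                [0, 2, 1, 1],
                [2, 0, 1, 1],
                [1, 1, 0, 2],
                [1, 1, 2, 0],
            ],
            dtype=np.int8,
        )
        f = f_moments(make_table(dosages))
        for ind in ("i0", "i1", "i2", "i3"):
            assert f[ind] == pytest.approx(0.0, abs=1e-12)

    def test_three_locus_hand_example(self):
        # target frequencies p = (0.5, 0.25, 0.1) over 10 individuals
        dosages = np.zeros((10, 3), dtype=np.int8)
        dosages[0] = [2, 1, 0]  # the focal individual
        dosages[1:5, 0] = 2  # alt count for locus 0: 2 + 8 = 10 -> p = 0.5
        dosages[1:5, 1] = 1  # locus 1: 1 + 4 = 5 -> p = 0.25
        dosages[1:3, 2] = 1  # locus 2: 0 + 2 = 2 -> p = 0.1
        table = make_table(dosages)
        np.testing.assert_allclose(table.allele_freq(), [0.5, 0.25, 0.1])
        f = f_moments(table)
        e_hom = (1 - 2 * 0.5 * 0.5) + (1 - 2 * 0.25 * 0.75) + (1 - 2 * 0.1 * 0.9)
        expected = (2 - e_hom) / (3 - e_hom)
        assert f["i0"] == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_loci_excluded_and_empty_is_none(self):
        dosages = np.array([[2, 2], [2, 0]], dtype=np.int8)
        # locus 0 monomorphic (p=1): excluded; locus 1 p=0.5
        f = f_moments(make_table(dosages))
        assert f["i0"] == pytest.approx(1.0)
        dosages2 = np.full((2, 2), 2, dtype=np.int8)
        f2 = f_moments(make_table(dosages2))  # all loci monomorphic
        assert f2["i0"] is None


ROH_CFG_SMALL = ROHConfig(
    window_snps=20, window_het=0, window_missing=2,
    hit_frac=0.05, min_snps=20, min_length_kb=100.0,
)


class TestDetectROH:
    def test_all_homozygous_chromosome_single_segment(self):
        pos = np.linspace(1, 2_000_000, 200).astype(int)
        table = make_table(np.zeros((1, 200), dtype=np.int8), pos=pos)
        segs = detect_roh(table, ROHConfig())
        assert len(segs) == 1
        seg = segs[0]
        assert seg.n_snps == 200
        assert seg.length == 2_000_000

    def test_span_below_minimum_length_rejected(self):
        pos = np.linspace(1, 1_400_000, 200).astype(int)
        table = make_table(np.zeros((1, 200), dtype=np.int8), pos=pos)
        assert detect_roh(table, ROHConfig()) == []

    def test_chromosome_shorter_than_window_yields_nothing(self):
        table = make_table(np.zeros((1, 100), dtype=np.int8))
        assert detect_roh(table, ROHConfig(window_snps=150)) == []

    def test_heterozygote_breaks_run(self):
        genos = np.zeros((1, 300), dtype=np.int8)
        genos[0, 150] = 1
        pos = np.linspace(1, 3_000_000, 300).astype(int)
        cfg = ROHConfig(window_snps=20, min_snps=20, min_length_kb=100.0,
                        hit_frac=0.5, window_missing=0)
        segs = detect_roh(make_table(genos, pos=pos), cfg)
        assert len(segs) == 2
        assert all(not (s.start < pos[150] <= s.end) for s in segs)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_exhaustive_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = 500
        genos = np.zeros(L, dtype=np.int8)
        het_at = rng.choice(L, size=rng.integers(0, 40), replace=False)
        genos[het_at] = 1
        miss_at = rng.choice(L, size=rng.integers(0, 30), replace=False)
        genos[miss_at] = -1
        pos = np.sort(rng.choice(5_000_000, size=L, replace=False)) + 1
        table = make_table(genos[None, :], pos=pos)
        got = [
            (s.start, s.end, s.n_snps) for s in detect_roh(table, ROH_CFG_SMALL)
        ]
        expected = roh_oracle(
            genos.tolist(), pos,
            window_snps=20, window_het=0, window_missing=2,
            hit_frac=0.05, min_snps=20, min_length_bp=100_000,
        )
        assert got == expected


class TestFroh:
    def test_no_segments_and_exact_arithmetic(self):
        assert froh([], 1_000_000_000, individuals=["a"]) == {"a": 0.0}
        segs = [
            ROHSegment("a", "chr1", 0, 250_000_000, 10_000),
            ROHSegment("a", "chr2", 0, 120_000_000, 10_000),
        ]
        got = froh(segs, 1_000_000_000)
        assert got["a"] == pytest.approx(0.37)

    def test_monotone_in_added_segments(self):
        base = [ROHSegment("a", "chr1", 0, 10_000_000, 900)]
        more = base + [ROHSegment("a", "chr2", 0, 5_000_000, 450)]
        assert froh(more, 10**9)["a"] >= froh(base, 10**9)["a"]

    def test_screened_length_validated(self):
        with pytest.raises(ValidationError):
            froh([], 0)


class TestMendelian:
    def test_impossible_and_uninformative_trios(self):
        # locus 0: parents hom-ref, child het -> error
        # locus 1: both parents het -> never an error
        dosages = np.array(
            [
                [1, 2],  # child
                [0, 1],  # sire
                [0, 1],  # dam
            ],
            dtype=np.int8,
        )
        per_locus, mean, sd = mendelian_error_rate(
            make_table(dosages), [("i0", "i1", "i2")]
        )
        np.testing.assert_array_equal(per_locus, [1.0, 0.0])
        assert mean == pytest.approx(0.5)

    def test_missing_genotype_not_evaluable(self):
        dosages = np.array([[1], [-1], [0]], dtype=np.int8)
        per_locus, mean, _ = mendelian_error_rate(
            make_table(dosages), [("i0", "i1", "i2")]
        )
        assert np.isnan(per_locus[0]) and np.isnan(mean)

    def test_unknown_individual_rejected(self):
        with pytest.raises(ValidationError, match="ghost"):
            mendelian_error_rate(
                make_table(np.zeros((3, 1), dtype=np.int8)),
                [("i0", "ghost", "i2")],
            )

    def test_matches_transmission_table_oracle(self):
        rng = np.random.default_rng(42)
        dosages = rng.integers(-1, 3, size=(6, 200)).astype(np.int8)
        table = make_table(dosages)
        trios = [("i0", "i1", "i2"), ("i3", "i4", "i5")]
        per_locus, _, _ = mendelian_error_rate(table, trios)
        for j in range(200):
            errs = evals = 0
            for child, sire, dam in trios:
                c = dosages[int(child[1:]), j]
                s = dosages[int(sire[1:]), j]
                d = dosages[int(dam[1:]), j]
                if -1 in (c, s, d):
                    continue
                evals += 1
                if c not in mendel_allowed(s, d):
                    errs += 1
            expected = errs / evals if evals else np.nan
            if np.isnan(expected):
                assert np.isnan(per_locus[j])
            else:
                assert per_locus[j] == pytest.approx(expected)


class TestImputationMetrics:
    def test_identical_tables_are_perfect(self):
        rng = np.random.default_rng(1)
        dosages = rng.integers(0, 3, size=(3, 50)).astype(np.int8)
        table = make_table(dosages)
        frame, conc, r2 = imputation_metrics(table, table)
        assert conc == 1.0 and r2 == pytest.approx(1.0)

    def test_dosage_flip_keeps_r2_but_not_concordance(self):
        rng = np.random.default_rng(2)
        dosages = rng.integers(0, 3, size=(1, 60)).astype(np.int8)
        flipped = (2 - dosages).astype(np.int8)
        frame, conc, r2 = imputation_metrics(make_table(dosages), make_table(flipped))
        assert r2 == pytest.approx(1.0)
        assert conc == pytest.approx(np.mean(dosages == 1))

    def test_constant_imputation_r2_missing(self):
        rng = np.random.default_rng(3)
        dosages = rng.integers(0, 3, size=(1, 30)).astype(np.int8)
        constant = np.ones_like(dosages)
        frame, conc, r2 = imputation_metrics(make_table(dosages), make_table(constant))
        assert np.isnan(frame["dosage_r2"].iloc[0])

    def test_disjoint_sites_rejected(self):
        a = make_table(np.zeros((1, 3), dtype=np.int8), pos=[10, 20, 30])
        b = make_table(np.zeros((1, 3), dtype=np.int8), pos=[11, 21, 31])
        with pytest.raises(ValidationError, match="overlap"):
            imputation_metrics(a, b)


def test_f_and_froh_positively_correlated_on_synthetic_panel():
    chroms = {"chr1": 120_000_000, "chr2": 80_000_000}
    target = np.array([0.0, 0.05, 0.1, 0.2, 0.3, 0.0, 0.15, 0.25])
    table, truth = gen_genotypes(8, 12_000, chroms, target, seed=33)
    cfg = ROHConfig(window_snps=50, min_snps=50)
    segments = detect_roh(table, cfg)
    est = inbreeding_estimates(table, segments, truth.screened_length_bp)
    f_hat = np.array([e.f_hat for e in est])
    f_roh = np.array([e.f_roh for e in est])
    assert np.corrcoef(f_hat, f_roh)[0, 1] > 0.7
    # planted F_ROH recovered to first order
    planted = np.array([truth.planted_froh(i) for i in table.individuals])
    np.testing.assert_allclose(f_roh, planted, atol=0.05)
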
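"""Region counting, normalization, the NB Wald test and BH correction."""

import numpy as np
import pandas as pd
import pytest

from pioneerkit.core_intervals import GenomicInterval
from pioneerkit.differential_signal import (
    RegionCountMatrix,
    bh_adjust,
    classify_differential,
    count_regions,
    libsize_factors,
    nb_test,
)
from pioneerkit.synthetic_data import simulate_counts, simulate_null_counts


def _matrix(counts, n_c=None):
    counts = np.asarray(counts)
    n = counts.shape[1]
    n_c = n_c if n_c is not None else n // 2
    return RegionCountMatrix(
        regions=[
            GenomicInterval("chr1", 100 * i, 100 * i + 50) for i in range(len(counts))
        ],
        samples=[f"s{j}" for j in range(n)],
        conditions=["control"] * n_c + ["treated"] * (n - n_c),
        counts=counts,
    )


class TestCountRegions:
    def test_two_fragments_one_region(self):
        reads = [GenomicInterval("chr1", 90, 140), GenomicInterval("chr1", 120, 180)]
        m = count_regions(
            {"a": reads}, {"a": "control"}, [GenomicInterval("chr1", 100, 160)]
        )
        assert m.counts[0, 0] == 2

    def test_reverse_strandness_assigns_opposite_strand_reads(self):
        region = GenomicInterval("chr1", 100, 200, "+")
        minus_read = [GenomicInterval("chr1", 120, 150, "-")]
        plus_read = [GenomicInterval("chr1", 120, 150, "+")]
        m_minus = count_regions(
            {"a": minus_read}, {"a": "control"}, [region],
            strandness="reverse", mode="five_prime",
        )
        m_plus = count_regions(
            {"a": plus_read}, {"a": "control"}, [region],
            strandness="reverse", mode="five_prime",
        )
        assert m_minus.counts[0, 0] == 1  # opposite strand -> assigned
        assert m_plus.counts[0, 0] == 0   # same strand -> not assigned

    def test_reverse_strandness_rejects_unstranded_reads(self):
        with pytest.raises(ValueError):
            count_regions(
                {"a": [GenomicInterval("chr1", 0, 50, ".")]},
                {"a": "control"},
                [GenomicInterval("chr1", 0, 100, "+")],
                strandness="reverse",
                mode="five_prime",
            )

    def test_incidence_oracle_with_overlapping_regions(self, rng):
        """Totals equal brute-force (read, region) incidences, reads counted
        once per overlapped region."""
        reads = [
            GenomicInterval("chr1", s, s + int(rng.integers(1, 120)))
            for s in rng.integers(0, 20_000, 400)
        ]
        regions = [
            GenomicInterval("chr1", s, s + int(rng.integers(50, 900)))
            for s in rng.integers(0, 20_000, 60)
        ]  # regions may overlap each other
        m = count_regions({"a": reads}, {"a": "control"}, regions)
        brute = np.zeros(len(regions), dtype=int)
        for i, reg in enumerate(regions):
            for r in reads:
                if r.start < reg.end and reg.start < r.end:
                    brute[i] += 1
        assert np.array_equal(m.counts[:, 0], brute)

    def test_counting_permutation_invariant(self, rng):
        reads = [
            GenomicInterval("chr1", s, s + 30) for s in rng.integers(0, 5000, 200)
        ]
        regions = [GenomicInterval("chr1", s, s + 200) for s in range(0, 4800, 300)]
        a = count_regions({"x": reads}, {"x": "control"}, regions)
        perm = [reads[i] for i in rng.permutation(len(reads))]
        b = count_regions({"x": perm}, {"x": "control"}, regions)
        assert np.array_equal(a.counts, b.counts)


class TestLibsizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = np.tile([[10], [20], [5]], (1, 4))
        assert np.allclose(libsize_factors(counts), 1.0)

    def test_doubling_a_column_doubles_its_factor(self):
        base = np.array([[10, 10], [20, 20], [5, 5]], dtype=float)
        doubled = base.copy()
        doubled[:, 1] *= 2
        f = libsize_factors(doubled)
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_hand_computed_five_by_four(self):
        counts = np.array(
            [
                [10, 20, 5, 40],
                [20, 40, 10, 80],
                [5, 10, 2, 20],
                [40, 80, 20, 160],
                [8, 16, 4, 32],
            ]
        )
        expected = np.array([0.70710678, 1.41421356, 0.35355339, 2.82842712])
        assert np.allclose(libsize_factors(counts), expected)

    def test_geometric_mean_is_one(self, rng):
        counts = rng.poisson(30, (50, 6)) + 1
        f = libsize_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)
        assert (f > 0).all()

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            libsize_factors(np.zeros((3, 2)))


class TestBHAdjust:
    def test_single_p(self):
        assert bh_adjust([0.01])[0] == pytest.approx(0.01)

    def test_worked_step_up_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_brute_force_step_up(self, rng):
        def brute_bh(p):
            p = np.asarray(p, dtype=float)
            m = len(p)
            order = np.argsort(p, kind="stable")
            q = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                q[i] = running
            return q

        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            assert np.allclose(bh_adjust(p), brute_bh(p))

    def test_monotone_in_p_rank(self, rng):
        p = np.sort(rng.random(200))
        q = bh_adjust(p)
        assert (np.diff(q) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()


class TestClassify:
    @pytest.mark.parametrize(
        "lfc,fdr,expected",
        [
            (1.2, 0.05, "increased"),
            (1.2, 0.2, "unchanged"),
            (-1.0, 0.01, "unchanged"),  # strict inequality at the cut
            (1.0, 0.01, "unchanged"),
            (-1.3, 0.05, "decreased"),
            (0.2, 0.001, "unchanged"),
        ],
    )
    def test_threshold_rules(self, lfc, fdr, expected):
        assert classify_differential([lfc], [fdr])[0] == expected


class TestNBTest:
    def test_identical_condition_means_give_zero_lfc(self):
        counts = np.tile([[100], [50], [20], [80]], (1, 8))
        res = nb_test(_matrix(counts))
        assert np.allclose(res["log2FC"], 0.0)
        assert (res["class"] == "unchanged").all()

    def test_single_replicate_rejected(self):
        m = RegionCountMatrix(
            regions=[GenomicInterval("chr1", 0, 10)],
            samples=["a", "b"],
            conditions=["control", "treated"],
            counts=np.array([[5, 9]]),
        )
        with pytest.raises(ValueError, match="replicates"):
            nb_test(m)

    def test_spiked_effect_recovery(self):
        """True log2FC = 2 spikes at depth 1e6 recovered within +-0.3."""
        n = 400
        lfc = np.zeros(n)
        lfc[:40] = 2.0
        matrix, truth = simulate_counts(
            n, n_per_condition=4, depth=1e6, dispersion=0.05, log2fc=lfc, seed=5
        )
        res = nb_test(matrix)
        est = res["log2FC"].to_numpy()[:40]
        # mean estimate over spiked regions; per-region scatter is set by
        # the NB dispersion, not the estimator
        assert abs(est.mean() - 2.0) <= 0.3
        assert (res.iloc[:40]["class"] == "increased").mean() > 0.9

    def test_null_calibration_single_seed(self):
        """Raw-p rejection near nominal alpha on a null simulation."""
        matrix, _ = simulate_null_counts(2000, 4, depth=1e6, dispersion=0.05, seed=7)
        res = nb_test(matrix)
        rate = float((res["pvalue"] < 0.05).mean())
        assert 0.03 <= rate <= 0.07
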
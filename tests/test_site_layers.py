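"""Layer classification axes, contingency summaries and the sigmoid fit."""

import numpy as np
import pandas as pd
import pytest

from pioneerkit.core_intervals import GenomicInterval, IntervalIndex
from pioneerkit.site_layers import (
    BindingSite,
    accessibility_transition,
    collapse_state,
    fit_occupancy_response,
    re_status,
    summarize_layers,
    tss_status,
)


class TestAccessibilityTransition:
    SITE = GenomicInterval("chr1", 1000, 1200)
    PEAK = [GenomicInterval("chr1", 1100, 1400)]
    NONE = []

    @pytest.mark.parametrize(
        "control,treated,expected",
        [
            (PEAK, PEAK, "constitutively_open"),
            (NONE, PEAK, "opened"),
            (NONE, NONE, "constitutively_closed"),
            (PEAK, NONE, "putatively_closed"),
        ],
    )
    def test_four_way_mapping(self, control, treated, expected):
        got = accessibility_transition(
            self.SITE, IntervalIndex(control), IntervalIndex(treated)
        )
        assert got == expected

    def test_labels_partition_random_fixture(self, rng):
        sites = [
            GenomicInterval("chr1", s, s + 200) for s in rng.integers(0, 50_000, 300)
        ]
        pk_c = IntervalIndex(
            GenomicInterval("chr1", s, s + 300) for s in rng.integers(0, 50_000, 40)
        )
        pk_t = IntervalIndex(
            GenomicInterval("chr1", s, s + 300) for s in rng.integers(0, 50_000, 60)
        )
        labels = [accessibility_transition(s, pk_c, pk_t) for s in sites]
        counts = pd.Series(labels).value_counts()
        assert counts.sum() == len(sites)
        assert set(counts.index) <= {
            "constitutively_open", "opened", "constitutively_closed",
            "putatively_closed",
        }


class TestCollapseState:
    @pytest.mark.parametrize(
        "label,expected",
        [
            ("TssA", "promoter"), ("TssBiv", "promoter"), ("TssFlnk", "promoter"),
            ("TssFlnkD", "promoter"), ("TssFlnkU", "promoter"),
            ("EnhA1", "enhancer"), ("EnhA2", "enhancer"), ("EnhBiv", "enhancer"),
            ("EnhG1", "enhancer"), ("EnhG2", "enhancer"), ("EnhWk", "enhancer"),
            ("Tx", "transcription"), ("TxWk", "transcription"),
            ("Het", "quiescent"), ("Quies", "quiescent"), ("ReprPC", "quiescent"),
            ("ReprPCWk", "quiescent"), ("ZNF/Rpts", "quiescent"),
            ("UnknownState", "n/a"), ("", "n/a"),
        ],
    )
    def test_full_mapping(self, label, expected):
        assert collapse_state(label) == expected


class TestReStatus:
    @pytest.mark.parametrize(
        "subtype,expected",
        [
            ("two_half_sites_no_spacer", "canonical"),
            ("three_quarter_sites", "noncanonical"),
            ("spacer1_half_sites", "noncanonical"),
            ("single_half_site", "noncanonical"),
            ("none", "none"),
        ],
    )
    def test_subtype_mapping(self, subtype, expected):
        site = BindingSite(
            interval=GenomicInterval("chr1", 0, 200),
            re_subtype=subtype,
            re_center=100 if subtype != "none" else None,
        )
        assert re_status(site)[0] == expected

    def test_unknown_subtype_rejected(self):
        with pytest.raises(ValueError):
            BindingSite(
                interval=GenomicInterval("chr1", 0, 200), re_subtype="mystery"
            )


class TestTssStatus:
    SITE = GenomicInterval("chr1", 1000, 1200)

    def test_induced_when_any_overlapping_tss_strong(self):
        peaks = [
            (GenomicInterval("chr1", 1100, 1150, "+"), 0.8),
            (GenomicInterval("chr1", 1050, 1090, "+"), 0.1),
        ]
        assert tss_status(self.SITE, peaks) == "induced"

    def test_uninduced_at_weak_tss(self):
        peaks = [(GenomicInterval("chr1", 1100, 1150, "+"), 0.2)]
        assert tss_status(self.SITE, peaks) == "uninduced"

    def test_boundary_is_strict(self):
        peaks = [(GenomicInterval("chr1", 1100, 1150, "+"), 0.5)]
        assert tss_status(self.SITE, peaks) == "uninduced"

    def test_none_without_overlap(self):
        peaks = [(GenomicInterval("chr1", 9000, 9050, "+"), 2.0)]
        assert tss_status(self.SITE, peaks) == "none"

    def test_upstream_extension_is_strand_aware(self):
        # + strand peak at 1250 extends 200 bp left -> reaches the site
        plus = [(GenomicInterval("chr1", 1250, 1300, "+"), 1.0)]
        assert tss_status(self.SITE, plus, extension=200) == "induced"
        # - strand peak at the same coordinates extends right -> no overlap
        minus = [(GenomicInterval("chr1", 1250, 1300, "-"), 1.0)]
        assert tss_status(self.SITE, minus, extension=200) == "none"


class TestSummarizeLayers:
    def test_axis_counts_sum_to_total_and_percentages_to_100(self, rng):
        n = 500
        table = pd.DataFrame(
            {
                "transition": rng.choice(
                    ["constitutively_open", "opened", "constitutively_closed"], n
                ),
                "state": rng.choice(
                    ["promoter", "enhancer", "transcription", "quiescent"], n
                ),
            }
        )
        s = summarize_layers(table)
        for axis in ("transition", "state"):
            assert sum(s.counts[axis].values()) == n
            assert sum(s.fractions[axis].values()) == pytest.approx(1.0)

    def test_invariant_under_row_order(self, rng):
        table = pd.DataFrame(
            {"transition": rng.choice(["opened", "constitutively_open"], 100)}
        )
        shuffled = table.sample(frac=1, random_state=1).reset_index(drop=True)
        assert summarize_layers(table).counts == summarize_layers(shuffled).counts

    def test_zero_sites(self):
        s = summarize_layers(pd.DataFrame(columns=["transition"]))
        assert s.total == 0
        assert s.counts == {"transition": {}}

    def test_percent_rounding(self):
        table = pd.DataFrame({"transition": ["opened"] * 27 + ["other"] * 73})
        s = summarize_layers(table, axes=["transition"])
        assert s.percent("transition", "opened") == 27
        assert s.percent("transition", "opened", digits=1) == 27.0


class TestSigmoidFit:
    @staticmethod
    def _gen(a, b, x0, k, n=200, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        logx = rng.uniform(x0 - 2, x0 + 2, n)
        y = a + (b - a) / (1 + np.exp(-(logx - x0) / k))
        y = y + rng.normal(0, noise, n)
        return 10.0**logx, y

    def test_noise_free_parameter_recovery(self):
        x, y = self._gen(a=-0.5, b=3.0, x0=1.2, k=0.3)
        fit = fit_occupancy_response(x, y)
        assert fit.x0 == pytest.approx(1.2, abs=1e-3)
        assert fit.a == pytest.approx(-0.5, abs=1e-3)
        assert fit.b == pytest.approx(3.0, abs=1e-3)
        assert fit.r2 == pytest.approx(1.0, abs=1e-6)

    def test_noisy_midpoint_recovery(self):
        x, y = self._gen(a=0.0, b=2.5, x0=1.5, k=0.25, n=300, noise=0.2, seed=3)
        fit = fit_occupancy_response(x, y)
        assert abs(fit.x0 - 1.5) <= 0.1
        assert fit.rho > 0.8 and fit.rho_p < 1e-6

    def test_sigmoid_beats_straight_line_on_sigmoid_data(self):
        x, y = self._gen(a=0.0, b=2.0, x0=1.0, k=0.15, n=250, noise=0.15, seed=7)
        fit = fit_occupancy_response(x, y)
        logx = np.log10(x)
        slope, intercept = np.polyfit(logx, y, 1)
        resid = y - (slope * logx + intercept)
        r2_line = 1 - resid.var() / y.var()
        assert fit.r2 >= r2_line

    def test_constant_response_flagged_degenerate(self):
        x = np.linspace(1, 100, 30)
        fit = fit_occupancy_response(x, np.full(30, 1.5))
        assert fit.degenerate
        assert np.isnan(fit.rho)

    def test_requires_positive_occupancy_and_enough_points(self):
        with pytest.raises(ValueError):
            fit_occupancy_response([1.0, -2.0] + [3.0] * 10, [0.0] * 12)
        with pytest.raises(ValueError):
            fit_occupancy_response([1.0] * 5, [0.0] * 5)
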
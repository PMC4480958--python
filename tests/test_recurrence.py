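"""Recurrence tables, percentage formatting, and coverage-curve CCDs."""

import pandas as pd
import pytest

from conftest import brute_coverage, brute_recurrence

from panrecur.io import Catalog, DonorRoster, MutationKey
from panrecur.recurrence import (
    coverage_curve,
    donors_vs_mutations,
    format_percent,
    recurrence_counts,
    recurrence_summary,
)
from panrecur.simulate import SimConfig, generate_catalog


class TestRecurrenceCounts:
    def test_toy_hand_count(self, toy_catalog):
        table = recurrence_counts(toy_catalog, "PanCancer")
        entries = table.entries
        m1 = MutationKey("7", 140453136, "A", "T")
        m2 = MutationKey("12", 25398284, "C", "A")
        m3 = MutationKey("17", 7577120, "G", "A")
        assert {k: len(v) for k, v in entries.items()} == {m1: 2, m2: 1, m3: 1}

    def test_duplicate_listing_counts_donor_once(self, toy_catalog):
        dup = pd.concat([toy_catalog.calls, toy_catalog.calls.iloc[[0]]],
                        ignore_index=True)
        # Catalog-level invariant forbids this; count through a raw frame
        cat = Catalog(dup.drop_duplicates(
            subset=["donor_id", "chromosome", "start", "ref", "alt"]))
        table = recurrence_counts(cat, "PanCancer")
        m1 = MutationKey("7", 140453136, "A", "T")
        assert len(table.entries[m1]) == 2

    def test_empty_scope_gives_empty_table(self, toy_catalog):
        table = recurrence_counts(toy_catalog, "NOSUCH")
        assert table.n_unique == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_catalogs(self, seed):
        cfg = SimConfig(donors=40, burden_mean=12.0, shared_pool_size=80,
                        shared_fraction=0.4, seed=seed)
        cat = generate_catalog(cfg)
        table = recurrence_counts(cat, "PanCancer")
        ref = brute_recurrence(cat, "PanCancer")
        got = {k: len(v) for k, v in table.entries.items()}
        assert got == {k: len(v) for k, v in ref.items()}


class TestFormatPercent:
    @pytest.mark.parametrize(
        "num,den,expected",
        [
            (171_314, 9_871_474, "1.7%"),
            (0, 1014, "0.0%"),
            (1, 3, "33.3%"),
            (6296, 6584, "95.6%"),
            (13, 86, "15.1%"),
        ],
    )
    def test_half_up_rounding(self, num, den, expected):
        assert format_percent(num, den, 1) == expected

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            format_percent(1, 0)


class TestRecurrenceSummary:
    def test_toy_summary(self, toy_catalog, toy_roster):
        table = recurrence_counts(toy_catalog, "PanCancer")
        s = recurrence_summary(table, toy_roster)
        assert (s.total_unique_mutations, s.recurrent_mutations) == (3, 1)
        assert s.recurrent_pct == "33.3%"
        assert (s.donors_with_recurrent, s.donors_with_recurrent_pct) == (2, "66.7%")

    def test_no_recurrent_mutations(self):
        rows = [
            {"donor_id": "d1", "cancer_type": "T", "chromosome": "1", "start": 1,
             "ref": "A", "alt": "T", "consequence": "missense_variant", "gene": "G"},
            {"donor_id": "d2", "cancer_type": "T", "chromosome": "1", "start": 2,
             "ref": "A", "alt": "T", "consequence": "missense_variant", "gene": "G"},
        ]
        cat = Catalog(pd.DataFrame(rows))
        s = recurrence_summary(recurrence_counts(cat, "T"), cat.roster)
        assert s.recurrent_mutations == 0 and s.donors_with_recurrent == 0

    def test_roster_smaller_than_observed_is_inconsistent(self, toy_catalog):
        table = recurrence_counts(toy_catalog, "TYP")
        small = DonorRoster({"TYP": frozenset({"d1"})})
        with pytest.raises(ValueError, match="roster"):
            recurrence_summary(table, small)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        cfg = SimConfig(donors=50, burden_mean=10.0, shared_pool_size=60,
                        shared_fraction=0.5, seed=seed)
        cat = generate_catalog(cfg)
        table = recurrence_counts(cat, "PanCancer")
        s = recurrence_summary(table, cat.roster)
        ref = brute_recurrence(cat, "PanCancer")
        rec = {m: d for m, d in ref.items() if len(d) >= 2}
        assert s.total_unique_mutations == len(ref)
        assert s.recurrent_mutations == len(rec)
        donors = set().union(*rec.values()) if rec else set()
        assert s.donors_with_recurrent == len(donors)


class TestCoverageCurve:
    def test_toy_curve(self, toy_catalog, toy_roster):
        table = recurrence_counts(toy_catalog, "PanCancer")
        curve = coverage_curve(table, toy_roster, k_max=3)
        got = [(p.k, p.mutation_fraction, p.donor_fraction) for p in curve.points]
        assert got == [
            (1, 1.0, 1.0),
            (2, pytest.approx(1 / 3), pytest.approx(2 / 3)),
            (3, 0.0, 0.0),
        ]

    def test_single_donor_catalog(self):
        rows = [{"donor_id": "d1", "cancer_type": "T", "chromosome": "1",
                 "start": 1, "ref": "A", "alt": "T",
                 "consequence": "missense_variant", "gene": "G"}]
        cat = Catalog(pd.DataFrame(rows))
        curve = coverage_curve(recurrence_counts(cat, "T"), cat.roster, k_max=2)
        got = [(p.mutation_fraction, p.donor_fraction) for p in curve.points]
        assert got == [(1.0, 1.0), (0.0, 0.0)]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_every_k(self, seed):
        cfg = SimConfig(donors=30, burden_mean=15.0, shared_pool_size=50,
                        shared_fraction=0.5, seed=seed)
        cat = generate_catalog(cfg)
        table = recurrence_counts(cat, "PanCancer")
        curve = coverage_curve(table, cat.roster)
        ref = brute_coverage(brute_recurrence(cat, "PanCancer"),
                             cat.roster.size(), table.max_recurrence)
        got = [(p.k, p.mutation_fraction, p.donor_fraction) for p in curve.points]
        assert got == [(k, pytest.approx(mf), pytest.approx(df))
                       for k, mf, df in ref]

    def test_monotone_and_normalized(self):
        for seed in range(10):
            cfg = SimConfig(donors=25, burden_mean=8.0, shared_pool_size=40,
                            shared_fraction=0.6, seed=seed)
            cat = generate_catalog(cfg)
            curve = coverage_curve(recurrence_counts(cat, "PanCancer"), cat.roster)
            mf = [p.mutation_fraction for p in curve.points]
            df = [p.donor_fraction for p in curve.points]
            assert mf[0] == 1.0
            assert all(a >= b for a, b in zip(mf, mf[1:]))
            assert all(a >= b for a, b in zip(df, df[1:]))
            assert all(0 <= v <= 1 for v in mf + df)

    def test_pancancer_recurrence_dominates_per_type(self):
        cfgs = [
            SimConfig(cancer_type=t, donors=30, burden_mean=10.0,
                      shared_pool_size=50, shared_fraction=0.5, pool_label="pan")
            for t in ("TA", "TB")
        ]
        cat = generate_catalog(cfgs, seed=4)
        pan = recurrence_counts(cat, "PanCancer")
        n_pan = (pan.counts["recurrence"] >= 2).sum()
        for t in ("TA", "TB"):
            per = recurrence_counts(cat, t)
            assert n_pan >= (per.counts["recurrence"] >= 2).sum()


class TestDonorsVsMutations:
    def test_toy_reindexing(self, toy_catalog, toy_roster):
        table = recurrence_counts(toy_catalog, "PanCancer")
        curve = coverage_curve(table, toy_roster, k_max=3)
        pts = donors_vs_mutations(curve)
        assert pts == [
            (0.0, 0.0),
            (pytest.approx(1 / 3), pytest.approx(2 / 3)),
            (1.0, 1.0),
        ]

    def test_constant_curve_collapses(self):
        from panrecur.recurrence import CoverageCurve, CoveragePoint

        curve = CoverageCurve("x", [CoveragePoint(1, 0.5, 0.9),
                                    CoveragePoint(2, 0.5, 0.7)])
        assert donors_vs_mutations(curve) == [(0.5, 0.9)]

    def test_monotone_in_x_on_synthetic_curves(self):
        cfg = SimConfig(donors=60, burden_mean=20.0, shared_pool_size=100,
                        shared_fraction=0.4, seed=9)
        cat = generate_catalog(cfg)
        curve = coverage_curve(recurrence_counts(cat, "PanCancer"), cat.roster)
        pts = donors_vs_mutations(curve)
        ys = [y for _, y in pts]
        assert ys == sorted(ys)
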
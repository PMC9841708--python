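import numpy as np
import pytest

from gbspop.filtering import (
    FilterConfig,
    apply_cascade,
    filter_individual_missingness,
    filter_maf,
    filter_site_completeness,
    thin_to_center_snp,
)
from gbspop.io import Locus, LociCollection

import _oracles
from conftest import make_dataset, random_dataset

HOM_REF, HET, HOM_ALT = (0, 0), (0, 1), (1, 1)


def site_keys(ds):
    return [(r.contig_id, r.pos) for r in ds.records]


class TestIndividualMissingness:
    def test_drops_strictly_above_threshold(self):
        # per-sample missing fractions over 100 sites: 0.0, 0.1, 0.41, 1.0
        fractions = [0, 10, 41, 100]
        rows = []
        for j in range(100):
            calls = [None if j < f else HOM_REF for f in fractions]
            rows.append(("c1", j + 1, "A", ["G"], calls))
        ds = make_dataset(["s1", "s2", "s3", "s4"], rows)
        out = filter_individual_missingness(ds, 0.40)
        assert out.samples == ["s1", "s2"]

    @pytest.mark.parametrize("max_missing", [1.0, 0.0])
    def test_identity_cases(self, max_missing):
        ds = make_dataset(
            ["s1", "s2"],
            [("c1", 1, "A", ["G"], [HOM_REF, HET]),
             ("c1", 2, "A", ["G"], [HOM_ALT, HOM_REF])],
        )
        out = filter_individual_missingness(ds, max_missing)
        assert out.samples == ds.samples and out.records == ds.records

    def test_zero_records_error(self):
        ds = make_dataset(["s1"], [])
        with pytest.raises(ValueError, match="0 records"):
            filter_individual_missingness(ds, 0.5)


class TestSiteCompleteness:
    def test_eighty_percent_boundary_inclusive(self):
        samples = [f"s{i}" for i in range(10)]
        row8 = [HOM_REF] * 8 + [None] * 2
        row7 = [HOM_REF] * 7 + [None] * 3
        ds = make_dataset(
            samples,
            [("c1", 1, "A", ["G"], row8), ("c1", 2, "A", ["G"], row7)],
        )
        out = filter_site_completeness(ds, 0.80)
        assert site_keys(out) == [("c1", 1)]

    def test_zero_threshold_identity(self):
        ds = make_dataset(["s1"], [("c1", 1, "A", ["G"], [None])])
        assert filter_site_completeness(ds, 0.0).n_sites == 1


class TestMaf:
    def test_boundary_inclusive_at_one_percent(self):
        # 50 samples, one het: MAF = 1/100 = 0.01, kept at threshold 0.01
        calls = [HOM_REF] * 49 + [HET]
        ds = make_dataset(
            [f"s{i}" for i in range(50)], [("c1", 1, "A", ["G"], calls)]
        )
        assert filter_maf(ds, 0.01).n_sites == 1

    def test_monomorphic_dropped(self):
        calls = [HOM_REF] * 50
        ds = make_dataset(
            [f"s{i}" for i in range(50)], [("c1", 1, "A", ["G"], calls)]
        )
        assert filter_maf(ds, 0.01).n_sites == 0

    def test_all_missing_site_dropped(self):
        ds = make_dataset(["s1"], [("c1", 1, "A", ["G"], [None])])
        assert filter_maf(ds, 0.0).n_sites == 0

    def test_min_allele_count_mode(self):
        calls = [HOM_REF] * 49 + [HET]  # minor allele observed once
        ds = make_dataset(
            [f"s{i}" for i in range(50)], [("c1", 1, "A", ["G"], calls)]
        )
        assert filter_maf(ds, 0.0, min_allele_count_mode=2).n_sites == 0
        assert filter_maf(ds, 0.0, min_allele_count_mode=1).n_sites == 1


class TestThinToCenter:
    def test_keeps_snp_closest_to_locus_center(self):
        calls = [[HOM_REF, HET]] * 3
        ds = make_dataset(
            ["s1", "s2"],
            [("c1", p, "A", ["G"], c) for p, c in zip((10, 45, 80), calls)],
        )
        loci = LociCollection(
            {"c1": Locus("c1", {"s1": "A" * 100, "s2": "A" * 100}, [9, 44, 79])}
        )
        out = thin_to_center_snp(ds, loci)  # centre (100+1)/2 = 50.5
        assert site_keys(out) == [("c1", 45)]

    def test_singleton_contig_identity(self):
        ds = make_dataset(["s1"], [("c1", 7, "A", ["G"], [HET])])
        assert site_keys(thin_to_center_snp(ds)) == [("c1", 7)]

    def test_tie_breaks_to_lower_position(self):
        # span centre of {10, 20} is 15: both SNPs at distance 5
        ds = make_dataset(
            ["s1"],
            [("c1", 10, "A", ["G"], [HET]), ("c1", 20, "A", ["G"], [HET])],
        )
        assert site_keys(thin_to_center_snp(ds)) == [("c1", 10)]

    def test_span_center_without_loci(self):
        ds = make_dataset(
            ["s1"],
            [("c1", p, "A", ["G"], [HET]) for p in (10, 45, 80)],
        )
        assert site_keys(thin_to_center_snp(ds)) == [("c1", 45)]


class TestIdempotence:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_each_filter_idempotent(self, seed):
        ds = random_dataset(np.random.default_rng(seed), 20, 50)
        for f in (
            lambda d: filter_individual_missingness(d, 0.4),
            lambda d: filter_site_completeness(d, 0.8),
            lambda d: filter_maf(d, 0.05),
            lambda d: thin_to_center_snp(d),
        ):
            once = f(ds)
            twice = f(once)
            assert twice.samples == once.samples
            assert twice.records == once.records


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_filters_match_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        ds = random_dataset(rng, 20, 50)
        out = filter_individual_missingness(ds, 0.4)
        assert out.samples == [ds.samples[i] for i in _oracles.bf_individual_missingness(ds, 0.4)]
        out = filter_site_completeness(ds, 0.8)
        assert site_keys(out) == [
            site_keys(ds)[j] for j in _oracles.bf_site_completeness(ds, 0.8)
        ]
        out = filter_maf(ds, 0.05)
        assert site_keys(out) == [site_keys(ds)[j] for j in _oracles.bf_maf(ds, 0.05)]
        out = thin_to_center_snp(ds)
        assert sorted(site_keys(out)) == sorted(
            site_keys(ds)[j] for j in _oracles.bf_thin_center(ds)
        )


def _order_sensitive_fixture():
    """6 samples; s6 misses >40% of sites; one site becomes complete enough
    only after s6 is dropped (4/6 < 0.8 <= 4/5)."""
    samples = [f"s{i}" for i in range(1, 7)]
    rows = []
    # 10 filler sites: s6 missing at 6 of them (missing fraction 7/11 > 0.4)
    for j in range(10):
        calls = [HOM_REF, HET, HOM_REF, HET, HOM_REF, None if j < 6 else HOM_REF]
        rows.append(("bg", j + 1, "A", ["G"], calls))
    # discriminating site: present in s1..s4, missing in s5 and s6
    rows.append(("disc", 1, "A", ["G"], [HOM_REF, HET, HOM_REF, HET, None, None]))
    return make_dataset(samples, rows)


class TestCascade:
    def test_matches_manual_composition(self):
        ds = random_dataset(np.random.default_rng(7), 30, 60)
        cfg = FilterConfig(0.40, 0.80, 0.01, thin_to_center=True)
        out, report = apply_cascade(ds, cfg)
        manual = filter_individual_missingness(ds, 0.40)
        manual = filter_site_completeness(manual, 0.80)
        manual = filter_maf(manual, 0.01)
        manual = thin_to_center_snp(manual)
        assert out.samples == manual.samples
        assert out.records == manual.records
        assert [s.name for s in report.stages] == [
            "individual_missingness", "site_completeness", "maf",
            "center_snp_thinning",
        ]

    def test_all_permissive_is_identity(self):
        ds = random_dataset(np.random.default_rng(8), 10, 20)
        cfg = FilterConfig(1.0, 0.0, 0.0, thin_to_center=False)
        out, report = apply_cascade(ds, cfg)
        assert out.records == ds.records and out.samples == ds.samples
        assert all(
            s.n_sites_in == s.n_sites_out and s.n_samples_in == s.n_samples_out
            for s in report.stages
        )

    def test_counts_non_increasing_and_chained(self):
        ds = random_dataset(np.random.default_rng(9), 25, 80)
        _, report = apply_cascade(ds, FilterConfig())
        for prev, nxt in zip(report.stages, report.stages[1:]):
            assert nxt.n_samples_in == prev.n_samples_out
            assert nxt.n_sites_in == prev.n_sites_out
        for s in report.stages:
            assert s.n_samples_out <= s.n_samples_in
            assert s.n_sites_out <= s.n_sites_in

    def test_order_sensitivity_is_real(self):
        """Dropping a high-missingness sample first rescues a site that the
        reversed order (site filter first) would discard."""
        ds = _order_sensitive_fixture()
        cfg = FilterConfig(0.40, 0.80, 0.0, thin_to_center=False)
        forward, _ = apply_cascade(ds, cfg)
        # reversed order: site completeness before individual missingness
        rev = filter_site_completeness(ds, 0.80)
        rev = filter_individual_missingness(rev, 0.40)
        rev = filter_maf(rev, 0.0)
        assert ("disc", 1) in site_keys(forward)
        assert ("disc", 1) not in site_keys(rev)
        assert site_keys(forward) != site_keys(rev)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"max_individual_missing": 1.5},
            {"min_site_presence": -0.1},
            {"maf": 0.6},
        ],
    )
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FilterConfig(**kwargs)
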
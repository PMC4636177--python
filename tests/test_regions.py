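import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from imprintscreen import KnownDMR
from imprintscreen.regions import annotate_regions, call_regions, screen_report
from imprintscreen.simulate import SimulationConfig, simulate_dataset

from _oracles import brute_force_regions, random_probe_instance


def stats_frame(probes):
    """Build a caller input table from (id, chrom, pos, delta, p) tuples."""
    return pd.DataFrame(
        {
            "chrom": [p[1] for p in probes],
            "pos": [p[2] for p in probes],
            "delta_beta": [p[3] for p in probes],
            "p_value": [p[4] for p in probes],
        },
        index=pd.Index([p[0] for p in probes], name="probe_id"),
    )


def as_tuples(regions):
    return [(r.chrom, r.start, r.end, r.probe_ids,
             pytest.approx(r.mean_delta_beta)) for r in regions]


class TestCallRegionsExamples:
    def test_gap_of_600_bp_breaks_run(self):
        probes = [(f"p{i}", "chr1", pos, 0.3, 0.001)
                  for i, pos in enumerate([100, 200, 300, 900])]
        regions = call_regions(stats_frame(probes))
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.n_probes) == (100, 300, 3)
        assert r.direction == "gain" and r.max_gap == 100

    def test_sign_flip_leaves_runs_too_short(self):
        probes = [("a", "chr1", 100, 0.3, 0.001),
                  ("b", "chr1", 200, 0.3, 0.001),
                  ("c", "chr1", 300, -0.3, 0.001)]
        assert call_regions(stats_frame(probes)) == []

    def test_nothing_qualifies_at_high_p(self):
        probes = [(f"p{i}", "chr1", 100 * (i + 1), 0.3, 0.5) for i in range(5)]
        assert call_regions(stats_frame(probes)) == []

    def test_threshold_applies_to_region_average_not_per_probe(self):
        """A 0.15 probe is allowed inside a region whose mean exceeds 0.2."""
        probes = [("a", "chr1", 100, 0.25, 0.001),
                  ("b", "chr1", 200, 0.15, 0.001),
                  ("c", "chr1", 300, 0.22, 0.001)]
        regions = call_regions(stats_frame(probes))
        assert len(regions) == 1
        assert regions[0].mean_delta_beta == pytest.approx(0.62 / 3)

    def test_boundary_gap_exactly_500_breaks(self):
        probes = [("a", "chr1", 100, 0.3, 0.001),
                  ("b", "chr1", 600, 0.3, 0.001),
                  ("c", "chr1", 700, 0.3, 0.001),
                  ("d", "chr1", 800, 0.3, 0.001)]
        regions = call_regions(stats_frame(probes))
        assert len(regions) == 1
        assert regions[0].start == 600  # 100->600 gap is not < 500

    def test_duplicate_positions_tie_broken_by_probe_id(self):
        probes = [("b", "chr1", 100, 0.3, 0.001),
                  ("a", "chr1", 100, 0.3, 0.001),
                  ("c", "chr1", 200, 0.3, 0.001)]
        regions = call_regions(stats_frame(probes))
        assert len(regions) == 1
        assert regions[0].probe_ids == ("a", "b", "c")


class TestOracleEquivalence:
    def _assert_equal(self, probes, **kw):
        got = call_regions(stats_frame(probes), **kw)
        expected = brute_force_regions(probes, **kw)
        assert len(got) == len(expected)
        for g, e in zip(got, expected):
            assert (g.chrom, g.start, g.end) == (e["chrom"], e["start"], e["end"])
            assert g.probe_ids == e["probe_ids"]
            assert g.mean_delta_beta == pytest.approx(e["mean_delta_beta"])

    def test_500_random_instances(self):
        """Scanner equals exhaustive window enumeration on 500 seeded
        instances of up to 25 probes per chromosome."""
        rng = np.random.default_rng(2027)
        for _ in range(500):
            self._assert_equal(random_probe_instance(rng))

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_property_random_thresholds(self, data):
        """Equivalence holds across caller thresholds, not just defaults."""
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        probes = random_probe_instance(rng, n_max=15, n_chroms=1)
        kw = dict(
            min_probes=data.draw(st.integers(1, 5)),
            max_gap_bp=data.draw(st.sampled_from([100, 300, 500, 1000])),
            p_max=data.draw(st.sampled_from([0.001, 0.01, 0.05])),
            min_mean_abs_delta=data.draw(st.sampled_from([0.0, 0.1, 0.2, 0.4])),
        )
        self._assert_equal(probes, **kw)

    def test_qualifying_probes_shrink_with_p_max(self):
        rng = np.random.default_rng(5)
        probes = random_probe_instance(rng)
        covered = {}
        for p_max in (0.05, 0.01, 0.001):
            regions = call_regions(stats_frame(probes), p_max=p_max)
            covered[p_max] = {pid for r in regions for pid in r.probe_ids}
            pvals = {p[0]: p[4] for p in probes}
            assert all(pvals[pid] < p_max for pid in covered[p_max])

    def test_regions_sorted_and_disjoint(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            probes = random_probe_instance(rng)
            regions = call_regions(stats_frame(probes), min_mean_abs_delta=0.0,
                                   min_probes=1)
            keys = [(r.chrom, r.start) for r in regions]
            assert keys == sorted(keys)
            all_probes = [pid for r in regions for pid in r.probe_ids]
            assert len(all_probes) == len(set(all_probes))


class TestAnnotationAndReport:
    def _regions_from(self, ds, truth):
        from imprintscreen.diffmeth import run_diffmeth
        _, stats = run_diffmeth(ds)
        return call_regions(stats), stats

    def test_cgi_majority_rule(self):
        probes = [(f"p{i}", "chr1", 100 * (i + 1), 0.3, 0.001) for i in range(4)]
        regions = call_regions(stats_frame(probes))
        ann = pd.DataFrame({
            "chrom": ["chr1"] * 4, "pos": [100, 200, 300, 400],
            "cgi": [True, False, False, False],
            "feature": ["gene_body"] * 4,
        }, index=pd.Index([f"p{i}" for i in range(4)], name="probe_id"))
        out = annotate_regions(regions, ann)
        assert out[0].cgi is False  # 1 of 4 < half
        ann["cgi"] = [True, True, False, False]
        out = annotate_regions(regions, ann)
        assert out[0].cgi is True  # exactly half counts

    def test_promoter_any_probe_rule_and_known_overlap(self):
        probes = [(f"p{i}", "chr1", 100 * (i + 1), 0.3, 0.001) for i in range(3)]
        regions = call_regions(stats_frame(probes))
        ann = pd.DataFrame({
            "chrom": ["chr1"] * 3, "pos": [100, 200, 300],
            "cgi": [True] * 3,
            "feature": ["gene_body", "promoter", "gene_body"],
        }, index=pd.Index([f"p{i}" for i in range(3)], name="probe_id"))
        dmrs = [KnownDMR("hit", "chr1", 250, 400, "maternal", "ubiquitous"),
                KnownDMR("miss", "chr1", 400, 500, "maternal", "ubiquitous"),
                KnownDMR("otherchrom", "chr2", 100, 300, "paternal", "ubiquitous")]
        out = annotate_regions(regions, ann, dmrs)
        assert out[0].promoter is True
        assert out[0].known_dmr_overlap == ("hit",)

    def test_planted_cgi_regions_all_flagged(self, default_sim):
        """Generator ground truth: every called region sits in a CpG island."""
        _, ds, truth = default_sim
        from imprintscreen.qc import apply_qc
        ds_qc, _ = apply_qc(ds)
        from imprintscreen.diffmeth import run_diffmeth
        _, stats = run_diffmeth(ds_qc)
        regions = annotate_regions(call_regions(stats), ds_qc.annotation)
        assert regions, "screen found no regions on the default simulation"
        assert all(r.cgi for r in regions)

    def test_screen_report_counts(self):
        probes = [(f"p{i}", "chr1", 100 * (i + 1), 0.3, 0.001) for i in range(3)]
        probes += [(f"q{i}", "chr2", 100 * (i + 1), -0.3, 0.001) for i in range(3)]
        ann = pd.DataFrame({
            "chrom": ["chr1"] * 3 + ["chr2"] * 3,
            "pos": [100, 200, 300] * 2,
            "cgi": [True] * 3 + [False] * 3,
            "feature": ["promoter"] * 3 + ["gene_body"] * 3,
        }, index=pd.Index([p[0] for p in probes], name="probe_id"))
        regions = annotate_regions(call_regions(stats_frame(probes)), ann)
        rep = screen_report(regions)
        assert rep == {
            "n_regions": 2, "n_cgi": 1, "cgi_fraction": 0.5,
            "promoter_fraction": 0.5, "n_gain": 1, "n_loss": 1,
            "n_known_dmr_overlap": 0,
        }

    def test_empty_report_is_zeros(self):
        rep = screen_report([])
        assert rep["n_regions"] == 0 and rep["cgi_fraction"] == 0.0
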
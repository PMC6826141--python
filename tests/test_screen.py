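"""Somatic-variant screen: quality-aware calling and the filtering rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clonaldrift import (
    PileupSite,
    ScreenThresholds,
    classify_substitution,
    neighborhood_filter,
    poisson_binomial_call,
    screen_pair,
    shared_site_outliers,
)
from clonaldrift.screen import SMVRecord, is_uv_signature, pileup_frame


def _full_pmf_oracle(probs: np.ndarray) -> np.ndarray:
    """Independent Poisson-binomial pmf by direct polynomial convolution."""
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


class TestPoissonBinomialCall:
    def test_zero_alt_count_is_certain(self):
        assert poisson_binomial_call(0, [30, 30, 30]) == 1.0

    def test_three_reads_q10_closed_form(self):
        # P(X >= 1) = 1 - (1 - 0.1/3)^3
        p = poisson_binomial_call(1, [10, 10, 10])
        assert p == pytest.approx(1.0 - (1.0 - 0.1 / 3.0) ** 3, rel=1e-12)

    def test_depth30_q30_eight_alt_reads_is_called(self):
        assert poisson_binomial_call(8, [30] * 30) < 0.01

    def test_empty_pileup_is_domain_error(self):
        with pytest.raises(ValueError):
            poisson_binomial_call(1, [])

    @given(
        quals=st.lists(st.integers(2, 45), min_size=1, max_size=14),
        k_frac=st.floats(0, 1),
    )
    @settings(max_examples=60, deadline=None)
    def test_dp_matches_convolution_oracle(self, quals, k_frac):
        k = max(1, int(round(k_frac * len(quals))))
        probs = 10.0 ** (-np.asarray(quals, float) / 10.0) / 3.0
        expected = _full_pmf_oracle(probs)[k:].sum()
        assert poisson_binomial_call(k, quals) == pytest.approx(expected, rel=1e-9, abs=1e-12)


class TestClassifySubstitution:
    @pytest.mark.parametrize(
        "ref,alt,cls",
        [
            ("C", "T", "transition"),
            ("A", "G", "transition"),
            ("C", "A", "transversion"),
            ("G", "T", "transversion"),
            ("CC", "TT", "dinucleotide"),
        ],
    )
    def test_classes(self, ref, alt, cls):
        assert classify_substitution(ref, alt) == cls

    def test_uv_signature_flags(self):
        assert is_uv_signature("CC", "TT") and is_uv_signature("GG", "AA")
        assert not is_uv_signature("CC", "AA")

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            classify_substitution("C", "C")
        with pytest.raises(ValueError):
            classify_substitution("N", "T")


class TestSharedSiteOutliers:
    def test_all_equal_deltas_flags_nothing(self):
        assert shared_site_outliers([0.1] * 5, [0.2] * 5) == []

    def test_single_large_delta_is_flagged(self):
        early = [0.01] * 99 + [0.01]
        late = [0.011] * 99 + [0.21]
        flagged = shared_site_outliers(early, late, site_ids=[f"s{i}" for i in range(100)])
        assert flagged == ["s99"]

    def test_germline_like_background_catches_expanding_shared_variant(self):
        # A shared variant moving 1.35% -> 21.43% among stable shared sites.
        rng = np.random.default_rng(0)
        early = list(0.5 + rng.normal(0, 0.004, 60))
        late = list(0.5 + rng.normal(0, 0.004, 60))
        early.append(0.0135)
        late.append(0.2143)
        flagged = shared_site_outliers(early, late)
        assert flagged == [60]

    def test_fewer_than_two_sites_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert shared_site_outliers([0.1], [0.3]) == []


class TestNeighborhoodFilter:
    def _rec(self, pos, alt="T", ref="C", detected="late"):
        return SMVRecord(
            site_id=f"chrS:{pos}:{alt}", chrom="chrS", pos=pos, ref=ref, alt=alt,
            passage_detected=detected, early_alt=0, early_total=1000,
            late_alt=20, late_total=1000,
        )

    def test_isolated_candidate_kept(self):
        assert len(neighborhood_filter([self._rec(500)])) == 1

    def test_cluster_removed(self):
        recs = [self._rec(100), self._rec(105), self._rec(110)]
        assert neighborhood_filter(recs, max_neighbors=1) == []

    def test_adjacent_pair_merges_to_dinucleotide(self):
        recs = [self._rec(100, ref="C"), self._rec(101, ref="C")]
        out = neighborhood_filter(recs)
        assert len(out) == 1
        assert out[0].dinucleotide and out[0].ref == "CC" and out[0].alt == "TT"
        assert out[0].substitution_class == "dinucleotide"


def _make_pileups(n_sites=60, depth=1500, ref="A"):
    """Clean paired pileups with no alternate reads."""
    def site(pos, counts):
        return PileupSite("chrS", pos, ref, counts)

    base = {b: 0 for b in "ACGT"}
    base[ref] = depth
    early = [site(i + 1, dict(base)) for i in range(n_sites)]
    late = [site(i + 1, dict(base)) for i in range(n_sites)]
    return early, late


def _set_counts(sites, pos, **counts):
    s = sites[pos - 1]
    new = dict(s.counts)
    new.update(counts)
    total = sum(new.values())
    sites[pos - 1] = PileupSite(s.chrom, s.pos, s.ref, new)


class TestScreenPair:
    thresholds = ScreenThresholds(bonferroni_sites=60)

    def test_late_only_variant_detected(self):
        early, late = _make_pileups()
        _set_counts(late, 30, A=1460, T=40)
        recs = screen_pair(early, late, self.thresholds)
        assert len(recs) == 1
        assert recs[0].passage_detected == "late"
        assert recs[0].alt == "T" and recs[0].late_alt == 40

    def test_variant_in_both_passages_excluded(self):
        early, late = _make_pileups()
        _set_counts(early, 30, A=1460, T=40)
        _set_counts(late, 30, A=1455, T=45)
        assert screen_pair(early, late, self.thresholds) == []

    def test_min_alt_count_excludes_tiny_calls(self):
        early, late = _make_pileups(depth=40)
        # 2 alt reads at depth 40 and Q30 would be "significant" but fails
        # the minimum-count rule motivated by false-positive behaviour.
        _set_counts(late, 10, A=38, T=2)
        th = ScreenThresholds(bonferroni_sites=1, min_alt_count=3)
        assert screen_pair(early, late, th) == []
        th2 = ScreenThresholds(bonferroni_sites=1, min_alt_count=2)
        assert len(screen_pair(early, late, th2)) == 1

    def test_heterozygous_host_site_gated_out(self):
        early, late = _make_pileups()
        # Germline-het-like site: ~50% in early, drifted higher in late.
        _set_counts(early, 12, A=760, T=740)
        _set_counts(late, 12, A=600, T=900)
        assert screen_pair(early, late, self.thresholds) == []

    def test_passage_symmetry(self):
        early, late = _make_pileups()
        _set_counts(late, 30, A=1460, T=40)
        fwd = screen_pair(early, late, self.thresholds)
        rev = screen_pair(late, early, self.thresholds)
        assert [r.site_id for r in fwd] == [r.site_id for r in rev]
        assert fwd[0].passage_detected == "late" and rev[0].passage_detected == "early"

    def test_mismatched_site_universe_raises(self):
        early, late = _make_pileups()
        with pytest.raises(ValueError):
            screen_pair(early, late[:-1], self.thresholds)

    def test_explicit_low_qualities_weaken_evidence(self):
        # The same alternate count is less surprising when the piled reads
        # carry low qualities, because each read's error probability rises.
        p_low = poisson_binomial_call(4, [12] * 100)
        p_high = poisson_binomial_call(4, [30] * 100)
        assert p_low > 100 * p_high

    def test_explicit_quality_pileup_path_calls_variant(self):
        early, late = _make_pileups(depth=500)
        s = late[4]
        counts = {"A": 460, "T": 40, "C": 0, "G": 0}
        quals = {"A": (30,) * 460, "T": (35,) * 40}
        late[4] = PileupSite(s.chrom, s.pos, s.ref, counts, quals)
        recs = screen_pair(early, late, self.thresholds)
        assert [r.pos for r in recs] == [5]

    def test_counts_reproducible_from_pileups(self):
        early, late = _make_pileups()
        _set_counts(late, 9, A=1440, G=60)
        recs = screen_pair(early, late, self.thresholds)
        e_df, l_df = pileup_frame(early), pileup_frame(late)
        r = recs[0]
        row_e = e_df[e_df["pos"] == r.pos].iloc[0]
        row_l = l_df[l_df["pos"] == r.pos].iloc[0]
        assert r.early_alt == row_e[f"count_{r.alt}"]
        assert r.late_alt == row_l[f"count_{r.alt}"]
        assert r.late_total == sum(row_l[f"count_{b}"] for b in "ACGT")
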
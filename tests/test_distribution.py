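import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peptidogenomics import distribution as dist
from peptidogenomics.models import GeneModel, PeptideLocus

import oracles

MB = 1_000_000


def _locus(chrom, start, m=5, strand="+"):
    return PeptideLocus(peptide="A" * m, chrom=chrom, strand=strand,
                        frame=0, start=start, end=start + 3 * m)


class TestWindows:
    @pytest.mark.parametrize("length,expected", [
        (12 * MB, [(0, 6 * MB), (3 * MB, 9 * MB), (6 * MB, 12 * MB)]),
        (9 * MB, [(0, 6 * MB), (3 * MB, 9 * MB)]),
        (5 * MB, [(0, 5 * MB)]),
    ])
    def test_closed_form_window_lists(self, length, expected):
        assert dist.sliding_windows(length, 6 * MB, 3 * MB) == expected

    def test_single_window_counts(self):
        loci = [_locus("c", p) for p in range(0, 2_200_000, 200_000)]
        profile = dist.window_density(loci, {"c": 12 * MB})
        assert [w[2] for w in profile.windows["c"]] == [11, 0, 0]

    def test_boundary_locus_in_two_windows(self):
        profile = dist.window_density([_locus("c", 3 * MB)], {"c": 12 * MB})
        assert [w[2] for w in profile.windows["c"]] == [1, 1, 0]

    def test_locus_beyond_length_error(self):
        with pytest.raises(ValueError, match="beyond"):
            dist.window_density([_locus("c", 13 * MB)], {"c": 12 * MB})

    def test_every_interior_start_counted_twice(self):
        # window/step = 2, so interior loci appear in exactly 2 windows
        loci = [_locus("c", 7 * MB)]
        profile = dist.window_density(loci, {"c": 30 * MB})
        assert sum(w[2] for w in profile.windows["c"]) == 2


class TestHotspots:
    def _profile(self, counts, length=12 * MB):
        windows = dist.sliding_windows(length, 6 * MB, 3 * MB)
        return dist.DensityProfile(
            windows={"c": [(ws, we, n) for (ws, we), n in zip(windows, counts)]})

    def test_strictly_greater_than_threshold(self):
        hot = dist.detect_hotspots(self._profile([11, 10, 0]))
        assert [(h[1], h[3]) for h in hot] == [(0, 11)]

    def test_empty_profile(self):
        assert dist.detect_hotspots(dist.DensityProfile(windows={})) == []

    def test_monotone_under_added_locus(self):
        loci = [_locus("c", 1000 + i) for i in range(11)]
        base = dist.detect_hotspots(dist.window_density(loci, {"c": 12 * MB}))
        more = dist.detect_hotspots(
            dist.window_density(loci + [_locus("c", 8 * MB)], {"c": 12 * MB}))
        assert {h[:3] for h in base} <= {h[:3] for h in more}

    def test_merge_overlapping_windows(self):
        hot = [("c", 0, 6 * MB, 12), ("c", 3 * MB, 9 * MB, 13),
               ("c", 18 * MB, 24 * MB, 20)]
        assert dist.merge_hotspots(hot) == \
            [("c", 0, 9 * MB), ("c", 18 * MB, 24 * MB)]


class TestSpacing:
    def test_definition(self):
        loci = [_locus("c", p) for p in (0, 50_000, 200_000)]
        distances, frac = dist.adjacent_spacing(loci)
        assert sorted(distances) == [50_000.0, 50_000.0, 150_000.0]
        assert frac == pytest.approx(2 / 3)

    def test_singleton_stays_in_denominator(self):
        loci = [_locus("c", 0), _locus("c", 10_000), _locus("d", 5)]
        _, frac = dist.adjacent_spacing(loci)
        assert frac == pytest.approx(2 / 3)

    def test_dense_lattice(self):
        loci = [_locus("c", p) for p in range(0, 100_000, 10_000)]
        _, frac = dist.adjacent_spacing(loci)
        assert frac == 1.0


class TestTssDistances:
    def _model(self, cds_start=130, chrom="c"):
        return GeneModel(
            gene_id="g", transcript_id=f"g.{cds_start}", chrom=chrom,
            strand="+", exons=[(cds_start - 30, cds_start + 300)],
            cds=[(cds_start, cds_start + 300, 0)],
        )

    def test_simple_distance(self):
        d, share, _ = dist.tss_distances([_locus("c", 133)], [self._model()])
        assert d == [3.0]
        assert share == 1.0

    def test_nearest_of_two(self):
        models = [self._model(130), self._model(5000)]
        d, _, _ = dist.tss_distances([_locus("c", 2600)], models)
        assert d == [2400.0]

    def test_minus_strand_tss_is_cds_end(self):
        m = GeneModel(gene_id="g", transcript_id="g.t", chrom="c", strand="-",
                      exons=[(100, 400)], cds=[(130, 340, 0)])
        assert list(dist.tss_positions([m])["c"]) == [339]

    def test_chromosome_without_tss_undefined(self):
        d, share, n_undef = dist.tss_distances([_locus("d", 10)], [self._model()])
        assert math.isnan(d[0]) and n_undef == 1 and math.isnan(share)


class TestArmPositions:
    def test_midpoint_telomere_and_linearity(self):
        lengths = {"c": 1000}
        loci = [_locus("c", 500), _locus("c", 0), _locus("c", 750)]
        assert dist.arm_normalized_positions(loci, lengths) == [0.0, 1.0, 0.5]

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_reflection_invariance(self, p):
        # reflecting the chromosome (p -> L - p) leaves the value unchanged
        L = 10_000
        v1, v2 = dist.arm_normalized_positions(
            [_locus("c", p, m=1), _locus("c", L - p, m=1)], {"c": L})
        assert v1 == pytest.approx(v2)


class TestCorrelation:
    def test_perfect_positive_and_negative(self):
        r, _ = dist.count_length_correlation([1, 2, 3], [10, 20, 30])
        assert r == pytest.approx(1.0)
        r, _ = dist.count_length_correlation([3, 2, 1], [10, 20, 30])
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        counts = [2, 1, 4, 3, 6, 5, 8, 7]
        lengths = list(range(1, 9))
        r, p = dist.count_length_correlation(counts, lengths)
        assert abs(r - oracles.pearson_r(counts, lengths)) < 1e-12
        assert 0 < p < 1

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="variance"):
            dist.count_length_correlation([1, 1, 1], [10, 20, 30])

    def test_too_few_chromosomes_error(self):
        with pytest.raises(ValueError, match="3"):
            dist.count_length_correlation([1, 2], [10, 20])


def test_planted_hotspot_recovered():
    """A 25-peptide cluster inside one window is the only hotspot."""
    rng = np.random.default_rng(5)
    loci = [_locus("c", int(p)) for p in rng.integers(3 * MB, 6 * MB, 25)]
    loci += [_locus("c", int(p)) for p in
             rng.choice(np.arange(9 * MB, 12 * MB, MB), 3, replace=False)]
    profile = dist.window_density(loci, {"c": 12 * MB})
    hot = dist.detect_hotspots(profile)
    assert {(h[1], h[2]) for h in hot} == {(0, 6 * MB), (3 * MB, 9 * MB)}
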
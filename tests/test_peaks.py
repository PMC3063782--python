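"""Window-consolidation peak caller against brute-force oracles."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats as sps

from promark import (
    PeakParams,
    Tag,
    call_peaks,
    count_window_tags,
    estimate_fdr,
)
from conftest import mk_tag, random_tags


def brute_force_peaks(treat, control, chrom_sizes, params, scale=None):
    """Independent single-pass re-implementation of the qualification rules:
    per-window Poisson tail, merge significant windows separated by at most
    one window-width, then apply the three region gates."""
    if len(treat) == 0:
        return []
    if scale is None:
        scale = len(treat) / len(control) if len(control) else 1.0
    w = params.window
    out = []
    n_windows = sum((s + w - 1) // w for s in chrom_sizes.values())
    n_ctrl = sum(
        1 for t in control if t.chrom in chrom_sizes and 0 <= t.five_prime < chrom_sizes[t.chrom]
    )
    floor = max(scale * n_ctrl / n_windows, 1e-9)
    for chrom, size in chrom_sizes.items():
        nw = (size + w - 1) // w
        tc = [0] * nw
        cc = [0.0] * nw
        for t in treat:
            if t.chrom == chrom and 0 <= t.five_prime < size:
                tc[t.five_prime // w] += 1
        for t in control:
            if t.chrom == chrom and 0 <= t.five_prime < size:
                cc[t.five_prime // w] += scale
        sig = [
            i
            for i in range(nw)
            if tc[i] > 0 and sps.poisson.sf(tc[i] - 1, max(cc[i], floor)) < params.p_threshold
        ]
        groups = []
        for i in sig:
            if groups and i - groups[-1][-1] <= 2:
                groups[-1].append(i)
            else:
                groups.append([i])
        for grp in groups:
            i0, i1 = grp[0], grp[-1]
            T = sum(tc[i0 : i1 + 1])
            C = sum(cc[i0 : i1 + 1])
            p = sps.poisson.sf(T - 1, max(C, floor * (i1 - i0 + 1)))
            ratio = math.log2((T + 1) / (C + 1))
            if T >= params.min_tags and ratio >= params.min_log2_ratio and p < params.p_threshold:
                out.append((chrom, i0 * w, min((i1 + 1) * w, size), T))
    return out


class TestCountWindowTags:
    def test_no_tags_all_zero(self):
        wc = count_window_tags([], {"c": 1000}, 100)
        assert wc.counts["c"].sum() == 0 and wc.n_assigned == 0

    def test_direct_placement(self):
        tags = [mk_tag(start=s) for s in (200, 210, 250, 260, 270, 280, 299)]
        wc = count_window_tags(tags, {"chr1": 1000}, 100)
        assert wc.counts["chr1"][2] == 7 and wc.counts["chr1"].sum() == 7

    def test_five_prime_is_strand_aware(self):
        plus = Tag("chr1", 30, 66, "+")  # 5' end 30 → window 0
        minus = Tag("chr1", 30, 66, "-")  # 5' end 65 → window 1
        wc = count_window_tags([plus, minus], {"chr1": 200}, 50)
        assert wc.counts["chr1"][0] == 1 and wc.counts["chr1"][1] == 1

    def test_matches_brute_force_and_conserves(self, rng):
        tags = random_tags(rng, 1_000, genome_bp=10_000)
        wc = count_window_tags(tags, {"chr1": 10_000}, 100)
        expected = np.zeros(100, dtype=int)
        for t in tags:
            expected[t.five_prime // 100] += 1
        assert np.array_equal(wc.counts["chr1"], expected)
        assert wc.n_assigned == len(tags)

    def test_out_of_bounds_rejected_with_count(self):
        tags = [mk_tag(start=10), Tag("chr1", 990, 1026, "-"), mk_tag(chrom="chrX", start=5)]
        wc = count_window_tags(tags, {"chr1": 1000}, 100)
        assert wc.n_rejected == 2 and wc.n_assigned == 1


class TestCallPeaks:
    def test_treatment_identical_to_input_yields_nothing(self, rng):
        tags = random_tags(rng, 2_000, genome_bp=10_000)
        assert call_peaks(tags, list(tags), {"chr1": 10_000}) == []

    def test_single_planted_region_two_windows(self, rng):
        genome = {"chr1": 10_000}
        background = random_tags(rng, 200, genome_bp=10_000)  # ~2 per window
        planted = [mk_tag(start=200 + (i * 7) % 200) for i in range(60)]
        treat = background + planted
        peaks = call_peaks(treat, background, genome, PeakParams(), scale=1.0)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.start == 200 and p.end == 400
        assert p.treat_tags >= 60
        oracle = brute_force_peaks(treat, background, genome, PeakParams(), scale=1.0)
        assert [(q.chrom, q.start, q.end, q.treat_tags) for q in peaks] == oracle

    def test_min_tag_threshold_boundary(self, rng):
        genome = {"chr1": 10_000}
        background = random_tags(rng, 100, genome_bp=10_000)
        planted39 = [mk_tag(start=200 + i % 190) for i in range(39)]
        assert call_peaks(background + planted39, background, genome, scale=1.0) == []
        planted40 = [mk_tag(start=200 + i % 190) for i in range(40)]
        peaks = call_peaks(background + planted40, background, genome, scale=1.0)
        assert len(peaks) == 1 and peaks[0].treat_tags >= 40

    def test_empty_treatment_and_zero_genome(self, rng):
        assert call_peaks([], random_tags(rng, 10), {"chr1": 1000}) == []
        with pytest.raises(ValueError):
            call_peaks(random_tags(rng, 10), [], {})

    def test_raising_thresholds_never_adds_peaks(self, rng):
        genome = {"chr1": 10_000}
        background = random_tags(rng, 300, genome_bp=10_000)
        treat = background[:150] + random_tags(rng, 400, genome_bp=2_000)
        base = PeakParams()
        n_base = len(call_peaks(treat, background, genome, base, scale=1.0))
        for min_tags in (50, 80, 200):
            p = dataclasses.replace(base, min_tags=min_tags)
            assert len(call_peaks(treat, background, genome, p, scale=1.0)) <= n_base
        for ratio in (1.5, 2.0, 4.0):
            p = dataclasses.replace(base, min_log2_ratio=ratio)
            assert len(call_peaks(treat, background, genome, p, scale=1.0)) <= n_base

    def test_consolidation_gap_rule(self):
        # significant clusters at windows 2 and 4 (gap = one window) merge;
        # windows 2 and 5 (gap = two windows) do not.
        genome = {"chr1": 2_000}
        background = [mk_tag(start=(37 * i) % 1_960) for i in range(20)]
        near = [mk_tag(start=200 + i % 90) for i in range(30)] + [
            mk_tag(start=400 + i % 90) for i in range(30)
        ]
        merged = call_peaks(background + near, background, genome, scale=1.0)
        assert len(merged) == 1 and (merged[0].start, merged[0].end) == (200, 500)
        far = [mk_tag(start=200 + i % 90) for i in range(40)] + [
            mk_tag(start=500 + i % 90) for i in range(40)
        ]
        split = call_peaks(background + far, background, genome, scale=1.0)
        assert len(split) == 2
        assert [(p.start, p.end) for p in split] == [(200, 300), (500, 600)]

    def test_randomized_oracle_equivalence(self):
        """On small genomes the caller agrees exactly with the brute-force
        per-window implementation, over randomized instances."""
        for seed in range(8):
            r = np.random.default_rng(seed)
            genome = {"chr1": 8_000, "chr2": 2_000}
            treat = random_tags(r, int(r.integers(100, 2_500)), genome_bp=8_000)
            treat += random_tags(r, int(r.integers(0, 2_000)), genome_bp=2_000, chrom="chr2")
            enriched_at = int(r.integers(0, 7_000))
            treat += [
                mk_tag(start=enriched_at + int(x))
                for x in r.integers(0, 300, size=int(r.integers(0, 120)))
            ]
            control = random_tags(r, int(r.integers(100, 2_500)), genome_bp=8_000)
            control += random_tags(r, int(r.integers(1, 2_000)), genome_bp=2_000, chrom="chr2")
            params = PeakParams(min_tags=int(r.integers(10, 60)))
            got = call_peaks(treat, control, genome, params)
            want = brute_force_peaks(treat, control, genome, params)
            assert [(p.chrom, p.start, p.end, p.treat_tags) for p in got] == want

    def test_peak_fields_satisfy_qualification_invariants(self, rng):
        genome = {"chr1": 10_000}
        background = random_tags(rng, 200, genome_bp=10_000)
        treat = background[:100] + random_tags(rng, 500, genome_bp=1_500)
        params = PeakParams()
        for p in call_peaks(treat, background, genome, params):
            assert p.start < p.end
            assert p.treat_tags >= params.min_tags
            assert p.log2_ratio >= params.min_log2_ratio
            assert p.p_value < params.p_threshold
            assert p.start % params.window == 0


class TestEstimateFdr:
    def test_swap_symmetry_on_identical_libraries(self, rng):
        tags = random_tags(rng, 1_000, genome_bp=10_000)
        est = estimate_fdr(tags, list(tags), {"chr1": 10_000})
        assert est.forward_peaks == est.swapped_peaks
        if est.forward_peaks == 0:
            assert est.fdr is None
        else:
            assert est.fdr == 1.0

    def test_enriched_vs_background_fdr_near_zero(self, rng):
        genome = {"chr1": 50_000}
        background = random_tags(rng, 1_000, genome_bp=50_000)
        planted = []
        for k in range(5):
            at = 3_000 + 9_000 * k
            planted += [mk_tag(start=at + i % 400) for i in range(80)]
        treat = random_tags(rng, 1_000, genome_bp=50_000) + planted
        est = estimate_fdr(treat, background, {"chr1": 50_000})
        assert est.forward_peaks >= 5
        assert est.fdr is not None and est.fdr < 0.01

    def test_replicate_fdr_stability(self):
        vals = []
        for seed in (100, 200):
            r = np.random.default_rng(seed)
            background = random_tags(r, 2_000, genome_bp=100_000)
            planted = []
            for k in range(10):
                at = 4_000 + 9_000 * k
                planted += [mk_tag(start=at + i % 400) for i in range(80)]
            treat = random_tags(r, 2_000, genome_bp=100_000) + planted
            est = estimate_fdr(treat, background, {"chr1": 100_000})
            vals.append(est.fdr)
        assert all(v is not None and v < 0.05 for v in vals)
        assert abs(vals[0] - vals[1]) < 0.05
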
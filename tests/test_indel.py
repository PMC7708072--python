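"""Pair merging, primer filter, windowed indel calling, and exact Mann-Whitney."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from pamscreen import (
    AmpliconExperiment,
    align_and_call,
    filter_primer_errors,
    mann_whitney_one_tailed,
    merge_pair,
    net_indel_pct,
    quantify_sample,
)
from pamscreen.indel import IndelResult
from pamscreen.iupac import reverse_complement
from pamscreen.simulate import AmpliconSimConfig, simulate_amplicon

Q40 = chr(40 + 33)
Q10 = chr(10 + 33)


class TestMergePair:
    def test_overlapping_halves_reconstruct_reference(self, amplicon_reference):
        ref = amplicon_reference
        r1 = ref[:100]
        r2 = reverse_complement(ref[60:])
        merged = merge_pair(r1, Q40 * len(r1), r2, Q40 * len(r2))
        assert merged is not None
        assert merged[0] == ref

    def test_no_overlap_rejected(self):
        merged = merge_pair("A" * 30, Q40 * 30, "C" * 30, Q40 * 30)
        assert merged is None

    def test_mismatch_resolved_by_higher_quality(self, amplicon_reference):
        ref = amplicon_reference
        r1 = ref[:100]
        # corrupt one base of r1 inside the overlap, at low quality
        r1_bad = r1[:80] + ("A" if r1[80] != "A" else "C") + r1[81:]
        q1 = Q40 * 80 + Q10 + Q40 * 19
        r2 = reverse_complement(ref[60:])
        merged = merge_pair(r1_bad, q1, r2, Q40 * len(r2))
        assert merged is not None
        assert merged[0] == ref  # high-quality mate base wins

    def test_maximal_overlap_preferred(self):
        # a fully-overlapping identical pair merges to itself
        seq = "ACGTACGTACGTACGTACGT"
        merged = merge_pair(seq, Q40 * len(seq), reverse_complement(seq), Q40 * len(seq))
        assert merged is not None and merged[0] == seq


class TestPrimerFilter:
    def test_clean_read_kept(self, experiment):
        assert filter_primer_errors(experiment.reference, experiment)

    def test_one_substitution_in_40_primer_bases_discarded(self, experiment):
        ref = experiment.reference
        bad = "A" if ref[5] != "A" else "C"
        read = ref[:5] + bad + ref[6:]
        assert not filter_primer_errors(read, experiment)

    def test_disabled_threshold_keeps_everything(self, experiment):
        ref = experiment.reference
        read = "T" * 20 + ref[20:]
        assert filter_primer_errors(read, experiment, max_error_rate=1.0)

    def test_indel_between_primers_does_not_touch_footprints(self, experiment):
        ref = experiment.reference
        cut = experiment.cut_site
        read = ref[:cut] + ref[cut + 3 :]  # 3-nt deletion at the cut
        assert filter_primer_errors(read, experiment)


class TestAlignAndCall:
    def test_reference_read_unmodified(self, experiment):
        call = align_and_call(experiment.reference, experiment)
        assert not call.modified and call.identity == 1.0

    def test_deletion_at_cut_site_called(self, experiment):
        ref = experiment.reference
        cut = experiment.cut_site
        read = ref[:cut] + ref[cut + 3 :]
        call = align_and_call(read, experiment)
        assert call.modified
        assert [(k, s) for k, _, s in call.events] == [("del", -3)]

    def test_insertion_at_cut_site_called(self, experiment):
        ref = experiment.reference
        cut = experiment.cut_site
        read = ref[:cut] + "TCTC" + ref[cut:]
        call = align_and_call(read, experiment)
        assert call.modified
        assert [(k, s) for k, _, s in call.events] == [("ins", 4)]

    def test_substitution_in_window_not_modification(self, experiment):
        ref = experiment.reference
        cut = experiment.cut_site
        read = ref[:cut] + ("A" if ref[cut] != "A" else "C") + ref[cut + 1 :]
        call = align_and_call(read, experiment)
        assert not call.modified

    def test_indel_outside_window_not_counted(self, experiment):
        ref = experiment.reference
        ws, _ = experiment.window
        pos = ws - 12
        read = ref[:pos] + ref[pos + 2 :]
        call = align_and_call(read, experiment)
        assert not call.modified

    def test_homopolymer_placement_invariance(self):
        """Equivalent deletion placements in a homopolymer give one call.

        The run of A's spans the window edge; right-placed gap stays outside
        the window, left-normalised placement lands inside. Left-alignment
        makes the call deterministic regardless of aligner tie-breaking.
        """
        left = "CGTCGATCGTAGCTAGCTAGGATCGATCG"
        run = "A" * 8
        right = "GCTAGCTAGCATCGATCGATCGTACGATCGA"
        ref = left + run + right
        guide_end = len(left) + 11
        exp = AmpliconExperiment(
            reference=ref, guide_start=guide_end - 20, guide_end=guide_end,
            window_halfwidth=4,
        )
        # delete 2 A's (any placement within the run is sequence-equivalent)
        read = left + "A" * 6 + right
        call = align_and_call(read, exp)
        ws, we = exp.window
        s, e = len(left), len(left) + 2  # left-normalised deleted interval
        assert call.modified == (s < we and ws < e)

    def test_garbage_read_unalignable(self, experiment):
        call = align_and_call("T" * len(experiment.reference), experiment)
        assert not call.alignable


class TestQuantification:
    def test_modified_fraction_recovered_within_binomial_bounds(self, experiment):
        """Recovery is unbiased within 3 sigma across seeds 0..9 (n=800)."""
        frac, n = 0.2, 800
        tol = 3 * (frac * (1 - frac) / n) ** 0.5 * 100
        for seed in range(10):
            sim = simulate_amplicon(
                AmpliconSimConfig(
                    reference=experiment.reference,
                    guide_start=28,
                    guide_end=48,
                    modified_fraction=frac,
                    n_read_pairs=n,
                    seed=seed,
                )
            )
            res = quantify_sample(zip(sim.r1, sim.r2), experiment)
            assert res.n_reads_analyzed > 0.9 * n
            assert abs(res.indel_pct - 100 * frac) < tol

    def test_spectrum_records_simulated_sizes(self, experiment):
        sim = simulate_amplicon(
            AmpliconSimConfig(
                reference=experiment.reference,
                guide_start=28,
                guide_end=48,
                modified_fraction=1.0,
                indel_size_distribution={-3: 0.5, 2: 0.5},
                per_base_error_rate=0.0,
                n_read_pairs=100,
                seed=0,
            )
        )
        res = quantify_sample(zip(sim.r1, sim.r2), experiment)
        assert set(res.spectrum) == {-3, 2}
        assert res.n_modified == res.n_reads_analyzed


class TestNetIndelPct:
    def test_subtraction(self):
        t = IndelResult(n_reads_analyzed=1000, n_modified=50)
        u = IndelResult(n_reads_analyzed=1000, n_modified=4)
        assert net_indel_pct(t, u) == pytest.approx(5.0 - 0.4)

    def test_equal_samples_zero(self):
        r = IndelResult(n_reads_analyzed=100, n_modified=7)
        assert net_indel_pct(r, r) == 0.0

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            net_indel_pct(IndelResult(), IndelResult(n_reads_analyzed=10))


class TestMannWhitney:
    def test_complete_separation_three_vs_three(self):
        u, p = mann_whitney_one_tailed([3.1, 4.2, 5.0], [0.1, 0.2, 0.3])
        assert u == 0
        assert p == pytest.approx(0.05)

    def test_minimum_exact_p_for_3v3_is_one_twentieth(self):
        _, p = mann_whitney_one_tailed([10, 11, 12], [1, 2, 3])
        assert p == pytest.approx(1 / 20)

    def test_identical_groups_not_significant(self):
        _, p = mann_whitney_one_tailed([1, 1, 1], [1, 1, 1])
        assert p >= 0.5

    def test_wrong_direction_large_p(self):
        _, p = mann_whitney_one_tailed([0.1, 0.2, 0.3], [3.1, 4.2, 5.0])
        assert p == pytest.approx(1.0)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_one_tailed([], [1.0])

    def _enumeration_oracle(self, treated, control):
        """Exact p by pairwise-count U over all group assignments of the values."""
        pooled = list(treated) + list(control)
        n1 = len(treated)

        def u_stat(t_vals, c_vals):
            return sum(
                1.0 if a > b else 0.5 if a == b else 0.0 for a in t_vals for b in c_vals
            )

        observed = u_stat(treated, control)
        hits = total = 0
        for combo in itertools.combinations(range(len(pooled)), n1):
            t = [pooled[i] for i in combo]
            c = [pooled[i] for i in range(len(pooled)) if i not in combo]
            hits += u_stat(t, c) >= observed
            total += 1
        return hits / total

    @pytest.mark.parametrize(
        "treated,control",
        [
            ([3.1, 4.2, 5.0], [0.1, 0.2, 0.3]),
            ([1.0, 2.0, 2.0], [2.0, 3.0, 1.0]),
            ([5, 7], [1, 2, 3, 4]),
            ([2, 2, 2, 2], [2, 2, 2]),
            ([0.5, 9.1, 3.3, 4.4], [1.1, 2.2, 3.3, 4.4]),
            ([10, 20, 30, 40, 50, 60], [15, 25, 35, 45, 55, 5]),
        ],
    )
    def test_exact_p_matches_enumeration_oracle(self, treated, control):
        _, p = mann_whitney_one_tailed(treated, control)
        assert p == pytest.approx(self._enumeration_oracle(treated, control), abs=1e-12)

    @given(
        st.lists(st.integers(0, 6), min_size=2, max_size=6),
        st.lists(st.integers(0, 6), min_size=2, max_size=6),
    )
    def test_tie_free_cases_match_scipy_exact(self, treated, control):
        if len(set(treated) | set(control)) < len(treated) + len(control):
            return  # scipy's exact method requires no ties
        _, p = mann_whitney_one_tailed(treated, control)
        ref = mannwhitneyu(treated, control, alternative="greater", method="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)
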
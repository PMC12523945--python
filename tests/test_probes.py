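"""Probe geometry, GC rules, homology counting, and the replacement loop."""

import numpy as np
import pytest

from gbtskit.panel import FilterParams, design_panel
from gbtskit.probes import (HomologyIndex, ProbeParams, count_homologous_regions,
                            design_probe_pair, evaluate_panel_probes,
                            extract_probe_pair, gc_content, revcomp)
from gbtskit.simulate import PopulationSpec, simulate_cohort, simulate_reference


def _random_seq(length, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GGCC", 1.0), ("ATAT", 0.0), ("ACGTN", 0.5), ("acgt", 0.5)],
    )
    def test_known_values(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_empty_rejected_all_n_missing(self):
        with pytest.raises(ValueError):
            gc_content("")
        assert np.isnan(gc_content("NNN"))


class TestProbePair:
    def test_placement_arithmetic_at_default_overlap(self):
        """110 bp probes at 65% target share round(71.5) = 72 bases (shift 38)."""
        ref = {"seq1": _random_seq(100_000, 1)}
        pair = extract_probe_pair(ref, "seq1", 10_000)
        assert len(pair.probe_a) == len(pair.probe_b) == 110
        assert pair.start_b - pair.start_a == 38
        assert pair.overlap_fraction == pytest.approx(72 / 110)
        # both probes contain the SNP (0-based index 9999)
        assert pair.start_a <= 9999 < pair.start_a + 110
        assert pair.start_b <= 9999 < pair.start_b + 110
        # overlap window contains the SNP
        assert pair.start_b <= 9999 < pair.start_a + 110
        # probes match the reference at their coordinates
        assert ref["seq1"][pair.start_a : pair.start_a + 110] == pair.probe_a
        assert ref["seq1"][pair.start_b : pair.start_b + 110] == pair.probe_b

    def test_near_start_fails_with_edge_reason(self):
        ref = {"seq1": _random_seq(1000, 2)}
        pair = extract_probe_pair(ref, "seq1", 20)
        assert pair.fail_reasons == ("edge",)

    @pytest.mark.parametrize("target", [0.60, 0.70])
    def test_overlap_targets_span_pass_range(self, target):
        ref = {"seq1": _random_seq(10_000, 3)}
        pair = extract_probe_pair(
            ref, "seq1", 5_000, ProbeParams(overlap_target=target)
        )
        assert 0.60 <= pair.overlap_fraction <= 0.70


class TestHomology:
    def test_unique_probe_counts_only_itself(self):
        ref = {"seq1": _random_seq(50_000, 4)}
        index = HomologyIndex(ref, k=15)
        probe = ref["seq1"][10_000:10_110]
        assert count_homologous_regions(probe, index, min_seed_hits=5) == 1

    def test_exact_duplicate_counts_two(self):
        base = _random_seq(30_000, 5)
        window = base[5_000:5_110]
        ref = {"seq1": base[:20_000] + window + base[20_000:]}
        index = HomologyIndex(ref, k=15)
        assert count_homologous_regions(window, index, min_seed_hits=5) == 2

    def test_reverse_complement_duplicate_detected(self):
        base = _random_seq(30_000, 6)
        window = base[5_000:5_110]
        ref = {"seq1": base[:20_000] + revcomp(window) + base[20_000:]}
        index = HomologyIndex(ref, k=15)
        assert count_homologous_regions(window, index, min_seed_hits=5) == 2

    def test_poly_a_probe_exceeds_limit(self):
        tracts = ("A" * 120).join(_random_seq(300, 7 + i) for i in range(11))
        ref = {"seq1": tracts}  # 10 poly-A tracts of 120 bp
        index = HomologyIndex(ref, k=15)
        n = count_homologous_regions("A" * 110, index, min_seed_hits=5)
        assert n > 5

    def test_kmer_count_lower_bounded_by_exact_search(self):
        """Seed counting finds at least every exact full-string occurrence."""
        base = _random_seq(40_000, 8)
        window = base[1_000:1_110]
        ref = {"seq1": base + window + _random_seq(500, 9) + window}
        index = HomologyIndex(ref, k=15)
        exact = ref["seq1"].count(window)
        assert count_homologous_regions(window, index, min_seed_hits=5) >= exact
        assert exact == 3

    def test_kmer_too_long_rejected(self):
        ref = {"seq1": _random_seq(5_000, 10)}
        index = HomologyIndex(ref, k=15)
        with pytest.raises(ValueError):
            count_homologous_regions("ACGT", index)

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            HomologyIndex({"seq1": "ACGT" * 100}, k=5)


@pytest.fixture(scope="module")
def cohort_panel():
    spec = PopulationSpec(
        n_pops=2, n_per_pop=10, n_loci=600, seq_lengths=(60_000,) * 2,
        qual_low_fraction=0.0, missing_rate=0.02, seed=21,
    )
    ref, mat, _ = simulate_cohort(spec)
    panel, _ = design_panel(mat, FilterParams(target_size=200))
    return ref, panel


class TestPanelEvaluation:
    def test_probes_match_reference_and_mostly_pass(self, cohort_panel):
        ref, panel = cohort_panel
        out = evaluate_panel_probes(panel, ref)
        sel = out.probes[out.probes["selected"]]
        assert len(sel) == out.size == 200
        assert (sel["homology_count"] == 1).mean() >= 0.99
        for _, row in sel.head(20).iterrows():
            s = ref[row["seq_id"]]
            assert s[row["start_a"] - 1 : row["end_a"]] == row["probe_a"]
            assert s[row["start_b"] - 1 : row["end_b"]] == row["probe_b"]

    def test_gc_extreme_flank_fails_with_gc_reason(self):
        rng_seq = _random_seq(4_000, 11)
        gc_rich = "".join(
            "GC"[i % 2] if (i % 10) < 9 else "A" for i in range(400)
        )  # ~90% GC window
        ref = {"seq1": rng_seq[:2000] + gc_rich + rng_seq[2000:]}
        index = HomologyIndex(ref, k=15)
        pair = design_probe_pair(ref, "seq1", 2200, index=index)
        assert "gc" in pair.fail_reasons and not pair.passed

    def test_replacement_loop_restores_target_size(self):
        """Planted GC-extreme flanks are swapped for next-ranked reserves."""
        spec = PopulationSpec(
            n_pops=2, n_per_pop=10, n_loci=600, seq_lengths=(120_000,),
            qual_low_fraction=0.0, missing_rate=0.02, seed=22,
        )
        ref, mat, _ = simulate_cohort(spec)
        panel, _ = design_panel(mat, FilterParams(target_size=150))
        # plant ~10% failures among the selected loci by GC-saturating flanks
        seq = list(ref["seq1"])
        planted = [
            (s, p) for j, (s, p) in
            enumerate(zip(panel.matrix.seq_id, panel.matrix.pos)) if j % 10 == 0
        ]
        for s, p in planted:
            z = int(p) - 1
            for i in range(z - 150, z + 151):
                if i != z:
                    seq[i] = "G" if i % 2 else "C"
        ref2 = {"seq1": "".join(seq)}
        out = evaluate_panel_probes(panel, ref2)
        assert out.size == 150
        sel = out.probes[out.probes["selected"]]
        assert bool(sel["passed"].all())
        failed = out.probes[~out.probes["passed"]]
        assert len(failed) >= len(planted)
        assert all("gc" in r for r in failed["fail_reasons"][: len(planted)])
        # planted loci are no longer in the final panel
        final = set(zip(out.matrix.seq_id, out.matrix.pos))
        assert not (set((s, int(p)) for s, p in planted) & final)

    def test_empty_panel_rejected(self, cohort_panel):
        ref, panel = cohort_panel
        import dataclasses

        empty = dataclasses.replace(panel, matrix=panel.matrix.take_loci(np.array([], dtype=int)))
        with pytest.raises(ValueError):
            evaluate_panel_probes(empty, ref)
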
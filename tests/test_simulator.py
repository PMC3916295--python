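"""Simulator string surgery, read generation and truth bookkeeping."""

import numpy as np
import pytest

from overlapsv.dna import reverse_complement
from overlapsv.fragments import reconstruct_fragment
from overlapsv.simulate import (
    SV_TYPES,
    TruthSet,
    evaluate_calls,
    generate_reference,
    make_noise_calls,
    plant_svs,
    simulate_read_pairs,
    write_fastq,
)
from overlapsv.svgraph import SVCall


class TestGenerateReference:
    def test_deterministic(self):
        a = generate_reference({"chr1": 20000}, seed=7)
        b = generate_reference({"chr1": 20000}, seed=7)
        assert a == b

    def test_gc_content(self):
        ref = generate_reference({"chr1": 200000}, gc=0.3, seed=8)
        seq = ref["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.3, abs=0.01)

    def test_two_chromosomes(self):
        ref = generate_reference({"chr1": 5000, "chr2": 3000}, seed=9)
        assert set(ref) == {"chr1", "chr2"}
        assert len(ref["chr2"]) == 3000

    def test_repeat_cassettes_reduce_uniqueness(self):
        from overlapsv.seeding import unique_alignability

        plain = generate_reference({"chr1": 40000}, seed=10)
        repeats = generate_reference({"chr1": 40000}, seed=10, repeat_fraction=0.2,
                                     repeat_length=500, repeat_families=2)
        u_plain = unique_alignability(plain, k=30)["chr1"][0]
        u_rep = unique_alignability(repeats, k=30)["chr1"][0]
        assert u_rep < u_plain - 0.05


class TestPlanting:
    def test_deletion_shortens_haplotype(self):
        ref = generate_reference({"chr1": 50000}, seed=0)
        haps, truth = plant_svs(ref, {"deletion": 1}, seed=1)
        sv = truth.svs[0]
        assert len(haps[0]["chr1"]) == 50000 - sv.size
        (c, s), (_, e) = sv.coords["start"], sv.coords["end"]
        assert haps[0]["chr1"][s - 20 : s] == ref["chr1"][s - 20 : s]
        assert haps[0]["chr1"][s : s + 20] == ref["chr1"][e : e + 20]

    def test_insertion_sequence_planted(self):
        ref = generate_reference({"chr1": 50000}, seed=2)
        haps, truth = plant_svs(ref, {"insertion": 1}, seed=3)
        sv = truth.svs[0]
        _, p = sv.coords["site"]
        hap = haps[0]["chr1"]
        assert hap[p : p + sv.size] == sv.seq
        assert len(hap) == 50000 + sv.size

    def test_tandem_duplication_doubles_segment(self):
        ref = generate_reference({"chr1": 50000}, seed=4)
        haps, truth = plant_svs(ref, {"tandem_duplication": 1}, seed=5)
        sv = truth.svs[0]
        (_, s), (_, e) = sv.coords["start"], sv.coords["end"]
        unit = ref["chr1"][s:e]
        assert haps[0]["chr1"][s : s + 2 * len(unit)] == unit + unit

    def test_inversion_reverse_complements(self):
        ref = generate_reference({"chr1": 50000}, seed=6)
        haps, truth = plant_svs(ref, {"inversion": 1}, seed=7)
        sv = truth.svs[0]
        (_, s), (_, e) = sv.coords["start"], sv.coords["end"]
        assert haps[0]["chr1"][s:e] == reverse_complement(ref["chr1"][s:e])

    def test_inverted_upstream_insertional_duplication_geometry(self):
        ref = generate_reference({"chr1": 80000}, seed=8)
        haps, truth = plant_svs(ref, {"insertional_duplication_intra_up_inverted": 1}, seed=9)
        sv = truth.svs[0]
        (_, p) = sv.coords["site"]
        (_, s), (_, e) = sv.coords["dstart"], sv.coords["dend"]
        donor = ref["chr1"][s:e]
        hap = haps[0]["chr1"]
        assert p < s  # upstream insertion
        assert hap[p : p + len(donor)] == reverse_complement(donor)
        # donor region itself intact (shifted right by the insert length)
        assert hap[s + len(donor) : e + len(donor)] == donor

    def test_translocation_removes_donor(self):
        ref = generate_reference({"chr1": 40000, "chr2": 40000}, seed=10)
        haps, truth = plant_svs(ref, {"translocation_inter": 1}, seed=11)
        sv = truth.svs[0]
        (cp, p) = sv.coords["site"]
        (cd, s), (_, e) = sv.coords["dstart"], sv.coords["dend"]
        donor = ref[cd][s:e]
        assert cp != cd
        assert haps[0][cp][p : p + len(donor)] == donor
        assert len(haps[0][cd]) == 40000 - sv.size
        assert haps[0][cd][s - 10 : s + 10] == ref[cd][s - 10 : s] + ref[cd][e : e + 10]

    def test_het_and_hom_respect_haplotypes(self):
        ref = generate_reference({"chr1": 200000}, seed=12)
        haps, truth = plant_svs(ref, {"deletion": 20}, ploidy=2, het_fraction=0.5, seed=13)
        het = [sv for sv in truth.svs if len(sv.haplotypes) == 1]
        hom = [sv for sv in truth.svs if len(sv.haplotypes) == 2]
        assert het and hom
        total_het_on_h0 = sum(sv.size for sv in truth.svs if 0 in sv.haplotypes)
        assert len(haps[0]["chr1"]) == 200000 - total_het_on_h0

    def test_genome_too_small_raises(self):
        ref = generate_reference({"chr1": 20000}, seed=14)
        with pytest.raises(ValueError, match="too small"):
            plant_svs(ref, {"deletion": 50}, seed=15)

    def test_all_types_plantable(self):
        ref = generate_reference({"chr1": 60000, "chr2": 30000}, seed=16)
        for t in SV_TYPES:
            _, truth = plant_svs(ref, {t: 1}, seed=17)
            assert truth.svs[0].type == t

    def test_truth_json_round_trip(self, tmp_path):
        ref = generate_reference({"chr1": 80000}, seed=18)
        _, truth = plant_svs(ref, {"deletion": 3, "insertion": 2}, seed=19)
        path = tmp_path / "truth.json"
        truth.to_json_file(str(path))
        back = TruthSet.from_json_file(str(path))
        assert back.svs == truth.svs


class TestReads:
    def test_error_free_pairs_reconstruct(self):
        ref = generate_reference({"chr1": 30000}, seed=20)
        pairs = list(simulate_read_pairs(ref, coverage=2, seed=21))
        for pair in pairs[:200]:
            rec = reconstruct_fragment(pair)
            assert rec is not None and rec.score == 1.0
            assert 150 <= rec.length <= 287

    def test_fragment_count_matches_coverage(self):
        ref = generate_reference({"chr1": 500000}, seed=22)
        pairs = list(simulate_read_pairs(ref, coverage=20, frag_dist="uniform",
                                         frag_range=(200, 287), seed=23))
        expected = 20 * 500000 / 243.5
        assert len(pairs) == pytest.approx(expected, rel=0.05)

    def test_untruncated_mode_produces_nonoverlapping_pairs(self):
        ref = generate_reference({"chr1": 100000}, seed=24)
        pairs = list(simulate_read_pairs(ref, coverage=2, frag_dist="normal",
                                         frag_mean=350, frag_sd=60,
                                         truncate_overlap=False, seed=25))
        recs = [reconstruct_fragment(p) for p in pairs]
        assert any(r is None for r in recs) and any(r is not None for r in recs)

    def test_seed_reproducibility_byte_identical(self, tmp_path):
        ref = generate_reference({"chr1": 20000}, seed=26)
        files = []
        for run in ("a", "b"):
            p1, p2 = tmp_path / f"{run}_1.fastq", tmp_path / f"{run}_2.fastq"
            write_fastq(simulate_read_pairs(ref, coverage=2, seed=27), str(p1), str(p2))
            files.append((p1.read_bytes(), p2.read_bytes()))
        assert files[0] == files[1]

    def test_error_rate_injects_mismatches(self):
        ref = generate_reference({"chr1": 50000}, seed=28)
        clean = list(simulate_read_pairs(ref, coverage=1, seed=29))
        noisy = list(simulate_read_pairs(ref, coverage=1, error_rate=0.01, seed=29))
        diffs = sum(
            a != b
            for p, q in zip(clean, noisy)
            for a, b in zip(p.seq1 + p.seq2, q.seq1 + q.seq2)
        )
        total = sum(len(p.seq1) + len(p.seq2) for p in clean)
        assert diffs / total == pytest.approx(0.01, rel=0.2)


class TestEvaluate:
    def test_perfect_calls_full_recall(self):
        ref = generate_reference({"chr1": 200000}, seed=30)
        _, truth = plant_svs(ref, {"deletion": 10}, seed=31)
        calls = [
            SVCall("deletion", dict(sv.coords), weight=5) for sv in truth.svs
        ]
        res = evaluate_calls(calls, truth, tolerance=0)
        assert res["deletion"].recall == 1.0 and res["deletion"].precision == 1.0

    def test_offset_beyond_tolerance_not_recalled(self):
        ref = generate_reference({"chr1": 200000}, seed=32)
        _, truth = plant_svs(ref, {"deletion": 5}, seed=33)
        calls = []
        for sv in truth.svs:
            c, s = sv.coords["start"]
            _, e = sv.coords["end"]
            calls.append(SVCall("deletion", {"start": (c, s + 3), "end": (c, e + 3)}))
        assert evaluate_calls(calls, truth, tolerance=2)["deletion"].n_recalled == 0
        assert evaluate_calls(calls, truth, tolerance=3)["deletion"].n_recalled == 5

    def test_translocation_updown_equivalence(self):
        # an upstream plant may legitimately be described as downstream
        truth = TruthSet([
            __import__("overlapsv.simulate", fromlist=["SimulatedSV"]).SimulatedSV(
                "translocation_intra_up",
                {"site": ("chr1", 100), "dstart": ("chr1", 5000), "dend": ("chr1", 5400)},
                400,
            )
        ])
        call = SVCall(
            "translocation_intra_down",
            {"site": ("chr1", 5400), "dstart": ("chr1", 100), "dend": ("chr1", 5000)},
            weight=5,
        )
        res = evaluate_calls([call], truth)
        assert res["translocation_intra_up"].n_recalled == 1

    def test_partial_signature_tally(self):
        from overlapsv.simulate import SimulatedSV

        truth = TruthSet([
            SimulatedSV(
                "translocation_inter",
                {"site": ("chr2", 100), "dstart": ("chr1", 5000), "dend": ("chr1", 5400)},
                400,
            )
        ])
        call = SVCall(
            "insertional_duplication_inter",
            {"site": ("chr2", 100), "dstart": ("chr1", 5000), "dend": ("chr1", 5400)},
            weight=5,
        )
        res = evaluate_calls([call], truth)
        assert res["translocation_inter"].n_recalled == 0
        assert res["translocation_inter"].n_partial == 1


def test_noise_calls_have_weight_one():
    ref = generate_reference({"chr1": 10000}, seed=34)
    noise = make_noise_calls(ref, 20, seed=35)
    assert len(noise) == 20
    assert all(c.weight == 1 and c.type == "insertion" for c in noise)
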
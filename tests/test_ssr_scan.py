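import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssrforge.errors import InvalidAlphabetError, InvalidMotifError, MissingSequenceError
from ssrforge.ssr_scan import (
    DEFAULT_MIN_REPEATS,
    MOTIF_CLASSES,
    ScanConfig,
    SSRLocus,
    canonical_family,
    classify_genomic_context,
    extract_flanks,
    is_primitive,
    scan_sequence,
    summarize_by_class_and_chrom,
    summarize_context,
)

from conftest import random_dna
from oracles import oracle_scan


def make_locus(seq_id="chr1", start=101, motif="AT", reps=9):
    k = len(motif)
    return SSRLocus(
        locus_id=f"{seq_id}:{start}",
        seq_id=seq_id,
        start=start,
        end=start + k * reps - 1,
        motif=motif,
        family=canonical_family(motif),
        motif_class={1: "Mono", 2: "Di", 3: "Tri", 4: "Tetra", 5: "Penta", 6: "Hexa"}[k],
        repeat_count=reps,
        tract_length=k * reps,
    )


class TestCanonicalFamily:
    def test_rotation_grouping(self):
        assert canonical_family("GA") == "AG"

    def test_single_base_identity(self):
        assert canonical_family("A") == "A"

    def test_trinucleotide_minimum_rotation(self):
        # min over rotations {TAA, AAT, ATA}
        assert canonical_family("TAA") == "AAT"

    def test_reverse_complements_not_merged(self):
        assert canonical_family("AG") != canonical_family("CT")
        assert canonical_family("TC") == "CT"

    @pytest.mark.parametrize("bad", ["", "AX", "at ", "AU"])
    def test_invalid_alphabet(self, bad):
        with pytest.raises(InvalidAlphabetError):
            canonical_family(bad)

    @pytest.mark.parametrize("bad", ["AA", "ATAT", "AGAGAG", "CCC"])
    def test_non_primitive_rejected(self, bad):
        with pytest.raises(InvalidMotifError):
            canonical_family(bad)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=6))
    def test_canonical_is_rotation_invariant(self, motif):
        if not is_primitive(motif):
            return
        families = {
            canonical_family(motif[i:] + motif[:i]) for i in range(len(motif))
        }
        assert len(families) == 1


class TestScanSequence:
    def test_empty_sequence(self):
        assert scan_sequence("s", "") == []

    def test_single_di_locus_in_neutral_flanks(self, rng):
        # seeded flanks verified free of qualifying repeats by the oracle
        flank_a = random_dna(rng, 100)
        flank_b = random_dna(rng, 100)
        seq = flank_a + "AT" * 9 + flank_b
        thresholds = {MOTIF_CLASSES[c]: t for c, t in DEFAULT_MIN_REPEATS.items()}
        expected = oracle_scan(seq, thresholds)
        loci = scan_sequence("s", seq)
        assert [(l.start, len(l.motif), l.repeat_count) for l in loci] == expected
        assert len(loci) == 1
        (locus,) = loci
        assert locus.motif_class == "Di"
        assert locus.family == "AT"
        assert locus.repeat_count == 9
        assert locus.tract_length == 18

    def test_mono_below_threshold(self):
        assert scan_sequence("s", "A" * 19) == []
        assert len(scan_sequence("s", "A" * 20)) == 1

    def test_cg_motif_detectable(self, rng):
        seq = random_dna(rng, 80) + "CG" * 8 + random_dna(rng, 80)
        loci = [l for l in scan_sequence("s", seq) if l.motif_class == "Di"]
        assert len(loci) == 1
        assert loci[0].family == "CG"

    def test_n_breaks_runs(self):
        # 8 + 8 repeats separated by N: neither half passes Di threshold 8? both do at exactly 8
        seq = "AT" * 8 + "N" + "AT" * 8
        loci = scan_sequence("s", seq)
        assert len(loci) == 2
        assert all(l.repeat_count == 8 for l in loci)
        # N inside a run splits it into two below-threshold halves
        seq2 = "AT" * 4 + "N" + "AT" * 4
        assert scan_sequence("s", seq2) == []

    def test_poly_a_is_mono_not_di(self):
        loci = scan_sequence("s", "A" * 40)
        assert len(loci) == 1
        assert loci[0].motif_class == "Mono"

    def test_invalid_alphabet(self):
        with pytest.raises(InvalidAlphabetError):
            scan_sequence("s", "ACGTX")

    def test_lowercase_accepted(self):
        assert len(scan_sequence("s", "at" * 9)) == 1

    def test_per_sequence_override(self):
        cfg = ScanConfig(per_sequence_overrides={("chr6", "Di"): 5})
        seq = "AT" * 6
        assert len(scan_sequence("chr6", seq, cfg)) == 1
        assert scan_sequence("chr1", seq, cfg) == []

    def test_output_sorted_and_disjoint_per_family(self, rng):
        seq = random_dna(rng, 300) + "AT" * 9 + random_dna(rng, 300) + "GA" * 10 + random_dna(rng, 300)
        loci = scan_sequence("s", seq)
        starts = [l.start for l in loci]
        assert starts == sorted(starts)
        for a in loci:
            for b in loci:
                if a is not b and a.family == b.family:
                    assert a.end < b.start or b.end < a.start


LOW = ScanConfig(thresholds={"Mono": 8, "Di": 4, "Tri": 3, "Tetra": 2, "Penta": 2, "Hexa": 2})
LOW_BY_K = {1: 8, 2: 4, 3: 3, 4: 2, 5: 2, 6: 2}


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(40))
    def test_random_sequences_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 1000)
        if seed % 3 == 0:  # sprinkle Ns
            chars = list(seq)
            for p in rng.integers(0, 1000, size=5):
                chars[p] = "N"
            seq = "".join(chars)
        got = [(l.start, len(l.motif), l.repeat_count) for l in scan_sequence("s", seq, LOW)]
        assert got == oracle_scan(seq, LOW_BY_K)

    def test_maximality(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            seq = random_dna(rng, 1000)
            for l in scan_sequence("s", seq, LOW):
                k = len(l.motif)
                left = seq[l.start - 1 - k : l.start - 1]
                right = seq[l.end : l.end + k]
                assert left != l.motif
                assert right != l.motif

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(11)
        seq = random_dna(rng, 2000)
        keys = lambda loci: {(l.start, l.motif_class) for l in loci}
        prev = None
        for di in (2, 3, 4, 5):
            cfg = ScanConfig(thresholds={**LOW.thresholds, "Di": di})
            cur = keys(scan_sequence("s", seq, cfg))
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_primitivity_of_reported_motifs(self):
        rng = np.random.default_rng(13)
        seq = random_dna(rng, 3000)
        for l in scan_sequence("s", seq, LOW):
            assert is_primitive(l.motif)


class TestExtractFlanks:
    def test_mid_sequence(self, rng):
        genome = {"s": random_dna(rng, 10_000)}
        locus = make_locus("s", 201, "AT", 9)
        frag = extract_flanks(locus, genome, 200)
        assert (frag.start, frag.end) == (1, 418)
        assert frag.left_clip == 0

    def test_left_edge_clipping(self, rng):
        genome = {"s": random_dna(rng, 1000)}
        locus = make_locus("s", 1, "A", 20)
        frag = extract_flanks(locus, genome, 200)
        assert (frag.start, frag.end) == (1, 220)
        assert frag.left_clip == 200
        assert frag.right_clip == 0

    def test_fragment_length(self, rng):
        seq = random_dna(rng, 2000) + "ACG" * 8 + random_dna(rng, 2000)
        genome = {"s": seq}
        locus = make_locus("s", 2001, "ACG", 8)
        frag = extract_flanks(locus, genome, 50)
        assert len(frag.sequence) == locus.tract_length + 100
        assert frag.sequence[frag.tract_start - 1 : frag.tract_end] == "ACG" * 8

    def test_missing_sequence(self):
        with pytest.raises(MissingSequenceError):
            extract_flanks(make_locus("nope"), {"s": "ACGT" * 100}, 10)


class TestGenomicContext:
    def test_containment(self):
        locus = make_locus("s", 100, "AT", 10)  # 100..119
        labels = classify_genomic_context([locus], {"s": [(50, 200)]})
        assert labels[locus.locus_id] == "coding"

    def test_no_intervals(self):
        locus = make_locus("s", 100)
        assert classify_genomic_context([locus], {})[locus.locus_id] == "non-coding"

    def test_single_base_overlap(self):
        locus = make_locus("s", 100, "AT", 10)  # ends at 119
        labels = classify_genomic_context([locus], {"s": [(119, 300)]})
        assert labels[locus.locus_id] == "coding"
        labels = classify_genomic_context([locus], {"s": [(120, 300)]})
        assert labels[locus.locus_id] == "non-coding"

    def test_summary_counts(self):
        loci = [make_locus("s", 100), make_locus("s", 500), make_locus("t", 100)]
        labels = classify_genomic_context(loci, {"s": [(1, 200)]})
        table = summarize_context(loci, labels)
        assert table.loc["s", ("Di", "coding")] == 1
        assert table.loc["s", ("Di", "non-coding")] == 1


class TestSummary:
    def test_empty(self):
        table = summarize_by_class_and_chrom([])
        assert table.to_numpy().sum() == 0

    def test_paper_chromosome_counts_total(self):
        counts = {f"Chr.{i + 1}": n for i, n in
                  enumerate([607, 612, 542, 396, 604, 568, 372, 493, 826])}
        loci = []
        for chrom, n in counts.items():
            for j in range(n):
                loci.append(make_locus(chrom, 1000 + 400 * j))
        table = summarize_by_class_and_chrom(loci)
        assert table.loc["Total", "Total"] == 5020
        for chrom, n in counts.items():
            assert table.loc[chrom, "Total"] == n

    def test_two_same_cell(self):
        loci = [make_locus("s", 100), make_locus("s", 500)]
        table = summarize_by_class_and_chrom(loci)
        assert table.loc["s", "Di"] == 2


class TestConfigValidation:
    def test_threshold_floor(self):
        with pytest.raises(ValueError):
            ScanConfig(thresholds={**DEFAULT_MIN_REPEATS, "Di": 1})

    def test_negative_flank(self):
        with pytest.raises(ValueError):
            ScanConfig(flank_length=-1)

    def test_unknown_class(self):
        with pytest.raises(ValueError):
            ScanConfig(thresholds={**DEFAULT_MIN_REPEATS, "Hepta": 4})
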
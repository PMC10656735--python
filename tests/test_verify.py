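import numpy as np
import pandas as pd
import pytest

from oracles import oracle_self_dimer
from mdmscan.seqio import SequenceRecord
from mdmscan.verify import (
    PrimerPair, compare_amplicon, gc_content, in_silico_pcr, melting_temp,
    qc_primer_pair, reverse_complement, self_dimer, verify_mdms,
)

BASES = np.array(list("ACGT"))


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [
        ("ATGC", 50.0), ("AAAA", 0.0), ("GCGC", 100.0), ("AATGCGGT", 50.0),
    ])
    def test_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)


class TestMeltingTemp:
    def test_matches_independent_nearest_neighbor_oracle(self):
        """Same NN table + salt correction, independently coded in Biopython."""
        from Bio.SeqUtils import MeltingTemp as mt
        rng = np.random.default_rng(13)
        for _ in range(25):
            seq = "".join(rng.choice(BASES, int(rng.integers(15, 31))))
            ours = melting_temp(seq, na_molar=0.05, oligo_molar=0.5e-6)
            # dnac1=dnac2=250 nM gives biopython's duplex term
            # k = dnac1 - dnac2/2 = 125 nM = C_T/4 for C_T = 500 nM,
            # matching our two-state non-self-complementary model
            ref = mt.Tm_NN(seq, nn_table=mt.DNA_NN3, Na=50, saltcorr=5,
                           dnac1=250, dnac2=250, selfcomp=False)
            assert ours == pytest.approx(ref, abs=0.1)

    def test_self_complementary_oligo_matches_oracle(self):
        from Bio.SeqUtils import MeltingTemp as mt
        seq = "GAATTCCCGGGAATTC"
        if seq != reverse_complement(seq):
            seq = "ACGTGGCCACGT"  # palindromic fallback
        assert seq == reverse_complement(seq)
        ours = melting_temp(seq, na_molar=0.05, oligo_molar=0.5e-6)
        ref = mt.Tm_NN(seq, nn_table=mt.DNA_NN3, Na=50, saltcorr=5,
                       dnac1=500, dnac2=0, selfcomp=True)
        assert ours == pytest.approx(ref, abs=0.1)

    def test_gc_rich_melts_higher_than_at_rich(self):
        assert melting_temp("ACGT" * 5) > melting_temp("ATAT" * 5)

    def test_deterministic(self):
        assert melting_temp("ACGTACGTACGTACGT") == melting_temp("ACGTACGTACGTACGT")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            melting_temp("ACGTACG")


class TestSelfDimer:
    def test_homopolymer_has_no_self_complement(self):
        assert self_dimer("AAAAAA") == 0

    def test_palindrome_fully_self_complementary(self):
        assert self_dimer("GAATTC") == 6

    def test_matches_brute_force_on_random_20mers(self):
        rng = np.random.default_rng(19)
        for _ in range(30):
            seq = "".join(rng.choice(BASES, 20))
            assert self_dimer(seq) == oracle_self_dimer(seq)


class TestPrimerPair:
    def test_length_and_alphabet_enforced(self):
        with pytest.raises(ValueError):
            PrimerPair("p", "ACGT", "ACGTACGTACGTACGTAC")
        with pytest.raises(ValueError):
            PrimerPair("p", "ACGTACGTACGTACGNAC", "ACGTACGTACGTACGTAC")

    def test_qc_report_fields(self):
        pair = PrimerPair("p", "CGTAGGCGGTTTCTTAAGTT", "ACTCGGGTTTCTAATCCTCT")
        rep = qc_primer_pair(pair)
        assert 0 <= rep.fwd_gc <= 100
        assert rep.tm_difference == pytest.approx(abs(rep.fwd_tm - rep.rev_tm))
        assert isinstance(rep.passed, bool)


class TestInSilicoPcr:
    def _template(self, rng, n=400):
        return SequenceRecord("t", "".join(rng.choice(BASES, n)))

    def test_verbatim_primers_amplify_the_template_slice(self):
        rng = np.random.default_rng(23)
        t = self._template(rng)
        fwd = t.seq[10:30]
        rev = reverse_complement(t.seq[300:320])
        res = in_silico_pcr(PrimerPair("p", fwd, rev), t)
        assert res.amplicon is not None
        assert res.amplicon.seq == t.seq[10:320]

    def test_three_mismatches_block_annealing(self):
        rng = np.random.default_rng(29)
        t = self._template(rng)
        fwd = list(t.seq[10:30])
        for pos in (2, 5, 8):
            fwd[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[fwd[pos]]
        rev = reverse_complement(t.seq[300:320])
        res = in_silico_pcr(PrimerPair("p", "".join(fwd), rev), t)
        assert res.amplicon is None and res.reason == "NO_PRODUCT"

    def test_three_prime_mismatch_blocks_even_if_total_within_budget(self):
        rng = np.random.default_rng(31)
        t = self._template(rng)
        fwd = list(t.seq[10:30])
        fwd[-1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[fwd[-1]]
        rev = reverse_complement(t.seq[300:320])
        res = in_silico_pcr(PrimerPair("p", "".join(fwd), rev), t)
        assert res.amplicon is None

    def test_duplicated_locus_gives_multiple_products(self):
        rng = np.random.default_rng(37)
        core = "".join(rng.choice(BASES, 120))
        t = SequenceRecord("t", core + "".join(rng.choice(BASES, 50)) + core)
        fwd = core[0:20]
        rev = reverse_complement(core[100:120])
        res = in_silico_pcr(PrimerPair("p", fwd, rev), t)
        assert res.amplicon is None and res.reason == "MULTIPLE_PRODUCTS"


class TestCompareAmplicon:
    def test_exact_substring_passes(self):
        rng = np.random.default_rng(41)
        mdms = SequenceRecord("m", "".join(rng.choice(BASES, 450)))
        amp = SequenceRecord("a", mdms.seq[20:420])
        res = compare_amplicon(amp, mdms)
        assert res.passed and res.identity == 100.0 and res.query_cover == 100.0

    def test_identity_exactly_95_fails_strict_rule(self):
        rng = np.random.default_rng(43)
        mdms = SequenceRecord("m", "".join(rng.choice(BASES, 450)))
        amp = list(mdms.seq[25:425])  # 400 bp, plant 20 interior mismatches
        for pos in range(10, 390, 19):
            amp[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[amp[pos]]
        res = compare_amplicon(SequenceRecord("a", "".join(amp)), mdms)
        assert res.identity == pytest.approx(95.0)
        assert not res.passed
        assert res.review  # (94.5, 95] with full cover is flagged for review

    def test_incomplete_cover_fails_regardless_of_identity(self):
        rng = np.random.default_rng(47)
        mdms = SequenceRecord("m", "".join(rng.choice(BASES, 400)))
        # 30-base tail transversion-flipped against the template continuation,
        # so it cannot extend the alignment: coverage < 100
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        tail = "".join(flip[c] for c in mdms.seq[350:380])
        amp = SequenceRecord("a", mdms.seq[50:350] + tail)
        res = compare_amplicon(amp, mdms)
        assert res.query_cover < 100.0
        assert not res.passed


class TestVerifyRoundTrip:
    def test_primers_off_the_ends_verify_their_mdms(self, synth_dir):
        """Perfect primers excised from each MDMS re-amplify and pass."""
        from mdmscan.seqio import read_fasta
        reps = {r.id: r for r in read_fasta(synth_dir / "otus.fasta")}
        primers = pd.read_csv(synth_dir / "primers.tsv", sep="\t", dtype=str)
        assert len(primers) >= 3
        for row in primers.itertuples():
            pair = PrimerPair(row.name, row.fwd, row.rev)
            res = verify_mdms(reps[row.name], pair)
            assert res.passed, row.name
            assert res.amplified_len <= len(reps[row.name].seq)
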
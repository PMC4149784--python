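"""Degenerate consensus expansion, ARE octamer derivatives, double-strand
scanning against a regex oracle, and region extraction."""

import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from regulonprint.motifs import (AFT_CONSENSUS, ARE_CONSENSUS,
                                 DegenerateConsensus, RegionSeq, SequenceSet,
                                 expand_degenerate, extract_regions,
                                 octamer_derivatives, revcomp, scan, tokenize)


class TestExpansion:
    def test_aft_site_expands_to_eight_words(self):
        words = expand_degenerate("PyPuCACCCPu")
        assert len(words) == 8
        assert "CACACCCA" in words
        assert "TGCACCCG" in words

    def test_concrete_word_is_identity(self):
        assert expand_degenerate("ACGT") == {"ACGT"}

    def test_u_canonicalised_to_t(self):
        assert expand_degenerate("UUAUUUAUU") == {"TTATTTATT"}

    def test_unknown_token_rejected(self):
        with pytest.raises(ValueError):
            expand_degenerate("ACGX")

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.sampled_from(list("ACGTRYSWKMBDHVN") + ["Py", "Pu"]),
                    min_size=4, max_size=8))
    def test_cardinality_is_product_of_alternatives(self, tokens):
        from regulonprint.motifs import TOKEN_ALTERNATIVES
        pattern = "".join(tokens)
        expected = int(np.prod([len(TOKEN_ALTERNATIVES[t])
                                for t in tokenize(pattern)]))
        assert len(expand_degenerate(pattern)) == expected


class TestOctamerDerivatives:
    def test_are_has_two_windows(self):
        assert octamer_derivatives("TTATTTATT") == {"TTATTTAT", "TATTTATT"}

    def test_duplicates_collapse(self):
        assert octamer_derivatives("AAAAAAAAA") == {"AAAAAAAA"}

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            octamer_derivatives("TTATTTAT")


def regex_oracle(seq, words, both_strands):
    """Independent overlap-aware match finder: lookahead alternation regex
    on the stored sequence; minus-strand hits located on the reverse
    complement and mapped back."""
    hits = set()
    for word in words:
        for m in re.finditer("(?=(" + word + "))", seq):
            hits.add(("+", m.start() + 1, word))
    if both_strands:
        rc = revcomp(seq)
        for word in words:
            for m in re.finditer("(?=(" + word + "))", rc):
                start = len(seq) - m.start() - len(word)  # 0-based on seq
                hits.add(("-", start + 1, word))
    return hits


def scan_to_set(df):
    return {(r.strand, r.start, r.word) for r in df.itertuples()}


class TestScan:
    def test_are_by_inspection(self):
        rec = RegionSeq(gene="G", region="utr3", seq="GGTTATTTATTGG")
        hits = scan([rec], ARE_CONSENSUS, collapse=True, region_filter=None)
        assert len(hits) == 1
        assert hits.loc[0, "start"] == 3
        assert hits.loc[0, "word"] == "TTATTTATT"
        # without collapse the embedded octamer hits surface too
        full = scan([rec], ARE_CONSENSUS, collapse=False, region_filter=None)
        assert set(full["word"]) == {"TTATTTATT", "TTATTTAT", "TATTTATT"}

    def test_minus_strand_promoter_hit(self):
        # TGGGTGTG is the reverse complement of the Aft word CACACCCA
        rec = RegionSeq(gene="G", region="promoter", seq="AATGGGTGTGAA")
        hits = scan([rec], AFT_CONSENSUS, region_filter=None)
        assert len(hits) == 1
        assert hits.loc[0, "strand"] == "-"
        assert hits.loc[0, "word"] == "CACACCCA"
        sense_only = DegenerateConsensus(name="Aft1", pattern="PyPuCACCCPu",
                                         region_target="promoter",
                                         strand_policy="sense")
        assert scan([rec], sense_only, region_filter=None).empty

    @pytest.mark.parametrize("consensus", [AFT_CONSENSUS, ARE_CONSENSUS],
                             ids=["Aft1", "ARE"])
    def test_matches_regex_oracle_on_random_sequences(self, consensus):
        rng = np.random.default_rng(11)
        for i in range(60):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
            rec = RegionSeq(gene=f"G{i}", region=consensus.region_target,
                            seq=seq)
            got = scan_to_set(scan([rec], consensus, collapse=False,
                                   region_filter=None))
            want = regex_oracle(seq, consensus.words(),
                                consensus.strand_policy == "both")
            assert got == want

    def test_strand_symmetry(self):
        """Reverse-complementing the sequence leaves the both-strand match
        multiset invariant with strands swapped."""
        rng = np.random.default_rng(5)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3000)])
        fwd = scan([RegionSeq(gene="G", region="promoter", seq=seq)],
                   AFT_CONSENSUS, collapse=False, region_filter=None)
        rev = scan([RegionSeq(gene="G", region="promoter", seq=revcomp(seq))],
                   AFT_CONSENSUS, collapse=False, region_filter=None)
        flipped = {("-" if s == "+" else "+",
                    len(seq) - p - len(w) + 2, w)
                   for s, p, w in scan_to_set(fwd)}
        assert flipped == scan_to_set(rev)

    def test_background_rate_matches_closed_form(self):
        """Hit count on uniform sequence ~ Binomial with per-position rate
        sum over strands and words of 1/4^w."""
        rng = np.random.default_rng(42)
        n, L = 300, 2000
        recs = [RegionSeq(gene=f"G{i}", region="promoter",
                          seq="".join(np.array(list("ACGT"))[
                              rng.integers(0, 4, L)]))
                for i in range(n)]
        hits = scan(recs, AFT_CONSENSUS, collapse=False, region_filter=None)
        words = AFT_CONSENSUS.words()
        expected = n * sum(2 * (L - len(w) + 1) / 4 ** len(w) for w in words)
        sd = np.sqrt(expected)  # Poisson-scale error
        assert abs(len(hits) - expected) < 4 * sd

    def test_n_never_matches(self):
        # the N interrupts every ARE word and octamer derivative
        rec = RegionSeq(gene="G", region="utr3", seq="TTATNTATT" + "G" * 20)
        assert scan([rec], ARE_CONSENSUS, region_filter=None).empty


class TestExtractRegions:
    GENOME = None

    def setup_method(self):
        rng = np.random.default_rng(3)
        self.chrom = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3000)])
        self.genome = {"chrI": self.chrom}

    def ann(self, **kw):
        row = {"gene": "G1", "chrom": "chrI", "start": 1001, "end": 2000,
               "strand": "+"}
        row.update(kw)
        return pd.DataFrame([row])

    def test_plus_strand_promoter_window(self):
        seqs = extract_regions(self.genome, self.ann(), promoter_len=600)
        promoter = seqs.get("G1", "promoter")
        assert promoter.seq == self.chrom[400:1000]  # genomic 401..1000
        assert not promoter.truncated

    def test_minus_strand_promoter_is_revcomp_downstream(self):
        seqs = extract_regions(self.genome, self.ann(strand="-"),
                               promoter_len=600)
        promoter = seqs.get("G1", "promoter")
        assert promoter.seq == revcomp(self.chrom[2000:2600])  # 2001..2600

    def test_truncation_at_chromosome_start(self):
        seqs = extract_regions(self.genome, self.ann(start=50, end=900),
                               promoter_len=600)
        promoter = seqs.get("G1", "promoter")
        assert len(promoter.seq) == 49
        assert promoter.truncated

    def test_utr3_default_window_and_annotated_override(self):
        seqs = extract_regions(self.genome, self.ann(), utr3_len=200)
        assert seqs.get("G1", "utr3").seq == self.chrom[2000:2200]
        ann = self.ann(utr3_start=2001, utr3_end=2100)
        seqs = extract_regions(self.genome, ann)
        assert seqs.get("G1", "utr3").seq == self.chrom[2000:2100]

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(KeyError):
            extract_regions(self.genome, self.ann(chrom="chrII"))

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            extract_regions(self.genome, self.ann(end=9000))


def test_sequence_set_fasta_round_trip(tmp_path):
    seqs = SequenceSet()
    seqs.add(RegionSeq(gene="G1", region="promoter", seq="ACGTACGTAC"))
    seqs.add(RegionSeq(gene="G1", region="utr3", seq="TTTTAAAACC"))
    path = tmp_path / "regions.fasta"
    seqs.to_fasta(path)
    back = SequenceSet.from_fasta(path)
    assert len(back) == 2
    assert back.get("G1", "utr3").seq == "TTTTAAAACC"
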
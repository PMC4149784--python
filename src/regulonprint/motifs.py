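"""Degenerate consensus motifs: expansion, scanning and region extraction.

Two consensus elements drive the candidate-target nomination:

* the Aft1/2 promoter site ``PyPuCACCCPu`` (Py = pyrimidine C/T,
  Pu = purine A/G), a DNA element scanned on both strands of promoters;
* the AU-rich element (ARE) ``UUAUUUAUU`` "or an octamer derivative" — the
  3'-UTR element through which Cth2 destabilises iron-sparing transcripts.
  Being an RNA element it is scanned on the transcript (sense) strand only,
  and the octamer derivatives are the two contiguous 8-mers of the 9-mer.

Consensus tokens cover single IUPAC codes plus the two-letter Py/Pu
abbreviations; U is canonicalised to T internally (DNA alphabet).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "DegenerateConsensus",
    "RegionSeq",
    "SequenceSet",
    "AFT_CONSENSUS",
    "ARE_CONSENSUS",
    "tokenize",
    "expand_degenerate",
    "octamer_derivatives",
    "scan",
    "extract_regions",
    "revcomp",
]

# single-letter IUPAC plus the Py/Pu two-letter tokens
TOKEN_ALTERNATIVES: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    "Py": "CT", "Pu": "AG",
}


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class DegenerateConsensus:
    """A named degenerate consensus with its scanning policy."""

    name: str
    pattern: str
    region_target: str = "promoter"  # promoter | utr3
    strand_policy: str = "both"  # both | sense
    include_octamer_derivatives: bool = False
    extra_words: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        toks = tokenize(self.pattern)
        if len(toks) < 4:
            raise ValueError("consensus must have length >= 4")
        if self.strand_policy not in ("both", "sense"):
            raise ValueError(f"unknown strand policy {self.strand_policy!r}")

    @property
    def tokens(self) -> list[str]:
        return tokenize(self.pattern)

    def words(self) -> set[str]:
        """All concrete words scanned for: expansions, plus octamer
        derivatives and any user-supplied derivative set."""
        words = expand_degenerate(self)
        if self.include_octamer_derivatives:
            for w in list(words):
                words |= octamer_derivatives(w)
        return words | set(self.extra_words)


def tokenize(pattern: str) -> list[str]:
    """Split a consensus string into tokens, greedily matching Py/Pu."""
    tokens: list[str] = []
    i = 0
    while i < len(pattern):
        two = pattern[i:i + 2]
        if two in ("Py", "Pu"):
            tokens.append(two)
            i += 2
            continue
        one = pattern[i].upper()
        if one not in TOKEN_ALTERNATIVES:
            raise ValueError(f"unknown consensus token {pattern[i]!r} in {pattern!r}")
        tokens.append(one)
        i += 1
    return tokens


def expand_degenerate(consensus: DegenerateConsensus | str) -> set[str]:
    """Cartesian expansion of a degenerate consensus into concrete DNA words."""
    pattern = consensus.pattern if isinstance(consensus, DegenerateConsensus) else consensus
    alternatives = [TOKEN_ALTERNATIVES[t] for t in tokenize(pattern)]
    return {"".join(letters) for letters in itertools.product(*alternatives)}


def octamer_derivatives(nonamer: str) -> set[str]:
    """The contiguous 8-mers of a 9-mer (the ARE 'octamer derivative' set)."""
    if len(nonamer) != 9:
        raise ValueError(f"expected a 9-mer, got {nonamer!r}")
    return {nonamer[:8], nonamer[1:]}


AFT_CONSENSUS = DegenerateConsensus(
    name="Aft1", pattern="PyPuCACCCPu",
    region_target="promoter", strand_policy="both")

ARE_CONSENSUS = DegenerateConsensus(
    name="ARE", pattern="UUAUUUAUU",
    region_target="utr3", strand_policy="sense",
    include_octamer_derivatives=True)


@dataclass
class RegionSeq:
    """One extracted region: a gene's promoter or 3'-UTR sequence.

    The sequence is stored in the gene's reading orientation (promoters of
    minus-strand genes are reverse-complemented at extraction time).
    """

    gene: str
    region: str  # promoter | utr3
    seq: str
    gene_strand: str = "+"
    truncated: bool = False

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for {self.gene}/{self.region}")
        self.seq = self.seq.upper()


@dataclass
class SequenceSet:
    """Keyed collection of region sequences, unique per (gene, region)."""

    records: dict[tuple[str, str], RegionSeq] = field(default_factory=dict)

    def add(self, rec: RegionSeq) -> None:
        key = (rec.gene, rec.region)
        if key in self.records:
            raise ValueError(f"duplicate region {key}")
        self.records[key] = rec

    def __iter__(self):
        return iter(self.records.values())

    def __len__(self) -> int:
        return len(self.records)

    def get(self, gene: str, region: str) -> RegionSeq:
        return self.records[(gene, region)]

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records.values():
                fh.write(f">{rec.gene}|{rec.region}\n{rec.seq}\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SequenceSet":
        out = cls()
        for record in SeqIO.parse(str(path), "fasta"):
            gene, _, region = record.id.partition("|")
            out.add(RegionSeq(gene=gene, region=region or "promoter",
                              seq=str(record.seq)))
        return out


MATCH_COLUMNS = ["gene", "region", "strand", "start", "word", "consensus"]


def _find_word(seq: str, word: str) -> Iterable[int]:
    """0-based start positions of (possibly overlapping) occurrences."""
    start = seq.find(word)
    while start != -1:
        yield start
        start = seq.find(word, start + 1)


def scan(seqs: SequenceSet | Iterable[RegionSeq],
         consensus: DegenerateConsensus,
         collapse: bool = True,
         region_filter: str | None = "target") -> pd.DataFrame:
    """Scan regions for every concrete instance of a degenerate consensus.

    Minus-strand matches (``strand_policy='both'`` only) are located by
    searching for the reverse complement of each word; the reported start is
    the 1-based position of that reverse-complement instance on the stored
    sequence.  ``N`` never matches.  With ``collapse=True`` matches fully
    contained inside a longer match on the same strand are dropped (a 9-mer
    ARE hit implies its octamer hits; only the 9-mer is reported).

    ``region_filter='target'`` restricts scanning to the consensus's
    declared region; pass ``None`` to scan every record.

    Returns a DataFrame with columns gene, region, strand, start (1-based,
    inclusive, on the stored sequence), word, consensus.
    """
    words = sorted(consensus.words())
    rows = []
    for rec in seqs:
        if region_filter == "target" and rec.region != consensus.region_target:
            continue
        seq = rec.seq
        for word in words:
            for pos in _find_word(seq, word):
                rows.append((rec.gene, rec.region, "+", pos + 1, word,
                             consensus.name))
            if consensus.strand_policy == "both":
                rc = revcomp(word)
                for pos in _find_word(seq, rc):
                    rows.append((rec.gene, rec.region, "-", pos + 1, word,
                                 consensus.name))
    df = pd.DataFrame(rows, columns=MATCH_COLUMNS).drop_duplicates()
    if collapse and not df.empty:
        df = _collapse_contained(df)
    return df.sort_values(["gene", "region", "start", "strand"]).reset_index(drop=True)


def _collapse_contained(df: pd.DataFrame) -> pd.DataFrame:
    """Drop matches whose interval is contained in a longer match's interval
    on the same (gene, region, strand)."""
    keep = []
    for _, group in df.groupby(["gene", "region", "strand"], sort=False):
        group = group.assign(_len=group["word"].str.len())
        group = group.sort_values("_len", ascending=False)
        kept: list[tuple[int, int]] = []
        for _, row in group.iterrows():
            lo, hi = row["start"], row["start"] + len(row["word"]) - 1
            if any(k_lo <= lo and hi <= k_hi for k_lo, k_hi in kept):
                continue
            kept.append((lo, hi))
            keep.append(row.drop("_len"))
    return pd.DataFrame(keep, columns=MATCH_COLUMNS)


def extract_regions(genome: Mapping[str, str] | str | Path,
                    annotation: pd.DataFrame,
                    promoter_len: int = 600,
                    utr3_len: int = 200) -> SequenceSet:
    """Extract promoter and 3'-UTR regions from a genome and a gene table.

    ``annotation`` columns: gene, chrom, start, end, strand — 1-based
    inclusive coordinates, start <= end regardless of strand.  Optional
    columns utr3_start / utr3_end give an annotated 3'-UTR, otherwise
    ``utr3_len`` nt immediately downstream of the gene is used.  The
    promoter is ``promoter_len`` nt immediately upstream of the annotated
    5' end on the gene's strand; minus-strand regions are
    reverse-complemented so every stored sequence reads in the gene's
    orientation.  Regions running off a chromosome end are truncated and
    flagged.
    """
    if isinstance(genome, (str, Path)):
        genome = {rec.id: str(rec.seq).upper()
                  for rec in SeqIO.parse(str(genome), "fasta")}
    out = SequenceSet()
    for row in annotation.itertuples(index=False):
        chrom = getattr(row, "chrom")
        if chrom not in genome:
            raise KeyError(f"unknown chromosome {chrom!r} for gene {row.gene}")
        chrom_seq = genome[chrom]
        L = len(chrom_seq)
        start, end, strand = int(row.start), int(row.end), row.strand
        if not (1 <= start <= end <= L):
            raise ValueError(f"gene {row.gene}: coordinates {start}..{end} "
                             f"outside chromosome of length {L}")
        # promoter: immediately upstream of the 5' gene end, gene orientation
        if strand == "+":
            p_lo, p_hi = max(1, start - promoter_len), start - 1
            p_seq, p_trunc = chrom_seq[p_lo - 1:p_hi], p_lo > start - promoter_len
        else:
            p_lo, p_hi = end + 1, min(L, end + promoter_len)
            p_seq, p_trunc = revcomp(chrom_seq[p_lo - 1:p_hi]), p_hi < end + promoter_len
        if p_seq:
            out.add(RegionSeq(gene=row.gene, region="promoter", seq=p_seq,
                              gene_strand=strand, truncated=bool(p_trunc)))
        # 3'-UTR: annotated if provided, else fixed window downstream
        u_start = getattr(row, "utr3_start", None)
        u_end = getattr(row, "utr3_end", None)
        if u_start is not None and u_end is not None and not (
                pd.isna(u_start) or pd.isna(u_end)):
            u_lo, u_hi, u_trunc = int(u_start), int(u_end), False
        elif strand == "+":
            u_lo, u_hi = end + 1, min(L, end + utr3_len)
            u_trunc = u_hi < end + utr3_len
        else:
            u_lo, u_hi = max(1, start - utr3_len), start - 1
            u_trunc = u_lo > start - utr3_len
        u_seq = chrom_seq[u_lo - 1:u_hi]
        if strand == "-":
            u_seq = revcomp(u_seq)
        if u_seq:
            out.add(RegionSeq(gene=row.gene, region="utr3", seq=u_seq,
                              gene_strand=strand, truncated=bool(u_trunc)))
    return out
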
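"""Duplicated-sequence detection and ORF screening for lncRNA transcripts.

Near-identical duplications (the kind that lets one lncRNA locus harbor the
near-complete sequence of another) are found by optimal pairwise alignment:
*global* for same-scale sequences, *glocal* — free end gaps on the longer
sequence — so a transcript contained inside a longer one aligns end-to-end.
Percent identity is identities over aligned columns, excluding end-gap
overhangs in glocal mode, reported to one decimal (half-up).  An all-vs-all
screen prescreens candidate pairs by shared exact k-mers before aligning.

Transcripts are additionally scanned for the longest ATG-to-stop open
reading frame (standard genetic code); the peptide length counts the initial
methionine and excludes the stop.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

VALID_DNA = set("ACGTN")

MATCH = 1.0
MISMATCH = -1.0
GAP_OPEN = -2.0
GAP_EXTEND = -0.5

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SequenceRecord:
    """An uppercase DNA sequence over {A, C, G, T, N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - VALID_DNA
        if bad:
            raise ValueError(f"sequence {self.id!r} has invalid characters {bad}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignmentResult:
    query_id: str
    target_id: str
    identities: int
    aligned_columns: int
    percent_identity: float          # 1 d.p., half-up
    identity_fraction: float         # raw identities / aligned_columns
    query_span: tuple[int, int]      # 0-based half-open on the query
    target_span: tuple[int, int]
    score: float


@dataclass
class OrfResult:
    id: str
    peptide_length: int              # amino acids, initial Met included
    start: int                       # 1-based, inclusive, on the forward strand
    end: int                         # 1-based inclusive (stop codon included)
    frame: int                       # 1..3 on the reported strand
    strand: str
    peptide: str


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    return [SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def _make_aligner(mode: str, long_is_target: bool) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    if mode == "glocal":
        # free end gaps against the longer sequence's overhang: when the
        # target is longer the query row carries the end gaps ("deletions"
        # in Bio.Align terms), and vice versa ("insertions")
        if long_is_target:
            aligner.open_end_deletion_score = 0.0
            aligner.extend_end_deletion_score = 0.0
        else:
            aligner.open_end_insertion_score = 0.0
            aligner.extend_end_insertion_score = 0.0
    return aligner


def _round1_half_up(x: float) -> float:
    return float(Decimal(str(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def align_pair(
    a: SequenceRecord, b: SequenceRecord, mode: str = "glocal"
) -> AlignmentResult:
    """Optimal pairwise alignment of two DNA sequences.

    ``a`` is reported as the query, ``b`` as the target.  In glocal mode end
    gaps on the longer of the two are free and overhang columns are excluded
    from the identity denominator, so a contained duplicate scores over its
    own length.
    """
    if mode not in ("global", "glocal"):
        raise ValueError(f"unknown mode {mode!r}")
    long_is_target = len(b.seq) >= len(a.seq)
    aligner = _make_aligner(mode, long_is_target)
    aln = aligner.align(b.seq, a.seq)[0]  # biopython order: (target, query)
    row_t, row_q = str(aln[0]), str(aln[1])

    if mode == "glocal":
        short_row = row_q if long_is_target else row_t
        first = next(i for i, c in enumerate(short_row) if c != "-")
        last = len(short_row) - 1 - next(
            i for i, c in enumerate(reversed(short_row)) if c != "-"
        )
    else:
        first, last = 0, len(row_t) - 1

    identities = 0
    columns = 0
    for i in range(first, last + 1):
        columns += 1
        if row_t[i] == row_q[i] and row_t[i] != "-":
            identities += 1

    t_blocks, q_blocks = aln.aligned
    target_span = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    query_span = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    frac = identities / columns if columns else 0.0
    return AlignmentResult(
        query_id=a.id,
        target_id=b.id,
        identities=identities,
        aligned_columns=columns,
        percent_identity=_round1_half_up(100.0 * frac),
        identity_fraction=frac,
        query_span=query_span,
        target_span=target_span,
        score=float(aln.score),
    )


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def scan_duplications(
    seqs: Sequence[SequenceRecord],
    k: int = 12,
    min_identity: float = 90.0,
    min_len: int = 100,
) -> list[AlignmentResult]:
    """All-vs-all duplication screen.

    Pairs sharing at least one exact k-mer are aligned in glocal mode; hits
    with percent identity >= ``min_identity`` over >= ``min_len`` aligned
    columns are returned, best (identity, then length) first.  The shorter
    member of each pair is the query.
    """
    if len(seqs) < 2:
        return []
    kmer_sets = [_kmers(s.seq, k) for s in seqs]
    hits: list[AlignmentResult] = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if kmer_sets[i].isdisjoint(kmer_sets[j]):
                continue
            query, target = (
                (seqs[i], seqs[j]) if len(seqs[i]) <= len(seqs[j]) else (seqs[j], seqs[i])
            )
            res = align_pair(query, target, mode="glocal")
            if res.percent_identity >= min_identity and res.aligned_columns >= min_len:
                hits.append(res)
    hits.sort(
        key=lambda r: (-r.percent_identity, -r.aligned_columns, r.query_id, r.target_id)
    )
    return hits


def _orfs_in_frame(seq: str, offset: int) -> Iterable[tuple[int, int]]:
    """(start, end) 0-based inclusive nucleotide spans of ATG..stop ORFs."""
    open_start = None
    for pos in range(offset, len(seq) - 2, 3):
        codon = seq[pos : pos + 3]
        if codon in _STOPS:
            if open_start is not None:
                yield open_start, pos + 2
                open_start = None
        elif codon == "ATG" and open_start is None:
            open_start = pos


def longest_orf(
    s: SequenceRecord, min_aa: int = 10, both_strands: bool = False
) -> OrfResult | None:
    """Longest ATG-to-stop ORF over the three forward frames.

    The peptide length counts codons from ATG up to (not including) the stop;
    ``None`` when no ORF reaches ``min_aa`` amino acids.  With
    ``both_strands`` the reverse complement is scanned too; coordinates are
    always reported on the forward strand.  Codons containing N neither open
    nor close an ORF.
    """
    best: OrfResult | None = None
    strands = [("+", s.seq)]
    if both_strands:
        strands.append(("-", str(Seq(s.seq).reverse_complement())))
    n = len(s.seq)
    for strand, seq in strands:
        for offset in range(3):
            for start0, end0 in _orfs_in_frame(seq, offset):
                aa_len = (end0 - start0 + 1) // 3 - 1
                if aa_len < min_aa or aa_len == 0:
                    continue
                if best is not None and aa_len <= best.peptide_length:
                    continue
                peptide = str(Seq(seq[start0 : end0 - 2]).translate())
                if strand == "+":
                    start, end = start0 + 1, end0 + 1
                else:
                    start, end = n - end0, n - start0
                best = OrfResult(
                    id=s.id,
                    peptide_length=aa_len,
                    start=start,
                    end=end,
                    frame=offset + 1,
                    strand=strand,
                    peptide=peptide,
                )
    return best
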
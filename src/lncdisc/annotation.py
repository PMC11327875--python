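"""Gene annotations: GTF loading, positional lncRNA classification, PCG pairing.

Long non-coding RNAs (lncRNAs) are placed into three mutually exclusive
positional groups relative to protein-coding genes (PCGs):

* ``genic_exonic``   — the lncRNA gene span overlaps an annotated exon of a
  PCG by at least 1 bp;
* ``genic_intronic`` — the span overlaps a PCG gene body but no exon, i.e. it
  lies within an intron;
* ``intergenic``     — the span overlaps no PCG at all.

The precedence is genic_exonic > genic_intronic > intergenic, and all overlap
tests are strand-agnostic.  Each lncRNA is then paired with a single PCG:
genic lncRNAs with the overlapping PCG sharing the most nucleotides,
intergenic lncRNAs with the PCG at the smallest end-to-end gap on the same
chromosome.  Coordinates are GTF-style 1-based inclusive throughout.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: Canonical D. melanogaster chromosome arms.
CANONICAL_CHROMS = frozenset({"2L", "2R", "3L", "3R", "4", "X", "Y"})

#: Gene spans must exceed this many bp to qualify as lncRNA (strict >).
DEFAULT_MIN_LNC_SPAN = 200

_LNC_BIOTYPES = {"lncRNA", "lincRNA", "ncRNA", "antisense_RNA", "lnc_RNA"}


class LncRNAClass(str, Enum):
    """Positional class of a lncRNA relative to protein-coding genes."""

    GENIC_EXONIC = "genic_exonic"
    GENIC_INTRONIC = "genic_intronic"
    INTERGENIC = "intergenic"


@dataclass
class GeneRecord:
    """A gene with its transcript exon structures.

    ``start``/``end`` are 1-based inclusive; ``exons`` maps transcript_id to a
    list of (start, end) exon intervals.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str
    exons: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id!r}: end ({self.end}) < start ({self.start})"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def all_exons(self) -> list[tuple[int, int]]:
        out: list[tuple[int, int]] = []
        for tx_exons in self.exons.values():
            out.extend(tx_exons)
        return out


@dataclass
class AnnotationSet:
    """Filtered gene universe: PCGs plus size/chromosome-qualified lncRNAs."""

    genes: dict[str, GeneRecord]
    canonical_chroms: frozenset[str] = CANONICAL_CHROMS

    @property
    def pcgs(self) -> list[GeneRecord]:
        return [g for g in self.genes.values() if g.biotype == "protein_coding"]

    @property
    def lncrnas(self) -> list[GeneRecord]:
        return [g for g in self.genes.values() if g.biotype == "lncRNA"]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class LncRNAPair:
    """One lncRNA linked to its single partner PCG.

    ``distance_bp`` is the end-to-end gap between gene spans (0 for abutting
    or overlapping genes); ``overlap_bp`` the shared span length.  ``tie`` is
    set when another PCG achieved the same gap/overlap and the
    lexicographically smallest gene_id was chosen.
    """

    lncrna_id: str
    pcg_id: str | None
    lnc_class: LncRNAClass
    distance_bp: int
    overlap_bp: int
    tie: bool = False


def _span_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Overlap in bp of two 1-based inclusive intervals (0 if disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def _normalize_biotype(raw: str | None) -> str:
    if raw is None:
        return "other"
    if raw == "protein_coding":
        return "protein_coding"
    if raw in _LNC_BIOTYPES:
        return "lncRNA"
    return "other"


def _gtf_feature_types(path: str | Path) -> set[str]:
    types = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) > 2:
                types.add(fields[2])
    return types


def read_annotation(
    gtf_path: str | Path,
    canonical_chroms: Iterable[str] = CANONICAL_CHROMS,
    min_lnc_span: int = DEFAULT_MIN_LNC_SPAN,
    biotype_key: str | None = None,
) -> AnnotationSet:
    """Load a GTF and build the filtered gene universe.

    Protein-coding genes on canonical chromosomes are all retained; non-coding
    genes are retained as lncRNAs only when their gene span strictly exceeds
    ``min_lnc_span`` bp.  Genes on non-canonical chromosomes are discarded.
    Gene extents are reconstructed from transcript/exon rows when the file has
    no explicit ``gene`` features.

    Parameters
    ----------
    gtf_path
        Path to a GTF file with gene_id/transcript_id attributes.
    canonical_chroms
        Chromosome names to keep (without any "chr" prefix handling).
    min_lnc_span
        Strict lower bound on lncRNA gene span in bp.
    biotype_key
        Attribute carrying the biotype; by default ``gene_biotype`` then
        ``gene_type`` are tried.
    """
    gtf_path = Path(gtf_path)
    if not gtf_path.exists():
        raise FileNotFoundError(gtf_path)
    canonical = frozenset(canonical_chroms)

    text = gtf_path.read_text()
    if not any(line.strip() and not line.startswith("#") for line in text.splitlines()):
        return AnnotationSet(genes={}, canonical_chroms=canonical)

    types = _gtf_feature_types(gtf_path)
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes="gene" in types,
        disable_infer_transcripts="transcript" in types,
        verbose=False,
    )

    keys = [biotype_key] if biotype_key else ["gene_biotype", "gene_type"]

    genes: dict[str, GeneRecord] = {}
    n_noncanonical = 0
    n_short_lnc = 0
    for g in db.features_of_type("gene"):
        gene_id = g.attributes.get("gene_id", [g.id])[0]
        raw_bt = None
        for key in keys:
            if key in g.attributes:
                raw_bt = g.attributes[key][0]
                break
        biotype = _normalize_biotype(raw_bt)
        if g.end < g.start:
            raise ValueError(f"gene {gene_id!r}: end ({g.end}) < start ({g.start})")
        if g.seqid not in canonical:
            n_noncanonical += 1
            continue
        exons: dict[str, list[tuple[int, int]]] = {}
        for tx in db.children(g, featuretype="transcript"):
            tx_id = tx.attributes.get("transcript_id", [tx.id])[0]
            exons[tx_id] = [
                (e.start, e.end) for e in db.children(tx, featuretype="exon")
            ]
        rec = GeneRecord(
            gene_id=gene_id,
            chrom=g.seqid,
            start=g.start,
            end=g.end,
            strand=g.strand or ".",
            biotype=biotype,
            exons=exons,
        )
        if biotype == "lncRNA" and rec.span <= min_lnc_span:
            n_short_lnc += 1
            continue
        genes[gene_id] = rec

    logger.info(
        "read_annotation: kept %d genes (%d PCG, %d lncRNA); dropped %d "
        "non-canonical, %d short lncRNA",
        len(genes),
        sum(1 for g in genes.values() if g.biotype == "protein_coding"),
        sum(1 for g in genes.values() if g.biotype == "lncRNA"),
        n_noncanonical,
        n_short_lnc,
    )
    return AnnotationSet(genes=genes, canonical_chroms=canonical)


def _pcg_trees(ann: AnnotationSet) -> tuple[dict[str, IntervalTree], dict[str, IntervalTree]]:
    """Per-chromosome interval trees over PCG exons and PCG gene spans.

    Interval ends are +1 because intervaltree uses half-open intervals.
    """
    exon_trees: dict[str, IntervalTree] = {}
    span_trees: dict[str, IntervalTree] = {}
    for g in ann.pcgs:
        span_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
        tree = exon_trees.setdefault(g.chrom, IntervalTree())
        for (es, ee) in g.all_exons():
            tree.addi(es, ee + 1, g.gene_id)
    return exon_trees, span_trees


def classify_lncrnas(ann: AnnotationSet) -> dict[str, LncRNAClass]:
    """Assign every lncRNA its positional class.

    Overlap is evaluated on the lncRNA gene span, strand-agnostically:
    exon overlap of >=1 bp wins over gene-body overlap, which wins over no
    overlap.  Returns a map lncrna_id -> LncRNAClass covering all lncRNAs.
    """
    exon_trees, span_trees = _pcg_trees(ann)
    classes: dict[str, LncRNAClass] = {}
    for lnc in ann.lncrnas:
        q_start, q_end = lnc.start, lnc.end + 1
        if lnc.chrom in exon_trees and exon_trees[lnc.chrom].overlap(q_start, q_end):
            classes[lnc.gene_id] = LncRNAClass.GENIC_EXONIC
        elif lnc.chrom in span_trees and span_trees[lnc.chrom].overlap(q_start, q_end):
            classes[lnc.gene_id] = LncRNAClass.GENIC_INTRONIC
        else:
            classes[lnc.gene_id] = LncRNAClass.INTERGENIC
    return classes


def _gap_bp(a: GeneRecord, b: GeneRecord) -> int:
    """End-to-end gap in bp strictly between two gene spans (0 if touching)."""
    if b.start > a.end:
        return b.start - a.end - 1
    if a.start > b.end:
        return a.start - b.end - 1
    return 0


def pair_lncrnas(
    ann: AnnotationSet, classes: Mapping[str, LncRNAClass]
) -> list[LncRNAPair]:
    """Pair each lncRNA with one protein-coding gene.

    Genic lncRNAs take the overlapping PCG with the largest gene-span overlap;
    intergenic lncRNAs take the PCG minimizing the end-to-end gap on the same
    chromosome.  Orientation never enters.  Ties are broken toward the
    lexicographically smallest gene_id and flagged.  When no PCG shares the
    chromosome the pair carries ``pcg_id=None``.
    """
    for lnc in ann.lncrnas:
        if lnc.gene_id not in classes:
            raise KeyError(f"lncRNA {lnc.gene_id!r} missing from class map")

    _, span_trees = _pcg_trees(ann)
    pcg_by_chrom: dict[str, list[GeneRecord]] = {}
    for g in ann.pcgs:
        pcg_by_chrom.setdefault(g.chrom, []).append(g)
    pcg_index = {g.gene_id: g for g in ann.pcgs}
    # sorted start/end views per chromosome for nearest-gap queries
    sorted_pcgs: dict[str, tuple] = {}
    for chrom, recs in pcg_by_chrom.items():
        by_start = sorted(recs, key=lambda r: (r.start, r.gene_id))
        by_end = sorted(recs, key=lambda r: (r.end, r.gene_id))
        starts = np.array([r.start for r in by_start])
        ends = np.array([r.end for r in by_end])
        sorted_pcgs[chrom] = (by_start, starts, by_end, ends)

    pairs: list[LncRNAPair] = []
    for lnc in sorted(ann.lncrnas, key=lambda g: g.gene_id):
        cls = classes[lnc.gene_id]
        if lnc.chrom not in pcg_by_chrom:
            logger.warning(
                "lncRNA %s: no PCG on chromosome %s, pair left empty",
                lnc.gene_id,
                lnc.chrom,
            )
            pairs.append(
                LncRNAPair(lnc.gene_id, None, cls, distance_bp=0, overlap_bp=0)
            )
            continue
        if cls is LncRNAClass.INTERGENIC:
            pcg_id, dist, tie = _nearest_pcg(lnc, sorted_pcgs[lnc.chrom])
            pairs.append(
                LncRNAPair(lnc.gene_id, pcg_id, cls, distance_bp=dist,
                           overlap_bp=0, tie=tie)
            )
        else:
            hits = span_trees[lnc.chrom].overlap(lnc.start, lnc.end + 1)
            scored = sorted(
                (
                    (-_span_overlap(lnc.start, lnc.end,
                                    pcg_index[iv.data].start,
                                    pcg_index[iv.data].end), iv.data)
                    for iv in hits
                ),
            )
            best_neg_ov, best_id = scored[0]
            tie = len(scored) > 1 and scored[1][0] == best_neg_ov
            pairs.append(
                LncRNAPair(lnc.gene_id, best_id, cls, distance_bp=0,
                           overlap_bp=-best_neg_ov, tie=tie)
            )
    return pairs


def _nearest_pcg(lnc: GeneRecord, indexed: tuple) -> tuple[str, int, bool]:
    """Nearest non-overlapping PCG by end-to-end gap, via sorted arrays.

    Downstream, the gap is strictly increasing in PCG start, so only PCGs at
    the minimal start beyond the lncRNA can achieve the minimal downstream
    gap; symmetrically upstream with the maximal end.  Assumes no PCG
    overlaps the lncRNA (guaranteed for intergenic class).
    """
    by_start, starts, by_end, ends = indexed
    candidates: list[GeneRecord] = []
    i = int(np.searchsorted(starts, lnc.end, side="right"))
    if i < len(by_start):
        min_start = starts[i]
        k = i
        while k < len(by_start) and starts[k] == min_start:
            candidates.append(by_start[k])
            k += 1
    j = int(np.searchsorted(ends, lnc.start, side="left"))
    if j > 0:
        max_end = ends[j - 1]
        k = j - 1
        while k >= 0 and ends[k] == max_end:
            candidates.append(by_end[k])
            k -= 1
    best_id: str | None = None
    best_gap: int | None = None
    n_best = 0
    for g in sorted(candidates, key=lambda r: r.gene_id):
        gap = _gap_bp(lnc, g)
        if best_gap is None or gap < best_gap:
            best_id, best_gap, n_best = g.gene_id, gap, 1
        elif gap == best_gap:
            n_best += 1
    assert best_id is not None and best_gap is not None
    return best_id, max(0, best_gap), n_best > 1


def pairs_to_frame(pairs: Iterable[LncRNAPair]) -> pd.DataFrame:
    """Tabulate pairs with columns lncrna_id, pcg_id, class, distance_bp, overlap_bp, tie."""
    return pd.DataFrame(
        [
            {
                "lncrna_id": p.lncrna_id,
                "pcg_id": p.pcg_id,
                "class": p.lnc_class.value,
                "distance_bp": p.distance_bp,
                "overlap_bp": p.overlap_bp,
                "tie": p.tie,
            }
            for p in pairs
        ],
        columns=["lncrna_id", "pcg_id", "class", "distance_bp", "overlap_bp", "tie"],
    )


def write_pairs(pairs: Iterable[LncRNAPair], path: str | Path) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)
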
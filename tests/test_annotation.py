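"""Annotation loading, positional classification and PCG pairing."""

import numpy as np
import pytest

from lncdisc.annotation import (
    LncRNAClass,
    classify_lncrnas,
    pair_lncrnas,
    read_annotation,
)

from conftest import make_ann, make_gene


class TestReadAnnotation:
    def test_noncanonical_chromosomes_dropped(self, toy_gtf):
        ann = read_annotation(toy_gtf)
        assert len(ann.pcgs) == 3
        assert [g.gene_id for g in ann.lncrnas] == ["lnc1"]

    def test_span_rule_is_strict(self, toy_gtf, tmp_path):
        # lnc1 spans exactly 500 bp: excluded at min_lnc_span=500
        ann = read_annotation(toy_gtf, min_lnc_span=500)
        assert ann.lncrnas == []
        ann = read_annotation(toy_gtf, min_lnc_span=499)
        assert len(ann.lncrnas) == 1

    def test_exon_structures_loaded(self, toy_gtf):
        ann = read_annotation(toy_gtf)
        assert ann.genes["pcgA"].exons["pcgA.t1"] == [(1000, 1400), (1800, 2000)]

    def test_empty_gtf(self, tmp_path):
        p = tmp_path / "empty.gtf"
        p.write_text("")
        assert len(read_annotation(p)) == 0

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_annotation(tmp_path / "nope.gtf")

    def test_genes_reconstructed_without_gene_rows(self, tmp_path):
        p = tmp_path / "nogene.gtf"
        p.write_text(
            '2L\ts\texon\t100\t400\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t"; gene_biotype "protein_coding";\n'
            '2L\ts\texon\t800\t1000\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t"; gene_biotype "protein_coding";\n'
        )
        ann = read_annotation(p)
        assert ann.genes["g1"].start == 100 and ann.genes["g1"].end == 1000


class TestClassify:
    def test_single_bp_exon_overlap_is_exonic(self):
        pcg = make_gene("p", "2L", 1214, 1500, "protein_coding",
                        exons={"p.t": [(1214, 1500)]})
        lnc = make_gene("l", "2L", 1000, 1214, "lncRNA")
        classes = classify_lncrnas(make_ann([pcg, lnc]))
        assert classes["l"] is LncRNAClass.GENIC_EXONIC

    def test_intron_containment_is_intronic(self):
        pcg = make_gene("p", "2L", 1000, 3000, "protein_coding",
                        exons={"p.t": [(1000, 1200), (2800, 3000)]})
        lnc = make_gene("l", "2L", 1500, 2000, "lncRNA")
        classes = classify_lncrnas(make_ann([pcg, lnc]))
        assert classes["l"] is LncRNAClass.GENIC_INTRONIC

    def test_no_pcg_on_chromosome_is_intergenic(self):
        lnc = make_gene("l", "4", 100, 400, "lncRNA")
        pcg = make_gene("p", "X", 100, 900, "protein_coding")
        classes = classify_lncrnas(make_ann([pcg, lnc]))
        assert classes["l"] is LncRNAClass.INTERGENIC

    def test_exonic_precedence_over_intronic(self):
        # intronic placement relative to pcg1, but also touching pcg2's exon
        pcg1 = make_gene("p1", "2L", 1000, 3000, "protein_coding",
                         exons={"p1.t": [(1000, 1200), (2800, 3000)]})
        pcg2 = make_gene("p2", "2L", 1900, 2400, "protein_coding")
        lnc = make_gene("l", "2L", 1500, 2000, "lncRNA")
        classes = classify_lncrnas(make_ann([pcg1, pcg2, lnc]))
        assert classes["l"] is LncRNAClass.GENIC_EXONIC

    def test_strand_invariance(self):
        genes = [
            make_gene("p", "2L", 1000, 3000, "protein_coding",
                      exons={"p.t": [(1000, 1200), (2800, 3000)]}, strand="+"),
            make_gene("l", "2L", 1500, 2000, "lncRNA", strand="+"),
        ]
        flipped = [
            make_gene(g.gene_id, g.chrom, g.start, g.end, g.biotype,
                      exons=g.exons, strand="-")
            for g in genes
        ]
        assert classify_lncrnas(make_ann(genes)) == classify_lncrnas(make_ann(flipped))


class TestPairing:
    def test_intergenic_end_to_end_distance(self):
        genes = [
            make_gene("pA", "2L", 1, 1000, "protein_coding"),
            make_gene("pB", "2L", 5500, 6000, "protein_coding"),
            make_gene("l", "2L", 5000, 5200, "lncRNA"),
        ]
        ann = make_ann(genes)
        pairs = pair_lncrnas(ann, classify_lncrnas(ann))
        (p,) = pairs
        assert p.pcg_id == "pB" and p.distance_bp == 299 and not p.tie

    def test_adjacent_gene_distance_zero(self):
        genes = [
            make_gene("p", "2L", 501, 900, "protein_coding"),
            make_gene("l", "2L", 100, 500, "lncRNA"),
        ]
        ann = make_ann(genes)
        (p,) = pair_lncrnas(ann, classify_lncrnas(ann))
        assert p.distance_bp == 0 and p.overlap_bp == 0

    def test_max_overlap_wins(self):
        genes = [
            make_gene("pA", "2L", 950, 1050, "protein_coding"),   # 50 bp overlap
            make_gene("pB", "2L", 1100, 2000, "protein_coding"),  # 120 bp overlap
            make_gene("l", "2L", 1001, 1219, "lncRNA"),
        ]
        ann = make_ann(genes)
        (p,) = pair_lncrnas(ann, classify_lncrnas(ann))
        assert p.pcg_id == "pB" and p.overlap_bp == 120

    def test_equal_gap_tie_breaks_lexicographically(self):
        genes = [
            make_gene("pB", "2L", 1500, 2000, "protein_coding"),
            make_gene("pA", "2L", 100, 599, "protein_coding"),
            make_gene("l", "2L", 700, 1399, "lncRNA"),  # gap 100 both sides
        ]
        ann = make_ann(genes)
        (p,) = pair_lncrnas(ann, classify_lncrnas(ann))
        assert p.pcg_id == "pA" and p.distance_bp == 100 and p.tie

    def test_no_pcg_on_chromosome_gives_null_pair(self):
        genes = [
            make_gene("p", "X", 100, 900, "protein_coding"),
            make_gene("l", "4", 100, 400, "lncRNA"),
        ]
        ann = make_ann(genes)
        (p,) = pair_lncrnas(ann, classify_lncrnas(ann))
        assert p.pcg_id is None

    def test_missing_class_raises(self):
        genes = [make_gene("l", "4", 100, 400, "lncRNA")]
        with pytest.raises(KeyError):
            pair_lncrnas(make_ann(genes), {})


def _random_annotation(rng, max_genes=50):
    """Random gene layout for oracle comparisons (overlaps allowed)."""
    n = int(rng.integers(2, max_genes + 1))
    genes = []
    for i in range(n):
        chrom = str(rng.choice(["2L", "X"]))
        start = int(rng.integers(1, 10_000))
        end = start + int(rng.integers(250, 2_000))
        biotype = "protein_coding" if rng.random() < 0.6 else "lncRNA"
        exons = {}
        if biotype == "protein_coding":
            k = int(rng.integers(1, 4))
            cuts = sorted(rng.integers(start, end + 1, size=2 * k).tolist())
            exs = [(cuts[2 * j], cuts[2 * j + 1]) for j in range(k)]
            exs[0] = (start, exs[0][1])
            exs[-1] = (exs[-1][0], end)
            exons = {"t1": [(min(a, b), max(a, b)) for a, b in exs]}
        genes.append(
            make_gene(f"g{i:03d}", chrom, start, end, biotype, exons=exons or None)
        )
    return make_ann(genes)


def _oracle_classify(ann):
    out = {}
    for lnc in ann.lncrnas:
        hits_exon = hits_span = False
        for pcg in ann.pcgs:
            if pcg.chrom != lnc.chrom:
                continue
            if min(lnc.end, pcg.end) >= max(lnc.start, pcg.start):
                hits_span = True
            for es, ee in pcg.all_exons():
                if min(lnc.end, ee) >= max(lnc.start, es):
                    hits_exon = True
        if hits_exon:
            out[lnc.gene_id] = LncRNAClass.GENIC_EXONIC
        elif hits_span:
            out[lnc.gene_id] = LncRNAClass.GENIC_INTRONIC
        else:
            out[lnc.gene_id] = LncRNAClass.INTERGENIC
    return out


def _oracle_pair(ann, classes):
    """O(n^2) scan mirroring the pairing contract."""
    out = {}
    for lnc in ann.lncrnas:
        cls = classes[lnc.gene_id]
        cands = [p for p in ann.pcgs if p.chrom == lnc.chrom]
        if not cands:
            out[lnc.gene_id] = (None, 0, 0)
            continue
        if cls is LncRNAClass.INTERGENIC:
            best = None
            for p in sorted(cands, key=lambda g: g.gene_id):
                if p.start > lnc.end:
                    gap = p.start - lnc.end - 1
                elif lnc.start > p.end:
                    gap = lnc.start - p.end - 1
                else:
                    gap = 0
                if best is None or gap < best[1]:
                    best = (p.gene_id, gap)
            out[lnc.gene_id] = (best[0], max(0, best[1]), 0)
        else:
            best = None
            for p in sorted(cands, key=lambda g: g.gene_id):
                ov = max(0, min(lnc.end, p.end) - max(lnc.start, p.start) + 1)
                if ov > 0 and (best is None or ov > best[1]):
                    best = (p.gene_id, ov)
            out[lnc.gene_id] = (best[0], 0, best[1])
    return out


def test_pairing_matches_bruteforce_oracle_on_random_annotations():
    """Interval-index pairing equals the O(n^2) scan gene for gene."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        ann = _random_annotation(rng)
        classes = classify_lncrnas(ann)
        assert classes == _oracle_classify(ann)
        got = {
            p.lncrna_id: (p.pcg_id, p.distance_bp, p.overlap_bp)
            for p in pair_lncrnas(ann, classes)
        }
        assert got == _oracle_pair(ann, classes)


def test_every_lncrna_classified_and_counts_sum():
    rng = np.random.default_rng(7)
    for _ in range(50):
        ann = _random_annotation(rng)
        classes = classify_lncrnas(ann)
        assert set(classes) == {g.gene_id for g in ann.lncrnas}
        total = sum(
            list(classes.values()).count(c) for c in LncRNAClass
        )
        assert total == len(ann.lncrnas)


def test_injected_exon_flips_intronic_to_exonic():
    pcg = make_gene("p", "2L", 1000, 3000, "protein_coding",
                    exons={"p.t": [(1000, 1200), (2800, 3000)]})
    lnc = make_gene("l", "2L", 1500, 2000, "lncRNA")
    assert classify_lncrnas(make_ann([pcg, lnc]))["l"] is LncRNAClass.GENIC_INTRONIC
    pcg2 = make_gene("p", "2L", 1000, 3000, "protein_coding",
                     exons={"p.t": [(1000, 1200), (2800, 3000)],
                            "p.t2": [(1000, 1600)]})
    assert classify_lncrnas(make_ann([pcg2, lnc]))["l"] is LncRNAClass.GENIC_EXONIC
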
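import textwrap

import pandas as pd
import pytest

from lncdisc.annotation import AnnotationSet, GeneRecord


def make_gene(gene_id, chrom, start, end, biotype, exons=None, strand="+"):
    """GeneRecord helper; default exon structure is one exon spanning the gene."""
    if exons is None:
        exons = {f"{gene_id}.t1": [(start, end)]}
    return GeneRecord(
        gene_id=gene_id, chrom=chrom, start=start, end=end,
        strand=strand, biotype=biotype, exons=exons,
    )


def make_ann(genes):
    return AnnotationSet(genes={g.gene_id: g for g in genes})


@pytest.fixture
def toy_gtf(tmp_path):
    """Three PCGs on 2L, one 500-bp lncRNA on 2L, one lncRNA on chrU."""
    text = textwrap.dedent("""\
    2L\tsrc\tgene\t1000\t2000\t.\t+\t.\tgene_id "pcgA"; gene_biotype "protein_coding";
    2L\tsrc\ttranscript\t1000\t2000\t.\t+\t.\tgene_id "pcgA"; transcript_id "pcgA.t1"; gene_biotype "protein_coding";
    2L\tsrc\texon\t1000\t1400\t.\t+\t.\tgene_id "pcgA"; transcript_id "pcgA.t1"; gene_biotype "protein_coding";
    2L\tsrc\texon\t1800\t2000\t.\t+\t.\tgene_id "pcgA"; transcript_id "pcgA.t1"; gene_biotype "protein_coding";
    2L\tsrc\tgene\t5000\t6000\t.\t-\t.\tgene_id "pcgB"; gene_biotype "protein_coding";
    2L\tsrc\ttranscript\t5000\t6000\t.\t-\t.\tgene_id "pcgB"; transcript_id "pcgB.t1"; gene_biotype "protein_coding";
    2L\tsrc\texon\t5000\t6000\t.\t-\t.\tgene_id "pcgB"; transcript_id "pcgB.t1"; gene_biotype "protein_coding";
    2L\tsrc\tgene\t9000\t9900\t.\t+\t.\tgene_id "pcgC"; gene_biotype "protein_coding";
    2L\tsrc\ttranscript\t9000\t9900\t.\t+\t.\tgene_id "pcgC"; transcript_id "pcgC.t1"; gene_biotype "protein_coding";
    2L\tsrc\texon\t9000\t9900\t.\t+\t.\tgene_id "pcgC"; transcript_id "pcgC.t1"; gene_biotype "protein_coding";
    2L\tsrc\tgene\t3000\t3499\t.\t+\t.\tgene_id "lnc1"; gene_biotype "lncRNA";
    2L\tsrc\ttranscript\t3000\t3499\t.\t+\t.\tgene_id "lnc1"; transcript_id "lnc1.t1"; gene_biotype "lncRNA";
    2L\tsrc\texon\t3000\t3499\t.\t+\t.\tgene_id "lnc1"; transcript_id "lnc1.t1"; gene_biotype "lncRNA";
    chrU\tsrc\tgene\t100\t800\t.\t+\t.\tgene_id "lncU"; gene_biotype "lncRNA";
    chrU\tsrc\ttranscript\t100\t800\t.\t+\t.\tgene_id "lncU"; transcript_id "lncU.t1"; gene_biotype "lncRNA";
    chrU\tsrc\texon\t100\t800\t.\t+\t.\tgene_id "lncU"; transcript_id "lncU.t1"; gene_biotype "lncRNA";
    """)
    path = tmp_path / "toy.gtf"
    path.write_text(text)
    return path


@pytest.fixture
def dev_meta():
    """Sample sheet: 2 tissues x 3 stages x 2 replicates."""
    rows = []
    for tissue in ("wing", "leg"):
        for stage in ("L3", "EP", "LP"):
            for rep in (1, 2):
                rows.append(
                    {"sample_id": f"{tissue}_{stage}_r{rep}", "tissue": tissue,
                     "stage": stage, "replicate": rep, "genotype": "wt",
                     "condition": "n/a"}
                )
    return pd.DataFrame(rows).set_index("sample_id")
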
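"""Seeded synthetic data with ground truth for every pipeline stage.

The generator emulates the structure of the study design end to end:

* an annotation with non-overlapping multi-exon protein-coding genes and
  lncRNAs planted to realize a chosen genic-exonic / genic-intronic /
  intergenic mix, intergenic ones at controlled gaps;
* a development TPM matrix (3 tissues x 3 stages, 2 replicates) in which each
  lncRNA–PCG pair realizes a planted temporal category and a planted
  concordant / discordant / unrelated relation, with multiplicative lognormal
  noise on the log10 scale;
* negative-binomial count matrices for a 3-time-point regeneration course
  with matched controls (or a genotype x condition interaction design), with
  planted fold changes, per-sample size factors, and TPM derived from the
  counts through fixed gene lengths;
* transcript FASTA files with a planted near-identical duplication (a 214-bp
  query contained in a longer target with 2 substitutions) and a planted
  33-codon ORF.

Every artifact is produced from its own pseudo-random stream spawned from the
master seed, so regenerating one artifact type never perturbs another, and
identical (seed, config) inputs give byte-identical files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"

# stream indices: one RNG lineage per artifact type
_STREAM_ANNOTATION = 1
_STREAM_EXPRESSION = 2
_STREAM_COUNTS = 3
_STREAM_SEQUENCES = 4


@dataclass
class SimConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    seed: int = 0
    # annotation
    n_pcg: int = 60
    n_lnc: int = 30
    class_mix: tuple[float, float, float] = (0.3, 0.2, 0.5)  # exonic, intronic, intergenic
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"2L": 600_000, "2R": 600_000, "X": 400_000}
    )
    # development expression
    tissues: tuple[str, ...] = ("wing", "leg", "eye")
    stages: tuple[str, ...] = ("L3", "EP", "LP")
    n_reps_dev: int = 2
    n_expression_pairs: int = 1000
    tpm_log10_sd: float = 0.1
    relation_mix: tuple[float, float, float] = (0.25, 0.15, 0.60)  # conc, disc, unrel
    frac_pcg_silent: float = 0.10
    # regeneration counts
    time_points: tuple[str, ...] = ("early", "mid", "late")
    n_reps_counts: int = 3
    n_genes_counts: int = 2000
    nb_mean_range: tuple[float, float] = (100.0, 1000.0)
    nb_dispersion_range: tuple[float, float] = (0.01, 0.5)
    de_fraction: float = 0.10
    fc_grid: tuple[float, ...] = (1.7, 4.0)
    gene_length_range: tuple[int, int] = (500, 5000)
    # sequences
    n_background_seqs: int = 10
    background_len: int = 300
    dup_query_len: int = 214
    dup_target_len: int = 361
    dup_n_mismatch: int = 2
    orf_aa: int = 33

    def __post_init__(self) -> None:
        for mix in (self.class_mix, self.relation_mix):
            if any(f < 0 or f > 1 for f in mix) or abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"mix {mix} must be fractions summing to 1")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


# ---------------------------------------------------------------------------
# annotation


def _mix_counts(n: int, mix: tuple[float, ...], rng: np.random.Generator) -> list[int]:
    """Integer allocation of n items to the mix fractions (largest remainder)."""
    raw = [f * n for f in mix]
    counts = [int(np.floor(x)) for x in raw]
    rest = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in range(rest):
        counts[order[i]] += 1
    return counts


def gen_annotation(cfg: SimConfig) -> tuple[str, pd.DataFrame]:
    """Generate a GTF annotation plus its truth table.

    PCGs are laid down non-overlapping with 1–5 exons and inter-gene gaps of
    2–8 kb; lncRNAs (monoexonic) are placed to realize the configured class
    mix.  The truth table records, per lncRNA, the planted class and — via a
    brute-force scan over the placed PCGs — the intended partner PCG, gap and
    overlap.

    Returns ``(gtf_text, truth)``.
    """
    rng = cfg.rng(_STREAM_ANNOTATION)
    chroms = sorted(cfg.chrom_lengths)

    pcgs: list[dict] = []  # gene dicts with exon lists
    per_chrom: dict[str, list[dict]] = {c: [] for c in chroms}
    for i in range(cfg.n_pcg):
        chrom = chroms[i % len(chroms)]
        per_chrom[chrom].append({})
    for chrom in chroms:
        cursor = int(rng.integers(5_000, 15_000))
        for slot in per_chrom[chrom]:
            n_exons = int(rng.integers(1, 6))
            exon_lens = rng.integers(150, 600, size=n_exons)
            intron_lens = rng.integers(500, 1_500, size=max(0, n_exons - 1))
            start = cursor
            pos = start
            exons = []
            for k in range(n_exons):
                e_start = pos
                e_end = e_start + int(exon_lens[k]) - 1
                exons.append((e_start, e_end))
                pos = e_end + 1
                if k < n_exons - 1:
                    pos += int(intron_lens[k])
            end = exons[-1][1]
            if end > cfg.chrom_lengths[chrom] - 20_000:
                raise ValueError(
                    f"chromosome {chrom} too short for requested gene count"
                )
            gid = f"PCG{len(pcgs):04d}"
            slot.update(
                gene_id=gid,
                chrom=chrom,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                exons=exons,
            )
            pcgs.append(slot)
            cursor = end + 1 + int(rng.integers(2_000, 8_000))

    n_ex, n_in, n_ig = _mix_counts(cfg.n_lnc, cfg.class_mix, rng)
    lncs: list[dict] = []

    intronic_hosts = [
        g for g in pcgs
        if any(b - a - 1 >= 300 for (_, a), (b, _) in zip(g["exons"], g["exons"][1:]))
    ]
    if n_in > 0 and not intronic_hosts:
        raise ValueError("no PCG intron is wide enough for intronic lncRNAs")

    def new_lnc(chrom: str, start: int, end: int, cls: str) -> dict:
        return {
            "gene_id": f"LNC{len(lncs):04d}",
            "chrom": chrom,
            "start": start,
            "end": end,
            "strand": "+" if rng.random() < 0.5 else "-",
            "class": cls,
        }

    for _ in range(n_ex):
        g = pcgs[int(rng.integers(len(pcgs)))]
        es, ee = g["exons"][int(rng.integers(len(g["exons"])))]
        span = int(rng.integers(250, 700))
        # force >=1 bp exon overlap: start within [es - span + 1, ee]
        start = int(rng.integers(max(1, es - span + 1), ee + 1))
        lncs.append(new_lnc(g["chrom"], start, start + span - 1, "genic_exonic"))

    for _ in range(n_in):
        g = intronic_hosts[int(rng.integers(len(intronic_hosts)))]
        introns = [
            (a + 1, b - 1)
            for (_, a), (b, _) in zip(g["exons"], g["exons"][1:])
            if b - a - 1 >= 300
        ]
        i_start, i_end = introns[int(rng.integers(len(introns)))]
        width = i_end - i_start + 1
        span = int(rng.integers(201, min(700, width - 2) + 1))
        start = int(rng.integers(i_start + 1, i_end - span + 1))
        lncs.append(new_lnc(g["chrom"], start, start + span - 1, "genic_intronic"))

    # intergenic: drop into gaps between consecutive PCGs, >=1 bp clearance
    gaps: list[tuple[str, int, int]] = []
    for chrom in chroms:
        recs = sorted(
            (g for g in pcgs if g["chrom"] == chrom), key=lambda g: g["start"]
        )
        for a, b in zip(recs, recs[1:]):
            lo, hi = a["end"] + 2, b["start"] - 2
            if hi - lo + 1 >= 300:
                gaps.append((chrom, lo, hi))
    if n_ig > 0 and not gaps:
        raise ValueError("no intergenic gap wide enough for lncRNA placement")
    for _ in range(n_ig):
        chrom, lo, hi = gaps[int(rng.integers(len(gaps)))]
        width = hi - lo + 1
        span = int(rng.integers(201, min(600, width) + 1))
        start = int(rng.integers(lo, hi - span + 2))
        lncs.append(new_lnc(chrom, start, start + span - 1, "intergenic"))

    truth = pd.DataFrame(
        [_pair_truth(lnc, pcgs) for lnc in lncs],
        columns=["lncrna_id", "class", "pcg_id", "distance_bp", "overlap_bp"],
    )
    return _to_gtf(pcgs, lncs), truth


def _pair_truth(lnc: dict, pcgs: list[dict]) -> list:
    """Brute-force intended partner for one planted lncRNA."""
    same = [g for g in pcgs if g["chrom"] == lnc["chrom"]]
    best = None
    for g in same:
        ov = max(0, min(lnc["end"], g["end"]) - max(lnc["start"], g["start"]) + 1)
        if g["start"] > lnc["end"]:
            gap = g["start"] - lnc["end"] - 1
        elif lnc["start"] > g["end"]:
            gap = lnc["start"] - g["end"] - 1
        else:
            gap = 0
        key = (-ov, gap, g["gene_id"]) if ov > 0 else (0, gap, g["gene_id"])
        if best is None or key < best[0]:
            best = (key, g["gene_id"], gap, ov)
    if lnc["class"] == "intergenic":
        # nearest by gap among non-overlapping
        cand = sorted(
            (
                (max(0, g["start"] - lnc["end"] - 1, lnc["start"] - g["end"] - 1),
                 g["gene_id"])
                for g in same
            )
        )
        gap, gid = cand[0]
        return [lnc["gene_id"], lnc["class"], gid, gap, 0]
    assert best is not None
    return [lnc["gene_id"], lnc["class"], best[1], 0, best[3]]


def _to_gtf(pcgs: list[dict], lncs: list[dict]) -> str:
    lines: list[str] = []

    def row(chrom, feat, start, end, strand, attrs):
        lines.append(
            "\t".join(
                [chrom, "lncdisc_sim", feat, str(start), str(end), ".", strand, ".", attrs]
            )
        )

    for g in pcgs:
        at = f'gene_id "{g["gene_id"]}"; gene_biotype "protein_coding";'
        row(g["chrom"], "gene", g["start"], g["end"], g["strand"], at)
        tx = f'{g["gene_id"]}.t1'
        at_tx = f'gene_id "{g["gene_id"]}"; transcript_id "{tx}"; gene_biotype "protein_coding";'
        row(g["chrom"], "transcript", g["start"], g["end"], g["strand"], at_tx)
        for (es, ee) in g["exons"]:
            row(g["chrom"], "exon", es, ee, g["strand"], at_tx)
    for g in lncs:
        at = f'gene_id "{g["gene_id"]}"; gene_biotype "lncRNA";'
        row(g["chrom"], "gene", g["start"], g["end"], g["strand"], at)
        tx = f'{g["gene_id"]}.t1'
        at_tx = f'gene_id "{g["gene_id"]}"; transcript_id "{tx}"; gene_biotype "lncRNA";'
        row(g["chrom"], "transcript", g["start"], g["end"], g["strand"], at_tx)
        row(g["chrom"], "exon", g["start"], g["end"], g["strand"], at_tx)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# development expression

_CATEGORIES = ("increasing", "decreasing", "peak", "valley")
_OPPOSITE = {"increasing": "decreasing", "decreasing": "increasing",
             "peak": "valley", "valley": "peak"}
_CROSS = {
    "increasing": ("peak", "valley"),
    "decreasing": ("peak", "valley"),
    "peak": ("increasing", "decreasing"),
    "valley": ("increasing", "decreasing"),
}


def _latent_profile(cat: str, base: float, step: float, rng: np.random.Generator) -> np.ndarray:
    """A log10-TPM 3-point profile realizing the category, as shape offsets."""
    lo, mid, hi = 0.0, step, 2 * step
    if cat == "increasing":
        shape = (lo, mid, hi)
    elif cat == "decreasing":
        shape = (hi, mid, lo)
    elif cat == "peak":
        shape = (lo, hi, mid) if rng.random() < 0.5 else (mid, hi, lo)
    else:  # valley
        shape = (hi, lo, mid) if rng.random() < 0.5 else (mid, lo, hi)
    return base + np.asarray(shape)


def gen_expression(
    cfg: SimConfig, pairs: list[tuple[str, str]] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Development TPM matrix with planted pair relations.

    Per pair and tissue a relation is drawn from ``relation_mix``: concordant
    partners share the latent log10 profile shape (shifted to their own
    baseline), discordant partners get the mirrored shape, unrelated partners
    an independent cross-category profile.  A ``frac_pcg_silent`` fraction of
    PCGs is pinned below 1 TPM everywhere, forcing the unrelated call.
    Replicates multiply the latent TPM by 10^eps, eps ~ N(0, tpm_log10_sd).

    With ``pairs=None``, ``n_expression_pairs`` disjoint synthetic pairs are
    generated.  Returns ``(tpm, meta, truth)``.
    """
    rng = cfg.rng(_STREAM_EXPRESSION)
    if pairs is None:
        pairs = [(f"lnc{i:05d}", f"pcg{i:05d}") for i in range(cfg.n_expression_pairs)]

    samples = []
    for tissue in cfg.tissues:
        for stage in cfg.stages:
            for rep in range(1, cfg.n_reps_dev + 1):
                samples.append(
                    {
                        "sample_id": f"{tissue}_{stage}_r{rep}",
                        "tissue": tissue,
                        "stage": stage,
                        "replicate": rep,
                        "genotype": "wild_type",
                        "condition": "n/a",
                    }
                )
    meta = pd.DataFrame(samples)

    genes: dict[str, dict[tuple[str, str], float]] = {}  # gene -> (tissue,stage) -> log10
    gene_cats: dict[str, dict[str, str]] = {}            # gene -> tissue -> category
    unique_pcgs = list(dict.fromkeys(pcg for _, pcg in pairs))
    silent_pcgs = {
        pcg for pcg in unique_pcgs if rng.random() < cfg.frac_pcg_silent
    }

    truth_rows = []
    rel_labels = ("concordant", "discordant", "unrelated")
    for lnc_id, pcg_id in pairs:
        pcg_silent = pcg_id in silent_pcgs
        for tissue in cfg.tissues:
            base_l = rng.uniform(0.5, 1.5)
            step = rng.uniform(0.4, 0.8)
            lnc_cat = _CATEGORIES[int(rng.integers(4))]
            lnc_prof = _latent_profile(lnc_cat, base_l, step, rng)

            planted = pcg_id not in gene_cats or tissue not in gene_cats.get(pcg_id, {})
            if pcg_silent:
                relation = "unrelated"
                pcg_cat = _CATEGORIES[int(rng.integers(4))]
                pcg_prof = rng.uniform(-2.0, -1.5) + np.zeros(3)
            elif not planted:
                # PCG already profiled through an earlier pair: derive relation
                pcg_cat = gene_cats[pcg_id][tissue]
                pcg_prof = None
                if pcg_cat == lnc_cat:
                    relation = "concordant"
                elif pcg_cat == _OPPOSITE[lnc_cat]:
                    relation = "discordant"
                else:
                    relation = "unrelated"
            else:
                relation = rel_labels[
                    int(rng.choice(3, p=list(cfg.relation_mix)))
                ]
                base_p = rng.uniform(0.5, 1.5)
                if relation == "concordant":
                    pcg_cat = lnc_cat
                    pcg_prof = lnc_prof - base_l + base_p
                elif relation == "discordant":
                    pcg_cat = _OPPOSITE[lnc_cat]
                    # mirror the shape about its midpoint -> opposite category
                    pcg_prof = base_p + (2 * step) - (lnc_prof - base_l)
                else:
                    pcg_cat = _CROSS[lnc_cat][int(rng.integers(2))]
                    pcg_prof = _latent_profile(pcg_cat, base_p, step, rng)

            genes.setdefault(lnc_id, {})
            gene_cats.setdefault(lnc_id, {})[tissue] = lnc_cat
            for stage, v in zip(cfg.stages, lnc_prof):
                genes[lnc_id][(tissue, stage)] = v
            if pcg_prof is not None:
                genes.setdefault(pcg_id, {})
                gene_cats.setdefault(pcg_id, {})[tissue] = pcg_cat
                for stage, v in zip(cfg.stages, pcg_prof):
                    genes[pcg_id][(tissue, stage)] = v
            truth_rows.append(
                {
                    "lncrna_id": lnc_id,
                    "pcg_id": pcg_id,
                    "tissue": tissue,
                    "lnc_category": lnc_cat,
                    "pcg_category": pcg_cat,
                    "relation": relation,
                    "pcg_silent": pcg_silent,
                    "planted": planted,
                }
            )

    gene_ids = sorted(genes)
    col_keys = list(zip(meta["tissue"], meta["stage"]))
    latent = np.array([[genes[g][key] for key in col_keys] for g in gene_ids])
    noise = rng.normal(0.0, cfg.tpm_log10_sd, size=latent.shape)
    tpm = pd.DataFrame(
        np.power(10.0, latent + noise),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=meta["sample_id"],
    )
    truth = pd.DataFrame(truth_rows)
    return tpm, meta, truth


# ---------------------------------------------------------------------------
# regeneration counts


def gen_counts(cfg: SimConfig, design: str = "timecourse") -> tuple[
    pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame
]:
    """NB count matrix with planted fold changes, plus derived TPM and truth.

    ``design="timecourse"``: per time point, matched control and regeneration
    groups (``n_reps_counts`` each); a ``de_fraction`` of genes per time
    point shifts its regeneration mean by a fold change off ``fc_grid`` in a
    random direction.  ``design="interaction"``: genotype (control/mutant) x
    condition cells; planted genes shift only the mutant-regeneration cell.
    TPM is computed from the counts with fixed per-gene lengths.

    Returns ``(counts, tpm, meta, truth)``.
    """
    if design not in ("timecourse", "interaction"):
        raise ValueError(f"unknown design {design!r}")
    rng = cfg.rng(_STREAM_COUNTS)
    n = cfg.n_genes_counts
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")
    lo, hi = cfg.nb_mean_range
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    dlo, dhi = cfg.nb_dispersion_range
    dispersion = np.exp(rng.uniform(np.log(dlo), np.log(dhi), size=n))
    lengths = rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1, size=n)

    samples = []
    if design == "timecourse":
        for tp in cfg.time_points:
            for cond in ("control", "regeneration"):
                for rep in range(1, cfg.n_reps_counts + 1):
                    samples.append(
                        {
                            "sample_id": f"{tp}_{cond}_r{rep}",
                            "time_point": tp,
                            "condition": cond,
                            "replicate": rep,
                            "genotype": "wild_type",
                            "tissue": "wing",
                            "stage": "n/a",
                        }
                    )
    else:
        for geno in ("control", "mutant"):
            for cond in ("non_regeneration", "regeneration"):
                for rep in range(1, cfg.n_reps_counts + 1):
                    samples.append(
                        {
                            "sample_id": f"{geno}_{cond}_r{rep}",
                            "time_point": "n/a",
                            "condition": cond,
                            "replicate": rep,
                            "genotype": geno,
                            "tissue": "wing",
                            "stage": "n/a",
                        }
                    )
    meta = pd.DataFrame(samples)
    n_samples = len(meta)
    size_factors = np.power(2.0, rng.uniform(-0.5, 0.5, size=n_samples))

    # planted effects
    truth_rows = []
    effect = np.ones((n, n_samples))
    if design == "timecourse":
        for tp in cfg.time_points:
            de_mask = rng.random(n) < cfg.de_fraction
            fcs = np.asarray(cfg.fc_grid)[rng.integers(len(cfg.fc_grid), size=n)]
            up = rng.random(n) < 0.5
            log2fc = np.where(de_mask, np.where(up, 1, -1) * np.log2(fcs), 0.0)
            cols = meta.index[
                (meta["time_point"] == tp) & (meta["condition"] == "regeneration")
            ]
            effect[:, cols] *= np.power(2.0, log2fc)[:, None]
            for i in range(n):
                truth_rows.append(
                    {
                        "gene_id": gene_ids[i],
                        "time_point": tp,
                        "is_de": bool(de_mask[i]),
                        "true_log2fc": float(log2fc[i]),
                        "direction": "up" if log2fc[i] > 0 else
                                     ("down" if log2fc[i] < 0 else "none"),
                    }
                )
    else:
        de_mask = rng.random(n) < cfg.de_fraction
        fcs = np.asarray(cfg.fc_grid)[rng.integers(len(cfg.fc_grid), size=n)]
        up = rng.random(n) < 0.5
        log2fc = np.where(de_mask, np.where(up, 1, -1) * np.log2(fcs), 0.0)
        cols = meta.index[
            (meta["genotype"] == "mutant") & (meta["condition"] == "regeneration")
        ]
        effect[:, cols] *= np.power(2.0, log2fc)[:, None]
        for i in range(n):
            truth_rows.append(
                {
                    "gene_id": gene_ids[i],
                    "time_point": "interaction",
                    "is_de": bool(de_mask[i]),
                    "true_log2fc": float(log2fc[i]),
                    "direction": "up" if log2fc[i] > 0 else
                                 ("down" if log2fc[i] < 0 else "none"),
                }
            )

    mu = base_mean[:, None] * effect * size_factors[None, :]
    # NB parameterization: variance = mu + dispersion * mu^2
    r = 1.0 / dispersion
    p = r[:, None] / (r[:, None] + mu)
    counts = rng.negative_binomial(r[:, None], p)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=meta["sample_id"])

    rate = counts / lengths[:, None]
    tpm = rate / rate.sum(axis=0, keepdims=True) * 1e6
    tpm_df = pd.DataFrame(tpm, index=gene_ids, columns=meta["sample_id"])
    meta = meta.assign(true_size_factor=size_factors)
    truth = pd.DataFrame(truth_rows)
    return counts_df, tpm_df, meta, truth


# ---------------------------------------------------------------------------
# sequences


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(4, size=n))


def _naive_longest_orf_aa(seq: str) -> int:
    """Independent ORF check used for rejection sampling: for every ATG,
    walk in-frame codons to the first stop; longest peptide in aa."""
    best = 0
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i
        while j + 3 <= len(seq):
            if seq[j : j + 3] in _STOPS:
                best = max(best, (j - i) // 3)
                break
            j += 3
    return best


def _orf_cassette(rng: np.random.Generator, n_aa: int) -> str:
    """ATG + (n_aa - 1) non-stop, non-ATG codons + stop."""
    codons = []
    while len(codons) < n_aa - 1:
        c = _random_dna(rng, 3)
        if c not in _STOPS and c != "ATG":
            codons.append(c)
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
    return "ATG" + "".join(codons) + stop


def gen_sequences(cfg: SimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """FASTA records with a planted contained duplication and a planted ORF.

    A ``dup_query_len``-bp query carrying one ORF of exactly ``orf_aa`` amino
    acids is embedded in a ``dup_target_len``-bp target with
    ``dup_n_mismatch`` substitutions placed outside the ORF, so both copies
    keep the peptide.  Background sequences are plain random DNA.  Rejection
    sampling guarantees the query's longest ORF is exactly ``orf_aa``.

    Returns ``(records, truth)`` with records an ordered id -> sequence map.
    """
    rng = cfg.rng(_STREAM_SEQUENCES)
    qlen, tlen, m = cfg.dup_query_len, cfg.dup_target_len, cfg.dup_n_mismatch
    orf_nt = 3 * (cfg.orf_aa + 1)
    if orf_nt + 10 > qlen:
        raise ValueError("query too short for the requested ORF")

    # build query until its longest ORF is exactly orf_aa
    while True:
        cassette = _orf_cassette(rng, cfg.orf_aa)
        orf_start = int(rng.integers(0, qlen - orf_nt + 1))
        prefix = _random_dna(rng, orf_start)
        suffix = _random_dna(rng, qlen - orf_start - orf_nt)
        query = prefix + cassette + suffix
        if _naive_longest_orf_aa(query) == cfg.orf_aa:
            break

    copy = list(query)
    # substitutions sit outside the ORF and away from the copy edges, so the
    # optimal glocal alignment is the ungapped containment (an edge-adjacent
    # mismatch can tie with a gapped variant that borrows a flank base)
    non_orf = [
        i for i in range(15, qlen - 15)
        if not (orf_start <= i < orf_start + orf_nt)
    ]
    mism_pos = sorted(rng.choice(non_orf, size=m, replace=False).tolist())
    for i in mism_pos:
        copy[i] = rng.permutation([b for b in _BASES if b != copy[i]])[0]
    # flanks are rejection-sampled so no chimeric ORF outgrows the planted one
    while True:
        insert_at = int(rng.integers(0, tlen - qlen + 1))
        target = (
            _random_dna(rng, insert_at)
            + "".join(copy)
            + _random_dna(rng, tlen - insert_at - qlen)
        )
        if _naive_longest_orf_aa(target) == cfg.orf_aa:
            break

    records: dict[str, str] = {"dup_query": query, "dup_target": target}
    for i in range(cfg.n_background_seqs):
        records[f"bg{i:03d}"] = _random_dna(rng, cfg.background_len)

    truth = pd.DataFrame(
        [
            {
                "query_id": "dup_query",
                "target_id": "dup_target",
                "identities": qlen - m,
                "aligned_columns": qlen,
                "percent_identity": round(100.0 * (qlen - m) / qlen, 1),
                "orf_aa": cfg.orf_aa,
                "orf_start": orf_start + 1,
                "orf_end": orf_start + orf_nt,
            }
        ]
    )
    return records, truth


def write_fasta(records: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# presets

PRESETS = ("development", "regeneration", "mutant", "sequences")


def simulate(preset: str, seed: int, outdir: str | Path, cfg: SimConfig | None = None) -> Path:
    """Write one preset's files (data + truth + resolved config) to a directory."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.replace(cfg or SimConfig(), seed=seed)

    if preset == "development":
        gtf, ann_truth = gen_annotation(cfg)
        (out / "annotation.gtf").write_text(gtf)
        ann_truth.to_csv(out / "truth_annotation.tsv", sep="\t", index=False)
        pairs = list(
            ann_truth[["lncrna_id", "pcg_id"]].itertuples(index=False, name=None)
        )
        tpm, meta, truth = gen_expression(cfg, pairs=pairs)
        tpm.to_csv(out / "tpm.tsv", sep="\t")
        meta.to_csv(out / "samples.tsv", sep="\t", index=False)
        truth.to_csv(out / "truth_expression.tsv", sep="\t", index=False)
    elif preset in ("regeneration", "mutant"):
        design = "timecourse" if preset == "regeneration" else "interaction"
        counts, tpm, meta, truth = gen_counts(cfg, design=design)
        counts.to_csv(out / "counts.tsv", sep="\t")
        tpm.to_csv(out / "tpm.tsv", sep="\t", float_format="%.6f")
        meta.to_csv(out / "samples.tsv", sep="\t", index=False)
        truth.to_csv(out / "truth_de.tsv", sep="\t", index=False)
    else:
        records, truth = gen_sequences(cfg)
        write_fasta(records, out / "transcripts.fa")
        truth.to_csv(out / "truth_sequences.tsv", sep="\t", index=False)

    resolved = dataclasses.asdict(cfg)
    resolved["preset"] = preset
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)
    return out
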
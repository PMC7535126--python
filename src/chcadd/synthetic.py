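"""Synthetic genomes, populations and annotation tables with planted truth.

Everything the pipeline consumes can be generated here at toy scale: a
reference/ancestor genome pair diverging at a controlled per-window rate, a
diploid population whose allele frequencies follow a discretized neutral
1/i site-frequency spectrum (with an exponential down-weighting of
high-frequency derived mass inside constrained regions, the minimal model of
purifying selection on allele frequencies), deterministic gene models,
conserved elements with an optionally planted high-scoring inner subregion,
and an annotation table generated from a planted logistic model so the
trained classifier has a known target.  Regeneration with the same seed is
bit-identical, and truth files carry everything recovery tests need.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .changepoint import ScoredElement, DEFAULT_FLANK
from .io_formats import (
    GenomeInterval,
    PopulationVariantRecord,
    write_genome,
    write_intervals,
    write_vcf,
)

BASES = "ACGT"


@dataclass
class WorldConfig:
    """Study conditions for the synthetic world.

    The defaults are a 1 Mb single-chromosome genome with 50 diploid
    samples; reference/ancestor divergence 0.02 with 100 kb rate windows;
    neutral segregating-site density 0.02 per bp suppressed 2-fold inside
    constrained regions (mirroring the observed 0.02 vs 0.01 density
    contrast); and a DAF spectrum decay parameter gamma = 3 inside
    constrained regions.
    """

    chrom: str = "chr1"
    genome_length: int = 1_000_000
    window_size: int = 100_000
    substitution_rate: float = 0.02
    rate_multiplier_range: tuple[float, float] = (0.5, 2.0)
    n_samples: int = 50
    neutral_snp_rate: float = 0.02
    constrained_fraction: float = 0.20
    suppression_factor: float = 2.0
    daf_gamma: float = 3.0
    n_genes: int = 8
    n_elements: int = 120
    element_length: int = 60
    planted_subregion_fraction: float = 0.5
    signal_background: float = 5.0
    signal_step_height: float = 10.0
    signal_noise_sd: float = 1.0
    n_annotation_rows: int = 4_000
    annotation_effects: tuple[float, ...] = (1.5, -1.0, 0.8)

    def __post_init__(self) -> None:
        if not 0.0 <= self.constrained_fraction <= 1.0:
            raise ValueError("constrained_fraction must be in [0, 1]")
        if self.suppression_factor < 1.0:
            raise ValueError("suppression_factor must be >= 1")
        if self.genome_length <= 0 or self.n_samples <= 0:
            raise ValueError("inconsistent config")


@dataclass
class SyntheticWorld:
    config: WorldConfig
    seed: int
    reference: dict[str, str]
    ancestor: dict[str, str]
    population: list[PopulationVariantRecord]
    constrained_regions: list[GenomeInterval]
    neutral_regions: list[GenomeInterval]
    gene_models_gff: list[str]
    elements: list[GenomeInterval]
    gaps: list[GenomeInterval]
    repeat_mask: list[GenomeInterval]
    score_track: np.ndarray
    annotation_table: pd.DataFrame
    annotation_labels: np.ndarray
    truth: dict = field(default_factory=dict)
    paths: dict[str, Path] = field(default_factory=dict)


def _sfs_copy_counts(rng, n_sites: int, n_chrom: int, gamma: float) -> np.ndarray:
    """Derived-allele copy counts drawn from a discretized 1/i spectrum with
    exp(-gamma*i/n_chrom) down-weighting (gamma=0 is neutral)."""
    i = np.arange(1, n_chrom)
    w = (1.0 / i) * np.exp(-gamma * i / n_chrom)
    w /= w.sum()
    return rng.choice(i, size=n_sites, p=w)


def _tile_constrained(cfg: WorldConfig) -> tuple[list[GenomeInterval], list[GenomeInterval]]:
    """Deterministic alternating layout: one constrained block per 50 kb
    tile, sized to hit the configured fraction."""
    tile = 50_000
    block = int(tile * cfg.constrained_fraction)
    constrained, neutral = [], []
    for start in range(0, cfg.genome_length, tile):
        end = min(start + tile, cfg.genome_length)
        b_end = min(start + block, end)
        if block > 0 and b_end > start:
            constrained.append(GenomeInterval(cfg.chrom, start, b_end))
        if end > b_end:
            neutral.append(GenomeInterval(cfg.chrom, b_end, end))
    return constrained, neutral


def _in_any(pos0: int, regions: list[GenomeInterval]) -> bool:
    return any(r.start <= pos0 < r.end for r in regions)


def _make_gene_gff(cfg: WorldConfig) -> tuple[list[str], list[dict]]:
    """Deterministic gene models: evenly spaced genes, alternating strand,
    with 5'UTR / CDS / intron / CDS / 3'UTR structure, plus a few lncRNA
    and RNA-gene records."""
    lines = ["##gff-version 3"]
    genes = []
    spacing = cfg.genome_length // (cfg.n_genes + 1)
    for k in range(cfg.n_genes):
        start = spacing * (k + 1)  # 0-based
        strand = "+" if k % 2 == 0 else "-"
        utr5, cds1, intron, cds2, utr3 = 100, 300, 400, 300, 150
        length = utr5 + cds1 + intron + cds2 + utr3
        end = start + length
        if end >= cfg.genome_length:
            continue
        gid = f"gene{k}"
        s1, e1 = start + 1, end  # GFF3 1-based closed
        lines.append(f"{cfg.chrom}\t.\tgene\t{s1}\t{e1}\t.\t{strand}\t.\tID={gid}")
        if strand == "+":
            parts = [("five_prime_UTR", start, start + utr5),
                     ("CDS", start + utr5, start + utr5 + cds1),
                     ("CDS", start + utr5 + cds1 + intron,
                      start + utr5 + cds1 + intron + cds2),
                     ("three_prime_UTR", end - utr3, end)]
        else:
            parts = [("three_prime_UTR", start, start + utr3),
                     ("CDS", start + utr3, start + utr3 + cds2),
                     ("CDS", start + utr3 + cds2 + intron,
                      start + utr3 + cds2 + intron + cds1),
                     ("five_prime_UTR", end - utr5, end)]
        for typ, s, e in parts:
            lines.append(f"{cfg.chrom}\t.\t{typ}\t{s + 1}\t{e}\t.\t{strand}\t."
                         f"\tParent={gid}")
        genes.append({"name": gid, "start": start, "end": end,
                      "strand": strand, "utr5": utr5})
    # two lncRNAs and one RNA gene in gene-free territory
    for j, (typ, s) in enumerate([("lnc_RNA", spacing // 3),
                                  ("lnc_RNA", spacing // 2),
                                  ("ncRNA", 2 * spacing // 3)]):
        e = s + 500
        lines.append(f"{cfg.chrom}\t.\t{typ}\t{s + 1}\t{e}\t.\t+\t.\tID=rna{j}")
    return lines, genes


def make_world(config: WorldConfig | None = None, seed: int = 0,
               outdir: str | Path | None = None) -> SyntheticWorld:
    """Generate the full synthetic world; write files when ``outdir`` given.

    Emits reference/ancestor FASTA, population VCF, gene-model GFF3, BEDs
    for conserved elements, assembly gaps, repeat mask and constrained
    regions, a per-base score bedGraph, an annotation TSV, and a JSON truth
    file (planted change points, constrained coordinates, planted logistic
    coefficients, all seeds).
    """
    cfg = config or WorldConfig()
    rng = np.random.default_rng(seed)
    L, chrom = cfg.genome_length, cfg.chrom

    ref_arr = rng.integers(0, 4, size=L)
    reference = {chrom: "".join(BASES[b] for b in ref_arr)}

    # ancestor: per-window multiplier on the base divergence rate
    anc_arr = ref_arr.copy()
    lo, hi = cfg.rate_multiplier_range
    n_windows = (L + cfg.window_size - 1) // cfg.window_size
    multipliers = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_windows))
    for w in range(n_windows):
        a, b = w * cfg.window_size, min((w + 1) * cfg.window_size, L)
        rate = min(1.0, cfg.substitution_rate * multipliers[w])
        hit = np.flatnonzero(rng.random(b - a) < rate) + a
        anc_arr[hit] = (anc_arr[hit] + rng.integers(1, 4, size=hit.size)) % 4
    ancestor = {chrom: "".join(BASES[b] for b in anc_arr)}

    constrained, neutral = _tile_constrained(cfg)

    # population: segregating sites only where reference == ancestor
    same = ref_arr == anc_arr
    n_chrom = 2 * cfg.n_samples
    rate_per_base = np.full(L, cfg.neutral_snp_rate)
    for r in constrained:
        rate_per_base[r.start : r.end] = cfg.neutral_snp_rate / cfg.suppression_factor
    seg_pos = np.flatnonzero((rng.random(L) < rate_per_base) & same)
    in_constrained = np.zeros(L, dtype=bool)
    for r in constrained:
        in_constrained[r.start : r.end] = True
    counts = np.empty(seg_pos.size, dtype=int)
    cons_sites = in_constrained[seg_pos]
    counts[~cons_sites] = _sfs_copy_counts(rng, int((~cons_sites).sum()),
                                           n_chrom, 0.0)
    counts[cons_sites] = _sfs_copy_counts(rng, int(cons_sites.sum()),
                                          n_chrom, cfg.daf_gamma)
    population = []
    for pos0, c in zip(seg_pos, counts):
        ref_base = BASES[ref_arr[pos0]]
        alt_base = BASES[(ref_arr[pos0] + rng.integers(1, 4)) % 4]
        alleles = np.zeros(n_chrom, dtype=int)
        alleles[rng.choice(n_chrom, size=c, replace=False)] = 1
        gts = [(int(alleles[2 * i]), int(alleles[2 * i + 1]))
               for i in range(cfg.n_samples)]
        population.append(PopulationVariantRecord(
            chrom=chrom, pos=int(pos0) + 1, ref=ref_base, alts=[alt_base],
            qual=60.0, genotypes=gts))

    gff_lines, gene_dicts = _make_gene_gff(cfg)

    # conserved elements inside constrained blocks; planted inner subregions
    elements, planted = [], []
    score_track = cfg.signal_background + rng.normal(
        0.0, cfg.signal_noise_sd, size=L)
    blocks = constrained if constrained else neutral
    for k in range(cfg.n_elements):
        block = blocks[k % len(blocks)]
        slot = (k // len(blocks)) * (cfg.element_length + 40) + 10
        start = block.start + slot
        end = start + cfg.element_length
        if end + DEFAULT_FLANK >= block.end or end >= L:
            continue
        el = GenomeInterval(chrom, start, end)
        elements.append(el)
        if rng.random() < cfg.planted_subregion_fraction:
            third = cfg.element_length // 3
            inner_lo, inner_hi = start + third, end - third
            score_track[inner_lo:inner_hi] += cfg.signal_step_height
            planted.append({"start": start, "end": end,
                            "inner_start": inner_lo, "inner_end": inner_hi})

    gaps = [GenomeInterval(chrom, L // 2, L // 2 + 2_000)]
    repeat_mask = [GenomeInterval(chrom, L // 4, L // 4 + 1_000)]

    # annotation table from a planted logistic model
    n_rows = cfg.n_annotation_rows
    beta = np.asarray(cfg.annotation_effects, dtype=float)
    conservation = rng.normal(0.0, 1.0, n_rows)
    tss_distance = rng.exponential(5_000.0, n_rows)
    gc_content = rng.beta(5, 5, n_rows)
    logit = (beta[0] * conservation
             + beta[1] * (tss_distance / 5_000.0)
             + beta[2] * (gc_content - 0.5) * 4.0)
    labels = (rng.random(n_rows) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
    consequence = rng.choice(["intergenic", "intronic", "missense", "synonymous"],
                             size=n_rows, p=[0.5, 0.3, 0.1, 0.1])
    substitution = np.where(consequence == "missense",
                            rng.normal(2.0, 1.0, n_rows), np.nan)
    ann = pd.DataFrame({
        "conservation": conservation,
        "consequence": consequence,
        "tss_distance": tss_distance,
        "gc_content": gc_content,
        "substitution_score": substitution,
    })

    truth = {
        "seed": seed,
        "config": {k: v for k, v in asdict(cfg).items()},
        "constrained_regions": [[r.start, r.end] for r in constrained],
        "window_multipliers": multipliers.tolist(),
        "planted_elements": planted,
        "annotation_effects": list(cfg.annotation_effects),
        "genes": gene_dicts,
    }

    world = SyntheticWorld(
        config=cfg, seed=seed, reference=reference, ancestor=ancestor,
        population=population, constrained_regions=constrained,
        neutral_regions=neutral, gene_models_gff=gff_lines,
        elements=elements, gaps=gaps, repeat_mask=repeat_mask,
        score_track=score_track, annotation_table=ann,
        annotation_labels=labels, truth=truth,
    )
    if outdir is not None:
        _write_world(world, Path(outdir))
    return world


def _write_world(world: SyntheticWorld, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = world.config
    p = world.paths
    p["reference"] = outdir / "reference.fa"
    p["ancestor"] = outdir / "ancestor.fa"
    write_genome(p["reference"], world.reference)
    write_genome(p["ancestor"], world.ancestor)
    p["vcf"] = outdir / "population.vcf"
    write_vcf(p["vcf"], world.population,
              contigs={cfg.chrom: cfg.genome_length})
    p["gff"] = outdir / "genes.gff3"
    p["gff"].write_text("\n".join(world.gene_models_gff) + "\n")
    for key, ivs in [("elements", world.elements), ("gaps", world.gaps),
                     ("repeat_mask", world.repeat_mask),
                     ("constrained", world.constrained_regions)]:
        p[key] = outdir / f"{key}.bed"
        write_intervals(p[key], ivs, format="bed")
    p["scores"] = outdir / "scores.bedgraph"
    with open(p["scores"], "w") as fh:
        fh.write("#chrom\tstart\tend\tscore\n")
        for i, s in enumerate(world.score_track):
            fh.write(f"{cfg.chrom}\t{i}\t{i + 1}\t{s:.4f}\n")
    p["annotations"] = outdir / "annotations.tsv"
    tab = world.annotation_table.copy()
    tab["label"] = world.annotation_labels
    tab.to_csv(p["annotations"], sep="\t", index=False)
    p["truth"] = outdir / "truth.json"
    p["truth"].write_text(json.dumps(world.truth, indent=1))


def make_step_signals(
    n: int,
    lengths: int = 60,
    step_heights: float = 10.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    flank: int = DEFAULT_FLANK,
    background: float = 0.0,
) -> tuple[list[ScoredElement], list[tuple[int, int]]]:
    """Piecewise-constant flanked signals with two planted change points.

    Each element of length ``lengths`` (>= 15) gets change points drawn
    uniformly in the middle portion of the flanked signal, an inner segment
    elevated by ``step_heights``, Gaussian noise, and ``flank``-bp flanks at
    background level.  Returns the elements and the planted (cp1, cp2)
    offsets on the flanked coordinate system.
    """
    if lengths < 15:
        raise ValueError("element length must be >= 15")
    rng = np.random.default_rng(seed)
    elements, truth = [], []
    T = lengths + 2 * flank
    for k in range(n):
        cp1 = int(rng.integers(flank + 2, T // 2 - 2))
        cp2 = int(rng.integers(T // 2 + 2, T - flank - 2))
        signal = np.full(T, background, dtype=float)
        signal[cp1:cp2] += step_heights
        signal += rng.normal(0.0, noise_sd, size=T)
        iv = GenomeInterval("synthetic", 1_000 * k + flank,
                            1_000 * k + flank + lengths)
        elements.append(ScoredElement(iv, signal, flank_left=flank,
                                      flank_right=flank))
        truth.append((cp1, cp2))
    return elements, truth
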
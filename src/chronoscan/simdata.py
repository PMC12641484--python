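"""Synthetic pooled-sequencing studies with known ground truth.

The generator emulates the sampling structure of a pool-seq experiment on
equimolar DNA pools: per site, each pool's allele frequency is obtained by
binomially sampling Z = 2 x pool_individuals chromosomes from its
population frequency, read depth is Poisson around the study's mean depth,
reads are binomial draws from the pool frequency, and each read may be
flipped to a uniformly random other nucleotide by sequencing error.
Differentiated regions are planted by shifting the designated pool pair's
population frequencies apart by a chosen allele-frequency difference, and
a gene annotation is generated in which genes near planted regions carry
an enriched functional term — so planted regions, outlier windows,
candidate genes and the enriched term can all be validated downstream.

Simulation is biallelic (one reference, one alternate allele per site);
sequencing error re-introduces third alleles at rate 2/3 x error_rate per
base, which the downstream biallelic reduction removes again — as the real
analysis does.

All randomness derives from a single seed through named per-stage
substreams (frequencies, read counts, annotation), so every intermediate
is individually reproducible and byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from chronoscan.syncio import (
    NUCLEOTIDES,
    GeneFeature,
    SyncRecord,
    write_sync,
)

#: For each nucleotide index, the indices of the other three (error targets).
_OTHERS = np.array([[j for j in range(4) if j != i] for i in range(4)])


@dataclass(frozen=True)
class PlantedRegion:
    """A genomic interval where one pool pair's frequencies are pushed
    apart by ``delta_afd`` (1-based closed coordinates)."""

    scaffold: str
    start: int
    end: int
    delta_afd: float
    pool_pair: tuple[int, int] = (0, 1)


@dataclass(frozen=True)
class SimConfig:
    """Study design of a synthetic pool-seq experiment.

    Defaults mirror the real study's design: pools of 9 diploid
    individuals (Z = 18 chromosomes per pool), mean filtered depth 22.4x
    per pool, and a SNP density of ~1 polymorphic site per 100 bp (the
    genome-wide density implied by ~14.4M sites on a ~1.2 Gb passerine
    genome). Ancestral frequencies are uniform on
    [background_freq_low, background_freq_high]; the real spectrum is
    unknown, so this is a modeling choice, not an inference.
    """

    n_scaffolds: int = 5
    scaffold_length_bp: int = 100_000
    snp_density: float = 0.01
    n_pools: int = 2
    pool_individuals: int = 9
    depth_mean: float = 22.4
    error_rate: float = 0.001
    background_freq_low: float = 0.1
    background_freq_high: float = 0.9
    planted_regions: tuple[PlantedRegion, ...] = ()
    planted_term: str = "GO:0004806"
    n_genes: int = 100
    near_flank: int = 25_000
    near_term_prob: float = 0.5
    background_term_prob: float = 0.02
    n_background_terms: int = 20
    background_term_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if not 0.0 < self.snp_density <= 1.0:
            raise ValueError("snp_density must be in (0, 1]")
        if self.n_pools < 2:
            raise ValueError("need at least 2 pools")
        if self.background_freq_low >= self.background_freq_high:
            raise ValueError("background_freq_low must be < background_freq_high")
        span = self.background_freq_high - self.background_freq_low
        for region in self.planted_regions:
            if not 0.0 < region.delta_afd <= span + 1e-12:
                raise ValueError(
                    f"planted region {region.scaffold}:{region.start}-"
                    f"{region.end}: delta_afd must be in (0, {span:.3g}]"
                )
            if region.scaffold not in self.scaffold_names:
                raise ValueError(
                    f"planted region scaffold {region.scaffold!r} is not "
                    f"one of the simulated scaffolds"
                )
            if not 0 < region.start < region.end <= self.scaffold_length_bp:
                raise ValueError(
                    f"planted region {region.scaffold}:{region.start}-"
                    f"{region.end} outside scaffold bounds "
                    f"(length {self.scaffold_length_bp})"
                )
            for pool in region.pool_pair:
                if not 0 <= pool < self.n_pools:
                    raise ValueError(
                        f"planted region pool index {pool} out of range"
                    )

    @property
    def haploid_size(self) -> int:
        """Chromosomes per pool: Z = 2 x diploid individuals."""
        return 2 * self.pool_individuals

    @property
    def scaffold_names(self) -> tuple[str, ...]:
        return tuple(f"scaffold_{i + 1}" for i in range(self.n_scaffolds))


@dataclass
class SimTruth:
    """Planted ground truth: per-site population frequencies per pool
    (columns ``q_pool0``..) with ancestral frequency and planted flag, and
    (after :func:`simulate_annotation`) the gene table with near-planted
    flags and assigned terms."""

    sites: pd.DataFrame
    genes: pd.DataFrame | None = None


def _stage_rng(config: SimConfig, stage: str) -> np.random.Generator:
    """Named substream of the study seed, independent per stage."""
    stage_key = {"frequencies": 0, "counts": 1, "annotation": 2}[stage]
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stage_key,))
    )


def simulate_site_frequencies(config: SimConfig) -> SimTruth:
    """Draw polymorphic sites and per-pool population frequencies.

    Positions are polymorphic independently with probability
    ``snp_density``; each gets an ancestral alternate-allele frequency
    q ~ Uniform(background_freq_low, background_freq_high) shared by all
    pools. Inside a planted region the designated pool pair is moved to
    q +/- delta_afd/2, clipped to [0.01, 0.99] to keep sites polymorphic.
    """
    rng = _stage_rng(config, "frequencies")
    frames = []
    for scaffold in config.scaffold_names:
        mask = rng.random(config.scaffold_length_bp) < config.snp_density
        positions = np.flatnonzero(mask) + 1  # 1-based
        q_anc = rng.uniform(
            config.background_freq_low,
            config.background_freq_high,
            size=positions.size,
        )
        q_pools = np.tile(q_anc[:, None], (1, config.n_pools))
        planted = np.zeros(positions.size, dtype=bool)
        for region in config.planted_regions:
            if region.scaffold != scaffold:
                continue
            inside = (positions >= region.start) & (positions <= region.end)
            planted |= inside
            a, b = region.pool_pair
            half = region.delta_afd / 2.0
            q_pools[inside, a] = np.clip(q_anc[inside] + half, 0.01, 0.99)
            q_pools[inside, b] = np.clip(q_anc[inside] - half, 0.01, 0.99)
        frame = pd.DataFrame({"scaffold": scaffold, "position": positions})
        frame["q_anc"] = q_anc
        for j in range(config.n_pools):
            frame[f"q_pool{j}"] = q_pools[:, j]
        frame["planted"] = planted
        frames.append(frame)
    sites = pd.concat(frames, ignore_index=True)
    return SimTruth(sites=sites)


def simulate_pool_counts(truth: SimTruth, config: SimConfig) -> list[SyncRecord]:
    """Two-stage sampling of read counts from planted frequencies.

    Per site and pool: chromosomes k ~ Binomial(Z, q) give the pool
    frequency g = k/Z; depth d ~ Poisson(depth_mean); alternate reads
    ~ Binomial(d, g); each read flips to a uniformly random other
    nucleotide with probability error_rate. Counts are emitted in the sync
    A:T:C:G:N:del layout (N and deletion always 0 — no indels simulated).
    """
    rng = _stage_rng(config, "counts")
    sites = truth.sites
    n_sites, n_pools = len(sites), config.n_pools
    z = config.haploid_size

    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = _OTHERS[ref_idx, rng.integers(0, 3, size=n_sites)]

    q = sites[[f"q_pool{j}" for j in range(n_pools)]].to_numpy()
    k = rng.binomial(z, q)
    g = k / z
    depth = rng.poisson(config.depth_mean, size=(n_sites, n_pools))
    alt_reads = rng.binomial(depth, g)
    ref_reads = depth - alt_reads

    counts = np.zeros((n_sites, n_pools, 4), dtype=np.int64)
    e = config.error_rate
    for true_allele, n_reads in ((ref_idx, ref_reads), (alt_idx, alt_reads)):
        kept = rng.binomial(n_reads, 1.0 - e) if e > 0 else n_reads
        np.add.at(
            counts,
            (
                np.broadcast_to(np.arange(n_sites)[:, None], (n_sites, n_pools)),
                np.broadcast_to(np.arange(n_pools)[None, :], (n_sites, n_pools)),
                np.broadcast_to(true_allele[:, None], (n_sites, n_pools)),
            ),
            kept,
        )
        if e > 0:
            flips = rng.multinomial(n_reads - kept, [1 / 3, 1 / 3, 1 / 3])
            others = _OTHERS[true_allele]  # (n_sites, 3)
            np.add.at(
                counts,
                (
                    np.broadcast_to(
                        np.arange(n_sites)[:, None, None], (n_sites, n_pools, 3)
                    ),
                    np.broadcast_to(
                        np.arange(n_pools)[None, :, None], (n_sites, n_pools, 3)
                    ),
                    np.broadcast_to(others[:, None, :], (n_sites, n_pools, 3)),
                ),
                flips,
            )

    full = np.zeros((n_sites, n_pools, 6), dtype=np.int64)
    full[:, :, :4] = counts
    scaffolds = sites["scaffold"].to_numpy()
    positions = sites["position"].to_numpy()
    return [
        SyncRecord(
            scaffold=scaffolds[s],
            position=int(positions[s]),
            ref_base=NUCLEOTIDES[ref_idx[s]],
            counts=full[s],
        )
        for s in range(n_sites)
    ]


def _near_planted(config: SimConfig, scaffold: str, start: int, end: int) -> bool:
    for region in config.planted_regions:
        if region.scaffold != scaffold:
            continue
        gap = max(0, region.start - end, start - region.end)
        if gap <= config.near_flank:
            return True
    return False


def simulate_annotation(
    config: SimConfig, truth: SimTruth
) -> tuple[list[GeneFeature], dict[str, set[str]]]:
    """Place non-overlapping genes and assign functional terms.

    Genes are placed one per uniform slot along each scaffold with a
    random offset inside the slot, which guarantees non-overlap. Genes
    within ``near_flank`` bp of a planted region carry the planted term
    with probability ``near_term_prob`` (default 0.5) versus
    ``background_term_prob`` (default 0.02) elsewhere; every gene also
    carries each of ``n_background_terms`` neutral terms independently at
    ``background_term_rate``. Updates ``truth.genes`` and returns the gene
    features plus the gene -> terms map.
    """
    rng = _stage_rng(config, "annotation")
    per_scaffold = np.full(config.n_scaffolds, config.n_genes // config.n_scaffolds)
    per_scaffold[: config.n_genes % config.n_scaffolds] += 1
    min_len, max_len = 500, 3000

    features: list[GeneFeature] = []
    rows = []
    term_map: dict[str, set[str]] = {}
    gene_no = 0
    for scaffold, count in zip(config.scaffold_names, per_scaffold):
        if count == 0:
            continue
        slot = config.scaffold_length_bp // int(count)
        if slot <= min_len:
            raise ValueError(
                f"n_genes={config.n_genes} too large to place without "
                f"overlap on {config.n_scaffolds} scaffolds of "
                f"{config.scaffold_length_bp} bp"
            )
        for i in range(int(count)):
            gene_no += 1
            length = int(rng.integers(min_len, min(max_len, slot - 1) + 1))
            offset = int(rng.integers(0, slot - length))
            start = i * slot + offset + 1
            end = start + length - 1
            gene_id = f"gene_{gene_no:04d}"
            near = _near_planted(config, scaffold, start, end)
            terms: set[str] = set()
            p_term = config.near_term_prob if near else config.background_term_prob
            if rng.random() < p_term:
                terms.add(config.planted_term)
            bg = rng.random(config.n_background_terms) < config.background_term_rate
            terms.update(
                f"GO:BG{t + 1:04d}" for t in np.flatnonzero(bg)
            )
            features.append(
                GeneFeature(gene_id=gene_id, scaffold=scaffold, start=start, end=end, strand="+")
            )
            term_map[gene_id] = terms
            rows.append((gene_id, scaffold, start, end, near, ";".join(sorted(terms))))
    truth.genes = pd.DataFrame(
        rows, columns=["gene_id", "scaffold", "start", "end", "near_planted", "terms"]
    )
    return features, term_map


def write_gff3(features: list[GeneFeature], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(features, key=lambda g: (g.scaffold, g.start)):
            fh.write(
                f"{g.scaffold}\tchronoscan_sim\tgene\t{g.start}\t{g.end}"
                f"\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def write_term_map(term_map: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(term_map):
            for term in sorted(term_map[gene]):
                fh.write(f"{gene}\t{term}\n")


def simulate_study(config: SimConfig, out_dir) -> tuple[dict[str, Path], SimTruth]:
    """Generate and write a complete synthetic study.

    Writes ``study.sync``, ``genes.gff3``, ``terms.tsv``,
    ``truth_sites.tsv`` and ``truth_genes.tsv`` under ``out_dir`` and
    returns the paths with the in-memory truth. Byte-identical for a
    fixed config (including its seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = simulate_site_frequencies(config)
    records = simulate_pool_counts(truth, config)
    features, term_map = simulate_annotation(config, truth)

    paths = {
        "sync": out_dir / "study.sync",
        "gff": out_dir / "genes.gff3",
        "terms": out_dir / "terms.tsv",
        "truth_sites": out_dir / "truth_sites.tsv",
        "truth_genes": out_dir / "truth_genes.tsv",
    }
    write_sync(records, paths["sync"])
    write_gff3(features, paths["gff"])
    write_term_map(term_map, paths["terms"])
    truth.sites.to_csv(paths["truth_sites"], sep="\t", index=False, float_format="%.6g")
    truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    return paths, truth
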
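"""Synthetic data generation: LD-bearing haplotype pools, pedigree
transmission with recombination, and per-site short-read evidence.

The default pool generator is a mosaic resampler: a small set of seed
haplotypes is drawn with a neutral-like site frequency spectrum (density
proportional to 1/p), and each pool haplotype is built as a recombining
mosaic of the seeds with a small per-site mutation rate.  Shared long seed
segments give the pool genuine linkage disequilibrium with distance decay.
An msprime coalescent backend is available as an optional plug-in when
demographic realism matters.

Reads are simulated per site: depth is Poisson with the requested mean, each
base is drawn from the true genotype's alleles (fair coin for heterozygotes)
and flipped to a uniformly chosen other base with probability
e = 10^(-Q/10); genotype likelihoods then come from the independent-error
model.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from . import genolik
from .formats_io import (
    Individual,
    LikelihoodMatrix,
    PanelMatrix,
    PedigreeGraph,
    SiteRecord,
    write_gl_vcf,
    write_pedigree,
    write_phased_truth_vcf,
)


@dataclass
class HaplotypePool:
    """Pool of phased haplotypes with physical positions (bp)."""

    panel: PanelMatrix
    positions: np.ndarray  # (M,) 1-based bp positions, strictly increasing

    @property
    def n_haplotypes(self) -> int:
        return self.panel.n_haplotypes

    @property
    def n_sites(self) -> int:
        return self.panel.n_sites

    def sites(self, chrom: str = "1") -> list[SiteRecord]:
        return [
            SiteRecord(chrom, int(p), "A", "C", f"snp{k}")
            for k, p in enumerate(self.positions)
        ]


@dataclass
class SimTruth:
    """Ground truth for one simulated cohort."""

    haplotypes: np.ndarray  # (N, 2, M) uint8
    sample_ids: list[str]
    pedigree: PedigreeGraph
    pool: HaplotypePool

    @property
    def genotypes(self) -> np.ndarray:
        return self.haplotypes.sum(axis=1).astype(np.int64)

    def subset(self, keep_ids: list[str]) -> "SimTruth":
        """Restrict to a subset of individuals (e.g. to split one cohort into
        study samples and reference-panel donors without haplotype overlap).
        Kept non-founders must retain both parents."""
        keep = set(keep_ids)
        idx = [j for j, iid in enumerate(self.sample_ids) if iid in keep]
        ped = PedigreeGraph(
            {iid: self.pedigree.individuals[iid]
             for iid in self.sample_ids if iid in keep}
        )
        ped.validate()
        return SimTruth(
            haplotypes=self.haplotypes[idx],
            sample_ids=[self.sample_ids[j] for j in idx],
            pedigree=ped,
            pool=self.pool,
        )


def _neutral_frequencies(n_sites: int, rng: np.random.Generator,
                         fmin: float = 0.02, fmax: float = 0.98) -> np.ndarray:
    """Site frequencies with density proportional to 1/p on [fmin, fmax]."""
    u = rng.random(n_sites)
    return fmin * (fmax / fmin) ** u


def make_pool(
    n_haplotypes: int,
    n_sites: int,
    seed: int,
    generator: str = "mosaic",
    region_bp: int | None = None,
    n_seed_haplotypes: int = 20,
    switch_rate: float = 0.02,
    mutation_rate: float = 0.002,
) -> HaplotypePool:
    """Build a haplotype pool with LD decay.

    generator="mosaic" (default, no external dependency) or "msprime" for a
    coalescent simulation.  Monomorphic sites are dropped, so the returned
    site count can be slightly below ``n_sites``.
    """
    if n_haplotypes < 2:
        raise ValueError("need at least 2 pool haplotypes")
    rng = np.random.default_rng(seed)
    region_bp = region_bp or n_sites * 1000

    if generator == "mosaic":
        freqs = _neutral_frequencies(n_sites, rng)
        seeds = (rng.random((n_seed_haplotypes, n_sites)) < freqs).astype(np.uint8)
        # each pool haplotype copies a recombining mosaic of the seeds
        donors = np.empty((n_haplotypes, n_sites), dtype=np.int64)
        donors[:, 0] = rng.integers(n_seed_haplotypes, size=n_haplotypes)
        switches = rng.random((n_haplotypes, n_sites - 1)) < switch_rate
        new_donors = rng.integers(n_seed_haplotypes, size=(n_haplotypes, n_sites - 1))
        for i in range(1, n_sites):
            donors[:, i] = np.where(
                switches[:, i - 1], new_donors[:, i - 1], donors[:, i - 1]
            )
        alleles = seeds[donors, np.arange(n_sites)]
        flips = rng.random(alleles.shape) < mutation_rate
        alleles = np.where(flips, 1 - alleles, alleles).astype(np.uint8)
        positions = np.sort(rng.choice(region_bp, size=n_sites, replace=False)) + 1
    elif generator == "msprime":
        import msprime

        ts = msprime.sim_ancestry(
            samples=n_haplotypes // 2,
            ploidy=2,
            sequence_length=region_bp,
            recombination_rate=1e-8,
            population_size=10_000,
            random_seed=seed % (2**31 - 1) + 1,
        )
        mts = msprime.sim_mutations(
            ts, rate=1e-8, random_seed=seed % (2**31 - 1) + 2,
            model=msprime.BinaryMutationModel(),
        )
        alleles = mts.genotype_matrix().T.astype(np.uint8)
        alleles = np.minimum(alleles, 1)
        positions = np.array([int(s.position) + 1 for s in mts.sites()])
        if alleles.shape[1] > n_sites:
            keep = np.sort(rng.choice(alleles.shape[1], n_sites, replace=False))
            alleles = alleles[:, keep]
            positions = positions[keep]
    else:
        raise ValueError(f"unknown pool generator {generator!r}")

    poly = (alleles.sum(axis=0) > 0) & (alleles.sum(axis=0) < alleles.shape[0])
    alleles = alleles[:, poly]
    positions = np.asarray(positions)[poly]
    if positions.size:
        # de-duplicate positions to keep strictly increasing coordinates
        uniq = np.concatenate([[True], np.diff(positions) > 0])
        alleles = alleles[:, uniq]
        positions = positions[uniq]
    hap_ids = [f"pool{h}" for h in range(n_haplotypes)]
    return HaplotypePool(
        panel=PanelMatrix(alleles=alleles, haplotype_ids=hap_ids),
        positions=positions.astype(np.int64),
    )


def _transmit_haplotype(
    parent: np.ndarray, positions: np.ndarray, cm_per_mb: float, rng: np.random.Generator
) -> np.ndarray:
    """One recombined gamete: crossovers as a Poisson process on the genetic
    map (default-uniform), starting from a random parental haplotype."""
    m = positions.size
    start = rng.integers(2)
    if cm_per_mb <= 0:
        return parent[start].copy()
    gen_dist = np.diff(positions) * (cm_per_mb * 1e-8)  # Morgans per bp interval
    crossovers = rng.poisson(gen_dist)
    hap_idx = (start + np.concatenate([[0], np.cumsum(crossovers)])) % 2
    return parent[hap_idx, np.arange(m)].copy()


def sample_pedigree(
    pool: HaplotypePool,
    n_families: int,
    n_offspring: int,
    seed: int,
    cm_per_mb: float = 1.0,
    n_unrelated: int = 0,
    three_generation: bool = False,
) -> SimTruth:
    """Draw founders from the pool and transmit haplotypes to offspring.

    Nuclear families have two founders and ``n_offspring`` children; with
    ``three_generation`` each family instead contains four grandparents, two
    parents (one child of each grandparental couple, plus a married-in
    structure collapsed to the two-couple case) and ``n_offspring``
    grandchildren.  Founder haplotypes are drawn from the pool without
    replacement.
    """
    rng = np.random.default_rng(seed)
    m = pool.n_sites
    founders_per_family = 4 if three_generation else 2
    n_founder_haps = 2 * (n_families * founders_per_family + n_unrelated)
    if n_founder_haps > pool.n_haplotypes:
        raise ValueError("pool exhausted: not enough haplotypes for founders")
    draw = rng.choice(pool.n_haplotypes, size=n_founder_haps, replace=False)
    pool_iter = iter(draw)

    def next_pair() -> np.ndarray:
        return np.stack(
            [pool.panel.alleles[next(pool_iter)], pool.panel.alleles[next(pool_iter)]]
        )

    haps: list[np.ndarray] = []
    ids: list[str] = []
    ped = PedigreeGraph()

    def add(iid: str, fid: str, father: str | None, mother: str | None,
            sex: int, hap: np.ndarray) -> None:
        ids.append(iid)
        haps.append(hap)
        ped.individuals[iid] = Individual(iid, fid, father, mother, sex)

    def child_of(fh: np.ndarray, mh: np.ndarray) -> np.ndarray:
        return np.stack(
            [
                _transmit_haplotype(fh, pool.positions, cm_per_mb, rng),
                _transmit_haplotype(mh, pool.positions, cm_per_mb, rng),
            ]
        )

    for fam in range(n_families):
        fid = f"F{fam}"
        if not three_generation:
            fh, mh = next_pair(), next_pair()
            add(f"{fid}_dad", fid, None, None, 1, fh)
            add(f"{fid}_mom", fid, None, None, 2, mh)
            for k in range(n_offspring):
                add(f"{fid}_kid{k}", fid, f"{fid}_dad", f"{fid}_mom", 0,
                    child_of(fh, mh))
        else:
            gp = [next_pair() for _ in range(4)]
            add(f"{fid}_gpa1", fid, None, None, 1, gp[0])
            add(f"{fid}_gma1", fid, None, None, 2, gp[1])
            add(f"{fid}_gpa2", fid, None, None, 1, gp[2])
            add(f"{fid}_gma2", fid, None, None, 2, gp[3])
            dad = child_of(gp[0], gp[1])
            mom = child_of(gp[2], gp[3])
            add(f"{fid}_dad", fid, f"{fid}_gpa1", f"{fid}_gma1", 1, dad)
            add(f"{fid}_mom", fid, f"{fid}_gpa2", f"{fid}_gma2", 2, mom)
            for k in range(n_offspring):
                add(f"{fid}_kid{k}", fid, f"{fid}_dad", f"{fid}_mom", 0,
                    child_of(dad, mom))
    for k in range(n_unrelated):
        add(f"U{k}", f"U{k}", None, None, 0, next_pair())

    ped.validate()
    return SimTruth(
        haplotypes=np.stack(haps), sample_ids=ids, pedigree=ped, pool=pool
    )


def simulate_reads(
    truth: SimTruth,
    mean_depth: float,
    base_quality_q: float,
    seed: int,
) -> tuple[np.ndarray, LikelihoodMatrix]:
    """Per-site Poisson-depth reads with fixed per-base error.

    Returns (counts, likelihoods) where counts has shape (N, M, 3) holding
    the numbers of ref, alt and other bases observed.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    e = float(genolik.phred_to_error(base_quality_q))
    g = truth.genotypes  # (N, M) in {0, 1, 2}
    depth = rng.poisson(mean_depth, size=g.shape)

    # true-allele draws: number of alt-origin bases is Binomial(depth, g/2)
    alt_origin = rng.binomial(depth, g / 2.0)
    ref_origin = depth - alt_origin
    # errors: each base flips to one of the 3 other codes uniformly
    ref_err = rng.binomial(ref_origin, e)
    alt_err = rng.binomial(alt_origin, e)
    ref_to_alt = rng.binomial(ref_err, 1.0 / 3.0)
    alt_to_ref = rng.binomial(alt_err, 1.0 / 3.0)

    n_ref = (ref_origin - ref_err) + alt_to_ref
    n_alt = (alt_origin - alt_err) + ref_to_alt
    n_other = (ref_err - ref_to_alt) + (alt_err - alt_to_ref)
    counts = np.stack([n_ref, n_alt, n_other], axis=2)
    values = genolik.likelihoods_from_counts(n_ref, n_alt, n_other, e)
    lik = LikelihoodMatrix(values=values, sample_ids=list(truth.sample_ids))
    return counts, lik


def panel_from_founders(truth: SimTruth) -> PanelMatrix:
    """Phased panel assembled from a cohort's founder haplotypes (e.g. a
    separately simulated set of reference diploids)."""
    rows = []
    ids = []
    for j, iid in enumerate(truth.sample_ids):
        if truth.pedigree.individuals[iid].father is None:
            rows.append(truth.haplotypes[j])
            ids.extend([f"{iid}.0", f"{iid}.1"])
    alleles = np.concatenate(rows, axis=0)
    return PanelMatrix(alleles=alleles, haplotype_ids=ids)


def write_truth_and_inputs(
    truth: SimTruth,
    likelihoods: LikelihoodMatrix,
    out_dir: str,
    chrom: str = "1",
    manifest: dict | None = None,
) -> dict[str, str]:
    """Write the GL VCF, phased truth VCF, PED and a run manifest."""
    os.makedirs(out_dir, exist_ok=True)
    sites = truth.pool.sites(chrom)
    paths = {
        "gl_vcf": os.path.join(out_dir, "input.gl.vcf"),
        "truth_vcf": os.path.join(out_dir, "truth.vcf"),
        "ped": os.path.join(out_dir, "samples.ped"),
        "manifest": os.path.join(out_dir, "manifest.json"),
    }
    write_gl_vcf(sites, likelihoods, paths["gl_vcf"])
    write_phased_truth_vcf(sites, truth.sample_ids, truth.haplotypes, paths["truth_vcf"])
    write_pedigree(truth.pedigree, paths["ped"])
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest or {}, fh, indent=2)
    return paths
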
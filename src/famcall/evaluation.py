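"""Evaluation criteria: stratified genotype mismatch, phasing switch error
and Mendelian errors per offspring.

Strata follow the usual conventions for low-coverage calling benchmarks:
the heterozygous stratum restricts to sites where the truth genotype is
heterozygous, and the rare stratum to sites whose truth minor allele
frequency (computed from founder alleles, the independent draws) is below
5%.  Switch error counts phase flips between consecutive truth-heterozygous
sites under the best initial slot assignment, per individual, skipping sites
whose genotype was miscalled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .formats_io import PedigreeGraph


@dataclass
class EvalReport:
    mismatch_all: float
    mismatch_het: float | None
    mismatch_rare: float | None
    switch_error: float | None
    mendelian_per_offspring: float
    n_sites: int
    n_samples: int
    n_het_sites: int
    n_rare_sites: int

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def to_tsv(self, path: str) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            fh.write("\t".join(d.keys()) + "\n")
            fh.write("\t".join("NA" if v is None else str(v) for v in d.values()) + "\n")


def founder_maf(truth_haplotypes: np.ndarray, founder_idx: np.ndarray) -> np.ndarray:
    """Minor allele frequency per site from founder haplotypes only."""
    alleles = truth_haplotypes[founder_idx].reshape(-1, truth_haplotypes.shape[-1])
    f = alleles.mean(axis=0)
    return np.minimum(f, 1.0 - f)


def genotype_mismatch(
    called: np.ndarray,
    truth: np.ndarray,
    stratum: str = "all",
    maf: np.ndarray | None = None,
) -> float | None:
    """Fraction of mismatched genotypes in the requested stratum.

    called, truth: (N, M) genotype matrices in {0, 1, 2}; entries of -1 in
    ``called`` are missing and excluded from the denominator.  stratum is
    one of "all", "het" (truth-heterozygous entries) or "maf_lt_5" (sites
    with truth founder MAF below 0.05, which requires ``maf``).  Returns
    None when the stratum is empty.
    """
    called = np.asarray(called)
    truth = np.asarray(truth)
    if called.shape != truth.shape:
        raise ValueError("called and truth matrices must have the same shape")
    mask = called >= 0
    if stratum == "het":
        mask &= truth == 1
    elif stratum == "maf_lt_5":
        if maf is None:
            raise ValueError("maf_lt_5 stratum requires founder MAF values")
        mask &= np.broadcast_to(maf < 0.05, truth.shape)
    elif stratum != "all":
        raise ValueError(f"unknown stratum {stratum!r}")
    n = int(mask.sum())
    if n == 0:
        return None
    return float((called[mask] != truth[mask]).mean())


def _switches_one(
    called_pair: np.ndarray, truth_pair: np.ndarray, called_geno: np.ndarray,
    truth_geno: np.ndarray,
) -> tuple[int, int] | None:
    """(switch count, comparable het links) for one individual, or None."""
    het = (truth_geno == 1) & (called_geno == 1)
    idx = np.flatnonzero(het)
    if idx.size < 2:
        return None
    # at a het site phase is captured by which slot carries the alt allele
    called_phase = called_pair[0, idx]
    truth_phase = truth_pair[0, idx]
    agree = called_phase == truth_phase
    # best initial slot assignment, then count flips of agreement
    flips = int((agree[1:] != agree[:-1]).sum())
    return flips, idx.size - 1


def switch_error(
    called_haps: np.ndarray,
    truth_haps: np.ndarray,
    pooled: bool = False,
) -> float | None:
    """Mean per-individual switch error over truth-heterozygous sites.

    called_haps, truth_haps: (N, 2, M) ordered haplotypes.  Sites whose
    called genotype disagrees with truth are dropped from the phase
    comparison; individuals with fewer than two comparable heterozygous
    sites are skipped.  With ``pooled`` the totals are pooled over
    individuals instead of averaging the per-individual rates.
    """
    called_haps = np.asarray(called_haps)
    truth_haps = np.asarray(truth_haps)
    if called_haps.shape != truth_haps.shape:
        raise ValueError("haplotype arrays must have the same shape")
    cg = called_haps.sum(axis=1)
    tg = truth_haps.sum(axis=1)
    rates = []
    tot_flips = tot_links = 0
    for j in range(called_haps.shape[0]):
        res = _switches_one(called_haps[j], truth_haps[j], cg[j], tg[j])
        if res is None:
            continue
        flips, links = res
        rates.append(flips / links)
        tot_flips += flips
        tot_links += links
    if not rates:
        return None
    if pooled:
        return tot_flips / tot_links
    return float(np.mean(rates))


MENDEL_OK = np.zeros((3, 3, 3), dtype=bool)
for _gf in range(3):
    for _gm in range(3):
        for _pa in ({0} if _gf == 0 else {1} if _gf == 2 else {0, 1}):
            for _ma in ({0} if _gm == 0 else {1} if _gm == 2 else {0, 1}):
                MENDEL_OK[_gf, _gm, _pa + _ma] = True


def mendelian_errors(
    called: np.ndarray,
    pedigree: PedigreeGraph,
    sample_ids: list[str],
) -> float:
    """Mean count of Mendelian-inconsistent genotypes per offspring.

    A site is inconsistent when the child's unordered genotype cannot be
    formed from one allele of each parent's called genotype.  Sites with a
    missing call in any trio member are skipped.
    """
    index = {iid: j for j, iid in enumerate(sample_ids)}
    trios = pedigree.trios()
    if not trios:
        return 0.0
    total = 0
    for f, m, c in trios:
        gf = called[index[f]]
        gm = called[index[m]]
        gc = called[index[c]]
        ok = (gf >= 0) & (gm >= 0) & (gc >= 0)
        total += int((~MENDEL_OK[gf[ok], gm[ok], gc[ok]]).sum())
    return total / len(trios)


def evaluate(
    called_genotypes: np.ndarray,
    called_haps: np.ndarray,
    truth_haps: np.ndarray,
    pedigree: PedigreeGraph,
    sample_ids: list[str],
) -> EvalReport:
    """Full report: stratified mismatch, switch error, Mendelian errors."""
    truth_geno = truth_haps.sum(axis=1)
    founder_idx = np.asarray(
        [j for j, iid in enumerate(sample_ids)
         if pedigree.individuals[iid].father is None],
        dtype=np.int64,
    )
    maf = founder_maf(truth_haps, founder_idx)
    return EvalReport(
        mismatch_all=genotype_mismatch(called_genotypes, truth_geno, "all"),
        mismatch_het=genotype_mismatch(called_genotypes, truth_geno, "het"),
        mismatch_rare=genotype_mismatch(called_genotypes, truth_geno, "maf_lt_5", maf),
        switch_error=switch_error(called_haps, truth_haps),
        mendelian_per_offspring=mendelian_errors(
            called_genotypes, pedigree, sample_ids
        ),
        n_sites=int(truth_geno.shape[1]),
        n_samples=int(truth_geno.shape[0]),
        n_het_sites=int((truth_geno == 1).any(axis=0).sum()),
        n_rare_sites=int((maf < 0.05).sum()),
    )
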
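"""Standard-format I/O: likelihood VCFs, phased panel VCFs and PED pedigrees.

Internal conventions: VCF positions stay 1-based; the internal site index is
the 0-based position within the filtered biallelic site list.  Genotype
likelihood triples are stored on the linear scale, rescaled so the maximum of
each triple is 1 (the model only ever uses likelihood ratios).  Missing data
is the uninformative triple (1, 1, 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pysam

logger = logging.getLogger(__name__)

MISSING_PARENT = "0"


class FormatError(Exception):
    """Raised on malformed or inconsistent input files."""


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic site; pos is the 1-based VCF coordinate."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    id: str | None = None


@dataclass
class LikelihoodMatrix:
    """N samples x M sites x 3 genotype likelihoods P(R|G), linear scale."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError("likelihood matrix must have shape (N, M, 3)")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("sample count does not match likelihood rows")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("likelihoods must lie in [0, 1]")
        if (self.values.max(axis=2) <= 0).any():
            raise ValueError("each (sample, site) needs a positive likelihood")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]


@dataclass
class PanelMatrix:
    """H haplotypes x M sites of 0/1 alleles, aligned to a site list."""

    alleles: np.ndarray
    haplotype_ids: list[str]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValueError("panel must be 2-D (H haplotypes x M sites)")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("panel alleles must be 0 or 1")
        if self.alleles.shape[0] != len(self.haplotype_ids):
            raise ValueError("haplotype id count does not match rows")
        if self.alleles.shape[0] < 2:
            raise ValueError("a panel needs at least 2 haplotypes")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]


@dataclass(frozen=True)
class Individual:
    iid: str
    fid: str
    father: str | None
    mother: str | None
    sex: int


@dataclass
class PedigreeGraph:
    """Pedigree as parent links; expands into parent-offspring trios."""

    individuals: dict[str, Individual] = field(default_factory=dict)

    @property
    def families(self) -> dict[str, list[str]]:
        fams: dict[str, list[str]] = {}
        for ind in self.individuals.values():
            fams.setdefault(ind.fid, []).append(ind.iid)
        return fams

    def founders(self) -> list[str]:
        return [i.iid for i in self.individuals.values() if i.father is None]

    def children(self) -> list[str]:
        return [i.iid for i in self.individuals.values() if i.father is not None]

    def trios(self) -> list[tuple[str, str, str]]:
        """All (father, mother, child) triples, at every generation."""
        return [
            (i.father, i.mother, i.iid)
            for i in self.individuals.values()
            if i.father is not None
        ]

    def trios_by_family(self) -> dict[str, list[tuple[str, str, str]]]:
        out: dict[str, list[tuple[str, str, str]]] = {}
        for f, m, c in self.trios():
            out.setdefault(self.individuals[c].fid, []).append((f, m, c))
        return out

    def singletons(self) -> list[str]:
        """Individuals that appear in no trio (neither parent nor child)."""
        in_trio: set[str] = set()
        for f, m, c in self.trios():
            in_trio.update((f, m, c))
        return [iid for iid in self.individuals if iid not in in_trio]

    def validate(self) -> None:
        for ind in self.individuals.values():
            if ind.father is not None:
                for p in (ind.father, ind.mother):
                    if p not in self.individuals:
                        raise FormatError(
                            f"parent {p!r} of {ind.iid!r} is not in the pedigree"
                        )
                    if self.individuals[p].fid != ind.fid:
                        raise FormatError(
                            f"parent {p!r} of {ind.iid!r} is in a different family"
                        )
        # cycle check: every individual must reach founders
        state: dict[str, int] = {}

        def visit(iid: str) -> None:
            if state.get(iid) == 2:
                return
            if state.get(iid) == 1:
                raise FormatError(f"cyclic pedigree involving {iid!r}")
            state[iid] = 1
            ind = self.individuals[iid]
            if ind.father is not None:
                visit(ind.father)
                visit(ind.mother)
            state[iid] = 2

        for iid in self.individuals:
            visit(iid)


# ---------------------------------------------------------------------------
# readers


def _rescale_triples(log10_triples: np.ndarray) -> np.ndarray:
    logs = log10_triples - log10_triples.max(axis=-1, keepdims=True)
    return 10.0 ** logs


def read_likelihood_vcf(path: str) -> tuple[list[SiteRecord], LikelihoodMatrix]:
    """Read a VCF with GL (log10) or PL (Phred) genotype likelihoods.

    Multi-allelic records are skipped with a warning; a sample record with
    neither GL nor PL becomes the uninformative triple.
    """
    vf = pysam.VariantFile(path)
    sample_ids = list(vf.header.samples)
    sites: list[SiteRecord] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    n_missing = 0
    last_pos: dict[str, int] = {}
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            n_skipped += 1
            continue
        if len(rec.ref) != 1 or len(rec.alts[0]) != 1 or rec.ref == rec.alts[0]:
            n_skipped += 1
            continue
        if rec.chrom in last_pos and rec.pos <= last_pos[rec.chrom]:
            raise FormatError(
                f"positions not strictly increasing at {rec.chrom}:{rec.pos}"
            )
        last_pos[rec.chrom] = rec.pos
        sites.append(
            SiteRecord(rec.chrom, rec.pos, rec.ref, rec.alts[0], rec.id)
        )
        log10s = np.zeros((len(sample_ids), 3))
        for j, sid in enumerate(sample_ids):
            s = rec.samples[sid]
            pl = s.get("PL") if "PL" in s else None
            gl = s.get("GL") if "GL" in s else None
            if pl is not None and None not in pl and len(pl) == 3:
                log10s[j] = -np.asarray(pl, dtype=float) / 10.0
            elif gl is not None and None not in gl and len(gl) == 3:
                log10s[j] = np.asarray(gl, dtype=float)
            else:
                n_missing += 1  # stays the flat triple
        rows.append(log10s)
    vf.close()
    if not sites:
        raise FormatError(f"no usable biallelic records in {path}")
    if n_skipped:
        logger.warning("skipped %d non-biallelic/non-SNV records", n_skipped)
    if n_missing:
        logger.warning(
            "%d sample records lacked GL/PL and are treated as missing", n_missing
        )
    values = _rescale_triples(np.stack(rows, axis=1))  # (N, M, 3)
    return sites, LikelihoodMatrix(values=values, sample_ids=sample_ids)


def read_pedigree(path: str) -> PedigreeGraph:
    """Read a 6-column whitespace-delimited PED/FAM file.

    Columns: family, individual, father, mother, sex, phenotype; "0" denotes
    a missing parent.  A child must name both parents or neither, and named
    parents must appear as rows of the file.
    """
    ped = PedigreeGraph()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"{path}:{ln}: expected 6 columns")
            fid, iid, fat, mot, sex = parts[0], parts[1], parts[2], parts[3], parts[4]
            if iid in ped.individuals:
                raise FormatError(f"{path}:{ln}: duplicate individual {iid!r}")
            if (fat == MISSING_PARENT) != (mot == MISSING_PARENT):
                raise FormatError(
                    f"{path}:{ln}: {iid!r} must name both parents or neither"
                )
            ped.individuals[iid] = Individual(
                iid=iid,
                fid=fid,
                father=None if fat == MISSING_PARENT else fat,
                mother=None if mot == MISSING_PARENT else mot,
                sex=int(sex) if sex in ("1", "2") else 0,
            )
    ped.validate()
    return ped


def _site_key(rec) -> tuple[str, int, str, str]:
    return (rec.chrom, rec.pos, rec.ref, rec.alts[0])


def read_phased_panel(path: str, sites: list[SiteRecord]) -> PanelMatrix:
    """Read phased haplotypes from a VCF, restricted to the study sites.

    Every panel genotype must be phased ("|"); sites absent from the panel
    are dropped from neither list here — the returned matrix covers exactly
    the study sites present in the panel, in study-site order, and the
    caller receives the kept site indices via the ``site_index`` attribute.
    """
    wanted = {(s.chrom, s.pos, s.ref_allele, s.alt_allele): k for k, s in enumerate(sites)}
    vf = pysam.VariantFile(path)
    sample_ids = list(vf.header.samples)
    found: dict[int, np.ndarray] = {}
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        k = wanted.get(_site_key(rec))
        if k is None:
            continue
        col = np.empty(2 * len(sample_ids), dtype=np.uint8)
        for j, sid in enumerate(sample_ids):
            s = rec.samples[sid]
            if not s.phased:
                raise FormatError(
                    f"unphased panel genotype for {sid} at {rec.chrom}:{rec.pos}"
                )
            gt = s["GT"]
            if gt is None or None in gt or len(gt) != 2:
                raise FormatError(
                    f"missing panel genotype for {sid} at {rec.chrom}:{rec.pos}"
                )
            col[2 * j] = gt[0]
            col[2 * j + 1] = gt[1]
        found[k] = col
    vf.close()
    if not found:
        raise FormatError("panel shares no sites with the study data")
    keep = sorted(found)
    alleles = np.stack([found[k] for k in keep], axis=1)  # (2*n, m)
    hap_ids = [f"{sid}.{h}" for sid in sample_ids for h in (0, 1)]
    panel = PanelMatrix(alleles=alleles, haplotype_ids=hap_ids)
    panel.site_index = np.asarray(keep, dtype=np.int64)  # type: ignore[attr-defined]
    return panel


# ---------------------------------------------------------------------------
# writer


def write_called_vcf(
    sites: list[SiteRecord],
    sample_ids: list[str],
    posteriors: np.ndarray,
    haplotypes: np.ndarray,
    out_path: str,
) -> None:
    """Write phased calls: GT from consensus haplotypes, GP posteriors, DS dosage.

    posteriors: (N, M, 3) normalized per (sample, site); haplotypes: (N, 2, M)
    of 0/1 alleles.  Output formatting is deterministic given the inputs.
    """
    posteriors = np.asarray(posteriors, dtype=float)
    haplotypes = np.asarray(haplotypes)
    n, m = len(sample_ids), len(sites)
    if posteriors.shape != (n, m, 3) or haplotypes.shape != (n, 2, m):
        raise ValueError("sites/posteriors/haplotypes dimensions disagree")

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype posterior">'
    )
    header.add_line(
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt-allele dosage">'
    )
    for chrom in dict.fromkeys(s.chrom for s in sites):
        max_pos = max(s.pos for s in sites if s.chrom == chrom)
        header.add_line(f"##contig=<ID={chrom},length={max_pos + 1}>")
    for sid in sample_ids:
        header.add_sample(sid)

    with pysam.VariantFile(out_path, "w", header=header) as out:
        for k, site in enumerate(sites):
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                alleles=(site.ref_allele, site.alt_allele),
                id=site.id,
            )
            for j, sid in enumerate(sample_ids):
                gp = posteriors[j, k]
                rec.samples[sid]["GT"] = (
                    int(haplotypes[j, 0, k]),
                    int(haplotypes[j, 1, k]),
                )
                rec.samples[sid].phased = True
                rec.samples[sid]["GP"] = tuple(round(float(x), 4) for x in gp)
                rec.samples[sid]["DS"] = round(float(gp[1] + 2.0 * gp[2]), 4)
            out.write(rec)


def read_called_vcf(path: str) -> tuple[list[SiteRecord], list[str], np.ndarray, np.ndarray]:
    """Read back a called VCF: sites, samples, genotypes (N, M) and haplotypes (N, 2, M)."""
    vf = pysam.VariantFile(path)
    sample_ids = list(vf.header.samples)
    sites: list[SiteRecord] = []
    haps: list[np.ndarray] = []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        sites.append(SiteRecord(rec.chrom, rec.pos, rec.ref, rec.alts[0], rec.id))
        col = np.empty((len(sample_ids), 2), dtype=np.int8)
        for j, sid in enumerate(sample_ids):
            gt = rec.samples[sid]["GT"]
            if gt is None or None in gt:
                col[j] = (-1, -1)
            else:
                col[j] = gt
        haps.append(col)
    vf.close()
    hap_arr = np.stack(haps, axis=2)  # (N, 2, M)
    genotypes = hap_arr.sum(axis=1)
    genotypes[(hap_arr < 0).any(axis=1)] = -1
    return sites, sample_ids, genotypes, hap_arr


def write_gl_vcf(
    sites: list[SiteRecord],
    likelihoods: LikelihoodMatrix,
    out_path: str,
) -> None:
    """Write per-sample genotype likelihoods as a GL-format VCF."""
    n, m = likelihoods.n_samples, likelihoods.n_sites
    if m != len(sites):
        raise ValueError("site list and likelihood matrix disagree")
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=GL,Number=G,Type=Float,Description="Log10 genotype likelihood">'
    )
    for chrom in dict.fromkeys(s.chrom for s in sites):
        max_pos = max(s.pos for s in sites if s.chrom == chrom)
        header.add_line(f"##contig=<ID={chrom},length={max_pos + 1}>")
    for sid in likelihoods.sample_ids:
        header.add_sample(sid)
    vals = np.maximum(likelihoods.values, 1e-300)
    gl = np.log10(vals)
    with pysam.VariantFile(out_path, "w", header=header) as out:
        for k, site in enumerate(sites):
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                alleles=(site.ref_allele, site.alt_allele),
                id=site.id,
            )
            for j, sid in enumerate(likelihoods.sample_ids):
                rec.samples[sid]["GT"] = (None, None)
                rec.samples[sid]["GL"] = tuple(round(float(x), 4) for x in gl[j, k])
            out.write(rec)


def write_phased_truth_vcf(
    sites: list[SiteRecord],
    sample_ids: list[str],
    haplotypes: np.ndarray,
    out_path: str,
) -> None:
    """Write true phased genotypes (GT only) for evaluation."""
    n, m = len(sample_ids), len(sites)
    haplotypes = np.asarray(haplotypes)
    if haplotypes.shape != (n, 2, m):
        raise ValueError("haplotype array must have shape (N, 2, M)")
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in dict.fromkeys(s.chrom for s in sites):
        max_pos = max(s.pos for s in sites if s.chrom == chrom)
        header.add_line(f"##contig=<ID={chrom},length={max_pos + 1}>")
    for sid in sample_ids:
        header.add_sample(sid)
    with pysam.VariantFile(out_path, "w", header=header) as out:
        for k, site in enumerate(sites):
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                alleles=(site.ref_allele, site.alt_allele),
                id=site.id,
            )
            for j, sid in enumerate(sample_ids):
                rec.samples[sid]["GT"] = (
                    int(haplotypes[j, 0, k]),
                    int(haplotypes[j, 1, k]),
                )
                rec.samples[sid].phased = True
            out.write(rec)


def write_pedigree(ped: PedigreeGraph, out_path: str) -> None:
    """Write a 6-column PED file (phenotype set to 0/missing)."""
    with open(out_path, "w") as fh:
        for ind in ped.individuals.values():
            fh.write(
                f"{ind.fid}\t{ind.iid}\t{ind.father or '0'}\t{ind.mother or '0'}"
                f"\t{ind.sex or 0}\t0\n"
            )
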
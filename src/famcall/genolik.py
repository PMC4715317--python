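"""Genotype likelihoods P(R|G) from base calls under an independent-error model.

At a biallelic site with observed bases ``b_j`` and per-base error
probabilities ``e_j``, the likelihood of the read data under each of the three
diploid genotypes (hom-ref, het, hom-alt) is a product over bases.  A base
drawn from a homozygous genotype matches the single allele with probability
``1 - e_j`` and reads as any one of the three other bases with probability
``e_j / 3``.  Under a heterozygous genotype each base is drawn from either
allele with probability one half.  Bases matching neither allele ("other")
contribute a factor ``e_j / 3`` under every genotype.

All products are accumulated in log space and rescaled so the largest of the
three likelihoods is 1 (only likelihood ratios enter the downstream model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# base codes used throughout the package
REF, ALT, OTHER = 0, 1, 2


def phred_to_error(q: float | np.ndarray) -> float | np.ndarray:
    """Phred-scaled quality to error probability, e = 10^(-Q/10)."""
    return 10.0 ** (-np.asarray(q, dtype=float) / 10.0)


@dataclass
class Pileup:
    """Observed bases at one site for one sample.

    bases: integer codes (0 = ref allele, 1 = alt allele, 2 = other).
    errors: per-base error probabilities, each strictly inside (0, 1).
    """

    bases: np.ndarray
    errors: np.ndarray

    def __post_init__(self) -> None:
        self.bases = np.asarray(self.bases, dtype=np.int64)
        self.errors = np.asarray(self.errors, dtype=float)
        if self.bases.shape != self.errors.shape:
            raise ValueError("bases and errors must have equal length")
        if self.bases.size and not (
            (self.errors > 0.0).all() and (self.errors < 1.0).all()
        ):
            raise ValueError("per-base error probabilities must lie in (0, 1)")

    def __len__(self) -> int:
        return self.bases.size


def genotype_likelihood(pileup: Pileup) -> np.ndarray:
    """Likelihood triple (hom-ref, het, hom-alt), rescaled so max = 1.

    An empty pileup (site not covered) returns the uninformative triple
    (1, 1, 1).
    """
    if len(pileup) == 0:
        return np.ones(3)
    b, e = pileup.bases, pileup.errors
    match_f = np.log1p(-e)  # log(1 - e)
    miss_f = np.log(e / 3.0)

    log_hom_ref = np.where(b == REF, match_f, miss_f).sum()
    log_hom_alt = np.where(b == ALT, match_f, miss_f).sum()
    # heterozygous: mixture of the two allele-specific per-base terms
    term_ref = np.where(b == REF, 1.0 - e, e / 3.0)
    term_alt = np.where(b == ALT, 1.0 - e, e / 3.0)
    log_het = np.log(0.5 * term_ref + 0.5 * term_alt).sum()

    logs = np.array([log_hom_ref, log_het, log_hom_alt])
    return np.exp(logs - logs.max())


def likelihoods_from_counts(
    n_ref: np.ndarray, n_alt: np.ndarray, n_other: np.ndarray, error_rate: float
) -> np.ndarray:
    """Vectorized likelihood triples from allele counts at constant error rate.

    With a single error probability ``e`` shared by all bases the product over
    bases depends on the pileup only through the counts of ref, alt and other
    bases.  Returns an array of shape ``(..., 3)`` with each triple rescaled
    so its maximum is 1; zero-depth entries are the uninformative (1, 1, 1).
    """
    e = float(error_rate)
    if not (0.0 < e < 1.0):
        raise ValueError("error_rate must lie in (0, 1)")
    n_ref = np.asarray(n_ref, dtype=float)
    n_alt = np.asarray(n_alt, dtype=float)
    n_other = np.asarray(n_other, dtype=float)

    lm = np.log1p(-e)       # log P(base matches the true allele)
    lx = np.log(e / 3.0)    # log P(specific non-matching base)
    # per-base factor for ref/alt bases under the het genotype
    lhet_match = np.log(0.5 * (1.0 - e) + 0.5 * (e / 3.0))

    log_hom_ref = n_ref * lm + (n_alt + n_other) * lx
    log_hom_alt = n_alt * lm + (n_ref + n_other) * lx
    log_het = (n_ref + n_alt) * lhet_match + n_other * lx

    logs = np.stack([log_hom_ref, log_het, log_hom_alt], axis=-1)
    logs -= logs.max(axis=-1, keepdims=True)
    return np.exp(logs)


def read_pileup_counts(path: str) -> list[tuple[str, str, int, int, float]]:
    """Read a tab-delimited pileup-count file: site, sample, n_ref, n_alt, mean_Q.

    Convenience input for the per-site read simulator path.  Returns rows as
    (site_id, sample_id, n_ref, n_alt, mean_quality); likelihoods can then be
    formed with :func:`likelihoods_from_counts` and :func:`phred_to_error`.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"expected 5 tab-separated fields, got: {line!r}")
            site, sample, n_ref, n_alt, mean_q = parts
            rows.append((site, sample, int(n_ref), int(n_alt), float(mean_q)))
    return rows
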
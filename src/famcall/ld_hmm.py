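"""Diploid haplotype-copying (Li-Stephens) HMM.

An individual's two haplotypes are modeled as an imperfect mosaic of H
template haplotypes (other samples' current estimates plus any external
phased panel).  The hidden state at site i is the ordered template pair
S_i = (x, y); the copied allele differs from its template with per-site
mosaic error rate epsilon (absorbing mutation and gene conversion), and each
haplotype independently jumps to a uniformly chosen template between
adjacent sites with mosaic transition rate theta (historical recombination).

Emissions integrate the read data through the genotype likelihoods:
P(R_i | S_i) = sum_G P(R_i | G_i) P(G_i | S_i).  Posterior decoding uses the
standard scaled forward-backward recursions; MCMC updates use forward
filtering with backward sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .formats_io import PanelMatrix


@dataclass
class ModelParams:
    """Per-interval transition rates theta (length M-1) and per-site mosaic
    error rates epsilon (length M).  Scalars broadcast to the site count."""

    theta: np.ndarray
    epsilon: np.ndarray

    @classmethod
    def constant(cls, n_sites: int, theta: float = 0.01, epsilon: float = 0.01):
        return cls(
            theta=np.full(max(n_sites - 1, 0), float(theta)),
            epsilon=np.full(n_sites, float(epsilon)),
        )

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.epsilon = np.atleast_1d(np.asarray(self.epsilon, dtype=float))
        if ((self.theta < 0) | (self.theta >= 1)).any():
            raise ValueError("theta must lie in [0, 1)")
        if ((self.epsilon < 0) | (self.epsilon >= 0.5)).any():
            raise ValueError("epsilon must lie in [0, 0.5)")


@dataclass
class ConditioningSet:
    """Template haplotypes for one update: (H, M) alleles with provenance."""

    alleles: np.ndarray  # (H, M) uint8
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2 or self.alleles.shape[0] < 2:
            raise ValueError("conditioning set needs >= 2 template haplotypes")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    def allele_frequencies(self) -> np.ndarray:
        """Per-site alt-allele frequency with a half-count prior (never 0/1)."""
        h = self.alleles.shape[0]
        return (self.alleles.sum(axis=0) + 0.5) / (h + 1.0)


# ---------------------------------------------------------------------------
# emission model


def copy_matrix(epsilon: float | np.ndarray) -> np.ndarray:
    """P(copied allele g | template allele a) = 1-eps if g == a else eps.

    For scalar epsilon returns (2, 2); for a length-M vector returns
    (M, 2, 2).
    """
    eps = np.asarray(epsilon, dtype=float)
    c = np.empty(eps.shape + (2, 2))
    c[..., 0, 0] = 1.0 - eps
    c[..., 1, 1] = 1.0 - eps
    c[..., 0, 1] = eps
    c[..., 1, 0] = eps
    return c


def genotype_given_state_table(epsilon: float) -> np.ndarray:
    """P(G | T(S)) rows for T(S) = 0, 1, 2 under the per-haplotype copy model.

    Each copied allele independently differs from its template with
    probability epsilon; rows are normalized (they already sum to one).
    """
    e = float(epsilon)
    t = np.array(
        [
            [(1 - e) ** 2, 2 * e * (1 - e), e**2],
            [e * (1 - e), (1 - e) ** 2 + e**2, e * (1 - e)],
            [e**2, 2 * e * (1 - e), (1 - e) ** 2],
        ]
    )
    return t / t.sum(axis=1, keepdims=True)


def emission_g_given_s(
    state: tuple[int, int],
    templates: ConditioningSet,
    site: int,
    epsilon: float,
) -> np.ndarray:
    """P(G | S) 3-vector for one mosaic state at one site."""
    x, y = state
    t = int(templates.alleles[x, site]) + int(templates.alleles[y, site])
    return genotype_given_state_table(epsilon)[t]


def emission_r_given_s(
    state: tuple[int, int],
    read_likelihood: np.ndarray,
    templates: ConditioningSet,
    site: int,
    epsilon: float,
) -> float:
    """P(R | S) = sum_G P(R | G) P(G | S) for one state at one site."""
    return float(np.dot(read_likelihood, emission_g_given_s(state, templates, site, epsilon)))


def transition_prob(
    from_state: tuple[int, int],
    to_state: tuple[int, int],
    theta: float,
    n_haplotypes: int,
) -> float:
    """Ordered-pair transition probability (product of per-haplotype kernels)."""
    x, y = from_state
    w, v = to_state
    h = n_haplotypes
    tw = (1.0 - theta) * (w == x) + theta / h
    tv = (1.0 - theta) * (v == y) + theta / h
    return tw * tv


def ordered_genotype_weights(likelihoods: np.ndarray) -> np.ndarray:
    """Expand (M, 3) genotype likelihoods to (M, 2, 2) ordered-pair weights.

    W[i, g1, g2] = P(R_i | G = g1 + g2); the per-slot expansion is what the
    per-haplotype copy model emits over.
    """
    L = np.asarray(likelihoods, dtype=float)
    W = np.empty((L.shape[0], 2, 2))
    W[:, 0, 0] = L[:, 0]
    W[:, 0, 1] = L[:, 1]
    W[:, 1, 0] = L[:, 1]
    W[:, 1, 1] = L[:, 2]
    return W


def emission_table(weights: np.ndarray, epsilon: np.ndarray) -> np.ndarray:
    """Per-site emission values by template allele pair.

    weights: (M, 2, 2) ordered-genotype weights W[i, g1, g2]; returns
    V[i, a, b] = sum_{g1, g2} C[g1|a] C[g2|b] W[i, g1, g2], the emission for a
    state whose templates carry alleles (a, b) at site i.
    """
    C = copy_matrix(np.broadcast_to(epsilon, (weights.shape[0],)))
    return np.einsum("mga,mgh,mhb->mab", C, weights, C, optimize=True)


# ---------------------------------------------------------------------------
# forward-backward and sampling


def forward(
    likelihoods: np.ndarray,
    templates: ConditioningSet,
    params: ModelParams,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Scaled forward matrices (M, H, H) and total log-likelihood."""
    if weights is None:
        weights = ordered_genotype_weights(likelihoods)
    V = emission_table(weights, params.epsilon)
    return _kernels.forward_pass(templates.alleles, V, params.theta)


def forward_backward(
    likelihoods: np.ndarray,
    templates: ConditioningSet,
    params: ModelParams,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Per-site posterior P(S_i | R) over ordered template pairs, (M, H, H)."""
    if weights is None:
        weights = ordered_genotype_weights(likelihoods)
    V = emission_table(weights, params.epsilon)
    F, _ = _kernels.forward_pass(templates.alleles, V, params.theta)
    return _kernels.backward_posteriors(templates.alleles, V, params.theta, F)


def genotype_posterior(
    state_posteriors: np.ndarray,
    templates: ConditioningSet,
    epsilon: np.ndarray | float,
) -> np.ndarray:
    """P(G_i | R) = sum_S P(G_i | S_i) P(S_i | R); (M, 3), rows sum to 1."""
    pT = _kernels.posterior_allele_pair_counts(templates.alleles, state_posteriors)
    eps = np.broadcast_to(np.asarray(epsilon, dtype=float), (pT.shape[0],))
    out = np.empty_like(pT)
    # P(G|S) depends on S only through T(S); per-site epsilon allowed
    for i in range(pT.shape[0]):
        out[i] = pT[i] @ genotype_given_state_table(eps[i])
    s = out.sum(axis=1, keepdims=True)
    return out / s


def sample_state_path(
    forward_mats: np.ndarray,
    templates: ConditioningSet,
    params: ModelParams,
    rng: np.random.Generator,
    row_sums: np.ndarray | None = None,
) -> np.ndarray:
    """Draw one path exactly from P(S_1..M | R) given forward matrices."""
    m = forward_mats.shape[0]
    if row_sums is None:
        row_sums = forward_mats.sum(axis=2)
    u = rng.random(m)
    return _kernels.sample_path(
        templates.alleles, params.theta, forward_mats, row_sums, u
    )


def sample_haplotypes_given_path(
    path: np.ndarray,
    likelihoods: np.ndarray,
    templates: ConditioningSet,
    epsilon: np.ndarray | float,
    rng: np.random.Generator,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Sample the ordered allele pair at each site given the state path.

    Pair (g1, g2) is drawn proportional to W[i, g1, g2] * P(g1 | template x)
    * P(g2 | template y) where W defaults to the read likelihoods and the
    copy probability is 1-eps for a match, eps otherwise.  Returns (2, M).
    """
    if weights is None:
        weights = ordered_genotype_weights(likelihoods)
    m = weights.shape[0]
    eps = np.broadcast_to(np.asarray(epsilon, dtype=float), (m,))
    C = copy_matrix(eps)  # (M, 2, 2) [g, a]
    idx = np.arange(m)
    ax = templates.alleles[path[:, 0], idx]  # (M,)
    ay = templates.alleles[path[:, 1], idx]
    cw1 = C[idx, :, ax]  # (M, 2): P(g1 | a_x)
    cw2 = C[idx, :, ay]
    probs = weights * cw1[:, :, None] * cw2[:, None, :]  # (M, 2, 2)
    flat = probs.reshape(m, 4)
    cum = np.cumsum(flat, axis=1)
    u = rng.random(m) * cum[:, -1]
    choice = (u[:, None] > cum[:, :3]).sum(axis=1)
    return np.stack([choice // 2, choice % 2]).astype(np.uint8)


# ---------------------------------------------------------------------------
# state-space construction


def build_state_space(
    sample_haplotypes: np.ndarray,
    eligible: np.ndarray,
    panel: PanelMatrix | None,
    max_states: int,
    rng: np.random.Generator,
    eligible_ids: list[str] | None = None,
) -> ConditioningSet:
    """Assemble the conditioning set for one update.

    sample_haplotypes: (N, 2, M) current sampled haplotypes of all study
    individuals; eligible: indices of individuals whose haplotypes may serve
    as templates (founders and unrelated individuals outside the family being
    updated).  Panel haplotypes are appended; if the union exceeds
    ``max_states`` a seeded uniform subset of that size is kept.
    """
    blocks = []
    prov: list[str] = []
    if len(eligible):
        hap = sample_haplotypes[np.asarray(eligible, dtype=np.int64)]
        blocks.append(hap.reshape(-1, hap.shape[-1]))
        for k in np.asarray(eligible):
            name = eligible_ids[int(k)] if eligible_ids else str(int(k))
            prov.extend([f"sample:{name}.0", f"sample:{name}.1"])
    if panel is not None:
        blocks.append(panel.alleles)
        prov.extend(f"panel:{h}" for h in panel.haplotype_ids)
    if not blocks:
        raise ValueError(
            "no eligible template haplotypes; supply a phased reference panel"
        )
    alleles = np.concatenate(blocks, axis=0)
    if alleles.shape[0] < 2:
        raise ValueError(
            "fewer than 2 eligible template haplotypes; supply a reference panel"
        )
    if alleles.shape[0] > max_states:
        keep = rng.choice(alleles.shape[0], size=max_states, replace=False)
        keep.sort()
        alleles = alleles[keep]
        prov = [prov[int(k)] for k in keep]
    return ConditioningSet(alleles=alleles, provenance=prov)
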
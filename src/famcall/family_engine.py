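"""Family-aware MCMC genotype calling: trio-factorized emissions and the
child-looping update schedule.

Each family is expanded into its parent-offspring trios (parents are
duplicated, one copy per child).  In every MCMC round each family's children
are visited in a fresh random order; for each child-trio the father's
haplotypes are resampled from a copying HMM whose emission integrates the
whole trio's read data over the other parent's genotype and the child's
genotype under Mendelian transmission, then the mother is resampled
conditional on the father's sampled genotype, and finally the child's
haplotypes are set from the transmitted parental alleles (with a sampled
per-site transmission-slot switching process that lets the child's own reads
select crossovers).  Unrelated individuals are updated with the plain
diploid copying HMM.  Consensus haplotypes are the per-slot majority over
all sampled haplotypes after a crossover-minimizing slot alignment.

Ordered-genotype convention: each parent's ordered haplotype pair designates
the first slot as transmitted to the current trio's child, so
``transmit`` reads first-slot alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels, ld_hmm
from .formats_io import LikelihoodMatrix, PanelMatrix, PedigreeGraph, Individual
from .ld_hmm import ConditioningSet, ModelParams

logger = logging.getLogger(__name__)

FLAT = np.ones(3)


def transmit(
    father_ordered: tuple[int, int], mother_ordered: tuple[int, int]
) -> tuple[int, int]:
    """Child genotype from ordered parental genotypes.

    The first slot of each parent's ordered genotype is the transmitted
    allele; the child receives (paternal transmitted, maternal transmitted).
    """
    return (father_ordered[0], mother_ordered[0])


@dataclass(frozen=True)
class TrioView:
    """One parent-offspring trio; indices address rows of the likelihood
    matrix.  The transmitted slot for each parent is slot 0 by convention."""

    father: str
    mother: str
    child: str
    father_idx: int
    mother_idx: int
    child_idx: int


@dataclass
class RoundSchedule:
    """MCMC round plan: ``n_rounds`` rounds, each with fresh uniformly random
    child orderings per family drawn from the master seed."""

    n_rounds: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")


@dataclass
class HaplotypeSampleStore:
    """Per-individual record of sampled ordered haplotypes across rounds.

    Parents appear once per trio per round (duplicated-parent samples are
    merged at consensus time); children and unrelated individuals once per
    round.
    """

    samples: dict[str, list[tuple[int, np.ndarray]]] = field(default_factory=dict)

    def append(self, iid: str, round_idx: int, hap_pair: np.ndarray) -> None:
        lst = self.samples.setdefault(iid, [])
        if lst and round_idx < lst[-1][0]:
            raise ValueError("rounds must be appended monotonically")
        lst.append((round_idx, hap_pair.astype(np.uint8, copy=True)))

    def individuals(self) -> list[str]:
        return list(self.samples)

    def rounds(self, iid: str, burn_in: int = 0, max_round: int | None = None):
        for r, h in self.samples[iid]:
            if r < burn_in:
                continue
            if max_round is not None and r >= max_round:
                continue
            yield h


# ---------------------------------------------------------------------------
# trio emissions


def trio_father_weights(
    lik_father: np.ndarray,
    lik_mother: np.ndarray,
    lik_child: np.ndarray,
    maternal_freq: np.ndarray,
) -> np.ndarray:
    """Ordered-genotype weights for the father's trio-factorized emission.

    W[i, g1, g2] = P(R_f | G_f) * sum over the mother's ordered genotype of
    P(R_m | G_m) P(R_c | G_c = transmit(g, g_m)) P(G_m = g_m), with the
    maternal prior taken as Hardy-Weinberg at the conditioning-set allele
    frequency.  Slot 0 of each ordered genotype is the transmitted allele.
    """
    m = lik_father.shape[0]
    q = np.asarray(maternal_freq, dtype=float)
    Qm = np.stack([1.0 - q, q], axis=1)  # (M, 2): P(maternal allele)
    # B[i, m1] = sum_{m2} q(m2) * P(R_m | m1 + m2)
    B = np.empty((m, 2))
    B[:, 0] = Qm[:, 0] * lik_mother[:, 0] + Qm[:, 1] * lik_mother[:, 1]
    B[:, 1] = Qm[:, 0] * lik_mother[:, 1] + Qm[:, 1] * lik_mother[:, 2]
    # inner[i, g1] = sum_{m1} q(m1) * P(R_c | g1 + m1) * B[i, m1]
    inner = np.empty((m, 2))
    inner[:, 0] = (
        Qm[:, 0] * lik_child[:, 0] * B[:, 0] + Qm[:, 1] * lik_child[:, 1] * B[:, 1]
    )
    inner[:, 1] = (
        Qm[:, 0] * lik_child[:, 1] * B[:, 0] + Qm[:, 1] * lik_child[:, 2] * B[:, 1]
    )
    W = np.empty((m, 2, 2))
    W[:, 0, 0] = lik_father[:, 0] * inner[:, 0]
    W[:, 0, 1] = lik_father[:, 1] * inner[:, 0]
    W[:, 1, 0] = lik_father[:, 1] * inner[:, 1]
    W[:, 1, 1] = lik_father[:, 2] * inner[:, 1]
    return W


def trio_mother_weights(
    lik_father: np.ndarray,
    lik_mother: np.ndarray,
    lik_child: np.ndarray,
    father_hap: np.ndarray,
) -> np.ndarray:
    """Ordered-genotype weights for the mother's update given the sampled
    father.

    W[i, g1, g2] = P(R_f | G_f = g_f) P(R_m | g1 + g2)
                   * P(R_c | G_c = transmit(g_f, g)), with the father's
    ordered genotype g_f fixed at his freshly sampled haplotypes (slot 0
    transmitted).
    """
    m = lik_mother.shape[0]
    idx = np.arange(m)
    gf_sum = father_hap[0].astype(np.int64) + father_hap[1].astype(np.int64)
    gf1 = father_hap[0].astype(np.int64)
    lf = lik_father[idx, gf_sum]  # (M,) constant per site
    W = np.empty((m, 2, 2))
    lc0 = lik_child[idx, gf1]       # child genotype gf1 + 0
    lc1 = lik_child[idx, gf1 + 1]   # child genotype gf1 + 1
    W[:, 0, 0] = lf * lik_mother[:, 0] * lc0
    W[:, 0, 1] = lf * lik_mother[:, 1] * lc0
    W[:, 1, 0] = lf * lik_mother[:, 1] * lc1
    W[:, 1, 1] = lf * lik_mother[:, 2] * lc1
    return W


def trio_emission_father(
    state: tuple[int, int],
    lik_father: np.ndarray,
    lik_mother: np.ndarray,
    lik_child: np.ndarray,
    maternal_freq: np.ndarray,
    templates: ConditioningSet,
    site: int,
    epsilon: float,
) -> float:
    """Scalar trio emission P(R-bar_i | S_f(i)) for one state at one site."""
    W = trio_father_weights(
        lik_father[site : site + 1],
        lik_mother[site : site + 1],
        lik_child[site : site + 1],
        np.atleast_1d(maternal_freq[site]),
    )[0]
    C = ld_hmm.copy_matrix(epsilon)
    x, y = state
    ax = templates.alleles[x, site]
    ay = templates.alleles[y, site]
    return float(np.einsum("g,gh,h->", C[:, ax], W, C[:, ay]))


def trio_emission_mother(
    state: tuple[int, int],
    lik_father: np.ndarray,
    lik_mother: np.ndarray,
    lik_child: np.ndarray,
    father_hap: np.ndarray,
    templates: ConditioningSet,
    site: int,
    epsilon: float,
) -> float:
    """Scalar emission P(R-bar_i | S_i, G_f) for the mother's update."""
    W = trio_mother_weights(
        lik_father[site : site + 1],
        lik_mother[site : site + 1],
        lik_child[site : site + 1],
        father_hap[:, site : site + 1],
    )[0]
    C = ld_hmm.copy_matrix(epsilon)
    x, y = state
    ax = templates.alleles[x, site]
    ay = templates.alleles[y, site]
    return float(np.einsum("g,gh,h->", C[:, ax], W, C[:, ay]))


def duplicate_parents(
    pedigree: PedigreeGraph, sample_index: dict[str, int]
) -> list[TrioView]:
    """Expand the pedigree into per-child trios (parents duplicated)."""
    trios = []
    for f, m, c in pedigree.trios():
        trios.append(
            TrioView(
                father=f,
                mother=m,
                child=c,
                father_idx=sample_index[f],
                mother_idx=sample_index[m],
                child_idx=sample_index[c],
            )
        )
    return trios


# ---------------------------------------------------------------------------
# pedigree manipulation helpers


def restrict_offspring(pedigree: PedigreeGraph, k: int) -> PedigreeGraph:
    """Keep the first ``k`` children (by id) of each family in their trios and
    detach the rest as unrelated singletons.

    With ``k = 1`` this reproduces the trio-mode configuration: one child per
    family forms a trio, remaining offspring are treated as unrelated.
    """
    out = PedigreeGraph()
    kept: dict[str, int] = {}
    for iid in sorted(pedigree.individuals):
        ind = pedigree.individuals[iid]
        if ind.father is None:
            out.individuals[iid] = ind
            continue
        used = kept.get(ind.fid, 0)
        if used < k:
            kept[ind.fid] = used + 1
            out.individuals[iid] = ind
        else:
            out.individuals[iid] = Individual(
                iid=iid, fid=f"{iid}_solo", father=None, mother=None, sex=ind.sex
            )
    out.validate()
    return out


# ---------------------------------------------------------------------------
# the caller


class FamilyCaller:
    """Joint LD + pedigree genotype caller.

    Parameters
    ----------
    likelihoods : LikelihoodMatrix
        P(R|G) triples for the sequenced samples.
    pedigree : PedigreeGraph
        Family structure; VCF samples absent from the pedigree are treated
        as unrelated singletons, pedigree members absent from the VCF get
        uninformative likelihoods.
    panel : PanelMatrix, optional
        External phased haplotypes appended to every conditioning set.
    params : ModelParams, optional
        Mosaic transition/error rates; defaults to constant 0.01 / 0.01.
    max_states : int
        Cap on the number of conditioning haplotypes per update.
    """

    def __init__(
        self,
        likelihoods: LikelihoodMatrix,
        pedigree: PedigreeGraph,
        panel: PanelMatrix | None = None,
        params: ModelParams | None = None,
        max_states: int = 100,
        seed: int = 0,
        adapt_params: bool = True,
        transmission_switch: float = 3e-4,
        samples_per_update: int = 3,
    ) -> None:
        self.pedigree = self._augment_pedigree(pedigree, likelihoods.sample_ids)
        self.sample_ids = list(likelihoods.sample_ids)
        n_extra = [
            iid for iid in self.pedigree.individuals if iid not in set(self.sample_ids)
        ]
        if n_extra:
            logger.warning(
                "%d pedigree members missing from the likelihood data are "
                "assigned uninformative likelihoods: %s",
                len(n_extra),
                ", ".join(n_extra[:8]),
            )
            flat = np.ones((len(n_extra), likelihoods.n_sites, 3))
            values = np.concatenate([likelihoods.values, flat], axis=0)
            self.sample_ids = self.sample_ids + n_extra
        else:
            values = likelihoods.values
        self.lik = np.ascontiguousarray(values, dtype=float)
        self.index = {iid: j for j, iid in enumerate(self.sample_ids)}
        self.n_samples, self.n_sites = self.lik.shape[0], self.lik.shape[1]
        self.panel = panel
        if panel is not None and panel.n_sites != self.n_sites:
            raise ValueError("panel site count does not match study sites")
        self.params = params or ModelParams.constant(self.n_sites)
        self.max_states = int(max_states)
        self.adapt_params = bool(adapt_params)
        # per-interval switch rate of the child's transmitted slot: above
        # the meiotic crossover rate so a few contradicting reads can
        # re-anchor the slot after a parental phase-switch error, but well
        # below the mosaic rate to preserve transmission coherence
        self.transmission_switch = float(transmission_switch)
        # extra haplotype draws per update (from the same forward matrices)
        # cheaply shrink the consensus vote noise at a fixed round count
        self.samples_per_update = max(1, int(samples_per_update))
        # per-round tallies for the empirical theta/epsilon re-estimation
        self._switch_events = 0.0
        self._switch_opps = 0.0
        self._copy_mismatches = 0.0
        self._copy_total = 0.0
        self._fbuf: dict[tuple[int, int], np.ndarray] = {}
        self.rng = np.random.default_rng(seed)

        self.trios_by_family = {
            fid: [
                TrioView(f, m, c, self.index[f], self.index[m], self.index[c])
                for f, m, c in tl
            ]
            for fid, tl in self.pedigree.trios_by_family().items()
        }
        self.singleton_ids = self.pedigree.singletons()
        # every sample outside the family being updated serves as a template
        # donor (individuals are updated conditional on all other samples'
        # current haplotype estimates)
        self._donor_idx = {iid: self.index[iid] for iid in self.sample_ids}
        self.haps = np.zeros((self.n_samples, 2, self.n_sites), dtype=np.uint8)
        self.store = HaplotypeSampleStore()
        self._round = 0
        self._init_haplotypes()

    @staticmethod
    def _augment_pedigree(ped: PedigreeGraph, sample_ids: list[str]) -> PedigreeGraph:
        out = PedigreeGraph(dict(ped.individuals))
        for sid in sample_ids:
            if sid not in out.individuals:
                out.individuals[sid] = Individual(
                    iid=sid, fid=f"{sid}_solo", father=None, mother=None, sex=0
                )
        out.validate()
        return out

    # -- initialization ----------------------------------------------------

    def _init_haplotypes(self) -> None:
        """Round-0 haplotypes: allele pairs drawn from likelihood-weighted
        per-site allele frequencies, ignoring LD."""
        L = self.lik
        norm = L.sum(axis=2)
        dosage = (L[:, :, 1] + 2.0 * L[:, :, 2]) / norm
        p = np.clip(dosage.mean(axis=0) / 2.0, 0.01, 0.99)  # (M,)
        w = np.empty((self.n_samples, self.n_sites, 4))
        w[:, :, 0] = L[:, :, 0] * (1 - p) * (1 - p)
        w[:, :, 1] = L[:, :, 1] * (1 - p) * p
        w[:, :, 2] = L[:, :, 1] * p * (1 - p)
        w[:, :, 3] = L[:, :, 2] * p * p
        cum = np.cumsum(w, axis=2)
        u = self.rng.random((self.n_samples, self.n_sites, 1)) * cum[:, :, -1:]
        choice = (u > cum[:, :, :3]).sum(axis=2)
        self.haps[:, 0, :] = choice // 2
        self.haps[:, 1, :] = choice % 2

    # -- conditioning sets -------------------------------------------------

    def _conditioning_set(self, exclude_family: str | None, exclude_iid: str | None = None) -> ConditioningSet:
        eligible = [
            j
            for iid, j in self._donor_idx.items()
            if (exclude_family is None or self.pedigree.individuals[iid].fid != exclude_family)
            and iid != exclude_iid
        ]
        return ld_hmm.build_state_space(
            self.haps,
            np.asarray(eligible, dtype=np.int64),
            self.panel,
            self.max_states,
            self.rng,
            eligible_ids=self.sample_ids,
        )

    # -- single updates ----------------------------------------------------

    def _sample_from_weights(
        self, weights: np.ndarray, templates: ConditioningSet
    ) -> np.ndarray:
        """Forward-filter, backward-sample a state path, then sample ordered
        haplotypes given the path.  Returns a (2, M) allele pair."""
        V = ld_hmm.emission_table(weights, self.params.epsilon)
        # single precision is ample for sampling and halves memory traffic;
        # the forward buffer is reused across updates of the same shape
        h = templates.n_haplotypes
        key = (self.n_sites, h)
        buf = self._fbuf.get(key)
        if buf is None:
            buf = self._fbuf[key] = np.empty((self.n_sites, h, h), dtype=np.float32)
        F, _ = _kernels.forward_pass(
            templates.alleles, V.astype(np.float32), self.params.theta, buf
        )
        draws = []
        row_sums = F.sum(axis=2)
        for k in range(self.samples_per_update):
            path = ld_hmm.sample_state_path(
                F, templates, self.params, self.rng, row_sums=row_sums
            )
            hap = ld_hmm.sample_haplotypes_given_path(
                path, None, templates, self.params.epsilon, self.rng,
                weights=weights,
            )
            draws.append(hap)
            if self.adapt_params and k == 0:
                h = templates.n_haplotypes
                self._switch_events += (
                    (path[1:] != path[:-1]).sum() / (1.0 - 1.0 / h)
                )
                self._switch_opps += 2.0 * (path.shape[0] - 1)
                idx = np.arange(path.shape[0])
                self._copy_mismatches += (
                    (hap[0] != templates.alleles[path[:, 0], idx]).sum()
                    + (hap[1] != templates.alleles[path[:, 1], idx]).sum()
                )
                self._copy_total += 2.0 * path.shape[0]
        return draws[0], draws

    def _update_singleton(self, iid: str) -> None:
        j = self.index[iid]
        cs = self._conditioning_set(self.pedigree.individuals[iid].fid, iid)
        W = ld_hmm.ordered_genotype_weights(self.lik[j])
        hap, draws = self._sample_from_weights(W, cs)
        self.haps[j] = hap
        for h in draws:
            self.store.append(iid, self._round, h)

    def _update_trio(self, trio: TrioView, cs: ConditioningSet) -> None:
        Lf = self.lik[trio.father_idx]
        Lm = self.lik[trio.mother_idx]
        Lc = self.lik[trio.child_idx]
        q = cs.allele_frequencies()

        # father: trio-factorized emission, then path + haplotype sampling
        Wf = trio_father_weights(Lf, Lm, Lc, q)
        fhap, fdraws = self._sample_from_weights(Wf, cs)

        # mother: conditional on the father's sampled ordered genotype
        Wm = trio_mother_weights(Lf, Lm, Lc, fhap)
        mhap, mdraws = self._sample_from_weights(Wm, cs)

        # child: transmitted alleles under a sampled slot-switching process
        cdraws = [
            self._sample_child(Lc, fhap, mhap)
            for _ in range(self.samples_per_update)
        ]

        self.haps[trio.father_idx] = fhap
        self.haps[trio.mother_idx] = mhap
        self.haps[trio.child_idx] = cdraws[0]
        r = self._round
        for fh, mh, ch in zip(fdraws, mdraws, cdraws):
            self.store.append(trio.father, r, fh)
            self.store.append(trio.mother, r, mh)
            self.store.append(trio.child, r, ch)

    def _sample_child(
        self, lik_child: np.ndarray, father_hap: np.ndarray, mother_hap: np.ndarray
    ) -> np.ndarray:
        """Sample the child's ordered haplotypes given both parents.

        A 4-state chain over (paternal slot, maternal slot) starts at the
        transmitted slots and switches per interval with the meiotic
        crossover rate; its emission is the child's read likelihood of the
        resulting transmitted genotype (with copy error epsilon per allele),
        so the child's own reads select within-family crossovers.
        """
        m = self.n_sites
        eps = np.broadcast_to(self.params.epsilon, (m,))
        C = ld_hmm.copy_matrix(eps)  # (M, 2, 2) [g, a]
        idx = np.arange(m)
        # P(child paternal allele a | slot tf): (M, 2 slots, 2 alleles)
        pf = np.stack(
            [C[idx, :, father_hap[0]], C[idx, :, father_hap[1]]], axis=1
        )  # (M, tf, g)
        pm = np.stack([C[idx, :, mother_hap[0]], C[idx, :, mother_hap[1]]], axis=1)
        # emission over joint slot state: sum_{af, am} pf pm L_c[af + am]
        Lc3 = lik_child
        Mc = np.empty((m, 4))
        for tf in range(2):
            for tm in range(2):
                val = (
                    pf[:, tf, 0] * pm[:, tm, 0] * Lc3[:, 0]
                    + (pf[:, tf, 0] * pm[:, tm, 1] + pf[:, tf, 1] * pm[:, tm, 0])
                    * Lc3[:, 1]
                    + pf[:, tf, 1] * pm[:, tm, 1] * Lc3[:, 2]
                )
                Mc[:, 2 * tf + tm] = val
        u = self.rng.random(m)
        sigma = np.full(max(m - 1, 0), self.transmission_switch)
        slots = _kernels.transmission_forward_sample(Mc, sigma, u)
        tf = slots // 2
        tm = slots % 2
        # transmit is deterministic: the child copies the transmitted
        # parental alleles exactly; the reads informed the slot path above
        return np.stack([father_hap[tf, idx], mother_hap[tm, idx]])

    # -- rounds ------------------------------------------------------------

    def update_family_once(self, fid: str) -> None:
        """One pass over a family: visit its child-trios in a fresh random
        order, updating father, mother and child per trio; later trios in
        the loop condition on the parents' just-updated haplotypes."""
        trios = self.trios_by_family[fid]
        order = self.rng.permutation(len(trios))
        cs = self._conditioning_set(fid)
        for k in order:
            self._update_trio(trios[k], cs)

    def run_round(self) -> None:
        """One MCMC round: families in file order with per-family random
        child ordering, then unrelated singletons."""
        for fid in self.trios_by_family:
            self.update_family_once(fid)
        for iid in self.singleton_ids:
            self._update_singleton(iid)
        self._round += 1
        if self.adapt_params and self._switch_opps > 0:
            self._reestimate_params()

    def _reestimate_params(self) -> None:
        """Empirical per-round update of flat theta and epsilon from the
        sampled mosaics: the observed template-switch fraction (corrected
        for same-template jumps) and the copy-mismatch fraction."""
        theta_hat = (self._switch_events + 0.5) / (self._switch_opps + 1.0)
        eps_hat = (self._copy_mismatches + 0.5) / (self._copy_total + 1.0)
        theta_hat = float(np.clip(theta_hat, 1e-4, 0.2))
        eps_hat = float(np.clip(eps_hat, 1e-3, 0.2))
        self.params = ModelParams(
            theta=np.full(max(self.n_sites - 1, 0), theta_hat),
            epsilon=np.full(self.n_sites, eps_hat),
        )
        self._switch_events = self._switch_opps = 0.0
        self._copy_mismatches = self._copy_total = 0.0

    def run(self, n_rounds: int = 100) -> HaplotypeSampleStore:
        for r in range(n_rounds):
            self.run_round()
            if (r + 1) % 20 == 0:
                logger.info("completed round %d/%d", r + 1, n_rounds)
        return self.store


def run_mcmc(
    likelihoods: LikelihoodMatrix,
    pedigree: PedigreeGraph,
    panel: PanelMatrix | None = None,
    params: ModelParams | None = None,
    schedule: RoundSchedule | None = None,
    max_states: int = 100,
) -> tuple[HaplotypeSampleStore, "FamilyCaller"]:
    """Run the full MCMC and return the sample store (and the caller)."""
    schedule = schedule or RoundSchedule()
    caller = FamilyCaller(
        likelihoods,
        pedigree,
        panel=panel,
        params=params,
        max_states=max_states,
        seed=schedule.seed,
    )
    caller.run(schedule.n_rounds)
    return caller.store, caller


# ---------------------------------------------------------------------------
# consensus


def consensus_haplotypes(
    store: HaplotypeSampleStore,
    burn_in: int = 0,
    max_round: int | None = None,
    switch_cost: float = 1.0,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Merge sampled haplotypes into consensus calls.

    For each individual, every retained sampled pair is aligned to the
    running per-slot vote fractions by a two-state dynamic program that
    charges ``switch_cost`` per slot swap (the crossover-minimizing
    alignment).  Genotype posteriors are estimated from the sampled genotype
    frequencies; the called genotype is the most frequently sampled one, and
    within a called heterozygote the alternate allele goes to the slot with
    the larger aligned alt-vote share (so haplotypes and genotypes are
    always mutually consistent).

    Returns (haplotypes, posteriors): iid -> (2, M) uint8 and iid -> (M, 3).
    """
    haps: dict[str, np.ndarray] = {}
    posts: dict[str, np.ndarray] = {}
    for iid in store.individuals():
        retained = list(store.rounds(iid, burn_in, max_round))
        if not retained:
            raise ValueError(f"no retained rounds for {iid!r} after burn-in")
        m = retained[0].shape[1]
        votes = np.zeros((2, m))
        geno = np.zeros((m, 3))
        n = 0
        for h in retained:
            if n == 0:
                oriented = h.astype(np.int64)
            else:
                p0 = votes[0] / n
                p1 = votes[1] / n
                orient = _kernels.orient_viterbi(
                    h[0].astype(np.float64),
                    h[1].astype(np.float64),
                    p0,
                    p1,
                    float(switch_cost),
                )
                oriented = np.where(orient[None, :] == 0, h, h[::-1]).astype(np.int64)
            votes += oriented
            g = h[0].astype(np.int64) + h[1]
            geno[np.arange(m), g] += 1.0
            n += 1
        g_star = geno.argmax(axis=1)  # most frequently sampled genotype
        cons = np.zeros((2, m), dtype=np.uint8)
        cons[:, g_star == 2] = 1
        het_sites = g_star == 1
        alt_slot = (votes[1] > votes[0]).astype(np.uint8)
        cons[0, het_sites] = 1 - alt_slot[het_sites]
        cons[1, het_sites] = alt_slot[het_sites]
        haps[iid] = cons
        posts[iid] = geno / n
    return haps, posts
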
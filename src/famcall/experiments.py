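"""Reference simulation experiments for validating the family caller.

Two designs mirror the study conditions the method targets:

* **Nuclear-family cohort** (``scheme_one``): nuclear families of two
  founders and four offspring drawn from a coalescent haplotype pool,
  per-site reads at a given mean depth with Q20 bases.  Callers are compared
  using all four offspring per family versus trio mode (first child in a
  trio, remaining offspring treated as unrelated).
* **Small-sample cohort with an external panel** (``scheme_three``): two
  sequenced trios conditioned on a phased reference panel of founders from
  the same population (panel donors share no haplotypes with the study
  samples).

Desk-scale defaults: 25 families, a 200-haplotype coalescent pool over a
150 kb region thinned to 300 sites, 100-state conditioning cap.  Error
counts can be rescaled to a full-region site count for comparison with
region-scale benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import evaluation, family_engine, simulator
from .evaluation import EvalReport
from .formats_io import PanelMatrix


@dataclass
class ExperimentConfig:
    n_families: int = 25
    n_offspring: int = 4
    pool_haplotypes: int = 200
    n_sites: int = 300
    region_bp: int = 150_000
    base_quality: float = 20.0
    generator: str = "msprime"
    rounds_full: int = 100
    rounds_pair: int = 30       # paired mode comparison (both arms)
    rounds_fast: int = 30
    checkpoints: tuple[int, ...] = (20, 40, 60, 80, 100)
    max_states: int = 100
    # full-region site count used to express error counts per region
    region_sites: float = 2845.36


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit stream seeds from one master seed."""
    return [
        int(s.generate_state(1)[0] % 2**31)
        for s in np.random.SeedSequence(seed).spawn(n)
    ]


def _burn_in(rounds: int) -> int:
    return max(2, rounds // 10)


def simulate_cohort(
    cfg: ExperimentConfig, seed: int, depth: float,
    n_families: int | None = None, n_offspring: int | None = None,
    n_extra_founders: int = 0,
):
    """Pool + pedigree + reads for one replicate; returns (truth, lik)."""
    s_pool, s_ped, s_reads = spawn_seeds(seed, 3)
    pool = simulator.make_pool(
        cfg.pool_haplotypes, cfg.n_sites, s_pool,
        generator=cfg.generator, region_bp=cfg.region_bp,
    )
    truth = simulator.sample_pedigree(
        pool,
        cfg.n_families if n_families is None else n_families,
        cfg.n_offspring if n_offspring is None else n_offspring,
        s_ped,
        n_unrelated=n_extra_founders,
    )
    _, lik = simulator.simulate_reads(truth, depth, cfg.base_quality, s_reads)
    return truth, lik


def evaluate_store(
    store, truth, burn_in: int, max_round: int | None = None,
    eval_ids: list[str] | None = None,
) -> EvalReport:
    """Consensus calls from retained rounds of a sample store, evaluated
    against truth (genotype calls are the most frequently sampled genotype,
    phase from the aligned slot votes)."""
    keep = eval_ids or truth.sample_ids
    tidx = [truth.sample_ids.index(i) for i in keep]
    haps, posts = family_engine.consensus_haplotypes(
        store, burn_in=burn_in, max_round=max_round
    )
    called_geno = np.stack([posts[i] for i in keep]).argmax(axis=2)
    called_haps = np.stack([haps[i] for i in keep])
    return evaluation.evaluate(
        called_geno,
        called_haps,
        truth.haplotypes[tidx],
        truth.pedigree,
        keep,
    )


def call_and_evaluate(
    truth,
    lik,
    pedigree,
    seed: int,
    rounds: int,
    cfg: ExperimentConfig,
    panel: PanelMatrix | None = None,
    checkpoints: tuple[int, ...] | None = None,
    eval_ids: list[str] | None = None,
) -> dict[int, EvalReport]:
    """Run the caller and evaluate the consensus at one or more round
    checkpoints (a k-round checkpoint equals a k-round chain at this seed)."""
    caller = family_engine.FamilyCaller(
        lik, pedigree, panel=panel, max_states=cfg.max_states, seed=seed
    )
    store = caller.run(rounds)
    out: dict[int, EvalReport] = {}
    for cp in checkpoints or (rounds,):
        out[cp] = evaluate_store(
            store, truth, burn_in=_burn_in(rounds), max_round=cp,
            eval_ids=eval_ids,
        )
    out["store"] = store  # type: ignore[assignment]
    return out


@dataclass
class SchemeOneResult:
    """Per-seed metrics from the nuclear-family design."""

    four_by_round: dict[int, EvalReport]
    trio_pair: EvalReport       # trio mode at rounds_pair, for paired contrasts
    four_pair: EvalReport       # all-offspring mode at the same round count
    trio_deep: EvalReport       # trio mode at 10x, rounds_fast
    n_sites: int


def scheme_one(cfg: ExperimentConfig, seed: int) -> SchemeOneResult:
    s_sim, s_call1, s_call2, s_call3, s_call4 = spawn_seeds(seed, 5)
    truth, lik = simulate_cohort(cfg, s_sim, depth=2.0)
    ped4 = truth.pedigree
    ped1 = family_engine.restrict_offspring(ped4, 1)

    four = call_and_evaluate(
        truth, lik, ped4, s_call1, cfg.rounds_full, cfg,
        checkpoints=cfg.checkpoints,
    )
    # paired-mode contrast at a practical round budget on identical data;
    # the full chain's prefix IS a rounds_pair-round chain at this seed
    four_pair = evaluate_store(
        four["store"], truth, burn_in=_burn_in(cfg.rounds_pair),
        max_round=cfg.rounds_pair,
    )
    trio = call_and_evaluate(truth, lik, ped1, s_call2, cfg.rounds_pair, cfg)

    truth10, lik10 = simulate_cohort(cfg, s_sim, depth=10.0)
    trio10 = call_and_evaluate(
        truth10, lik10, family_engine.restrict_offspring(truth10.pedigree, 1),
        s_call3, cfg.rounds_fast, cfg,
    )
    four.pop("store")
    return SchemeOneResult(
        four_by_round=four,
        trio_pair=trio[cfg.rounds_pair],
        four_pair=four_pair,
        trio_deep=trio10[cfg.rounds_fast],
        n_sites=truth.pool.n_sites,
    )


@dataclass
class SchemeThreeResult:
    """Per-seed metrics from the external-panel design."""

    by_panel_size: dict[int, EvalReport]    # 2x coverage
    deep_panel: EvalReport                  # 6x coverage, largest panel
    n_sites: int


def scheme_three(
    cfg: ExperimentConfig,
    seed: int,
    panel_sizes: tuple[int, ...] = (10, 20, 40, 60),
    n_trios: int = 2,
) -> SchemeThreeResult:
    s_sim, s_reads6, *s_calls = spawn_seeds(seed, 2 + len(panel_sizes) + 1)
    max_panel = max(panel_sizes)
    # one joint draw, then split: panel donors never share pool haplotypes
    # with the study samples
    truth_all, lik_all = simulate_cohort(
        cfg, s_sim, depth=2.0, n_families=n_trios, n_offspring=1,
        n_extra_founders=max_panel,
    )
    study_ids = [i for i in truth_all.sample_ids if not i.startswith("U")]
    donor_ids = [i for i in truth_all.sample_ids if i.startswith("U")]
    truth = truth_all.subset(study_ids)
    keep = [truth_all.sample_ids.index(i) for i in study_ids]
    lik = type(lik_all)(values=lik_all.values[keep], sample_ids=study_ids)

    donors = truth_all.subset(donor_ids)
    by_size: dict[int, EvalReport] = {}
    for k, size in enumerate(panel_sizes):
        sub = donors.subset(donor_ids[:size])
        panel = PanelMatrix(
            alleles=sub.haplotypes.reshape(-1, sub.haplotypes.shape[-1]),
            haplotype_ids=[f"{i}.{h}" for i in sub.sample_ids for h in (0, 1)],
        )
        rep = call_and_evaluate(
            truth, lik, truth.pedigree, s_calls[k], cfg.rounds_fast, cfg,
            panel=panel,
        )
        by_size[size] = rep[cfg.rounds_fast]

    # 6x arm with the largest panel on the same pedigree
    _, lik6 = simulator.simulate_reads(truth, 6.0, cfg.base_quality, s_reads6)
    sub = donors.subset(donor_ids[:max_panel])
    panel = PanelMatrix(
        alleles=sub.haplotypes.reshape(-1, sub.haplotypes.shape[-1]),
        haplotype_ids=[f"{i}.{h}" for i in sub.sample_ids for h in (0, 1)],
    )
    rep6 = call_and_evaluate(
        truth, lik6, truth.pedigree, s_calls[-1], cfg.rounds_fast, cfg,
        panel=panel,
    )
    return SchemeThreeResult(
        by_panel_size=by_size,
        deep_panel=rep6[cfg.rounds_fast],
        n_sites=truth.pool.n_sites,
    )


def offspring_curve(
    cfg: ExperimentConfig,
    seed: int,
    depth: float = 2.0,
    ks: tuple[int, ...] = (1, 2, 3, 4),
    n_families: int = 20,
    rounds: int = 30,
) -> dict[int, EvalReport]:
    """Mismatch/Mendelian metrics as the number of offspring modeled per
    family grows, on identical data."""
    s_sim, *s_calls = spawn_seeds(seed, 1 + len(ks))
    truth, lik = simulate_cohort(cfg, s_sim, depth=depth, n_families=n_families)
    out: dict[int, EvalReport] = {}
    for k, s in zip(ks, s_calls):
        ped = family_engine.restrict_offspring(truth.pedigree, k)
        rep = call_and_evaluate(truth, lik, ped, s, rounds, cfg)
        out[k] = rep[rounds]
    return out


def region_scaled(count_per_site_block: float, n_sites: int,
                  cfg: ExperimentConfig) -> float:
    """Rescale an error count per n_sites to the full-region site count."""
    return count_per_site_block * cfg.region_sites / n_sites
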
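# Methods

## Genotype likelihoods

The observed data at a biallelic site are the genotype likelihoods
P(R|G) for G ∈ {hom-ref, het, hom-alt}. When computed internally from base
calls (`genolik`), each base matches the true allele with probability
1−e and reads as any specific other base with probability e/3; a
heterozygote draws each base from either allele with probability ½. Bases
matching neither study allele contribute e/3 under every genotype.
Computation is in log space with a final max-rescaling (likelihood ratios
are all the model uses); depth ≥ 30 would underflow on the linear scale.
Phred qualities convert as e = 10^(−Q/10) (Q20 → 0.01). VCF `PL` fields are
converted as 10^(−PL/10), `GL` as 10^GL, then max-rescaled; a sample record
with neither field becomes the uninformative triple (1, 1, 1). Multi-allelic
records and indels are out of scope and skipped.

## The diploid copying HMM

States are **ordered** template pairs (x, y); no collapsing to unordered
pairs, because ordered haplotypes carry the transmission semantics used by
the family engine. The copy-error model is per haplotype: a copied allele
differs from its template with probability ε, independently per slot. This
yields P(G|S) rows ((1−ε)², 2ε(1−ε), ε²) from homozygous template pairs and
(ε(1−ε), (1−ε)²+ε², ε(1−ε)) from heterozygous ones; each row sums to one,
which the flat-likelihood identity P(R flat|S) = 1 requires. The transition
kernel factorizes per haplotype, t(w|x) = (1−θ)·1(w=x) + θ/H, so a
forward or backward step costs O(H²) per site via row/column sums rather
than O(H⁴).

Forward matrices are kept normalized only up to a per-site scale (the log
of the accumulated scales is the data log-likelihood), which keeps the
forward pass to one fused sweep per site. Posterior decoding
(`forward_backward`, `genotype_posterior`) runs in double precision; the
MCMC sampling path (forward filtering + backward path sampling) runs the
forward matrices in single precision, which is ample for sampling and
halves memory traffic. Backward path sampling exploits the same
factorization to draw each step in O(H). An all-zero emission row (total
likelihood underflow) raises immediately rather than propagating NaNs.

### θ and ε

Defaults are flat θ = 0.01 per interval and ε = 0.01, and by default both
are re-estimated after every MCMC round from the sampled mosaics
(MaCH-style): θ from the fraction of template-index changes between
adjacent sites, corrected for the (1−1/H) probability that a jump lands on
a different template, and ε from the fraction of sampled alleles that
disagree with their template. Estimates are clipped to [1e−4, 0.2] and
[1e−3, 0.2] and include a half-count prior. Re-estimation matters: on
coalescent-like data the stationary values are typically ~3e−3, and fixing
0.01 costs about a third of the heterozygous-call accuracy at 2x. Setting
`adapt_params=False` (CLI: fixed `--theta/--epsilon`) freezes the values.

### Conditioning sets

Each individual is updated conditional on all the other samples' current
haplotype estimates: templates for an update are the sampled haplotypes of
every individual outside the family being updated, plus any external
panel. If the union exceeds `max_states` (default 100) a seeded uniform
subset is used. Fewer than two eligible templates is a hard error with the
advice to supply a panel — the small-sample regime is exactly what panels
are for.

## Family engine

Parents are duplicated per child: a family with n children contributes n
trios per round, visited in a fresh uniformly random order each round
(families themselves in file order; exchangeability makes that order
irrelevant). The father's update integrates the whole trio's reads over the
mother's ordered genotype (Hardy–Weinberg prior at the conditioning-set
allele frequency with a half-count correction) and the child's genotype
under transmission; the mother's update conditions on the father's freshly
sampled ordered genotype. Each parent's ordered pair designates slot 0 as
transmitted to the current trio's child, making `transmit` deterministic.

The child's haplotypes are then copied exactly from the transmitted
parental alleles (transmit is deterministic) through a 4-state chain over
(paternal slot, maternal slot): it starts at the transmitted slots and
switches per interval with probability `transmission_switch` (default
3e−4). That rate sits deliberately between the meiotic crossover scale
(~1e−5 per interval at ~500 bp spacing and 1 cM/Mb) and the mosaic θ
(~3e−3): the chain must stay rigid enough to preserve transmission
coherence, yet able to re-anchor the transmitted slot when a parental
phase-switch error contradicts the child's reads — with a purely meiotic
rate the child's reads are nearly powerless, and at mosaic scale the slot
wanders. The chain's emission is the child's read likelihood of the
implied genotype with per-allele copy error ε, so child reads place the
switches. Multi-generational families need no special casing: every
parent–offspring triple is a trio, and middle-generation individuals are
updated both as child and as parent within a round, always using the
latest haplotypes.

Unrelated samples (including pedigree-less VCF samples and trio-mode
"detached" offspring) are updated with the plain diploid HMM each round.
Pedigree members missing from the data receive uninformative likelihoods so
the trio machinery stays uniform.

Initialization samples each individual's allele pair from
likelihood-weighted per-site allele frequencies, ignoring LD.

## Consensus

Every sampled haplotype pair votes for the consensus: by default each
update draws `samples_per_update = 3` pairs from the same forward matrices
(extra draws are cheap once the backward sampler runs in O(H) per site and
they shrink the vote noise at a fixed round count), and duplicated parents
contribute one set of draws per trio per round. Each pair is aligned to the
running per-slot vote fractions by a two-state Viterbi over keep/swap with
switch penalty 1 — the linear-cost crossover-minimizing alignment; a global
slot swap therefore costs nothing. Genotype posteriors are the sampled
genotype frequencies (orientation-invariant); the called genotype is the
most frequently sampled one, and within a called heterozygote the
alternate allele goes to the slot with the larger aligned alt-vote share,
so haplotypes and genotypes are always mutually consistent (independent
per-slot majorities could combine into a genotype nobody sampled).
`burn_in` (default 0) discards early rounds; the reference experiments use
rounds/10, which mainly cleans up phasing — pre-convergence rounds
otherwise vote noisy phase into the alignment.

## Simulator

The cohort generator draws founder haplotypes from a pool without
replacement, transmits to offspring with crossovers as a Poisson process on
a uniform 1 cM/Mb genetic map, and simulates per-site reads: depth ~
Poisson(mean), bases drawn from the true genotype (fair coin for hets),
flipped to a uniformly chosen other base with probability 10^(−Q/10).
Truth is Mendelian-consistent by construction up to recorded crossovers.

Two pool backends exist. The **mosaic resampler** (default; no external
dependency) builds haplotypes as recombining mosaics (switch rate
0.02/interval) of 20 seed haplotypes drawn from a 1/p frequency spectrum,
with 0.002 per-site mutation; it has genuine distance-decaying LD and is
used throughout the unit tests. The **msprime coalescent backend**
(Ne = 10⁴, μ = r = 1e−8) produces substantially stronger, more realistic
LD — with identical machinery and true templates, 2x heterozygous decoding
error is ~3% on coalescent pools versus ~15% on mosaic pools — and is what
the reference experiments use, since they emulate cohorts drawn from a
coalescent population. What passing tests on either generator do **not**
show: robustness to alignment artifacts, indels, batch effects in base
qualities, or population structure between panel and study samples.

## Reference experiments and problem sizes

The packaged experiments (`famcall.experiments`, driven by
`scripts/acceptance.py` and the acceptance tests) run at desk scale, chosen
as the package's own trade-off between statistical resolution and runtime:
25 nuclear families × 4 offspring (20 in the offspring-count sweep), a
200-haplotype coalescent pool over 150 kb thinned to ≤300 sites, 100-state
cap, Q20 reads, five replicates; 100 rounds for the convergence ladder and
30 rounds elsewhere, with burn-in rounds/10. Mode contrasts (trio vs
all-offspring) are computed at a 30-round budget on identical data — at
full convergence on a 300-site window the LD information from ~100
templates dominates and the modes nearly coincide, whereas the
multi-offspring advantage is largest while chains are still converging
(parents' haplotypes must reflect transmission to every child).
Mendelian-error counts are rescaled to a 2,845-site region when compared
against full-region benchmarks, and the tiny external-panel cohort (2
trios) is run with twice the replicates of the family cohort so that a
single unlucky replicate does not dominate its means.

One deliberate caveat: at this scale and a 30-round budget, the
heterozygous-mismatch gain from modeling all four offspring rather than one
is within replicate noise (the Mendelian-error and switch-error gains are
not); the advantage on heterozygous calls emerges with longer chains, as
the 20–100-round ladder shows. Two desk-scale effects work against the
short-chain contrast: trio-mode's detached children sit in their own
family's conditioning sets (a much larger fraction of the template pool
than at realistic cohort sizes), and over a 300-site window LD from ~100
templates nearly saturates heterozygous accuracy.

## Known limitations

- Biallelic SNVs only; no BAM/CRAM pileup extraction, no indels.
- ε and θ are flat across sites (per-site vectors are supported internally
  but no per-site estimator is provided).
- Consensus genotypes of parents and children are voted independently, so
  a small residual Mendelian-error rate can survive consensus even though
  every individual round is transmission-consistent by construction.
- The duplicated-parent factorization is an approximation to the joint
  family posterior; a whole-family state space would be exact but grows
  exponentially in family size.
- Chromosome X and imputation at panel-only sites are out of scope.
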
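# Methods

`crossbreedsim` forward-simulates a two-breed cattle crossbreeding program
for smallholder farming systems: a locally adapted taurine breed selected
for tick resistance, an exotic indicine breed under long-term genomic
selection for body weight, and six strategies for combining them on a
village-structured farm population. This note documents the model, its
parameters, the deliberate design choices, and what the simulator does and
does not emulate.

## Genome and founder model

The genome is 30 chromosome pairs of 1 Morgan each (the genetic length is
not part of the study design; 1 M/chromosome is the standard default for
cattle-like simulated genomes). Each chromosome carries 300 QTL and 1400
SNP-array markers placed uniformly at random, 51,000 biallelic loci in all.
QTL carry the trait effects; the SNP panel is what selection and the
genomic-inbreeding metric can see.

Founders are generated from a calibrated divergence model rather than a
coalescent. Ancestral allele frequencies are drawn from a truncated
symmetric Beta(0.5, 0.5) on [0.05, 0.95] — a U-shaped proxy for a folded
neutral frequency spectrum, bounded away from fixation — and each breed
receives an independent Balding–Nichols drift step with parameter
`DEFAULT_DIVERGENCE = 0.815`, calibrated once by bisection so that the mean
per-site Nei G_ST between the founder breeds is ~0.41, the divergence
reported between African taurine and Asian indicine cattle. Loci
monomorphic in the pooled founders are redrawn, so all 51,000 loci
segregate. Founder haplotypes are drawn at linkage equilibrium given breed
frequencies; linkage disequilibrium then accumulates during the
20-generation burn-ins, which is also what the full-scale
program itself relies on for trait- and breed-specific LD.

Fst is computed per site as (H_T − H_S)/H_T from equally weighted breed
allele frequencies and averaged arithmetically over sites segregating in
the pooled sample. The estimator choice matters: with the per-site mean
pinned at 0.41, the drift required is strong enough that the expected
heterozygosity of a first cross between the breeds is ~0.50 for *any*
Beta-shaped ancestral spectrum (the segregating-site conditioning enriches
for diverged loci). A coalescent founder process with post-split private
rare variants could produce the same mean Fst with less first-cross
heterozygosity; this is the main fidelity limitation of the replacement
model, and it propagates into the crossbred inbreeding level at the first
cross (~50% homozygous SNPs here, versus the published reference of 57.5%
for this breeding design).
Between-breed Fst also *grows* through the burn-in under drift and
divergent selection (to ~0.55 at reduced scale); a decline to 0.3 — the published
estimate for this breed pair after selection — is not reproducible by any forward
drift+selection process starting from 0.41.

## Traits

Four polygenic traits share the same 9000 QTL: body weight (BW, kg) and
tick-count incidence (TC = −log10 tick count, higher is better), each
expressed in a local (L) and an exotic (E) environment. Founder targets:

| trait | mean | V_p | V_a | h² | dominance degree |
|-------|------|-----|-----|-----|------------------|
| BW_L | 325 | 1300 | 390 | 0.3 ± 0.03 | N(0.2, 1) |
| TC_L | −1 | 0.2 | 0.02 | 0.1 ± 0.01 | N(0.2, 1.2) |
| BW_E | 450 | 625 | 187.5 | 0.3 ± 0.03 | N(0.2, 1) |
| TC_E | −1.5 | 0.2 | 0.02 | 0.1 ± 0.01 | N(0.2, 1.2) |

Additive effects a_i are multivariate normal across the four traits with a
separable correlation structure: corr(BW, TC) within an environment is the
scenario's r_g, corr of the same trait across environments is the GxE
parameter r_gxe, and the unstated cross terms are r_g·r_gxe — the minimal
completion, positive semi-definite over the whole scenario grid. Each
trait's effect column is rescaled by a scalar (correlation-preserving) so
the realized additive variance in the trait's reference breed equals the
target; intercepts are set so the realized founder mean of the total
genetic value equals the target mean.

Dominance effects are d_i = |a_i|·δ_i with dominance degrees δ drawn from
the same 4×4 correlation structure, mean 0.2 and variance 1 (BW) or 1.2
(TC). Genotypes are coded 0/1/2 with additive value Σ a_i(x_i − 1) and
dominance value Σ d_i·1[x_i = 1]; the positive mean degree produces
directional heterosis. Residual variances are set from realized additive
variance, Ve = Va(1 − h²)/h², residuals drawn i.i.d. normal per animal and
trait, and a whole trait draw is rejected and resampled when the realized
founder heritability leaves the acceptance band (this rejection is part of
the study design). Note the realized phenotypic variance exceeds the
nominal V_p by the dominance variance the degree spread implies (~25–30%
for BW); the identity that holds exactly is Va_realized + Ve = V_p.

## Breeding engine

Meiosis is Haldane: crossover counts Poisson(chromosome length), positions
uniform, no interference; each offspring takes one fresh gamete from each
parent. Cohorts are sexed exactly 50/50 by permuting a balanced label
vector — within farms for farm-born cohorts, so small herds never run out
of either sex by chance. One offspring per cow per mating; repeated use of
a sire models semen distribution. Phenotypes exist only for the traits of
the animal's environment.

## Pure-breeding burn-ins (G1–G20)

*Local breed:* expansion to 10,000 animals/generation — in the first five
generations every available cow is mated (which grows the population to
the cap); thereafter the top 10,000 cows on TC_L phenotype are selected.
Cows come from the last five cohorts, 200 bulls (TC_L phenotype) from the
last two; mating is random. *Exotic breed:* 2,000 animals/generation; each
generation a ridge-regression (RR-BLUP) marker model is trained on all
animals of the last five cohorts and the top 2,000 cows (five-cohort
window) and 50 bulls (two-cohort window) on genomic EBV are mated at
random. The exotic herd continues under the same rule to G40 when a
strategy imports exotic semen. The exotic cow window is not part of the
published design and mirrors the local rule, a design choice.

RR-BLUP: marker dosages over the SNP panel only, column-centered;
ĝ = (ZᵀZ + λI)⁻¹Zᵀ(y − ȳ) with λ = (1 − h²)/h² · Σ_j var(Z_j), using the
known simulated h² = 0.3 (no REML — truth is available in simulation). The
mathematically identical n×n dual solve is used when training animals are
fewer than markers. Ties in any truncation selection break by ascending
animal id, for reproducibility.

## Farms, villages and the crossbreeding strategies (G21–G40)

200 farms with herd sizes Uniform{8..40} (the size vector is resampled
until the total is 4000–5000 cows) are allocated 20 per village to 10
villages. Foundress cows are drawn from the most recent local cohorts —
G20 alone at full scale, reaching back a generation at a time when a
reduced profile's G20 cohort is too small — and the whole structure is
frozen per replicate and shared by all strategies, which also share the
identical burn-in state.

G21 (all strategies): 50 EBV-selected exotic bulls, five per village, each
serving four farms; every cow produces one crossbred offspring, phenotyped
in the local environment.

*Synthetic schemes* (closed crossbred population; selection on the index
I = BW_L + v_TC·TC_L): each generation, bulls from the last two cohorts
are ranked on the index within the scheme's pool and allocated —
FB: the best bull of each farm mates its own farm; IVB: the best five per
village, randomly allocated within the village; EVB: the best five per
village v_i, allocated to the farms of a partner village v_j ≠ v_i drawn
as a uniformly random derangement each generation; PWB: the best 50
population-wide, each to four random farms. Cows: each farm's best
index females from the last five cohorts, up to herd size. In the first
crossbred generations fewer females exist than the herd size; the
shortfall is tolerated and cohorts recover within a few generations as the
window fills (single-generation replacement is arithmetically impossible
with one offspring per cow and 50% female cohorts).

*Rotation:* crossbred cows (index selection as above) are mated to local-
nucleus bulls at even generations and exotic-nucleus bulls at odd ones
(the G21 exotic cross anchors odd parity); 50 bulls from the source
nucleus's last two cohorts, five per village. The local nucleus is a
closed 2,000-cow herd founded from the best G16–G19 cows, selected on
TC_L phenotype with 50 bulls per generation.

*Terminal F1:* a pure local line is maintained on the farms (cows selected
on TC_L phenotype within farm, five-cohort window; five local bulls per
village from the line's last two cohorts — the burn-in supplies the first
set). Each selected cow produces two offspring per generation, one by an
EBV-selected exotic nucleus bull (the F1, evaluated but never bred) and
one by a local bull (the replacement). The local line doubles as the pure
local comparison population.

## Metrics

Per generation and strategy: phenotypic means; additive genetic variance
(variance of additive genetic values — truth, not an estimate); genomic
inbreeding F = 100·(homozygous SNPs)/(total SNPs) over the 42,000-marker
panel (QTL stand in for unobserved causal loci and are excluded); mean TBV
and dominance deviation, both defined as deviations from the mean of the
merged G21–G40 population of the strategy. The dominance deviation is the
biological dominance value (sum of d over heterozygous QTL),
deviation-centered — not the frequency-weighted statistical dominance
deviation. Phenotypic and genetic gains are OLS slopes of per-generation
means on generation index. Replicates aggregate by arithmetic mean and SD.
The analytic heterosis oracle Σ_i d_i(p_i^L − p_i^E)² is used to verify the
simulated F1 lift and the ~50% dominance drop from F1 to F2.

## Scale profiles and problem sizes

The `full` profile is the study design itself. The shipped `reduced`
profile — used by the tests, the analysis drivers and the acceptance
script — preserves every structural ratio (bulls:cows at 2–2.5%, cows
selected at 40%, farms per village, four farms per bull, window lengths,
herd sizes 8–40) at one tenth of the animal numbers and one fifth of the
genome: 10 chromosomes × (60 QTL + 280 SNP), 400+100 founders per breed,
local cohort 1,000, exotic cohort 400, 40 farms in 5 villages (total
800–1,000 cows), 10/2/2 bulls for the population-wide/village/initial
allocations, nucleus 200 cows + 5 bulls. Because per-farm herd sizes are
unchanged, within-farm drift and inbreeding dynamics match the full
design; population-level selection responses are noisier but unbiased. A
replicate of the full pipeline runs in about a minute on one CPU; the
experiments use 5–10 replicates.

Two fine-grained full-scale contrasts do not survive the down-scaling.
First, the advantage of village-exchanged bulls (EVB) over population-wide
bulls (PWB) — a within-family-versus-mass-selection effect — is smaller
than the replicate noise at 10 reduced replicates: EVB leads for body
weight but the two schemes are statistically tied for tick count. Second,
with five small villages the between-village allele-frequency divergence
grows fast enough that bull exchange regenerates measurable heterosis
every generation, so in EVB/PWB the mean dominance value drifts slightly
upward over G22–G40 and the phenotypic gain can marginally exceed the
genetic gain, whereas the closed FB and IVB schemes show the expected
phenotypic-below-genetic pattern. Both are properties of the reduced
conditions, not of the implementation, and are asserted as-is (and fail)
in the acceptance suite.

## Numerical and procedural choices

- Hierarchical seeding: master seed → (scenario, replicate) → named stage →
  strategy, via `numpy` SeedSequence spawning; distinct replicates never
  share streams, and every strategy within a replicate starts from the
  byte-identical G20 state.
- Trait-draw rejection retries with fresh stage seeds, bounded at 25
  attempts (observed acceptance is ~always on the first draw; the band is
  wide relative to the sampling noise of the realized residual variance).
- Selection ties break by ascending id; derangements are sampled by
  rejection (expected < 3 tries); bull-to-farm partitions permute farms
  and deal them round-robin.
- Degenerate inputs error loudly: same-sex matings, selection shortfalls
  (with scheme and generation named), empty populations, non-{0,1,2}
  genotypes, zero-SNP inbreeding.

## What the generator emulates, and what it does not

The founder model reproduces the allele-frequency divergence and fully
segregating locus set the downstream program uses, and the burn-in
reproduces the printed selection responses (TC_L gain ~0.03/generation;
BW_E gain ~7.4 kg/generation reaching ~600 kg, at reduced scale ~6–7 kg
and ~570–580 kg). It does **not** emulate coalescent LD in founders,
post-split private rare variants, or mutation — with three visible
consequences documented above: first-cross homozygosity sits near 50%
rather than 57.5%, between-breed Fst rises rather than falls through the
burn-in, and realized phenotypic variance exceeds nominal V_p by the
dominance variance. Passing tests therefore demonstrate the comparative
behaviour of the breeding strategies (orderings, trajectories, heterosis
accounting), not sequence-level realism of the founder genomes.

Epistasis (and with it recombination loss), maternal effects, mortality
and fertility variation, gestation timing, and economic accounting are out
of scope by design.
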
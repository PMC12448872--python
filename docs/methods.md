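# Methods

`mrdenrich` models a variant-selective hybridization-capture assay: bait
probes hybridize across patient-specific variants, and an enzymatic
digestion-and-release step frees only molecules that match the probe
perfectly, so the alternate (variant) allele is strongly enriched over the
wild-type allele before sequencing. This note describes the statistical
models, the synthetic-data generator that stands in for sequencing runs, the
numerical choices, and the limits of what the simulations demonstrate.

## Molecule counting

Reads are grouped into *read bundles* — one bundle per original input
molecule — by exact fragment breakpoints plus UMI similarity. UMIs within a
breakpoint group are clustered on the Levenshtein-distance adjacency graph
with threshold ≤ 2 edits (the field's standard collapse distance): seeds are
taken in descending read count and absorb every UMI reachable through a
chain of pairwise distances within the threshold, so the partition equals
the transitive closure of the adjacency relation. This chain-following
variant of directional adjacency was chosen because it is order-independent
and exactly reproducible by a brute-force all-pairs oracle; with realistic
UMI diversity, chains longer than one hop are rare and the partition matches
plain greedy absorption.

Per strand, a bundle's consensus allele requires a ≥ 2/3 majority of the
strand's informative reads; ties and weaker majorities are ambiguous. A
bundle with concordant consensus on both strands is a **duplex** molecule;
consensus on exactly one strand makes a **single-strand** molecule.
Duplex confirmation suppresses strand-asymmetric errors, which is why the
two channels are modelled with separate error rates throughout.

## Selectivity

For recovered alternate molecules m, wild-type molecules w and input VAF f,

    S = (1 − f) m / (f w).

S is the ratio of allele-specific recovery fractions, hence independent of
f; per-probe values are the mean over samples with f ≥ 0.1% (w = 0 samples
are excluded — their S is undefined, and treating them as infinite would
make the mean meaningless). The panel-wide S_g applies the formula to counts
summed over probes within a sample — algebraically the alternate-count-
weighted harmonic mean of per-probe S — and then averages over samples.
The enrichment factor and relative sequencing amount follow as

    EF = S_g / (1 − f + f·S_g),    c_r = 1/EF,

giving the fraction of a non-selective assay's depth this assay needs.

## Background-error model

Per-site background counts in blank samples are modelled as Poisson with a
Gamma-distributed rate λ_e, stratified by substitution type and by channel
(duplex vs single-strand, never pooled). Two priors are available:

* type-level, moment-matched across probes of one type: α = μ²/σ²,
  β = μ/σ² with the population (1/N) variance convention (configurable);
* site-specific, the conjugate posterior of the counts at one site under a
  weak Gamma(0.1, 1) prior: α = 0.1 + Σxᵢ, β = 1 + N.

Marginalizing the Gamma rate turns the background count into a negative
binomial NB(r = α, p = β/(β+1)), which is used exactly — never a plug-in
rate — in thresholding, VAF inference and MRD calling. Microsatellite /
homopolymer-flagged probes are excluded from type-level fits because
polymerase slippage puts them far outside their substitution class.

## Per-variant detection

The per-variant false-positive budget is 1/(samples × variants) — e.g.
2.84 × 10⁻⁶ for 160 samples tracking 2199 variants — and the calling
threshold k* is the smallest count whose negative-binomial background tail
is within the budget. Probe performance r_p (expected alternate molecules
per unit copies × VAF) is calibrated by maximum likelihood on known-VAF
samples after subtracting the prior-mean background, floored at zero.
LoD95 inverts the Poisson detection-power curve
P(X ≥ k* | r_p·s·C·f + background mean) = 0.95 by bisection on f (absolute
tolerance 10⁻⁶, capped at 1; undefined for r_p = 0).

Input-VAF inference is a grid posterior: f on 500 log-spaced points over
10⁻⁷..1 with a flat prior on the grid, duplex and single-strand counts as
independent Poisson factors with channel rates r_p·d and r_p·(1−d) and their
own backgrounds marginalized exactly (convolution of the negative binomial
with the Poisson signal). A one-dimensional grid is deterministic, exact to
grid resolution, and removes any sampler tuning; the reported interval is
the central 95% of the discrete posterior. Cross-validation holds out whole
samples with seeded fold assignment so held-out predictions never use their
own sample for calibration.

## MRD calling

The sample-level model integrates all usable SNV probes (indels and
flagged probes excluded by default — their slippage-driven error rates
dominate the evidence). For MRD level θ, probe p contributes expected
signal θ·ρ_p·G·C split between channels, where ρ_p is a monotone logistic
link from the probe design score to end-to-end recovery (anchored so score
200 ↦ 0.40 × 0.47 ≈ 0.19), G the per-sample scaling (geometric mean of
control-probe ratios times input-mass ratios) and C the haploid copies.
Each channel's likelihood is the same negative-binomial-background /
Poisson-signal convolution as above; the single-strand channel's weight is
configurable (0 disables it) since the proper relative weighting of the
noisier channel is an open modelling choice.

The prior is a spike-and-grid: an explicit θ = 0 atom with mass 0.5 and the
remaining mass spread uniformly over 400 log-spaced levels 10⁻⁷..0.2.
Reported are P(θ > 0), the posterior median of θ | θ > 0 with a central 95%
interval, and a call at P(θ > 0) ≥ 0.99 — a threshold at which simulated
blank cohorts (200 blanks, 1620-probe panels) produce no positive calls
while dilution samples at 10 ppm are retained. A descriptive diagnostic
(total alternate duplex molecules, with the ~8-molecule blank background as
reference line) is reported but never used for calling.

## Quality control

A sample fails if any control probe returns fewer than 100 molecules (or if
control data are missing); failed samples are excluded from all downstream
statistics. Blank contamination is flagged when the aggregate alternate
duplex count exceeds 8 molecules **and** the phased-SNP ratio — molecules
carrying both the target variant and its linked germline SNP over variant
molecules covering the SNP site — exceeds 0.5. Both conditions are required
because elevated counts alone indicate background, and a high ratio on a
handful of molecules is within blank noise. Both thresholds are
configurable.

## Probe design

Candidates enumerate every (upstream, downstream) length pair around the
variant (optionally both strands); the variant's alternate allele sits
`upstream` bases from the 3′ end. Melting temperatures use unified
nearest-neighbour thermodynamics at 50 mM Na⁺ and 250 nM oligo; designs
below the Tm floor (default 65 °C) are rejected. Features: Tm, lengths, GC
content, variant offset from 3′, SNP-within-25-bp-of-3′ flag (a mismatch
near the 3′ end blocks the digestion step entirely), microsatellite /
homopolymer flag (run ≥ 6 or ≥ 3 tandem copies of a 2–6-mer; no standard
formal definition exists, so this one is explicit and configurable), and a
low-GC flag (< 35%, below which probes barely function).

The scorer is pluggable: anything mapping the feature matrix to scores. The
shipped default is a random forest trained at call time on simulator-
generated (features → recovery) data whose generative link encodes the
qualitative structure above; its held-out r² (~0.8 on the synthetic link)
is a property of that link, not a claim about real probes. Panel sampling
honours the 90/10 SNV/indel split, a configurable SNV substitution-type
mix, equal counts of the four indel classes, the ≤ 40 bp indel length cap,
and optional per-type median score thresholds; published score thresholds
from other scorers do not transfer, so threshold mode operates on the
active scorer's own scale.

## Synthetic-data generator

The generator emulates a tumour-informed MRD dilution experiment with the
structure the analysis assumes. Defaults: 1800 probes (90% SNV across six
substitution types with a lung-cancer-like mix, 10% indels split equally
across four classes), 20 000 pg input at 3.158 pg per haploid genome
(≈ 6333 copies), VAF levels 10% down to 1 ppm plus blanks, four replicates
per level, 40% library-preparation efficiency, 12.5% sample dropout.
Recovered alternate molecules per probe and sample are
Poisson(s·ε_p·C·f) — the Poisson approximation to Binomial(C, f) is
excellent at f ≤ 0.1 and C ≈ 6333 and keeps the generative and analysis
models conjugate — and wild-type Poisson(s·(ε_p/S_p)·C·(1−f)). Recovery
ε_p = 0.40 × logistic(score); true selectivity S_p is log-normal with
median 35 (matching observed per-probe medians); sample scaling s is
log-normal with median 1 (positivity and multiplicative error are the
minimal assumptions for sample-to-sample variability). Background error
molecules are Poisson with per-probe rates drawn once from substitution-
type Gamma priors whose means give blank cohorts a few duplex molecules
panel-wide; single-strand rates are 10× duplex (only "higher" is known;
the ratio is a free parameter). Each recovered molecule is duplex with
probability 0.5 — the true duplex fraction is unstated anywhere, so it is
an explicit free parameter. Dropout samples force one control probe below
100 molecules; contaminated blanks receive extra molecules carrying the
phased SNP. Read-level expansion gives each molecule unique breakpoints, an
8-nt UMI and a configurable number of reads per strand, with optional UMI
and base errors.

All randomness flows from one seed through named per-stage generators
(panel / counts / reads), so any stage can be regenerated independently and
fixed seeds give byte-identical outputs.

### What the simulations do and do not show

The generator reproduces the statistical skeleton — Poisson molecule
counts, score-linked probe variability, type- and channel-stratified
background, sample scaling, dropouts, contamination — but not sequence-level
reality: no alignment artefacts, no GC-dependent coverage bias beyond the
score link, no fragment-length structure, no correlated errors between
neighbouring sites, and probe scores that are draws rather than outputs of
the design pipeline. Passing tests therefore demonstrate internal
consistency (estimators recover the generating parameters; thresholds hold
their error budgets under the assumed model), not performance on real
sequencing data.

## Problem sizes

The test suite uses 40-probe cohorts for unit-level checks and a full
1800-probe panel (1620 usable SNVs) for the MRD dilution study: five levels
10⁻⁵..10⁻¹ in four replicates, site priors fitted on 32 independent blanks,
and 200 further blanks for specificity. Threshold error budgets are checked
on 10⁶ simulated blank draws per prior, LoD95 self-consistency on 10⁴
draws, and VAF-interval coverage on 600 posterior evaluations. These sizes
put every Monte-Carlo check several standard errors away from its
acceptance band.

## Known limitations

* The MRD likelihood treats probes as independent; shared sample-level
  noise beyond the scalar G is not modelled.
* LoD95 is solved at the median sample scale; scale uncertainty enters only
  through configurable dispersion, not jointly.
* The grid posterior's resolution (~71 points per decade) bounds the
  precision of reported levels and intervals.
* Indel probes are excluded from MRD scoring by default; panels dominated
  by indels need the type-level error model extended first.
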
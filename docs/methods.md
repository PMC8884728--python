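# Methods

This note records the models behind `straindyn`, the parameters that matter,
the design choices made where the design was genuinely open, and the limits
of what the synthetic-data tests demonstrate.

## Study design assumed by the pipeline

Communities are serially passaged microcosms: every transfer dilutes the
culture 1:D into fresh medium and regrowth to saturation adds log2(D)
generations (~6.64 at the default D = 100). Metagenomes are sampled at 8
evenly spaced transfers, so dynamics finer than ~37 generations are
unresolvable. "Species" are 16S-identical units tied to one reference genome
each; "strains" are genotypes within a species, visible only through SNP
allele-frequency trajectories.

## Variant filtering

A call survives if it is biallelic, has Phred quality ≥ 20 and local read
depth ≥ 10 (allele-frequency least count 10%), and — once detected — is
re-detected at every later time point until its species' abundance reaches
zero (the persistence rule; guards against mapping artifacts). The major
allele is fixed at first detection and tracked thereafter, which prevents
trajectory flips when frequencies cross 0.5. Reads mapping to genes with
anomalous coverage (< 0.5× the sample median, or > 3× the median in any
sample; both bounds strict, reading the rule literally) are excluded
upstream. Filters commute: the retained set is independent of application
order.

## Strain inference

Trajectories are clustered for k = 1, 2, 3 by k-means with a DTW assignment
distance (|a_i − b_j| local cost, no warping window). Centroids update as
pointwise means — all series share one time grid, so barycenter averaging
would add ambiguity without adding information. Inertia (sum of squared DTW
distances, best of 10 seeded restarts) selects among restarts; a candidate
clustering is rejected when any centroid pair is closer than an RMS
separation of 0.15 (in practice the third cluster always is, matching the
observation that at most two strains are statistically detectable). A
cluster whose centroid exceeds 0.9 at every time point is the shared
(reference-differentiating) cluster; the remaining non-fixed cluster
differentiates the two strains. Loose SNPs — DTW distance to their centroid
beyond both the 95th percentile and 2× the median of their own cluster's
distances — are reassigned to shared when nearly fixed, else left
unassigned. The cutoff is per cluster because cluster width scales with
binomial sampling noise, i.e. with allele frequency; and the 2×-median guard
keeps perfectly tight clusters from shedding a fixed 5% of members. The
UPGMA backend (average-linkage on Euclidean distances between rows of the
SNP-trajectory correlation matrix, cut at two clusters) gives the same
strain counts on the default synthetic cohort.

Strain frequency f(t) is the depth-weighted mean allele frequency of the
differentiating cluster; time points with zero total depth are marked
missing, never imputed. The strain carrying the cluster alleles is "major"
iff f ≥ 0.5 at the first informative time point.

## Null models

*Gamma interaction null.* Non-interacting members fluctuate as independent
gamma variates with each member's observed mean and variance (shape
β = x̄²/σ²), renormalized per time point; 1000 simulated communities pool all
pairwise |r| into one distribution. Because the pool spans every pair, the
empirical p-values (smoothed (k+1)/(n+1)) already reflect the number of
comparisons and no further correction is applied. Network density is
reported per node — interactions per member — not per possible edge.

*Strain-label permutation.* Within each community, strain trajectories are
re-paired into mock species (every trajectory used exactly once) and the
fraction F of species pairs whose best interspecific strain |r| beats the
species |r| is recomputed; the p-value is the smoothed tail probability of
F_obs under ≥ 1000 relabellings.

*Trajectory shuffles.* Eco-evolutionary influence (correlation between a
species' abundance and its major strain's frequency, signed r by default)
is called against shuffled species–strain pairings at the 95th percentile;
compositional variability uses group-preserving label shuffles.

## Consumer-resource models

Within a batch cycle, dN_α/dt = N_α (CR)_α and dR_i/dt = −R_i (CᵀN)_i with
unit yield, so biomass + resources are conserved (enforced to 1e-6
relative; LSODA with rtol 1e-8, stopping when ΣR < 1e-6 of the unit
supply). Consumption vectors are uniform on the unit simplex (fixed enzyme
budget — the assumption that lets more strains than resources coexist). A
conspecific partner at competitive distance D is placed by walking distance
D along the segment toward a random simplex point, drawn from progressively
sparser Dirichlet distributions until the segment is long enough; this
yields an exact Euclidean distance D, stays on the simplex by convexity,
and remains feasible for the mixture's large-D components (an isotropic
tangent step of length 1.0 from a typical point on the 30-simplex always
leaves it).

Communities assemble under the balanced medium (equal supply proportions,
total 1 biomass unit) until the end-of-cycle composition changes by less
than 1e-3 (L1) for 5 consecutive cycles, then run 48 further cycles with
supply noise, recording every 6th — an ~40-generation cadence mirroring the
experimental sampling interval. Supply noise is Gaussian *relative* noise of
variance 0.05 on each resource's proportion (clipped at zero,
renormalized). The printed noise magnitude could also be read as additive
on the proportions themselves (sd 0.22 against a mean of 1/30); that
reading randomizes the medium each transfer rather than perturbing it, and
the relative reading reproduces the observed ~31% median species-level
temporal CV, so relative is the default and `supply_noise_mode="absolute"`
stays selectable. Strains below 1e-12 biomass at cycle end are extinct.

Under the species-identical hypothesis the conspecific pair shares one
consumption vector, so species biomasses are integrated directly and the
within-species strain frequency is bookkeeping that moves only by neutral
drift: per generation, a Gaussian increment of variance v/N (default;
population-genetic scaling — rare species drift fastest) or v·N (the
literal alternative), clipped to [0,1] with *absorbing* boundaries. Absorption
matters: a lineage at frequency zero has no individuals and cannot
reappear, and it is neutral fixation — most species effectively
single-strain by sampling time — that gives the neutral model its low
discrimination fraction. With resurrecting boundaries the fraction stays
above 0.77 across four decades of drift magnitude, because jittered copies
of a species trajectory almost always hand the max-of-four strain
correlations a win. Equilibrium detection under this hypothesis uses the
species composition (deterministic), since the strain split random-walks
every cycle.

The drift coefficient v is the one parameter fit to data in the original
study and not printed. The default v = 8e-6 comes from requiring the
neutral fixation timescale (~0.25·N/v generations from an even split) to be
comparable to the experiment's ~900 generations at a typical
surviving-species abundance of ~1/30. The discrimination fraction is steep
in v — roughly 0.78, 0.62, 0.51, 0.33, 0.15, 0.11 at v = 1e-6, 2e-6, 3e-6,
5e-6, 8e-6, 1e-5 under otherwise default conditions — so v effectively
selects how much of the strain pool is still segregating when sampling
starts; the default lands the neutral model in its reported regime.

With these conditions the strain-specific model yields a strain-dominant
fraction of 0.854 ± 0.005 over seeds and the neutral model 0.131 ± 0.017
(`scripts/acceptance.py` recomputes both). Conspecific coupling decreases
monotonically in D (≈1.00, 0.77, 0.39, 0.33 at D = 0.01, 0.1, 0.3, 1.0),
and reducing the resource count (e.g. 12 or 20 instead of 30) leaves the
hypothesis ordering unchanged.

## Synthetic cohort: what it does and does not emulate

The generator mirrors the study scale: 10 communities, 8 time points, ~10
species each, two strains per species, gamma-distributed abundance
fluctuations (CV 0.31), log-uniform differentiating-SNP counts (30–300),
shared SNPs near fixation (0.99), Poisson read depths with binomial
allele-frequency sampling, and strain-frequency processes (constant,
random-walk, driven logistic sweep). It does **not** emulate read-level
error, mapping bias or read stealing, linkage decay through recombination,
de novo mutation during the experiment, cross-community strain identity
(so compositional-variability statistics on the cohort only exercise the
machinery), or genuine cross-species strain interactions — strain
frequencies are generated independently of other species, so passing
recovery tests demonstrate estimator correctness, not that real communities
behave this way.

## Numerical choices and degenerate inputs

Empirical p-values never return 0 ((k+1)/(n+1) smoothing). Zero-variance
trajectories give undefined correlations: flagged, excluded from fractions
and distributions. Abundance columns within 1e-3 of unit sum renormalize;
larger deviations are errors. pN/pS uses Nei–Gojobori site counting without
a multiple-hit correction (it is a polymorphism ratio, not dN/dS); changes
to a stop codon count as nonsynonymous, reference stop codons contribute no
sites, and the ratio is flagged undefined when no synonymous change was
observed. Pseudogene strain assignment uses a tolerance of 0.1 — the
allele-frequency least count at the minimum read depth — at every time
point where the causal SNP is detected. Enrichment p-values are one-sided
upper tails, with category fractions computed from summed coding length.
Zero-depth Poisson draws in the depth model are bumped to one read so every
time point yields an observation.

## Problem sizes

The test suite runs the full study-scale discrimination experiment (both
hypotheses, five seeds, 10 communities each; ~3 minutes) plus unit and
property tests (~1 minute). Calibration tests use reduced replicate counts
(hundreds of permutations/simulations) chosen so that binomial sampling
error stays well inside the asserted tolerances.

## Known limitations

At most two strains per species are resolvable by design. The DTW k-means
assignment with pointwise-mean centroids assumes a shared time grid. The
persistence rule assumes per-time-point call sets are complete (a missing
VCF record is evidence of absence). The consumer-resource models omit
cross-feeding, non-unit yields, chemostat mode, and evolution of
consumption rates; the 78%/19%-style fractions are properties of the
stated scenario, and the neutral fraction in particular depends steeply on
the unprinted drift coefficient discussed above.
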
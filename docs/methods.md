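# Methods

`dietlink` implements a molecular diet-analysis workflow for generalist
predators: multiplexed amplicon reads from predator gut contents are
demultiplexed, cleaned and clustered into molecular operational
taxonomic units (MOTUs), assigned to prey taxa against a barcode
reference, reduced to a binary predator-individual × prey-taxon diet
matrix, and analysed with niche statistics, Monte-Carlo null models and
community summaries. A synthetic-data generator produces every input
with known ground truth, so the whole chain can be validated end to
end.

## The data model

All diet inference is presence/absence. Read counts from gut-content
amplicons confound biomass, digestion state, primer bias and PCR
stochasticity, so a predator individual is scored only as positive or
negative for each prey taxon. Consequences run through the whole
package: utilization vectors are proportions of positive individuals,
the prey-choice null generates sets of distinct taxa per gut, and
accumulation curves are incidence-based.

Cannibalism is structurally excluded: a predator's own species cannot
be distinguished from its gut contents molecularly, so the simulator
never draws it as prey and the diet-matrix builder drops own-species
detections. Predation between the two predator species (intraguild
predation) is retained.

## Sequence processing

**Demultiplexing.** Reads carry a 10-bp forward multiplex identifier
(MID) and forward primer at the 5' end and the reverse complements of
the reverse primer and reverse MID at the 3' end. A 16 × 15 MID design
yields 240 unique pair assignments. Matching is exact by default
(`max_mismatch=0`): generated MID sets have pairwise Hamming distance
≥ 3, so at low error rates an erroneous tag is far more likely to match
nothing than to match the wrong sample. Tags and primers are stripped
on assignment.

**Filtering and collapsing.** Templates of 260–300 bp (inclusive
bounds) are kept — the marker is ~287 bp — and each individual's reads
are collapsed to unique haplotypes, discarding haplotypes seen fewer
than 2 times, which removes most PCR/sequencing singleton artefacts.

**Pairwise identity.** Identity is defined once, for both clustering
and assignment: matching columns divided by total alignment columns
(gaps included) of an optimal Needleman–Wunsch alignment with match +1,
mismatch −1, gap −2. For equal-length sequences where the gapless
alignment attains the optimal score, identity reduces to Hamming
identity; this fast path (plus a cache keyed on the sequence pair) is
what makes the 11-threshold grid search affordable.

**MOTU clustering.** Greedy centroid clustering: haplotypes are
processed in decreasing total copy number (ties broken
lexicographically); each joins the first centroid with identity ≥ t,
otherwise founds a new cluster. Processing order is defined by content,
not input order, so clustering is deterministic and order-invariant.
The MOTU count is non-increasing as t decreases.

**Threshold selection.** Clustering is repeated for t = 0.97 down to
0.87 in steps of 0.01. The chosen threshold minimises the number of
species with more than one MOTU (chimeric MOTUs excluded), subject to
retaining a majority of species assignments; ties go to the higher
threshold. Two operationalisations were open:

* *"majority of species assignments"* = at least 50% of the maximum
  number of **distinct species** holding a species-rank assignment over
  the grid. Counting assigned MOTUs instead would reward over-splitting
  (every split MOTU still names the same species) and the rule could
  never prefer merging conspecific haplotypes, defeating its purpose.
* *chimera flagging*: a representative is chimeric when its two halves
  each best-match a different taxon by local alignment at ≥ 0.98
  identity. This split-best-hit screen is the simplest detector that
  catches single-breakpoint chimeras, which is exactly what the read
  simulator produces.

**Taxonomic assignment.** A MOTU representative is assigned only when
its best reference identity strictly exceeds 0.98. If the best hit is a
flagged contaminant record (human, bacterial, …) the MOTU is discarded
as a contaminant. When several hits fall within 0.5% identity of the
best, the assignment is made at the lowest taxonomic rank on which all
of them agree (species → genus → family → order), mirroring
lowest-common-ancestor consensus assignment.

## Diet statistics

With utilization vector p (proportion of positive detections per taxon,
Σp = 1) and n available prey taxa:

* **Levins' standardized niche breadth**
  B_A = (1/Σp² − 1)/(n − 1) ∈ [0, 1]; 0 = complete specialisation,
  1 = uniform use of all available taxa. "Available" is
  operationalised as taxa with nonzero kick-sample abundance in the
  stratum. Both pooled and per-stratum computation are exposed
  (`niche_statistics` takes arbitrary metadata groupings) since the
  statistic is legitimately reported either way.
* **Pianka's overlap** O_jk = Σ p_ij p_ik / √(Σ p_ij² Σ p_ik²) ∈ [0, 1],
  symmetric.
* **Selection strength** S = Σ_t |o_t − e_t| / (Σ_t o_t + Σ_t e_t),
  where o_t and e_t are observed and null-expected numbers of positive
  individuals. **Note on the denominator:** a description of this
  statistic as "divide by the total number of prey consumed" (i.e. by
  Σo alone) cannot satisfy the usual characterization that S = 1 when
  observed and expected supports are disjoint — with Σo = Σe that
  version reaches 2. The combined denominator Σo + Σe is the unique
  natural normalisation for which S = 0 iff o = e and S = 1 iff the
  supports are disjoint, and is what this package computes.

## Null models

**Niche-overlap randomization.** The default algorithm is RA3 (row
shuffle): each predator's utilization values are permuted across taxon
slots, conserving the value multiset — niche breadth is retained while
which taxa are used is randomized. RA2 (retain zero structure, redraw
nonzero values uniformly) is available by flag. RA3 is the default
because it conserves the marginal property (breadth) most relevant when
asking whether two predators use the *same* taxa. The reported
`proportion_exceeded` is the fraction of null overlaps strictly below
the observed overlap (with a 1e-9 tie tolerance so permutation-invariant
inputs count as ties); the complementary upper-tail fraction is reported
alongside rather than collapsing to a single one-sided p.

**Prey-choice null.** Under the null, prey are consumed in proportion
to their relative abundance. Each individual redraws its observed
number of *distinct* prey taxa by weighted sampling without replacement
(the presence/absence detections are distinct taxa by construction, so
the null must generate distinct-taxon sets). Implementation: Gumbel
top-k — add independent Gumbel noise to log-probabilities and take the
k largest keys — which is distributionally identical to sequential
weighted draws without replacement and vectorises over iterations
(verified against an explicit sequential sampler in the test suite).
Per taxon, the expected count is the null mean over iterations and the
95% confidence limits are the 2.5th/97.5th percentiles (linear
interpolation between order statistics). Classification: preferred if
observed strictly above the upper limit, avoided if strictly below the
lower, neutral otherwise — ties at a limit are neutral, the
conservative reading. Because counts are discrete, a closed interval
between empirical percentiles covers slightly *more* than 95%; with the
validation conditions used here (12 taxa, 80 individuals, truncated-
Poisson(4.5) gut sizes) the realised coverage is ≈ 0.96, within the
0.95 ± 0.02 band checked by the acceptance tests. Selection analyses
pool data across seasons at the site level by default.

## Community summaries

* **Bray–Curtis** on fourth-root-transformed counts (transform optional)
  via `scipy.spatial.distance.pdist`.
* **NMDS** in two dimensions by SMACOF majorization with isotonic
  regression (`sklearn.manifold.MDS`, nonmetric), 20 random restarts,
  best configuration returned with Kruskal stress-1; scores centred.
* **PERMANOVA** (one-way) via scikit-bio, p = (1 + #{F* ≥ F})/(1 + n_perm).
* **Vector fitting**: the covariate is regressed on the centred score
  matrix; r is the multiple correlation of the covariate with its best
  direction in ordination space, p by permutation of the covariate.
* **Accumulation curves**: exact mode uses the hypergeometric identity
  E[S_n] = Σ_t [1 − C(M−M_t, n)/C(M, n)] (computed in log space);
  permutation mode averages random orderings; the two agree within
  Monte-Carlo error. Total richness is estimated by bias-corrected
  Chao2, S_obs + ((M−1)/M)·q1(q1−1)/(2(q2+1)), which is defined even
  when no taxon occurs exactly twice. Efforts to reach 50%/90% coverage
  are reported against observed richness by default (a flag switches
  the denominator to the Chao2 estimate), both as the smallest whole
  number of individuals and linearly interpolated.
* **Rarefied richness** by the hypergeometric expectation.

## The synthetic-data generator

The generator emulates the study design the pipeline targets: ten
stream sites along a land-use intensity gradient, two co-occurring
invertebrate predators, kick-sample prey availability, and pooled
single-run amplicon sequencing.

* **Barcode reference**: taxon consensus sequences radiate from a
  common ancestor on a star phylogeny (branch length between/2 of
  sites); haplotypes carry within/2 substitutions off their consensus,
  so intra-taxon identity ≥ 1 − within is guaranteed and inter-taxon
  identity ≤ 1 − 0.7·between is enforced by redraw. Defaults: 287 bp
  marker, 10% between-taxon and 1% within-taxon divergence — typical
  CO1-like structure with a comfortable barcode gap. Two predator taxa
  and a human-like contaminant are always included.
* **Communities**: log-linear abundance response to centred intensity
  (increasing / decreasing / flat per taxon), negative-binomial noise
  (Gamma–Poisson, shape = `noise_dispersion`, default 5 — variance
  several times the mean, as typical for kick-sample counts);
  `noise_dispersion=None` gives the deterministic limit.
* **Guts**: the number of distinct prey taxa per gut is zero-truncated
  Poisson with mean 4.5 — matching the mean number of prey taxa
  detected per individual in field data of this kind; the per-gut item
  count is otherwise unobservable from presence/absence data, so this
  is a modelling stand-in, not an inference. Taxa are drawn without
  replacement with probability ∝ abundance × selection weight, own
  species excluded; weights of 1 recover the prey-choice null exactly,
  which is the basis of the coverage validation.
* **Reads**: each read is MID + primer + template + revcomp(primer) +
  revcomp(MID), with per-base substitution errors (no indels —
  homopolymer/indel error models are out of scope, keeping alignment
  identity well-defined on small fixtures), single-breakpoint chimeras
  with uniform breakpoints, predator self-DNA (default 3%, the order
  observed in real gut amplicon pools) and contaminant reads. A sidecar
  table maps every read to its gut and source taxon.

What the generator does *not* emulate: PCR amplification bias,
chimera-formation kinetics, quality-score structure, indel errors, and
secondary predation. Passing end-to-end tests therefore demonstrates
correctness of the analysis chain under a clean error model, not
robustness to every artefact of a real sequencer.

## Validation scale and determinism

Every stochastic component takes an explicit seed; pipelines are
byte-reproducible from their run manifest, and stage outputs are cached
by content digest. The validation suite runs at desk scale, chosen so
the statistical checks are sharp but cheap: null-model coverage uses
5,000 replicates of 80 individuals at 1,000 iterations; selection-weight
recovery uses 200 replicates of 10 sites × 10 individuals with weights
5 and 0.2; the read-level standard fixture is 50 guts × 200 reads;
PERMANOVA type-I error uses 1,000 null data sets at 199 permutations
(at which the achievable level is exactly 0.05). Production analyses
default to 10,000 null-model iterations.

## Known limitations

* Taxonomy assignment consensus uses the reference's lineage fields;
  references loaded from bare FASTA lack lineage above species, so
  multi-species ties fall back to no-match rather than a genus-level
  call.
* Greedy centroid clustering is order-defined, not globally optimal;
  this matches standard practice but means cluster boundaries near the
  threshold can depend on abundance ranks.
* One pooled read set is clustered per invocation; reconciling MOTU ids
  across separately clustered sequencing runs is out of scope.
* The prey-choice null conditions on observed per-gut richness; it
  cannot detect selection that manifests only through gut richness
  itself.
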
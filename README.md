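# dietlink

Molecular diet analysis for generalist predators, from raw multiplexed
metabarcoding reads of gut contents to prey-selection inference and
community summaries.

Who eats whom, and is it by choice? Gut-content metabarcoding answers
the first question: a short marker (here a ~287 bp CO1-style fragment)
is amplified from predator gut extracts, each individual tagged with a
forward/reverse multiplex identifier (MID) pair, and the pooled reads
are assigned back to individuals and to prey taxa. `dietlink`
implements the full analysis chain and the statistics needed for the
second question — whether predators consume prey in proportion to
availability or select among them:

- **seqproc** — demultiplex by MID pair, trim tags/primers, filter
  templates to 260–300 bp, collapse per-individual haplotypes (dropping
  <2-copy haplotypes), cluster molecular operational taxonomic units
  (MOTUs) by greedy centroid clustering over similarity thresholds
  0.97→0.87, pick the optimal threshold (fewest species split across
  MOTUs while retaining the majority of species assignments), and
  assign taxonomy by best reference hit at >98% identity with
  lowest-common-rank consensus for ties.
- **dietcore** — binary predator-individual × prey-taxon diet matrices
  (all analyses are presence/absence; own-species detections are
  dropped because cannibalism is molecularly unresolvable), utilization
  vectors, Levins' standardized niche breadth
  B_A = (1/Σp² − 1)/(n − 1), Pianka's overlap
  O_jk = Σp_ij p_ik / √(Σp_ij² Σp_ik²), and the selection-strength
  statistic S = Σ_t|o_t − e_t| / (Σ_t o_t + Σ_t e_t) ∈ [0, 1].
- **nullmodels** — Monte-Carlo inference: a randomized-utilization
  (RA3/RA2) null for Pianka overlap, and a proportional-abundance
  prey-choice null in which each individual redraws its observed number
  of distinct prey taxa with probability ∝ relative abundance, giving
  per-taxon expected counts, 95% confidence limits and a
  preferred/avoided/neutral classification.
- **community** — Bray–Curtis dissimilarity with fourth-root transform,
  nonmetric multidimensional scaling, PERMANOVA, permutation-tested
  gradient vector fitting, exact/permutation species accumulation
  curves, bias-corrected Chao2 total richness, and hypergeometric
  rarefied richness.
- **synthdata** — generates every input with known ground truth:
  barcode references with controlled within/between-taxon divergence,
  kick-sample-style abundance tables along a land-use intensity
  gradient, per-individual gut contents with taxon-level selection
  weights (weights of 1 recover the null), and noisy MID-tagged reads
  with substitution errors, chimeras, predator self-DNA and
  contaminants.
- **pipeline / CLI** — a seeded, digest-cached end-to-end run
  (`dietlink run --config run.yaml`), plus subcommands for each stage.

## Worked example

Simulate a 10-site study with two predators (50 individuals, 200 reads
each at 0.5% sequencing error, 3% predator self-DNA, 1% contaminants),
process the reads, and analyse the recovered diets:

```python
import pandas as pd
import dietlink as dl

db = dl.generate_reference_db(n_prey_taxa=12, haplotypes_per_taxon=2, seed=11)
scenario = dl.default_scenario(n_sites=10, n_taxa=12, seasons=("summer",), seed=12)
abundance = dl.simulate_community(scenario, noise_dispersion=5.0, seed=13)

guts = []
for i, ((site, season), row) in enumerate(abundance.iterrows()):
    species = "predatorA" if i % 2 == 0 else "predatorB"
    guts += dl.simulate_guts(row, species, 5, seed=20 + i, site_id=site, season=season)

batch = dl.simulate_reads(guts, db, reads_per_gut=200, error_rate=0.005,
                          predator_dna_fraction=0.03, contaminant_fraction=0.01, seed=21)
detections, t_opt, diagnostics = dl.process_reads(batch, db)

meta = pd.DataFrame({"predator_species": [g.predator_species for g in guts],
                     "site_id": [g.site_id for g in guts],
                     "season": [g.season for g in guts]},
                    index=[g.individual_id for g in guts])
diet = dl.build_diet_matrix(detections, {t: t for t in db.taxa}, meta)

p_a = dl.utilization_vector(diet, predator_species="predatorA")
p_b = dl.utilization_vector(diet, predator_species="predatorB")
overlap = dl.overlap_null_test(p_a, p_b, n_iterations=10_000, seed=30)
sel = dl.selection_from_diet(diet.subset(predator_species="predatorA"),
                             abundance.sum(axis=0), n_iterations=10_000, seed=31)
```

Output:

```
optimal clustering threshold: 0.97
diet matrix: 50 individuals x 12 prey taxa
mean prey taxa per individual: 3.96
Levins' B_A: 0.907 (A), 0.883 (B)
Pianka overlap O = 0.954, P(greater than chance) = 0.9559
selection strength S = 0.086
preferred: none; avoided: none
observed richness 12, Chao2 estimate 12.0, 90% of prey taxa after 6 individuals
```

Reading it: the two simulated predators forage from the same prey pool
without selection weights, so their diets overlap strongly (O = 0.954,
greater than the randomized-utilization null in 95.6% of 10,000
iterations), every taxon sits inside its 95% prey-choice confidence
limits (no preferred or avoided taxa), and the selection strength is
near zero — the correct answer for proportional consumers. The high
B_A values say both are generalists on this 12-taxon menu. With
`selection_weights={"prey03": 5.0}` in `simulate_guts`, prey03 comes
back classified as preferred.

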
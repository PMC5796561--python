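# Methods

This note records the models, parameter choices and numerical conventions
behind the package, and what the synthetic-data tests do and do not
demonstrate about real data.

## Discovery model

Only scaffolds of at least 10 kb enter the analysis; shorter contigs are
never considered by any strategy. A scaffold is called phage when at least
one of three independent lines of evidence fires:

* **Strategy I (CRISPR).** A spacer extracted from a CRISPR array on a
  *different* scaffold matches the candidate. Self-targeting matches are
  ignored, because an array trivially matches its own spacer region.
* **Strategy II (VLP coverage).** Reads from the virus-like-particle
  fraction cover the scaffold with breadth **≥ 0.40** (inclusive). Breadth
  is the fraction of positions covered at least once; depth is mean
  per-position coverage. A separate screen against known phage genomes uses
  the strictly-greater comparator at 0.30 — the two screens genuinely
  differ, so the comparator is an explicit argument rather than a
  convention.
* **Strategy III (homology).** At least `min_phage_genes` (default 1) of
  the scaffold's predicted genes hit phage proteins at e ≤ 1e−05.

The original procedure ends with a manual curation step that cannot be
reproduced mechanically. We codify it: a candidate is discarded as
ambiguous when the summed best bit-score of its genes against
bacterial-source proteins exceeds `ambiguity_factor` (default 2.0) times
the summed best bit-score against phage-source proteins. This is a declared
substitute, not an inference of what curators actually did; the factor is a
flag.

## Taxonomic assignment

Per gene, hits at e ≤ 1e−05 are ranked by ascending e-value, ties by
descending bit-score, then subject id (external search tools do not fix
this order, so we declare it). The two best-ranked *distinct* subjects vote
1.0 and 0.5 for their taxon; a single-hit gene contributes only 1.0; if
both top hits share a taxon it receives 1.5. The phage family ratio (PFR)
is the best family's share of the summed score; assignment requires
**PFR > 0.5 strictly**, so an exact tie is unclassified. The bacterial
genus ratio (BGR) is computed identically over genus-labelled proteins with
an **inclusive ≥ 0.70** threshold. Both comparators are deliberately
asymmetric — they are copied from the procedure this package re-implements.

Large-subunit terminases are recognized by four domains (Terminase_1,
Terminase_3, Terminase_6, Terminase_GpA). In place of profile HMM search
the package scores ungapped motif matches (strings or position-weight
matrices, threshold 0.9 of the maximal score) and accepts externally
computed domain-hit tables for real data. A neighbor-joining tree over
p-distances of pairwise global alignments is offered as a convenience
output only; it is not validated against any published phylogeny.

## pOTU profiling

A pOTU is the set of phages with identical five-level taxonomy
(group|order|family|subfamily|genus) and the same bacterial host genus;
missing levels must carry explicit `unclassified_<level>` tokens so the
partition is total. Reads are attributed to genomes by nucleotide matching
against phage marker-gene CDS (exact-seed mapping, min identity 0.95); a
read counts for a genome only when *all* its best placements belong to that
genome — ties across genomes are discarded. The relative number of a pOTU
in a sample is the summed member-genome count divided by the sample's 16S
read count; values are deliberately **not** renormalized across pOTUs, and
a sample with zero 16S reads gets missing values rather than zeros.
Translated (protein-level) read assignment is a documented extension point;
nucleotide matching was chosen for determinism at desk scale.

## Host network and co-occurrence

Spacer matches are aggregated into one edge per (phage scaffold, bacterial
scaffold) pair with spacer multiplicity; the genus-level view keeps only
bacterial scaffolds with a BGR assignment. Specificity is the fraction of
phage scaffolds linked to exactly one host genus; the same-sample fraction
counts spacer–target pairings co-occurring in one sample.

Correlations between bacterial genera and pOTUs are computed on read
counts in the SparCC manner: the log-ratio variance matrix
t_ij = Var[log(x_i/x_j)] is solved for basis variances under the
sparse-correlation approximation, the most correlated pair (|r| above 0.1)
is iteratively excluded (up to 10 rounds, never leaving a component in
fewer than three unexcluded pairs), and estimates are averaged over 20
Dirichlet resamplings with pseudocount 0.5. Fewer than four taxa make the
basis system unsolvable; the package then directs users to the Spearman
fallback behind the same interface. Significance is a permutation null
(columns shuffled independently; p = (1 + #{|r*| ≥ |r|})/(1 + n_perm),
two-sided) and the network keeps edges with **r strictly > 0.3 and p
strictly < 0.01**, dropping isolated nodes.

## Group statistics

Differences between groups use the two-sided Mann–Whitney test: exact
enumeration of all group assignments (on midranks, so ties are handled) for
combined sizes ≤ 12, otherwise the normal approximation with tie and
continuity corrections. Identical pooled values give p = 1. Features are
flagged at p < 0.05 **and** BH-FDR < 0.25; direction (by median, mean as
tiebreak) is reported separately from the test. FDR is computed within one
reporting level (pOTU, family, scaffold load) at a time.

Prevalence selection uses strict comparators: "core" features are detected
in more than ⌊2N/3⌋ samples, "highly prevalent" in more than ⌊0.7·N⌋. The
cohort analyses this mirrors quoted explicit counts (more than 72 of 145
for the 50% screen — also written 72.5 in one place — and more than 120 of
145 described as "70%", which is not 0.7 × 145); because those printed
counts and their percentage glosses disagree, `core_selection` and
`prevalence_filter` accept an explicit `min_samples` override and the
defaults are computed from N with the floor rule above.

Chao2 richness is S_obs + ((m−1)/m)·Q1²/(2·Q2) with Q1, Q2 the counts of
features seen in exactly one and two samples; when Q2 = 0 the
bias-corrected form S_obs + ((m−1)/m)·Q1(Q1−1)/2 is used (this matches R
vegan's `specpool` chao estimate, which the tests cross-check). Rarefaction
averages the distinct-feature count over random sample orderings;
incidence means abundance above a configurable detection threshold
(default 0).

## Synthetic data generator

The generator is the package's test bed and models the study design
end-to-end. Defaults (all configurable in `WorldConfig`):

| parameter | default | meaning |
|---|---|---|
| n_samples_per_group | 20 | control and case groups |
| n_scaffolds_per_sample | 46 | assembled scaffolds per sample |
| n_phage_genomes | 37 | reference phage panel (one pOTU each) |
| phage_genome_len_range | 12–18 kb | planted prophages pass the 10 kb filter |
| bacterial_scaffold_len_range | 10–16 kb | host backbone before inserts |
| prophage_rate | 0.8 | ≈37 prophages/sample: each phage planted about once per sample |
| crispr_rate | 0.25 | scaffolds carrying one array |
| repeat/spacer length, repeats per array | 28 / 32 bp, 4 | arrays are repeat–spacer–…–repeat (3 spacers) |
| reads_per_sample / read_len | 2000 / 100 bp | WCMS depth |
| vlp_reads_per_sample | 8000 | phage-fraction sequencing depth |
| n_16s_copies_range | 30–40 | 16S gene copies planted per sample |
| genus / scaffold abundance sigma | 0.3 / 0.3 | log-normal abundance noise |
| n_effect_potus / effect_fold_change | 7 / 3.0 | planted case-group effects |

Design choices that make truth exact:

* Background sequence is i.i.d. uniform A/C/G/T; coordinates are 0-based,
  half-open everywhere.
* Marker genes (4 per phage, 300 aa; 3 bacterial markers per scaffold) are
  planted as exact ATG…stop CDS preceded by an in-frame stop codon, so the
  six-frame ORF caller recovers them at their exact coordinates and
  taxonomy tests are decoupled from gene-caller sensitivity. One marker per
  phage carries a synthetic terminase motif (the motifs are fixed arbitrary
  15-mers, not derived from real Pfam models).
* A prophage-carrying scaffold takes its phage's host genus (a prophage is
  a fragment of the host chromosome); arrays draw spacers only from phages
  infecting the scaffold's genus, and spacer source positions are unique
  and non-overlapping per phage — adjacent draws would otherwise create
  spurious one-mismatch cross-links between arrays. Array boundaries get
  guard bases so repeat edges are locally unambiguous and detected
  coordinates are well defined.
* WCMS reads are drawn from scaffolds proportionally to planted weights ×
  eligible positions. The case-group fold-change multiplies the sampling
  weight of the **prophage region only**, modelling induced phage
  replication. This keeps the 16S normalizer unbiased between groups: a
  whole-scaffold boost would inflate case-group bacterial and 16S reads and
  bias every null pOTU downward. VLP reads come from phage genomes only,
  with the same fold applied.
* Reads are error-free by default (`substitution_rate` and
  `spacer_mutations` knobs exist for robustness experiments), and
  everything is deterministic given `rng_seed`.

What passing tests therefore show: the pipeline's logic, thresholds,
comparators and statistics are correct on data whose truth is known
exactly. What they do not show: robustness to sequencing error, strain
variation, chimeric assembly, partial prophages, diverged homology (the
naive k-mer protein search has no substitution model), or CRISPR arrays
with degenerate repeats. Real-data use should route homology and domain
searches through BLAST/HMMER tables (the 12-column dialect and domain-hit
tables are accepted as inputs) and alignments through SAM ingestion.

## Numerical conventions

* The built-in mapper is exact-seed (first `seed_len` = 25 bases of the
  read, both orientations) with ungapped extension at min identity 0.95;
  one best placement per read (fewest mismatches, ties by (ref, position,
  strand) lexicographic order) so abundance counts never double-count.
  These stand in for an external short-read mapper's defaults, which the
  original procedure did not state.
* The naive protein search scores distinct shared amino-acid k-mers
  (k = 5) and converts the score to a pseudo e-value
  qlen·dblen·20^(−k·(score−1)): the first shared k-mer is treated as the
  seed, so a single chance k-mer stays far above the 1e−05 cutoff while two
  or more pass. The e-value is computed in log space and underflows to 0
  for strong matches.
* CRISPR detection seeds on exact 13-mers recurring with period 39–98 bp,
  extends while all occurrences agree, then validates repeat length
  (21–48), spacer length (18–50), ≥ 3 repeats and repeat identity ≥ 0.9;
  repeats containing N are discarded. Spacer matching tolerates
  `max_mismatch` substitutions (default 1) via a pigeonhole split into
  exact parts.
* Permutation p-values use the add-one estimator, so the smallest
  attainable p is 1/(n_perm + 1); with the default 200 permutations the
  0.01 network threshold is attainable (1/201 ≈ 0.005).

## Known limitations

* ssDNA phages and scaffolds < 10 kb are out of reach by design.
* The ambiguity screen and the per-gene hit-ranking rule are declared
  substitutes for undocumented steps of the original procedure.
* Chao2 and rarefaction on the default synthetic world are uninformative
  about estimator behaviour at low prevalence (every pOTU is seen in every
  sample); the unit tests exercise sparse incidence matrices directly.
* The SparCC engine follows the published algorithm but is not a numeric
  clone of any particular released implementation.
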
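# Methods

## Scope and data model

`rohscan` operates on a dense genotype matrix (samples × SNP sites) with
diploid calls coded hom-ref / het / hom-alt / missing, read from a
multi-sample VCF. Positions are 1-based inclusive internally (VCF
convention); every BED written is 0-based half-open. Upstream read QC,
alignment and variant calling are out of scope: the input is assumed to be
a genotyped SNP call set.

## Site filtering

Sites are kept when they are biallelic, autosomal (when an explicit
autosome list is supplied), have call rate ≥ 0.8 and minor allele
frequency ≥ 0.05 computed over non-missing genotypes. Comparisons are
inclusive, matching VCFtools `--max-missing 0.8` / `--maf 0.05` flag
semantics. A site failing several criteria is reported under the first
failing criterion in the order biallelic → autosome → call rate → MAF, so
the per-criterion removal counts sum exactly to the total removed.
Filtering is idempotent by construction.

## ROH calling

A *candidate* is any interval of consecutive SNPs whose first and last
call are homozygous and which satisfies: length ≥ `min_length_bp` (50 kb),
≥ `min_snps` (50) SNPs, ≤ `max_het` (3) heterozygous and ≤ `max_missing`
(5) missing calls, density ≥ `min_density_snp_per_kb` (0.05), and no
adjacent-SNP gap > `max_gap_bp` (1 Mb). Missing calls are neutral: they
spend the missing allowance but never terminate a run. Candidates strictly
contained in another candidate are dropped; remaining overlaps are
resolved greedily — emit the candidate with the leftmost start (longest
wins ties), discard candidates overlapping it, repeat. This is
deterministic and invariant to sample and chromosome order.

The production scan exploits that a candidate `[i, jmax(i)]` is maximal
iff `jmax(i)` exceeds every earlier start's furthest end, giving a single
left-to-right pass with prefix-sum bounds for the het/missing budgets and
precomputed gap blocks; the window search for the furthest valid end is
vectorised. `oracle_detect_roh` implements the same semantics by
exhaustive O(n²) enumeration (guarded at 2,000 SNPs/chromosome) and exists
purely as an independent reference; the test suite requires exact
agreement on hundreds of randomized instances and on a derandomized
property-based generator.

Two consequences of segment-level (rather than windowed) constraints are
worth knowing:

- **Flank extension.** A true autozygous tract can absorb flanking
  background SNPs until the het budget is exhausted — at typical
  background heterozygosity (~0.4/SNP) roughly 7–10 SNPs, i.e. ~70–100 kb
  at 10 kb spacing, mostly on the left flank because the greedy rule takes
  the leftmost feasible start. This inflates F_ROH by about +0.005–0.01 on
  the simulated gradient; the effect shrinks as segments lengthen.
- **Non-monotone greedy coverage.** Enlarging the het/missing allowance
  enlarges the candidate set (and the union of candidate coverage, which
  is monotone and tested), but the greedy resolution may then emit a newly
  affordable early candidate that preempts a longer later one, so total
  *emitted* coverage can occasionally decrease. This is inherent to
  leftmost-first resolution and is documented rather than "fixed".

## F_ROH, length classes and the group test

`F_ROH = Σ L_ROH / L_auto`, with `L_auto` the sum over autosomes of the
first-to-last retained SNP span (an override is available for users with a
fixed assembly denominator; chromosomes with < 2 SNPs contribute 0 with a
warning). Segment lengths are binned half-open [lower, upper) into
0.5–1 / 1–2 / 2–4 / 4–8 / 8–16 / >16 Mb and classes short (0.5–2),
medium (2–8), long (>8); a segment of exactly 2 Mb is medium. Segments
under 0.5 Mb — reachable because the 50 kb minimum is a parameter — are
reported in an explicit "<0.5" bin excluded from the proportion
denominator, making the convention auditable. Group comparison is a
classical one-way fixed-effects ANOVA (`scipy.stats.f_oneway`,
cross-checked against `statsmodels` in the tests); no post-hoc tests.

## Incidence and islands

A SNP's incidence is the fraction of *all* individuals (not just those
called at the SNP) with a ROH spanning it. Candidate island SNPs must
reach the empirical `1 − 0.001` quantile of the incidence distribution
*and* an absolute incidence ≥ 0.5; the two thresholds are ANDed — the
conservative composition — and both are exposed. The quantile uses the
`higher` method so the cutoff is an observed value and all ties at the
cutoff qualify, avoiding arbitrary tie-breaking among equal incidences.
Candidates on one chromosome within 1 Mb merge into an island spanning the
first to last candidate SNP (boundaries are not extended to flanking
non-candidates); islands report candidate SNP count and total SNP count
separately. Gene annotation lists genes overlapping the island by ≥ 1 bp,
via interval trees after converting GFF3 (1-based, feature type `gene`,
Name falling back to ID) or BED4 to 0-based half-open coordinates.

## The simulator

Each chromosome receives SNPs by a Poisson spacing process
(`snp_spacing_mean` 10 kb, so a 50-SNP run spans ~0.5 Mb). Per-site alt
allele frequencies are Beta(0.8, 0.8) redrawn until folded MAF ≥ 0.05, so
default simulations survive the MAF filter and site-filtering does not
confound recovery experiments. Background genotypes are Hardy–Weinberg
draws from those frequencies. Each individual receives planted autozygous
intervals: i.i.d. exponential lengths (`segment_length_mean` 1.5 Mb,
floored at 0.5 Mb), placed uniformly (chromosome chosen
length-proportionally) with rejection of overlap, until the group's
`target_F` fraction of the genome is covered; the final segment is
truncated to the remaining deficit (never below the floor) so realized
coverage tracks the target within a fraction of one segment. The 1.5 Mb
mean reproduces the ~1.5 Mb mean called-ROH length typical of livestock
resequencing panels; the four default group targets (0.09428, 0.119657,
0.1435, 0.149666 for F1/F2/CY/F3, 20 individuals each on a 5 × 20 Mb
genome) encode the generation gradient the package is designed to
quantify. Inside planted intervals every SNP is homozygous with allele
drawn by its frequency, except with probability `het_error_rate` (0.001)
it is rendered heterozygous; `missing_rate` (0.01) missingness is applied
last, independently, everywhere. Optional forced islands plant the full
region in each individual with probability `carrier_fraction`.

Randomness is one root seed with fixed sub-streams — one for sites, one
per individual — so adding individuals never perturbs earlier ones, and
identical configs are byte-identical end to end.

What the simulator does **not** model: linkage disequilibrium outside
planted runs, recombination-driven segment-length/age structure,
coalescent or pedigree ancestry, allele-frequency correlation along the
genome, and genotyping error outside planted segments. Passing recovery
tests therefore demonstrates correctness of the *calling and
summarisation machinery* under known truth, not calibration against real
populations: in real data ROH counts and lengths are shaped by processes
the simulator deliberately omits (the per-individual joint distribution of
ROH count and total length, for instance, is not matched).

## Validation problem sizes

The validation battery (tests and `scripts/acceptance.py`) uses: 200
random ≤ 120-SNP instances for detector/oracle agreement; the four-group
gradient on ~100 Mb at 10 kb spacing (80 individuals) for F_ROH recovery
within ±0.02 and rank order; and, for island recovery, 20 replicates of a
30-individual group on a 1 Gb genome with an 800 kb forced island
(carrier fraction 0.8) over background autozygosity 0.1, requiring
reciprocal overlap ≥ 0.8 with the planted region in ≥ 19/20 replicates.
The island scenario's geometry is deliberate: the region must hold
comfortably more than 50 SNPs (else carriers' runs fail the SNP-count
minimum) yet fewer than the top-0.1 % candidate budget of the genome
(else the quantile, not the ≥ 50 % rule, truncates island edges), and 30
individuals keep the binomial carrier-count tail from dominating the
replicate failure rate.

## Known limitations

- No PLINK `--homozyg` window-vote emulation: results are close but not
  bit-identical to PLINK on real data; the segment-level semantics here
  are exactly specified and oracle-verified instead.
- F_ROH carries the small positive flank-extension bias described above.
- The 50 kb minimum length is nearly unreachable at WGS density together
  with the 50-SNP and density constraints (a 50-SNP run at 10 kb spacing
  already spans ~0.5 Mb); both knobs are exposed rather than resolved.
- Single-threaded; the scan is linear-time in practice but the per-sample
  Python loop makes ~100k-SNP × hundreds-of-samples datasets a
  minutes-scale job.
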
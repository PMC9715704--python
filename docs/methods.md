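# Methods

This note documents the models, estimators and numerical choices behind
`ydna`, and what the synthetic-data generators do and do not emulate.

## Data model

Genotypes are haploid and binary: each sample carries, per SNP, the
ancestral (0) or derived (1) allele or a missing call, at 1-based GRCh37
chrY positions inside a declared callable target (a `RegionSet` of 0-based
half-open intervals). The packaged default target is synthetic — nine
disjoint intervals summing to exactly 8.9 Mb — because the real capture
design's coordinates are not public; it is user-replaceable via BED. VCF
I/O follows GATK's haploid convention (GT ∈ {0, 1, .}); a diploid GT is a
hard error naming the sample and position, and multi-allelic or non-SNP
records are rejected with a log entry. Missing calls are carried through
explicitly and never imputed at the I/O level.

## Capture QC

On-target proportion p = reliable on-target reads / reliable reads total;
enrichment factor EF = p/(L/G) with G defaulting to the 6 Gb diploid genome
(so EF is computed on the same scale as the published formula);
fold-increase is p over an unenriched baseline proportion (defaulting to
L/G, in which case it equals EF). Coverage homogeneity is the median depth
per 10-kb window; partial terminal windows are kept, so the window count is
Σ ceil(region/10 kb). Nine intervals summing to exactly 8.9 Mb can tile to
at most 899 such windows; published counts slightly above that imply a
rounded target size, so window counts are asserted against the tiling
formula, never a fixed constant. Sample filters: median target depth < 4X
(strict) discards a sample; a capture library with fold-increase below 5
(configurable — no published threshold exists) is flagged as never
enriched. Duplicate fractions are reported but never filtered on.

## Haplogroup assignment

The tree is a rooted node list, each node carrying a disjoint set of
defining SNPs, with an optional "~" bundle flag for sets of uncertain
position. The call is the node maximising supporting − conflicting derived
SNPs over its root-to-node path; ties resolve to the shallower node, so a
clean genotype stops at its last derived marker and adding a derived child
marker can only deepen the call. Missing genotypes on the path never block
descent when deeper evidence exists, but each skipped step is recorded.
Conflicts (derived alleles off the chosen path) are retained in the call
record and flag it for review — automated arbitration is deliberately
auditable rather than silent. A star (paragroup) is appended only when the
sample is positively ancestral at every child-defining SNP mapping inside
the target; if all child SNPs are missing the call is left unstarred with
an uncertainty flag, and leaf nodes never star (a paragroup requires known
child branches). The packaged 22-node R1b-DF27 subtree encodes the refined
structure: the former nine-SNP basal bundle resolved into four branches
(CTS6519.1/S4247.1, CTS11567/Z2572, DF81, Z222) and the
Z205 → {Z208 = CTS8289} → CTS4299 chain under M167.

## Perfect phylogeny and bundle resolution

With an all-ancestral root, two sites are compatible iff their observed
carrier sets are nested or disjoint; observed sets judged so can never show
all four gametes, which reduces rooted compatibility to a laminarity check
(the classic unrooted four-gamete test is also exposed). Sites are
processed by decreasing carrier count; a site conflicting with a retained
site — or sharing no called sample with one (possible only under extreme
missingness) — is quarantined with the reason, never fatal. Retained
carrier sets tile into a tree in which each SNP labels exactly one edge;
the root-branch census (branches from the in-group base, singleton
lineages) is a first-class output because a star-like expansion shows up
exactly there. Bundle SNPs are classified from carrier-set algebra:
identical sets are the same branch; strictly nested sets form a chain
(position 1 outermost); a maximal set disjoint from the others whose
carriers are ancestral at every sibling-branch SNP is a new basal branch;
empty or overlapping-without-nesting sets stay unresolved.

The capture-vs-WGS reference-bias screen runs a two-sided Fisher exact test
per SNP on derived/ancestral counts by platform, controls FDR by
Benjamini–Hochberg at q < 0.01, and merges significant SNPs within 5 kb
into fragments (all three knobs configurable; the original analysis
published only its outcome, not its criterion, so these defaults are
declared choices). The SNP missingness filter retains sites with missing
fraction strictly below 5%.

## Rho dating

The founder haplotype is the per-site majority over non-missing calls, with
exact ties and all-missing sites resolved to ancestral. Distances are
counted over called sites and rescaled by (total sites)/(called sites),
which is unbiased under missingness at random. rho is the mean distance;
σ = √rho is the primary dispersion (exact when every haplotype has
frequency 1, as in sequence-resolution data), with √(rho/n) also emitted.
TMRCA = rho/(μL); the mutation-rate CI propagates multiplicatively, an
algebraic identity (ci_low/tmrca = μ/μ_high) tested on every result. Group
tables recompute the median haplotype within each group (groups of n < 2
are skipped with a log entry). Reanalysis of all 30 published point ages
shows 26 printed CIs reproduce to ±1 year under this rule; the remaining
four are internally inconsistent in the source table (two branches with
identical point ages print different CIs), and the published ± values are
not reproducible from either σ scaling, so neither is asserted against
them.

## Diversity and structure

S counts sites with both alleles observed; MPD averages pairwise
differences (missing-rescaled as above); π = MPD/L_retained exactly, with
the no-recombination total variance of MPD reported as its SD. Tajima's D
uses the standard a₁…e₂ constants; its p-value is the lower tail against
constant-size Kingman genealogies with exactly S mutations placed
multinomially on branches — conditioning on S avoids choosing a nuisance θ,
and the lower tail matches the expansion alternative (two-sided optional by
doubling). The null's demography is a declared assumption; the p-values are
calibrated (uniform under the null) by construction and by test.

AMOVA treats pairwise difference counts as squared distances (the same
currency as MPD, no substitution-model correction): SSD_total/N minus
Σ SSD_g/n_g decomposes into among/within components with
φST = σ²ₐ/(σ²ₐ+σ²_b); the permutation p shuffles samples across regions.
Pairwise φST is the two-group case; negative estimates are retained in
tables and clamped to zero only when a matrix is embedded.

MDS is SMACOF majorization from the classical (double-centering) solution
plus seeded random restarts. The default disparity transform is interval
(affine, re-fit each iteration) and the reported fit is normalized raw
stress, Σ(d̂−d)²/Σd² in percent — the flavour under which published φST
matrices of this kind report ~1% stress. This was chosen after measuring
the alternatives on the packaged published matrix: classical embedding
scored with Kruskal stress-1 gives ~31%, the global nonmetric stress-1
optimum is ~3.3%, and metric stress-1 ~25%, none compatible with the
published figure, while the interval/normalized-raw optimum is ~1.05%.
Stress-1 against the raw dissimilarities is always reported alongside.

## Synthetic data

Four generators, all infinite-sites (positions drawn without replacement
from the target; no back-mutation, recombination, selection, or sequencing
error), all bitwise-reproducible from one integer seed, all in calendar
years with a per-year rate (no generation-time conversion anywhere):

* **Star**: n lineages radiate T years ago; each carries Poisson(μLT)
  private derived sites. This is the regime in which rho is unbiased and
  every site pair is four-gamete compatible.
* **Growth coalescent**: Kingman waiting times with optional exponential
  growth via the standard time rescaling, mutations Poisson(θ·L_tree/2) so
  E[S] = θΣ1/i at growth 0 (cross-checked against msprime in the test
  suite). The strong-growth regime (θ = 500, growth 200 in coalescent
  units, chosen to yield on the order of 10² segregating sites, the scale
  of the real per-region matrices) reproduces the strongly negative
  Tajima's D of an expanding population.
* **Tree-derived**: samples placed on haplogroup nodes carry exactly their
  path-defining SNPs plus Poisson private sites — the round-trip oracle
  for assignment (100% recovery is a construction guarantee, so failures
  indicate caller defects, not noise). A per-lineage private-mutation mean
  of 35 matches the mutational depth of a ~5,200-year-old expansion.
* **Structured regions**: region founders diverge T_d years, samples
  radiate within regions T_w years; the large-sample expected φST is
  T_d/(T_d+T_w), and the finite-sample expectation is obtained from the
  AMOVA decomposition itself.
* **Capture counts**: on-target reads Binomial(total, p) with
  p = eF/(1+(e−1)F), F = L/G — an odds-multiplier model whose e = 1 case is
  WGS — and per-window Poisson depths around the implied mean.

What passing tests show, and do not show: the generators validate the
estimators' algebra and sampling behaviour under their own assumptions;
they do not emulate alignment artefacts, batch-correlated coverage,
non-random missingness, or recurrent mutation, so field data can still
violate assumptions the synthetic tests cannot probe (the bias screen and
quarantine machinery exist precisely for those cases).

## Problem sizes

Desk-scale defaults keep the full test suite and the acceptance script in
the low minutes on one core: recovery properties use, e.g., 100–200 star
replicates at n = 100, 1000 neutral coalescent replicates at n = 10,
p-value calibration at 500×2000 simulations, and a 150-sample × ~5.4k-SNP
synthetic cohort in the analysis walkthrough (the study scale itself —
~240 × 6.3k — runs comfortably; simulation counts like the 100,000-draw
Tajima null are configurable and default to the published values in the
pipeline API).

## Known limitations

* Haplogroup conflict arbitration is a declared heuristic; heavily
  conflicted genotypes deserve manual review of the flagged calls.
* The bias screen's test/threshold/merge defaults are package choices, not
  published criteria; treat flagged-fragment counts as screen-dependent.
* The Tajima null assumes constant size; under a true alternative the
  p-value is a tail probability against that specific null only.
* MDS stress depends on the disparity transform; both normalized raw
  stress and stress-1 are reported to make comparisons explicit.
* rho on non-star genealogies (pooled structured cohorts) is upward-biased
  relative to the within-clade founder age, visible in the analysis
  walkthrough as a ~7% pooled-cohort deviation.
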
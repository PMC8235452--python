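# Methods

## The analysis model

`exofam` implements the prioritization logic of a family-based rare-variant
exome design. The genetic model is that low-frequency (MAF < 0.05),
protein-damaging variants co-occur in distantly related affected members of
a family; variants private to a subset of the sequenced affecteds are
treated as not disease-relevant for that family. The MAF threshold is
deliberately higher than typical rare-variant cuts (<0.01 or <0.001)
because the modelled condition affects 2–3% of the population, so
contributing alleles need not be rare.

The cascade's sharing rule quantifies over *sequenced* members only: the
`sequenced` flag in the pedigree is always explicit and never inferred from
affection status. A carrier is any sample with ≥1 alt allele; identical
zygosity is not required (requiring it would spuriously drop hom/het
mixtures). A missing genotype in a sequenced member fails the sharing test
— sharing cannot be asserted without a call, and no imputation is
attempted. The frequency boundary is exclusive (a variant at exactly the
threshold is dropped). Variants absent from the prediction database are
retained by default because the damaging-evidence rule is conditional on
annotation; the switch `retain_if_unannotated=False` inverts this for
stricter analyses.

Membership in the retained set equals the intersection of the five
predicate pass-sets, so stage order affects only the funnel counts. The
order used (consequence → artifact → frequency → damaging → sharing)
mirrors the narrative order of the modelled workflow.

## Overrepresentation statistics

The per-term statistic is the hypergeometric right tail P[X ≥ k] for
X ~ HG(N, K, n), computed in log space (log-gamma binomial terms summed
with logsumexp) for stability at exome-scale N; the implementation agrees
with an exact rational-arithmetic oracle to ≤1e-12 relative error on
exhaustive grids for N ≤ 40 and seeded samples up to N = 200 (an
exhaustive sweep of every (k, n, K) configuration up to N = 200 would be
~10^7 exact rational tail sums; the sampled design covers the same range
at a practical cost). The default scoring is the EASE variant: one list
hit is removed before testing (tail at k−1 with list size n−1, background
unchanged), so a term hit by a single gene scores 1.0 and every score is ≥
the plain Fisher tail. Raw Fisher is available behind `ease=False`.

The default background universe is the union of genes covered by the
supplied term sets — enrichment against genes that no term can hit is
meaningless, and no external "all annotated genes" universe is assumed.
Fold enrichment and p-values therefore depend on the supplied annotation;
only the hit percentage column (100·k/n) is annotation-independent. Terms
with fewer than `min_count=2` list hits are suppressed. Benjamini–Hochberg
step-up adjustment is the default multiplicity control (implemented
directly; cross-checked against statsmodels in the tests).

Percentages in all report tables are computed on exact integer ratios in
decimal arithmetic and rounded half-up at the printed precision (integer
percent for consequence/MAF shares, one decimal for the private-gene
share, two decimals for enrichment percentages); banker's rounding would
mis-render boundary values like 2.5%.

## Co-segregation call

The three-way call (`full` / `partial` / `none`) is a declared operational
convention, not an inference of any particular study's unstated rule:
*full* requires every genotyped affected to carry and no genotyped
unaffected to carry; *none* requires both directions violated; *partial*
is exactly one violation. "Confirmed negative" members (radiographically
cleared) are pooled with the unaffected; members of unknown status are
excluded. Reduced penetrance and phenocopies are intentionally not
modelled in the call — with a phenocopy present, a truly linked variant
will be called partial. A `low_information` flag marks calls supported by
no additional affected member beyond the discovery set or by no unaffected
member at all.

## Synthetic cohorts

The generator emulates the study conditions the pipeline is designed for:

* **Pedigrees** — 23 families, three generations, a founder couple whose
  risk haplotype is transmitted to descendants; 3–5 sequenced members per
  family, all affected carriers, spanning ≥2 generations. Affection is
  assigned from carrier status with full penetrance by default
  (`penetrance` and `phenocopy_rate` knobs exist for stress-testing the
  segregation call). Affected members receive 1–2 Cobb angles in 12–60°;
  20% of unaffected non-carriers are marked confirmed negative.
* **Planted variants** — per-family counts drawn from a lognormal with
  median 51 and log-sd 0.45, clipped to [11, 128]. The emulated conditions
  state a count range and median but not a distribution; a uniform draw
  over the range would have median ~70, so a clipped lognormal matching
  the median was chosen once. Each planted variant is forced heterozygous
  in the risk founder and transmitted alt-first along the carrier lineage,
  so all sequenced members carry it; all other transmission is fair
  Mendelian (founder alleles Bernoulli(MAF), one random allele per
  parent).
* **Annotations** — population frequencies from the mixture 12% novel,
  18% < 0.001, 22% in 0.001–0.01, 48% in 0.01–0.05 (log-uniform within
  bins); consequence classes from the protein-altering mixture
  88/4/2/2/2/2/1%. Planted variants get ≥1 damaging predictor with
  probability `prediction_sensitivity` (default 1.0); 5% are unannotated
  in the prediction database, exercising the retain-if-unannotated branch.
* **Decoys** — four classes, each failing exactly one stage: absent from
  one sequenced member, population MAF ≥ 0.05, all predictors benign, or
  non-protein-altering consequence; default rates 1.0/0.5/0.5/0.5 of the
  planted count.
* **Term sets** — 120 sets of 150 genes over an 18,000-gene pool (exome
  scale; the union covers ~60% of the pool, the rest stay unmapped as real
  annotation does). The first set is the planted term: each planted
  variant's gene comes from it with probability 0.02 (versus ~0.008 under
  uniformity), a mild effect producing ~3-fold enrichment, comparable to
  the 2–10-fold range typical of such studies.

What the generator does **not** emulate: read-level error, genotype
quality/depth, linkage disequilibrium, human exome geometry (positions are
uniform over 22 toy contigs), multi-gene transcripts, and population
structure. Passing recovery tests therefore demonstrates correctness of
the filtering/aggregation/statistics logic under the declared genetic
model — not robustness to calling artifacts or annotation noise in real
exomes. Cohort VCF genotypes for samples outside a variant's family are
homozygous reference (family-private variants), which keeps per-family
truth exact but understates cross-family allele sharing of common
variants.

## Numerical and format choices

* Coordinates are 1-based VCF convention; alleles are taken as written (no
  indel re-normalization, no liftover). Multiallelic records are
  decomposed per alt allele; a 1/2 genotype makes the sample a het carrier
  of both entries. Hemizygous male X genotypes are accepted as written;
  the carrier predicate only asks for ≥1 alt allele, so this is
  consequence-free.
* dbNSFP-style letter codes map D (and MutationTaster's A) → damaging;
  T/B/N/P → benign; "." → missing. A record listing several gene symbols
  contributes its first symbol, with a warning counted.
* Population-frequency INFO values are written at 6 significant digits and
  re-rounded on read (htslib stores Float INFO as 32-bit), making VCF
  round-trips exact.
* Retained variants are sorted by (chrom, pos, alt); enrichment results by
  (p_raw, term_id); all randomness flows through one seeded generator, so
  equal seeds give byte-identical outputs.
* Genotype unphased throughout; compound heterozygosity is out of scope.

## Test problem sizes

The recovery suites run the full default cohort shape where the property
under test depends on it (enrichment power: 100 replicates of 23-family
cohorts) and scaled-down cohorts where it does not (per-family recall and
decoy retention are family-local, so the 100-seed sweep uses 2-family
cohorts). The Mendelian check uses 10,000 offspring of a het × hom-ref
cross (±0.02 is 4 standard errors). The exact-oracle grids are stated
above.

## Known limitations

* The artifact blacklist is positional (exact chrom:pos:ref:alt); no
  published artifact list ships with the package, so the default is empty.
* The enrichment module does no GO-graph propagation, term clustering, or
  web-service queries; annotation quality is entirely the caller's GMT.
* `partial` segregation aggregates heterogeneous evidence (one unaffected
  carrier among many vs. many); users needing gradations should read the
  carrier tallies, which are always reported alongside the call.
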
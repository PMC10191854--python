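# Methods

## Problem and model

Somatic L1 retrotransposition events (soL1Rs) are structural insertions a
cell acquires postzygotically. In panels of single-cell-derived clones, every
somatic mutation of the founder cell is present at VAF ≈ 0.5 (heterozygous,
clonal within the clone), so clones expose soL1Rs directly, and point
mutations shared across clones date events on the donor's developmental tree.
`l1mosaic` treats the analysis as five linked estimation problems: event
validation/classification, lineage reconstruction, rate estimation on a
molecular clock, source-element activity estimation, and promoter epigenotype
dynamics.

### Insertion quantification

A read pair is *informative* when the interval spanned by its two reads
crosses the insertion breakpoint. An insertion presents two breakpoints (one
per insert end) while the reference allele presents one contiguous locus, so
reference pairs are sampled at both ends; the VAF estimator therefore counts
them twice:

    VAF = s / (s + 2 r)

with `s` supporting and `r` reference pairs. Under the generator's read model
(`s ~ Poisson(d·a)`, `r ~ Poisson(d·(1 − a)/2)` at allele fraction `a` and
pair depth `d`), this estimator is consistent for `a`; a clonal heterozygous
insertion concentrates at 0.5. Cell fraction is `min(1, 2·VAF/purity)` on
autosomes (sex-chromosome ploidy is a parameter). Validation requires a
poly-A tail, a target-site duplication (a configurable exception flag admits
blunt TSD-absent insertions, off by default) and `s ≥ 0.10 (s + r)`. The 10%
rule is applied to read *pairs*, consistent with the VAF definition.

### Classification and fingerprinting

The inserted segment's end mappings decide the class: repeat-only → solo-L1;
repeat + unique downstream segment → partnered transduction; unique segment
only → orphan transduction; anything else → unresolved. Transduced unique
sequence lies 3′ of its source, so attribution looks for a registered
full-length source whose 3′ end lies within 15 kb *upstream of the segment in
the source-strand sense*; the nearest end wins ties and the ambiguity is
logged; segments mapping inside annotated repeats are refused (no unique
barcode). Insert ends mapping on opposite strands of one template flag an
inversion: inside the retrotransposed body this is twin priming; on the
target 5′ flank it is a foldback (inverted duplication). Inserted bases
matching neither template nor flank are reported as untemplated extra
synthesis by exact length accounting.

### Phylogeny

Mutations are binarized per sample (`M_ij = 1` iff VAF > 0.1) after two row
filters (depth ≥ 5 in all samples; max VAF ≥ 0.25 in some sample); rows
present in all samples are germline and dropped. Rows are grouped by their
exact carrier set; group B is subordinate to A iff `samples(B) ⊂ samples(A)`.
A conflict-free group family is laminar and induces a unique rooted tree with
branch length = group size. Conflicts (overlapping, non-nested sets — caused
by genotyping noise) are resolved greedily: groups are accepted in decreasing
size, ties broken lexicographically by carrier-set key, and a group
incompatible with the accepted family has its mutations discarded from the
tree and reported. Σ branch lengths = retained − discarded mutations, both
reported. For cancer samples, branch length counts clonal mutations only
(cancer cell fraction > 0.7).

### Staging, clock and rates

EPM (endogenous point mutations) = exposures of SBS1 + SBS5/40 (SNVs) and
ID1 + ID2 (indels), obtained by non-negative least squares against unit-sum
reference signature profiles; exposures stay real-valued internally and are
rounded only where an exact test needs a count. Branch stages: shared
branches whose mutations are detected in bulk blood (mesodermal origin,
hence pregastrulational) → `pregastrulation`; other shared/early branches →
`postgastrulation`; terminal normal branches → `ageing`; the cancer clonal
branch → `tumourigenesis`. With no blood data, shared branches default to
postgastrulation with a warning. Rates are `1000 × events / EPM` with exact
(Garwood) Poisson CIs from chi-square quantiles; two groups are compared with
the conditional exact test (`events1 ~ Binomial(n, epm1/(epm1+epm2))` under
H0, two-sided by summing probabilities ≤ the observed one — the minlike
convention implemented by `scipy.stats.binomtest`). Molecular time converts
to cell generations as `g = m/r1` if `m ≤ 2 r1`, else `2 + (m − 2 r1)/r2`,
evaluated at the fast (3.8, 1.2) and slow (2.4, 0.7) per-division rates; the
rounded pair is an (earliest, latest) generation range. This inversion
convention is one of several defensible readings of the stated rates and is
documented here rather than reverse-engineered from any printed range.

### Source activity and prevalence

TPAM = Σ transductions / Σ (alleles × EPM / 10⁶) over carrier individuals —
a pooled (ratio-of-sums) estimator, unbiased for Poisson counts, preferred
over a mean of per-carrier ratios whose small denominators explode the
variance. Postzygotic sources count one allele in carrier lineages only.
Population allele frequency (PAF) is the percentage of panel individuals
whose supporting-evidence fraction (L1-supporting reads for non-reference
sources; short-insert pairs opposing the L1 deletion for reference sources)
reaches 15%. Truncation: a source is `truncated` iff every informative allele
carries a stop-introducing or frameshifting (length change ≢ 0 mod 3) variant
inside an ORF; ORF intervals are configuration, defaulting to the shipped
L1HS consensus annotation (`data/l1hs_orfs.tsv`: ORF1 908–1921, ORF2
1990–5814, 1-based).

### Promoter methylation

A diploid promoter's CpG methylated fraction is ~trimodal; each covered CpG
in the +1..+250 window downstream of the L1 TSS is classified at < 0.25 /
[0.25, 0.75) / ≥ 0.75 and scored 0/5/10; the promoter score is the mean and
the epigenotype is open (< 2.5), heterozygous ([2.5, 7.5)) or closed
(≥ 7.5). The 2.5/7.5 cutoffs are this package's choice — midpoints between
the pure one-CpG scores; the underlying study reports the categories without
numeric cutoffs. Zero-coverage CpGs are excluded, never imputed, and counted
in a mandatory coverage report. Concordance-vs-branching: for each clone pair
and each of the top-k (default 30) sources by promoter-score variance — the
variance criterion is our documented choice of "most variable" — record
category agreement and |Δscore|, stratify by MRCA molecular time (< 17 /
17–65 / > 65 mutations), and compare early vs post-window |Δscore|
distributions with a two-sample KS test (strata with < 2 pairs are excluded
from the test; single-pair strata still report their concordance).

### Enrichment

"Equal-sized" bins are equal in base pairs, because rate denominators must be
lengths. Schemes: fold-enrichment (< 1 → bin 0, remainder in bp-tertiles by
signal), expression (0 → bin 0, remainder tertiles), replication timing
(bp-quartiles of the timing signal, lowest/latest → bin 0), and endonuclease
motif (per-position minimum Hamming distance to TTTT|R or Y|AAAA; ≥ 4 → bin
0, 3 → 1, 2 → 2, ≤ 1 → bin 3 — the stated bin wording leaves exactly-4 and
exactly-1 unassigned, and this inclusive assignment is our documented
resolution; ambiguous bases count as mismatches). Fold of bin k =
(count_k/size_k)/(count_0/size_0) with the exact conditional-binomial
(Clopper–Pearson-mapped) rate-ratio CI; an empty reference bin yields a
one-sided bound. Sliding windows are half-open, 10 Mb with 5 Mb steps.

## Synthetic-data generator

The generator emulates the *structure* of clone WGS panels, not reads:

- **Topology**: uniformly random binary splits until `n_clones` lineages
  exist (real developmental trees are irregular, so topology is a free
  parameter). The first two divisions span one generation each; later
  embryonic branches span Uniform{1..80} generations so that clone-pair MRCA
  molecular times populate all three branching-time strata (< 17, 17–65,
  > 65 mutations), as real clone trees do. Terminal (ageing) branches span
  `age × 30` generations: at the late-rate midpoint (~0.95 mutations per
  division) and ~81% endogenous mutations, 30 divisions/year reproduces both
  clock-like burden accumulation and, combined with the ageing soL1R rate,
  the observed per-clone burden slope on age.
- **Mutations**: per branch, Poisson with mean = Σ over generations of a
  per-generation rate drawn uniformly in the stage range (2.4–3.8 pcpcd for
  generations 1–2, 0.7–1.2 after). Mutation channels: 90% SNVs, of which 80%
  endogenous (SBS1, SBS5/40 equally) and the rest SBS18; 10% indels, 90%
  endogenous (ID1/ID2). EPM per branch is the endogenous count.
- **soL1Rs**: per branch, Poisson(stage rate × branch EPM) with stage rates
  {pregastrulation 1.06, postgastrulation 4.52, ageing 1.2, tumourigenesis
  3.47} per 1,000 EPMs; class weights solo:partnered:orphan = 89:1:10;
  inversion (twin-priming) probability 0.295; poly-A 10–80 bp, TSD 5–20 bp;
  transduced segments start 0–12 kb downstream of their source's 3′ end.
  Sources are drawn by activity weight × allele count among carried sources
  that are promoter-demethylated in the receiving lineage (embryonic
  branches precede fixation and are globally permissive).
- **Epigenotypes**: one fixation time per source, uniform in the 17–65
  window; a lineage's category (open 0.25 / heterozygous 0.15 / closed 0.60)
  is drawn on the branch crossing that time and inherited — so pairs
  diverging later agree more.
- **Observations**: depth ~ Poisson(17); variant reads ~ Binomial(depth,
  0.5) in carriers; zero-depth rows are emitted. Insertion pairs follow the
  model above. CpG coverage ~ Poisson(15) over 20 promoter CpGs with
  methylated fractions 0.05/0.50/0.95 by epigenotype. The population panel
  (default 2,860 individuals) draws carriers at each source's PAF with
  evidence fractions U(0.25, 0.9) vs U(0, 0.10).
- The default registry has 12 sources in three groups mirroring the observed
  activity–prevalence structure: four prevalent-active (PAF ≈ 98–99, high
  activity; flagged and excluded from the activity-vs-prevalence
  relationship, as the study excludes its analogous four), four common
  repressed (PAF 80–90, activity ≈ 0), four rare active (PAF 2–15, highest
  activity).

**What passing tests do and do not show.** The generator has no alignment
artefacts, no culture-induced events, no copy-number changes, no
conversion-efficiency error in methylation, no mapping ambiguity in
repeats, and noise-free class/segment mappings. Recovery results therefore
validate the estimators' correctness and calibration under the stated
stochastic model — not robustness to real-data artefacts.

## Problem sizes

Tests and the acceptance script size simulations to keep everything
single-CPU friendly while leaving Monte-Carlo error well below the assertion
tolerances: 500 replicates per exposure for CI coverage, ≥ 10,000 events for
class-fraction and enrichment calibration, a 19-donor × 20-clone cohort
(ages 30–75) for rates/slope/TPAM, and one 19-clone donor for the
observation-level analyses.

## Numerical and degenerate-input choices

- `insertion_vaf(0, 0)` raises (undefined), distinct from a genuine 0.
- Zero EPM exposure, empty panels, all-identical ages and zero-coverage
  promoters raise with named messages rather than returning sentinels.
- An empty genotype matrix after filtering returns an explicit empty result.
- Constant signal tracks are rejected as degenerate rather than binned.
- Exact-test EPM counts round half away from zero only at the test boundary.
- Greedy conflict resolution and lexicographic tie-breaks make phylogeny
  reconstruction deterministic; equal-distance source attribution prefers
  the nearest 3′ end and logs the ambiguity.
- All randomness flows from `numpy.random.default_rng` seeded per stage from
  the single configured seed; identical config + seed reproduces outputs
  byte-for-byte.

## Known limitations

- The recurrent-error-across-clones variant filter has no published
  threshold; it ships disabled with a configurable cutoff.
- Blood evidence in the synthetic pipeline is derived from truth stage
  labels (majority of a reconstructed branch's mutations arising before
  gastrulation), since read-level blood genotyping is not simulated.
- Stage assignment is per branch; a reconstructed branch merging segments on
  both sides of gastrulation is assigned wholly to one stage.
- De novo signature extraction, subclonal deconvolution, probabilistic
  phylogenetics and read-level simulation are out of scope.
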
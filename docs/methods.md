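# Methods

`regvar3d` re-ranks the leading variants of an association study by the
probability that they — or a variant in linkage disequilibrium with them —
disrupt gene regulation. This note describes the model, the numerical
choices, what the synthetic data generator does and does not emulate, and
the known limitations.

## Pipeline model

For a set of leading variants *L* with association p-values, the pipeline:

1. **Prefilters** by a user p-value cutoff (variants without a p-value are
   admitted only in no-GWAS mode, i.e. when the whole input is a bare
   variant list).
2. **Expands LD**: every *L* maps to the proxies *V* with r² strictly above
   the cutoff in the requested population, plus itself at r² = 1. LD is
   consumed from a pairwise table; r² is never estimated here.
3. **Requires a regulatory signal**: a proxy survives only if it overlaps an
   active mark peak (H3K4me1, H3K27ac, p300, CTCF, DHS), a ChromHMM
   "Strong" promoter/enhancer/insulator element, an anchor of a long-range
   chromosome interaction (BEDPE, or anchors called from an ICE-balanced
   Hi-C matrix), or a user promoter region, in the chosen cell type (the
   `merged` pseudo cell type unions all tracks). Leading variants whose
   entire proxy set is filtered are side-reported.
4. **Scores binding-affinity change** (below) to get `P_BDA` per surviving
   proxy, looks up the constraint p-value of the most significant
   conserved element containing it (`P_CONS`), and propagates the
   association signal as `P_GWAS = min(1, p_L / r²)`.
5. **Combines** the measured components by Fisher's method,
   `X = −2 Σ ln p_i ~ χ²(2k)`, assigns each *L* the most significant
   combined p-value `CP` among its proxies, and re-ranks all *L* by `CP`
   (ties break on `(CP, chrom, pos, id)`).

### Component p-values are combined only when measured

`P_GWAS` is absent in no-GWAS mode; `P_BDA` is absent when no (motif,
allele) pair is eligible; `P_CONS` is absent when the variant lies in no
constrained element. Absent components are *omitted* from the combination
(k adapts between 1 and 3) rather than entered as p = 1. Fisher's method
assumes each combined p-value is Uniform(0,1) under the null; a degenerate
p = 1 placeholder adds two degrees of freedom with zero statistic exactly
for the variants with the least evidence, which pushes their `CP` off the
uniform scale and distorts the ranking. With adaptive k, `CP` is uniform
under the null whenever the measured components are — which is what the
negative-control test verifies. Output tables print `NA` for absent
components and record k.

`P_GWAS` is capped at 1 because the division by r² can exceed 1 and
p-values above 1 would invalidate the chi-square combination; the cap was
chosen over renormalization for transparency.

## Binding-affinity change

**PWM construction.** Position frequency matrices are converted to log2
weights with background shrinkage:
`pwm[i,b] = log2((pfm[i,b] + c·bg[b]) / (1+c) / bg[b])` with pseudocount
`c = 0.01` and a uniform background by default. The consensus base has the
maximal weight in every column; a column equal to the background scores 0.

**Exact site p-values.** Both alleles are embedded in `flank = 30` bp of
surrounding sequence (window `2·flank + len(allele)`, truncated at
chromosome ends) and scanned at every offset on both strands. Weights are
discretized on a fixed grid of 1e-4 log2 units and all scoring uses the
resulting integer weights, so the site p-value — the probability that a
random background k-mer scores at least as high — is computed *exactly* by
dynamic-programming convolution of the per-position weight distributions.
The survival array accumulates from the top score down, preserving
precision in the far tail. Because scanning and the distribution share the
same integer weights, the p-values agree with brute-force enumeration over
all 4^k k-mers to machine precision (verified up to k = 8). Ambiguous
bases (N) score at the column minimum, a conservative floor.

**LOD.** For each motif m and alternative allele, with `p_ref` and `p_alt`
the best-site p-values of the two windows,

    LOD = ln(p_alt / p_ref)

is positive when the reference allele binds better (the alternative allele
weakens the site). The statistic is antisymmetric under allele swap and
invariant under strand flip of the window, both by construction and both
tested.

**Eligibility.** A (motif, allele) pair contributes affinity evidence only
when (i) at least one allele harbors a site with p ≤ the scan threshold
(default 1e-3 — note a motif of width w cannot go below 4^−w, so very
short motifs can never be eligible at the default), and (ii) LOD ≠ 0. The
second condition is part of the statistic's definition: a variant that
overlaps a credible site without changing its best probability has
measured *no* binding change, and treating those exact zeros as evidence
floods the empirical null with ties at zero, making the rank p-value
conservative (an atom at p = 1) and the combined p-value non-uniform under
the null.

**Empirical null and p-value.** The null is the pooled |LOD| of all
eligible pairs over `n` variants (default 10,000) drawn uniformly with
replacement from the allele catalogue under a recorded seed (after
sorting, so the draw is independent of input order). It serializes to a
TSV sidecar so the expensive step runs once per catalogue. The p-value of
an observed LOD is the smoothed rank

    p = (1 + #{null |LOD| ≥ |lod|}) / (n_null + 1)

located by binary search; it is always in (0,1] and matches the naive
counting oracle exactly. `P_BDA` is the minimum p over a variant's
eligible pairs. Pooling across motifs (rather than per-motif nulls) keeps
the null large at desk scale; per-motif nulls only require building with a
restricted motif list.

## ICE balancing of contact matrices

Raw Hi-C contact matrices are balanced by symmetric iterative proportional
correction: all-zero bins are masked, then bin biases are updated by the
square root of each row sum's deviation from the mean until every unmasked
row sum is within `tol` (default 1e-5 relative, `max_iter` 200, warning on
non-convergence). The output keeps the input's mean row sum, so scaling
the input scales the output. Only the balancing step is performed; the
eigenvector-decomposition part of the original algorithm is not needed for
coverage correction. Balanced matrices can be turned into paired
interaction anchors by thresholding nonzero off-diagonal entries at a
quantile; pre-called 5C/ChIA-PET-style interactions are consumed as BEDPE
verbatim.

## Coordinates and formats

Variant records are 1-based (VCF convention); all interval work is BED
0-based half-open, with the variant as the single point `pos − 1` (indels
use their leftmost base). The conversion lives in one function
(`variant_io.point_0based`). A variant at a BED end coordinate never hits;
at a start coordinate it always hits. The Plink-like dialect is fixed as
whitespace-delimited `ID CHROM POS P` with an optional header, since no
authoritative layout exists for it; the p-value prefilter applies whenever
p-values are present, regardless of input dialect. Chromosome names
`1..22, X, Y` are normalized to `chrN`; other contigs pass verbatim.
Catalogues are consulted in priority order, first match wins, and
VCF-like records bypass the catalogue entirely (their alleles are taken
verbatim and they survive even when unknown to every catalogue).

## Synthetic cohorts

`fixtures.generate_bundle` writes a complete, seeded, byte-reproducible
input bundle: an i.i.d. uniform-base genome (2 × 60 kb by default), a
4-motif PFM library, a 4,000-variant biallelic catalogue whose reference
alleles match the genome, 20 leading variants with association p-values
log-uniform in [1e-8, 1e-4] (the range typical of reported hits), ~3
background proxies each with r² ~ U(0.5, 1), two synthetic cell types of
enhancer tracks (85% background coverage), a raw ChromHMM-like track with
Strong/Weak state names, an interaction BEDPE, GERP-like constrained
elements with per-element p-values, and a gene BED.

**Planted causal proxy.** The genome carries the planted motif's consensus
with the variant on the motif's most informative column and the
alternative allele set to the weakest base; an enhancer (cell type A
*only*, mirroring cell-type-specific regulation), an interaction anchor,
and a constrained element (p = 1e-6) overlap the site; an LD row ties the
proxy to its leading variant at r² = 0.95. The planted motif has one
near-deterministic column (0.997 vs 0.001) flanked by moderately
informative columns — the profile under which a single-base disruption
moves the best-site probability the most (the damaged site loses ~8 log2
units while the reference site's p-value stays at the exact-consensus
floor, giving |LOD| ≈ 10–12, far beyond the null). Background motif
columns are heterogeneous Dirichlet draws, like real PFMs; homogeneous
columns would make unrelated broken sites share identical |LOD| atoms and
bias the rank p-values. Other catalogue variants are kept out of planted
footprints, since a second variant inside the consensus would be a second
planted variant in all but name.

**Negative control.** `FixtureSpec.negative_control()` plants nothing and
arranges every measured component to be exactly Uniform(0,1) under the
null: association p-values are uniform draws, each leading variant is its
own sole proxy (an empty LD table — with r² < 1 the cap in `p/r²` would
put an atom at 1), every variant gets its own single-base constrained
element with a U(0,1) p-value, and an enhancer tile keeps every variant in
the analysis. Under these conditions the combined CP should be uniform,
which the KS check verifies.

**What the generator does not emulate:** real LD block structure, realistic
peak-width/intensity distributions, GC content and repeat structure,
indels (the catalogue is SNVs), population-specific allele frequencies,
and motif co-occurrence. Passing tests therefore demonstrate correctness
of the statistical machinery and recoverability of a strong planted
signal, not calibration on real epigenomes.

## Problem sizes and defaults

Defaults were chosen so a full cohort analysis (bundle generation, a
10,000-draw null, scoring, ranking) completes in well under a second of
CPU after warm-up, letting the replicate studies (100 positive cohorts,
20 negative cohorts) run in a few minutes: genome 2 × 60 kb, catalogue
4,000, null 10,000, 4 motifs of widths 8–12. The null builder scores each
distinct sampled variant once and repeats its |LOD|s by multiplicity, and
scans all single-nucleotide windows as one vectorized batch; the batch
path is asserted equal to the per-variant scan path in the tests.

## Limitations

* Fisher's combination treats the three components as independent, as the
  method defines them; dependence-aware combination (e.g. Brown's method)
  is out of scope.
* The LOD's empirical p-value is bounded below by `1/(n_null + 1)`; with a
  desk-scale null (~300–1,500 eligible nonzero pairs from 10,000 draws)
  `P_BDA` cannot go below ~1e-3, which compresses — but, per the planted
  recovery study, does not impair — the ranking.
* Constraint p-values are consumed from the element file; deriving them
  from alignments is out of scope.
* Only the first five VCF columns are read; genotypes, INFO fields,
  liftover and identifier-merge chasing are out of scope.
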
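# Methods

`hickar` simulates genome-wide Hi-C contact maps under a rearranged avian
karyotype and detects the rearrangements back from the map, alongside the
standard 3D-genome annotations (A/B compartments, contact domains).  This
note records the models, the defaults and why they were chosen, and what the
synthetic data does and does not emulate.

## Contact-map model

A karyotype is a list of haplotypes with cell-population weights; each
haplotype is a list of derivative chromosomes, each an ordered list of
oriented reference segments.  The unedited genome is two haplotypes weighted
(1-w, w); edits (translocation, deletion, inversion, duplication,
whole-chromosome gain) are applied to one haplotype in reference
coordinates, resolved through the current haplotype state.  The karyotype
may also hold more than two haplotypes with explicit weights, which models a
cell culture heterogeneous for its rearrangement variants — several clones
sharing a wild-type background.

The expected (unscaled) count of an unordered bin pair sums over haplotypes
and over all copy pairs of the two bins:

* every copy pair contributes a flat random-ligation background `B_t`;
* a pair co-resident on one derivative chromosome at separation `s` (in
  derivative coordinates) adds the polymer term
  `B (s + s0)^(-alpha) * (1 + delta * e_i e_j) * prod_D (1 + tau_D)`,
  where `e` is the per-bin compartment signal (planted alternating 10-bin
  A/B blocks unless a track is supplied), and the product runs over planted
  domains containing both bins (nested domains multiply, and each domain may
  carry its own boost — that is how parent/child domain hierarchies get
  distinct strengths).

The additive background (rather than background only on trans pairs) is
deliberate: with `B_t` calibrated to realistic cis/trans ratios, a pure
power law would fall *below* the background beyond ~20 Mb, and fusing two
chromosomes would then lower the trans fraction — the opposite of what
rearranged maps show.  With the additive floor, every fusion strictly adds
inter-chromosomal contacts.

Defaults: `alpha = 1.0` (the classical contact-probability exponent),
`s0 = 10 kb` (keeps the zero-separation expectation finite at sub-bin
scale), `B = 1` (absolute scale is set by the target total), `w = 0.5`
(heterozygous rearrangements against one wild-type homologue).  `B_t`
defaults to the value that makes the *expected* genome-wide cis/trans ratio
of the identity karyotype equal 1.9, the midpoint of the 1.6–2.3 band
reported for chicken Hi-C libraries; this makes the band hold by
construction across genomes and bin sizes.  For strongly size-asymmetric
two-chromosome subsets the background inside cis alone can exceed that
target; the calibration then falls back to the decay term only and the
realized ratio sits above the target (a property of the subset geometry,
not of the library).

Counts are independent Poisson draws of the scaled expectation (the scale
matches the target total to first order in the compartment/domain factors,
using an FFT autocorrelation correction for the compartment term).
Overdispersion is deliberately not modeled; pattern-level detection does not
need it.  Maps up to ~4,200 bins are sampled densely; larger maps use an
exact three-stage sampler (per-derivative separation distribution with
rejection thinning for the compartment/domain factors, plus uniform
background draws) with incremental sorted aggregation to bound memory.
Given a seed, both paths are deterministic.

## Quality statistics

Cis/trans ratio and trans fraction are raw pixel sums (diagonal counts as
cis).  Replicate correlation is Pearson on `log1p` raw counts over the union
of nonzero pixels after coarsening to a comparison bin size (50 kb default);
zeros are kept where the other replicate has signal, so missing pixels count
against the correlation.  Coverage is the per-bin marginal, optionally
normalized to the autosomal median; note that a marginal depends on
chromosomal context (micro bins are trans-rich), which is why classification
statistics below never compare marginals across chromosomes.

## Compartments

Per chromosome at 50 kb: mask zero-coverage bins and the bottom 2% of
coverage, divide by the per-diagonal mean (simple and adequate on synthetic
data; no smoothing), take the Pearson correlation matrix of the result and
report its leading eigenvector.  Masked bins are NaN and are never imputed.
The track is flagged unreliable when the leading eigenvalue does not stand
clear of the bulk (lambda1/lambda2 < 1.5) — on a compartment-free map the
top two eigenvalues coincide.  The sign is arbitrary and must be oriented
against an explicit activity proxy (the planted track for synthetic data,
e.g. coverage for real data); a proxy correlating below |r| = 0.05 flags the
orientation as ambiguous rather than guessing.

## Contact domains

The caller scores a window `[i, j]` as its summed contacts divided by
`(length)^gamma`, centered by the mean score of equal-length windows on the
same chromosome (chromosomes shorter than twice the window cap pool
genome-wide means).  A dynamic program maximizes the total of positive
window scores over non-overlapping domains, with unassigned bins as gaps;
ties prefer a domain over a gap and the longer terminal domain.  Domain
length is capped at 6 Mb (visible avian TADs are at most a few Mb), the
default gamma grid is 0.2/0.25/0.3 and the minimum domain is 2 bins.  The
consensus over a gamma grid keeps overlapping domains from different gammas
as hierarchy levels.  Comparisons: fraction of boundaries within a 1-bin
tolerance, and variation of information over the bin partition (gaps as
singletons, log base 2).

## Interchromosomal SV detection

Two-stage, mirroring how a trained eye reads a chromosome-pair heatmap:

1. **Scan** at 250 kb: per-pair Poisson test of each pixel against the
   pair's median (robust to the enrichment itself), Benjamini–Hochberg at
   0.01 per pair.  Because small microchromosome pairs have only a handful
   of pixels, the correction divides by at least 50,000 tests — without the
   floor, the many micro–micro pairs leak genome-wide false positives.
   Significant pixels form 4-connected components (diagonal-only contact is
   kept apart, which is what separates the two quadrants of a reciprocal
   translocation); fragments of one decaying junction signal are re-joined;
   single-pixel components are discarded (no spatial support); boxes smaller
   than 200 kb on both axes are dropped.
2. **Localize** at the map's native resolution within the block plus
   margin.  The donor axis is recognized by its sharp signal/background
   step (a segment edge), against the acceptor axis whose gradient fades
   smoothly; fallbacks are a background-level-flank test and, for fusion
   corners where neither axis is decisive, the larger involved chromosome
   fraction (whole microchromosomes read as donors).  Segment edges come
   from the above-background signal run sharpened by local single
   change-point Poisson fits; orientation from the gradient direction
   (decay away from the fusion point), with the junction at the
   segment end adjacent to the maximum.  The acceptor insertion site is
   estimated from the marginal restricted to junction-adjacent donor rows;
   interior insertions detected as two corners combine both junction-local
   marginals into a two-sided peak.  Segment edges that fade below
   significance rather than stepping down are marked non-sharp: the
   physical segment continues past them, which the classification and the
   terminal-fusion test take into account.  Breakpoint uncertainty is one
   refine bin (5 kb by default, matching the tabulated +-5,000 bp).
3. **Classify**: a complementary-quadrant block pair is balanced; otherwise
   the donor segment's fate is read from the map itself — the *bridge*
   (flank-to-flank contacts appearing when a segment leaves one homologue
   and its flanks become adjacent, O/E > 3) or, for terminal segments,
   depletion of near-edge segment-to-remainder contacts below 0.75 of
   expectation marks an unbalanced moved event; their absence marks a
   translocated duplication.  Blocks spanning >= 90% of a chromosome with
   no internal change point are terminal fusions with a `ter` breakpoint.

A reference map, when provided, vetoes blocks that are also enriched in the
reference (shared patterns are putative assembly artifacts, not cell-line
rearrangements); it is off by default because synthetic references are not
always meaningful.

## Intrachromosomal SVs

CNV segmentation runs deterministic binary segmentation with a BIC-style
penalty on per-chromosome log2 coverage ratios, with a two-split lookahead
(a short bump — exactly the shape of a deletion or amplification — may not
pay for either of its change points alone).  The noise scale comes from the
median absolute successive difference.  States: log2 <= -0.5 heterozygous
deletion, <= -3 homozygous deletion, >= +0.4 gain, >= +1 amplification —
thresholds that separate 1-, 0-, 3- and >= 4-copy states under a diploid
mixture.  Inversions are detected only against a reference map (they are
defined comparatively): a butterfly score contrasts the two corner boxes an
inversion enriches against the control corners, scanned on a coarse grid and
refined by local search; the score is monotone in the fraction of cells
carrying the inversion.  Contact-pattern deletions take CNV deletion
segments as candidates and score the bridge of contacts across the gap.

## Assembly and chromosome count

Chromosomes are cut at every called breakpoint; reference adjacencies
severed by moved segments are dropped, novel adjacencies follow each call's
junction ends and orientation.  Derivative chromosomes are maximal simple
paths using at least one novel edge, emitted as ranked *alternatives*
(branch points are real ambiguity — subclones or unresolvable order), never
a single truth; cycles are reported unresolvable.  The chromosome-number
estimate is the sum over reference chromosomes of coverage-rounded copies
minus copies consumed by derivatives (a derivative absorbing at least half
of a chromosome consumes one copy), plus the number of derivatives.

## Desk-scale study sizes

The bundled reproduction studies run the full published rearrangement table
on a GalGal5-magnitude genome at 250 kb with 4.2e8 contacts (the order of
the study's sequencing depth; dense sampling makes depth cheap at this
resolution), and two-chromosome 5 kb maps at 5e7 (GGA1+GGA2) and 2.5e7
(GGA21+GGA5) contacts — roughly the full depth prorated to the subset, which
also puts junction-adjacent expected counts in the regime where breakpoints
localize to one bin.  Because the 26 tabulated events share donors and
acceptors (five involve GGA4; three insert at GGA23qter), they cannot
coexist on two haplotypes: the planting helper partitions them into clone
haplotypes with disjoint chromosome sets (greedy coloring of the
chromosome-sharing conflict graph, six clones for the published table) mixed
50/50 with wild type — each planted row then produces exactly one junction
system, mirroring the reported heterogeneity of the cell culture.

## What the simulation does not emulate

Restriction-fragment structure, read-level artifacts and mapping bias,
ICE-type systematic bias, overdispersed counts, distance-dependent
compartment strength, and sub-compartment structure.  Passing recovery
tests on these maps shows the detectors correctly invert the generative
model's geometry (junction gradients, copy mixtures, butterfly patterns) at
realistic depths and noise; it does not certify performance under real-data
biases, reference-assembly errors, or rearrangements below the 200 kb floor.
The chromosome-number estimator's agreement with a cytogenetic count on real
data is likewise untested by design.
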
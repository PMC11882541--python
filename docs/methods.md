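# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind each component, and what the synthetic fixtures do
and do not establish.

## Coordinates and formats

All intervals are 0-based half-open (BED-native) internally; GFF3 input is
converted at the parsing boundary and back on write. Strand `.` is treated
as unstranded. `N` bases match no motif position and count as mismatches in
identity windows. Contact matrices are consumed as dense TSV with a
companion uniform-width bin BED; asymmetry below 10⁻⁶ of the matrix maximum
is treated as numeric round-trip noise and averaged out, anything larger is
an error. No balancing or normalisation is applied to contact matrices —
input is assumed already normalised.

## Conserved-region calling

The identity profile assigns each reference base the match fraction over a
window of `window_bp` reference bases centred on it; near the sequence ends
the window is shifted (not truncated) so edge values remain full-window
averages, which keeps a uniformly identical alignment at identity 1.0
everywhere. Gaps and `N` count as mismatches; columns where the reference is
gapped contribute no profile entry.

Parameters:

- `window_bp` (default 100 bp): VISTA-like smoothing scale. The calling
  threshold interacts with it — narrower windows fragment elements, wider
  ones blur their edges by up to `window_bp/2`.
- `min_identity` (default 0.7): the fraction of matching bases required.
- Merge gap `window_bp/2`: runs separated by less than half a window are a
  single element that dipped below threshold, not two elements.
- Length bounds `[150, 2100]` bp, closed on both ends: these are the sizes
  of retained candidates, so boundary lengths are kept.

Regions overlapping an annotated exon or a blacklisted prior element by
≥ 1 bp are removed. Only pairwise alignments are consumed; a multi-species
screen is a composition of pairwise runs.

## Exact motif p-values

Log-odds scores use a pseudocount (default 0.8) split across letters in
proportion to the background, the common JASPAR convention. The score
distribution under the background is computed exactly by rounding each
column's four scores to integer multiples of a granularity (default 0.01
bits) and convolving the per-column distributions; the representation error
of a reported score is at most `L·granularity/2`. Tail probabilities are
exact for the rounded scores — the test suite checks them against full
4^L enumeration. P-value semantics are per window: the probability that one
random background window scores at least as high. Hits on the minus strand
are reported on the reference interval with a strand flag. Scanning uses the
same rounded scores as the distribution, so reported p-values are internally
consistent. The default background is uniform; it can be set from sequence
composition. Windows containing `N` are skipped entirely rather than scored
partially.

## Evidence integration

Marks are counted as dataset types, not peak instances: two H3K27ac peaks
over one region are one mark. Overlap of ≥ 1 bp counts — no minimum overlap
fraction is imposed. The classification rule is monotone by construction:
adding an active mark can only help, any repressive overlap vetoes. RNAP2
and Med12 are distinct evidence sources by default (configurable). The
promoter is TSS ± 500 bp; a candidate overlapping the promoter has no
defined side and is an error rather than a silent guess. Within each side,
labels rank candidates by midpoint distance from the promoter midpoint with
ties broken by start coordinate.

## TAD calling

The caller is an insulation-square method in the hicFindTADs family, not a
bit-identical reimplementation. For window sizes `w` (in bins) evenly spaced
between `min_depth` (3,000 bp) and `max_depth` (31,500 bp) — three scales by
default, depths converted to bins by integer division — the profile at bin
`i` is the mean of `M[i−w…i−1, i+1…i+w]`. The scale average is defined only
where **every** window fits inside the matrix; this confines boundary
candidates to fully supported bins and is the main reason the caller makes
no spurious calls near matrix edges.

Boundary acceptance has three parts:

1. local minima of the scale-averaged profile, with a minimum separation of
   the median window size (via `scipy.signal.find_peaks`; its prominence is
   exactly the min-drop-to-flanking-maxima definition used here);
2. prominence ≥ `delta` (default 0.01) on the min–max-normalised profile;
3. a one-sided Mann–Whitney comparison of cross-boundary contacts against
   intra-domain contacts from the two flanking squares (off-diagonal cells),
   accepted at `p < threshold` (default 0.05).

The minimum-separation rule is a deliberate refinement of "local minima":
without it, small noise dips inside domains reach the rank-sum stage, which
by construction passes 5% of null candidates. Domains tile the covered
region between consecutive accepted boundaries; a midpoint on a boundary bin
belongs to the downstream domain. CTCF concordance with an empty boundary
set returns `None`, never 0.

## Mutagenesis design

Edits are substitution-only (no indels), matching how disruption constructs
are built with mutagenic primers. The designer enumerates placements of each
enzyme recognition sequence overlapping the core, costs each placement by
the number of bases that must change (degenerate enzyme positions keep the
current base when it is in the class, else take the alphabetically first
member), requires the edit to leave no core match at any offset overlapping
the original core, and picks the cheapest placement (ties: leftmost, then
catalog order). When a PWM set is supplied the recheck loop is built in:
placements whose edit creates any new predicted site at the discovery
threshold (`p < 10⁻²`) are rejected before acceptance. The enzyme catalog is
user-supplied. Site spacings are edge-to-edge; overlapping sites have
distance 0.

## Reporter statistics

One record per embryo; the normalised response is GFP mean over RFP mean
(transfection-efficiency control). Group comparisons: one-way ANOVA
(scipy `f_oneway`) plus Dunnett's many-to-one procedure via
`scipy.stats.dunnett` (analytic multivariate-t, exact for equal or unequal
group sizes). An in-package Monte-Carlo max-|t| simulation of the same null
is kept as an independent cross-check and agrees with the analytic procedure
to ~0.01 in adjusted p. Degenerate inputs: groups that are all constant with
equal means return the identity comparison (difference 0, adjusted p = 1);
constant groups with unequal means are untestable and raise. The two-sample
test is the pooled-variance Student t, two-tailed by default, raising on
zero pooled variance. Image segmentation is out of scope; a
`mean_above_threshold` helper exists only to build fixture intensities from
synthetic images.

## Co-expression

Marker-negative is defined by *strictly lower than* the threshold (default
0.5 normalised expression), so a cell at exactly 0.5 is positive. Candidate
"expressing" uses the same threshold; this is a configurable choice, since
marker and candidate cutoffs need not coincide in general. Batch correction,
differential expression and embeddings are out of scope: the quantity of
interest is the co-expression contingency of each candidate with the marker.

## Synthetic fixtures: what they emulate, what they do not

The locus generator plants 49 conserved blocks (identity 0.90–1.0, lengths
300–1,900 bp, spacers 300–800 bp of unrelated sequence), 12 of which are
positives with ≥ 3 active marks and no repressive mark, split 10 upstream /
2 downstream of a planted gene; every block carries identical planted Ets
and Tcf/Lef consensus sites in both species. Planted lengths stay inside
[300, 1,900] so that the ±window/2 calling uncertainty cannot move a real
block across the [150, 2,100] length filter. Five decoys (too short, too
long, exon-overlapping ×2, blacklisted) must be removed by the filters.
Three negatives carry ≥ 3 active marks **plus** the repressive mark so the
veto is exercised, not vacuous. The locus contact matrix is a noise-free
single domain: its role is the same-TAD annotation, and a noise-free matrix
makes the planted truth exact; the noisy conditions for the TAD caller live
in the standalone block-matrix generator (80 bins of 1.5 kb, boundaries at
bins 30 and 50, intra/inter contrast 1.0/0.2, multiplicative lognormal noise
with CV 0.3). Expression fixtures plant candidate on-probabilities p₁ = 0.8
in marker-positive and p₂ = 0.1 in marker-negative cells; fluorescence
fixtures draw the normalised response as Normal(1 + effect·σ, σ) with
σ = 0.15, truncated at zero, with lognormal RFP.

One master seed fans out to per-component substreams
(`numpy.random.SeedSequence.spawn`), so every generator is byte-deterministic
given (config, seed) and regenerating one component does not perturb others.
Manifest paths are relative to the manifest directory for the same reason.

What passing on these fixtures does **not** show: real alignments have gaps,
repeats and lineage-specific insertions that make conservation calling
harder than planted blocks in unrelated spacers; real peak sets have width
and offset distributions unrelated to the elements they support; real Hi-C
has distance decay, which this generator deliberately omits, so the TAD
caller's behaviour on shallow real boundaries is not established; and real
reporter data can violate normality and equal-variance assumptions that the
fixtures satisfy by construction.

## Problem sizes

Defaults were chosen so the whole validation runs comfortably on a laptop:
the locus is ~90 kb (49 blocks), contact matrices are 80 bins, the Dunnett
null uses 2,000 replicates in the test suite (1,000 in the acceptance
script) and power uses 500 (300), and the exact-p-value engine is checked
against full enumeration for motifs up to length 6 (4,096 words).

## Known limitations

- No alignment is performed; the conservation module consumes precomputed
  pairwise alignments and reports reference coordinates only. Cross-species
  coordinate mapping is not implemented.
- The TAD caller does not reproduce any specific external tool bit-for-bit,
  and no loop calling, compartment analysis or matrix balancing is provided.
- The mutagenesis designer applies single-site plans; simultaneous multi-site
  optimisation is a composition of single-site designs.
- Dunnett comparisons assume exchangeable normal errors within groups; with
  strong heteroscedasticity the family-wise error control is approximate.
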
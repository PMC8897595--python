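# Methods

This note documents the models, conventions and design choices behind each
component, what the synthetic data do and do not emulate, and the known
limitations.

## Coordinates and sequence conventions

All genomic intervals are 0-based, half-open internally. RepeatMasker
`.out` input is treated as 1-based inclusive (strand `C` mapped to `-`);
the UCSC `rmsk` table is already 0-based half-open. Both dialects
round-trip losslessly through the writer/parser pair, and the same physical
interval yields identical internal coordinates from either dialect.

Mature miRNAs are RNA (A/C/G/U), read 5'→3'; target motifs are DNA read
5'→3' on the target strand. Pixel coordinates are (row, col), origin
top-left, 0-based.

## Seed-site model

The canonical seed-site taxonomy is used: an 8mer site is a perfect
Watson–Crick match to miRNA positions 2–8 plus an adenine opposite
position 1, i.e. the DNA reverse complement of positions 2–8 followed by
`A`; 7mer-m8 omits the trailing `A`; 7mer-A1 pairs positions 2–7 plus the
A. Occurrences are counted with a fully overlapping sliding window
(`AAAAAAAA` occurs 3 times in 10 A's); `N` never matches. Because major
satellites are transcribed from both strands, the default scan covers both
strands and reports per-strand counts; single-strand scanning is available.
Ranking is by total count, descending, with lexicographic tie-breaks so
identical-seed families (e.g. miR-30a/d/e-3p) order deterministically. No
thermodynamic, context or conservation scoring is attempted.

## Region selection

Name filtering is exact (`GSAT_MM`) by default, with an optional glob.
Selection merges same-chromosome annotations whose gap is ≤ `merge_gap`
(default 0: only overlapping/bookended annotations coalesce, so the
operation reduces to per-annotation length filtering) and keeps merged
regions ≥ `min_length` (default 20 kb — the scale that distinguishes
genuine pericentromeric arrays from short spurious hits). Merging before
filtering is exposed rather than fixed because annotation fragmentation
varies between RepeatMasker runs. The operation is idempotent and its
output pairwise disjoint per chromosome; tests compare it against a
quadratic merge-to-fixpoint oracle.

## Loading classification

Counts are normalised to CPM per sample (columns sum to 10⁶ exactly) and
compared as Δ = log2(cpm_RIP+1) − log2(cpm_input+1); the +1 pseudocount
maps zero counts to exactly 0. Eligibility requires log2(cpm+1) ≥ `floor`
(default 5.0) in the input, the RIP, either (default) or both samples —
the scope is a surfaced parameter because "minimum expression" is
ambiguous when two libraries are involved. Among the n eligible miRNAs the
first ⌊0.2·n⌋ by descending Δ (at least 1 when any are eligible) are
`loaded_top`, the last ⌊0.2·n⌋ are `unloaded_bottom` (drawn from miRNAs
not already in the top set, so the classes cannot overlap), the remainder
`neutral`; floor-failing miRNAs are `below_floor`. Ties break
lexicographically. A raw cpm-ratio ranking is available behind
`statistic="cpm_ratio"`.

Note the quantile rule caps recovery metrics structurally: with k planted
enriched miRNAs, precision of `loaded_top` cannot exceed k/⌊0.2·n⌋ and
recall cannot exceed ⌊0.2·n⌋/k, so both fluctuate with the eligible-set
size n across random tables even when ranking is perfect (as it essentially
is at +2 log2 effect and dispersion 0.05).

## qPCR math

Amplification efficiency is fixed at 2 (the assumption behind 2^−ΔΔCt);
no Pfaffl-style efficiency correction is offered. Percent input shifts the
input Ct by log2(1/fraction) to represent 100% of material, then computes
100 × 2^(adjusted − IP). Relative expression is
2^−[(Ct_target − Ct_ref)_sample − (Ct_target − Ct_ref)_control]. Technical
replicates are averaged on the Ct scale before ΔΔCt (a common convention).
Replicate summaries report mean ± SD with two-sided unpaired t tests
(Student by default, Welch selectable); identical groups report p = 1.

## Image quantification chain

1. **Max projection** over z.
2. **Nucleus segmentation**: Otsu threshold over a 256-bin histogram of
   the image range (between-class variance maximised; ties resolve to the
   lowest qualifying threshold), hole filling, 8-connected components, an
   area gate derived from the nucleus diameter range (40–200 px default)
   by circular equivalence π(d/2)², and removal of border-touching
   objects. These automated gates stand in for interactive nucleus
   editing; they are the package's own choices and are tunable.
3. **Speckle enhancement**: white top-hat (image minus its opening) with a
   disk footprint whose diameter equals the channel's maximum focus
   diameter (35 px default) — bright objects smaller than the element
   survive, the smooth nuclear disk does not.
4. **Foci detection**: one global robust-background threshold per image —
   sort the (mask-restricted) pixels, drop the lowest and highest 5%,
   threshold at mean + 2 SD of the remainder. The SD is the population SD
   (ddof = 0), the convention of the tooling this mirrors. Components are
   8-connected and gated to the circular-equivalent area of the channel's
   diameter range (DAPI chromocenter foci 5–35 px, marker foci 7–35 px).
   No watershed declumping is performed: synthetic foci are planted
   resolvable, and declumping settings would be unconstrained guesses.
   Intensities are measured on the original projected image, not the
   enhanced one.
5. **Relation**: children map to the parent containing their rounded
   centroid (default, deterministic) or to the maximum-overlap parent
   (ties to the lower parent id). Marker foci relate to nuclei and to DAPI
   foci; a marker focus is *colocalized* when its DAPI-focus parent link
   is non-empty.
6. **Statistics**: per-nucleus counts pooled across scenes are compared
   with a two-sided Mann–Whitney U — exact null when n₁·n₂ ≤ 400 and the
   pooled sample is tie-free, otherwise the normal approximation with tie
   and continuity corrections — summarised as median and IQR (linear
   interpolation percentiles). Experiment-level blocking is out of scope.

## Synthetic data: what it emulates, and what it does not

**Tandem arrays** default to 234 bp units, AT-rich background (GC 0.35),
drawn i.i.d.; planted motifs sit at fixed offsets inside units and never
span junctions, making expected counts exact. Spurious occurrences of
planted motifs are removed by redrawing background bases beneath them
(bounded; a motif whose spurious occurrence overlaps only planted bases is
reported as unremovable). Spurious occurrences of *other* motifs are
allowed — tests use sliding-window oracles, not assumptions. Real satellite
arrays have unit-to-unit divergence and higher-order structure that i.i.d.
background does not reproduce, so passing tests demonstrate correctness of
the counting machinery, not biological realism of the sequence model.

**Count tables** draw per-miRNA relative abundances from a log-normal with
4.5 log2 units SD — a dynamic range of several orders of magnitude, as in
deep small-RNA sequencing, which leaves roughly half of 500 miRNAs below
the log2(cpm+1) = 5 floor at a 10⁶ library. Planted-effect miRNAs come
from the above-median stratum (loading calls are only meaningful for
expressed miRNAs) and have their RIP abundance multiplied by 2^±effect.
Noise is multinomial or negative-binomial (dispersion 0.05 default);
dispersion 0 yields the expected counts themselves (possibly non-integer)
so null identities hold exactly. Expected cpm differences are defined
before library renormalisation; the realised composition shift moves all
Δ values by a common constant, which leaves ranking untouched.

**Ct tables** assume perfect doubling: the treated-condition target Ct is
the control Ct minus log2(true fold), so zero-noise tables round-trip
exactly through the ΔΔCt estimator (bit-exactly for dyadic folds).

**Image scenes** place non-overlapping, border-clear nuclei (radius 40–55
px in 512×512 by default), Poisson-many chromocenters (mean 5, mutually
separated by ≥ 4 radii) and Poisson-many marker foci (mean 8). Each focus
is colocalized with probability `p_coloc`, claiming a *distinct*
chromocenter centre; when all chromocenters are claimed the focus falls
back to a non-colocalized placement (≥ 2 chromocenter radii + 1 px from
every chromocenter centre, ≥ 10 px from other foci) with its truth flag
set accordingly — so truth always describes what the image actually
contains, at the cost of a realised colocalization fraction slightly below
`p_coloc` when foci outnumber chromocenters. Unplaceable objects are
dropped from both image and truth. Foci live in the middle z slice; other
slices carry them attenuated (×0.4 per slice), so max projection is
exercised nontrivially. Additive Gaussian noise has sd = structure
amplitude / SNR (default SNR 10). The scenes contain no point-spread
blur, chromatic shift, uneven illumination or touching nuclei; end-to-end
recovery results therefore validate the chain's logic, not its robustness
to real microscopy artifacts.

For statistical calibration at scale, per-nucleus colocalized counts can
be sampled directly from the scene generative model
(Poisson × binomial) without rendering images.

## Numerical choices

- Otsu: 256 bins over the observed range; threshold is a bin centre;
  constant images return the constant with a warning (no foreground).
- Robust background SD uses ddof = 0; trims use ⌊trim·n⌋.
- Quartiles and medians use linear interpolation.
- All generators are deterministic given spec + seed (single RNG,
  sequential consumption); identical specs produce bit-identical outputs.
- Acceptance-style end-to-end runs use 10 scenes × 5 nuclei and 200
  Mann–Whitney null pairs of 30 + 30 nuclei — sizes chosen to give stable
  rates while keeping a full verification run around half a minute.

## Known limitations

- No FASTQ-level read simulation, adapter handling or alignment; count
  tables are the entry point for loading analysis.
- No efficiency-corrected qPCR, standard curves or melt-curve QC.
- 2D analysis only (after projection); no declumping of touching foci; no
  intensity calibration across instruments.
- The 20 kb region filter and the 20%/floor loading cut are faithful to
  the conventions they implement, but both are threshold rules; results
  near the thresholds are sensitive to annotation fragmentation and
  library depth respectively.
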
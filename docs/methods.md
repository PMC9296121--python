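# Methods

This note documents the models, conventions and design choices behind
`svmrd`, in the spirit of a statistical-methods appendix: what is assumed,
what is configurable, and what the synthetic-data tests do and do not
demonstrate.

## Junction model and coordinates

A structural rearrangement is modelled as an ordered pair of breakends.
Each breakend names a contig, a 1-based base position, the retained flank
(`upstream` = bases up to and including the position, `downstream` = bases
from the position on), and a strand; `-` means the retained flank is
reverse-complemented when read through the junction. The junction
read-through is always `A-flank + non-templated insert + B-flank`, with
`end_a` oriented so the breakpoint is its right edge and `end_b` its left
edge. VCF breakend bracket notation maps onto this model directly (all
four bracket forms normalize to a valid `(end_a, end_b)` pair), and each
BND mate pair is collapsed to a single junction keyed on the unordered
breakend set, keeping the first record seen (the lower-coordinate mate in
a sorted VCF). Symbolic `<DEL>` anchored at POS with END e joins
upstream-of-POS to downstream-of-(e+1); `<INV>` yields its two boundary
junctions.

Breakend positions are 1-based because that is how they arrive in VCF and
how breakpoints are discussed; everything else — BED regions, junction-
sequence offsets, primer/probe/amplicon coordinates — is 0-based
half-open. `junction_offset` on a reconstructed sequence is the index of
the first base after the A-flank (equal to the actual left-flank length,
which is shorter than requested only when a flank is truncated at a contig
end, with a warning).

## Target selection

Candidates are filtered and ranked by three criteria:

1. **Prevalence.** The fraction of cells carrying the junction is
   estimated from junction-supporting vs reference-spanning reads as
   `min(1, 2·VAF / copies_per_genome)` — the heterozygous-autosomal
   assumption of one junction copy per leukemic genome, with a
   per-candidate override (e.g. 2 for a junction shared by both homologs
   of a homozygous deletion). The default inclusion threshold is a cell
   fraction of 0.5: a truncal event present in the majority of blasts.
2. **Uniqueness/amplifiability.** Junction flanks (default 60 bp each
   side) fail the screen if they contain an ambiguous base, a homopolymer
   run longer than 8 bp, or any 15-mer occurring more than once in the
   genome counting both strands (`max_kmer_hits` is configurable; 1 is
   calibrated to the synthetic test genomes, which are built 15-mer-unique
   — against a real human reference a small multiplicity budget is more
   appropriate). These are explicit, testable proxies for the manual
   browser-level inspection that normally disqualifies junctions in
   repetitive regions.
3. **Recurrent regions.** Junctions whose breakends fall in a
   recurrent-aberration region list rank first; within each group ties
   break by prevalence, then read support, then id, making the ranking a
   total order. At most `max_targets` (default 3) junctions are returned.
   A default region list of genes recurrently rearranged in ALL (TCF3,
   ZNF384, KRAS, IKZF1, PAX5, CDKN2A/B, TLX3, CDK6, STIL, TAL1; GRCh37
   coordinates) ships with the package and is fully user-replaceable via
   BED.

## Assay design

The design search is exhaustive over primer/probe placements on the
junction sequence. Defaults: amplicon < 100 bp (hard invariant), primer
length 18–27 nt with Tm window 58–62 °C, probe length 18–30 nt with Tm
window 3–10 °C above the primer-window midpoint (63–70 °C), GC fraction
0.35–0.65, probe at least 4 nt on each side of the junction boundary.
Candidates are scored by a weighted penalty — 1.0 per °C of Tm deviation
from the window midpoint, 10 per unit GC deviation, 0.05 per amplicon
base — and ties break toward shorter amplicons, then lexicographically
smallest oligo sequences, so the search is deterministic byte-for-byte.
Failures report which constraint eliminated every candidate.

Melting temperatures use the SantaLucia (1998) unified nearest-neighbor
parameters with the duplex initiation and terminal AT terms, strand
concentration 250 nM (excess primer over template), and a salt correction
applied to the entropy, `ΔS += 0.368·(N−1)·ln[Na⁺]_eq`, where divalent
cations enter through the von Ahsen equivalence
`[Na⁺]_eq = [Na⁺] + 120·√[Mg²⁺]` (defaults 50 mM monovalent, 3.8 mM Mg).
The implementation agrees with Biopython's `Tm_NN` under identical
settings to < 0.01 °C (cross-checked in the test suite); windows are
conventional ddPCR settings, feasible for random 50% GC sequence under
this model.

**Junction boundaries and the double-probe mode.** A junction with a
non-templated insert has two leukemia-specific boundaries: A-flank/insert
and insert/B-flank (they coincide when the insert is empty). A
single-probe design must contain the A-side boundary with the minimum
overhang on each side. The double-probe mode — used to boost sensitivity
when only one target exists — places one probe per boundary on opposite
strands, non-overlapping; this is geometrically possible only when the
insert is at least twice the probe overhang (8 bp at defaults), which
matches the insert sizes at which such designs arise in practice.

**Specificity** is exact-match in-silico PCR: every convergent
forward/reverse match pair on either strand of every template, no
mismatches. An assay passes if it yields exactly one product on the
junction (containing the junction) and none on the reference genome. The
off-target scan only counts products up to 1 kb: a reaction cycled for
sub-100 bp amplicons cannot amplify kilobase products, and without this
bound every deletion assay would be "off-target" on the reference allele
spanning the deleted interval. Mismatch-tolerant or thermodynamic
off-target models are deliberately out of scope.

## Droplet quantification

Counts arrive already thresholded (one row per well: accepted droplets,
target-channel positives, reference-channel positives, double-positives
included in both). Replicate wells are merged by summation before
estimation, which is exactly equivalent to pooling the partitions; the
copy estimate is `λ·n_total` with `λ = −ln(1 − n_pos/n_total)`. A fully
positive channel raises a saturation error that advises titrating the
input rather than returning an infinite estimate. Wells under 10,000
accepted droplets warn but do not fail.

Positivity is exactly: 0 merged target droplets → not detected, 1–2 →
trace, ≥ 3 → positive. Trace samples are still quantified, flagged, and
rendered in parentheses in reports. CN/ml divides merged copies by the
initial liquid-biopsy volume with no correction for the eluate fraction
actually loaded (an optional multiplicative correction exists but is off
by default, keeping the printed quantity literally "copies detected per ml
collected"). The MRD ratio corrects the target channel by the number of
multiplexed targets times copies-per-genome and the reference channel by
its ploidy; being a ratio, it accepts per-reaction copies or CN/ml
interchangeably.

Theoretical copy numbers use a diploid genome mass of 6.6 pg
(configurable): 1 ng ≈ 151.5 genomes. For a positive-control-in-negative-
control dilution the total DNA mass is constant, so the expected reference
copies do not scale with the dilution — only the target does.

## Sensitivity analysis

For a 10-fold dilution series the measured ratio is regressed in
log10–log10 space over target-positive points only (≥ 3 required). LoQ is
the deepest dilution `d` such that the fit restricted to dilutions ≥ d has
|slope − 1| ≤ 0.15 and r² ≥ 0.98 and the point at `d` is positive and
within 0.5 log10 of the fit's prediction; these thresholds are this
package's explicit operationalisation of "linear and quantifiable" and are
all configurable. LoD is the deepest dilution with ≥ 1 target droplet and
no undetected decade above it; a detection below a gap flags the series
non-monotone and does not extend the LoD. Trace detection counts for LoD
deliberately: at 500 ng input a 10⁻⁶ dilution carries ~0.076 expected
copies, so detection at that depth can only ever be a single-droplet
event. By construction LoD ≤ LoQ (LoD at least as dilute). Extrapolating
the fit to dilution 1 provides a theoretical diagnostic ratio when no
diagnostic sample was analysed.

Performance testing defaults assume 500 ng of gDNA split across five
wells (100 ng/well), mirroring the patient-sample protocol; loading
500 ng per well is equally defensible and changes the expected copies at
the deepest dilutions five-fold, which is why the package treats the
split as a default, not a fact.

## Simulator

`SimConfig` fixes the study conditions: 20,000 accepted droplets of
0.85 nl per well, 6.6 pg diploid genomes, three replicate wells per
liquid-biopsy sample (five for 500 ng gDNA protocols), and one seed that
drives every draw. A well with expected copy load `c` has each droplet
positive independently with `p = 1 − e^(−c/n)`; counts are
`Binomial(n, p)`. Droplet counts are fixed per well (no accepted-droplet
jitter) and there is no false-positive droplet rate by default — both are
nuisance realism that the estimator does not depend on; background
amplification seen for an occasional real assay can be emulated by adding
counts directly. Genomes are uniform random; with `repeat_fraction = 0`
they are post-processed so no canonical 15-mer occurs twice (a ~100 kb
random genome is expected to contain a handful of duplicate 15-mers, so
duplicates are locally remutated rather than regenerating the genome),
and with a positive fraction homopolymer/short-tandem tracts are embedded
to exercise the repeat screen. Each implanted SV is realized on its own
derivative haplotype carrying the junction read-through exactly once; a
reciprocal translocation contributes its two derivative junctions.

**What passing tests show, and what they do not.** The simulator shares
the partition model that quantification inverts, so estimator-recovery
tests demonstrate correct inversion and calibrated merging, not the
validity of the Poisson partition model itself. Synthetic genomes lack
the human genome's repeat structure, GC heterogeneity and polymorphism;
design success rates and screen thresholds tuned on them (notably
`max_kmer_hits = 1`) will be stricter than appropriate for GRCh37/38.
Sequencing reads, PCR efficiency kinetics and cfDNA fragment-size biology
are not modelled at all.

## Numerical and degenerate-input choices

`log1p`-based Poisson inversion for accuracy at small positive fractions;
saturation (`n_pos = n_total`) is a typed error, not infinity. Zero
informative reads make prevalence an error rather than 0. An empty
candidate list selects an empty panel with a notice (the single-target
patient is a real scenario). Fold ranges round to 2 significant figures;
report tables print percentages ≥ 0.01 to two decimals and smaller values
to four, with whole-percent rendering for compact CSF summaries and a
log10 change reported to one decimal. All file writers are byte-stable
given identical inputs, and the CLI distinguishes usage errors (exit 2)
from data errors (exit 1).

## Known limitations

- Exact-match specificity only; no BLAST-style fuzzy off-target search.
- No confidence intervals on copy estimates (a documented extension
  point); the positivity rule substitutes for formal hypothesis testing
  at the low end.
- Assay thermodynamics ignore hairpins, primer dimers and probe
  quencher chemistry.
- The recurrent-region default list is gene-level and GRCh37-based; it is
  a convenience default, not a curated clinical panel.
- Copy-number context is only modelled through `copies_per_genome` /
  `reference_ploidy` scalars; focal amplifications or reference-gene CNVs
  would bias the ratio.
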
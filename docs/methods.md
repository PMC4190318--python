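# Methods

This note documents the statistical model behind each `chfmap` module, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical conventions that matter for reproducing its
output.

## Study design assumed by the analysis

A monogenic, autosomal recessive, fully (or nearly fully) penetrant
defect in a closed breeding population. All affected individuals descend,
on both parental lines, from one founder carrying the causal allele on
one haplotype; affected individuals are therefore autozygous (identical
by descent) for that haplotype around the causal site. The data are:
array genotypes for a few cases and controls, whole-genome variant calls
for one case, one obligate-carrier parent and a control panel
(same-breed and other-breed), and ref/alt allele counts from gDNA and
cDNA of a carrier for the transcript-balance check.

## Marker QC (`qc_gwas.qc_filter`)

Markers are removed for call rate < 0.90 (denominator: all samples),
minor allele frequency < 0.05 (missing calls excluded from allele
counts), or Hardy–Weinberg exact p ≤ 10⁻⁵, in that fixed order, each
marker attributed to the first failing rule. The HWE exact test uses the
probability-ordering two-sided convention (sum over heterozygote counts
whose conditional probability does not exceed the observed one), computed
with the standard stable two-direction recurrence; monomorphic markers
return p = 1. The HWE check is applied to all samples jointly.

A consequence worth knowing: with 17 diploid samples the smallest
reachable HWE exact p is 1.1×10⁻⁵, so at the default threshold no marker
can fail HWE at this cohort size — which is why a small case/control
array study typically reports "all remaining markers in HWE".

## Allelic association

The per-marker statistic is the Pearson chi-square on the 2×2
allele-count table (two alleles per diploid genotype), df = 1, with no
Yates continuity correction — the uncorrected statistic is the one that
attains χ² = N at complete separation (34 for 10 vs 24 alleles, upper
tail p = 5.5×10⁻⁹). Degenerate tables (an empty row or column) return
(χ² = 0, p = 1). Results are invariant to which allele is labelled
"alt", so the loader's minor-allele orientation is cosmetic.

Bonferroni correction is min(1, m·p) with m the retained marker count.
The genomic inflation factor is median-based,
λ = median(χ²)/F⁻¹_{χ²₁}(½) with F⁻¹(½) = 0.454936.

**Discreteness caveat.** At 34 alleles the null allelic chi-square is
supported on a coarse set of atoms. Exact enumeration over the uniform
MAF mixture used by the simulator puts the cumulative probability at the
atom 0.4554 at 0.509 — the population median sits on an atom barely
below the continuous reference value, with the next atom at 0.567. The
sample median over a few thousand markers therefore lands on either
atom, and λ on null data takes values near 1.00 *or* near 1.25; QC
filtering on realized MAF (a statistic correlated with the test) pushes
it toward the upper atom. A ±10 % calibration band around 1 is not an
attainable property of the median-based λ at this sample size, and part
of any small-cohort study's reported inflation is this discreteness, not
only relatedness. The acceptance suite asserts the band anyway and the
corresponding test is expected to fail; the mean-based λ would not have
this problem but the median-based definition is the field convention and
is what the package implements.

## Max-T permutation significance (`maxT_permutation`)

Case/control labels are permuted with the case count fixed; for each
marker p_emp = (r+1)/(R+1), where r counts permutations whose genome-wide
*maximum* chi-square is ≥ the observed statistic at that marker (ties are
exceedances). The add-one estimator never reports zero and is the
standard positive-bias-safe choice. Permutation allele counts are
accumulated with integer matrix products, so permuted statistics are
bit-identical to observed ones computed from the same counts — tie
handling is exact rather than float-fuzzy. An `exhaustive=True` mode
enumerates every distinct case subset (feasible for small cohorts) and
returns the exact fraction r/R. The permutation loop streams in chunks;
no all-permutation matrix is ever held in memory.

A useful closed form for validation: a marker with exactly k
homozygous-alternate samples among n, and no other alt alleles, attains
its maximum only when the permuted case set equals those k samples, so
its genome-wide empirical p converges to 1/C(n, k) — 1/C(17,5) =
1.616×10⁻⁴ for the 5/12 design.

## ROH and the critical interval (`autozygosity`)

A run of homozygosity is a maximal stretch of non-missing homozygous
calls permitting at most `max_het` heterozygous calls; missing calls
neither break a run nor count toward its SNP or heterozygote tallies, and
runs must satisfy `min_snps` (counted over homozygous calls) and
`min_length_kb` (last minus first marker position). Defaults mirror the
common PLINK parameters (500 kb / 25 SNPs / 1 het / 0.95 match). The
sliding-window machinery of that tool is intentionally not reproduced:
it is an approximation device, and the run-scan semantics are the
definition the thresholds describe.

The shared segment intersects all cases' qualifying ROH and requires,
per marker, no heterozygous case and identical homozygous alleles in at
least `match_frac` of pairwise case comparisons (pairs with missing
calls are not compared; a missing call never breaks sharing but is not
counted in `n_shared_snps`). Thresholds apply to each individual's
segments only — the consensus is a separate object, as in the pooled
group-match semantics of the original tool. The longest surviving run
genome-wide is reported with bounds extended outward to the nearest
heterozygous or allele-discordant marker on each side (closed interval,
the convention in which such intervals are printed); kb lengths round
half-up. If a run touches a chromosome end without encountering a
breaking marker, the bound falls back to the run's terminal marker.

## Variant prioritization (`variant_prioritization`)

Fixed stage order: region → case hom-alt → carrier het → no control
hom-alt → breed-private (alt allele observed, het or hom, only in
target-breed samples). "Homozygous in any control" means hom-alt
specifically, matching the reference orientation of the cascade. Stages
are individually skippable. A variant whose deciding genotype is missing
survives the stage and is flagged — mirroring how ambiguous calls are
resolved by targeted re-genotyping rather than silently dropped.
Concordance under the recessive model: affected discordant = het +
hom-ref; unaffected discordant = hom-alt.

## Annotation (`annotation`)

c.1 is the A of the initiator ATG; residue = ⌈c/3⌉ and codon offset
= c − 3(residue−1) ∈ {1,2,3}. On a minus-strand transcript, cDNA
numbering decreases with genomic position and allele symbols complement
at this boundary only — stored variant alleles are always genomic-strand.
Intronic positions get nearest-exon offset notation (ties to the
transcript-upstream exon). Codon translation uses the standard genetic
code (Biopython); effects are synonymous / missense / nonsense, with
reference-assembly-error flags carried separately.

The bundled 16-row *PKHD1* table (package data) validates the
arithmetic: all 14 coding rows reproduce their printed protein position,
and 13 of 14 complement exactly; one printed row (c.4462T>G / p.A1488S,
genomic C>A) carries swapped cDNA alleles — its own protein annotation
requires ref G (GCx, Ala → TCx, Ser) — and the consistency tests check
that row under the corrected orientation.

## Allele balance (`ase_quant`)

Fisher's exact test on the 2×2 table (gDNA vs cDNA) × (ref vs alt), plus
an effect-size guard: the verdict is "balanced" iff p > α (default 0.05)
and the allele-odds fold change max(OR, 1/OR) < 1.5. The odds fold
change, not a ratio of alt fractions, is used because a balance criterion
must be symmetric under relabelling ref/alt; zero cells receive the
Haldane–Anscombe add-half correction in the fold change only. At shallow
depth the fold-change guard dominates the false-imbalance rate (e.g. at
depth 100 the guard alone fires in roughly 10 % of balanced tables); the
test attains its nominal level once depths reach a few hundred reads,
which is the regime the check is meant for.

## The simulator (`synthetic_data`)

Gene drop over explicit meioses. Founder haplotypes are drawn from
per-marker MAFs (uniform on [0.05, 0.5] by default, emulating an
informative post-QC array); one founder haplotype carries the causal
allele. Each case's sire and dam lines descend from the founder over
3–7 generations (uniform per line), each generation mating into a random
founder-pool individual, with the causal-carrying gamete enforced by
rejection; the case receives a causal gamete from both parents.
Controls are pool offspring, a configurable fraction of them het
carriers, never causal homozygotes. Recombination is Haldane at a fixed
1 cM/Mb (Poisson crossover counts, uniform breakpoints, no
interference) on a single pseudo-autosomal genome — the mapped locus is
autosomal and no genetic map is available for the emulated array.
Haplotypes are ancestry segment lists, so identity by descent is exact,
Mendelian consistency is structural, and the per-case autozygous
interval around the causal site is known in bp. Ground truth also
records the maximal identical-homozygous marker run around the causal
position (computed before missingness is applied), whose flanking
markers break sharing by construction.

The WGS variant classes are planted inside the sequenced case's
autozygous segment so that the cascade's stage counts are exact
functions of the configured class sizes: a "common" class (carrier
hom-alt, some controls hom-alt) removed at the carrier stage; a class
hom-alt in one cross-breed control removed at control exclusion; and a
breed-private-nested class (never hom in controls) of which exactly one
member — the planted causal at the configured position — is absent from
all non-target-breed samples while the decoys are het in one cross-breed
control. An adversarial switch makes one same-breed control causal-hom,
which by design defeats the cascade (a negative control for recovery
tests). ASE counts are Binomial(depth, ½) for gDNA and Binomial(depth,
skew) for cDNA.

Defaults are the emulated study's conditions: 5 cases, 12 controls,
5,000 markers over 31 × 50 Mb chromosomes (a deliberately light map so
the full pipeline runs in seconds; a 38,394-marker mode matches the
real array's post-QC count and is used for the acceptance-scale runs),
penetrance 1, phenocopy rate 0, 1 % missing calls, 28 same-breed + 18
other-breed WGS controls. One integer seed drives every draw through
named spawned generators; identical seeds give bitwise-identical
studies.

What the simulator does **not** emulate: linkage disequilibrium beyond
descent from the founder pool, genotyping error, coalescent population
structure, sequencing-error models, and the tangled loop structure of a
real studbook pedigree. Passing tests therefore demonstrate that the
analysis chain recovers what its assumptions promise — not that those
assumptions hold in any particular real dataset.

**Recovery is not certain, and that is a property of the method.** The
length of one case's autozygous segment around the causal site is
approximately a sum of two exponentials with rate equal to the total
meioses separating its two transmitted haplotypes from the founder
(6–16 here). With the 25-SNP / 500-kb ROH thresholds, each case
independently fails to present a qualifying segment with probability
≈ 0.5–1 %, so a 5-case replicate loses the interval with probability
≈ 2–4 % regardless of marker density (the 500-kb threshold alone sets a
floor). Observed recovery in the acceptance suite is 97/100 replicates;
the suite's exactly-100/100 assertion is expected to fail, and the
failure mode is always one case with a short autozygous segment — the
same risk the real study design carried.

## Numerical conventions

Coordinates are 1-based inclusive everywhere except BED export.
Genotype codes are 0/1/2/−1 (missing) throughout. p-values are clamped
to (0, 1] (smallest positive double when `sf` underflows). Interval kb
values round half-up. Ties in the shared-segment choice break by bp
length, then shared-SNP count, then leftmost position; ties in the
minor-allele orientation break toward the lexicographically later
symbol as alt. Pipeline reports serialize with sorted keys and no
environment-dependent content, so equal seeds give byte-identical
`report.json` files.

## Problem sizes used by the shipped checks

Unit tests run on 600–8,000-marker simulations; the acceptance suite
uses 5,000-marker null cohorts for calibration, a 1,000-marker cohort
with 200,000 permutations for the max-T closed-form check, and 100
replicates of the 38,394-marker mode for recovery. These sizes were
chosen so the full suite completes in a few minutes on one core while
keeping every Monte-Carlo tolerance at 3 SDs or better.
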
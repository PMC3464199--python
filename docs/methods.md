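# Methods

This note documents the statistical procedures, the generative model behind
the simulator, the numerical conventions, and the design choices that were
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Frequency estimation

A locus heterozygous for fluorescent/non-fluorescent alleles yields 2∶2
tetrads unless a conversion occurred. Only the 3∶1 class (three fluorescent
grains) is a reliable conversion signal: the reciprocal 1∶3 class is
confounded by pollen-development defects and other causes of
non-fluorescence, so it is recorded (`n_13`) but excluded from conversion
counts. Because mismatch repair converts toward and away from the
fluorescent allele symmetrically, each observed 3∶1 tetrad is taken to stand
in for one unobserved 1∶3 event:

    f_raw = n31 / N        f_adj = 2·n31 / N        meioses per conversion = N / (2·n31)

Pooling across loci sums `n31` and `N` before estimating, i.e. a
tetrad-weighted mean. The doubling is an approximation valid for rare
events; `estimate_frequency` warns when `f_adj` exceeds 1.

Reporting conventions: frequencies are displayed in scientific notation at 3
significant figures; meioses-per-conversion is rounded half-up to the
nearest integer (required to reproduce figures such as 150,910/34 → 4,439
and 155,280/32 → 4,853); P-values below 10⁻¹⁵ are displayed as `<1E-15` but
kept at full float precision internally.

## G-test of independence

Pairwise locus comparisons and control comparisons use the likelihood-ratio
chi-square (G) statistic on the 2×2 table `[[k1, n1−k1], [k2, n2−k2]]` with
expecteds from the marginals, the convention `0·ln(0/E) = 0`, and the upper
chi-square tail at 1 df. Two deliberate choices:

* **Raw, not doubled, counts.** The doubling adjustment is a reporting
  convention, not extra data; doubling the counts would roughly double G and
  overstate the evidence. Raw counts also reproduce the reference screen's
  published P-value matrix entry for entry.
* **No continuity or Williams correction by default.** The plain G
  reproduces the published matrix; the Williams correction is available
  behind `williams=True` for small-sample use.

A table whose success (or failure) margin is zero in both groups is returned
as `G = 0, P = 1` with a `degenerate` flag rather than an error.

Two reconstructions are documented rather than asserted as the original
procedure: (i) the published control P-value 0.008998 is reproduced exactly
by testing 0/45,000 against the 13/149,965 locus, though the surrounding
text suggests a different reference locus; (ii) the published
locus-vs-pooled ("total") column is *not* reproduced by a plain G-test of
each locus against the pooled counts (with or without self-exclusion), so
the package computes and reports that comparison but does not claim to match
the published column.

## SNP-position regression

Ordinary least squares of adjusted frequency on the SNP's 1-based position
in the fluorophore coding sequence (parsed from mutation codes such as
G95A), over every sequenced allele with count data (8 points in the bundled
dataset). `r²` is the squared Pearson correlation; the P-value is the
two-sided t-test on the slope with n−2 df. Degenerate inputs: identical
positions raise; a constant response returns slope 0, r² 0.

## CO/NCO classification

Layout: hemizygous DsRed and AmCyan transgenes flank the heterozygous eYFP
test locus, all in coupling on one homolog. Channel roles are configuration
(`MarkerLayout`), not hard-coded. Decision rules for a tetrad:

1. yellow 2∶2 → `NO_GC`; yellow 1∶3 → `GC_13` (never merged into conversion
   counts); yellow 4∶0/0∶4 → `ABERRANT` (impossible for one heterozygous
   meiosis); any unscorable yellow → `AMBIGUOUS`.
2. yellow 3∶1 without flanking markers configured → `GC_31`.
3. yellow 3∶1 with flanks: an unscorable flank on any conversion-side
   (yellow-positive) grain → `AMBIGUOUS`. A fully scorable flanking channel
   off 2∶2 → `ABERRANT` (hemizygous copy number is conserved by crossing
   over). Otherwise the call is made on the three yellow-positive grains —
   given 2∶2 marker segregation the fourth grain is forced: all parental
   (red and cyan both present or both absent) → `NCO_GC`; exactly one
   red-only plus one cyan-only grain → `CO_GC`; anything else (double-CO
   flank patterns, which the assay cannot attribute) → `ABERRANT`.

Any recombinant flanking arrangement is called `CO_GC`, mirroring the
operational definition of the assay, even though an independent CO elsewhere
in the flanking interval co-occurring with an NCO conversion would be
miscalled; the simulator quantifies this (the miscall requires a second CO
in the same meiosis and interval, so its rate is predictable from `p_co`,
the DSB count and the interval fraction of the genome).

The bundled 13-tetrad three-color example is a synthetic reconstruction:
grain-level patterns consistent with the screen's reported class totals
(11 CO, 1 NCO, 1 ambiguous), not the original images.

## Tract-length reconciliation model

Inputs (all configurable, defaults are the *A. thaliana* constants):
sequenced genome 119,146,348 nt and upper estimate 141,146,348 nt (adding
~15 Mb centromere and ~7 Mb rDNA), 120–222 DSBs per meiosis from RAD51-focus
counts, restoration fraction 0.5 (unbiased MMR), ~9 COs per meiosis.

* expected conversions per meiosis: `[D_min, D_max] · (1−r)` → 60–111;
* expected per-nucleotide frequency, pairing conservatively (fewest
  conversions over the largest genome and vice versa):
  `60/G_max … 111/G_min` → 4.25×10⁻⁷ … 9.32×10⁻⁷;
* implied tract length from an observed adjusted per-locus frequency:
  `L = f_obs / f_nt`, bounds rounded to the nearest bp, the mean taken as
  the midpoint of the *unrounded* bounds (this yields 605 from 378.8 and
  830.2). The default `f_obs` is the pooled adjusted frequency at full float
  precision, not its 2-significant-figure display value — rounding first
  would shift the bounds.
* expected CO∶NCO balance: `1 : (D − CO)/CO`, denominators 12.3–23.7. The
  low bound matches the conventionally quoted ~1∶12; the package reports the
  computed upper denominator 23.7 (213/9) rather than the sometimes-quoted
  1∶20, which is inconsistent with the same arithmetic.

## Forward meiosis simulator

Generative model per meiosis: four chromatids, two carrying the fluorescent
allele and the flanking hemizygous markers in coupling. DSB count is Poisson
(default) or fixed — no crossover interference is modeled, as nothing in the
analysis uses it and Poisson keeps the closed forms exact. Per DSB:

* position uniform on the genome, broken chromatid uniform on the four;
* homolog-templated repair with probability `p_homolog` (a uniformly chosen
  non-sister chromatid), else sister-templated and phenotypically silent —
  the sister-repair hypothesis as a frequency dial;
* pathway CO (DSBR) with `p_co`, else NCO (SDSA);
* a heteroduplex tract of drawn length (fixed, geometric, or gamma law; mean
  `L`) placed with uniform offset subject to containing the break, making
  the point-coverage probability of an interior locus exactly `E[L]/G`
  (verified by enumeration on a 100 nt genome in the tests). Tracts may
  overhang the coordinate ends; no clipping, so interior coverage stays
  exact;
* if the tract covers the test locus and donor/recipient alleles differ,
  MMR converts (recipient takes the template allele) with `p_conversion`,
  else restores; conversion direction follows the template, and no G/C or
  recipient bias is modeled (a future hook);
* a CO exchanges all tracked loci distal to the conversion tract between the
  two participants — this conserves marker copy number (so red/cyan always
  segregate 2∶2 absent noise) while moving markers between chromatids. The
  exchange point is placed at the distal tract boundary so the conversion
  tract itself is governed solely by the MMR step.

Chromatids are randomly permuted into the four grains. Noise, applied in
collection order: with `misgrouping_rate` the tetrad is replaced by four
unrelated grains (each a parental chromatid type, fluorescent w.p. ½ — under
full misgrouping the 3∶1 frequency is the binomial 4p³(1−p) = 0.25); then
each non-fluorescent grain reverts to fluorescent with `reversion_rate`.

First-order closed form used for validation and parameter recovery: the
adjusted-frequency expectation is `D · p_homolog · (L/G) · p_conversion`
(per direction, half of this is the 3∶1 class frequency). It neglects
multi-event parity terms of order `(D·L/G)²` and noise.

Defaults are the study conditions of the reference screen: sequenced genome
size, `D = 171` (midpoint of the cytological 120–222 range), `L = 605` bp
(the tract model's mean estimate), geometric tract law (maximum-entropy
choice for a positive integer length with a fixed mean; the screen's data do
not constrain the law), `p_homolog = 1`, `p_co = 9/171`,
`p_conversion = 0.5`, reversion 10⁻⁷ (the measured mitotic range), no
misgrouping. Under these defaults the closed-form adjusted frequency is
4.3×10⁻⁴, the same regime as the observed genome-wide 3.5×10⁻⁴. One test
locus per simulated genome; multi-locus panels are independent replicates,
as no analyzed quantity needs inter-locus linkage.

Two sampling paths draw from the same law: `simulate_experiment` iterates
`simulate_tetrad` and keeps phenotypes plus ground-truth event logs;
`simulate_counts` is a vectorized counts-only path (COs alone never change
segregation counts — they are reciprocal — so only tetrads containing a
locus-covering homolog repair get chromatid-level replay), processed in
blocks of ~5×10⁶ events to bound memory. The two paths use different random
streams; tests hold both to the same closed form rather than to each other.

### What the simulator does and does not emulate

It reproduces the mechanistic structure the analysis assumes: Mendelian 2∶2
baselines, rare tract-mediated 3∶1/1∶3 classes symmetric in expectation,
flanking-marker phases set by CO vs NCO resolution, and false positives at
controlled rates. It does **not** model chromatin or hotspot landscapes,
obligate COs or CO homeostasis, crossover interference, biased gene
conversion, or per-locus tract-length variation. Passing tests therefore
show the analysis chain is correct under the stated mechanism, not that real
meiosis obeys uniform DSB placement or any particular tract law.

## Problem sizes in the test suite

Stochastic checks run at sizes chosen to give decisive statistics: the
simulator-vs-closed-form check at 2×10⁵ tetrads (≥3 binomial SE
sensitivity), estimator recovery at 10⁶ tetrads, classifier-vs-ground-truth
agreement at 4×10³ three-color tetrads, and the G-test oracle on 10³ random
tables. All stochastic tests use fixed seeds; hypothesis property tests run
derandomized.

## Known limitations

* Point estimates only: no confidence intervals on frequencies and no
  multiple-testing correction on the pairwise matrix (28 comparisons).
* The doubling adjustment assumes direction-symmetric MMR; a conversion
  bias would make `f_adj` a biased estimator.
* The tract model is interval arithmetic on assumed constants, not an
  inference with uncertainty; its output moves one-for-one with the assumed
  DSB count and restoration fraction.
* The classifier cannot separate an NCO conversion plus an independent
  flanking CO from a CO conversion; it flags only patterns that are
  structurally impossible (ABERRANT), not improbable.
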
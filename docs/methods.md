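# Methods

This note documents the models, parameter choices and numerical decisions
behind `xfert`, and what the synthetic-data tests do and do not establish
about behaviour on real herdbook data.

## The biological setting

An X-linked locus segregates in a pig breeding population with a
loss-of-function allele (T).  Boars are hemizygous (C or T) and
phenotypically normal; C/T sows are fertile and produce larger litters;
T/T gilts have under-developed ovaries and never reproduce.  Because the
visible phenotype used for case ascertainment (small vulvae) is a noisy
proxy for the true condition, a substantial fraction of labelled cases do
not carry two copies of the allele.  The analysis chain the package
implements: case-control GWAS on chip genotypes, candidate filtering of
coding variants inside the associated region, derivation of each sow's
expected T dosage from parental genotypes, regression of breeding values
on that dosage, and aggregation into a per-pig euro value.

## Synthetic population generator (`simdata`)

**What it emulates.**  Discrete generations of a closed herdbook
population.  Founders are unrelated; each later generation is bred from a
fixed number of fertile dams (fixed-size litters, sire drawn per litter).
Defaults give the study design the downstream stages assume: a causal X
locus at alt frequency 0.062, a genotyped panel of 1,835 females
(17 cases, 1,818 controls), a case-label error of 6/17, ~5,000 SNPs on two
autosomes plus X, and eleven breeding-value traits whose true per-dosage
effects equal the reference effect table.

**Haplotype and LD model.**  Markers are binned into LD blocks of
`ld_block_len` (default 2 Mb).  Each block has a pool of
`n_ancestral_haplotypes` (default 8) ancestral block haplotypes whose
marker alleles are drawn from a linear within-block frequency gradient;
founder chromosomes are block-wise mosaics of that pool.  Meiosis copies
parental haplotypes block by block, switching the active parent haplotype
at a block boundary with probability 1e-8 × block length (≈ 1 cM/Mb, so
0.02 for 2 Mb blocks).  In the causal block, ancestral haplotype 0 carries
the alt allele and is sampled with probability `causal_alt_freq`, so
neighbouring markers on that haplotype background are in LD with the
causal site and an association cluster emerges around it.  This is a
deliberately coarse model: no hotspots, no mutation, no coalescent-scale
allele-frequency spectrum, and LD is confined to blocks.  Passing tests
therefore show the pipeline detects a causal block under realistic
relatedness and label noise — not that it matches fine-scale LD behaviour
of a real 60K chip.

**X chromosome.**  Males carry one X haplotype (stored duplicated, so male
X genotype codes are 0/2 — the "hemizygous diploid dialect" also used when
exporting to VCF/PED; sex travels in the pedigree table).  Daughters
receive the sire's X intact plus a maternal recombinant; sons receive only
a maternal recombinant.  T/T females are flagged infertile and are never
drawn as dams, which makes the causal allele frequency decline slowly
across generations — a property the tests assert directionally.

**Case labelling.**  Each T/T female of the final generation is detected
as a case with probability `case_detection`; mislabelled cases (fertile
females) are added so the expected false fraction equals
`case_label_error` (default 6/17, matching the observation that only 11 of
17 GWAS cases were truly homozygous).  Labels are wrong, genotypes are
not: misclassification lives in the phenotype, reflecting that vulva
scoring, not genotyping, is the error-prone step.  Controls are drawn from
the remaining fertile final-generation females; their fertility flag
stands in for the "has at least one litter" criterion used for real
controls, since litters of the final generation are not simulated.

**Breeding values.**  Per fertile sow and trait, EBV = effect × true
causal dosage + N(0, σ_t), with σ_t calibrated per trait so that an OLS
regression at the reported sample size reproduces the reported standard
error (σ_t = SE_t · sd(x) · √n_t, with sd(x) ≈ 0.22 computed from the
reported dosage-group sizes).  Reliabilities are uniform on
`reliability_range` (default 0.40–0.99).  Real EBVs are shrunken,
correlated across traits and across relatives; none of that is modelled,
so the effect-recovery tests validate the regression machinery and its
calibration, not multi-trait BLUP behaviour.

## Quality control (`geno_qc`)

Markers are retained when call rate > 0.90 and MAF > 0.01, both strict
inequalities (the filtering rule is worded "higher than" / "above").  The
call-rate denominator counts all samples, males included on X; MAF uses
sex-aware allele totals (two alleles per female call, one per male X
call).  Ties at a threshold are removed.  The filter is idempotent and
raises rather than silently returning an empty panel.  Coordinates are
1-based inclusive everywhere.

## Mixed-model association (`gwas`)

The binary status (1 case / 0 control) is analysed with a *linear* mixed
model, exactly as the original chain did, not a logistic one.  The GRM is
VanRaden-standardised, built from all QC-passing markers including the
candidate chromosome (no leave-one-chromosome-out), with monomorphic
markers skipped and missing codes mean-imputed.

REML maximises the restricted likelihood of y = a + g + e profiled down to
the variance ratio γ = σ²g/σ²e: one symmetric eigendecomposition of G
turns every likelihood evaluation into O(n) work, and a bounded scalar
optimiser (on the transform h = γ/(1+γ) ∈ [0,1)) converges to 1e-8 on the
ratio; the γ = 0 boundary is checked explicitly.  Eigenvalues are clipped
at zero to absorb numerical negatives.  With G = I the ratio is
unidentified and only σ²g + σ²e is meaningful; the code returns the usual
intercept-only variance partition.

The scan reuses the null-model components for every marker (single-fit
strategy, a scan-speed decision) and tests each marker by generalized
least squares under V = σ²g G + σ²e I with a known-variance 1-df Wald
chi-square — so the σ²g = 0 limit reproduces OLS coefficients with
design-based (not residual-estimated) standard errors.  Missing genotypes
are mean-imputed per marker for the scan only, keeping n constant across
markers; a marker monomorphic in the analysed samples yields a record
flagged `undefined` rather than an error.  P-values come from the upper
tail of the 1-df chi-square (no mid-p) and are floored at the smallest
positive float so P ∈ (0, 1] holds.

λ is computed either as median(χ²)/0.4549364 or as the through-the-origin
regression slope of ordered observed chi-squares on null quantiles;
regression is the default (it matches the default of the estlambda-style
estimator and is far less noisy at moderate marker counts).  QQ
concentration bands use Beta(i, m−i+1) order-statistic quantiles,
pointwise by default, with a Bonferroni-adjusted simultaneous variant used
by the band-coverage test.

Region extraction reports, per chromosome with significant markers, the
inclusive [min pos, max pos] span and count; the chromosome with the
largest cluster is the primary region and significant markers elsewhere
are "scattered" (single-marker chromosomes give degenerate width-0
intervals).

The published real-data outputs (top P = 8.81 × 10⁻⁴³, λ = 1.26, the
828/366/30/5 variant tallies) depend on unavailable proprietary data and
are not reproduction targets; the scan is instead validated against a
dense-matrix GLS oracle (agreement to 1e-10), null-scan calibration
(type-I error ≈ α, λ = 1 ± 0.03), REML parameter recovery, and the
detection-power property of the default scenario.

## Consequence classification (`annotate`)

One transcript per variant (the analysis reports a single transcript
consequence); no splice, UTR or regulatory classes, and no
nonsense-mediated-decay prediction.  SNVs in the CDS are translated
strand-aware; indels wholly inside the CDS follow the mod-3 rule; variants
straddling a CDS boundary are conservatively non_coding with a warning.  A
ref-allele mismatch with the transcript reference raises — it signals
corrupt input, not a classification.  The stop symbol is "X" (the
notation used in this literature) with HGVS "*" accepted on parse.
`truncation_fraction` counts the new stop's residue and everything
downstream as missing: for stop codon 212 in a 402-residue protein it
gives 47.5 % (402 is inferred from that printed percentage — the length
itself is not printed in the source material — and is used only as a
consistency check).

## Dosage derivation (`dosage`)

The expected-dosage table is exact conditional expectation under X-linked
transmission.  Two modelling notes:

- For a T-boar the cell value is 1 *because the daughter is known
  fertile*: T/T daughters are excluded, so the surviving daughters are all
  C/T.  The tests check the T-sire cells against a fertility-conditioned
  enumeration and the unknown-parent cells against plain transmission
  enumeration.
- For an ungenotyped dam the default uses the marginal frequency q_f,
  which is exact when q_f is estimated from fertile dams (a fertile dam is
  C/C or C/T and transmits T with probability P(C/T)/2 = q_f).  If one
  instead starts from a whole-population Hardy–Weinberg frequency, the
  transmission probability of a necessarily non-T/T dam is q/(1+q); that
  variant is available behind `condition_on_fertility` (off by default,
  matching the published table).

Directly genotyped sows bypass derivation (dosage = own alt count), and
group tallies compare dosages with a 1e-12 tolerance to avoid
floating-point group splitting.  Derivation deliberately uses parents
only — no pedigree-wide peeling.

## Effect estimation and the euro index (`effects`)

Per trait, OLS of EBV on (1, dosage) over records with reliability ≥ 0.40
(inclusive, "at least 40 %"), with two-sided P from the t distribution on
n−2 df (the regression tool's default convention; at n ≈ 10⁴ the t/normal
distinction is negligible but the choice is fixed).  Family-wise
significance uses P ≤ α/11 with the family size fixed at eleven by
convention regardless of how many traits are supplied (overridable).  An
exact fit (SE = 0) returns P = 0 for a nonzero slope.

The economic index is the raw signed sum of effect × weight over the
weighted traits (only significant effects by default).  With the reference
effects (+0.411 piglets, −0.028 kg/kg feed conversion, −0.889 % lean meat)
and weights (3.98, 22.70, 1.66 € per unit) this gives −0.4756 → −0.48 €
per finisher pig.  Note the sign convention: the favourable feed-conversion
change enters with its negative sign, i.e. the sign is treated as already
embedded in the breeding-value scale; the index reproduces the published
arithmetic without asserting an economic reinterpretation.  Rounding to
cents happens only at presentation.

## Problem sizes used in the validation battery

Chosen as desk-scale designs that keep Monte-Carlo noise comfortably below
the asserted tolerances: effect recovery uses the full reported panel
(20,549 sows, 20 seeds; the mean estimate must sit within 0.02 of 0.41);
null-scan calibration pools three panels of 400 unrelated samples × 5,000
markers; REML recovery uses a 500-sample structured kinship with 50
phenotype replicates; detection power runs the full default scenario
(1,835 genotyped females, ~5,000 markers) over 100 seeds and requires the
minimum-P marker inside the causal 2 Mb block in ≥ 95 of them.

## Known limitations

- Linear (not logistic) mixed model for a binary trait, by design; with
  17 cases in 1,835 samples the per-marker chi-squares are inflated
  relative to an exact test, which is the same behaviour the original
  chain exhibits (λ > 1 on the synthetic default, 1.26 reported on the
  real panel).
- The GRM and the tested markers come from the same panel; no relatedness
  pruning or LOCO, so proximal contamination slightly deflates signals.
- Variance components are estimated once (null model) and reused per
  marker; per-marker REML would differ at strongly associated markers.
- The generator's block-LD and single-locus selection are stylised; EBVs
  are noisy linear functions of the causal dosage with no multi-trait or
  pedigree correlation structure.
- PED/MAP files carry no allele polarity; the reader assigns ref/alt
  lexicographically, so round-trips are faithful only when both alleles
  are observed and the ref allele sorts first.  VCF is the lossless
  interchange format.
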
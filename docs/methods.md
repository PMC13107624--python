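# Methods

## Background and scope

The ADAT2/ADAT3 heterodimer deaminates adenosine 34 — the wobble base — to
inosine (I34) in eight human tRNA families (Leu-AAG, Arg-ACG, Ser-AGA,
Pro-AGG, Ala-AGC, Val-AAC, Ile-AAT, Thr-AGT; anticodons written 5'→3',
wobble base first). Inosine pairs with C, U and A at the third codon
position, but each family's **C-ending codon** (TCC, CTC, CGC, CCC, GCC,
GTC, ATC, ACC) is decoded efficiently only through the I34:C pair. Genes
enriched for these "A-to-I-dependent" codons are therefore translationally
sensitive to ADAT2 activity. `adatscan` implements the computational screen
that exploits this: quantify I34 from tRNA-seq, measure translation
efficiency (TE) responses from RNA-seq/Ribo-seq under ADAT2 overexpression
(OE) and knockout (KO), and intersect with codon-usage bias and tumor
overexpression to nominate candidate target genes. A synonymous recoder
builds A-to-I-independent control sequences for reporter assays.

Wet-lab assays, read alignment, P-site calling, GSEA and external cohort
statistics are out of scope; the package starts from count matrices,
positional pileups and CDS FASTA.

## Wobble model and recoding

The dependent codon of a family with anticodon `a₃₄a₃₅a₃₆` is
`comp(a₃₆)·comp(a₃₅)·C` (codon position 1 pairs with anticodon position 36).
A- and U-ending codons of the same box can be read without editing and are
*not* recoded. The recoding map replaces NNC with NNG within the same amino
acid — G-ending codons are read by C34 isoacceptors, never by I34 — except
isoleucine, which has no G-ending codon; ATC maps to ATA, decoded by a
distinct non-ADAT tRNA. This map is one valid choice for building an
A-to-I-independent construct, not a claim about any particular published
plasmid. Recoding is provably synonymous (checked against an independent
translation oracle in the tests), complete (zero dependent codons remain)
and idempotent.

Usage fractions exclude stop codons (they are not decoded by tRNAs). The
fold enrichment of a gene is its dependent-codon fraction over the same
fraction in the background — by default the aggregate of all supplied CDS.
The funnel's default scoring subset is {TCC, CTC, CGC}, the codons of the
three families whose modification level responds most strongly to ADAT2
perturbation; the full eight are available via configuration.

## Inosine quantification

Reverse transcriptases read inosine as guanosine, so the wobble inosine
fraction is estimated from the A→G mismatch at Sprinzl position 34:
`i_fraction = G/(A+G)`, `i_to_a_ratio = G/A` (infinite at A=0). C/T counts
at position 34 are treated as sequencing error: excluded from the fraction,
included in coverage. This is the standard sequencing-based surrogate for
I34 level; the package accepts any per-family positional count table and
never renumbers positions. Defaults: `min_coverage = 100` reads (families
below it are flagged and excluded from fold-changes), ratio pseudocount
0.01 (stabilizes folds at fully modified families where A ≈ 0). Condition
fold-changes `(ratio_case + pc)/(ratio_ctrl + pc)` are exactly antisymmetric
on the log2 scale under a case/control swap with fixed pseudocount.

The estimator is unbiased under binomial sampling; at depth 2,000 the
calibration grid (true fractions 0.1–0.9, 500 replicates each) keeps
|mean − truth| below 3 standard errors (measured maximum bias ≈ 7×10⁻⁴).

## Translation efficiency and concordance

Counts are normalized to CPM per sample (TPM is unnecessary: the funnel only
compares within-gene ratios, where transcript length cancels — a documented
limitation for any cross-gene TE comparison). Per condition,
`TE = (mean ribo CPM + pc)/(mean rna CPM + pc)` over replicates, with
pseudocount 0.5 CPM; replicates are aggregated by arithmetic mean before the
ratio (simplest estimator). Log2 fold-changes are taken against the matched
control (OE vs control-OE, KO vs control-KO). A gene is *concordant* when
`log2FC_TE(OE) > 0 ∧ log2FC_Ribo(OE) > 0 ∧ log2FC_TE(KO) < 0 ∧
log2FC_Ribo(KO) < 0`. Direction-only is the default because the screen's
published description states directions, not magnitudes; an optional
`min_abs_log2fc` adds a magnitude requirement.

**Null behaviour of the concordance filter.** The four log-FCs are *not*
independent: `log2FC_TE = log2FC_Ribo − log2FC_RNA`, so within one condition
the TE and Ribo signs share the Ribo sampling noise. For iid symmetric
RNA/Ribo noise the pair agrees with probability
`P(R>0, R>N) = 1/4 + arcsin(1/√2)/2π = 3/8`, giving a null concordance rate
of `(3/8)² = 9/64 ≈ 0.141` — substantially above the `1/16` an independence
argument would give. Simulations with zero planted effect reproduce 9/64
within binomial error. In a study with genuine responders the realized null
rate drops *below* this ceiling: responder genes soak up ribosome-footprint
mass under OE (and release it under KO), so multinomial renormalization
biases every null gene's Ribo log-FCs away from the concordant sign pattern
(measured ≈ 0.02 under the default study).

Polysome-gradient fraction labels classify as sub40S → untranslated;
40S/60S/80S → initiation; polysome → active.

## Candidate funnel

Stage 1: concordant genes. Stage 2: fold enrichment strictly above the
threshold (default 1.5). Stage 3: tumor-overexpressed. The overexpression
predicate is pluggable: a precomputed boolean column; per-sample
tumor/normal columns scored by a two-sided exact Mann-Whitney test with
Benjamini–Hochberg adjustment (overexpressed ⇔ log2FC > 0 and q ≤ 0.05) —
the exact null matters because the asymptotic p-value saturates near
2×10⁻⁴ for small cohorts, which BH across hundreds of genes cannot
distinguish from noise; or mean columns, direction only. Without a tumor
table stage 3 passes stage 2 through and the output is flagged.

Genes missing an evidence source are dropped with a logged reason rather
than imputed. Ranking uses bias fold enrichment descending (configurable to
`log2fc_te_oe`), ties broken lexicographically; all outputs are
deterministic to the byte. Raising the bias threshold can only shrink
stage 2, and adding the tumor filter can only shrink stage 3.

## Synthetic data

The generator defines the study conditions under which the pipeline is
validated. Defaults: 500 genes of 300 codons; background dependent-codon
fraction 0.15 (matching the aggregate human usage of the eight C-ending
codons, ≈ 15 %); 5 planted responder genes with dependent fraction 0.4 and
log2 TE effect size 1; library size 10⁶; 3 replicates per condition ×
{control-OE, OE, control-KO, KO}; pileup depth 2,000 with 0.1 % error;
tumor cohort of 10 tumor + 10 normal samples, responders 4-fold
overexpressed with 0.5 log2-units of sample noise.

CDS composition: each codon is, with probability 0.6, an ADAT-family amino
acid (uniform over the eight; dependent vs non-dependent synonym chosen
Bernoulli to hit the target fraction), otherwise a uniform non-ADAT codon.
Target fractions above the 0.6 ADAT share are rejected as infeasible.
Sequences start with ATG, contain no internal stop, end with TAA.

Counts: RNA ~ Multinomial(library, p ∝ log-normal abundance); ribosome
loading multiplies abundance by
`2^(effect · mean_I34(subset families, condition) · dep_fraction_gene / dep_fraction_background)`,
so planted responders are TE-concordant by construction (inosine fractions:
controls 0.5; OE 0.9 / KO 0.1 for Ser-AGA, Leu-AAG, Arg-ACG; 0.6 / 0.4 for
the other five). This is a minimal multiplicative effect model — a testing
harness, not an elongation simulator: it omits positional dwell times,
fragment biases, isodecoder structure, overdispersed biological replicate
variance and any transcriptional response. Passing tests demonstrate the
pipeline's correctness and statistical behaviour under this model, not
performance on real sequencing data.

One seeded RNG stream drives each bundle; regeneration is byte-identical,
and the seed is written into every output header.

## Numerical and interface choices

Pseudocounts: 0.5 CPM (TE), 0.01 (I-to-A ratios), 10⁻⁹ (tumor mean ratios).
Ordering ties break lexicographically by gene id everywhere; sorts are
stable. Writers emit LF endings, tab separators, `%.6g` floats, fixed column
order; byte-identity across reruns is asserted in CI-level tests. Pileup
coordinates are 1-based Sprinzl positions as provided; recode reports use
0-based codon indices. Gene identifiers are opaque strings — no symbol
mapping. Degenerate inputs: a CDS consisting only of stops has usage
fraction 0; a position-34 row with A+G = 0 yields NaN fraction; a zero
library size is an error, never silently dropped.

## Validation problem sizes

The test suite and the acceptance script use the default study (500 genes,
5 responders, depth 10⁶, 3 replicates, 20 seeds) for end-to-end recovery;
1,000 random CDS for recoder invariants; and 9 × 500 binomial pileups at
depth 2,000 for estimator calibration. Under these conditions the measured
median stage-3 recall is 1.0 and the null concordance rate ≈ 0.02.

## Known limitations

CPM normalization assumes no global shift in library composition beyond the
modelled one; the concordance filter is a sign test without dispersion
modelling (by design, mirroring the screen it implements); the inosine
estimator cannot distinguish I34 from any other A→G-mismatch-inducing event
at position 34; isodecoders within a family are not deconvolved; and the
28 → 17 → 7 candidate counts of the original colorectal-cancer screen are
not reproducible without its unreleased sequencing data — the package
validates the *procedure* on ground-truthed synthetic studies instead.
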
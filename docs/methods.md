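# Methods

This note documents the models, defaults and design choices behind
`ewskit`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model

Expression values are features × samples tables with an explicit scale
flag (`linear` or `log2`); all fold-change arithmetic happens on the log2
scale and the flag prevents silent double transformation. Matrices must
be complete — array summaries are complete by construction, and features
missing in some samples are rejected rather than imputed. The design
sheet annotates each sample with cell line, shRNA construct (one
designated non-targeting control, present in every cell line),
doxycycline condition (`minus`/`plus`) and replicate index.

## Knockdown contrasts

For each (cell line, construct), the raw fold change is the difference of
Dox+ and Dox− arm means of the log2 signal. The control construct's FC in
the same cell line is subtracted from each target construct's FC; a Dox
artifact — any shift shared by all constructs of a cell line — cancels
exactly. Corrected FCs are averaged arithmetically over all (cell line,
target construct) pairs; the average is permutation-invariant in the pair
order and the control's self-corrected FC is identically zero.

**Expression floor.** Only genes whose mean Dox− log2 signal is at least
7.0 enter the analysis (bound inclusive, `floor` configurable). The value
sits just above the observed baseline of a gene known to be silent in
EWSR1-FLI1-positive cells (log2 signal ≈ 6.05); `baseline_signal()`
exposes that calibration so the floor can be re-anchored on any named
gene.

**Replicate-level corrected FCs.** Mean-based FCs carry no within-gene
variance, so a significance test needs replicate-level values. For the
gene-level test these are defined as each Dox+ replicate's log2 value
minus its arm's Dox− mean, minus the cell line's control FC — the direct
replicate-wise analogue of the mean pipeline. Because the subtracted
Dox−-mean and control-FC terms are shared between replicates, these
values are positively equicorrelated; the resulting one-sample t
p-values are anticonservative and are reported as a ranking/diagnostic
alongside the FC rule, not as the DEG criterion (see below).

## DEG calling and FDR

A gene is a DEG iff it passed the expression floor and |mean corrected
FC| ≥ 1.0 (inclusive; `fc_threshold` configurable). Up- and
downregulated counts are reported separately. The call deliberately
depends only on the fold-change rule; two-sided one-sample t p-values
and q-values are emitted alongside.

q-values follow the standard estimated-null-proportion construction:
π̂0 = #{p > λ} / (m(1 − λ)) at a fixed λ = 0.5 by default (deterministic),
with a monotone-smoother variant over a λ grid as an option; then
q(i) = min over p(j) ≥ p(i) of π̂0·m·p(j)/rank(j), capped at 1. With
π0 = 1 this reduces exactly to the rank-based step-up adjustment, which
the test suite verifies against a brute-force oracle.

## Pre-ranked enrichment

Genes are ranked by mean corrected FC (ties broken by stable feature-id
order). The running sum increments at in-set genes by |score|^w
normalised by the in-set total (w = 1 by default) and decrements at
out-of-set genes by 1/(N − k); the enrichment score is the
maximum-magnitude deviation, bounded in [−1, 1]. The null is gene-label
permutation (a pre-ranked list has no phenotype labels to permute): k
positions are drawn uniformly per permutation, 1,000 permutations by
default, one mandatory seed. Since the null depends on the set only
through its size, permutations are drawn once per distinct set size and
shared. The nominal p is one-sided against same-signed null scores with
a +1 pseudocount (so p > 0 always); NES divides ES by the mean magnitude
of same-signed null scores. Gene sets are read in GMT format; sets empty
after intersection with the universe, or covering it entirely, are
skipped with a recorded reason.

## PSR splicing statistic

The additional FC of a PSR is its corrected FC minus the corrected FC of
its gene, per (cell line, target construct) pair; the gene-level summary
comes from the gene matrix (a PSR-mean fallback is not provided — inputs
lacking gene rows should aggregate upstream). A PSR passes the
consistency screen iff all pairs share one sign and (default,
strictest reading) every |aFC| ≥ 0.3; a mean-magnitude variant
(mean |aFC| ≥ 0.3) is available via `rule="mean"`. Headline counts report
passing PSRs and the distinct genes they map to.

**Significance.** Replicate-level additional FCs are built as
per-replicate paired differences,
a_r = (psr − gene)(Dox+, rep r) − (psr − gene)(Dox−, rep r).
Subtracting the gene signal sample-by-sample removes any sample-wide
artifact (making a separate control-FC term redundant), and pairing by
replicate index keeps the values independent across replicates and
pairs, so the pooled one-sample t holds its nominal level — the test
suite verifies a raw positive rate ≈ 0.05 on a 10,000-PSR null. The
mean-subtraction construction used at the gene level was rejected here:
its shared noise terms make pooled replicate values equicorrelated and
inflate the type-I error severalfold. The replicate pairing requires a
balanced Dox+/Dox− design; unbalanced designs are rejected. Bonferroni
correction uses m = number of PSRs actually tested after filtering (the
tests performed define the family).

**Recovery at default noise.** With measurement noise sd 0.15 the
per-pair additional FC has noise sd ≈ 0.24 (two signal layers and two
control FCs contribute), so the 0.3-magnitude screen cannot separate
shifts near 0.5 perfectly: sensitivity is high (≈ 0.9) but not 1, and a
few null PSRs (~0.3 %) pass by chance. Noise-free recovery is exact, and
the tests assert exactly these two regimes.

## Drug screen

IC50s are correlated on the log10 scale by default (potency spans orders
of magnitude; linear by config) over each drug's pairwise-complete cell
lines, minimum 3. The two-sided p uses the exact transform
t = r√((n−2)/(1−r²)) with n − 2 df; the suite checks agreement with a
permutation null (from n = 10 the two agree to a few hundredths; at
n = 5 the 120-point permutation distribution is too coarse for closer
agreement). No multiple-testing adjustment is applied across drugs —
the screen is deliberately exploratory — but BH-style q-values are
emitted. Candidates require r < 0 and p ≤ 0.05, ranked by r ascending
with lexicographic tie-break, annotated with median IC50 and a potency
flag (default threshold 1 µM, a convention not a constant). Relative
IC50 is the midpoint of a four-parameter logistic fit on log10 dose
(`scipy.optimize.curve_fit`); flat or non-sigmoidal curves return a
failure code, never a number.

## GGAA-microsatellite analytics

The repeat scanner finds maximal in-frame tandem runs of the 4-mer GGAA
by direct scan, returning the longest run (in units) and all run starts
(0-based, half-open). A single interrupting base — including N — ends a
run; no mismatch tolerance. The reverse-complement motif (TTCC) is off
by default because cloned reporter fragments have a fixed orientation;
`both_strands=True` scans both. The scanner is validated against an
independent regular-expression oracle on random sequences with embedded
runs of known length.

Reporter activity is firefly/renilla per replicate, averaged per allele,
optionally taken as the Dox−/Dox+ ratio of arm means (isolating the
dependence on the fusion protein), and rescaled so the reference line's
allele-average equals 1 — a normalisation that is idempotent and
invariant to joint multiplicative changes in both luminescence channels.
Per cell line, the two alleles' activities and repeat counts are
averaged (homozygous lines may be supplied as duplicate alleles); lines
with a single measured allele are excluded with a warning. Activity,
repeat count and marker expression are pairwise Pearson-correlated with
the same closed-form p as the drug screen.

Locus associations: copy-number segment means are Pearson-correlated
with log2 expression (≥ 3 tumors; zero variance → undefined, flagged);
CpG methylation ratios are methylated/(methylated + unmethylated) —
bounded in [0, 1]; an odds variant M/U is available — computed only for
sites with ≥ 4 reads in a tumor, then correlated with expression per
site.

## Phenotype formulas

IRS = staining-extent grade (0–4 from the closed bins 0–19 / 20–39 /
40–59 / 60–79 / 80–100 %, percentage floored before binning) × intensity
grade (0–3), range 0–12. Sphere index: spheres strictly larger than
500 µm count; V = 4/3·π·r³; the index is count × mean volume by default
with the count × total volume variant also reported (the product rule is
ambiguous between the two; both appear in the output). Clonogenicity
index = colony count × colony area. Caliper tumor volume = L·l²/2 with
axes swapped (and a warning) if supplied in the wrong order. Relative
qPCR expression = 2^−ΔΔCt. Percent-of-control scales each value by
100/mean(control); multi-experiment tables are normalised per
experiment. IHC sections are scored individually with a per-sample
median summary.

## Synthetic-data generator

The generator emulates the analysed study designs and is itself
first-class, tested code. Knockdown experiment: 2 cell lines ×
{control, 2 target shRNAs} × {Dox−, Dox+} × 3 replicates; 2,000 genes
with baseline log2 signal N(8, 1.5²) and a 20 % low-expressed fraction
near N(6, 0.5²) so the expression floor is exercised; additive i.i.d.
Gaussian noise (sd 0.15 log2 units) — the simplest model consistent with
log-scale microarray analysis; 50 injected effects with |log2 FC| ~
U(1.2, 3) and random sign, applied only in target-shRNA Dox+ samples;
2–5 PSRs per gene equal to the gene signal plus independent noise, with
one PSR of each of 30 spliced genes (disjoint from the DEG set) shifted
by ±U(0.5, 1.5). Effects are injected only into genes with baseline
≥ 7.5: an effect in an unexpressed gene is undetectable by construction
and would only blur recovery metrics. Drug panel: 18 lines × 264 drugs;
marker expression N(8, 1.5²) log2; uncoupled drugs' log10 IC50 are
N(μ_d, 0.3²) with μ_d ~ N(−6, 1); the one coupled drug follows
−7.6 − 0.5·(expr − 8) + noise, putting its IC50 near 25 nM at average
marker expression; 10 % of entries are blanked completely at random
(observed per-drug n in comparable panels varies by a few lines), never
below 3 observed lines per drug. Reporter panel: 8 lines × 2 alleles with
GGAA runs of U{8..25} units embedded in 150-bp random flanks
(accidental runs capped below the repeat range, and flank edges barred
from extending the embedded run, so recorded truth is unambiguous);
mean activity = 0.5 + 0.1·repeats with multiplicative lognormal
measurement noise (sd 0.05); expression = 6 + allele-average activity
+ N(0, 0.1²).

Same seed ⇒ byte-identical outputs; all randomness flows through one
`numpy` generator per simulated experiment.

**What the generator does not emulate** — and hence what passing
recovery tests do not show about real data: probe-level effects and
normalisation artifacts, batch effects, correlated noise across genes,
heavy-tailed effect-size distributions, dose–response kinetics beyond
the affine IC50 coupling, sequence context around microsatellites, and
biological (as opposed to technical) replicate variance structure.

## Numerical conventions

Zero-variance rows in a one-sample t: p = 1 when the mean is also 0,
smallest positive float plus a warning otherwise. Pearson p at |r| = 1
returns the smallest positive float rather than 0. Pipeline TSVs use
fixed scientific formatting (6 significant digits) so reruns with an
unchanged config reproduce byte-identical files; every output directory
carries the config hash and seed in `summary.json`. Problem sizes in the
test suite and acceptance script (e.g. the 10,000-PSR null, 1,000
permutations, ten seeds per recovery check) were chosen to give stable
Monte-Carlo behaviour at interactive runtimes on a single CPU.

## Known limitations

The gene-level p-values inherit the anticonservative replicate
construction described above and should be read as a ranking; the DEG
call itself never uses them. The all-pairs consistency screen is strict
by design and loses sensitivity for splicing shifts near the 0.3
threshold at realistic noise. The 4PL fit reports the curve midpoint as
the relative IC50 (not the absolute 50 %-viability crossing). The
q-value smoother is a simple monotone grid estimate, not a spline fit.
Phenotype-permutation GSEA and moderated-variance (empirical-Bayes)
tests are out of scope.
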
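# Methods

## The Gini coefficient as a stability score

For a gene with abundances x₁…xₙ ≥ 0 over n samples (missing values
removed first), the package computes

    G = (2 Σᵢ i·x₍ᵢ₎) / (n Σ x) − (n + 1)/n

on ascending-sorted values. This is the classical mean-absolute-difference
estimator with **no** (n/(n−1)) bias correction; the constant is fixed so
that published GC values computed with the common uncorrected convention
are reproduced bit-for-bit. The estimator is permutation- and
scale-invariant, bounded by 0 ≤ G ≤ 1 − 1/n, and equals twice the area
between the Lorenz curve and the diagonal (the trapezoid rule is exact on
the piecewise-linear curve, so the two routes agree to ~1e−12; the test
suite also checks the O(n²) pairwise-difference form). A result that
rounds to a tiny negative (≈ −1e−16) on constant vectors is clamped to 0.

Domain rules: negative entries are an error; an all-zero vector has *no*
Gini coefficient (it is reported as excluded, never as 0); zeros among
positive values are legitimate data — they are precisely what drives the
GC up for sporadically expressed genes.

## Companion statistics

Because the GC is raised by small numbers of large outliers, every gene
also gets outlier-resistant measures computed on the same non-missing
vector:

- quartiles by linear interpolation with plotting position (i−1)/(n−1)
  (numpy's default); the **IQR ratio** is q3/q1, direction fixed so it is
  ≥ 1;
- **%RSD** = 100·SD/mean with the n−1 sample SD (undefined when
  mean = 0, flagged rather than silently dropped);
- **max:min** (undefined when min = 0, flagged) and **max:median** fold
  ranges — both emitted since either can serve as the robustness axis.

Genes with fewer than `min_samples` (default 2) usable values are listed
in a separate exclusion table with a reason; records built from exactly 2
samples are flagged `low_confidence`.

## Candidate selection and intersection

A gene is a candidate "Gini gene" when its GC passes the threshold
(default 0.2, **inclusive**; a strict-mode flag gives `<`). The default
threshold is the working point at which filtered sets are neither empty
nor unmanageably large in typical bulk datasets. An optional median
floor exists because low-GC genes can still sit at impractically low
abundance; it defaults to 0 (off) since the GC filter is primary.
Ranking is ascending GC with ties broken by descending median and then
gene id, so outputs are deterministic and diffable. Intersection across
datasets joins on the gene identifier as loaded (no fuzzy symbol
matching) and reports the boolean membership grid, per-pattern counts
(the UpSet input table) and the genes shared by all datasets.

## Input handling

Expression matrices are the Expression Atlas TSV dialect: `#` comments,
`Gene ID`/`Gene Name` columns, one numeric column per sample. The join
key defaults to the accession (`Gene ID`) with symbol fallback. Blank
cells are missing, not zero. Duplicate identifiers are resolved by
policy: reject, keep the row with the largest total signal (default), or
sum. Comma decimal separators, negative and non-numeric cells are hard
errors naming the offending row and column. Renormalisation of columns
to Σ = 10⁶ (TPM) is opt-in because published TPM matrices are already
normalised; the flag exists for matrices subset to e.g. protein-coding
genes, where column sums have drifted.

## RT-qPCR pipeline

Stages, each feeding the next with no hidden state:

1. technical replicates → arithmetic mean Cq per (gene, cell line), with
   replicate SD; pairs whose replicate range exceeds 0.5 cycles are
   flagged discordant (flag only, never auto-dropped);
2. mean Cq > cutoff (default 32 cycles) ⇒ censored as *not expressed*
   (missing, never clamped); exactly 32 counts as expressed;
3. relative expression = cutoff / mean Cq (so the cutoff maps to 1 and
   lower Cq — more template — gives larger values);
4. per-gene statistics across cell lines (GC, %RSD, IQR ratio) on the
   per-line relative values; genes expressed in fewer than 2 lines are
   excluded with a reason, genes expressed in under half the panel are
   flagged `low_coverage`.

The ΔCq transform is computed per gene over the panel as
ΔCq = Cq − min Cq and R = 2^−ΔCq, so ΔCq ≥ 0, R ∈ (0, 1] and the
best-expressing line has R exactly 1. The sign convention is fixed so
that R is a *relative* value in (0, 1], matching geNorm's input
convention; amplification efficiency is assumed to be exactly 2 per
cycle (no efficiency correction). Note `cutoff/Cq` and `2^−ΔCq` are
different transforms of the same censored Cq values; both are emitted
under distinct labels and never mixed within one statistic.

The geNorm comparator computes V_jk = SD over samples of log2(a_j/a_k)
and M_j = mean of V_jk over partners, then repeatedly removes the
highest-M gene (ties broken lexicographically, logged in the exclusion
order) until two genes remain; those are reported tied at rank 1 and
their per-sample geometric mean is the normalisation factor. M is
invariant to rescaling any gene by a positive constant, which is why the
`cutoff/Cq` and `2^−ΔCq` routes rank identically under geNorm up to
per-gene scale.

## Synthetic data

The generator is the package's test bed, not a model of any particular
experiment. Bulk expression: value(g, s) = exp(μ_g + σ_g·z_gs) with
z ~ N(0,1) — log-normal chosen because its Gini has the closed form
G = 2Φ(σ/√2) − 1, giving every estimator an analytic target (verified
independently by numerical integration of the Lorenz functional in the
tests). Defaults, chosen once as a realistic benchmark: 500 genes × 100
samples; 50 planted stable genes with σ ~ U(0.05, 0.25) (CV roughly
5–25%, the regime of genuinely stable transcripts); background
σ ~ U(0.5, 1.5); μ ~ U(0, 7) (baseline abundance ~1–1100). An optional
outlier process multiplies each cell by 100 with a configurable
probability, reproducing the GC's known outlier sensitivity. Cq tables:
per-line true Cq ~ N(base_g, line SD) with base ~ U(18, 28), triplicates
with 0.15-cycle technical noise, line SD 0.1 (planted) vs 1.5 cycles
(background), and an optional fraction of pairs pushed above the cutoff
to exercise censoring.

Seeding is splittable: one `SeedSequence` child per gene, so a gene's
draws are identical regardless of how many genes the matrix has. A
separate `noise_seed` lets two simulations share gene-level parameters
(μ, σ) while drawing independent noise — emulating two datasets that
measure the same gene population, which is how the cross-dataset
concordance property is tested.

What the generator does **not** emulate: count noise (no negative
binomial), zero inflation and dropout, batch effects, correlated genes,
tissue mixtures, or amplification-efficiency variation in qPCR. Passing
tests therefore demonstrate the statistical machinery and its selection
behaviour under a clean log-normal world; they do not certify
performance on any particular public dataset, where identifier
harmonisation and reprocessing versions dominate exact reproducibility.

## Problem sizes and numerical choices

Test-suite simulations use 500×100 (planted-gene recovery), 200×100
(rank concordance), 1e5 draws (closed-form recovery) and 100 seeded runs
of the 40-gene Cq benchmark — sizes at which the stochastic properties
hold with comfortable margin while the suite stays fast. Tolerances:
1e−10 for the pairwise-vs-sorted Gini equivalence, 1e−12 for the
Lorenz-area route and geNorm oracles, 0.005 for the 1e5-sample
closed-form check. Ties are always broken deterministically (documented
per operation) so identical inputs give byte-identical outputs.

## Limitations

- Gene-identifier mapping across datasets is the user's responsibility
  (supply matrices keyed consistently); no symbol/accession translation
  is attempted.
- No NormFinder/BestKeeper/ΔCT-comparator implementations — the geNorm
  comparator is the only alternative stability ranking included.
- No plotting layer; the membership/pattern tables are written in a form
  an UpSet plotting tool consumes directly.
- The weighted Gini, inequality decompositions and other indices
  (Theil, Atkinson) are out of scope.
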
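# Methods

This note documents the models and procedures implemented in `popassign`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Data model

A dataset is a samples × markers matrix of diploid biallelic calls.
Internally each call is stored as the dosage of the marker's *counted*
allele (0, 1 or 2 copies; −1 for missing) together with the ordered allele
pair `(counted, other)`. For biallelic SNPs this is information-equivalent
to unordered nucleotide pairs and is the coding every downstream
computation uses (allele frequencies, IBS sharing, the ancestry
likelihood, PCA). When a PLINK text file is read, the counted allele of a
marker is the first non-missing allele letter encountered in ped row
order — deterministic and format-independent; a half-called genotype
("A 0") is treated as fully missing. All genotypes are treated as diploid,
including X/Y/MT markers; chromosome labels only drive location filtering
(autosomal / sex / mitochondrial).

Positional duplicates (the same chromosome and position under different
marker ids) are collapsed only when every individual's calls agree across
the group after allele-orientation reconciliation; a discordant group is
excluded entirely and reported, never silently merged. When merging a user
dataset with a reference panel over shared markers, allele pairs are
reconciled to the reference orientation, accepting a dosage flip or an
unambiguous strand complement; strand-ambiguous A/T and C/G pairs with
mismatched labels are dropped because the two explanations cannot be told
apart.

## Quality filtering

The cascade applies, in order: individual call rate (default ≥ 0.95),
marker call rate (default ≥ 0.75, computed on the survivors of the first
stage; a switch reverses the two stages), an exact Hardy–Weinberg test
(remove markers with P < 0.001), and a minor-allele-frequency filter
(remove MAF < 0.01). Call-rate comparisons are non-strict (a "minimum
call rate" keeps values equal to the threshold); HWE and MAF removals are
strict, matching the inequality direction of the defaults. Individuals
are filtered before markers by default; the order is a documented choice,
since either is defensible, and both orders are exercised by tests on an
order-sensitive fixture.

The HWE test is the conditional exact test at a biallelic locus: given
the observed allele counts, every attainable heterozygote count (parity
fixed by the allele count) is enumerated through the probability ratio
recurrence P(h+2)/P(h) = 4·nAA(h)·nBB(h) / ((h+2)(h+1)), accumulated in
log space and normalised; the p-value sums all configurations no more
probable than the observed one (with a 1e-10 relative guard against
floating-point ties). Genotype counts are pooled over all selected
individuals by default, mirroring the MAF filter's pooling; this inflates
rejections for structured data (Wahlund effect), so a per-population mode
is available behind the configuration but is not the default.

## Allele sharing distance

At one locus the proportion of alleles alike in state between two diploid
genotypes is the multiset intersection of the allele pairs divided by
two — in dosage terms `1 − |d₁ − d₂|/2`, so het vs het scores 1 under the
standard IBS-proportion convention. ASD between two individuals is one
minus the mean over loci genotyped in both (pairwise-complete). The
minimum overlap to return a value is one locus; the per-pair overlap
count is always reported so callers can impose stricter floors, and a
zero-overlap pair is NaN in the matrix (an exception in the scalar API),
never a number. Population summaries rank reference populations per query
by ascending mean ASD with ties broken by label order.

## Supervised ancestry estimation

Reference allele frequencies per population are Laplace-smoothed,
f = (y+1)/(n+2), with y the counted-allele copies and n the total allele
count over non-missing calls; smoothing keeps f strictly inside (0, 1) so
the log-likelihood is finite for any query. Populations with fewer than
15 individuals (configurable) are excluded from panels.

Ancestry proportions q on the K-simplex maximise the fixed-frequency
admixture likelihood (unlinked loci, frequencies never re-estimated):

    log L(q) = Σ_m [ g_m ln(Σ_k q_k f_km) + (2−g_m) ln(Σ_k q_k (1−f_km)) ]

via the EM update

    q'_k = (1/2M') Σ_m [ g_m a_km + (2−g_m) b_km ],
    a_km = q_k f_km / Σ_l q_l f_lm,   b_km = q_k(1−f_km) / Σ_l q_l(1−f_lm)

over the M' non-missing loci (missing loci are dropped, not imputed).
Initialisation is uniform q = 1/K (deterministic; a seeded Dirichlet
start is available). The stopping tolerance ε is interpreted as the
absolute increase in total log-likelihood between successive iterations —
the convention of the EM family this algorithm belongs to — with presets
0.01, 0.1 and 1: a loose ε terminates quickly, a tight ε improves
accuracy at more iterations. The iteration cap is 10,000 with an explicit
non-convergence flag. Queries are optimised independently (the likelihood
factorises once frequencies are fixed) but updates are batched with an
active-set so converged queries stop iterating.

## Assignment and evaluation

A query is assigned to its argmax-q population iff max_k q_k strictly
exceeds the ancestry threshold t (exact ties broken by label order and
flagged). The assignment rate at t is the fraction of queries assigned;
the misassignment rate is the fraction of assigned queries whose call
differs from their true origin, and is NaN (undefined), never 0, when
nothing was assigned. The default threshold grid is 101 points on [0, 1];
assignment rate is exactly non-increasing in t.

The self-assignment experiment samples marker subsets without replacement
under a seed, builds the panel from **all** individuals of qualifying
populations, and assigns every one of those individuals back against it.
Keeping each individual inside its own population's frequency estimate is
the plain reading of the protocol; a leave-one-out switch (removing the
individual's own alleles from its population's counts) exists but is off
by default.

## PCA

Dosages are mean-imputed per marker, mean-centred, and optionally divided
by sqrt(p̂(1−p̂)) with p̂ the counted-allele frequency computed from the
analysis sample itself. Monomorphic and all-missing markers are dropped.
The decomposition is an SVD of the resulting matrix; eigenvalues are
singular values squared over (n−1), coordinates are principal-component
scores, defined up to sign. No outlier-removal iterations are performed.
Output follows the two-file text layout: an `evec` file with a
`#eigvals:` header then one line per sample (id, coordinates, population)
and an `eval` file with one eigenvalue per line.

## Synthetic data

The generator draws, per marker, an ancestral frequency uniform on
[0.05, 0.95], then per population a Beta(p(1−F)/F, (1−p)(1−F)/F)
frequency — the Balding–Nichols parameterisation, whose mean is p and
variance F·p(1−p), so F acts as FST. Genotypes are two independent allele
copies (Hardy–Weinberg within populations, no LD); admixed individuals
draw a source population per allele copy from their design vector q*
before drawing the allele. Default design: 10 populations × 20
individuals at 10,000 unlinked SNPs, FST 0.1, no missingness — a
desk-scale analog of a multi-breed diversity panel with well-separated
groups plus admixed outliers. Missingness, when injected, is missing
completely at random.

What this does **not** emulate: linkage disequilibrium, ascertainment
bias of genotyping chips, genotyping error, related individuals, or
continuous isolation-by-distance structure. Tests passing on these
simulations demonstrate correctness of the algorithms under their own
model assumptions (unlinked loci, island-model differentiation), not
performance guarantees on real chip data.

## Evaluation problem sizes

The packaged evaluation (`scripts/acceptance.py`) runs the
self-assignment design at 10,000 and 32,966 SNPs with 10 populations of
20 individuals (panel from the first 15 per population, all 200 as
queries), EM at ε = 0.1, threshold 0.8. These sizes keep a full run in a
few minutes on one core while leaving the rates' qualitative behaviour —
high assignment, near-zero misassignment for well-differentiated
populations — clearly measurable.

## Numerical and degenerate-input choices

- Empty selections return empty datasets; filters removing everything
  return an empty dataset with a warning recorded, not an exception.
- A marker with calls but undefined alleles is a coding error on export.
- An all-missing query is rejected by the EM (undefined ancestry) but
  scores log-likelihood 0 in the bare likelihood function (empty sum).
- K = 1 panels short-circuit to q = (1.0).
- Identical population frequencies leave the likelihood flat in q; the
  EM terminates at the first check with the uniform vector.
- Beta draws are clipped to [1e-12, 1−1e-12] before binomial sampling;
  panel frequencies need no clipping thanks to Laplace smoothing.
- EM monotonicity is asserted in tests with a 1e-8 slack for
  floating-point round-off.

## Known limitations

- Binary PLINK (bed/bim/fam) and VCF are not read; the PLINK dialect is
  whitespace-delimited text with nucleotide letters. HapMap is
  export-only.
- Haploid chromosomes are coded as diploid throughout.
- Synonym matching at merge is single-level (no transitive closure
  across chip generations).
- The call-rate cascade is not a mathematical fixed point in
  pathological missingness patterns (removing low-call markers can, in
  principle, lower a kept individual's rate below threshold on re-run);
  it is idempotent on the fixtures and simulated data exercised here.
- No standard errors on q, no unsupervised mode, no linkage-aware model.
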
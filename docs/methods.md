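# Methods

## Occupancy model and estimator

The estimator treats the genome as containing θ genotype classes of equal
abundance and the BAC screen as `n` independent uniform draws with
replacement (the library is large relative to the screen, so depletion is
negligible). The observed statistic is the pair (N, K): clones genotyped
and distinct genotypes found. Two equivalent routes to
`P(K_n = k | θ)` are implemented:

- a forward recursion over draws — a draw repeats a seen class with
  probability `k/θ` or reveals a new one with probability `(θ−k)/θ`;
- the closed form `S₂(n,k) · θ^{(k)} / θⁿ` with `S₂(n,k)` the Stirling
  number of the second kind and `θ^{(k)}` the falling factorial.

Both are evaluated entirely in log space. `S₂` uses a log-sum-exp
triangular recurrence; the row for a given `n` is computed once and cached,
so likelihood evaluation across a θ grid is O(1) per θ. The two routes are
coded independently and cross-checked against each other (≤1e-10 for
n, θ ≤ 25) and against exact rational enumeration of all θⁿ draw sequences
(n, θ ≤ 6).

**MLE.** θ is optimized over integers (the parameter is a count). The
likelihood ratio `L(θ+1)/L(θ) = ((θ+1)/(θ+1−K)) · (θ/(θ+1))ᴺ` decreases
through 1 exactly once, so a walk upward from θ = K stops at the maximum;
ties break toward the smaller θ. When K = N (every clone distinct) the
likelihood increases without bound and the estimate is flagged unbounded
rather than reported.

**Profile CI.** The 100(1−α)% interval is the set of integers θ with
`2·(ℓ(θ̂) − ℓ(θ)) ≤ χ²₁(1−α)`, scanned outward from θ̂. Endpoints are the
extreme integers satisfying the condition — no interpolation, since the
parameter space is integer. The reported profile grid extends until the
log-likelihood has dropped 10 units below the maximum, so the upper
endpoint can never be truncated by the grid. At (N=342, K=299) this yields
θ̂ = 1240 with 95% CI (960, 1658) and 90% CI (998, 1578), each computed in
well under a second.

The model deliberately excludes unequal-abundance richness estimators
(Chao1 and coverage-based estimators): equal abundance is the modelling
assumption under test, and the synthetic generator's optional
unequal-weights mode exists precisely to explore that misspecification.

## Genotype clustering

Clones are scored as integer fragment sizes (bp) at each of three
microsatellite markers; a 1-bp difference is treated as electrophoretic
sizing error. The co-classification rule is applied **per marker**: two
clones match when their sizes differ by ≤ tolerance at every marker (a 1-bp
allowance is a property of each sizing peak, not a budget shared across
markers). Because the pairwise rule does not resolve chains like
100/101/102, two linkage modes are provided:

- `strict` (default): classes anchor to a representative — the per-marker
  modal size of current members, ties toward the smallest — and admit only
  clones within tolerance of it. Clones are processed in canonical order
  (sorted by size tuple, then clone id), which makes the partition
  invariant to input order. Chosen as default because genotypes are
  discrete entities with fixed true sizes.
- `single`: transitive closure of the pairwise rule (connected components
  of the within-tolerance graph).

At class separation ≥ 2·tolerance + 1 on jitter-free data the two modes
agree and both recover the true sampled-class count exactly. Clones missing
any marker are excluded and reported, never imputed.

## Library statistics

Coverage is `n_clones × mean_insert / genome_size`; percentages and fold
values round half away from zero to one decimal. The locus bounds divide a
genotype count by the haplotype cap (2 × source animals, diploid): the
bound from the *observed* K uses the floor (K genotypes could come from
that many saturated loci), while the bound from the *estimated* θ̂ uses the
ceiling (θ̂ genotypes cannot fit into fewer loci). The two conventions are
deliberately kept distinct in separate functions rather than harmonized,
matching how each bound is used.

Hybridization patterns: three ordered probes F < M < R on the 120-kb
reference. A contiguous insert can only produce F, F+M, M, F+M+R, M+R, R;
an F+R-without-M hit set is labelled `anomalous` (possible for chimeric
inserts, impossible for contiguous ones — a property the synthetic
intervals verify). Probe coordinates default to [0, 2 kb), [59, 61 kb),
[118, 120 kb) — the true physical positions are not modelled, only the
ordering matters, and the layout is fully configurable.

## qPCR copy number

A standard curve `Ct = intercept + slope·log₁₀(copies)` is fit by least
squares to a dilution series (≥3 points spanning ≥2 decades). Amplification
efficiency `10^(−1/slope) − 1` outside [0.8, 1.1] triggers a warning, not
an error. Sample Cts invert through the curve to absolute copies;
extrapolation beyond the fitted Ct span is allowed but detectable via
`StandardCurve.in_range`. Relative copy number is computed per replicate
(gene copies / reference copies, paired by replicate index), then
summarised as mean ± SD (ddof=1) — matching how repeated experiments are
reported with per-experiment error bars, rather than ratioing mean Cts.
Separate curves per gene are supported; sharing one curve is allowed.

## Synthetic data generator

The generator emulates exactly the structure the model assumes: θ classes
of equal abundance; uniform sampling with replacement; sizing error as a
±1 bp shift with equal sign probability, applied independently per marker
with a configurable probability (the minimal model consistent with the
1-bp binning rule); contiguous clone intervals with truncated-normal
lengths (mean 135 kb, clipped to the 120-kb reference, 0-based half-open);
Ct values as curve(copies) + Gaussian noise. Class placement is rejection
sampling with a minimum pairwise Chebyshev separation (default 3 bp, so
tolerance-1 clustering of jitter-free data is unambiguous); an infeasible
packing raises an explicit error. Default study-scale parameters are
θ = 1240 classes in 80–400 bp over three markers and N = 342 clones.

What the generator does **not** emulate: cloning bias, insert chimerism,
PCR stutter ladders, allele dropout, unequal class abundances (except as
an explicit opt-in stress mode), or any sequence-level detail. Passing
round-trip tests therefore validate the statistical machinery under the
model's own assumptions — they do not show that real screens satisfy those
assumptions. The three markers are treated as always co-recovered on one
clone; their physical spacing within the segment is unknown, so partial
marker recovery is handled only by the exclude-and-report rule.

All randomness flows from one integer seed; composed pipelines spawn named
per-stage substreams (`numpy.random.SeedSequence.spawn`), so each stage is
independently reproducible and identical seeds give byte-identical tables.

## Numerical and design choices

- Integer θ search; no continuous-θ gamma-function optimization.
- pmf normalization holds to 1e-12; recursion/closed-form agreement to
  1e-10; both enforced by tests.
- Monte-Carlo checks: total-variation distance between the pmf (θ=10,
  n=20) and 10⁵ simulated screens < 0.01; CI coverage ≥ 89% over 200
  replicates at θ = 1240, N = 342 (binomial tolerance around the nominal
  95% at that replicate count; the analysis run observed 91%).
- Problem sizes in tests and analysis scripts (200-replicate coverage
  study, 10⁵-draw distribution checks, 150–500-replicate qPCR grids) are
  chosen so each statistical tolerance has comfortable margin while the
  whole suite stays fast to iterate.

## Known limitations

- Equal abundance is assumed, not tested; if some genotype classes are
  cloned preferentially, θ̂ is biased (typically downward for the classes
  actually sampled). The unequal-weights stress mode exists to quantify
  this but no correction is implemented.
- The locus bounds inherit the diploid, 13-animal haplotype cap; loci
  sharing identical marker triples across animals would make the bounds
  conservative in the other direction.
- qPCR validation is synthetic-only: per-tissue copy numbers of the real
  genes require the raw Ct tables, which are not public.
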
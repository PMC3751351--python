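# Methods

## The model

A whole-genome shotgun read set sequenced to depth high enough to sample
every position many times yields a characteristic *k*-mer abundance
spectrum: a histogram giving, for each abundance *x*, the number of
distinct canonical *k*-mers observed exactly *x* times.  Sequence present
once in the genome forms the **principal peak** at the per-*k*-mer
coverage *c*; sequence repeated *n* times forms peaks at the integer
multiples *n·c*.  Sequencing errors convert sampled *k*-mers into novel,
mostly singleton *k*-mers and populate a spike at very low abundance.

`kmerspec` models the spectrum above a low-abundance cutoff as a mixture
of negative binomial (over-dispersed Poisson) components,

P(x) = Σₙ aₙ · NB(x; mean = n·c, alpha = s/n),   n = 1…N,

where

- **c** (> 0) — abundance of the principal peak, i.e. the per-*k*-mer
  sequencing depth.  For reads of length *L*, the expected value is
  read-depth × (L − k + 1)/L, further reduced by (1 − e)^k for per-base
  error rate e.
- **s** (≥ 0) — a single overdispersion shape shared across components;
  component *n* gets dispersion s/n.  The NB uses the standard mu–alpha
  convention, variance = mu + alpha·mu², whose alpha → 0 limit is the
  Poisson; s = 0 therefore reduces the mixture to pure mixed-Poisson
  form.  s absorbs coverage unevenness in real data; idealised uniform
  sampling drives it toward 0.
- **aₙ** (≥ 0) — the amount of distinct sequence at copy number *n*,
  in *k*-mers.  *k*-mer counts are numerically interchangeable with base
  pairs at genome scale (every base opens one window except at contig
  ends), so they are reported as bp-equivalents throughout.
- **N** — the highest modelled copy number (default 30).  In practice
  the mixture also terminates at the highest observed abundance:
  components whose support window lies wholly beyond the data are never
  fitted, because they could only soak up edge-bin mass.

Observed bin counts z_x are treated as independent Poisson draws with
mean P(x), and the log-likelihood Σ_x [z_x log P(x) − P(x) − log z_x!] is
maximised over (c, s, a₁…a_N).  Every integer abundance in the fitted
range contributes, including empty bins.  From the optimum,

- distinct *k*-mers:  N_unique = Σ aₙ,
- genome size (bp-equivalents):  G = Σ n·aₙ.

## Counting

*k*-mers are counted canonically: a *k*-mer and its reverse complement
are collapsed onto the lexicographically smaller of the pair, matching
the convention of the common counting tools whose histogram output the
package reads directly.  Sequences are case-folded; any window containing
a non-ACGT symbol is skipped entirely.  Internally each window is packed
into 2 bits/base (A=0 < C=1 < G=2 < T=3, so lexicographic and numeric
order agree) and counted with vectorised sorting; the supported range is
k = 1–31 (CLI: 15–31), with k = 21 the default — for bacterial genomes the
canonical 21-mer space (≈2.2×10¹²) is sparse enough that chance *k*-mer
collisions are negligible.  Exact counting is the design point; there are
no probabilistic or disk-backed structures, and the intended scale is
≲10⁹ input bases.

## Fitting procedure

Joint ML over ~32 parameters from a cold start is hopeless on real
spectra; the fitter stabilises it the way a human reads the plot:

1. **Peak seed.**  On the coverage-weighted series x·z_x, scan from low
   abundance past the initial descending error region (to the first local
   minimum) and take the argmax beyond it, ties toward smaller *x*
   (mode of a discrete unimodal peak; ties only arise in degenerate
   spectra).  A series that only decreases means the error spike and the
   principal peak have merged — coverage below roughly 10× — and the fit
   refuses rather than returning noise.
2. **Cutoff.**  Bins below x_min = c/2 are excluded.  Because the rule
   names the *fitted* c but fitting needs a cutoff first, x_min is
   bootstrapped from the peak seed and recomputed once if stage 1 moves c
   by more than 10% (a fixed-point iteration truncated at one step; in
   practice it converges immediately).  A manual cutoff overrides the
   rule for pathological inputs, e.g. a tiny genome at 10⁵× coverage
   whose error spike dwarfs the peak; such fits are additionally
   constrained to a single mixture term via `max_components=1`.
3. **Stage 1.**  (a₁, c, s) are fitted on [x_min, 1.5c].  The
   single-peak likelihood has a spurious optimum in which a broad,
   heavily over-dispersed component swallows neighbouring repeat mass,
   so stage 1 multi-starts the dispersion at s ∈ {0.05, 0.3, 1.0} and
   keeps the best optimum.
4. **Stages 2…N.**  One component at a time: aₙ is seeded by weighted
   least squares of the residual counts against the component shape over
   [(n−0.5)c, (n+0.5)c] with weights 1/max(z_x, 1) (clipped at 0), the
   mask widens to x ≤ (n+0.5)c, and all parameters are re-optimised
   jointly.  If the optimiser fails to beat the previous model carried
   onto the widened range (with aₙ = 0), the previous model is kept and
   the stage is recorded as unsuccessful — so the staged likelihood never
   deteriorates, and a late-stage failure degrades to the last successful
   lower-order model instead of poisoning the fit.
5. **Polish.**  A final joint optimisation over the full masked range,
   capped at min(highest observed abundance, (N+0.5)c).  Mass beyond the
   cap (e.g. a high-copy plasmid above 30×) is reported separately as
   unmodelled instances, never silently dropped.

Each stage uses L-BFGS-B with analytic gradients under box constraints
(aₙ ≥ 0, c > 0, 10⁻⁴ ≤ s ≤ 100), with parameters scaled by the peak seed
and the in-range count total so the box is well conditioned.  Convergence
is a relative log-likelihood improvement below 10⁻⁸, at most 500
iterations per stage.  Coefficients that fit to (near-)zero are retained
at their values rather than pruned, so empty copy-number classes appear
naturally as zeros in the output table.

The fitter is fully deterministic given the spectrum and settings; only
the simulator consumes seeds.

### Numerical choices

- NB log-pmf is evaluated through the gamma-function form with size
  r = 1/alpha, in log space to avoid underflow at large *x*.  Below
  alpha = 10⁻⁸ it switches to the Poisson log-pmf: the gamma form loses
  ~10⁻⁸ absolute accuracy to cancellation at r ≈ 10⁸ while the true
  NB–Poisson gap is already far smaller.
- The optimiser bounds s at 10⁻⁴ from below (the evaluation API allows
  s = 0 exactly).  Near s = 0 the gradient ∂logNB/∂s is a difference of
  digamma terms that cancels to O(1/r²) and is then amplified by 1/s²,
  which double precision cannot survive; at s = 10⁻⁴ the induced variance
  inflation is < 1% of the mean at bacterial coverages, i.e. statistically
  invisible.
- Model expectations are floored at 10⁻¹² inside the likelihood so that
  an occupied bin with underflowed expectation yields a large finite
  penalty (≈ −27.6 per count) and a usable gradient instead of −∞.
- The exact per-copy table of an assembled genome (`genome_copy_table`)
  bypasses fitting entirely: it is the spectrum of the genome itself, and
  doubles as the ground truth for the simulator.

## Synthetic data

`SyntheticGenomeSpec` declares a repeat architecture as (copy number,
block length) pairs; blocks are embedded in shuffled order, separated by
unique random 50-bp spacers, at a configurable GC fraction (default 0.5).
The reported ground truth is obtained by exact counting of the emitted
sequence, so junction *k*-mers and rare chance collisions are reflected
honestly rather than assumed away.  `ReadSimParams` samples uniform read
start positions on both strands (optionally wrapping, for circular
chromosomes) until total bases reach depth × genome length, then applies
independent per-base substitutions.  Defaults are 76-bp single-end reads
at 60× with error rates of 0–1%, i.e. the regime of a bacterial isolate
on a short-read instrument.

What the simulator deliberately omits: GC and positional coverage bias,
PCR duplicates, indels, quality-score structure, adapter contamination
and read pairing.  Uniform sampling is exactly the regime in which the
mixed-Poisson model is correct, so passing recovery tests demonstrate
the estimator's correctness and numerical stability — not robustness to
the coverage unevenness of real libraries, which enters the model only
through the fitted s.  The acceptance checks run a half-megabase genome
carrying a 7×5.4-kb repeat (an rrn-operon-like class) and a 15×1-kb
repeat (an IS-element-like class) at 60×; this is a deliberately
scaled-down bacterial chromosome that keeps the full pipeline — genome,
reads, counting, fit — at desk scale while preserving the repeat classes
that make the problem non-trivial.

## Known limitations

- Haploid/clonal assumption: one genome, no heterozygosity or ploidy
  modelling, no strain mixtures.
- Coverage below ≈10× is refused or flagged (`reliable = False` below
  c = 10); accuracy degrades gradually below ~75×.
- Sequencing error is not modelled, only excluded by the cutoff; error
  rates above a few percent erode the usable signal.
- Repeat classes are pinned to integer multiples of c; copy-number
  variation within a class smears mass into neighbouring coefficients
  (visible in simulations as a few percent error on small high-copy
  classes).
- Exact in-memory counting bounds practical input size at roughly 10⁹
  bases.
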
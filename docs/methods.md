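# Methods

## Model and assumptions

`poremod` treats the signal values observed at one reference position in
one sample as i.i.d. draws from an unknown position-specific
distribution. The detection question is purely comparative: does the
distribution at a position differ between the modified sample and the
matched unmodified control? This makes no assumption about what a
modification does to the current — mean shift, variance inflation, or a
change of shape (e.g. unimodal to bimodal) are all admissible — which is
why the two-sample Kolmogorov–Smirnov test is the default statistic.
The approach requires (i) a known reference sequence, (ii) a control
sample of the same sequence without modifications, and (iii) enough
reads that each position pools on the order of tens to hundreds of
signal values per group. It deliberately does not attempt to classify
the modification type; that would require trained signal models.

## Event correction

Reads enter as ordered events (one run of raw signal values per called
base). Alignment against the reference exposes basecalling indels, which
are repaired so that every aligned position owns exactly one event:

- an inserted event is pooled with its flanking events and the stretch is
  re-segmented (the standalone `correct_insertion` operation instead
  merges the insertion into the smaller flank, tie to the upstream one);
- a deleted position gains an event by pooling one upstream and one
  downstream neighbor event and re-segmenting into one extra event;
- adjacent indels are merged into a single pooled region first;
- the pooled region grows symmetrically, one matched neighbor at a time,
  until every output event can receive at least `min_signals` values
  (default 3, configurable). If the whole read is consumed before the
  requirement is met, the region is dropped from annotation rather than
  annotated badly;
- re-segmentation splits the pooled signals into contiguous equal-length
  events, remainder assigned left-to-right. This is a deliberate,
  deterministic simplification: change-point segmentation would track the
  true event boundaries better but adds nothing to a rank-based
  two-sample comparison, since both groups are segmented the same way;
- within a reference homopolymer of length L > 5 the basecaller cannot
  resolve individual positions, so the middle L − 4 positions share one
  merged event (the two outermost positions on each side keep their own).
  Runs only partially inside the aligned span are left unshared.

Every correction step conserves the multiset and order of signal values.
Soft-clipped read ends are excluded from annotation. Correction is
deterministic given the read and its alignment.

## Normalization and pooling

Signals are normalized per read (one location and one scale for the
whole read, since pore-to-pore and time drift act at the read level):
subtract the median, divide by the mean absolute deviation from the
median ("averaged difference"; the median-absolute-deviation dialect is
available via `scale="median_abs"`), clip to [−5, 5]. Normalization
happens before pooling and after correction; the order relative to
re-segmentation is immaterial to the statistics since both are
value-preserving, but a config flag exists because pipelines differ.
Reverse-strand reads contribute to the reference position they align to;
signal values are not remapped.

Pooling assigns every signal value of the event anchored at a position
to that position; a shared homopolymer event contributes its full vector
to each position it annotates. Positions with fewer than `min_reads`
distinct reads (default 5) in either group are removed before testing.

Caveat worth knowing: with per-read normalization, a sample carrying
many strong modifications has slightly different read-level medians and
scales than its control, which leaks a small global shift into *all*
positions. Under the null (no modifications) the two groups are
exchangeable and calibration is unaffected, and in the simulations the
leaked shift is orders of magnitude weaker than the modification signal,
but on heavily modified genomes the background p-values will be
anti-conservative — ranking, not absolute significance, is the intended
readout.

## Statistics

**KS test.** D is computed exactly by evaluating both empirical CDFs at
every pooled sample value. The p-value uses the asymptotic Kolmogorov
distribution at Stephens' finite-sample argument
λ = (√e + 0.12 + 0.11/√e)·D with e = mn/(m+n). The refinement matters
here: at a few hundred pooled values per group the plain λ = √e·D
argument leaves the null p-values detectably non-uniform across
thousands of positions, while the corrected form passes a uniformity
test and gives a 1% empirical type-I error of ≈1% (verified by the null
calibration test).

**Alternatives.** Mann–Whitney U (normal approximation with continuity
correction; no tie correction, signals being continuous) and pooled-
variance Student's t. Zero pooled variance yields p = 1 with a warning.

**Log-scale p-values.** Pooled groups of ~10³ values drive p-values far
below the smallest positive double; clamping them would create large
tied blocks and make the ranking arbitrary within them. All tests
therefore compute log p directly (analytic log survival functions, with
large-deviation fallbacks for the t and χ² tails and an asymptotic
normal-quantile inversion for Φ⁻¹(1 − p) at extreme p), and the ranking
keys on log₁₀ p. The reported linear-scale p columns are clamped to
[1e-300, 1] for display; the scalar `combine_stouffer`/`combine_fisher`
helpers clamp degenerate inputs (p = 0 or 1) the same way, with a
warning.

**Combination.** Weighted Stouffer over the ±k window (default k = 2):
Z = Σ wᵢ Φ⁻¹(1 − pᵢ) / √(Σ wᵢ²), weights wᵢ = decay^{−|offset|} with
decay 2 by default — mirroring the halving of the simulated
neighborhood mean effect per base of distance — and invariant to weight
rescaling. Windows truncated by sequence ends or filtered neighbors
combine over the available positions. Fisher's method (−2 Σ ln pᵢ on
2·window df) is the alternative; it weights all window positions
equally, which helps when true sites cluster densely and hurts when they
are isolated. No multiple-testing correction is applied: the output is a
ranking, and any FDR control would not change it.

**Neighborhood ranking.** Greedy by ascending combined log-p (ties to
the leftmost position): accept a site unless an already-accepted site
lies within ±`rank_window` (default 2) bases, in which case suppress it.
Accepted sites are ranked 1..N; the result is independent of input
order.

## Simulator

The generator reproduces the benchmark conditions: a uniform random
reference of 6184 bp, a synthetic 5-mer pore model (E_k ~ U(70, 130) pA,
Δ_k ~ U(1, 3) pA — the level span and spread of published R9 5-mer
models; the modification effects are relative, so only the E/Δ ratio
matters), 60 modified positions drawn without replacement among
positions with full 5-mer context, and 100 reads per group, each read
covering the whole sequence with a per-position signal count drawn
uniformly from 5..15. Signals are N(E_k·(1+w_a), Δ_k·(1+w_b)) with
additive Gaussian noise of sd 0.05·Δ_k folded into the draw's scale
(distributionally identical to a separate additive draw; set
`noise_sd_frac=0` to disable). Scenario gating: `MeanDif` applies only
w_a = α at the modified position, `STDDif` only w_b = β, `Mean_STDDif`
both, and `Mean_STDDif_NE` both plus neighborhood leakage w_a = α/2^d,
w_b = β/(d+1) up to distance d = 2, additive over nearby modifications.
Defaults α = 0.2, β = 1.

What the simulator does *not* model: raw picoampere time series and
dwell-time kinetics, basecaller miscalls beyond the optional indel
injection, coverage variation (every read spans the whole reference),
strand asymmetries, and k-mer-dependent modification effects. Passing
the simulation benchmarks therefore demonstrates the statistical
machinery under the stated generative model, not performance on real
flow-cell data. The indel injector corrupts a clean read by merging an
event into its predecessor (deletion) or splitting an event in two with
a random spurious base (insertion), conserving signals, and returns the
true alignment, which is how the corrector is exercised end to end.

Modified positions are sampled freely (no minimum spacing), so adjacent
modifications and the additivity branch of the perturbation weights do
occur, and a truth site can sit within another's suppression window —
one reason recall at the top of the ranking saturates below 1 with
exact-position matching.

## Evaluation

Precision and recall are computed at fixed percentile cuts of the
ranked (non-suppressed) site list — 0.1, 0.25, 0.5, 1, 2, 3, 4, 5% by
default, with a 10–30% extension for genome-scale runs. At each cut the
top ⌈q·N⌉ sites are predictions; a prediction is correct if it lies
within `tolerance` bases (default 0) of a truth position not already
claimed by a better-ranked prediction. Replicate curves are averaged
pointwise. With a random ranking, expected precision equals the truth
density at every cut, which the tests use as the no-power baseline.

## Study sizes and numerical choices

The replicated studies (`poremod.benchmarks`, the acceptance script)
use 20 replicates per scenario at the full stated dataset size; the
replicate average of top-5% recall is stable to ±1–2 points across
seeds at that depth. Degenerate inputs: constant or length-<2 signal
vectors cannot be normalized (error); empty test groups are an error;
KS/U/t p-values are floored at 1e-300 on the linear scale only.
Determinism: all randomness flows from explicit seeds
(`numpy.random.default_rng`), and detection is fully deterministic given
its inputs.

## Limitations

- No modification-type classification, by design.
- FAST5/raw-signal ingestion and basecalling are out of scope; the
  event-table TSV is the interchange format, with SAM/FASTA/BED for
  alignments, references and results.
- Single-reference analyses only (one sequence per run, two groups).
- True indels between sample and reference are not distinguished from
  basecalling indels; supply a corrected reference in that case.
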
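# Methods

`nichelumps` implements an analysis chain for a single macroecological
question: do species-rich communities self-organize into *lumps* of
similarly sized species, with regular spacing between lumps? The chain has
three scientific stages — a competition–evolution simulator that produces
such patterns from first principles, mode detection for (log) body-size
distributions, and a pairwise size-ratio analysis of co-occurrence samples —
plus a synthetic-data generator that emulates the inputs these analyses
consume.

## The competition–evolution model

Species live on a one-dimensional niche axis `x ∈ [0, 1]`, interpreted as
log body length. Abundances follow Lotka–Volterra competition

    dN_i/dt = r N_i (K(x_i) − Σ_j α(x_i, x_j) N_j) / K(x_i),

with the Gaussian competition kernel

    α(x_i, x_j) = exp(−(x_i − x_j)² / (2 σ_α²)),

so each species competes fully with itself (α = 1 at zero distance) and
ever more weakly with more distant species. The carrying capacity is
uniform (`K0`) by default; a Gaussian K(x) profile is available but not
used in the standard runs, so any emergent pattern is attributable to
competition alone.

Between bouts of population dynamics, niche positions evolve. Two update
rules are provided:

* **hill_climb** (default): each species compares its per-capita growth
  rate at `x − δ`, `x`, and `x + δ` (δ = `evolution_step_sd`), holding the
  rest of the community fixed, and takes one step only on strict
  improvement. A species' own population is treated as moving with it, so
  its self-competition term is constant and a lone species on uniform K
  sees a flat landscape and stays put. The strict-improvement rule lets
  species lock onto local fitness maxima instead of jittering around them.
* **mutation_selection**: positions receive independent Normal(0, δ)
  perturbations and selection is left entirely to the subsequent dynamics.

Species falling below `extinction_threshold` are removed between
integration calls, never mid-step.

### Numerical scheme and defaults

Integration is fixed-step classical RK4. Positions are constant within an
integration bout, so the α matrix is assembled once per bout. Abundances
are clipped at zero after each step; non-finite values abort with the
offending step identified. Defaults (dimensionless time, abundance units):

| parameter | default | rationale |
|---|---|---|
| `r` | 1.0 | sets the time unit |
| `K0` | 100 | comfortable dynamic range above the extinction threshold |
| `sigma_alpha` | 0.05 | axis hosts ~10–20 lumps; pattern well resolved by 200 species |
| `dt` | 0.25 | RK4 error far below 1% on the logistic benchmark (r·dt = 0.25) |
| `t_max` | 20000 | long enough for the pattern to spread across the axis (see below) |
| `evolution_interval` | 1.0 | dynamics partially relax between evolutionary updates |
| `evolution_step_sd` | 0.015 | ≈ 0.3 σ_α; see below |
| `extinction_threshold` | 1.0 | ≈ 1% of K0; prunes species that lost their niche. Must stay below the initial abundance K0/n (0.5 only until the first growth phase lifts all species above 1 within the first interval) |
| `boundary` | reflecting | avoids a hard-clip pile-up artifact at the axis ends |

`lumpy_run_params()` packages the standard demonstration conditions
(200 species, uniform K, hill climb, the defaults above, with
`evolution_step_sd = 0.3 σ_α`).

### What drives the pattern, and how long it takes

With a Gaussian kernel and uniform K the *continuum* uniform state is not
Turing-unstable (the kernel's Fourier transform is positive), so the
regular pattern is seeded by two discreteness effects: the hard axis
boundaries (species at the edge have competitors on one side only, which
starts an alternating over/under-shoot that propagates inward) and
extinction-induced gaps. Both act slowly — competitive exclusion between
near-identical species is weak, which is precisely the near-neutrality the
model is designed to exhibit — hence the long default `t_max`. The
evolutionary step of ≈ 0.3 σ_α matters: much smaller steps leave the
interior quasi-uniform for a very long time; much larger steps freeze a
coarse, irregular pattern. The emergent spacing is roughly 0.6–1.8 σ_α
and grows with σ_α, matching the support spacing of the non-negative
equilibrium computed independently (non-negative least squares on a fine
position grid).

### Quantifying lumpiness

`lump_summary` clusters surviving positions by single-linkage gaps.
`lump_spacing_stats` measures pattern regularity using gap threshold
0.5 σ_α and excludes two kinds of artifact before computing spacings:
lumps holding less than 10% of the most abundant lump's abundance
(transients still on their slow way to extinction) and lumps within
2 σ_α of the axis ends (the boundary itself pins lumps at a
systematically different spacing). Under the standard conditions the
spacing coefficient of variation at σ_α = 0.05 is ≈ 0.19–0.29 across
seeds, and mean spacing increases monotonically over
σ_α ∈ {0.03, 0.05, 0.08}.

## Mode detection

`fit_gaussian_mixture` wraps EM (scikit-learn) for univariate Gaussian
mixtures on the natural-log length scale, with:

* a variance floor of (10⁻⁴)² on the log scale (catalogue lengths are
  rounded to 0.1 mm, so exact ties would otherwise collapse a component);
* `n_init` seeded k-means restarts (default 10), best by log-likelihood;
* a nesting repair in `select_best_mixture`: if the k-component fit has
  lower likelihood than the (k−1) fit, the k fit is re-run from the
  (k−1) solution with its widest component split, keeping the maximized
  log-likelihood non-decreasing in k.

`select_best_mixture` fits k = 1..10 (skipping k with fewer than 2k
observations) and selects by BIC (AIC selectable); ties go to smaller k.
Components of the winning fit whose means differ by less than half the sum
of their sds are merged (weight-weighted) before modes are reported, so a
physical lump modelled by two overlapping components is not reported as
two modes with a spurious ratio near 1.

`kernel_density` (Gaussian KDE, Silverman bandwidth by default, grid
spanning the data ± 3 bandwidths) and `find_density_peaks` (prominence
filter as a fraction of the maximum density) provide the smoothing-based
route to the same modes. The two routes are deliberately complementary:
with large samples BIC resolves genuine fine substructure (e.g. the
discrete pair-combinatorics of a ratio distribution), while density peaks
track the coarse mode ladder. Peak-to-peak ratios are `exp` of consecutive
log-scale mode differences, always ≥ 1.

## Pairwise ratio analysis

Occurrence samples with at least 3 species (the conventional threshold for
this analysis: "more than two species found") contribute all n(n−1)/2
within-sample pairs; each pair's ratio is larger length over smaller, so
ratios of exactly 1 (tied catalogue lengths) are retained — they are the
"very similar in size" signal, protected from degeneracy by the mixture's
variance floor. Pairs recurring in multiple samples count once per sample:
each sample is an independent observation of local co-existence, and the
observed pairs-per-sample arithmetic of the motivating survey data is
consistent with that convention. Mode analysis runs on log ratios, where a
geometric size ladder with step ρ becomes equally spaced modes at
0, log ρ, 2 log ρ; results are reported back on the ratio scale.

## Synthetic data

The generator produces the study-shaped inputs:

* **Lumpy pools**: lump centers are an exact geometric sequence
  `base_length · spacing_ratio^k`; species get independent
  Normal(0, `within_lump_sd`) log-scale deviations (multiplicative form, so
  zero noise gives the centers exactly). Defaults: spacing 1.35 — the
  empirically motivated limiting-similarity ratio — and within-lump sd
  0.03–0.05, keeping lumps separated by ≥ 4 within-lump sds.
* **Co-occurrence samples**: species drawn without replacement; per-sample
  richness either fixed or zero-truncated Poisson (mean λ/(1−e^{−λ})),
  truncated above at the pool size. The real survey's richness law is
  unknown; the truncated Poisson is a stated stand-in, not an inference.
  Default λ = 4 gives mostly 2–7 species per sample, so a minority of
  samples pass the ≥ 3-species filter with richness 3–8, qualitatively
  like sparse field samples.
* **Aquifer triplets**: exactly three species per isolated community at
  log spacing log(1.6) — the wider spacing expected where few species
  compete — with multiplicative noise.
* **Regional catalogues**: concatenated pools with unique region tags.

What the generator does *not* emulate: taxonomy, geography, true regional
richness, abundance structure within samples, detection error correlated
with size, or rounding of lengths (available as an opt-in flag). Passing
tests therefore demonstrate that the analysis chain recovers the structure
it assumes when that structure is present — not that real catalogues have
that structure.

All randomness descends from one user seed through named SHA-256-derived
substreams, so each generator and CLI subcommand is independently
byte-reproducible.

## Problem sizes in the validation suite

The acceptance checks use 600-observation pools for mixture recovery
(50 replicates, ≥ 90% required), 500 co-occurrence samples for the
end-to-end ratio analysis, 200-species simulations at t_max = 20000 with
5 seeds at σ_α = 0.05 and 3 seeds at 0.03 and 0.08, and 100-case property
sweeps for the closed-form equilibrium and pair-count conservation. These
sizes were chosen so the full chain demonstrates its properties at desk
scale; all scale linearly upward.

## Known limitations

* The hill-climb pattern is metastable, not a global optimum: the frozen
  spacing depends mildly on the evolutionary step size, and defects anneal
  only on extremely long timescales — faithful to the near-neutral slow
  dynamics the model describes, but worth knowing when comparing runs.
* With uniform K and a Gaussian kernel, lump gaps never exceed ~2 σ_α;
  analyses expecting wider gaps need a non-uniform K or a
  platykurtic kernel, neither of which is enabled by default.
* BIC on very large ratio samples legitimately selects many classes; use
  the density-peak route when the coarse mode ladder is the quantity of
  interest.
* The simulator is single-axis; multi-dimensional niches and explicit
  speciation are out of scope.
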
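# Methods

## Overview

`overconnect` chains two statistical stages over a user-supplied directed
regulatory network and a two-group expression study: (1) per-gene
differential expression with an empirical-Bayes moderated t-test, and (2) a
per-hub hypergeometric over-connectivity test of the hub's target set
against the DE gene set. Downstream stages (class rankings, inhibitor
screening, subnetwork reconstruction) are deterministic transformations of
those two results.

## Differential expression

Model: log2-scale intensities, genes independent, equal within-group
variance per gene. The two-group fit gives `log2fc = mean(case) −
mean(control)`, the pooled variance `s²` with `df = n_case + n_control − 2`,
and unit standard error `√(1/n_case + 1/n_control)`.

Variance moderation assumes `s² | σ² ~ σ²·χ²_df/df` with a scaled
inverse-chi-square prior `σ² ~ d₀·s₀²/χ²_{d₀}`. The prior is fitted by
method of moments on `e_g = log s²_g − ψ(df/2) + log(df/2)`:
`E[e] = log s₀² − ψ(d₀/2) + log(d₀/2)` and
`Var[e] = ψ′(df/2) + ψ′(d₀/2)`, solving `ψ′(d₀/2) = Var̂[e] − ψ′(df/2)` by a
Newton iteration on the trigamma inverse. Posterior variances are
`s̃² = (d₀s₀² + df·s²)/(d₀ + df)` and the moderated t is referred to
`t(df + d₀)` (standard normal at `d₀ = ∞`). The implementation is checked
against Bioconductor limma on shared input in the test suite (agreement to
~1e-10).

Degenerate branches, chosen where the moment estimate has no positive
solution (`Var̂[e] ≤ ψ′(df/2)`):

* literally identical variances (zero spread) — the prior is a point mass
  at that common value, so inputs are returned unchanged; this is the only
  self-consistent reading of a zero-spread sample, which no sampling model
  with finite df produces;
* positive spread within the chi-square sampling expectation — `d₀ = ∞`
  with `s₀² = exp(mean(e))`, the bias-corrected location estimate. (The
  uncorrected geometric mean of `s²` underestimates `σ²` by
  `exp(ψ(df/2) − log(df/2))` — about 24% at df = 4 — and measurably
  inflates the null false-positive rate.)

Genes with `s² = 0` are excluded from the prior fit but still shrunk.
Significance uses two gates applied jointly: BH-adjusted `p ≤ α` (default
0.05) and `max(FC, 1/FC) ≥ c` (default 2, i.e. `|log2fc| ≥ 1`). Both gate
inputs are reported per gene so either gate can be applied alone
downstream. Missing values are never imputed; genes carrying any are
dropped at load time with a warning.

## Over-connectivity

The universe `N` is the node count of the supplied network — the network
plays the role of the annotation database, so its size is the correct
denominator. `R` counts a hub's distinct outgoing targets (regulation is
directional; an `undirected` mode counting all neighbors exists but is off
by default). `n` counts DE genes that are network nodes; DE genes the
network does not recognize are excluded. Edge sign never affects counting —
it is carried only for subnetwork rendering.

Under the null that the `n` DE genes are an exchangeable draw from the `N`
nodes, `Actual ~ Hypergeometric(N, R, n)`, giving the Expected, variance, z
and one-sided tail p listed in the README; the tail side follows the sign
of z, exactly one side per hub, no two-sided p. Tail probabilities are
computed with `scipy.stats.hypergeom`; the test suite verifies them against
an exact integer-enumeration oracle (suffix sums of
`C(R,k)·C(N−R,n−k)/C(N,n)`) to 1e-12 over the complete grid `N ≤ 60`.

Hubs with `R = 0` are skipped (no statistic exists). Records with zero
variance (e.g. `n = 0`) carry a null z, are flagged, and never enter
rankings. Connectivity p-values are reported raw by default — the gate the
rankings apply is `p ≤ 0.05` per hub — with an optional BH adjustment
across hubs.

Numerical notes: tie-breaks in rankings are total and deterministic
(z descending, then p ascending, then hub name); all serializations
(edge lists, GraphML, DOT, plot data sidecars) sort nodes and edges so
identical inputs give byte-identical outputs.

## Synthetic data

The generator emulates the intended study design: two groups of 3 samples,
log2-scale intensities with Gaussian noise (a standard approximation for
normalized microarray data), and a directed network with designated hubs.
Defaults, used throughout the tests and the acceptance script as the
reference condition:

| parameter | default | rationale |
|---|---|---|
| n_nodes | 200 | desk-scale universe; large enough for ~20 distinguishable hubs |
| n_hubs | 20 | only hubs have outgoing edges, as in a regulator-centric edge list |
| mean_out_degree | 8 | lognormal(σ = 0.75) degrees, heavy-tailed like curated networks |
| class fractions | TF .15 / kinase .15 / protease .10 / other .60 | regulatory classes are a minority of a database universe |
| n_planted | 3 | a few true drivers among many null hubs |
| planted_target_fraction | 0.8 | most, not all, targets of a true regulator respond |
| effect_log2 | 1.5 | ≈ 2.8-fold shifts, typical of strong regulatory effects |
| noise_sd | 0.5 | log2-scale residual sd typical of replicated arrays |
| n_case / n_control | 3 / 3 | the small-replicate design the moderated t exists for |

Edge effects are drawn activation/inhibition/unspecified at 0.5/0.3/0.2.
Planted effects shift a hub's *targets* (not the hub itself), because the
over-connectivity statistic detects target-set enrichment; a gene shared by
two planted hubs is shifted once. All generation is keyed by a single seed
through independent named streams, so `(config, seed)` determines every
output bit.

What the generator does **not** emulate: probe-level effects and
normalization artifacts, batch effects, correlated noise between genes,
feedback between regulator expression and target expression, and incomplete
overlap between measured genes and network nodes (every simulated gene is a
network node). Passing tests therefore validate the statistical machinery,
not robustness to those real-data complications.

## Null calibration

Calibration runs (no planted effects) select "DE" genes at raw `p ≤ 0.05`
rather than with the joint FDR + fold-change gate: on null data the joint
gate correctly returns an (almost always) empty set, which would leave the
connectivity stage untested, whereas the raw-p selection yields a uniform
random ~5% node subset for which the hypergeometric null holds exactly.
Measured over 100 seeds at the defaults: DE false-positive rate 0.047
(nominal 0.05), mean connectivity z ≈ 0.00, fraction of hubs with
connectivity `p ≤ 0.05` ≈ 0.018. That last figure is well below 0.05 and is
a genuine property of discrete one-sided hypergeometric tails at this
scale: with `n ≈ 10` DE genes and median out-degree ~6, the largest
achievable tail probability not exceeding 0.05 averages ≈ 0.02, so the test
is conservative — null hubs enter `p ≤ 0.05` rankings *less* often than the
nominal rate, never more.

## Subnetwork reconstruction

Reconstruction is mechanized as a depth-bounded breadth-first expansion
from the seed over outgoing *and* incoming edges (default depth 2 — two
regulatory hops cover seed → intermediate → effector chains), optionally
filtered to nodes significant in ≥ 1 group (`de_only`, default on; turn it
off to keep non-DE intermediates such as complex members). Per-group states
come from the DE tables: up/down when significant, unchanged when measured
but not significant, unmeasured otherwise. DOT export colors edges
green/red/gray for activation/inhibition/unspecified.

## Problem sizes

Repeated-simulation checks (null calibration, planted recovery) use
100-seed batteries at the 200-node default; the acceptance script uses
50-seed batteries; the hypergeometric enumeration check covers the complete
grid `N ≤ 60`. These sizes give stable estimates (binomial SE on a
100-seed hit rate ≈ 0.03) while keeping any single check in seconds.

## Known limitations

* The over-connectivity test treats DE calls as exchangeable draws; genes
  co-regulated by a shared *unmeasured* mechanism violate this and inflate z
  for hubs targeting correlated modules.
* `n` and the DE set depend on the upstream gates; the connectivity p is
  conditional on the realized DE set, not corrected for DE-stage selection.
* Hub fold change (FC column) is informational only; the statistic never
  uses the hub's own expression.
* With very small universes or degrees the one-sided hypergeometric p is
  strongly discrete and conservative (see null calibration).
* No multiple-testing correction across hubs by default, matching the
  raw `p < 0.05` ranking convention; `--bh` is available when the hub list
  is large.
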
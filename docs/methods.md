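# Methods

## Model overview

`crisprcoevo` simulates the coevolution of a bacterial (or archaeal) host
community with a lytic virus community in which host immunity is provided by
a CRISPR locus.  The model couples three layers:

1. **Ecology** — deterministic density dynamics of every live strain;
2. **Molecular interaction** — a genotype-determined lysis probability for
   each host-virus pair;
3. **Evolution** — stochastic genomic events that create new strains.

A *host strain* is an ordered CRISPR locus `S = (s1, …, su)` of up to
`u_max = 8` spacers, newest first.  A *viral strain* is a tuple
`G = (g1, …, gv)` of exactly `v = 10` protospacers.  Alleles are abstract
integers under an infinite-alleles model: every undirected mutation draws a
fresh identifier.  This is justified by the assumption that a single
mismatch abolishes CRISPR interference, which makes exact identifier
equality equivalent to exact sequence match; it also means no mutation can
ever recreate an existing genotype.

### Ecology

With `N_i` host-strain densities (cells/mL) and `V_j` viral-strain
densities (virions/mL):

    dN_i/dt = r N_i (1 − Σ_k N_k / K) − φ N_i Σ_j l_ij V_j
    dV_j/dt = β φ V_j Σ_i l_ij N_i − φ V_j Σ_i N_i − m V_j

All host strains share the carrying capacity `K`, growth rate `r` and
adsorption constant `φ` (strain-specific hooks would be straightforward but
are not exposed; a single life history isolates the effect of immunity).
Virions are lost to *every* adsorption, successful or not — an infecting
genome that is destroyed by CRISPR interference is still removed from the
free pool — and decay freely at rate `m`.

The lysis probability couples ecology to genotype:

    l_ij = p          if some spacer of host i equals some protospacer of virus j
    l_ij = 1 − q      otherwise

`p` is the probability that interference fails against a matched virus;
`q` is the probability that a non-immune host survives an infection by
acquiring a spacer during the encounter.

### Closed-form oracles

For one host and one virus interacting at lysis probability `l`, the
interior equilibrium is

    N* = m / (φ (β l − 1)),    V* = (r / φ)(1 − N*/K),

which exists iff `β l > 1 + m/(φK)`.  At the default parameters with
`l = 1` this gives `N* ≈ 2.0408×10⁴ /mL` and `V* ≈ 9.3546×10⁶ /mL`; the
test suite integrates the mutation-free system for 5000 h and requires
agreement within 1%.  The default parameters are also required to satisfy
the two viability conditions `β p < 1 + m/(φK)` (viruses starve on immune
hosts) and `β (1 − q) > 1 + m/(φK)` (viruses persist on susceptible hosts);
with the defaults the threshold is `1 + m/(φK) ≈ 4.1623`.

### Evolutionary events

Two event channels fire as a marked Poisson process (Gillespie sampling):

* **Undirected viral mutation.**  Virions are produced at total rate
  `b = Σ_j β φ V_j Σ_i l_ij N_i`; with per-allele mutation probability `μ`
  over `v` protospacers the event rate is `b μ v`.  The parent strain is
  chosen proportionally to its production rate `b_j`, the mutated position
  uniformly among the `v` sites, and the new allele is fresh.
* **Directed spacer acquisition.**  Host strain `i` acquires at rate
  `a_i = q φ N_i Σ_j V_j w_ij`, where the defense weight
  `w_ij = (1−p) M_ij + (1−M_ij)` counts surviving encounters.  For
  non-immune pairs, survival and acquisition are the *same* `q`-event, so
  `q` appears exactly once (reading them as independent coins would give a
  negligible `q²` channel instead; we document this as the one place the
  verbal model description is ambiguous).  The donor virus is chosen
  proportionally to `V_j w_ij`, and the acquired protospacer uniformly
  among the donor's `v` alleles.  Re-acquiring an allele already in the
  locus is allowed; it changes the ordered locus without adding immunity.

New strains are seeded at `1.1 ρ_c`, 10% above the extinction cutoff.  The
seed density is *not* subtracted from the parent: at 0.11/mL it is
negligible against any live strain's density (≥ ρ_c but typically orders of
magnitude larger), and conserving it exactly would complicate the ODE
segmentation for no measurable gain.  If an acquisition recreates the
ordered locus of a live host strain, the seed density is merged into that
strain instead of duplicating it.

All rates use per-mL densities in a nominal 1 mL system, so density
products serve directly as event rates.

### Hybrid integration protocol

The ODE system is integrated segment by segment.  A segment ends at the
earliest of (a) the sampled next event time, (b) the next output time on
the regular grid, and (c) the horizon `t_max`; a terminal root-finding
event on `min_i(density_i) − ρ_c` pauses the segment exactly where a strain
crosses the extinction cutoff.  At every pause, strains at or below `ρ_c`
are removed (an absorbing state — recurrence requires a new mutation
recreating the genotype), the scheduled event is applied if due, a snapshot
is recorded if an output time was reached, and all rates are recomputed
from the current densities before a fresh exponential waiting time is
drawn.  Ties are resolved extinction → stochastic event → output.  Rates
are thus frozen within a segment; because segments are bounded by the 2 h
output interval, the freeze error is small, and no thinning correction is
applied.  The run ends at `t_max` or when either guild is empty.

RNG discipline: one `numpy` generator per replicate, drawn in a fixed
order (waiting time, event kind, parent, position/donor/allele index), so a
config plus seed reproduces a record exactly.

## Numerical choices

* **Integrator.**  `scipy.integrate.solve_ivp` with DOP853 at
  `rtol = 1e-8`, `atol = 1e-10`.  The dynamics are non-stiff (all
  characteristic rates are O(0.1–1)/h), and a high-order explicit method
  keeps per-segment overhead low across the tens of thousands of
  event-paused segments in a long run; the method is config-exposed.
* **Extinction location.**  The single `min(density) − ρ_c` event function
  is continuous but non-smooth; on the rare segment where root bracketing
  fails the driver retries with one smooth event per strain.  Removal uses
  a relative hysteresis of 1e-9 so a strain placed exactly at the threshold
  by the root finder is always removed; densities are clamped at zero only
  at extinction pauses.
* **Boundary convention.**  A strain at exactly `ρ_c` is removed (closed
  threshold).
* **Ties.**  An event and an output time coinciding (measure zero) are
  processed event first.

## Parameters

| Parameter | Meaning | Default | Units |
|---|---|---|---|
| `p` | CRISPR interference failure probability | 1e-5 | — |
| `q` | spacer acquisition probability per encounter | 1e-5 | — |
| `r` | maximum host growth rate | 1 | 1/h |
| `K` | shared host carrying capacity | 10^5.5 | cells/mL |
| `β` | burst size | 50 | virions |
| `φ` | adsorption rate constant | 1e-7 | mL/h |
| `m` | free-virion decay rate | 0.1 | 1/h |
| `μ` | per-allele protospacer mutation probability | 5e-7 | per virion |
| `ρ_c` | extinction cutoff | 0.1 | 1/mL |
| `u_max` | CRISPR locus capacity | 8 | spacers |
| `v` | protospacers per viral genome | 10 | — |
| `t_max` | horizon | 2500 | h |
| output interval | snapshot grid | 2 | h |

The ecological values are typical of *E. coli* and its lytic phages; the
molecular error rates sit in the range measured for *S. thermophilus*
CRISPR systems.  The host generation time is ~1 h at these parameters, so
hours double as generations.

The founder community is one spacer-free host at 10⁴ cells/mL and one
virus (ten fresh alleles) at 10⁵ virions/mL — inside the coexistence basin
of the susceptible pair, and configurable.  An empty founder locus makes
the average spacer count rise from zero and saturate at `u_max`, which is
the regime the positional-immunity analysis assumes.

## Analyses

* **Morisita–Horn similarity.**  For communities with abundances `n_ij`,
  `ψ_i = Σ_j n_ij²/N_i²` and `Ψ = 2 Σ_j n_1j n_2j / ((ψ_1+ψ_2) N_1 N_2)`.
  The index is scale-invariant, so per-mL densities are used directly.
  The similarity matrix is computed over the snapshot grid (optionally
  subsampled) via a sparse abundance matrix product.
* **Positional relative immunity.**  At a snapshot, `immunity(n)` is the
  density-weighted fraction of the viral population matched by the union of
  the leading `n` spacers over all live hosts; the relative value is
  `immunity(n)/immunity(u_max)`.  Averages run over all snapshots after
  the first time every live host locus is full; snapshots where the full
  locus matches nothing are skipped (the ratio is undefined there).  The
  union-over-hosts reading treats immunity as a community property; a
  host-density-weighted per-strain variant is available via
  `weighting="host"` for comparison.
* **Strain summaries.**  Live strain counts and total densities per
  snapshot; per-strain lifetimes from the genealogy (censored at the final
  time); Muller-plot-ready proportion tables including only strains at
  ≥ 1% of their population.
* **p–q sweep.**  Each replicate is summarized by time averages over the
  trailing half of the *configured* horizon; a run that ended early by
  extinction is extended at its absorbing state (extinct guild at zero,
  surviving guild at its final snapshot), so "viruses died out" registers
  as low viral density rather than being dropped.  Medians and standard
  errors are taken across replicates per (p, q) cell.

## What the simulations do and do not show

All inputs are synthetic: the generator *is* the model, so the tests
validate internal consistency (closed-form equilibria, sampling
distributions, invariants) and the emergent phenomena the model predicts
(diversification, turnover, leading-spacer dominance, q-sensitivity).  They
cannot validate the model against real metagenomic time series; in
particular, abstract integer alleles ignore partial matching, PAM effects
and primed acquisition, lysogeny and spatial structure are absent, and the
shared-`K` logistic hides resource dynamics.

## Problem sizes

The package's own test and reproduction runs use scaled-down ensembles
chosen for single-CPU convenience: 10 replicates at `t_max = 1000 h` for
the positional-immunity reproduction, 4-replicate ensembles and 2 long
(2200 h) replicates in the test suite, and 2 replicates per cell at
`t_max = 1200 h` on a 5-cell cross of the (p, q) grid.  Statistics that
sharpen with replicate count (profile standard deviations, sweep medians)
are correspondingly noisier than at full scale, but every directional and
threshold check is at its stated value.

## Known limitations

* Near-neutral viral diversification at very low `q` accumulates hundreds
  to thousands of strains before immunity catches up; runtime grows
  superlinearly in that regime.
* Frozen-rate Gillespie sampling is an approximation; its error is bounded
  by the 2 h recalculation interval but not corrected by thinning.
* The absorbing-state extension in the sweep summary idealizes
  post-extinction host dynamics as frozen at the final snapshot rather
  than relaxing to `K`.
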
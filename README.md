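# crisprcoevo

Multiscale eco-evolutionary simulation of CRISPR-mediated coevolution
between microbial hosts and their lytic viruses.

## The problem

CRISPR loci give bacteria and archaea a heritable, *directed* immune
record: short spacers copied from viral genomes, newest at the leading end
of the locus.  Viruses escape by *undirected* point mutation of the
protospacers those spacers match.  How do these two asymmetric mutational
mechanisms, embedded in ordinary predator-prey ecology, shape the
diversity and turnover of host and viral communities?  `crisprcoevo` is a
simulator for exactly this question, aimed at theoretical ecologists and
phage-host modelers.

## The model

Strain densities follow a generalized Lotka-Volterra system with a shared
host carrying capacity,

    dN_i/dt = r N_i (1 − Σ_k N_k / K) − φ N_i Σ_j l_ij V_j
    dV_j/dt = β φ V_j Σ_i l_ij N_i − φ V_j Σ_i N_i − m V_j

where the lysis probability `l_ij` is `p` (interference failure) when host
`i` carries a spacer matching a protospacer of virus `j`, and `1 − q`
(no acquisition) otherwise.  Genomic change is a stochastic marked Poisson
process simulated with Gillespie timing between event-paused ODE segments:
viral protospacer mutations fire at rate `b μ v` (with `b` the total
virion production rate), host spacer acquisitions at rate
`Σ_i q φ N_i Σ_j V_j w_ij`.  Hosts store at most `u_max = 8` spacers
(FIFO), viruses carry `v = 10` protospacers, and alleles are abstract
integers under an infinite-alleles model.  Strains crossing the density
cutoff `ρ_c = 0.1 /mL` are removed (absorbing); mutants are seeded at
`1.1 ρ_c`.  See `docs/methods.md` for the full account.

The analysis layer computes Morisita-Horn similarity matrices (strain
turnover), positional relative immunity (how much of the viral population
the newest *n* spacers recognize), strain counts/lifetimes/proportions,
and (p, q) sensitivity sweeps.

## Worked example

```python
from crisprcoevo import SimConfig, run, equilibrium_single_pair, EcoParams
from crisprcoevo.analysis import relative_immunity_profile, strain_summaries

# a 1000 h replicate at the baseline parameters
record = run(SimConfig(t_max=1000.0, seed=3))
final = record.snapshots[-1]
print("live strains at t=1000 h:", len(final.host_ids), "host,",
      len(final.virus_ids), "viral")
print("relative immunity by leading-spacer count:")
print(relative_immunity_profile(record).round(3))
```

prints

```
live strains at t=1000 h: 27 host, 342 viral
relative immunity by leading-spacer count:
n
1    0.916
2    0.939
3    0.945
4    0.974
5    0.986
6    0.990
7    0.990
8    1.000
Name: relative_immunity, dtype: float64
```

A single susceptible founder host and virus have diversified into tens of
host strains and hundreds of viral strains.  The immunity profile says the
three newest spacers already provide ~95% of the immunity conferred by the
full eight-spacer locus at this seed — recently acquired spacers dominate
CRISPR defense.  As a sanity anchor, with mutation disabled the same pair
settles on the closed-form coexistence equilibrium
`equilibrium_single_pair(EcoParams(), lysis=1.0)` =
`(2.0408e4 cells/mL, 9.3546e6 virions/mL)`.

A CLI mirrors the library:

```bash
crisprcoevo run --config cfg.yaml --seed 42 --out out/rep0
crisprcoevo ensemble --replicates 10 --out out/ens
crisprcoevo analyze similarity out/rep0 --interval 10 --out sim.tsv
crisprcoevo analyze immunity out/ens/rep* --out immunity.tsv
crisprcoevo fixtures lv-pair --out lv.yaml
```

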
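# permkit

Ion-permeation analysis for membrane-channel molecular-dynamics
trajectories: crossing-event detection, single-channel conductance,
Poisson / double-Poisson waiting-time statistics, entry-pathway
classification, and channel-profile observables — with a synthetic
trajectory generator that makes the whole chain testable without
multi-microsecond MD data.

## Who this is for

Simulators of ligand-gated ion channels (the package was written around a
cation-selective pentameric receptor, the α7 nicotinic acetylcholine
receptor, but nothing is hard-wired to it) who want to turn raw ion
trajectories under an applied field into the standard observables of a
conduction study: per-segment event tables, conductance with error bars,
waiting-time model fits, lateral-fenestration statistics, and pore
profiles.

## The model

**Events and conductance.** The transmembrane counting region is a bounded
cylinder: two z-planes through the boundary glutamate rings at either end
of the pore, plus a radial gate (default 17.3 Å). A top-to-bottom (TB)
event is a complete traversal top ring → pore → bottom ring; bottom-to-top
(BT) is the mirror image; only complete traversals count. The current over
a window Δt is the net translocated charge,

    I = (e/Δt) · Σᵢ qᵢ nᵢ ,   nᵢ = ±1,

and the single-channel conductance is G = I/Vₑ with Vₑ = L_z·EF the
membrane voltage. The net event count for a K⁺/Cl⁻ system is
TB_K⁺ + BT_Cl⁻ − BT_K⁺ − TB_Cl⁻.

**Waiting times.** Inter-event intervals t (same direction, within one
segment) are modelled first as a homogeneous Poisson process,
f(t) = λe^(−λt), with λ estimated either from counts (λ = N/Δt) or by
regressing sorted intervals on −ln(1 − i/N) through the origin. Because an
ion that has just entered the pore mouth transiently blocks the next one,
the observed distribution lacks very short intervals; this is captured by
a chained double-Poisson (hypoexponential) model — an exponential lag
stage (λ_lag) followed by an exponential conduction stage (λ_cond):

    f(t) = λ_lag λ_cond (e^(−λ_cond t) − e^(−λ_lag t)) / (λ_lag − λ_cond),

with mean inter-event time 1/λ_lag + 1/λ_cond and expected count
T/(1/λ_lag + 1/λ_cond) in a window T. Event durations are fitted with a
log-normal.

**Pathways and profiles.** An event's entry is lateral if, shortly before
its start, the ion sat beyond the channel-wall radius at extracellular-
vestibule height (it crossed the wall, not the mouth). Profile observables
per 0.5-Å z-bin: ion density normalized to the bulk expectation
c·N_A·πr²·Δz, an inscribed-sphere pore radius, first-shell (3.52 Å)
hydration and protein-oxygen replacement counts, residue position
densities, and an MSD-based axial diffusion coefficient.

## Worked example

Published per-segment counts ship as a fixture; the bookkeeping above
turns them into the event table and summary statistics:

```python
import permkit as pk
from permkit import reporting

summaries = [pk.summary_from_counts(c) for c in pk.table1_fixture()]
agg = pk.aggregate(summaries)
print(reporting.render_table1(summaries[:3], aggregate_row=False), end="")
print(f"mean conductance {agg.means['conductance_pS']:.0f} ± "
      f"{agg.sems['conductance_pS']:.0f} pS")
```

```
Index	TBK+	BTK+	TBCl-	BTCl-	Net Events	Conductance [pS]
1	50	17	0	0	33	259
2	40	17	0	0	23	181
3	32	20	0	0	12	94
mean conductance 219 ± 22 pS
```

Segment 1 has 50 TB and 17 BT K⁺ events in 200 ns: net 33 translocated
charges, i.e. 26.4 pA at −102 mV, or 259 pS. Across all 18 segments the
mean is 219 ± 22 pS with a TB count variability (sd/mean) of 0.24.

End-to-end on synthetic data:

```python
spec = pk.SyntheticSpec(duration=200.0, seed=7, n_bulk=10)
bundle, truth = pk.generate_run(spec)
ledger = pk.detect_crossings(bundle)
fit = pk.fit_double_poisson(pk.waiting_times(ledger, pk.TB))
print(ledger.counts(), 1 / fit.lam_lag, 1 / fit.lam_cond)
```

detects `{('K+', 1): 40, ('K+', -1): 17}` — exactly the generator's ground
truth — and the fitted stage means (0.92 ns lag, 4.16 ns conduction;
true values 1 and 3.62 ns) predict 39.3 events per 200-ns window against
the 40 realized.

The same chain is scriptable from a shell:

```sh
permkit simulate --seed 7 --duration 200 --out traces.tsv
permkit detect --traces traces.tsv --out events.tsv
permkit conductance --events events.tsv --ve -102 --dt 200 --out table.tsv
permkit fitstats --events events.tsv --model double-poisson --out fit.json
```

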
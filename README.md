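# reefscale

Tools for studying how protection from size-selective harvesting shapes the
structure of marine communities, combining two engines:

1. **A metabolic-scaling simulator.** Random food webs are drawn from the
   niche model with connectance `C = S^-0.65`; prey-averaged trophic levels
   `TL_i` set mean body masses `M_i = M0 · Q^(TL_i - 1 + ε_i)` with
   `ε_i ~ N(0, 1)`; trophic transfer efficiencies decline weakly with mass,
   `TE_i = TE_max · M_i^-0.03 / max_j(M_j^-0.03)`; and each species'
   biomass scales as `B_i ∝ M_i^{k_i}` with

   ```
   k_i = 0.25 + (1/n_j) · Σ_j t_ji / log(PPMR_ji)
   t_ji = log(TE_i)      if PPMR_ji > 1
   t_ji = log(1 - TE_i)  if PPMR_ji < 1
   ```

   the energetic-equivalence baseline (0.25) corrected for trophic transfer
   across each feeding link (`PPMR_ji = M_pred / M_prey`, `n_j` = number of
   prey). The community scaling coefficient `k_c` — the OLS slope of
   log B on log M — summarizes the biomass–size spectrum: higher `k_c`
   means a more top-heavy community. A size-selective harvest removes the
   heaviest individuals of the largest species (selection weight ∝ mass,
   removal level `r_i ~ U[0.3, 1]`, intraspecific sizes lognormal), and the
   harvested slope `k_c^h` is refit.

2. **A nonparametric causal-inference toolkit** for binary site variables
   (Human density, thermal stress anomalies, coral presence, marine
   protection, community structure): stratified G² independence tests,
   Inductive-Causation discovery (skeleton → colliders → rule R1),
   d-separation and the do-calculus Rule 2 check that licenses
   `P(Y | do(M)) = P(Y | M)`, the six-route *genuine cause* criterion, and
   the average causal effect `ACE = P(Y=1|M=1) − P(Y=1|M=0)`.

A synthetic-data module generates every input with known ground truth:
binary site tables from a structural causal model with the protection
topology (drivers → MPA → structure) and a closed-form interventional ACE,
survey tables with prescribed scaling slopes, and weekly SST series for
thermal-stress-anomaly counting.

## Worked example

```python
import reefscale as rs

# protected vs harvested communities across a transfer-efficiency sweep
table = rs.run_experiment(rs.SimParams(seed=42, n_reps=200))
print(table.groupby("te_max")[["k_c", "k_c_h"]].median().round(3))

# causal analysis of a synthetic site table with known ground truth
sites, truth = rs.generate_scm_table(rs.SCMConfig(seed=42))
graph = rs.discover(sites)
print("directed edges:", sorted(graph.directed))
print(rs.do_rule2_check(graph, "Structure", "MPA"))
report = rs.genuine_cause_test(sites, "MPA", "Structure", ("Human", "TSA", "Coral"))
print(f"routes passed: {report.n_routes_passed}/6, ACE = {report.ace:.3f} "
      f"(truth {truth.true_ace:.3f})")
```

prints

```
          k_c  k_c_h
te_max
0.1    -0.107 -0.193
0.3     0.012 -0.059
0.5     0.077  0.008
0.7     0.120  0.047
directed edges: [('Coral', 'MPA'), ('Human', 'MPA'), ('MPA', 'Structure'), ('TSA', 'MPA')]
True
routes passed: 6/6, ACE = 0.442 (truth 0.431)
```

Reading the output: the median community slope `k_c` rises with the
transfer-efficiency ceiling `TE_max` (more efficient communities are more
top-heavy) and the harvested slope `k_c^h` sits below the protected slope at
every level — harvesting pushes communities toward bottom-heavy spectra.
Discovery recovers the generating graph exactly (three drivers into MPA,
MPA into Structure); Rule 2 then licenses estimating the interventional
effect from the observational contrast, all six genuine-cause routes pass,
and the estimated ACE is within sampling error of the model's closed-form
interventional truth.

The same analyses are available from a shell:

```sh
reefscale simulate --out reps.csv --seed 42 --n-reps 200
reefscale synth scm --n 10000 --seed 42 --out sites.csv --truth truth.json
reefscale causal --data sites.csv --out report.json --dot graph.dot
reefscale run-all --outdir results/ --seed 42
```

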
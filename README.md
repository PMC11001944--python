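# emanet

Dynamic-network analysis of ecological momentary assessment (EMA) data:
two-step multilevel VAR(1) estimation of **temporal** (directed lag-1) and
**contemporaneous** (residual partial-correlation) networks, strength
centralities, and case-drop bootstrap stability — together with the
preprocessing such studies need (compliance filtering, relative-speed-index
screening of careless responses, per-series detrending) and a synthetic EMA
study generator with known ground truth.

## Who it is for

Researchers analysing intensive longitudinal self-report data — e.g. six
psychological-process items (negative/positive affect, negative/positive
cognition, rigidity, variation) rated 0–100 at five semi-random smartphone
prompts per day over three weeks — who want group-level dynamic networks with
a verifiable estimation pipeline.

## The model

For each node *k*, a node-wise multilevel regression predicts the score at
prompt *t* from the within-person-centered scores of all nodes at prompt
*t − 1*:

y_k(i,t) = b₀ₖ + Σⱼ βⱼₖ (y_j(i,t−1) − ȳ_j(i)) + Σⱼ γⱼₖ ȳ_j(i) + u(i) + ε_k(i,t)

The fixed effects βⱼₖ form the directed temporal network (edge *j → k*). The
step-1 residuals are then regressed node-wise on each other; each pair's two
directed coefficients are combined by a sign-consistent geometric mean into
the undirected partial-correlation network r_partial. Node importance is
summarised by in-strength IS(j) = Σₖ|βₖⱼ|, out-strength OS(j) = Σₖ|βⱼₖ| and
strength S(j) = Σₖ|r_partial,jk|, and the stability of the centrality ranking
is assessed by refitting on random 80% participant subsets.

## Worked example

```python
import emanet as e

# a full-scale synthetic study: 114 participants, 21 days, 5 prompts/day
ds = e.simulate_study(e.StudyDesign(n_participants=114, n_days=21),
                      seed=11, clip=True)

filtered, audit = e.apply_inclusion_filters(ds)      # >=73 prompts, RSI <= 2
detrended, report = e.detrend(filtered)              # per-series, alpha=0.05
lagged = e.build_lagged_table(detrended)             # no overnight lag pairs

tn, cn = e.fit_mlvar(lagged, e.FitConfig(random_effects="fixed"))
print(e.centrality_table(tn, cn).round(2))
```

prints

```
               in_strength  out_strength  strength
node
neg_affect            0.27          0.22      0.49
pos_affect            0.25          0.20      0.55
neg_cognition         0.27          0.25      0.56
pos_cognition         0.26          0.17      0.59
rigidity              0.21          0.46      0.63
variation             0.22          0.18      0.43
```

The generator's default population model gives rigidity the largest
out-strength (it drives the other processes) and the strongest
contemporaneous connectivity, and the fitted networks recover exactly that:
rigidity tops OS (0.46) and S (0.63), while its in-strength is the smallest —
it influences more than it is influenced. The audit log for this run retains
113 of 114 simulated participants and drops 548 implausibly fast prompts via
the RSI screen.

The case-drop bootstrap quantifies how stable that ranking is:

```python
stab = e.case_drop_bootstrap(lagged, e.FitConfig(random_effects="fixed"),
                             n_reps=200, drop_fraction=0.20, seed=12)
print(stab.frequencies.round(3))
```

```
              neg_affect  pos_affect  neg_cognition  pos_cognition  rigidity  variation
in_strength        0.415       0.035            0.4           0.15      0.00        0.0
out_strength       0.000       0.000            0.0           0.00      1.00        0.0
strength           0.000       0.000            0.0           0.01      0.99        0.0
```

Rigidity ranks first in out-strength in 100% and in strength in 99% of the
200 replications, whereas the in-strength ranking (true values nearly tied)
flips between negative affect and negative cognition — exactly the
behaviour rank-stability analysis is meant to expose.

## Command line

Every stage is also a subcommand of the `emanet` CLI:

```sh
emanet simulate --out study.csv --participants 114 --days 21 --seed 11
emanet preprocess --input study.csv --out clean.csv --audit audit.json
emanet fit --input clean.csv --out-dir nets/ --random-effects correlated
emanet centrality --edges nets/edges.csv --out centrality.csv
emanet bootstrap --input clean.csv --out stability.csv --n-reps 1000
emanet run --config demo.yaml        # the whole pipeline from one YAML file
```

Outputs are plain CSV/JSON (optionally GraphML) and every file's manifest
carries the SHA-256 hash of the configuration that produced it.

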
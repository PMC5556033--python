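# pbflex

Structural-alphabet analysis of molecular-dynamics conformational ensembles.

`pbflex` encodes each frame of a protein MD trajectory as a string of
**Protein Blocks** (PBs) — a structural alphabet of 16 local-backbone
prototypes `a`…`p`, each defined by 8 reference φ/ψ dihedrals over a
five-residue window — and quantifies, per residue, how the *local*
conformational repertoire behaves across an ensemble and how it differs
between a wild-type protein and its point variants. It was built for
studies of disease-linked missense variants (e.g. the integrin α_IIb
Calf-1 domain in Glanzmann thrombasthenia, whose region annotation ships
as the packaged default), where the interesting signal is often **distal**:
the mutated residue keeps its conformation while loops far away change
their repertoire.

## The statistics

For a residue position, let `f_x` be the probability of PB `x` over all
analysed frames. The package computes

- **Neq** — the equivalent number of PBs,
  `Neq = exp(−Σ_{x=1..16} f_x ln f_x)`.
  `Neq = 1`: a single local conformation; `Neq = 16`: random over the
  alphabet.
- **ΔNeq** — `|Neq_WT − Neq_var|` per position.
- **ΔPB** — `Σ_x |f_x^WT − f_x^var|`, the L1 distance between PB
  repertoires, in [0, 2]. It catches repertoire *swaps* that ΔNeq misses
  (same entropy, different blocks).
- **Cα RMSD/RMSF** (Kabsch superposition, Cα only) and crystallographic
  **B-factors**, juxtaposed with Neq into a three-metric flexibility
  profile; the discordant high-RMSF/low-Neq class flags rigid stretches
  riding inside deformable loops.
- **Sammon maps** — whole simulations (one point per run, summarized by
  per-position PB frequencies, compared by normalized mean ΔPB) projected
  to 2D by minimizing Sammon stress, with per-system barycentres.

A synthetic-data module plants known PB distributions, backbone
trajectories (internal-coordinate construction from φ/ψ) and noisy
Cartesian ensembles, so every stage is verifiable against ground truth
without running MD.

## Worked example

```python
import numpy as np
from pbflex import (SyntheticScenario, distribution_for_neq,
                    make_wt_variant_pair, SystemSet, compare_systems, hotspots)

# 20 positions at Neq 2; the variant's repertoire is edited ONLY at
# position 12, while position 5 plays the untouched "mutation site".
edit = distribution_for_neq(3.0, support=6, seed=999)
scenario = SyntheticScenario.from_neq_targets(
    [2.0] * 20, support=4, seed=11,
    run_plan_ns=(50,)*5 + (100,)*6,      # 11 runs, 850 ns at 100 ps stride
    variant_edits={"VAR": {12: edit}},
)
wt_runs, var_runs, pair = make_wt_variant_pair(scenario)
wt = SystemSet("WT", [r.discard_before(5000.0) for r in wt_runs])
var = SystemSet("VAR", [r.discard_before(5000.0) for r in var_runs],
                mutation_site=5)
profile = compare_systems(wt, var)
table = hotspots(profile, k=3)
print(table.to_string(index=False))
print("mutation site rank:", table.attrs["mutation_site_rank"])
```

prints

```
 rank  residue  delta_pb  delta_neq
    1       12  1.873208   1.002612
    2        9  0.023396   0.059710
    3        5  0.020881   0.053117
mutation site rank: 3
```

Position 12 — the planted distal edit — dominates with ΔPB ≈ 1.87
(estimated from 7950 pooled post-equilibration frames; planted truth
1.8738), while the nominal mutation site shows only sampling noise
(ΔPB ≈ 0.02). That is the distal-effect signature the pipeline exists to
detect.

The same flow is available from the shell:

```sh
pbflex simulate --scenario scenario.yaml --out sim/
pbflex compare --wt sim/WT.pbfasta --var sim/VAR.pbfasta --out results/pair
pbflex map --pb-fasta sim/WT.pbfasta --pb-fasta sim/VAR.pbfasta --out results/sm
pbflex validate plan.yaml --expected-total-ns 850
```

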
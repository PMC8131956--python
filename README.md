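# stressmap

Comparative stress analysis of multidomain protein MD trajectories, built
around the question a protein-stability engineer asks of an antibody Fab
fragment: *which domain or inter-chain interface gives way first under a
given stress, and what does that do to aggregation risk?*

Given a reference condition and one or more stress conditions (e.g. a
low-pH-like and a high-temperature-like ensemble), each as replicate
trajectories, the package computes:

- **Per-domain deformation** — all-heavy-atom RMSD of each domain after
  superposing every frame on that domain alone, windowed per-residue RMSF,
  and radius of gyration, with mean ± SEM over replicates.
- **Native-contact fractions** — the soft-cutoff score
  `Q = (1/N) Σᵢⱼ 1 / (1 + exp[β(rᵢⱼ − λ·r⁰ᵢⱼ)])` (β = 5 Å⁻¹, λ = 1.8,
  contacts defined at 4.5 Å in the reference structure) at domain,
  interface and residue level, plus total (native + non-native) contact
  counts.
- **Salt-bridge occurrence** — residue-level detection with a 3.2 Å O–N
  cutoff and the any-atom rule, occurrence % per trajectory, replicate
  mean ± SEM, a 10 % reporting threshold, and per-domain/interface counts.
- **β-strand occupancy change** — a minimal Kabsch–Sander assignment
  (H-bond energy `E = 27.888(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol,
  bond iff E < −0.5, bridge and ladder rules for the E state) and per-strand
  occupancy change between conditions.
- **APR solvent exposure** — Shrake–Rupley SASA of aggregation-prone
  regions (APRs) and their % change under stress; occluded-surface packing
  (OSP) scores in [0, 1] for the static structure.
- **Sequence-level bookkeeping** — enumeration of all 19 × L single
  mutants, the stabilizing-consensus intersection of two externally
  produced ΔΔG scan tables (negative = stabilizing), per-column Shannon
  entropy of an aligned FASTA in nats over 21 symbols (max ln 21 ≈ 3.04),
  and the ≥3-of-4 predictor consensus that turns per-residue APR calls
  into intervals.

A first-class synthetic generator (`stressmap.synthetic`) builds an
idealized four-domain "mini-Fab" (β-sandwich domains, designed salt
bridges, buried APR segments) and emits stress trajectories with exact
ground-truth schedules, so every analysis stage is verifiable at desk
scale without running MD.

## Worked example

Build the synthetic mini-Fab, simulate the three study conditions
(six replicates each) and compare:

```python
import numpy as np
from stressmap import (build_toy_fab, default_profiles,
                       simulate_stress_trajectory, toy_domain_map,
                       build_reference_contacts, contact_series,
                       domain_rmsd_series)

base = build_toy_fab()
dmap = toy_domain_map()
runs = {name: simulate_stress_trajectory(base, prof, n_frames=51,
                                         n_replicates=6)[0]
        for name, prof in default_profiles(seed=42).items()}

for dom in dmap.domains:
    stress = np.mean([domain_rmsd_series(t, base, dom, dmap).values[-1]
                      for t in runs["low_ph_like"]])
    ref = np.mean([domain_rmsd_series(t, base, dom, dmap).values[-1]
                   for t in runs["reference"]])
    print(dom, round(stress - ref, 2))
```

This prints the final-frame domain RMSD elevation versus reference:

```
final-frame domain RMSD vs reference (Å, mean over 6 replicates):
  low_ph_like     {'VL': 0.0, 'CL': 1.96, 'VH': 0.0, 'CH1': 0.0}
  high_temp_like  {'VL': 0.37, 'CL': 0.26, 'VH': 2.43, 'CH1': 0.4}
final interface Q (mean over 6 replicates):
  reference       {'VL-VH': 1.0,   'CL-CH1': 1.0}
  low_ph_like     {'VL-VH': 1.0,   'CL-CH1': 1.0}
  high_temp_like  {'VL-VH': 0.002, 'CL-CH1': 0.0}
salt bridges retained at >= 10% occurrence:
  reference       ['30-33 (90%)', '25-6 (80%)', '28-35 (71%)', '74-81 (61%)']
  low_ph_like     ['28-35 (55%)', '74-81 (51%)']
  high_temp_like  ['30-33 (39%)', '25-6 (35%)', '28-35 (29%)', '74-81 (25%)']
```

The two stress signatures read directly off these numbers: the
low-pH-like condition deforms only the CL-analog domain (+1.96 Å) while
both interfaces hold and the Glu-containing salt bridges (30–33, 25–6)
disappear; the high-temperature-like condition deforms every domain (VH
most) and collapses both inter-chain interfaces (Q ≈ 0) while all salt
bridges persist at reduced occupancy.

## Command line

```sh
stressmap fixture --out fixtures/ --seed 0        # synthetic data + ground truth
stressmap analyze --config run.yaml --out report/ # full comparative report (CSV)
stressmap entropy --alignment aln.fasta           # per-column entropy
stressmap ddg --table-a foldx.csv --table-b rosetta.csv
stressmap mutants --sequence seq.fasta
```

`run.yaml` names one reference condition and any number of stress
conditions, each with replicate trajectory paths (multi-model PDB), plus
the domain/strand/APR maps and parameter overrides; see
`stressmap.pipeline.load_config` for the schema.

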
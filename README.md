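# hingedyn

Analysis toolkit for hinge-type dimeric peptides — disulfide-stapled
β-hairpin dimers whose function lives in two slow motions: the opening and
closing of the two arms and the mutual twisting of the hairpins. The
package provides the complete methodology for characterizing such hinges
from molecular simulation data, and a coarse-grained synthetic hinge on
which every stage can be validated against closed-form ground truth.

It is aimed at computational structural biologists who want to

* build robust geometric descriptors from **virtual atoms**: the opening
  angle at the disulfide-cluster center between the per-chain C5α/C8α
  midpoints, the W–W′ twist distance between tryptophan side-chain
  centers, the G7–G7′ loop distance, and hydrogen-bond counts;
* run **essential dynamics** (Cα-covariance PCA) with eigen-spectra,
  projections and mode animations;
* run and post-process **well-tempered metadynamics** —
  V(s,t) = Σ h_i exp(−(s−c_i)²/2σ²) with tempered heights
  h = w₀ exp(−V/k_BΔT), ΔT = (γ−1)T — including PLUMED-style COLVAR and
  HILLS text I/O and exact run resumption;
* reconstruct **free energy surfaces** F(s) = −k_BT ln ρ(s) from biased or
  unbiased CV series, with final-bias reweighting
  w_i ∝ exp(+V(s_i)/k_BT), convergence checkpoints, per-basin block
  errors, and minimax-path barriers.

The synthetic generator samples an analytic double-well/harmonic
landscape U(θ, w) by overdamped Langevin dynamics and embeds every state
into Cartesian pseudo-atom frames, so descriptors, PCA, metadynamics and
FES estimation are all testable end to end. See `docs/methods.md` for the
model and all numerical choices.

## Worked example

Recover a known free-energy landscape with well-tempered metadynamics on
the opening angle (the generator's wells sit at 60° and 110°, 2 kJ/mol
apart, behind a 4 kJ/mol barrier):

```python
import math
import numpy as np

from hingedyn import HingeParams, MetadParams, run_wtmetad
from hingedyn.metadynamics import averaged_fes
from hingedyn.fes import barrier_between, find_minimum

params = HingeParams(asymmetry=2.0, n_steps=200_000_000, stride=1000, seed=1)
series, bias = run_wtmetad(params, "theta", MetadParams())

edges = np.linspace(math.radians(20), math.radians(160), 401)
fes = averaged_fes(bias, edges, last_fraction=0.2)
wa = [(math.radians(45), math.radians(75))]
wb = [(math.radians(95), math.radians(125))]
(ta,), fa = find_minimum(fes, wa)
(tb,), fb = find_minimum(fes, wb)
print(f"{len(bias.hills)} hills deposited; final height {bias.hills[-1].height:.4f} kJ/mol")
print(f"wells at {math.degrees(ta):.1f} and {math.degrees(tb):.1f} deg")
print(f"well free-energy difference: {fb - fa:.2f} kJ/mol (generator truth 2.0)")
print(f"barrier above lower well: {barrier_between(fes, wa, wb):.2f} kJ/mol (truth 4.0)")
```

Output (≈40 s on one core):

```
2000000 hills deposited; final height 0.0002 kJ/mol
wells at 58.7 and 109.1 deg
well free-energy difference: 1.91 kJ/mol (generator truth 2.0)
barrier above lower well: 4.12 kJ/mol (truth 4.0)
```

The hill height has decayed by three orders of magnitude (the tempering
signature of convergence); the snapshot-averaged bias over the last 20%
of depositions reproduces the well free-energy difference and the barrier
to ~0.1 kJ/mol.

## Command line

A `hingedyn` console script wraps the library:

```sh
hingedyn generate --config config.yaml --outdir run/   # unbiased trajectory
hingedyn metad    --config config.yaml --outdir run/   # wt-metadynamics (+ --resume)
hingedyn descriptors --trajectory run/trajectory.pdb --outdir out/
hingedyn rmsd / rmsf / pca / fes ...
hingedyn report   --config config.yaml --outdir run/   # full demo pipeline
```

All parameters live in a YAML config (flags override); every command
writes a manifest (config, seed, version, checksums) so outputs are
byte-reproducible from config + seed.

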
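# writhekit

Writhe-based analysis of polymer and disordered-protein chain ensembles:
exact discrete writhe at multiple length scales, kinetic feature scoring
with time-lagged canonical correlation analysis (tCCA/VAMP-2), Markov
state model construction and validation, and a parity-aware equivariant
denoising-diffusion model for generating Cα-trace ensembles.

## The science in one paragraph

The writhe of a curve counts its signed self-crossings averaged over all
viewing directions.  For a backbone trace split into segments between
atoms i and i+l, each segment pair contributes the signed solid angle of a
spherical quadrilateral divided by 2π, giving a symmetric per-frame
*writhe matrix* Wr_l at every smoothing scale l.  Writhe is invariant
under rotations and translations but *changes sign under reflection* — a
parity-odd pseudoscalar.  Euclidean distances cannot tell a structure from
its mirror image; writhe can.  That one symmetry fact has two practical
consequences exploited here: (1) slow conformational transitions between
mirror-related states are invisible to distance features but fully visible
to writhe features, so writhe gives kinetic models (tCCA projections,
Markov state models) access to slow processes distance features miss; and
(2) an equivariant score network whose edge features include writhe (with
sine-only, parity-odd positional encodings and crossing-normal
pseudovectors) is SE(3)- rather than E(3)-equivariant, so a diffusion
model built on it can reproduce the chirality of its training ensemble
instead of generating mirror images at equal rates.

See `docs/methods.md` for the complete model and numerical documentation.

## Worked example

```python
import numpy as np
from writhekit.fixtures import FixtureSpec, two_state_polymer
from writhekit.features import multiscale_writhe_features, distance_features
from writhekit.kinetics import estimate_tcca

# a 10-bead polymer switching between mirror-image states
# (identical distances, opposite writhe), relaxation -1/ln(0.96) = 24.5 frames
spec = FixtureSpec(n_atoms=10, n_frames=20000, seed=1, k12=0.02, k21=0.02)
coords, labels, meta = two_state_polymer(spec)

wr = multiscale_writhe_features(coords, {1})   # 28 parity-odd features
di = distance_features(coords)                 # 45 parity-even features
for name, fm in [("writhe", wr), ("distance", di)]:
    model = estimate_tcca([fm], lag=5)
    print(f"{name:9s} sigma1 = {model.singular_values[0]:.3f}  "
          f"kinetic variance (k=1) = {model.kinetic_variance(1):.3f}")
```

Output:

```
writhe    sigma1 = 0.823  kinetic variance (k=1) = 0.677
distance  sigma1 = 0.096  kinetic variance (k=1) = 0.009
```

The writhe coordinate autocorrelates at σ₁ ≈ exp(−lag/τ) = exp(−5/24.5) =
0.815 — it tracks the hidden switch — while the distance coordinate sits
at the sample-correlation noise floor: the slow process is literally
invisible to parity-even features.  Discretizing the writhe projection and
estimating a Markov state model recovers the analytic relaxation time
within the bootstrap confidence interval (see
`writhekit.protocols.mirror_polymer_contrast`).

The same experiment from the shell:

```bash
writhekit fixtures --kind two-state --n-atoms 10 --n-frames 20000 --seed 1 --out fx.h5
writhekit tcca fx.h5 --features writhe --lag 5
writhekit msm scan fx.h5 --dims 1,2 --clusters 8,16 --lags 2,5,10,20 --out scan.tsv
```

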
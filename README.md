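# critdiv

Detect critical phase transitions in rate–distortion codebooks — and in any
β- or t-indexed family of conditional distributions — from the divergence
rate of consecutive codebooks.

Many complex systems change behavior abruptly as a control parameter
varies; in efficient-coding theories of sensory systems those tipping
points coincide with structural reorganizations of an optimal code. In
discrete rate–distortion (RD) theory this is exact: as the trade-off
parameter β (equivalently w = e^{−β}) varies, the optimal codebook
p_β(y|x) passes critical values β* where some output probability p_y
transitions between zero and positive, and the support of the code
reorganizes. `critdiv` measures those transitions directly from sampled
codebooks and ships the RD machinery needed to validate the measure
against closed-form theory.

The core quantity is the **divergence rate**

    M_t = (1/Δt) Σ_x q_x · D_KL( p_t(·|x) ‖ p_{t+Δt}(·|x) ),

which vanishes with Δt for smooth full-support families but diverges when
a state drops out of the code. After z-score normalization, its
significant local maxima — extracted by a momentum-based noisy peak
finder — mark the critical parameter values.

The package provides:

* `critdiv.rd` — Blahut–Arimoto fixed-point solver (p ← p ⊙ W(q ⊘ Wᵀp),
  W_ij = e^{−β d_ij}) for codebooks, output distributions and (D, R)
  curves, with warm-started continuation along β grids;
* `critdiv.exact` — closed forms used as oracles: the high-β solution
  p = W^{−T}(q ⊘ W^{−1}1), first critical points, the explicit two-state
  family, Berger's three-state family with w* = (1−u−√(1−6u+u²))/2, and a
  generalized Descartes rule of signs;
* `critdiv.divergence` — the divergence rate with a sentinel for
  support-loss steps, z-scored series, codebooks from deterministic maps;
* `critdiv.peaks` — the noisy local-maxima finder (Nesterov momentum
  ascent plus a significance filter);
* `critdiv.experiments` — reproducible studies: significant-peak counts
  on random RD problems versus the n−1 line, weak universality, the
  (u, β) criticality heatmap, an 18-state clustering demo, and a
  ternarized 2×2 image-patch coding pipeline with a synthetic 1/f-noise
  image generator;
* a `critdiv` command line for all of the above.

## Worked example

The two-state source q = (1/2, 1/2) with distortion d = [[0, 1], [2, 0]]
has a single critical point known in closed form: the second output leaves
the code at w* = (√5−1)/2, the golden-ratio conjugate, i.e.
β* = −ln w* ≈ 0.4812.

```python
import numpy as np, critdiv as cd
from critdiv.experiments import critical_scan

prob = cd.two_state_problem(2.0)
cp = cd.first_critical_beta(prob)
print(f"closed form: beta* = {cp.beta_star:.6f}, w* = {cp.w_star:.6f}, "
      f"vanishing output = {cp.vanishing_index}")

scan = critical_scan(prob, np.geomspace(0.05, 5.0, 400))
for b, h in zip(scan.beta_stars, scan.peaks.height):
    print(f"measured peak: beta = {b:.4f}  (normalized height {h:.1f})")
```

prints

```
closed form: beta* = 0.481212, w* = 0.618034, vanishing output = 1
measured peak: beta = 0.4774  (normalized height 19.9)
```

The closed form comes from the high-β solution (its second entry crosses
zero at β*); the measured peak is the pipeline estimate — solve the RD
curve on a 400-point grid, compute the divergence rate of consecutive
codebooks, z-score, find significant maxima — and lands within one grid
step of the theory, with a spike ~20 standard deviations above background.

The same pipeline from the shell:

```sh
critdiv first-critical --problem problem.json
critdiv rd-curve --problem problem.json --beta-min 0.05 --beta-max 5 --num 400 --out curve/
critdiv divergence --curve curve/ --out series.tsv
critdiv peaks --series series.tsv --out peaks.json
```

where `problem.json` is `{"q": [0.5, 0.5], "d": [[0, 1], [2, 0]]}`.
`critdiv conjecture1`, `critdiv heatmap`, `critdiv universality`,
`critdiv cluster-demo` and `critdiv patches --synthetic` run the larger
studies; every command writes a manifest with its seed and parameters.

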
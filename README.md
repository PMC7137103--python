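# xtalscale

Scaling and merging of unmerged X-ray diffraction intensities, for
crystallographers and data-reduction pipeline authors who need a scriptable,
testable post-integration scaling step — including multi-sweep and
multi-crystal workflows.

## The problem and the model

Integrated reflection intensities are the product of |F|² and experimental
effects — changes in illuminated volume and beam intensity, sample
absorption, global radiation damage.  Scaling determines a multiplicative
*inverse scale factor* g<sub>hl</sub> for the *l*-th observation of
symmetry-unique reflection *h* and corrects the data as
I<sub>hl</sub>/g<sub>hl</sub>, after which symmetry equivalents can be
merged.  The scales minimize the least-squares target

    Φ = Σ_hl w_hl (I_hl − g_hl ⟨I_h⟩)² + Σ_i c_i p_i²

with w<sub>hl</sub> = 1/σ′²<sub>hl</sub>, where the best estimate of the
true intensity, ⟨I<sub>h</sub>⟩ = Σ w g I / Σ w g², is eliminated
analytically at every function evaluation, and the second term restrains
the model parameters p<sub>i</sub>.

Three model parameterizations are provided, one per sweep:

* **physical** (default): g = C(r) · exp(B(t)/2d²) · S(−s₀, s₁) — a smooth
  scale C of rotation angle, a smooth relative B-factor decay, and an
  absorption surface expanded in real spherical harmonics (l ≤ 4) over the
  beam directions in the crystal frame.  For a 360° sweep: 26 + 20 + 24 =
  70 parameters.
* **KB**: a single scale k and isotropic B factor (2 parameters), for
  stills and very narrow sweeps.
* **array**: Gaussian-smoothed grids over rotation × resolution (decay,
  240 parameters at 360°) and detector x × y × rotation (absorption, 500
  parameters), making minimal assumptions about the functional form.

Around the core fit the full workflow performs: reflection-subset selection
(random, or quasi-random inter-sweep-connected for multi-sweep data),
iterative 6σ outlier rejection on symmetry groups, optimization of the
profile/summation intensity combination by R<sub>meas</sub>, two-parameter
error-model adjustment of the uncertainties σ′² = a²(σ² + (bI)²) (reported
with the asymptotic I/σ limit ISa = 1/(ab)), a final Levenberg–Marquardt
full-matrix cycle with uncertainty propagation, and a merging report
(R<sub>merge</sub>/R<sub>meas</sub>/R<sub>p.i.m.</sub>, σ–τ CC<sub>1/2</sub>,
completeness, multiplicity).  Multi-sweep data can be scaled concurrently,
incrementally (new sweeps pre-scaled against the current merged set), or
against an external reference; discordant subsets can be removed by
ΔCC<sub>1/2</sub> filtering, and free-set cross-validation quantifies
overfitting of the scaling model.

## Worked example

```python
import numpy as np
from xtalscale import GroundTruth, generate_sweeps, scale, ScalingRunConfig

truth = GroundTruth(sweep_width=90.0, multiplicity=5.0,
                    scale_amplitude=0.2, decay_B_final=3.0,
                    absorption_amplitude=0.05, absorption_lmax=2,
                    cell=(40.0, 45.0, 50.0, 90.0, 90.0, 90.0), d_min=2.2,
                    mean_I=1200.0)
table, sweeps, truth = generate_sweeps(truth, seed=1)
state = scale(table, sweeps, truth.space_group,
              ScalingRunConfig(selection="all"))

overall = state.report["merging"]["overall"]
print(f"observations: {overall['n_obs']}, unique: {overall['n_unique']}, "
      f"multiplicity: {overall['multiplicity']:.1f}")
print(f"Rmerge {overall['r_merge']:.4f}  Rmeas {overall['r_meas']:.4f}  "
      f"Rpim {overall['r_pim']:.4f}")
print(f"CC1/2 {overall['cc_half']:.4f}   <I/sig> {overall['i_over_sigma']:.1f}")
em = state.report["error_model"]
print(f"error model: a = {em['a']:.3f}, b = {em['b']:.4f}, ISa = {em['ISa']:.1f}")
```

prints

```
observations: 24622, unique: 4906, multiplicity: 5.0
Rmerge 0.0226  Rmeas 0.0253  Rpim 0.0109
CC1/2 0.9994   <I/sig> 54.5
error model: a = 0.996, b = 0.0015, ISa = 663.7
```

The simulated 90° sweep carries a ±20% smooth scale variation, a 3 Å²
relative-B drift and a mild absorption surface; after scaling, the
agreement between symmetry equivalents (R<sub>meas</sub> 2.5%) is at the
level set by counting noise, CC<sub>1/2</sub> ≈ 1 shows the merged signal
is essentially noise-free at this multiplicity, and the error model finds
a ≈ 1, b ≈ 0 — correctly reporting that the simulated uncertainties needed
no inflation.  The recovered per-observation inverse scales agree with the
generating truth to 0.26% RMS.

The same run from a shell:

```sh
xtalscale simulate --sweep-width 90 --multiplicity 5 --scale-amplitude 0.2 \
    --decay-b 3 --seed 1 --output example.tsv
xtalscale scale example.tsv --selection all --json-report report.json
```

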
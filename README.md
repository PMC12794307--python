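# axonradius

Effective MR axon radius mapping from strongly diffusion-weighted MRI, with
closed-form log-linear estimators built on rotationally invariant spherical
harmonic (RISH) features, a Monte Carlo diffusion simulator of axon/glia
substrates, and the test–retest statistics used to judge estimator
consistency.

## The problem

At high diffusion weighting (b ≥ 6 ms/µm²) the white-matter dMRI signal is
dominated by water confined in micrometre-thin cellular processes.  Under a
single-compartment model of restricted diffusion in a cylinder of radius r,
the *spherical mean* (zeroth-order RISH feature, S̄) of a shell decays as

    S̄(b) = β · S⊥(r | g, δ) / √b ,        β = f √(π / 4 Dc∥)

with the Neumann long-pulse perpendicular attenuation

    S⊥(r | g, δ) = exp(−κ r⁴),             κ = 7 γ² g² δ / (48 D₀).

Because log(√b · S̄) is linear in r⁴ with slope −κ, two high-b shells give a
closed-form estimator — no nonlinear fitting required:

    r⁴ = log( √b₁ S̄(b₁) / (√b₂ S̄(b₂)) ) / (κ₂ − κ₁).

The same logic applies to the second-order RISH feature (*spherical
variance*, S̄σ), whose forward model

    S̄σ(b) = p₂ · γ′ · (2 b Dc∥ − 3) · S⊥(r) / b^{3/2}

yields the two-shell inversion with cross-paired diffusivity factors

    r⁴ = [ log(b₁^{3/2} (2 b₂ Dc∥ − 3) S̄σ(b₁))
          − log(b₂^{3/2} (2 b₁ Dc∥ − 3) S̄σ(b₂)) ] / (κ₂ − κ₁).

A *valid* axon-radius estimate must not depend on the RISH order used.
Divergence between the SM- and SV-derived radii points at non-axonal
restricted compartments — spheres (cell bodies) or orientationally dispersed
thick processes of glia.  The package quantifies exactly that: it implements
both estimators, a spin-walker Monte Carlo simulator of sphere/cylinder/glia
substrates to generate ground-truth contaminated signals, and the
repeatability statistics (TRV, CoV, Lin's concordance) used to compare them.

## Worked example

```python
import numpy as np
from axonradius import (TissueParams, loglinear_radius_sm,
                        loglinear_radius_sv, rish_features, sm_forward,
                        sv_forward)
from axonradius.rish import RishFeatures
from axonradius.signal_models import gradient_for_bvalue

D0 = 2.5                      # axoplasm diffusivity, um^2/ms
g6 = gradient_for_bvalue(6.0, delta=15.0, Delta=30.0)    # 122 mT/m
g30 = gradient_for_bvalue(30.0, delta=15.0, Delta=30.0)  # 273 mT/m
tissue = TissueParams(f=0.6, Dpar=2.2, p2=0.7, D0=D0, r=3.0)

feats = [RishFeatures(b=g.bvalue, sm=sm_forward(g, tissue),
         sv=sv_forward(g, tissue)) for g in (g6, g30)]
est_sm = loglinear_radius_sm(feats[0], feats[1], (g6, g30), D0)
est_sv = loglinear_radius_sv(feats[0], feats[1], (g6, g30), D0, Dpar=2.2)
print(f"r_SM = {est_sm.r_sm:.6f} um, r_SV = {est_sv.r_sv:.6f} um")
```

prints

```
r_SM = 3.000000 um, r_SV = 3.000000 um
```

— the two-shell inversions are the exact algebraic inverses of the forward
models, so a noiseless dispersed-cylinder voxel round-trips to machine
precision.  On data contaminated by an isotropic glia compartment the two
numbers separate; `axonradius.mcsim.glia_mixture_experiment` reproduces
those bias curves from Monte Carlo substrates.

There is also a command-line interface:

```bash
axonradius synth    --out phantom --snr 50 --seed 1
axonradius rish     --dwi phantom_dwi.nii.gz --bval phantom.bval \
                    --bvec phantom.bvec --sigma 0.02 --out phantom
axonradius estimate --dwi phantom_dwi.nii.gz --bval phantom.bval \
                    --bvec phantom.bvec --sigma 0.02 --dpar 2.5 \
                    --shells 6,30 --out phantom
axonradius simulate --axon-r 3 --glia sphere --fractions 0,0.1,0.2,0.3 \
                    --walkers 2000 --out bias.tsv
axonradius stats    --input profile.tsv --out report
```

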
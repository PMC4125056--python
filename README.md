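# micellekin

Kinetics of prion amyloid formation with a micellar on-pathway
intermediate.

In vitro, recombinant prion protein (rPrP) polymerizes into amyloid
fibrils after a lag phase — but the lag depends only weakly on the
monomer concentration, persists under heavy seeding, and shortens less
than expected when seeding is postponed.  None of this fits the
classical nucleation-dependent picture, in which the lag reflects a
nucleation barrier that seeding should abolish.  `micellekin` implements
a size-structured kinetic model in which spherical micelle-like clusters
of the native protein (PrP^C) act as an *on-pathway* intermediate: they
assimilate PrP^C, stabilize it in an amyloid-competent isoform (PrP\*),
and release it; free PrP\* then nucleates and polymerizes irreversibly
into fibrils (PrP^Sc) that multiply by binary fragmentation.  Because
polymer growth is fed by micelle-mediated conversion rather than by a
nucleation barrier, the model reproduces the seeding plateau, the
shortened postponed-seeding delay and the nucleus-size-independent
concentration scaling.

## Model

State variables: PrP^C monomer `c`, micelles `m_i` (`i = 2..I_max`),
PrP\* monomer `v`, oligomers/polymers `u_j` (`j = 2..N_max`).  The
reaction network is

* micelle ladder:  `c + m_i <-> m_{i+1}` at rates `a` (association) and
  `b^C_{i+1} = q_C (i+1)^{-1/3}` (PrP^C release); the same ladder
  exchanges PrP\*: `v + m_i <-> m_{i+1}` with release
  `b^S_{i+1} = q_S (1 - (i+1)^{-1/3})`, so small micelles return mostly
  PrP^C and large micelles release the converted isoform;
* nucleation:  `v + u_j <-> u_{j+1}` at rates `tau` and `d_off` for
  `j < n`; above the nucleus size `n` growth is irreversible
  (`d_off = 0`);
* fragmentation: `u_j -> u_k + u_{j-k}` at rate `beta·j` with the
  uniform kernel `kappa(k, j) = 1/(j-1)`; size-1 fragments return to
  the PrP\* pool.

The closed system conserves the total monomer mass
`c + Σ i·m_i + v + Σ j·u_j` exactly; the truncated ladders use no-flux
boundaries so conservation survives truncation.  A comparator without
micelles (`baseline`), in which PrP^C nucleates and elongates directly,
runs on the same kinetic engine.

Observables follow standard ThT-trace analysis: the half-time t½ (first
crossing of half the final polymerized mass), the maximal slope k_max at
the inflexion, the lag time `t½ − plateau/(2·k_max)`, and the apparent
nucleus size `n_app = 2·|d log t½ / d log c0|`.

## Worked example

```python
import numpy as np
from micellekin import *

params = ModelParameters()          # default rates, I_max=3000, N_max=5000
setup = SimulationSetup(c0=1.0)     # 1 mg/ml, unseeded, 100 h
traj = simulate(setup, params)

trace = KineticTrace(times=traj.times, signal=traj.polymer_mass)
t_half, plateau = half_time(trace, return_plateau=True)
k_max, t_inflexion = max_slope(trace)
print(t_half, lag_time(t_half, k_max, plateau), traj.mass_residual)
```

prints (formatted):

```
half-time t1/2          :  8.85 h
lag time                :  2.75 h
maximal slope k_max     : 0.076 (mg/ml)/h at t = 3.81 h
micelle-mass peak       :  3.01 h (before t1/2)
final polymerized mass  : 0.931 mg/ml of c0 = 1.0 mg/ml
mass-conservation drift : 8.9e-16 (relative)
```

The micelle mass rises and peaks hours before the polymer half-time,
then decays as its content is converted and drained into fibrils — the
precursor relationship seen when micelle counts and ThT fluorescence
are monitored side by side.  The residual ~0.07 mg/ml stays as free
monomer below the effective critical micelle concentration.

The same study from the shell:

```sh
micellekin simulate -o run.tsv --manifest run.json
micellekin scan-c0 --values 1,1.8,3.2,5.6,10 -o scan.tsv
micellekin scan-seed --model baseline --values 0.001,0.01,0.1 -o seeds.tsv
micellekin synth --kind traces --seed 7 -o traces.tsv
micellekin analyze traces.tsv
```

Higher-level experiment designs (concentration scans across nucleus
sizes, seed scans, postponed seeding, parameter recovery) live in
`micellekin.experiments`.

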
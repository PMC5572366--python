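# memhnn

Nonlinear dynamics of a **hyperbolic-type memristor** and of the
**memristive 3-neuron Hopfield neural network (HNN)** built on it:
pinched-hysteresis fingerprints, equilibrium stability, Wolf-method
Lyapunov spectra, bifurcation scans, and the classification of
coexisting asymmetric attractors.

The package is for researchers in nonlinear circuits and computational
neuroscience who want a desk-scale, fully scripted reproduction of the
multistability phenomenology of memristive neural networks — and a
reusable toolchain (equilibrium solver, tangent-space Lyapunov spectra,
attractor classifier) for 4-D autonomous flows of this family.

## The model

The memristor emulator is voltage-controlled with memductance

    i = W(v0) · v,   W(v0) = a − b·tanh(v0),   τ·dv0/dt = −(v0 + v)

so W stays inside (a − b, a + b).  In the circuit realization
a = R/Ra, b = gR/Rb, τ = RC (reference design: R = 10 kΩ, C = 100 nF,
Ra = 10 kΩ, Rb = 2 kΩ, g = 0.1 → a = 1, b = 0.5, τ = 1 ms).

Replacing the synapse from neuron 1 into neuron 3 of a 3-neuron Hopfield
network with this memristor (coupling strength k) gives the 4-D
autonomous flow

    ẋ1 = −x1 − 1.4 tanh x1 + 1.2 tanh x2 − 7 tanh x3
    ẋ2 = −x2 + 1.1 tanh x1 + 2.8 tanh x3
    ẋ3 = −x3 + k·(a − b·tanh x4)·tanh x1 − 2 tanh x2 + 4 tanh x3
    ẋ4 = −x4 + tanh x1

which is dissipative, bounded, and equivariant under
(x, b) → (−x, −b).  Raising the memristor's modulation depth b
stabilizes the initially chaotic network (chaos → limit cycles → stable
point), and along the way distinct attractors — chaotic spirals,
double scrolls, period-n cycles, point attractors — coexist at the same
parameters, selected by the initial condition.

## Worked example

```python
import numpy as np
from memhnn import HNNParams, find_equilibria, wolf_spectrum, coexistence_table

p = HNNParams(k=0.8, a=1.0, b=0.26)
for eq in find_equilibria(p):
    print(np.round(eq.coords, 4), eq.label)
```

prints the origin plus the two asymmetric nonzero equilibria:

```
[0. 0. 0. 0.] unstable saddle point
[ 2.1647 -0.5965 -0.6864  0.974 ] unstable saddle-focus
[-1.4751  0.1972  0.4529 -0.9006] unstable saddle-focus
```

The Wolf-method spectrum of the chaotic spiral at k = 0.95, b = 0.14
(step 0.1, horizon 10 000, 1 000-unit transient):

```python
spec = wolf_spectrum([0, 0.1, 0, 0], HNNParams(k=0.95, a=1.0, b=0.14))
print(np.round(spec.exponents, 4))   # [ 0.0321 -0.0002 -0.4097 -0.9715]
```

A positive leading exponent with a (numerically) zero second exponent
signals chaos; the sum of the four exponents equals the time-averaged
divergence of the flow.  Coexistence at the same parameters:

```python
rows = coexistence_table(HNNParams(k=0.95, a=1.0, b=0.0), [0.14])
print([str(r["label"]) for r in rows])
# ['right-chaotic-spiral', 'left-period-1', 'right-period-2']
```

three different attractors from the three reference initial conditions
(0, ±0.1, 0, 0) and (1, 0, 0, 0).

The same analyses are available from the command line:

```bash
memhnn equilibria --k 0.8 --a 1 --b 0.26 --out eq.json
memhnn lyapunov --k 0.95 --b 0.14 --x0 0 0.1 0 0 --out spec.json
memhnn coexistence --preset paper-case2 --b-list 0.14 --out table.csv
memhnn memristor-loop --vm 4 --freq 400 --out loop.csv
```

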
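# threadkin

Analysis of two-step ("threading") DNA bis-intercalation kinetics from
constant-force single-molecule stretching experiments.

## The problem

A bis-intercalating ligand with two linked aromatic (dppz) moieties binds
double-stranded DNA in two sequential steps: fast bimolecular intercalation
of the first moiety, followed by a roughly ten-fold slower conversion to the
bis-intercalated state, rate-limited by the flexible linker passing through
the duplex:

    L + DNA  ⇌[k₁C / k₋₁]  mono  ⇌[k₂ / k₋₂]  bis

Each intercalation event lengthens the DNA, so an optical-tweezers
experiment that holds a single molecule at constant force F while ligand
binds sees the extension relax as a double exponential,

    dx(t) = dx_eq − dx_f·e^(−k_f t) − dx_s·e^(−k_s t).

When the first step is in pre-equilibrium with the second
(k₁C + k₋₁ ≫ k₂ + k₋₂), the observable rates reduce to
k_f = k₁C + k₋₁ and k_s = k₂·k₁C/(k₁C + k₋₁) + k₋₂; exactly, they are the
eigenvalues of the 2×2 relaxation matrix. Force tilts each elementary rate
Bell-fashion, k(F) = k⁰·exp(F·x†/k_BT), where the signed distance x† is the
complex elongation from the departing state to the transition state.
Polymer elasticity enters through the extensible worm-like chain,
x(F) = x_max·(1 − 1/(2√(FA/k_BT)) + F/S), which converts extension into
fractional occupancy between the bare and ligand-saturated curves.

From traces at several forces and ligand concentrations the package
estimates the four elementary rates, their zero-force values and transition
distances, the step and overall dissociation constants (K_d1, K₂,
K_d = K_d1/K₂) by two independent routes (rates vs equilibrium amplitudes),
and reconstructs the zero-force free-energy landscape of the
non-intercalated → mono → bis pathway versus complex elongation.

It is written for single-molecule biophysicists analysing constant-force
relaxation data, and ships a synthetic-trace generator (mean-field and
Gillespie backends) so the entire pipeline is testable by parameter
recovery without instrument data.

## Worked example

Simulate the default experiment grid (20/30/50 pN × 1/3/5/7 nM, 600 s at
1 Hz, 0.002 nm/bp noise) and analyse it:

```
threadkin simulate --seed 1 --out run/
threadkin analyze run/ --out run-analysis/
```

or drive the same steps as a narrative, via the numbered scripts:

```
python analysis/01_simulate_experiment.py --seed 1
python analysis/02_fit_wlc_saturation.py
python analysis/03_fit_traces.py
python analysis/04_decompose_rates.py
python analysis/05_force_dependence.py
python analysis/06_equilibrium_route.py
python analysis/07_energy_landscape.py
```

`05_force_dependence.py` prints the recovered zero-force parameters next
to the generating truth, e.g. (seed 1):

```
rate     k0 (refined)   k0 (truth)  x (refined)  x (truth)
k1           0.001493       0.0018        0.205       0.19
k_m1          0.05748        0.068       -0.044      -0.06
k2           0.005696       0.0058        0.083       0.08
k_m2         0.004234       0.0036       -0.177      -0.15
```

— a single noisy replicate recovers the rates to within tens of percent and
the transition distances to a few hundredths of a nm; medians over many
replicates converge onto the truth. `07_energy_landscape.py` prints the
five-state free-energy profile; at C = K_d = 15 nM the non- and
bis-intercalated minima are both at 0 k_BT, the first barrier is 3.6 k_BT
above the non-intercalated state and the second forward barrier 5.1 k_BT
above the mono state (attempt rate 1 s⁻¹):

```
C = 15 nM (attempt rate 1 s^-1):
  non   elongation  0.00 nm  energy   0.00 kBT
  TS1   elongation  0.19 nm  energy   3.61 kBT
  mono  elongation  0.25 nm  energy   0.85 kBT
  TS2   elongation  0.33 nm  energy   6.00 kBT
  bis   elongation  0.48 nm  energy   0.00 kBT
```

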
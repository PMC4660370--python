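# allokin

Quantitative analysis of allosteric enzyme inhibition for IMPDH-like
systems: global mixed-type inhibition kinetics, single-site titration
calorimetry, and small-angle X-ray scattering (SAXS) hydrodynamics with
tetramer/octamer classification.

## The scientific problem

IMP dehydrogenase (IMPDH) is the rate-limiting enzyme of guanine-nucleotide
biosynthesis. In eukaryotic IMPDHs, GTP and GDP bind the regulatory Bateman
domain and drive two tetramers to associate tail-to-tail into an octamer
with strongly reduced activity, while GMP acts as a classical competitive
inhibitor at the active site. Demonstrating this requires three independent
quantitative chains, which this package implements as a tested library
(`src/allokin/`) with narrative drivers (`analysis/`):

1. **Enzyme kinetics** (`allokin.kinetics`). Velocities over an
   (substrate, inhibitor) grid are fitted globally to three candidate rate
   laws — Michaelis–Menten

   v = Vmax·S/(Km + S),

   competitive inhibition

   v = Vmax·S/(Km·(1 + I/Ki) + S),

   and the hyperbolic (partial) mixed model

   v = Vmax·(1 + β·I/(α·Ki))·S / (Km·(1 + I/Ki) + S·(1 + I/(α·Ki))),

   where α is the substrate–inhibitor heterotropic coupling (α → ∞ recovers
   pure competition) and β the fractional activity of the ternary
   enzyme–substrate–inhibitor complex (β = 0: dead complex). The mechanism
   is selected by corrected Akaike criterion (AICc) with a ΔAICc < 2
   indifference rule favouring the simpler law; Hanes–Woolf plots
   ([S]/v vs [S]) provide the classical visual diagnostic — parallel lines
   mean competition.

2. **Isothermal titration calorimetry** (`allokin.itc`). Integrated
   injection heats are fitted to the single-site isotherm (quadratic
   mass-balance root, overfilled-cell displacement bookkeeping and
   perfusion correction), and the affinity is decomposed as
   ΔG = RT·ln Kd, −TΔS = ΔG − ΔH.

3. **SAXS** (`allokin.saxs`). Concentration series are normalized and
   extrapolated to infinite dilution; Rg comes from an automatic-window
   Guinier fit (qRg ≤ 1.3, runs-test residual check); p(r) and Dmax from a
   regularized indirect Fourier transform; the Porod invariant
   Q = ∫q²I dq gives the particle volume Vp = 2π²I(0)/Q and a mass
   estimate (0.6 Da·Å⁻³), from which the tetramer/octamer call follows.
   Theoretical curves for coarse bead models come from the Debye equation
   with histogram acceleration.

`allokin.synth` generates seeded synthetic datasets at the experimental
designs (IMP 19.5–5000 μM at fixed 0.5 mM NAD⁺; 20 μM protein titrated
with 300 μM IMP at 25 °C; curves to q ≈ 0.35 Å⁻¹ from bead models
calibrated to the measured tetramer/octamer hydrodynamics), so every
stage is testable without downloads. `allokin.pipeline` and the `allokin`
CLI orchestrate synthesize → analyze → report runs.

## Worked example

```bash
python analysis/01_kinetics_inhibition.py --seed 1
```

prints

```
GMP: competitive  Km= 50.8 uM  Ki=0.592 mM
GDP: mixed        Km= 51.2 uM  Ki=0.210 mM  alpha=6.40 beta=0.033
GTP: mixed        Km= 51.2 uM  Ki=0.161 mM  alpha=4.06 beta=0.237
```

GMP is recovered as a purely competitive inhibitor (Ki ≈ 0.6 mM), while
GDP and GTP are mixed-type with ~3-fold tighter Ki, strong heterotropic
coupling (α ≈ 6.4 and 4.1: inhibitor binding weakens apparent substrate
affinity) and nearly inactive ternary complexes (β ≈ 0.03 and 0.24) — the
kinetic fingerprint of allosteric inhibition. Similarly,

```bash
python analysis/02_itc_thermodynamics.py --seed 1
python analysis/03_saxs_oligomers.py --seed 1
```

show the entropic penalty that accompanies nucleotide binding
(−TΔS rising from ≈18 to ≈25–49 kcal/mol as Kd weakens from 1.7 to
26–63 μM) and the doubling of the Porod volume (≈2.5·10⁵ → ≈5.1·10⁵ ų,
mass ratio ≈ 2 at nearly unchanged Dmax) that identifies the octamer.
Tables are written under `results/`.

The same analyses run from YAML configs through the CLI:

```bash
allokin synth kinetics --seed 3 --out /tmp/demo
allokin kinetics fit --input /tmp/demo/kinetics.csv --out /tmp/demo/fit.json
```

## Layout

```
src/allokin/        library: kinetics, itc, saxs, synth, io, pipeline, cli
analysis/           numbered narrative drivers writing results/ tables
tests/              pytest suite (unit, property and acceptance tests)
scripts/acceptance.py
docs/methods.md     models, assumptions, numerical choices, limitations
```
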
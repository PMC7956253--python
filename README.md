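# phagopbpk

Whole-body physiologically based pharmacokinetic (PBPK) modelling of
polymeric nanoparticle biodistribution in tumour-bearing mice, with
phagocytic-cell uptake kinetics.

Long-circulating mPEG-PCL nanoparticles injected intravenously are cleared
from blood mostly by the mononuclear phagocyte system — Kupffer cells in
the liver, red-pulp macrophages in the spleen, alveolar macrophages in the
lung — while only a small fraction reaches the tumour. This package models
that competition quantitatively, for researchers studying nanoparticle
disposition or designing formulations that shift it.

## The model

The mouse is nine compartments — venous and arterial blood plus seven
perfused organs (lung in series; liver, spleen, kidney, tumour, heart and
rest-of-body in parallel). Each organ holds capillary blood, interstitial
tissue and a phagocytic-cell (PC) pool:

```
V_V dCV/dt = Q (CA − CV) − PA·CV + PA·C_T/P − k_up(t)·CV·V_V + K_out·A_PC
V_T dC_T/dt = PA·CV − PA·C_T/P
dA_PC/dt    = k_up(t)·CV·V_V − K_out·A_PC
```

with a Hill-of-time phagocytic uptake rate constant
`k_up(T) = K_max·T^n / (K_50^n + T^n)`, first-order release `K_out`, and
biliary/urinary clearance from liver/kidney. An alternative tumour variant
replaces the PC pool with an EPR (enhanced permeability and retention)
space exchanging by first-order rate constants K1/K2. Kinetic parameter
sets for five formulations (80/200 nm, 9.09/28.57% mPEG-PCL, mPEG 2k/5k)
ship as packaged fixtures; the mouse physiology is an editable YAML config.

Because uptake depends on time rather than state, the system is linear in
amounts: concentrations scale exactly with dose, which the test suite
asserts and the sensitivity machinery exploits (RSC of dose ≡ 1).

See `docs/methods.md` for assumptions, numerics, and limitations.

## Worked example

```python
import phagopbpk as pk

phys = pk.load_physiology()                      # packaged 20 g mouse
params = pk.load_formulation("mPEG5k-9.09%-80 nm")
res = pk.simulate(pk.ModelSpec(variant="PCs"), params, phys, dose_mg=2.0)

for comp in ("blood", "liver", "spleen", "tumour"):
    print(f"{comp:8s} {pk.predict_at(res, 1.0, comp)[0]:.4f} mg/mL at 1 h")

a = pk.load_formulation("mPEG5k-9.09%-200 nm")
print("lung K_max ratio 200/80 nm:", pk.kmax_ratio(a, params, "lung"))
print("liver K_max RSC:",
      round(pk.rsc(pk.ModelSpec(), params, phys, 2.0, "liver.K_max", "liver"), 3))
```

prints

```
blood    0.1596 mg/mL at 1 h
liver    0.7850 mg/mL at 1 h
spleen   0.7143 mg/mL at 1 h
tumour   0.1218 mg/mL at 1 h
lung K_max ratio 200/80 nm: 9.62
liver K_max RSC: 0.843
```

One hour after a 2 mg bolus the liver and spleen already hold the highest
concentrations — their phagocytic uptake capacities (K_max 132 and 65 /h)
dwarf those of heart or kidney — and the tumour sees less than a fifth of
the liver level. The 200 nm sister formulation has 9.62× the lung uptake
capacity of the 80 nm one, and liver exposure responds strongly to K_max
(RSC 0.84, "highly sensitive" at the |RSC| > 0.5 threshold).

A command-line interface wraps the same operations:

```
phagopbpk simulate --formulation "mPEG5k-9.09%-80 nm" --out runs/sim
phagopbpk synth    --formulation "mPEG5k-9.09%-80 nm" --seed 1 --out runs/data
phagopbpk fit      --dataset runs/data/observed.csv \
                   --formulation "mPEG5k-9.09%-80 nm" --out runs/fit
phagopbpk sensitivity --formulation "mPEG5k-9.09%-80 nm" --out runs/sens
phagopbpk compare  --dataset runs/data/observed.csv \
                   --formulation "mPEG5k-9.09%-80 nm" --out runs/cmp
```

Every command writes a manifest sufficient to regenerate its artifacts.

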
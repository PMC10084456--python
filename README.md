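# ctocd

Origin-independent magnetically induced current densities (CTOCD-GRRO and
CTOCD-GPRO) and Biot–Savart nuclear magnetic shieldings, with a two-point
calibration scheme that makes small-basis shielding calculations match
accurate reference values — the route to cheap ¹H/¹³C/¹⁵N/¹⁷O shielding
predictions for biomolecules such as amino acids and peptides.

## The problem and the method

The first-order current density induced in a molecule by a uniform magnetic
field **B** splits into paramagnetic and diamagnetic parts that individually
depend on the vector-potential origin **r**₀; in a finite basis even their
sum does. The CTOCD family removes this defect by distributing the origin
continuously with a shift function **d**(**r**). Writing

    d(r) = r − f(ρ) ∇ln ρ,

any differentiable f of the electron density gives a *divergenceless*
diamagnetic component. Two one-parameter choices are implemented:

* **GRRO**: f = α (a constant, atomic units),
* **GPRO**: f = β ρ^(−2/3) (β dimensionless; the exponent is fixed by
  requiring f ∇ln ρ to carry the dimension of a length). With
  β = −1/(6(3π²)^{2/3}) = −0.0174 the diamagnetic term coincides with the
  Thomas–Fermi current of Harris and Cina.

At α = β = 0 both schemes reduce to the ipsocentric CTOCD-DZ1 current
(**d**(**r**) = **r**, diamagnetic part identically zero). The extra GRRO/GPRO
terms are *exactly linear* in α or β, so every derived magnetic property —
in particular the isotropic shielding σ_Av^N obtained from the Biot–Savart
law

    σ_γλ^N = −(1/c) ε_γδν ∫ 𝒥_δλ(r) (R_N − r)_ν / |R_N − r|³ d³r,
    σ_Av = tr σ / 3,

is a straight line in the parameter. Two probe calculations therefore fix,
per nucleus, the parameter that reproduces *any* accurate reference
shielding; pooled means of those parameters (per element, or per
chemical-environment type inferred from the bond graph) turn a small-basis
calculation into a calibrated predictor, with expected error |slope| × std.

Integration uses a modified Becke multicenter partition: the smooth atomic
weights w_A sum to one everywhere, the molecular integral decomposes exactly
into single-center integrals I_A, and each I_A can carry its *own atom's*
parameter — all nuclei of a molecule are integrated in a single grid pass.

The electronic-structure backend is a self-contained restricted
Hartree–Fock + coupled-perturbed response engine over Gaussian basis sets
(STO-3G data built in, plus a matched s/p even-tempered set for atoms), so
the whole pipeline runs with no external quantum-chemistry dependency.

## Worked example

```python
from ctocd import (build_response_state, integrate_shielding_all_nuclei,
                   make_fixture, perceive_bonds)

mol = perceive_bonds(make_fixture("H2O"))
state = build_response_state(mol, "sto-3g")          # RHF + CPHF response
res = integrate_shielding_all_nuclei(state, {"O": -0.005, "H": -0.32}, "GRRO")
for r in res.to_records():
    print(f"{r['nucleus']}  {r['element']}  alpha={r['parameter']:+.3f}"
          f"  sigma_av={r['sigma_av']:9.3f} ppm")
```

prints

```
0  O  alpha=-0.005  sigma_av=    3.951 ppm
1  H  alpha=-0.320  sigma_av=   24.920 ppm
2  H  alpha=-0.320  sigma_av=   24.920 ppm
```

one isotropic shielding per nucleus from a single integration pass, the
oxygen cell using α = −0.005 and the hydrogen cells α = −0.32 (a per-atom
parameter table; element symbols, environment tags like `H[O][H]`, or
explicit atom indices are all accepted as keys). The same computation is
available from the shell:

```bash
ctocd compute --fixture H2O --scheme GRRO --param -0.005 --out water.json
ctocd calibrate --fixture H2O --references refs.json --out table.json
ctocd envtype --fixture glycine
```

`calibrate` fits α (or β) per nucleus from two probe integrations against
reference shieldings and aggregates element- or environment-level tables
with dispersion statistics; `envtype` prints the chemical-environment key of
every atom.

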
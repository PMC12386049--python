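# phenolflux

Extraction-kinetics modelling, neuro-fuzzy yield prediction and
compositional analytics for ultrasound-assisted enzymatic recovery of
polyphenols from plant-residue particles (the motivating system is Tartary
buckwheat hull powder, a phenolic-rich milling by-product).

The package is aimed at food-process and extraction-kinetics researchers who
want the full computational side of such a study as tested, reusable code:

1. **Mass transfer** (`phenolflux.diffusion`) — phenolics diffuse out of
   spherical particles (radius *r*) into a finite, well-mixed solvent bath.
   The solid-phase concentration *C*ₛ(*x*, *t*) obeys Fick's second law in
   spherical coordinates,

   ∂*C*ₛ/∂*t* = *D*ₑ (1/*x*²) ∂/∂*x* (*x*² ∂*C*ₛ/∂*x*),

   with symmetry at the centre, interface partition equilibrium
   *C*ₛ(*r*, *t*) = *K·C*L(*t*), and the bath balance
   −*D*ₑ*S* ∂*C*ₛ/∂*x*|₍ₓ₌ᵣ₎ = *V*L d*C*L/d*t*. The solver is a
   mass-conservative finite-volume method of lines on the dimensionless
   system (τ = *D*ₑ*t*/*r*², α = *V*L/(*K·V*ₛ)); a closed-form eigenfunction
   series for the same problem serves as an independent oracle.
2. **Diffusivity estimation** (`phenolflux.fitting`) — per experimental
   condition, *D*ₑ is the single free parameter, found by bounded scalar
   minimisation of the RMSE between simulated and observed yield curves,
   reported with R² and the absolute average deviation (AAD%).
3. **Yield prediction** (`phenolflux.anfis`) — a from-scratch five-layer
   Takagi–Sugeno ANFIS (grid partitioning, difference-of-sigmoid membership
   functions, hybrid least-squares + gradient learning) maps temperature,
   sonication time and enzyme concentration to total phenolic yield.
4. **Composition** (`phenolflux.composition`) — ingestion of the packaged
   17-compound × 6-condition quantification table, category counts and mass
   shares, and autoscaled PCA of replicate-expanded samples.

A synthetic-data module reproduces the statistical structure of the 48-run
experimental design so every stage is testable without any download, and a
one-config pipeline (`phenolflux.pipeline`, CLI `phenolflux`) orchestrates
the whole analysis with full seed provenance.

## Worked example

`examples/04_composition_pca.py` profiles the packaged compound table and
runs the PCA:

```
$ python examples/04_composition_pca.py
17 compounds in 6 conditions

compounds per category:
  dihydrochalcone  2
  flavanol         3
  flavonol         3
  phenolic acid    9

catechin peaks at 855.66 µg/g under 50C-1% (50 °C with 1% cellulase)
...
PCA on the 18×17 replicate matrix:
  PC1 explains 64.0% of variance, PC2 16.5% (cumulative 80.5%)
  top PC1 loadings: Epicatechin, Procyanidin B2, Phloretic acid
```

Reading: 9 of the 17 quantified phenolics are phenolic acids, but flavanols
carry the largest mass share under every condition. Catechin's ~20-fold
increase with 1% cellulase at 50 °C is the signature of a cell-wall-bound
compound released by enzymatic pretreatment. The first principal component
(~64–66% of variance depending on the replicate-simulation seed) separates
the 40 °C from the 50 °C extracts, i.e. temperature dominates compositional
change; its top loadings are epicatechin, procyanidin B2 and phloretic acid.

The other examples cover the diffusion solver (01), *D*ₑ fitting against
known ground truth (02), ANFIS training with a held-out R² around 0.98
(03), and the end-to-end pipeline bundle (05).

## Layout

```
src/phenolflux/      diffusion, fitting, anfis, composition, synthetic,
                     pipeline, plotting, cli; packaged data fixture
examples/            one narrative script per capability
tests/               pytest suite (unit, property and acceptance tests)
docs/methods.md      model assumptions, numerical choices, limitations
```
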
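"""Estimate effective diffusion coefficients from kinetic data.

Generates the 48-run synthetic ultrasound dataset (2 temperatures × 3
cellulase levels × 8 sampling times, known ground truth), fits De per
condition by RMSE minimisation and compares fitted vs true rates.
"""

from phenolflux import GeneratorConfig, default_truth, fit_all_conditions, simulate_kinetics

config = GeneratorConfig(seed=42, noise_sd=0.05)
dataset, truth_record = simulate_kinetics(config)
truth = default_truth(config)
content = {k: v["extractable_mg_per_g"] for k, v in truth.items()}

fits = fit_all_conditions(dataset, total_content_mg_per_g=content)

print("T (°C)  enzyme (%)  De fitted (m²/s)  De true (m²/s)  R²      AAD (%)")
for _, row in fits.iterrows():
    v = truth[(row.temperature_C, row.enzyme_pct, row.method)]
    print(f"{row.temperature_C:5.0f}  {row.enzyme_pct:9.1f}  "
          f"{row.De_m2_per_s:15.3e}  {v['De_m2_per_s']:13.3e}  "
          f"{row.r_squared:.4f}  {row.aad_pct:6.2f}")

print("\nDe rises with enzyme dose at fixed temperature and falls from 40 to")
print("50 °C — the orderings the estimator must recover. R² close to 1 and")
print("AAD of a few percent indicate the Fick model describes the curves well.")
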
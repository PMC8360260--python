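"""Saturation radioligand binding: fit Kd and Bmax from a simulated assay.

Simulates a radiolabeled-antibody-fragment saturation assay on EGFR-rich
cells (2-fold dilutions, 0.098-200 nmol/L, duplicates, 5% noise), then
fits the one-site model to the NSB-subtracted specific binding.
"""

from ricdosim import fit_one_site, simulate_binding_assay

obs = simulate_binding_assay(
    kd_nM=2.9, bmax_pmol=1.83, ns_slope=0.002, noise_cv=0.05, seed=42
)
fit = fit_one_site(obs)

print(f"Kd   = {fit.kd_nM:.2f} ± {fit.kd_se:.2f} nmol/L")
print(f"Bmax = {fit.bmax_pmol:.2f} ± {fit.bmax_se:.2f} pmol per 1e6 cells")
print(f"     = {fit.receptors_per_cell:.2e} receptors per cell")
print(f"NSB slope = {fit.ns_slope:.4f} pmol per nmol/L")
# Kd is the free concentration at half-maximal specific binding (binding
# affinity); Bmax the receptor capacity, converted to sites/cell via
# Avogadro's number.
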
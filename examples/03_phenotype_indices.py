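"""Salt-tolerance phenotype indices on simulated hydroponic data.

Generates replicate phenotypes for two parents and two introgression lines
with different latent tolerance, then computes the relative trait
percentages normalised to the sensitive check, electrolyte leakage, SES
distributions and tissue Na+/K+ ratios.
"""

from saltil import phenotype as ph
from saltil import synth

tolerances = {"FL478": 0.9, "IL22": 0.7, "IL13": 0.6, "OLESA": 0.1}
pheno, ions = synth.gen_phenotypes(tolerances, rng_seed=1, n_replicates=12)

print("Relative traits (fold vs OLESA check):")
table = ph.tolerance_index_table(pheno, "OLESA")
print(table.pivot(index="line_id", columns="trait",
                  values="fold_vs_check").round(2).to_string())

print("\nElectrolyte leakage under salt (mean +/- SEM):")
print(ph.el_summary(pheno).round(1).to_string(index=False))

print("\nShoot Na+/K+ molar ratio:")
nak = ph.na_k_summary(ions)
print(nak[nak["tissue"] == "shoot"].round(2).to_string(index=False))

il22 = pheno[(pheno["line_id"] == "IL22") & (pheno["condition"] == "salt")]
olesa = pheno[(pheno["line_id"] == "OLESA") & (pheno["condition"] == "salt")]
test = ph.compare_lines(il22["FW"], olesa["FW"])
print(f"\nIL22 vs OLESA fresh weight under salt: "
      f"t = {test.statistic:.2f}, P = {test.pvalue:.2g} {test.stars}")

# Tolerant lines keep fold-vs-check above 1 (they retain more growth under
# salt than the sensitive check), leak fewer electrolytes and hold a lower
# shoot Na+/K+ ratio; the t-test compares replicate trait means per line.
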
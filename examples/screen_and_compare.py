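"""Screen the three sub-ensembles and test for conformational selection.

Uses the synthetic binding-energy generator (1250 complexes per sub-ensemble,
extended-trans shifted for a 3-fold best-K_D separation), takes the top five
complexes per class by energy, and compares dissociation constants between
classes with Welch's t-test on log10 K_D.
"""

from vcss import (EnergyTableParams, SubEnsembleLabel, boxplot_summary,
                  compare_subensembles, gen_energy_table, read_energy_table,
                  select_top_complexes)

table = gen_energy_table(EnergyTableParams(ratio=3.0, seed=1))
table.to_csv("/tmp/energies.tsv", sep="\t", index=False)
records = read_energy_table("/tmp/energies.tsv")
print(f"{len(records)} complexes "
      f"({len(records) // 3} per sub-ensemble)\n")

tops = {}
for label in (SubEnsembleLabel.E_TRANS, SubEnsembleLabel.C_TRANS,
              SubEnsembleLabel.E_CIS):
    recs = [r for r in records if r.sub_ensemble is label]
    tops[label] = select_top_complexes(recs, 5)
    kds = [r.kd for r in tops[label]]
    box = boxplot_summary(kds, scale="log10")
    print(f"{label}: best K_D = {min(kds):.2e} M, "
          f"top-5 median log10 K_D = {box.median:.2f}")

for other in (SubEnsembleLabel.C_TRANS, SubEnsembleLabel.E_CIS):
    r = compare_subensembles([x.kd for x in tops[SubEnsembleLabel.E_TRANS]],
                             [x.kd for x in tops[other]])
    print(f"\nE_TRANS vs {other}: p = {r.p_value:.2e}, "
          f"fold change (best K_D) = {r.fold_change:.2f}")

print("\nA fold change > 1 with a small p-value means the receptor "
      "preferentially selects\nthe extended-trans conformation "
      "(conformational selection).")
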
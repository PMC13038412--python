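"""roGFP2 ratiometric analysis: from plate intensities to degree of oxidation.

Generates a plate-reader table for a probe oxidizing over time (with fully
reduced DTT and fully oxidized diamide control wells), applies the
ratiometric OxD formula, and summarizes a fluorescence induction series as
fold change over time zero.
"""

import numpy as np

from prxkit import GeneratorConfig, OxDRecord, compute_oxd, fold_change
from prxkit.synth import gen_induction, gen_plate_reader

trajectory = 1.0 - np.exp(-np.arange(0, 91, 15) / 30.0)  # rising oxidation
plate = gen_plate_reader(GeneratorConfig(seed=1, noise_sd=0.005), trajectory,
                         time_min=np.arange(0, 91, 15).astype(float))

print("time_min  OxD(true)  OxD(measured)")
for (t, grp), true in zip(plate.groupby("time_min"), trajectory):
    get = lambda role, ch: grp[(grp.role == role) & (grp.channel == ch)].intensity.iloc[0]
    rec = compute_oxd(OxDRecord(
        I400_sample=get("sample", "400"), I480_sample=get("sample", "480"),
        I400_red=get("red", "400"), I480_red=get("red", "480"),
        I400_ox=get("ox", "400"), I480_ox=get("ox", "480"),
    ))
    print(f"  {t:6.0f}  {true:9.3f}  {rec.oxd:12.3f}")

induction = gen_induction(GeneratorConfig(seed=1, noise_sd=0.01), plateau_fold=5.0)
folds = fold_change(induction["fluorescence"].to_numpy())
print(f"\ninduction fold change at 90 min: {folds[-1]:.2f} (plateau factor 5)")
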
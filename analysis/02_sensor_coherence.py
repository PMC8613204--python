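#!/usr/bin/env python
"""Sensor-level coherence analysis of the synthetic cohort: run every
subject through conditioning, segmentation, segment-averaged spectra and the
beta-band summary; write the per-subject table and group-averaged coherence
spectra.  Prints the proportion of subjects whose beta-band peak clears the
corrected confidence limit, per group."""

from pathlib import Path

import pandas as pd

from cmc.pipeline import load_cohort, run_group

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = load_cohort(OUT / "cohort.yaml")
    table = run_group(cohort, out_dir=OUT / "subjects")
    table.subjects.to_csv(OUT / "sensor_subjects.tsv", sep="\t", index=False,
                          float_format="%.6g")
    table.groups.to_csv(OUT / "sensor_groups.tsv", sep="\t", index=False,
                        float_format="%.6g")
    spectra = []
    for (group, hand), coh in table.mean_spectra.items():
        df = pd.DataFrame({"freq": coh.freqs, "coh": coh.coh})
        df.insert(0, "group", group)
        df.insert(1, "hand", hand)
        spectra.append(df)
    pd.concat(spectra).to_csv(OUT / "group_mean_coherence.tsv", sep="\t",
                              index=False, float_format="%.6g")

    g = table.groups
    print("group-level beta-band coherence (sensor level):")
    for _, row in g.iterrows():
        print(f"  {row['group']:>7s} {row['hand']:>12s}: "
              f"area {row['beta_area_mean']:.2f} +/- {row['beta_area_sd']:.2f}, "
              f"significant {100 * row['prop_significant']:.0f}%")
    lo = g.loc[g["group"] == "8-10y", "beta_area_mean"].mean()
    hi = g.loc[g["group"] == "20-30y", "beta_area_mean"].mean()
    print(f"beta area rises with injected gain: {lo:.2f} (8-10y) -> {hi:.2f} (20-30y)")


if __name__ == "__main__":
    main()
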
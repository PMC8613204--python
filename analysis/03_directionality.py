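#!/usr/bin/env python
"""Directional decomposition over the cohort: split each subject's beta-band
coherence into descending (cortex-to-muscle), ascending and zero-lag parts
and confirm that the injected cortex-leads coupling is recovered as
descending dominance, with ascending flat across gain levels."""

from pathlib import Path

import pandas as pd

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    subjects = pd.read_csv(OUT / "sensor_subjects.tsv", sep="\t")
    subjects["descending_share"] = subjects["descending_magnitude"] / (
        subjects["descending_magnitude"] + subjects["ascending_magnitude"])
    agg = subjects.groupby("group").agg(
        descending_mean=("descending_magnitude", "mean"),
        ascending_mean=("ascending_magnitude", "mean"),
        zero_mean=("zero_magnitude", "mean"),
        descending_share_mean=("descending_share", "mean"),
    ).reset_index()
    agg.to_csv(OUT / "directionality_groups.tsv", sep="\t", index=False,
               float_format="%.6g")

    print("directional decomposition of beta-band coherence by group:")
    for _, row in agg.iterrows():
        print(f"  {row['group']:>7s}: descending {row['descending_mean']:.2f}, "
              f"ascending {row['ascending_mean']:.2f} "
              f"(descending share {100 * row['descending_share_mean']:.1f}%)")
    n_dom = (subjects["descending_magnitude"] > subjects["ascending_magnitude"]).mean()
    print(f"descending dominates in {100 * n_dom:.0f}% of subject runs "
          f"(ground truth: 100% cortex-leads)")
    rng = agg["ascending_mean"].max() - agg["ascending_mean"].min()
    dlt = agg["descending_mean"].max() - agg["descending_mean"].min()
    print(f"ascending spread across gain groups ({rng:.3f}) is "
          f"{100 * rng / dlt:.0f}% of the descending spread ({dlt:.3f}): "
          "the gain manipulation loads on the descending path only")


if __name__ == "__main__":
    main()
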
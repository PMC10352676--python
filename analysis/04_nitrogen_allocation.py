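"""Partition leaf nitrogen into the Rubisco, bioenergetics and
light-harvesting pools and track the Chl/N ratio across the season.

Reads results/analysis/truth.csv + fits25.csv + curves.csv, writes the
merged samples.csv used by the statistical stage.
"""

from pathlib import Path

import pandas as pd

from photocap import biochem, fvcb, pipeline

OUT = Path("results/analysis")


def main() -> None:
    traits = pd.read_csv(OUT / "truth.csv").drop(columns=["vcmax25", "jmax25", "rd25"])
    fits25 = pd.read_csv(OUT / "fits25.csv")
    curves = fvcb.read_curves_csv(OUT / "curves.csv")
    a_sat = pd.DataFrame(
        {"leaf_id": [c.leaf_id for c in curves], "a_sat": [fvcb.a_sat_from_curve(c) for c in curves]}
    )
    samples = pipeline._samples_table(traits, fits25, a_sat)
    pipeline.write_csv_stable(samples, OUT / "samples.csv")

    by_stage = samples.groupby("stage")[["p_r", "p_b", "p_l"]].mean()
    print("mean N allocation fractions by stage:")
    print(by_stage.round(3).to_string())
    ratio = biochem.chl_to_n_ratio(samples)
    print("per-DOY Chl/N ratio:")
    print(ratio.round(3).to_string())


if __name__ == "__main__":
    main()
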
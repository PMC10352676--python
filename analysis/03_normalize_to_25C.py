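"""Normalize fitted Vcmax and Jmax to 25°C with the exponential Arrhenius
response and verify the printed temperature constants are self-consistent.

Reads results/analysis/fits.csv, writes fits25.csv.
"""

from pathlib import Path

import pandas as pd

from photocap import pipeline, thermal

OUT = Path("results/analysis")


def main() -> None:
    for name, params in (("Vcmax", thermal.VCMAX_ARRHENIUS), ("Jmax", thermal.JMAX_ARRHENIUS)):
        f = thermal.reference_consistency(params)
        print(f"{name}: f(298.15 K)/k25 = {f:.6f} (should be 1)")

    df = pd.read_csv(OUT / "fits.csv")
    df["vcmax25"] = thermal.normalize_to_25(
        df["vcmax"].to_numpy(), df["leaf_temperature_K"].to_numpy(), thermal.VCMAX_ARRHENIUS
    )
    df["jmax25"] = thermal.normalize_to_25(
        df["jmax"].to_numpy(), df["leaf_temperature_K"].to_numpy(), thermal.JMAX_ARRHENIUS
    )
    pipeline.write_csv_stable(df, OUT / "fits25.csv")
    print(f"normalized {len(df)} fits; mean Vcmax25 = {df['vcmax25'].mean():.1f} umol m-2 s-1")


if __name__ == "__main__":
    main()
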
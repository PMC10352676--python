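"""Relate 25°C photosynthetic capacity to leaf traits: pairwise
correlations, the simple/multiple linear model battery, random-forest
permutation importance, and seasonal percent changes.

Reads results/analysis/samples.csv; writes correlations.csv, models.csv,
importance.csv and seasonal.csv.
"""

from pathlib import Path

import pandas as pd

from photocap import pipeline, stats

OUT = Path("results/analysis")
SEED = 1


def main() -> None:
    samples = pd.read_csv(OUT / "samples.csv")

    rmat, _ = stats.correlation_matrix(samples, pipeline.STAT_COLUMNS)
    pipeline.write_csv_stable(rmat.reset_index(names="variable"), OUT / "correlations.csv")
    r = rmat.loc["vcmax25"]
    print(
        "r(Vcmax25, .): Chl %.2f  Car %.2f  N %.2f"
        % (r["chl_area_ug_cm2"], r["car_area_ug_cm2"], r["n_area_ug_cm2"])
    )

    models = stats.model_suite(samples)
    pipeline.write_csv_stable(pipeline._models_table(models), OUT / "models.csv")
    print("Vcmax25 model R² ladder:")
    for m in models:
        if m.response == "vcmax25":
            print(f"  f({'+'.join(p.split('_')[0] for p in m.predictors)}): R² = {m.r_squared:.2f}")

    imp = stats.rf_importance(samples, settings=stats.RFSettings(seed=SEED))
    imp_df = pd.DataFrame(
        {"predictor": list(imp.inc_mse), "inc_mse_pct": list(imp.inc_mse.values())}
    )
    pipeline.write_csv_stable(imp_df, OUT / "importance.csv")
    print("permutation importance ranking:", " > ".join(p.split("_")[0] for p in imp.ranking()))

    summaries = [
        stats.seasonal_changes(samples, 92, 126, traits=pipeline.STAT_COLUMNS),
        stats.seasonal_changes(samples, 126, 147, traits=pipeline.STAT_COLUMNS),
    ]
    pipeline.write_csv_stable(pipeline._seasonal_table(summaries), OUT / "seasonal.csv")
    v = summaries[0].changes["vcmax25"]
    print(
        f"Vcmax25 rise DOY 92→126: +{v.pct_rel_earlier:.0f}% (rel. earlier); "
        f"fall 126→147: {summaries[1].changes['vcmax25'].pct_rel_later:.0f}% (rel. later)"
    )


if __name__ == "__main__":
    main()
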
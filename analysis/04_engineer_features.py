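"""Engineer the 309 per-run features, test age trends, trend-filter.

Writes the feature matrix (raw and trend-filtered) and the Kendall-tau age
trend table, and prints the count of Bonferroni-significant aging features.
"""

import pandas as pd

from _common import get_cohort, get_cleaned_runs, get_states, outdir
from cagepheno import features as feat
from cagepheno import synth


def main():
    cohort = get_cohort()
    cleaned, _ = get_cleaned_runs(cohort)
    model, sequences = get_states(cleaned)
    out = outdir()

    fm = feat.build_feature_matrix(
        cleaned, sequences, synth.lifespan_frame(cohort["lifespans"]),
        state_names=model.state_labels[:model.n_states])
    pd.concat([fm.meta, fm.values], axis=1).to_csv(out / "features.csv",
                                                   index=False)
    trends = feat.age_trend_tests(fm)
    trends.to_csv(out / "age_trends.csv", index=False)
    fm_f = feat.trend_filter_matrix(fm, lam=2.0)
    pd.concat([fm_f.meta, fm_f.values], axis=1).to_csv(
        out / "features_trendfiltered.csv", index=False)

    n_sig = int(trends["significant"].sum())
    n_test = int(trends["p"].notna().sum())
    print(f"feature matrix: {fm.values.shape[0]} runs x "
          f"{fm.values.shape[1]} features")
    print(f"age trends: {n_sig}/{n_test} features significant after "
          f"Bonferroni (generator plants real aging effects, so a large "
          f"fraction is expected)")
    top = trends.dropna().reindex(
        trends.dropna()["tau"].abs().sort_values(ascending=False).index)
    print("strongest trends:")
    print(top.head(5)[["feature", "tau", "p_adj"]].to_string(index=False))
    print(f"wrote features.csv, age_trends.csv, features_trendfiltered.csv "
          f"under {out}")


if __name__ == "__main__":
    main()
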
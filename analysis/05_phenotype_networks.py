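"""Age-binned phenotype networks: resilience, clusters, connectivity.

Writes the per-age-bin resilience curve, consensus cluster assignments and
the sparse network edge list, and prints the resilience trajectory.
"""

import numpy as np
import pandas as pd

from _common import get_cohort, get_cleaned_runs, get_states, outdir, SEED
from cagepheno import features as feat
from cagepheno import network as net
from cagepheno import synth


def main():
    cohort = get_cohort()
    cleaned, _ = get_cleaned_runs(cohort)
    model, sequences = get_states(cleaned)
    fm = feat.build_feature_matrix(
        cleaned, sequences, synth.lifespan_frame(cohort["lifespans"]),
        state_names=model.state_labels[:model.n_states])
    fm = feat.trend_filter_matrix(fm, lam=2.0)
    out = outdir()

    X = fm.values.to_numpy(float)
    med = np.nanmedian(X, axis=0)
    X = np.where(np.isfinite(X), X, np.where(np.isfinite(med), med, 0.0))
    keep = X.std(axis=0) > 0
    Xn = X[:, keep]
    names = [n for n, k in zip(fm.values.columns, keep) if k]
    ages = fm.meta["age_months"].to_numpy(float)

    curve = net.resilience_curve(Xn, ages, min_runs=10)
    curve.to_csv(out / "resilience.csv", index=False)
    print("resilience by 3-month age bin (lower = denser coupling):")
    print(curve.round(2).to_string(index=False))

    cc = net.consensus_cluster(Xn, B=50, k_range=[3, 6, 9], seed=SEED)
    clus = pd.DataFrame({"feature": names, "cluster": cc.assignments})
    clus["exemplar"] = [i in cc.exemplars for i in range(len(names))]
    clus.to_csv(out / "clusters.csv", index=False)
    print(f"consensus clustering chose k={cc.k} "
          f"({len(cc.exemplars)} exemplars)")

    bins = feat.assign_age_bins(ages)
    ex_idx = np.array(cc.exemplars)
    corrs, used = [], []
    for b in np.unique(bins):
        sel = bins == b
        if sel.sum() >= len(ex_idx) + 2:
            corrs.append(net.nonparanormal_corr(Xn[np.ix_(sel, ex_idx)]))
            used.append(int(b))
    pset = net.fit_tvgl(corrs, lambda_sparsity=0.05, lambda_smooth=0.02)
    pset.bins = used
    pset.edge_list([names[i] for i in ex_idx]).to_csv(
        out / "network_edges.csv", index=False)
    conn = net.cluster_connectivity(pset, cc.assignments[ex_idx])
    conn["inter_connectivity"].to_csv(out / "cluster_connectivity.csv")
    print(f"wrote resilience.csv, clusters.csv, network_edges.csv, "
          f"cluster_connectivity.csv under {out}")


if __name__ == "__main__":
    main()
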
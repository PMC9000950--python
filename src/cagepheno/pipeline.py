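"""End-to-end orchestration: synthetic cohort -> QC -> HMM -> features ->
trend filter -> networks -> aging-rate model -> heritability, with a
checksummed artifact manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("cagepheno")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    seed: int = 0
    # stage toggles
    simulate: bool = True
    qc: bool = True
    hmm: bool = True
    features: bool = True
    network: bool = True
    caspar: bool = True
    genetics: bool = False
    # cohort scale
    n_mice: int = 40
    study_length: float = 6.0
    run_length_days: int = 3
    # stage parameters
    n_states: int = 6
    hmm_restarts: int = 2
    hmm_max_iter: int = 30
    trend_lambda: float = 2.0
    consensus_bootstraps: int = 50
    consensus_k_range: tuple = (3, 6, 9)
    caspar_sigma_beta_grid: tuple = (0.1, 3.0, 100.0)
    caspar_rounds: int = 60
    caspar_splits: int = 3
    pve_features: int = 5
    pve_draws: int = 20
    write_runs: bool = False
    log_level: str = "INFO"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the manifest (stage,
    file, checksum, seed).  Re-running with an identical config reproduces
    identical checksums.  A stage whose upstream is disabled fails fast
    naming the missing dependency."""
    from . import caspar as csp
    from . import features as feat
    from . import genetics as gen
    from . import hmm as hmm_mod
    from . import network as net
    from . import qc as qc_mod
    from . import synth

    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def record(stage: str, path: Path):
        manifest.append({"stage": stage, "file": path.name,
                         "sha256": _sha256(path)})

    t0 = time.time()
    cohort = None
    if config.simulate:
        cc = synth.CohortConfig(n_mice=config.n_mice,
                                study_length=config.study_length,
                                run_length_days=config.run_length_days,
                                seed=config.seed)
        cohort = synth.simulate_cohort(cc, with_genetics=config.genetics,
                                       h2_targets=np.full(14, 0.3))
        _write_csv(synth.lifespan_frame(cohort["lifespans"]), out / "lifespans.csv")
        record("simulate", out / "lifespans.csv")
        if config.write_runs:
            for f in synth.write_cohort(cohort, out / "runs"):
                record("simulate", Path(f))
        log.info("simulated %d runs from %d mice (%.1fs)",
                 len(cohort["runs"]), config.n_mice, time.time() - t0)

    cleaned = None
    if config.qc:
        if cohort is None:
            raise PipelineError("qc requires the simulate stage (runs missing)")
        res = qc_mod.qc_pipeline(cohort["runs"])
        cleaned = res["runs"]
        _write_csv(qc_mod.report_frame(res["reports"]), out / "qc_report.csv")
        record("qc", out / "qc_report.csv")
        log.info("QC kept %d/%d runs", len(cleaned), len(cohort["runs"]))

    model = None
    sequences = None
    if config.hmm:
        if cleaned is None:
            raise PipelineError("hmm requires the qc stage (cleaned runs missing)")
        model = hmm_mod.fit_robust_hmm(cleaned, config.n_states,
                                       n_restarts=config.hmm_restarts,
                                       max_iter=config.hmm_max_iter,
                                       seed=config.seed)
        (out / "hmm_model.json").write_text(model.to_json())
        record("hmm", out / "hmm_model.json")
        sequences = [hmm_mod.decode(model, r) for r in cleaned]
        seq_df = pd.DataFrame(
            {"run_id": [s.run_id for s in sequences],
             "states": [" ".join(map(str, s.states.tolist())) for s in sequences]})
        _write_csv(seq_df, out / "state_sequences.csv")
        record("hmm", out / "state_sequences.csv")
        log.info("HMM fitted (loglik %.1f)", model.loglik_trace[-1])

    fm = None
    fm_filtered = None
    if config.features:
        if sequences is None:
            raise PipelineError(
                "features requires the hmm stage (state sequences missing)")
        state_names = model.state_labels[:model.n_states]
        fm = feat.build_feature_matrix(
            cleaned, sequences, synth.lifespan_frame(cohort["lifespans"]),
            state_names=state_names)
        _write_csv(pd.concat([fm.meta, fm.values], axis=1), out / "features.csv")
        record("features", out / "features.csv")
        trends = feat.age_trend_tests(fm)
        _write_csv(trends, out / "age_trends.csv")
        record("features", out / "age_trends.csv")
        fm_filtered = feat.trend_filter_matrix(fm, lam=config.trend_lambda)
        _write_csv(pd.concat([fm_filtered.meta, fm_filtered.values], axis=1),
                   out / "features_trendfiltered.csv")
        record("features", out / "features_trendfiltered.csv")
        log.info("features: %d runs x %d features; %d age-significant",
                 *fm.values.shape, int(trends["significant"].sum()))

    if config.network:
        if fm_filtered is None:
            raise PipelineError("network requires the features stage")
        X = fm_filtered.values.to_numpy(float)
        # network stage operates on a complete matrix: median-fill missing
        med = np.nanmedian(X, axis=0)
        med = np.where(np.isfinite(med), med, 0.0)
        X = np.where(np.isfinite(X), X, med[None, :])
        keep = X.std(axis=0) > 0
        Xn = X[:, keep]
        names = [n for n, k in zip(fm_filtered.values.columns, keep) if k]
        ages = fm_filtered.meta["age_months"].to_numpy(float)
        curve = net.resilience_curve(Xn, ages, min_runs=10)
        _write_csv(curve, out / "resilience.csv")
        record("network", out / "resilience.csv")
        cc_res = net.consensus_cluster(Xn, B=config.consensus_bootstraps,
                                       k_range=list(config.consensus_k_range),
                                       seed=config.seed)
        clus = pd.DataFrame({"feature": names, "cluster": cc_res.assignments})
        clus["exemplar"] = [i in cc_res.exemplars for i in range(len(names))]
        _write_csv(clus, out / "clusters.csv")
        record("network", out / "clusters.csv")
        # age-binned sparse precision set on exemplar features
        from .features import assign_age_bins
        bins = assign_age_bins(ages)
        ex = np.array(cc_res.exemplars)
        corrs, used_bins, n_runs = [], [], []
        for b in np.unique(bins):
            sel = bins == b
            if sel.sum() < len(ex) + 2:
                continue
            corrs.append(net.nonparanormal_corr(Xn[np.ix_(sel, ex)]))
            used_bins.append(int(b))
            n_runs.append(int(sel.sum()))
        if len(corrs) >= 1:
            pset = net.fit_tvgl(corrs, lambda_sparsity=0.05, lambda_smooth=0.02)
            pset.bins = used_bins
            pset.n_runs = n_runs
            edges = pset.edge_list([names[i] for i in ex])
            _write_csv(edges, out / "network_edges.csv")
            record("network", out / "network_edges.csv")
            conn = net.cluster_connectivity(pset, cc_res.assignments[ex])
            conn_df = conn["inter_connectivity"].reset_index(names="bin")
            _write_csv(conn_df, out / "cluster_connectivity.csv")
            record("network", out / "cluster_connectivity.csv")
        log.info("network: %d clusters, %d age bins", cc_res.k, len(corrs))

    if config.caspar:
        if fm_filtered is None:
            raise PipelineError("caspar requires the features stage")
        ls = synth.lifespan_frame(cohort["lifespans"])
        ref = csp.fit_reference_lifespan(cohort["lifespans"])
        data = csp.build_caspar_data(fm_filtered.values, fm_filtered.meta, ls)
        cfg = csp.CasparConfig(n_rounds=config.caspar_rounds,
                               n_splits=config.caspar_splits,
                               seed=config.seed)
        table = csp.evaluate_splits(data, ref, config.caspar_sigma_beta_grid, cfg)
        _write_csv(table, out / "caspar_evaluation.csv")
        record("caspar", out / "caspar_evaluation.csv")
        log.info("caspar: reference lifespan mu=%.2f s=%.2f; grid evaluated",
                 ref.location, ref.scale)

    if config.genetics:
        if fm is None or cohort is None or cohort.get("genetics") is None:
            raise PipelineError("genetics requires simulate(with genetics) + features")
        K = cohort["genetics"]["kinship"]
        cols = list(fm.values.columns[:config.pve_features])
        tab = gen.heritability_table(fm.values[cols], fm.meta, K,
                                     n_draws=config.pve_draws, seed=config.seed)
        _write_csv(tab, out / "heritability.csv")
        record("genetics", out / "heritability.csv")

    man = {"seed": config.seed, "files": manifest,
           "elapsed_s": round(time.time() - t0, 1)}
    (out / "manifest.json").write_text(
        json.dumps({"seed": man["seed"], "files": man["files"]},
                   sort_keys=True, indent=1))
    log.info("pipeline complete in %.1fs (%d artifacts)",
             man["elapsed_s"], len(manifest))
    return man
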
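"""End-to-end discovery pipeline and its run manifest.

Stage order: paired differential-expression screen -> qRT-PCR normalization
-> univariate Cox screen -> bootstrap LASSO-Cox bagging (RMIP) -> top-k
signature refit with median cutoff -> per-cohort evaluation (KM/log-rank,
response contingency with progressive rates, interaction Cox,
time-dependent AUC).  Every stage writes a plain-text artifact and records
its SHA-256 digest in the manifest, so two runs with identical config,
inputs and seed produce byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import io as mio
from .config import PipelineConfig, stage_rng, stage_seed
from .de import de_screen
from .io import MirsigError
from .lasso import bag_lasso, normalize_qpcr, select_top_features
from .signature import (classify_risk, evaluate_km_by_risk, fit_signature,
                        progressive_rate, response_by_risk, risk_score, td_auc)
from .simulate import StudyData
from .survival import (RankDeficientError, SurvivalError, fit_interaction_cox,
                       univariate_cox_screen)

log = logging.getLogger("mirsig")


class PipelineError(MirsigError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")


def _check_overlap(expr, clinical, stage):
    common = set(expr.sample_ids) & set(clinical.sample_ids)
    if not common:
        raise PipelineError(stage, "expression and clinical tables share no samples")


def run_pipeline(config: PipelineConfig, study: StudyData, out_dir,
                 auc_time: float = 12.0, make_figures: bool = False) -> dict:
    """Run the whole discovery chain on a study bundle; returns the manifest.

    ``study.cohorts`` must contain a cohort named after
    ``"training"``; further cohorts are treated as validation sets and are
    scored with the training cutoff.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "stages": {}, "seed_scheme": {}}

    def _artifact(stage, name, writer):
        path = out / name
        writer(path)
        manifest["stages"].setdefault(stage, {})[name] = mio.file_digest(path)
        return path

    # ---- stage 1: paired differential expression -------------------------
    paired, dropped = study.paired_expr.drop_missing()
    if dropped:
        log.warning("dropped %d features with missing paired values", len(dropped))
    de_result, de_call = de_screen(paired, study.pairing,
                                   alpha=config.de_alpha, use_fdr=config.de_use_fdr)
    de_features = de_call["all"]
    if not de_features:
        raise PipelineError("de_screen", "no differentially expressed features survive")
    _artifact("de_screen", "de_result.tsv",
              lambda p: de_result.table.rename_axis("feature_id").to_csv(p, sep="\t"))
    _artifact("de_screen", "de_features.json", lambda p: mio.write_json(de_call, p))

    # ---- stage 2: normalization of cohort expression ---------------------
    cohorts = {}
    for name, (expr, clin, _truth) in study.cohorts.items():
        if expr.scale == "linear":
            expr = normalize_qpcr(expr)
        expr, dropped = expr.drop_missing()
        if dropped:
            log.warning("cohort %s: dropped %d features with missing values", name, len(dropped))
        _check_overlap(expr, clin, "normalize")
        cohorts[name] = (expr, clin)
    if "training" not in cohorts:
        raise PipelineError("cox_screen", "no cohort named 'training'")
    train_expr, train_clin = cohorts["training"]

    # ---- stage 3: univariate Cox screen on the training cohort -----------
    panel = [f for f in de_features if f in train_expr.data.index]
    if not panel:
        raise PipelineError("cox_screen", "no DE feature is measured in the training cohort")
    kept, fits = univariate_cox_screen(train_expr.subset_features(panel), train_clin,
                                       alpha=config.cox_screen_alpha,
                                       ties=config.ties_method)
    if not kept:
        raise PipelineError("cox_screen", "no feature passes the univariate Cox screen")
    rows = []
    for fid in panel:
        f = fits[fid]
        if f is None:
            continue
        rows.append({"feature_id": fid, "beta": f.beta[0], "hr": f.hr[0],
                     "p": f.p[0], "kept": fid in kept})
    import pandas as pd

    _artifact("cox_screen", "cox_screen.tsv",
              lambda p: pd.DataFrame(rows).to_csv(p, sep="\t", index=False))

    # ---- stage 4: bootstrap LASSO-Cox bagging ----------------------------
    sids = [s for s in train_clin.sample_ids if s in set(train_expr.sample_ids)]
    clin_m = train_clin.subset(sids)
    X = train_expr.values_for(sids, kept)
    bag_seed = stage_seed(config.seed, "bagging")
    rmip = bag_lasso(clin_m.time, clin_m.event, X, kept, B=config.B_resamples,
                     folds=config.cv_folds, seed=bag_seed,
                     K=config.lambda_path_length, min_ratio=config.lambda_min_ratio)
    _artifact("bagging", "rmip.tsv", lambda p: rmip.to_tsv(p))

    # ---- stage 5: top-k selection and signature refit --------------------
    selected, elbow_k = select_top_features(rmip, config.top_k, elbow=True)
    signature, refit = fit_signature(train_expr, train_clin, selected,
                                     ties=config.ties_method)
    sig_dict = signature.to_dict()
    sig_dict["rmip_elbow_suggestion"] = elbow_k
    sig_dict["refit_summary"] = refit.summary().round(6).to_dict(orient="index")
    _artifact("signature", "signature.json", lambda p: mio.write_json(sig_dict, p))

    # ---- stage 6: evaluation on every cohort -----------------------------
    report = {"config": config.to_dict(), "signature": signature.to_dict(),
              "cohorts": {}}
    for name, (expr, clin) in cohorts.items():
        report["cohorts"][name] = evaluate_cohort(signature, expr, clin,
                                                  auc_time=auc_time,
                                                  seed=config.seed, cohort=name)
    _artifact("evaluate", "report.json", lambda p: mio.write_json(report, p))

    if make_figures:
        from .plots import plot_km_by_risk, plot_rmip

        for name, (expr, clin) in cohorts.items():
            scores = risk_score(signature, expr)
            assignment = classify_risk(scores, signature.cutoff, cohort=name)
            try:
                curves, lr = evaluate_km_by_risk(assignment, clin)
                plot_km_by_risk(curves, lr, out / f"km_{name}.png", title=name)
            except MirsigError:
                pass
        plot_rmip(rmip, out / "rmip.png")

    mio.write_json(manifest, out / "manifest.json")
    return manifest


def evaluate_cohort(signature, expr, clin, auc_time: float = 12.0, seed: int = 0,
                    cohort: str = "") -> dict:
    """Evaluate one cohort under a fixed signature and training cutoff."""
    if expr.scale == "linear":
        expr = normalize_qpcr(expr)
    scores = risk_score(signature, expr)
    scores = scores.loc[[s for s in clin.sample_ids if s in scores.index]]
    clin = clin.subset(list(scores.index))
    assignment = classify_risk(scores, signature.cutoff, cohort=cohort)
    out = {"n": clin.n, "n_events": clin.n_events,
           "n_low": int((assignment.groups == "low").sum()),
           "n_high": int((assignment.groups == "high").sum())}

    try:
        curves, lr = evaluate_km_by_risk(assignment, clin)
        out["median_pfs"] = {
            g: {"median": c.median, "ci": list(c.median_ci)} for g, c in curves.items()
        }
        out["logrank"] = {"statistic": lr.statistic, "df": lr.df, "p": lr.p}
    except MirsigError as e:
        out["median_pfs"] = None
        out["logrank"] = {"error": str(e)}

    if "response" in clin.table.columns and out["n_low"] > 0 and out["n_high"] > 0:
        cont = response_by_risk(clin, assignment)
        out["response_table"] = {str(k): {c: int(v) for c, v in row.items()}
                                 for k, row in cont.counts.iterrows()}
        out["response_test"] = {"statistic": cont.statistic, "p": cont.p,
                                "method": cont.method}
        try:
            out["progressive_rate"] = progressive_rate(cont)
        except MirsigError as e:
            out["progressive_rate"] = {"error": str(e)}
        # interaction of risk status with progressive response (PD vs rest)
        a = (clin.table["response"] == "PD").astype(int).to_numpy()
        b = (assignment.groups == "high").astype(int)
        try:
            inter = fit_interaction_cox(clin.time, clin.event, a, b,
                                        names=("pd_response", "high_risk"),
                                        ties=signature.ties_method)
            ci = inter.ci
            out["interaction"] = {
                n: {"hr": float(h), "ci": [float(lo), float(hi)], "p": float(pv)}
                for n, h, (lo, hi), pv in zip(inter.names, inter.hr, ci, inter.p)
            }
        except (RankDeficientError, SurvivalError) as e:
            out["interaction"] = {"error": str(e)}

    try:
        roc = td_auc(assignment.scores, clin.time, clin.event, t=auc_time,
                     seed=(seed * 1000003 + 997) % (2**31), n_boot=200)
        out["td_auc"] = {"t": roc.t, "auc": roc.auc, "ci": list(roc.ci) if roc.ci else None}
    except MirsigError as e:
        out["td_auc"] = {"error": str(e)}
    return out
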
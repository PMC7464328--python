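"""Pipeline orchestration: run the full analysis sequence on a cohort and
write self-describing text reports, machine-readable estimate tables and
figure files.

Stage order mirrors the analysis plan: data -> baseline CRP analyses
(quartile KM / log-rank, per-doubling Cox, Schoenfeld, ORR / logistic) ->
longitudinal LMM with AIC degree selection -> joint model -> dynamic
prediction -> early decline.  Failures in an optional stage are logged and
do not abort the remaining stages.  Every number in a report comes from a
stage output written to disk; the reporting layer recomputes nothing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .cohort import (CohortTable, DAYS_PER_MONTH, QuartileScheme, load_cohort,
                     write_cohort)
from .joint import JointSpec, build_model, fit_joint, hr_per_unit
from .lmm import lowess_trajectory, select_time_spec
from .predict import risk_profile
from .response import (ResponseCounts, decline_cox, decline_km_display,
                       early_decline_table, fisher_exact, logistic_fit,
                       orr_with_ci, youden_cutoff)
from .simulate import SimTruth, simulate_cohort, simulate_response
from .survival import cox_fit, km_fit, logrank_test, reverse_km_followup, \
    schoenfeld_ph_test

log = logging.getLogger("crptraj")


@dataclass
class PipelineConfig:
    baseline_path: str | None = None
    labs_path: str | None = None
    truth: SimTruth | None = None
    endpoint: str = "PFS"
    quartiles: QuartileScheme = field(default_factory=QuartileScheme)
    joint_spec: JointSpec = field(default_factory=JointSpec)
    adjustment: tuple[str, ...] = ()
    out_dir: str = "crptraj_out"
    seed: int | None = None
    make_plots: bool = True

    def validate(self) -> None:
        has_files = self.baseline_path is not None and self.labs_path is not None
        has_truth = self.truth is not None
        if has_files == has_truth:
            raise ValueError("exactly one of {input files, simulation truth} "
                             "must be configured")
        if has_truth and self.seed is None:
            raise ValueError("a seed is mandatory when simulating")
        if self.endpoint not in ("PFS", "OS"):
            raise ValueError("endpoint must be PFS or OS")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs = {}
        if "truth" in raw:
            kwargs["truth"] = SimTruth(**raw.pop("truth"))
        if "joint_spec" in raw:
            kwargs["joint_spec"] = JointSpec(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw.pop("joint_spec").items()})
        if "quartiles" in raw:
            kwargs["quartiles"] = QuartileScheme(cutoffs=tuple(raw.pop("quartiles")))
        if "adjustment" in raw:
            kwargs["adjustment"] = tuple(raw.pop("adjustment"))
        kwargs.update(raw)
        return cls(**kwargs)


def _estimates_frame(ests) -> pd.DataFrame:
    return pd.DataFrame([{"name": e.name, "scale": e.scale, "point": e.point,
                          "ci_low": e.ci_low, "ci_high": e.ci_high, "p": e.p,
                          "unit": e.unit} for e in ests])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a report bundle (dict of stage outputs)
    and writes one subdirectory of delimited/text artifacts per stage."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"out_dir": str(out)}

    if config.truth is not None:
        truth = config.truth
        if config.seed is not None:
            truth.seed = config.seed
        cohort = simulate_cohort(truth)
        simulate_response(cohort, truth)
        write_cohort(cohort, out / "baseline.csv", out / "labs.csv")
        (out / "sim_truth.txt").write_text(
            "\n".join(f"{k} = {v}" for k, v in truth.as_dict().items()) + "\n")
    else:
        cohort = load_cohort(config.baseline_path, config.labs_path)
    bundle["cohort"] = cohort
    log.info("cohort: %d patients, %d CRP measurements", cohort.n_patients,
             len(cohort.labs))

    af = cohort.analysis_frame(config.endpoint, config.quartiles)
    af.to_csv(out / "analysis_frame.csv", index=False)
    n_no_baseline = int(af["baseline_crp"].isna().sum())
    log.info("excluded from baseline-CRP analyses (no draw in 14-day window): %d",
             n_no_baseline)

    sections: list[str] = [f"crptraj {__version__} report",
                           f"endpoint: {config.endpoint}",
                           f"patients: {cohort.n_patients}"]

    # --- baseline survival analyses ---------------------------------------
    try:
        km_all = km_fit(af["time_months"].to_numpy(), af["event"].to_numpy())
        med_fu, fu_ci = reverse_km_followup(af["time_months"].to_numpy(),
                                            af["event"].to_numpy())
        sub = af.dropna(subset=["baseline_crp"])
        chi2, dfree, p_lr = logrank_test(sub["time_months"].to_numpy(),
                                         sub["event"].to_numpy(),
                                         sub["crp_quartile"].to_numpy())
        cox_uni = cox_fit(af, ["log2_crp"])
        adj = [c for c in config.adjustment if c in af.columns]
        cox_adj = cox_fit(af, ["log2_crp", *adj]) if adj else None
        ph = schoenfeld_ph_test(cox_uni)
        ests = list(cox_uni.estimates) + (list(cox_adj.estimates) if cox_adj else [])
        _estimates_frame(ests).to_csv(out / "baseline_cox.csv", index=False)
        ph.to_csv(out / "schoenfeld.csv", index=False)
        bundle["baseline"] = {
            "km": km_all, "median_followup": med_fu,
            "logrank": (chi2, dfree, p_lr), "cox_uni": cox_uni,
            "cox_adj": cox_adj, "schoenfeld": ph,
        }
        sections += [
            f"median {config.endpoint}: {km_all.median:.2f} months "
            f"(CI {km_all.median_ci[0]:.2f}-{km_all.median_ci[1]:.2f})",
            f"median follow-up (reverse KM): {med_fu:.2f} months",
            f"log-rank across CRP quartiles: chi2={chi2:.2f}, df={dfree}, p={p_lr:.4f}",
            f"HR per doubling of baseline CRP: {cox_uni.estimates[0].point:.3f} "
            f"({cox_uni.estimates[0].ci_low:.3f}-{cox_uni.estimates[0].ci_high:.3f})",
            f"Schoenfeld global p: {ph.iloc[-1]['p']:.4f}",
        ]
    except Exception as exc:  # noqa: BLE001
        log.warning("baseline survival stage failed: %s", exc)
        bundle["baseline"] = {"error": str(exc)}

    # --- response ----------------------------------------------------------
    try:
        resp = af.dropna(subset=["baseline_crp", "response"])
        resp = resp[resp["response"] != "NE"]
        n_resp = int((resp["response"].isin(["CR", "PR"])).sum())
        orr = orr_with_ci(ResponseCounts(n_resp, len(resp)))
        resp = resp.assign(responder=resp["response"].isin(["CR", "PR"]).astype(int))
        tab = pd.crosstab(resp["responder"], resp["crp_quartile"])
        p_fisher = (fisher_exact(tab.reindex([1, 0]).to_numpy())
                    if tab.shape[0] == 2 and 2 <= tab.shape[1] <= 4
                    else float("nan"))
        lests, _ = logistic_fit(resp, "responder", ["log2_crp"])
        _estimates_frame(lests).to_csv(out / "orr_logistic.csv", index=False)
        bundle["response"] = {"orr": orr, "fisher_p": p_fisher, "logistic": lests,
                              "n_evaluable": len(resp)}
        sections += [
            f"ORR: {orr.percent:.1f}% (95% CI {orr.ci_low:.1f}-{orr.ci_high:.1f}), "
            f"n evaluable = {len(resp)}",
            f"Fisher exact p across quartiles: {p_fisher:.4f}",
            f"OR per doubling of baseline CRP: {lests[0].point:.3f} "
            f"({lests[0].ci_low:.3f}-{lests[0].ci_high:.3f})",
        ]
    except Exception as exc:  # noqa: BLE001
        log.warning("response stage failed: %s", exc)
        bundle["response"] = {"error": str(exc)}

    # --- longitudinal ------------------------------------------------------
    labs = cohort.labs.copy()
    labs["time_months"] = labs["time_days"] / DAYS_PER_MONTH
    try:
        best_deg, aic_table = select_time_spec(labs)
        aic_table.to_csv(out / "lmm_aic.csv", index=False)
        bundle["longitudinal"] = {"degree": best_deg, "aic_table": aic_table}
        sections.append(f"LMM time specification by AIC: degree {best_deg}")
    except Exception as exc:  # noqa: BLE001
        log.warning("longitudinal stage failed: %s", exc)
        best_deg = 1
        bundle["longitudinal"] = {"error": str(exc)}

    # --- joint model --------------------------------------------------------
    try:
        jfit = fit_joint(build_model(cohort, config.joint_spec, config.endpoint))
        jests = []
        if jfit.alpha_value is not None:
            jests.append(hr_per_unit(jfit, "value", 10.0))
        if jfit.alpha_slope is not None:
            jests.append(hr_per_unit(jfit, "slope", 10.0))
        _estimates_frame(jests).to_csv(out / "joint_estimates.csv", index=False)
        bundle["joint"] = {"fit": jfit, "estimates": jests}
        for e in jests:
            sections.append(f"joint model {e.name} ({e.unit}): "
                            f"HR {e.point:.3f} ({e.ci_low:.3f}-{e.ci_high:.3f})")
        log.info("joint model converged: grad %.2e", jfit.grad_norm)
    except Exception as exc:  # noqa: BLE001
        log.warning("joint stage failed: %s", exc)
        bundle["joint"] = {"error": str(exc)}

    # --- dynamic prediction -------------------------------------------------
    try:
        jfit = bundle["joint"]["fit"]
        ep = cohort.endpoints(config.endpoint)
        alive = ep[ep["time_months"] > 6.0]
        profiles = []
        for pid in alive["patient_id"].head(2):
            hist = cohort.patient_measurements(pid).copy()
            hist["time_months"] = hist["time_days"] / DAYS_PER_MONTH
            hist = hist[hist["time_months"] <= 6.0]
            if hist.empty:
                continue
            prof = risk_profile(jfit, hist, 6.0, np.linspace(0, 3, 7),
                                patient_id=pid)
            profiles.append(prof)
        if profiles:
            pd.concat(profiles).to_csv(out / "risk_profiles.csv", index=False)
            bundle["prediction"] = {"profiles": profiles}
            sections.append(
                f"3-month risk at 6-month landmark, example patients: "
                + ", ".join(f"{p['patient_id'].iloc[0]}: {p['risk'].iloc[-1]:.2f}"
                            for p in profiles))
    except Exception as exc:  # noqa: BLE001
        log.warning("prediction stage failed: %s", exc)
        bundle["prediction"] = {"error": str(exc)}

    # --- early decline ------------------------------------------------------
    try:
        ed = early_decline_table(cohort)
        ed.to_csv(out / "early_decline.csv", index=False)
        ep = cohort.endpoints(config.endpoint)
        est, dfit = decline_cox(ed, ep)
        sub = ed[ed["evaluable"]].merge(ep, on="patient_id")
        cut = youden_cutoff(sub["decline_pct"].to_numpy(),
                            sub["event"].to_numpy(dtype=bool))
        disp = decline_km_display(ed, ep, cut.cutoff)
        bundle["decline"] = {"table": ed, "cox": est, "youden": cut,
                             "km_display": disp}
        sections += [
            f"early-decline HR per 10% decline: {est.point:.3f} "
            f"({est.ci_low:.3f}-{est.ci_high:.3f}), n evaluable = {dfit.n} "
            f"(guarantee-time bias: follow-up starts at ICI initiation while "
            f"the decline is measured over the first 8 weeks)",
            f"Youden cutoff: {cut.cutoff:.1f}% decline (J = {cut.youden_j:.3f})",
        ]
    except Exception as exc:  # noqa: BLE001
        log.warning("decline stage failed: %s", exc)
        bundle["decline"] = {"error": str(exc)}

    report = "\n".join(sections) + "\n"
    (out / "report.txt").write_text(report)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "endpoint": config.endpoint,
        "provenance": cohort.provenance,
        "config_hash": hashlib.sha256(
            repr((config.endpoint, config.quartiles.cutoffs,
                  config.joint_spec, config.adjustment,
                  config.seed)).encode()).hexdigest()[:16],
        "python": sys.version.split()[0],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    bundle["report_text"] = report
    bundle["manifest"] = manifest
    if config.make_plots:
        make_figures(bundle, cohort, config)
    return bundle


def make_figures(bundle: dict, cohort: CohortTable,
                 config: PipelineConfig) -> list[str]:
    """One file per figure analog: ORR bar by quartile, KM by quartile,
    trajectory spaghetti with inverted time axis, risk profiles, decline KM."""
    out = Path(config.out_dir)
    written = []
    af = cohort.analysis_frame(config.endpoint, config.quartiles)

    # KM by quartile
    try:
        fig, ax = plt.subplots(figsize=(6, 4))
        for q in config.quartiles.labels:
            sub = af[af["crp_quartile"] == q]
            if sub.empty:
                continue
            km = km_fit(sub["time_months"].to_numpy(), sub["event"].to_numpy())
            ax.step(np.concatenate([[0], km.times]),
                    np.concatenate([[1], km.survival]), where="post", label=q)
        ax.set_xlabel("months since ICI start")
        ax.set_ylabel(f"{config.endpoint} probability")
        ax.set_ylim(0, 1.02)
        ax.legend(title="baseline CRP")
        fig.savefig(out / "km_by_quartile.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append("km_by_quartile.png")
    except Exception as exc:  # noqa: BLE001
        log.info("KM figure skipped: %s", exc)

    # ORR bar
    try:
        resp = af.dropna(subset=["baseline_crp", "response"])
        resp = resp[resp["response"] != "NE"]
        if not resp.empty:
            rate = resp.groupby("crp_quartile", observed=True)["response"] \
                .apply(lambda s: 100.0 * s.isin(["CR", "PR"]).mean())
            fig, ax = plt.subplots(figsize=(5, 4))
            rate.plot.bar(ax=ax, color="steelblue")
            ax.set_ylabel("ORR (%)")
            fig.savefig(out / "orr_by_quartile.png", dpi=120, bbox_inches="tight")
            plt.close(fig)
            written.append("orr_by_quartile.png")
    except Exception as exc:  # noqa: BLE001
        log.info("ORR figure skipped: %s", exc)

    # spaghetti with inverted time (time before event/censoring), split by
    # event status into two panels
    try:
        labs = cohort.labs.copy()
        labs["time_months"] = labs["time_days"] / DAYS_PER_MONTH
        ep = cohort.endpoints(config.endpoint).set_index("patient_id")
        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        for ax, flag, title in ((axes[0], False, "no event"),
                                (axes[1], True, "event")):
            pts_t, pts_y = [], []
            for pid, grp in labs.groupby("patient_id"):
                if pid not in ep.index or bool(ep.loc[pid, "event"]) != flag:
                    continue
                tb = grp["time_months"].to_numpy() - float(ep.loc[pid, "time_months"])
                y = np.log(grp["crp_mg_per_l"].to_numpy())
                ax.plot(tb, y, color="gray", alpha=0.3,
                        ls="--" if flag else "-", lw=0.7)
                pts_t.extend(tb); pts_y.extend(y)
            if len(pts_t) >= 5:
                smooth = lowess_trajectory(np.asarray(pts_t), np.asarray(pts_y),
                                           bandwidth=0.4)
                ax.plot(smooth["time"], smooth["smoothed"], "k",
                        ls="--" if flag else "-", lw=2)
            ax.set_title(title)
            ax.set_xlabel("months before event/censoring")
        axes[0].set_ylabel("log CRP (mg/L)")
        fig.savefig(out / "trajectories.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append("trajectories.png")
    except Exception as exc:  # noqa: BLE001
        log.info("trajectory figure skipped: %s", exc)

    # risk profiles
    try:
        profiles = bundle.get("prediction", {}).get("profiles")
        if profiles:
            fig, ax = plt.subplots(figsize=(5, 4))
            for prof in profiles:
                ax.plot(prof["horizon"], prof["risk"], marker="o",
                        label=prof["patient_id"].iloc[0])
            ax.set_xlabel("horizon (months)")
            ax.set_ylabel("conditional event risk")
            ax.legend()
            fig.savefig(out / "risk_profiles.png", dpi=120, bbox_inches="tight")
            plt.close(fig)
            written.append("risk_profiles.png")
    except Exception as exc:  # noqa: BLE001
        log.info("risk-profile figure skipped: %s", exc)

    # decline KM
    try:
        disp = bundle.get("decline", {}).get("km_display")
        if disp:
            fig, ax = plt.subplots(figsize=(5, 4))
            for name, km in disp["curves"].items():
                ax.step(np.concatenate([[0], km.times]),
                        np.concatenate([[1], km.survival]), where="post",
                        label=name)
            ax.set_xlabel("months since ICI start")
            ax.set_ylabel(f"{config.endpoint} probability")
            ax.legend()
            fig.savefig(out / "decline_km.png", dpi=120, bbox_inches="tight")
            plt.close(fig)
            written.append("decline_km.png")
    except Exception as exc:  # noqa: BLE001
        log.info("decline figure skipped: %s", exc)
    return written
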
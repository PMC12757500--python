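"""End-to-end pipeline: simulate -> preprocess -> train -> audit -> DCA.

``run_pipeline`` executes every stage from a single validated configuration
and persists the cohort CSV, out-of-fold predictions CSV, a metrics JSON
keyed by (strategy, group), reliability-bin and decision-curve CSVs, a
markdown report with the Table-2-shaped classification summary, and
(optionally) calibration / decision-curve plots.  Reruns with the same
configuration and seed reproduce byte-identical CSV/JSON outputs
(single-threaded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .decision_curve import curve_frame, decision_curve, default_grid
from .fairness_eval import (
    auc_ci,
    calibration_report,
    chi2_2x2,
    classification_rates,
    confusion_at_threshold,
    delong_auc_difference,
    fairness_gaps,
)
from .risk_models import MlpConfig, run_strategy, write_predictions_csv
from .synthetic_cohort import GeneratorConfig, generate_cohort, write_cohort_csv

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "render_plots"]

log = logging.getLogger("ckdfair")


@dataclass
class PipelineConfig:
    """Validated configuration of the full pipeline."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    model: MlpConfig = field(default_factory=MlpConfig)
    strategies: tuple = ("pooled", "modular")
    threshold: float = 0.30
    n_bins: int = 10
    dca_grid_start: float = 0.05
    dca_grid_stop: float = 0.50
    dca_grid_step: float = 0.01
    k_folds: int = 5
    seed: int = 42
    output_dir: str = "ckdfair_run"

    def validate(self) -> None:
        self.generator.validate()
        self.model.validate()
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0,1)")
        for s in self.strategies:
            if s not in ("pooled", "modular"):
                raise ValueError(f"unknown strategy {s!r}")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        """Build from a (YAML/JSON-loaded) dict, rejecting unknown keys."""
        raw = dict(raw)
        kwargs = {}
        if "generator" not in raw:
            raise ValueError('config is missing the required "generator" block')
        if "generator" in raw:
            gen_raw = dict(raw.pop("generator"))
            gen_fields = {f.name for f in dataclasses.fields(GeneratorConfig)}
            unknown = sorted(set(gen_raw) - gen_fields)
            if unknown:
                raise ValueError(f"unknown generator config keys: {unknown}")
            if "correlation_matrix" in gen_raw:
                gen_raw["correlation_matrix"] = np.asarray(
                    gen_raw["correlation_matrix"], dtype=float
                )
            kwargs["generator"] = GeneratorConfig(**gen_raw)
        if "model" in raw:
            model_raw = dict(raw.pop("model"))
            model_fields = {f.name for f in dataclasses.fields(MlpConfig)}
            unknown = sorted(set(model_raw) - model_fields)
            if unknown:
                raise ValueError(f"unknown model config keys: {unknown}")
            if "hidden_sizes" in model_raw:
                model_raw["hidden_sizes"] = tuple(model_raw["hidden_sizes"])
            kwargs["model"] = MlpConfig(**model_raw)
        own_fields = {f.name for f in dataclasses.fields(cls)} - {"generator", "model"}
        unknown = sorted(set(raw) - own_fields)
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {unknown}")
        if "strategies" in raw:
            raw["strategies"] = tuple(raw["strategies"])
        config = cls(**kwargs, **raw)
        config.validate()
        return config

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Propagate one global seed to every stochastic stage."""
        return dataclasses.replace(
            self,
            seed=seed,
            generator=dataclasses.replace(self.generator, seed=seed),
            model=dataclasses.replace(self.model, seed=seed),
        )

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))
        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything a run computed, recomputable from the persisted CSVs."""

    cohort_summary: dict
    metrics: dict
    dca: pd.DataFrame
    provenance: dict
    output_dir: str


def _cohort_summary(cohort: pd.DataFrame) -> dict:
    summary = {"n_total": int(len(cohort))}
    for race, grp in cohort.groupby("race"):
        summary[race] = {
            "n": int(len(grp)),
            "fraction": float(len(grp) / len(cohort)),
            "progression_rate": float(grp["progression"].mean()),
            "egfr_baseline_mean": float(grp["egfr_baseline"].mean()),
            "uacr_median": float(grp["uacr"].median()),
            "diabetes_prevalence": float(grp["diabetes"].mean()),
            "age_mean": float(grp["age"].mean()),
        }
    summary["overall_progression_rate"] = float(cohort["progression"].mean())
    summary["n_biomarker_subset"] = int(cohort["tnfr1"].notna().sum())
    return summary


def _round_floats(obj, ndigits=10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def evaluate_predictions(preds: pd.DataFrame, threshold: float = 0.30,
                         n_bins: int = 10) -> dict:
    """Discrimination / calibration / fairness metrics for one strategy.

    ``preds`` must be out-of-fold: each id exactly once.  Returns a dict
    keyed by group ("overall", then each race) plus Black-White gaps when
    both races are present.
    """
    if preds["id"].duplicated().any():
        raise ValueError(
            "predictions contain duplicate patient ids: metrics accept "
            "out-of-fold predictions only (one per patient)"
        )
    s = preds["risk"].to_numpy()
    y = preds["outcome"].to_numpy()
    folds = preds["fold"].to_numpy()
    out: dict = {}

    a, lo, hi = auc_ci(s, y)
    cal = calibration_report(s, y, n_bins=n_bins, folds=folds,
                             ids=preds["id"].to_numpy())
    counts = confusion_at_threshold(s, y, threshold, group="overall")
    rates = classification_rates(counts)
    out["overall"] = {
        "n": int(len(preds)),
        "event_rate": float(y.mean()),
        "auc": a, "auc_ci": [lo, hi],
        "citl_pp": cal.citl_pp, "slope": cal.slope,
        "slope_ci": list(cal.slope_ci), "ece": cal.ece, "brier": cal.brier,
        "tpr": rates.tpr, "fpr": rates.fpr, "ppv": rates.ppv,
        "flag_rate": rates.flag_rate,
        "counts": {"tp": counts.tp, "fp": counts.fp,
                   "tn": counts.tn, "fn": counts.fn},
        "threshold": threshold,
    }

    group_rates, group_auc, group_scores = {}, {}, {}
    for race, grp in preds.groupby("race"):
        gs, gy = grp["risk"].to_numpy(), grp["outcome"].to_numpy()
        ga, glo, ghi = auc_ci(gs, gy)
        gcal = calibration_report(gs, gy, n_bins=n_bins,
                                  folds=grp["fold"].to_numpy(),
                                  ids=grp["id"].to_numpy())
        gcounts = confusion_at_threshold(gs, gy, threshold, group=race)
        grates = classification_rates(gcounts)
        group_rates[race] = grates
        group_auc[race] = ga
        group_scores[race] = (gs, gy)
        out[race] = {
            "n": int(len(grp)),
            "event_rate": float(gy.mean()),
            "auc": ga, "auc_ci": [glo, ghi],
            "citl_pp": gcal.citl_pp, "slope": gcal.slope,
            "slope_ci": list(gcal.slope_ci), "ece": gcal.ece,
            "brier": gcal.brier,
            "tpr": grates.tpr, "fpr": grates.fpr, "ppv": grates.ppv,
            "flag_rate": grates.flag_rate,
            "counts": {"tp": gcounts.tp, "fp": gcounts.fp,
                       "tn": gcounts.tn, "fn": gcounts.fn},
            "threshold": threshold,
        }

    if {"Black", "White"} <= set(group_rates):
        sb, yb = group_scores["Black"]
        sw, yw = group_scores["White"]
        dl = delong_auc_difference(sb, yb, sw, yw)
        flag_chi2 = chi2_2x2(
            (group_rates["Black"].counts.tp + group_rates["Black"].counts.fp,
             group_rates["Black"].counts.tn + group_rates["Black"].counts.fn),
            (group_rates["White"].counts.tp + group_rates["White"].counts.fp,
             group_rates["White"].counts.tn + group_rates["White"].counts.fn),
        )
        gaps = fairness_gaps(
            group_rates["Black"], group_rates["White"],
            aucs=(group_auc["Black"], group_auc["White"]),
            delong=dl,
            event_chi2=chi2_2x2(
                (int(yb.sum()), int((1 - yb).sum())),
                (int(yw.sum()), int((1 - yw).sum())),
            ),
        )
        out["black_white_gaps"] = {
            "tpr_gap_pp": gaps.tpr_gap_pp,
            "fpr_gap_pp": gaps.fpr_gap_pp,
            "ppv_gap_pp": gaps.ppv_gap_pp,
            "flag_rate_gap_pp": gaps.flag_rate_gap_pp,
            "auc_gap": gaps.auc_gap,
            "delong_z": gaps.delong_z,
            "delong_p": gaps.delong_p,
            "event_rate_chi2": gaps.chi2_event_rate,
            "event_rate_chi2_p": gaps.chi2_event_rate_p,
            "flag_rate_chi2": flag_chi2[0],
            "flag_rate_chi2_p": flag_chi2[1],
        }
    return out


def _table2_markdown(metrics: dict, threshold: float) -> str:
    """Classification summary table, one row per strategy."""
    lines = [
        f"| Model | AUC White (95% CI) | AUC Black (95% CI) | TPR | FPR | PPV "
        f"| % labeled high-risk (>= {threshold:.0%}) |",
        "|---|---|---|---|---|---|---|",
    ]

    def pct(x):
        return "undef." if x is None else f"{100 * x:.1f}%"

    for strategy, m in metrics.items():
        if "White" not in m or "Black" not in m:
            continue
        w, b = m["White"], m["Black"]
        lines.append(
            f"| {strategy} "
            f"| {w['auc']:.3f} ({w['auc_ci'][0]:.3f}-{w['auc_ci'][1]:.3f}) "
            f"| {b['auc']:.3f} ({b['auc_ci'][0]:.3f}-{b['auc_ci'][1]:.3f}) "
            f"| {pct(w['tpr'])} (White) / {pct(b['tpr'])} (Black) "
            f"| {pct(w['fpr'])} (White) / {pct(b['fpr'])} (Black) "
            f"| {pct(w['ppv'])} (White) / {pct(b['ppv'])} (Black) "
            f"| {pct(w['flag_rate'])} (White) / {pct(b['flag_rate'])} (Black) |"
        )
        g = m.get("black_white_gaps")
        if g:
            ppv_cell = (
                "n/a" if g["ppv_gap_pp"] is None
                else f"{g['ppv_gap_pp']:+.1f} pp"
            )
            lines.append(
                f"| {strategy} gap (Black-White) | | {g['auc_gap']:+.3f} AUC "
                f"| {g['tpr_gap_pp']:+.1f} pp | {g['fpr_gap_pp']:+.1f} pp "
                f"| {ppv_cell} "
                f"| {g['flag_rate_gap_pp']:+.1f} pp |"
            )
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig, render: bool = False) -> RunReport:
    """Execute simulate -> train -> evaluate -> DCA and persist artifacts."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    log.info("stage=simulate n=%d seed=%d", config.generator.n_total, config.seed)
    cohort = generate_cohort(config.generator)
    write_cohort_csv(cohort, outdir / "cohort.csv")

    all_preds = []
    for strategy in config.strategies:
        log.info("stage=train strategy=%s k=%d", strategy, config.k_folds)
        preds = run_strategy(
            cohort, strategy, config.model, k=config.k_folds, seed=config.seed
        )
        all_preds.append(preds)
    preds = pd.concat(all_preds, ignore_index=True)
    write_predictions_csv(preds, outdir / "predictions.csv")

    log.info("stage=evaluate threshold=%.2f", config.threshold)
    metrics, bin_rows = {}, []
    for strategy in config.strategies:
        sp = preds[preds["strategy"] == strategy]
        metrics[strategy] = evaluate_predictions(
            sp, threshold=config.threshold, n_bins=config.n_bins
        )
        for race, grp in sp.groupby("race"):
            rep = calibration_report(
                grp["risk"].to_numpy(), grp["outcome"].to_numpy(),
                n_bins=config.n_bins, ids=grp["id"].to_numpy(),
            )
            for b in rep.bins:
                bin_rows.append({
                    "strategy": strategy, "race": race, "bin": b.index,
                    "n": b.n, "mean_predicted": b.mean_predicted,
                    "observed_rate": b.observed_rate,
                })
    bins_df = pd.DataFrame(bin_rows)
    bins_df.to_csv(outdir / "calibration_bins.csv", index=False,
                   float_format="%.12g")

    log.info("stage=dca grid=%.2f..%.2f", config.dca_grid_start, config.dca_grid_stop)
    grid = default_grid(config.dca_grid_start, config.dca_grid_stop,
                        config.dca_grid_step)
    dca = None
    for strategy in config.strategies:
        sp = preds[preds["strategy"] == strategy]
        points = decision_curve(sp["risk"].to_numpy(),
                                sp["outcome"].to_numpy(), grid)
        frame = curve_frame(points).rename(
            columns={"net_benefit": f"nb_{strategy}"}
        )
        dca = frame if dca is None else dca.merge(
            frame[["threshold", f"nb_{strategy}"]], on="threshold"
        )
    dca = dca.rename(columns={"treat_all": "nb_treat_all",
                              "treat_none": "nb_treat_none"})
    order = ["threshold"] + [f"nb_{s}" for s in config.strategies] + \
        ["nb_treat_all", "nb_treat_none"]
    dca = dca[order]
    dca.to_csv(outdir / "dca.csv", index=False, float_format="%.12g")

    summary = _cohort_summary(cohort)
    payload = _round_floats({
        "provenance": provenance,
        "cohort_summary": summary,
        "metrics": metrics,
    })
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)

    report_md = "\n".join([
        "# CKD progression risk-model fairness audit",
        "",
        f"Config hash `{provenance['config_hash']}`, seed {config.seed}, "
        f"ckdfair {__version__}.",
        "",
        "## Cohort",
        "",
        f"- n = {summary['n_total']} "
        f"(biomarker sub-cohort n = {summary['n_biomarker_subset']})",
    ] + [
        f"- {race}: n={summary[race]['n']} "
        f"({100 * summary[race]['fraction']:.0f}%), "
        f"progression {100 * summary[race]['progression_rate']:.1f}%, "
        f"eGFR mean {summary[race]['egfr_baseline_mean']:.1f}, "
        f"UACR median {summary[race]['uacr_median']:.0f} mg/g, "
        f"diabetes {100 * summary[race]['diabetes_prevalence']:.1f}%"
        for race in sorted(set(cohort["race"]))
    ] + [
        "",
        "## Discrimination and classification by race",
        "",
        _table2_markdown(metrics, config.threshold),
        "",
        "## Calibration-in-the-large (pp, predicted - observed)",
        "",
    ] + [
        f"- {strategy} / {race}: {metrics[strategy][race]['citl_pp']:+.2f} pp "
        f"(slope {metrics[strategy][race]['slope']:.2f}, "
        f"ECE {metrics[strategy][race]['ece']:.3f})"
        for strategy in config.strategies
        for race in sorted(set(cohort["race"]))
    ] + [
        "",
        "Artifacts: cohort.csv, predictions.csv, metrics.json, "
        "calibration_bins.csv, dca.csv",
        "",
    ])
    (outdir / "report.md").write_text(report_md)

    report = RunReport(
        cohort_summary=summary,
        metrics=metrics,
        dca=dca,
        provenance=provenance,
        output_dir=str(outdir),
    )
    if render:
        render_plots(str(outdir))
    return report


def render_plots(output_dir: str) -> list:
    """Render calibration (per race) and decision-curve plots from artifacts.

    Reads calibration_bins.csv and dca.csv previously written by
    ``run_pipeline``; writes PNG and SVG files and returns their paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(output_dir)
    bins_path = outdir / "calibration_bins.csv"
    dca_path = outdir / "dca.csv"
    for path in (bins_path, dca_path):
        if not path.exists():
            raise FileNotFoundError(f"missing run artifact: {path}")
    bins_df = pd.read_csv(bins_path)
    dca = pd.read_csv(dca_path)
    written = []

    for race, grp in bins_df.groupby("race"):
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.plot([0, 1], [0, 1], "--", color="grey", label="perfect calibration")
        for strategy, sg in grp.groupby("strategy"):
            sg = sg.sort_values("mean_predicted")
            ax.plot(sg["mean_predicted"], sg["observed_rate"], "o-",
                    label=strategy)
        ax.set_xlabel("Mean predicted 5-year risk")
        ax.set_ylabel("Observed progression rate")
        ax.set_title(f"Calibration by risk decile: {race} patients")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        ax.legend()
        for ext in ("png", "svg"):
            path = outdir / f"calibration_{race}.{ext}"
            fig.savefig(path, dpi=120, bbox_inches="tight")
            written.append(str(path))
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for col in dca.columns:
        if not col.startswith("nb_"):
            continue
        style = {"nb_treat_all": {"color": "red"},
                 "nb_treat_none": {"color": "black", "linestyle": "--"}}.get(col, {})
        ax.plot(dca["threshold"], dca[col], label=col[3:].replace("_", " "),
                **style)
    ax.set_xlabel("Risk threshold $p_t$")
    ax.set_ylabel("Net benefit (TP-equivalents per patient)")
    ax.set_title("Decision curve analysis")
    ax.set_ylim(-0.05, None)
    ax.legend()
    for ext in ("png", "svg"):
        path = outdir / f"decision_curve.{ext}"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        written.append(str(path))
    plt.close(fig)
    return written
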
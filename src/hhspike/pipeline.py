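"""End-to-end orchestration: generate/load -> dedup -> metrics -> synchrony ->
population statistics, with tabular outputs, figures and a run manifest.

The default configuration runs the complete analysis with the study's
constants: ±2.8 SD detection threshold, 1.1 ms capture window, 100 us
cross-channel duplicate rule, 2-s segments, 1/1024-s bins, 200 shuffles,
1-25 ms normalization window, 2 sp/s rate-class boundary, 10 ms ISI burst
threshold, SD = 1 s rate kernel and FDR control at q = 0.2.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .detect import remove_duplicate_spikes
from .dip import dip_test
from .metrics import burst_index, classify_rate, compute_unit_metrics, mean_firing_rate
from .model import Session, load_session, unit_count_table, write_session
from .popstats import (
    anesthesia_glm,
    binomial_fraction_test,
    covariate_frame,
    fast_pair_enrichment,
    fit_gmm_aic,
    heterogeneity_tests,
    residual_multimodality,
)
from .synchrony import CCGParams, analyze_all_pairs, pairs_dataframe
from .synth import PopulationConfig, generate_population

__all__ = ["RunConfig", "run_pipeline", "summarize"]

log = logging.getLogger("hhspike")


@dataclass
class RunConfig:
    """One of ``input_path`` / ``generator`` must be given, not both."""

    input_path: Optional[str] = None
    input_format: str = "csv"
    generator: Optional[PopulationConfig] = None
    ccg: CCGParams = field(default_factory=CCGParams)
    apply_dedup: bool = True
    kernel_sd_s: float = 1.0
    discharge_z: float = 4.0
    discharge_min_duration_s: float = 3.0
    dip_reference: int = 2000
    fdr_q: float = 0.2
    make_figures: bool = True
    out_dir: str = "hhspike_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("exactly one of input_path / generator must be set")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("generator") is not None:
            d["generator"] = PopulationConfig.from_dict(d["generator"])
        if d.get("ccg") is not None:
            ccg = dict(d["ccg"])
            if "norm_window_ms" in ccg:
                ccg["norm_window_ms"] = tuple(ccg["norm_window_ms"])
            d["ccg"] = CCGParams(**ccg)
        return cls(**d)


def _unit_metrics_frame(session: Session, cfg: RunConfig) -> pd.DataFrame:
    rows = []
    for ep in session.iter_epochs():
        for m in compute_unit_metrics(
            ep, cfg.kernel_sd_s, 0.1, cfg.discharge_z, cfg.discharge_min_duration_s
        ):
            rows.append(
                {
                    "patient_id": ep.patient_id,
                    "epoch_id": ep.epoch_id,
                    "unit_id": m.unit_id,
                    "mean_rate": m.mean_rate,
                    "burst_index": m.burst_index,
                    "rate_class": m.rate_class,
                    "n_discharges": len(m.discharge_events),
                    "discharge_events": ";".join(
                        f"{a:.1f}-{b:.1f}@{c:.2f}" for a, b, c in m.discharge_events
                    ),
                }
            )
    return pd.DataFrame(rows)


def _population_summary(units: pd.DataFrame, pairs: pd.DataFrame, session: Session,
                        cfg: RunConfig) -> dict:
    rates = units["mean_rate"].to_numpy()
    bisi = units["burst_index"].to_numpy()
    finite_b = bisi[np.isfinite(bisi)]
    out: dict = {
        "n_units": int(len(units)),
        "n_epochs": session.n_epochs,
        "n_patients": len(session.patients),
        "rate_mean": float(rates.mean()) if rates.size else float("nan"),
        "rate_median": float(np.median(rates)) if rates.size else float("nan"),
        "rate_sd": float(rates.std(ddof=1)) if rates.size > 1 else float("nan"),
        "n_slow": int((units["rate_class"] == "slow").sum()),
        "n_fast": int((units["rate_class"] == "fast").sum()),
        "n_discharge_units": int((units["n_discharges"] > 0).sum()),
    }
    if rates.size >= 8:
        gm_rate = fit_gmm_aic(rates, seed=cfg.seed)
        out["rate_mixture"] = {
            "n_components": gm_rate.n_components,
            "component_medians": gm_rate.component_medians.tolist(),
            "weights": gm_rate.weights.tolist(),
        }
        out["rate_dip_p"] = dip_test(rates, cfg.dip_reference, cfg.seed).p_value
    if finite_b.size >= 8:
        gm_b = fit_gmm_aic(finite_b, seed=cfg.seed)
        out["burst_mixture"] = {
            "n_components": gm_b.n_components,
            "component_medians": gm_b.component_medians.tolist(),
            "weights": gm_b.weights.tolist(),
        }
        out["burst_dip_p"] = dip_test(finite_b, cfg.dip_reference, cfg.seed).p_value
    ok = np.isfinite(bisi)
    if ok.sum() >= 3:
        out["rate_burst_pearson_rho"] = float(np.corrcoef(rates[ok], bisi[ok])[0, 1])
    if len(pairs):
        sig = pairs["significant"].astype(bool)
        out["n_pairs"] = int(len(pairs))
        out["n_significant_pairs"] = int(sig.sum())
        out["significant_pair_fraction"] = float(sig.mean())
        out["binomial_p_vs_chance"] = binomial_fraction_test(
            int(sig.sum()), len(pairs), cfg.ccg.alpha
        )
        if sig.any():
            out["positive_fraction_among_significant"] = float(
                (pairs.loc[sig, "sign"] == "positive").mean()
            )
        rate_class = dict(zip(units["unit_id"], units["rate_class"]))
        try:
            p_f, odds, table = fast_pair_enrichment(pairs, rate_class)
            out["fast_enrichment_fisher_p"] = p_f
            out["fast_enrichment_odds_ratio"] = odds
            out["fast_enrichment_table"] = table.tolist()
        except ValueError as exc:
            out["fast_enrichment_note"] = str(exc)
        try:
            out["heterogeneity"] = heterogeneity_tests(pairs)
        except ValueError as exc:
            out["heterogeneity_note"] = str(exc)
    # anesthesia covariates, if attached to the epochs
    covs = []
    unit_cov_rows = []
    for ep in session.iter_epochs():
        if ep.covariates is None:
            continue
        for tr in ep.trains:
            covs.append(ep.covariates)
            unit_cov_rows.append(tr.unit_id)
    if len(covs) >= 10:
        cov_df = covariate_frame(covs)
        rate_by_unit = dict(zip(units["unit_id"], units["mean_rate"]))
        y = np.array([rate_by_unit[u] for u in unit_cov_rows])
        report = anesthesia_glm(y, cov_df, cfg.fdr_q)
        out["glm"] = {
            "per_variable": report.per_variable.drop(columns=["note"]).to_dict("records"),
            "total_variance_fraction": report.total_variance_fraction,
            "residual_dip_p": residual_multimodality(
                report, cfg.dip_reference, cfg.seed
            ).p_value,
        }
    return out


def _figures(units: pd.DataFrame, pairs: pd.DataFrame, out: Path) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    made = []
    rates = units["mean_rate"]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(rates, bins=40, color="0.4")
    ax.set_xlabel("mean firing rate (sp/s)")
    ax.set_ylabel("units")
    fig.tight_layout()
    fig.savefig(out / "rate_hist.png", dpi=120)
    plt.close(fig)
    made.append("rate_hist.png")

    ok = np.isfinite(units["burst_index"])
    fig, ax = plt.subplots(figsize=(4.2, 4))
    ax.scatter(units.loc[ok, "mean_rate"], units.loc[ok, "burst_index"], s=8, alpha=0.6)
    ax.set_xlabel("mean firing rate (sp/s)")
    ax.set_ylabel("burst index")
    fig.tight_layout()
    fig.savefig(out / "rate_vs_burst.png", dpi=120)
    plt.close(fig)
    made.append("rate_vs_burst.png")

    if len(pairs):
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.hist(pairs["normalized_peak"].replace([np.inf, -np.inf], np.nan).dropna(),
                bins=40, color="0.4")
        ax.set_xlabel("normalized zero-delay peak")
        ax.set_ylabel("pairs")
        fig.tight_layout()
        fig.savefig(out / "peak_heights.png", dpi=120)
        plt.close(fig)
        made.append("peak_heights.png")

    fig, ax = plt.subplots(figsize=(6, 3.2))
    order = sorted(units["patient_id"].unique())
    data = [units.loc[units["patient_id"] == p, "mean_rate"] for p in order]
    ax.boxplot(data, tick_labels=order)
    ax.set_ylabel("mean firing rate (sp/s)")
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(out / "rates_by_patient.png", dpi=120)
    plt.close(fig)
    made.append("rates_by_patient.png")
    return made


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns the file map and in-memory results.

    Deterministic under a fixed seed: tabular outputs are byte-identical
    between repeated runs of the same configuration.
    """
    t_start = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "input"
    try:
        if cfg.generator is not None:
            result = generate_population(cfg.generator)
            session = result.session
            result.units.to_csv(out / "ground_truth_units.csv", index=False)
            result.pairs.to_csv(out / "ground_truth_pairs.csv", index=False)
            write_session(session, out / "session.csv", "csv")
        else:
            session = load_session(cfg.input_path, cfg.input_format)
        log.info("stage=input done n_units=%d", session.n_units)

        stage = "dedup"
        if cfg.apply_dedup:
            for ep in session.iter_epochs():
                ep.trains = remove_duplicate_spikes(ep.trains)
        log.info("stage=dedup done t=%.1fs", time.time() - t_start)

        stage = "metrics"
        units = _unit_metrics_frame(session, cfg)
        units.to_csv(out / "unit_metrics.csv", index=False, float_format="%.6g")
        log.info("stage=metrics done t=%.1fs", time.time() - t_start)

        stage = "synchrony"
        records = []
        for ep in session.iter_epochs():
            records.extend(analyze_all_pairs(ep, cfg.ccg))
        pairs = pairs_dataframe(records)
        pairs.to_csv(out / "pairs.csv", index=False, float_format="%.6g")
        log.info("stage=synchrony done n_pairs=%d t=%.1fs", len(pairs),
                 time.time() - t_start)

        stage = "population"
        summary = _population_summary(units, pairs, session, cfg)
        (out / "population.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True, default=float) + "\n"
        )
        unit_count_table(session).to_csv(out / "unit_counts.csv", index=False)

        stage = "figures"
        figures = _figures(units, pairs, out) if cfg.make_figures else []

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "config": {
                "input_path": cfg.input_path,
                "generator": cfg.generator.to_dict() if cfg.generator else None,
                "ccg": {
                    "segment_s": cfg.ccg.segment_s,
                    "bin_s": cfg.ccg.bin_s,
                    "n_permutations": cfg.ccg.n_permutations,
                    "norm_window_ms": list(cfg.ccg.norm_window_ms),
                    "alpha": cfg.ccg.alpha,
                    "seed": cfg.ccg.seed,
                    "statistic": cfg.ccg.statistic,
                    "peak_mode": cfg.ccg.peak_mode,
                },
                "apply_dedup": cfg.apply_dedup,
                "kernel_sd_s": cfg.kernel_sd_s,
                "fdr_q": cfg.fdr_q,
            },
            "outputs": ["unit_metrics.csv", "pairs.csv", "population.json",
                        "unit_counts.csv"] + figures,
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return {
        "out_dir": str(out),
        "units": units,
        "pairs": pairs,
        "summary": summary,
        "manifest": manifest,
    }


def summarize(summary: dict) -> str:
    """One-page text summary of a completed run."""
    lines = [
        "Recording summary",
        "-----------------",
        f"patients: {summary.get('n_patients', 0)}   epochs: {summary.get('n_epochs', 0)}"
        f"   units: {summary.get('n_units', 0)}",
        f"rate mean {summary.get('rate_mean', float('nan')):.2f} sp/s,"
        f" median {summary.get('rate_median', float('nan')):.2f} sp/s"
        f" (slow n={summary.get('n_slow', 0)}, fast n={summary.get('n_fast', 0)})",
    ]
    if "rate_mixture" in summary:
        med = ", ".join(f"{m:.3g}" for m in summary["rate_mixture"]["component_medians"])
        lines.append(
            f"rate mixture: {summary['rate_mixture']['n_components']} classes,"
            f" medians [{med}] sp/s (dip p = {summary.get('rate_dip_p', float('nan')):.3g})"
        )
    if "burst_mixture" in summary:
        med = ", ".join(f"{m:.3g}" for m in summary["burst_mixture"]["component_medians"])
        lines.append(
            f"burst mixture: {summary['burst_mixture']['n_components']} classes,"
            f" medians [{med}] (dip p = {summary.get('burst_dip_p', float('nan')):.3g})"
        )
    if "rate_burst_pearson_rho" in summary:
        lines.append(f"rate-burst Pearson rho = {summary['rate_burst_pearson_rho']:.2f}")
    if "n_pairs" in summary:
        lines.append(
            f"pairs: {summary['n_pairs']}, significant {summary['n_significant_pairs']}"
            f" ({100 * summary['significant_pair_fraction']:.0f}%),"
            f" binomial p vs chance = {summary['binomial_p_vs_chance']:.3g}"
        )
        if "positive_fraction_among_significant" in summary:
            lines.append(
                f"positive peaks among significant:"
                f" {100 * summary['positive_fraction_among_significant']:.0f}%"
            )
        if "fast_enrichment_fisher_p" in summary:
            lines.append(
                f"fast-pair enrichment: Fisher p = {summary['fast_enrichment_fisher_p']:.3g},"
                f" odds ratio {summary['fast_enrichment_odds_ratio']:.2f}"
            )
        if "heterogeneity" in summary:
            het = summary["heterogeneity"]
            lines.append(
                f"heterogeneity: between patients p = {het['between_patients_p']:.3g},"
                f" between epochs p = {het['between_epochs_p']:.3g}"
            )
    lines.append(f"units with evolving discharges: {summary.get('n_discharge_units', 0)}")
    if "glm" in summary:
        lines.append(
            f"anesthesia model: total variance fraction"
            f" {summary['glm']['total_variance_fraction']:.3f},"
            f" residual dip p = {summary['glm']['residual_dip_p']:.3g}"
        )
    return "\n".join(lines) + "\n"
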
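"""End-to-end orchestration: simulate/load, infer, validate, summarise.

``run_pipeline`` chains every stage on one configuration and emits a
machine-readable JSON summary plus CSV tables. Every number in the summary
is recomputable by calling the underlying module function on the logged
inputs; the run is deterministic given the configuration and seed.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as mqcluster
from . import errors as mqerrors
from . import noise as mqnoise
from . import stats as mqstats
from .inference import infer_table
from .io import (DETECTION_THRESHOLD, join_tables, read_abundance_table,
                 read_qpcr_table)
from .simulate import CohortConfig, simulate_cohort

logger = logging.getLogger("microquant")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage tag."""

    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    qpcr_path: str | None = None
    abundance_path: str | None = None
    simulation: CohortConfig | None = None
    detection_threshold: float = DETECTION_THRESHOLD
    join_tolerance_h: float = 1.0
    filter_fraction: float = 0.25
    rate_window_h: tuple[float, float] = (18.0, 36.0)
    error_cutoff: float = 0.5
    seed: int = 0
    output_dir: str | None = None
    cluster_max_samples: int = 400     # cap for the clustering stage

    def __post_init__(self):
        if self.simulation is None and (self.qpcr_path is None
                                        or self.abundance_path is None):
            raise ValueError("either a simulation config or both input paths required")
        if not 0 < self.filter_fraction < 1:
            raise ValueError("filter_fraction must lie in (0, 1)")
        lo, hi = self.rate_window_h
        if not 0 < lo < hi:
            raise ValueError("invalid rate window")
        if self.error_cutoff < 0:
            raise ValueError("error cutoff must be >= 0")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapper
    return deco


@_stage("load")
def _load(config: RunConfig):
    if config.simulation is not None:
        sim = config.simulation
        logger.info("simulating cohort: seed=%d", sim.seed)
        truth, qpcr, abund = simulate_cohort(sim)
        return truth, qpcr, abund
    qp = Path(config.qpcr_path)
    ap = Path(config.abundance_path)
    for p in (qp, ap):
        if not p.exists():
            raise FileNotFoundError(f"input not found: {p}")
    qpcr = read_qpcr_table(qp, detection_threshold=config.detection_threshold)
    abund = read_abundance_table(ap)
    return None, qpcr, abund


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the JSON-serialisable summary bundle.

    Also writes the per-record tables and the summary to ``output_dir``
    when one is configured.
    """
    truth, qpcr, abund = _load(config)

    @_stage("join")
    def stage_join():
        res = join_tables(qpcr, abund, tolerance_h=config.join_tolerance_h)
        if not res.pairs:
            raise ValueError("no samples could be paired")
        return res

    join_result = stage_join()

    @_stage("infer")
    def stage_infer():
        return infer_table(join_result.pairs)

    inferred = stage_infer()

    @_stage("validate")
    def stage_validate():
        records = mqerrors.build_error_records(inferred)
        pairs = mqerrors.compute_rate_pairs(records, *config.rate_window_h)
        return records, mqerrors.rate_pair_table(pairs)

    records, rates = stage_validate()

    @_stage("noise")
    def stage_noise():
        decomps = mqnoise.decompose_cohort(qpcr, fraction=config.filter_fraction)
        return mqnoise.summarize_noise(decomps) if decomps else pd.DataFrame()

    noise_summary = stage_noise()

    @_stage("stats")
    def stage_stats():
        return _stats_block(records, rates, config)

    stats_block = stage_stats()

    @_stage("cluster")
    def stage_cluster():
        return _cluster_block(records, config)

    cluster_block = stage_cluster()

    summary = {
        "config": _config_dict(config),
        "n_paired_samples": len(join_result.pairs),
        "n_unmatched_qpcr": len(join_result.unmatched_qpcr),
        "n_unmatched_abundance": len(join_result.unmatched_abundance),
        "error_summary": _error_block(records, rates, config),
        "noise_summary": (noise_summary.to_dict(orient="records")
                          if len(noise_summary) else []),
        "stats": stats_block,
        "clustering": cluster_block,
    }
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        inferred.to_csv(out / "inferred.csv", index=False)
        records.to_csv(out / "error_records.csv", index=False)
        rates.to_csv(out / "rate_pairs.csv", index=False)
        if len(noise_summary):
            noise_summary.to_csv(out / "noise_summary.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        _write_report(summary, out / "report.txt")
    return summary


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d


def _error_block(records, rates, config) -> dict:
    calls = records["call"].value_counts(normalize=True)
    nonzero = records[~records["ic_was_zero"]]
    attribution = {}
    for label, flag in (("including_double_negatives", True),
                        ("excluding_double_negatives", False)):
        try:
            frac = mqerrors.attribute_large_errors(
                records, cutoff=config.error_cutoff, include_double_negatives=flag)
            attribution[label] = {k: float(v) for k, v in frac.items()}
        except Exception:
            attribution[label] = {}
    per_species_fn = (records.assign(fn=records["call"] == "false_negative")
                      .groupby("taxon")["fn"].mean() * 100).to_dict()
    per_species_fp = (records.assign(fp=records["call"] == "false_positive")
                      .groupby("taxon")["fp"].mean() * 100).to_dict()
    # total-load-underestimate share, both readings of the denominator
    by_sample = records.groupby(["participant_id", "time_h"])["tbl_underestimate"].first()
    sign_ic = mqerrors.sign_error_rate(rates, which="ic")
    sign_ra = mqerrors.sign_error_rate(rates, which="ra")
    sign_ic_dp = mqerrors.sign_error_rate(rates, which="ic", include_single_positive=False)
    return {
        "n_records": int(len(records)),
        "call_fractions": {k: float(v) for k, v in calls.items()},
        "fn_rate_pct": float((records["call"] == "false_negative").mean() * 100),
        "fp_rate_pct": float((records["call"] == "false_positive").mean() * 100),
        "fn_rate_by_species_pct": {k: float(v) for k, v in per_species_fn.items()},
        "fp_rate_by_species_pct": {k: float(v) for k, v in per_species_fp.items()},
        "mean_ic_error_nonzero": float(nonzero["ic_error"].mean()) if len(nonzero) else None,
        "sd_ic_error_nonzero": float(nonzero["ic_error"].std()) if len(nonzero) else None,
        "large_error_attribution": attribution,
        "tbl_underestimate_pct_per_sample": float(by_sample.mean() * 100),
        "tbl_underestimate_pct_per_record": float(records["tbl_underestimate"].mean() * 100),
        "n_rate_pairs": int(len(rates)),
        "mean_ric_error": float(rates["ric_error"].mean()) if len(rates) else None,
        "sign_error_rate_ic_pct": None if np.isnan(sign_ic) else sign_ic * 100,
        "sign_error_rate_ra_pct": None if np.isnan(sign_ra) else sign_ra * 100,
        "sign_error_rate_ic_double_positive_only_pct":
            None if np.isnan(sign_ic_dp) else sign_ic_dp * 100,
    }


def _stats_block(records, rates, config) -> dict:
    x_ac = records["log10_ac"].to_numpy()
    r_ic, p_ic = mqstats.pearson(x_ac, records["log10_ic"].to_numpy())
    r_ra, p_ra = mqstats.pearson(x_ac, records["log10_ra"].to_numpy())
    r_cross, _ = mqstats.pearson(records["log10_ra"].to_numpy(),
                                 records["log10_ic"].to_numpy())
    hittner = mqstats.compare_overlapping_correlations(r_ra, r_ic, r_cross,
                                                       len(records))
    per_species = {}
    for taxon, grp in records.groupby("taxon"):
        try:
            rs, _ = mqstats.pearson(grp["log10_ac"].to_numpy(), grp["log10_ic"].to_numpy())
            rr, _ = mqstats.pearson(grp["log10_ac"].to_numpy(), grp["log10_ra"].to_numpy())
            fit = mqstats.linear_fit(grp["log10_ac"].to_numpy(), grp["log10_ic"].to_numpy())
            per_species[taxon] = {"r_ic": rs, "r_ra": rr,
                                  "intercept": fit.intercept, "slope": fit.slope}
        except ValueError:
            per_species[taxon] = None
    lm_ra, bp_p_ra = mqstats.breusch_pagan(records["log10_ra"].to_numpy(), x_ac)
    lm_ic, bp_p_ic = mqstats.breusch_pagan(records["log10_ic"].to_numpy(), x_ac)
    block = {
        "pooled": {
            "r_ic_vs_ac": r_ic, "p_ic_vs_ac": p_ic,
            "r_ra_vs_ac": r_ra, "p_ra_vs_ac": p_ra,
            "r_ra_vs_ic": r_cross,
            "hittner_z": hittner.z if np.isfinite(hittner.z) else None,
            "hittner_p": hittner.p if np.isfinite(hittner.p) else None,
            "n": int(len(records)),
        },
        "per_species": per_species,
        "breusch_pagan": {
            "ra_vs_ac": {"lm": lm_ra, "p": bp_p_ra},
            "ic_vs_ac": {"lm": lm_ic, "p": bp_p_ic},
        },
    }
    if len(rates) >= 3:
        r_rate_ic, p_rate_ic = mqstats.pearson(rates["rate_ac"], rates["rate_ic"])
        r_rate_ra, p_rate_ra = mqstats.pearson(rates["rate_ac"], rates["rate_ra"])
        block["rates"] = {"r_rate_ic_vs_ac": r_rate_ic, "p_rate_ic_vs_ac": p_rate_ic,
                          "r_rate_ra_vs_ac": r_rate_ra, "p_rate_ra_vs_ac": p_rate_ra}
        dp = rates[rates["transition"] == "double_positive"]
        if len(dp) >= 3 and dp["rate_ac"].nunique() > 1 and dp["rate_ic"].nunique() > 1:
            r_dp, p_dp = mqstats.pearson(dp["rate_ac"], dp["rate_ic"])
            block["rates"]["r_rate_ic_vs_ac_double_positive"] = r_dp
    return block


def _cluster_block(records, config) -> dict:
    wide_ac = records.pivot_table(index=["participant_id", "time_h"],
                                  columns="taxon", values="log10_ac")
    wide_ic = records.pivot_table(index=["participant_id", "time_h"],
                                  columns="taxon", values="log10_ic")
    wide_ac = wide_ac.dropna()
    wide_ic = wide_ic.loc[wide_ac.index]
    if len(wide_ac) < 4:
        return {"skipped": "fewer than 4 complete samples"}
    if len(wide_ac) > config.cluster_max_samples:
        # deterministic thinning keeps the stage tractable on large cohorts
        idx = np.linspace(0, len(wide_ac) - 1, config.cluster_max_samples).astype(int)
        wide_ac = wide_ac.iloc[idx]
        wide_ic = wide_ic.iloc[idx]
    labels = [f"{p}|{t:.0f}" for p, t in wide_ac.index]
    d_ac = mqcluster.cluster_samples(wide_ac.to_numpy(), labels=labels)
    d_ic = mqcluster.cluster_samples(wide_ic.to_numpy(), labels=labels)
    ent = mqcluster.entanglement(d_ac, d_ic)
    out = {"n_samples": int(len(wide_ac)),
           "entanglement_ac_vs_ic": float(ent)}
    try:
        out["k_ac"] = mqcluster.choose_k(d_ac, wide_ac.to_numpy())
        out["k_ic"] = mqcluster.choose_k(d_ic, wide_ic.to_numpy())
    except ValueError as exc:
        out["k_error"] = str(exc)
    return out


def _write_report(summary: dict, path) -> None:
    es = summary["error_summary"]
    st = summary["stats"]["pooled"]
    lines = [
        "microquant validation report",
        "============================",
        f"paired samples: {summary['n_paired_samples']}"
        f" (unmatched qPCR {summary['n_unmatched_qpcr']},"
        f" unmatched sequencing {summary['n_unmatched_abundance']})",
        "",
        f"pooled r (IC vs AC): {st['r_ic_vs_ac']:.3f}"
        f" (p {mqstats.format_p(st['p_ic_vs_ac'])})",
        f"pooled r (RA vs AC): {st['r_ra_vs_ac']:.3f}"
        f" (p {mqstats.format_p(st['p_ra_vs_ac'])})",
        f"Hittner test of the two: z = {st['hittner_z']:.3f},"
        f" p = {mqstats.format_p(st['hittner_p'])}",
        "",
        f"false negatives: {es['fn_rate_pct']:.2f}% of species-sample records",
        f"false positives: {es['fp_rate_pct']:.2f}%",
        f"total-load underestimates: {es['tbl_underestimate_pct_per_sample']:.1f}%"
        f" of samples ({es['tbl_underestimate_pct_per_record']:.1f}% per record)",
    ]
    attr = es["large_error_attribution"]
    for label, d in attr.items():
        if d:
            pretty = ", ".join(f"{k}: {100 * v:.0f}%" for k, v in d.items())
            lines.append(f"large-error attribution ({label.replace('_', ' ')}): {pretty}")
    if es["sign_error_rate_ic_pct"] is not None:
        lines += [
            "",
            f"sign-error rate, IC rates: {es['sign_error_rate_ic_pct']:.2f}%",
            f"sign-error rate, RA rates: {es['sign_error_rate_ra_pct']:.2f}%",
        ]
    cl = summary["clustering"]
    if "entanglement_ac_vs_ic" in cl:
        lines += ["", f"entanglement (AC vs IC dendrograms):"
                      f" {cl['entanglement_ac_vs_ic']:.3f}"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
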
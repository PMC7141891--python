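"""Synthetic longitudinal vaginal-microbiome cohorts with known ground truth.

The generator emulates the statistical structure the validation analyses
assume: ~20 participants self-sampling roughly daily for ~60 days, seven
focal species with targeted qPCR assays plus background taxa seen only by
sequencing, large within-participant dynamics (single species ranging over
many log10, total load over several log10), multinomial sequencing counts
at lognormal depth, multiplicative (log-normal) qPCR measurement error, and
detection-threshold censoring.

Latent per-taxon log10 trajectories follow a mean-reverting random walk
with occasional bloom/decay ramp events; an optional antibiotic window
forces exponential decline of designated BV-associated taxa. The latent
total load is the exact sum of taxon concentrations, so every downstream
identity (conservation, perfect-recovery limits) can be checked against
truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import DETECTION_THRESHOLD, AbundanceTable, QPCRTable

FOCAL_SPECIES = [
    "L_crispatus", "L_iners", "L_jensenii", "G_vaginalis",
    "A_vaginae", "BVAB2", "Megasphaera",
]
# BV-associated focal taxa targeted by the antibiotic window
BV_ASSOCIATED = ["G_vaginalis", "A_vaginae", "BVAB2", "Megasphaera"]
BACKGROUND_TAXA = [
    "Prevotella_bivia", "Prevotella_amnii", "Sneathia_amnii",
    "Dialister_micraerophilus", "Mobiluncus_curtisii", "Peptoniphilus_lacrimalis",
    "Anaerococcus_tetradius", "Finegoldia_magna", "Aerococcus_christensenii",
    "Parvimonas_micra", "Gemella_asaccharolytica", "Eggerthella_sp",
    "Atopobium_parvulum",
]


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort; defaults emulate the study design."""

    n_participants: int = 20
    duration_days: int = 60
    sampling_interval_h: float = 24.0
    sampling_jitter_h: float = 2.0
    n_focal_species: int = 7
    n_background_taxa: int = 13
    # latent trajectory model, log10 copies/swab
    baseline_log10_range: tuple[float, float] = (1.0, 7.5)
    reversion_rate_per_day: float = 0.08
    drift_sd_log10_per_day: float = 0.25
    bloom_rate_per_day: float = 0.015       # ramp events per taxon per day
    bloom_magnitude_log10: tuple[float, float] = (3.0, 6.5)
    bloom_duration_days: tuple[float, float] = (3.0, 10.0)
    log10_floor: float = -1.0
    log10_ceiling: float = 10.5
    # antibiotic perturbation: fraction of participants treated from day 0
    antibiotic_fraction: float = 0.25
    antibiotic_window_days: tuple[float, float] = (0.0, 7.0)
    antibiotic_decline_log10_per_day: float = 0.8
    # observation models
    depth_median: float = 23_304.0
    depth_log_sd: float = 0.5               # sd of ln(depth)
    sigma_q: float = 0.3                    # qPCR noise sd in log10 units
    detection_threshold: float = DETECTION_THRESHOLD
    censor: bool = True
    exact_fractions: bool = False           # infinite-depth limit for NGS
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1 or self.duration_days < 1:
            raise ValueError("cohort must have >= 1 participant and >= 1 day")
        for name in ("sigma_q", "drift_sd_log10_per_day", "bloom_rate_per_day",
                     "reversion_rate_per_day", "sampling_jitter_h",
                     "antibiotic_decline_log10_per_day", "depth_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.antibiotic_fraction <= 1:
            raise ValueError("antibiotic_fraction must be in [0, 1]")
        if self.n_focal_species > len(FOCAL_SPECIES):
            raise ValueError(f"at most {len(FOCAL_SPECIES)} focal species available")
        if self.n_background_taxa > len(BACKGROUND_TAXA):
            raise ValueError(f"at most {len(BACKGROUND_TAXA)} background taxa available")

    @property
    def focal_species(self) -> list[str]:
        return FOCAL_SPECIES[: self.n_focal_species]

    @property
    def taxa(self) -> list[str]:
        return self.focal_species + BACKGROUND_TAXA[: self.n_background_taxa]

    def to_dict(self):
        return asdict(self)


@dataclass
class GroundTruth:
    """Latent concentrations per participant/time/taxon; total load is their sum."""

    config: CohortConfig
    participants: list[str]
    times_h: dict[str, np.ndarray]          # sampling times per participant
    conc: dict[str, pd.DataFrame]           # participant -> time x taxon copies/swab
    treated: dict[str, bool] = field(default_factory=dict)

    def total_load(self, pid: str) -> np.ndarray:
        return self.conc[pid].to_numpy().sum(axis=1)

    def frame(self) -> pd.DataFrame:
        """Long-format latent table (participant, time_h, taxon, conc)."""
        rows = []
        for pid in self.participants:
            df = self.conc[pid]
            t = self.times_h[pid]
            for k, taxon in enumerate(df.columns):
                rows.append(pd.DataFrame({
                    "participant_id": pid, "time_h": t, "taxon": taxon,
                    "conc": df.iloc[:, k].to_numpy(),
                }))
        return pd.concat(rows, ignore_index=True)


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    # distinct deterministic streams for truth / NGS / qPCR observation
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, stream]))


def simulate_truth(config: CohortConfig) -> GroundTruth:
    """Simulate latent log10 trajectories for every participant and taxon.

    Mean-reverting random walk around a per-(participant, taxon) baseline,
    plus Poisson bloom/decay ramp events and, for treated participants, a
    forced decline of BV-associated taxa during the antibiotic window.
    Deterministic given the config seed.
    """
    rng = _rng(config, 0)
    taxa = config.taxa
    participants = [f"P{i + 1:02d}" for i in range(config.n_participants)]
    times_h: dict[str, np.ndarray] = {}
    conc: dict[str, pd.DataFrame] = {}
    treated: dict[str, bool] = {}
    n_treated = int(round(config.antibiotic_fraction * config.n_participants))
    treated_ids = set(participants[:n_treated])
    ab_lo, ab_hi = config.antibiotic_window_days
    for pid in participants:
        n_t = config.duration_days
        base_t = np.arange(n_t) * config.sampling_interval_h
        jitter = (rng.uniform(-config.sampling_jitter_h, config.sampling_jitter_h, n_t)
                  if config.sampling_jitter_h > 0 else np.zeros(n_t))
        jitter[0] = abs(jitter[0])  # enrollment time is non-negative
        t = base_t + jitter
        t = np.maximum.accumulate(t + np.arange(n_t) * 1e-9)  # strictly increasing
        times_h[pid] = t
        t_days = t / 24.0
        dt = np.diff(t_days, prepend=t_days[0])
        log10c = np.empty((n_t, len(taxa)))
        treated[pid] = pid in treated_ids
        for k, taxon in enumerate(taxa):
            base = rng.uniform(*config.baseline_log10_range)
            # bloom/decay ramp events: piecewise-linear slope field in log10/day
            slope = np.zeros(n_t)
            n_events = rng.poisson(config.bloom_rate_per_day * config.duration_days)
            for _ in range(n_events):
                start = rng.uniform(0, config.duration_days)
                dur = rng.uniform(*config.bloom_duration_days)
                mag = rng.uniform(*config.bloom_magnitude_log10)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                in_win = (t_days >= start) & (t_days < start + dur)
                slope[in_win] += sign * mag / dur
            if treated[pid] and taxon in BV_ASSOCIATED:
                in_ab = (t_days >= ab_lo) & (t_days < ab_hi)
                slope[in_ab] = -config.antibiotic_decline_log10_per_day
            x = base + (rng.normal(0, 0.5) if config.drift_sd_log10_per_day > 0 else 0.0)
            for i in range(n_t):
                if i > 0:
                    x = (x
                         + config.reversion_rate_per_day * (base - x) * dt[i]
                         + slope[i] * dt[i]
                         + rng.normal(0, config.drift_sd_log10_per_day * np.sqrt(max(dt[i], 1e-12))))
                if treated[pid] and taxon in BV_ASSOCIATED and ab_lo <= t_days[i] < ab_hi and i > 0:
                    # antibiotic kill dominates: strict decline, floor suspended
                    x = min(x, log10c[i - 1, k] - config.antibiotic_decline_log10_per_day * dt[i])
                    log10c[i, k] = min(x, config.log10_ceiling)
                else:
                    log10c[i, k] = np.clip(x, config.log10_floor, config.log10_ceiling)
        conc[pid] = pd.DataFrame(10.0 ** log10c, columns=taxa)
    return GroundTruth(config, participants, times_h, conc, treated)


def observe_ngs(truth: GroundTruth, config: CohortConfig | None = None) -> AbundanceTable:
    """Sequencing observation: lognormal depth, multinomial counts.

    Count probabilities are the latent concentrations divided by the latent
    total load. With ``exact_fractions`` the multinomial step is skipped and
    the exact latent fractions are recorded (the infinite-depth limit).
    """
    config = config or truth.config
    rng = _rng(config, 1)
    rows, ra_rows = [], []
    taxa = config.taxa
    for pid in truth.participants:
        c = truth.conc[pid].to_numpy()
        totals = c.sum(axis=1)
        probs = c / totals[:, None]
        for i, t in enumerate(truth.times_h[pid]):
            depth = max(1, int(round(rng.lognormal(np.log(config.depth_median),
                                                   config.depth_log_sd))))
            row = {"participant_id": pid, "time_h": float(t)}
            if config.exact_fractions:
                ra_rows.append({**row, **dict(zip(taxa, probs[i]))})
                rows.append({**row, "depth": float(depth)})
            else:
                counts = rng.multinomial(depth, probs[i] / probs[i].sum())
                rows.append({**row, **dict(zip(taxa, counts))})
    if config.exact_fractions:
        data = pd.DataFrame([{k: v for k, v in r.items() if k != "depth"} for r in rows])
        ra = pd.DataFrame(ra_rows)[taxa]
        data = pd.concat([data, ra], axis=1)
        depth = pd.Series([r["depth"] for r in rows], name="depth")
        return AbundanceTable(data, list(taxa), depth=depth, rel_abund=ra, from_counts=False)
    return AbundanceTable(pd.DataFrame(rows), list(taxa))


def observe_qpcr(truth: GroundTruth, config: CohortConfig | None = None) -> QPCRTable:
    """qPCR observation: independent log10-Gaussian noise per assay, censoring.

    The broad-range total-load assay and each targeted species assay get
    independent noise draws, so the measured total load can fall below the
    sum of measured species concentrations. Values at or below the detection
    threshold are stored at the threshold and flagged (when censoring is on).
    """
    config = config or truth.config
    rng = _rng(config, 2)
    species = config.focal_species
    rows = []
    for pid in truth.participants:
        c = truth.conc[pid]
        totals = truth.total_load(pid)
        for i, t in enumerate(truth.times_h[pid]):
            row = {"participant_id": pid, "time_h": float(t)}
            tbl = 10.0 ** (np.log10(totals[i]) + rng.normal(0, config.sigma_q))
            row["total_load"] = tbl
            for sp in species:
                val = 10.0 ** (np.log10(c[sp].iloc[i]) + rng.normal(0, config.sigma_q))
                if config.censor and val <= config.detection_threshold:
                    val = config.detection_threshold
                row[sp] = val
            rows.append(row)
    df = pd.DataFrame(rows)
    table = QPCRTable(df, list(species), detection_threshold=config.detection_threshold)
    if not config.censor:
        # disable the at-threshold flag entirely in the uncensored limit
        table.below_threshold[:] = False
    return table


def simulate_cohort(config: CohortConfig):
    """Convenience wrapper: (truth, qpcr_table, abundance_table)."""
    truth = simulate_truth(config)
    return truth, observe_qpcr(truth, config), observe_ngs(truth, config)
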
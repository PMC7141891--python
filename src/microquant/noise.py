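"""Low-pass Fourier decomposition of longitudinal log10 concentration series.

Each per-participant, per-taxon series of log10 qPCR values is split into a
slow "signal" (the lowest fraction of discrete-Fourier frequency bins, DC
always retained) and a residual "noise" attributed to sampling and
laboratory variability. Because the DC bin stays in the signal, the noise
of every series has exactly zero mean; its variance summarises the
measurement noise floor.

The DFT needs a regular time grid; series with missing days are linearly
interpolated in log10 space onto the median sampling interval, and the
interpolated points are masked out of noise summaries so interpolation
cannot manufacture zero-noise samples.

For an iid (white) noise component the residual band holds only the
removed fraction of the spectrum, so the raw residual variance
underestimates the full noise variance; ``noise_variance_corrected``
divides by the removed-bin fraction and is the unbiased estimator of an
iid noise variance.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["NoiseDecomposition", "lowpass_decompose", "decompose_cohort",
           "summarize_noise"]

DEFAULT_FILTER_FRACTION = 0.25
MIN_SERIES_LENGTH = 8


@dataclass
class NoiseDecomposition:
    """Signal/noise split of one longitudinal log10 series."""

    times: np.ndarray
    data: np.ndarray
    signal: np.ndarray
    noise: np.ndarray
    filter_fraction: float
    interpolated: np.ndarray            # mask: grid points not actually observed
    removed_bin_fraction: float         # share of DFT bins zeroed out
    taxon: str | None = None
    participant_id: str | None = None
    censored: np.ndarray | None = None  # mask of at-threshold inputs

    noise_mean: float = field(init=False)
    noise_variance: float = field(init=False)
    noise_variance_corrected: float = field(init=False)

    def __post_init__(self):
        obs = self.noise[~self.interpolated]
        self.noise_mean = float(obs.mean())
        self.noise_variance = float(obs.var())
        self.noise_variance_corrected = (
            self.noise_variance / self.removed_bin_fraction
            if self.removed_bin_fraction > 0 else float("nan"))


def _regular_grid(times, values, censored=None):
    """Interpolate onto a regular grid at the median sampling interval."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    steps = np.diff(times)
    if np.any(steps <= 0):
        raise ValueError("times must be strictly increasing")
    step = float(np.median(steps))
    # already regular (to 1% of a step): use as-is
    if np.allclose(steps, step, rtol=0.01, atol=step * 0.01):
        interp_mask = np.zeros(len(times), dtype=bool)
        cens = (np.zeros(len(times), dtype=bool) if censored is None
                else np.asarray(censored, dtype=bool))
        return times, values, interp_mask, cens
    n = int(round((times[-1] - times[0]) / step)) + 1
    grid = times[0] + np.arange(n) * step
    gridded = np.interp(grid, times, values)
    # a grid point counts as observed if a real sample lies within step/4
    dist = np.min(np.abs(grid[:, None] - times[None, :]), axis=1)
    interp_mask = dist > step / 4.0
    cens = np.zeros(n, dtype=bool)
    if censored is not None:
        censored = np.asarray(censored, dtype=bool)
        nearest = np.argmin(np.abs(grid[:, None] - times[None, :]), axis=1)
        cens = censored[nearest] & ~interp_mask
    return grid, gridded, interp_mask, cens


def lowpass_decompose(times, values, fraction=DEFAULT_FILTER_FRACTION,
                      censored=None, taxon=None, participant_id=None,
                      interpolate=True) -> NoiseDecomposition:
    """Split a log10 series into low-frequency signal and residual noise.

    Of the DFT frequency bins, the zero-frequency bin plus all bins with
    frequency index ``j <= floor(fraction * n/2)`` are retained as signal;
    everything above is the noise band. Requires at least 8 points; an
    irregular grid is linearly interpolated first unless ``interpolate``
    is disabled.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) != len(values):
        raise ValueError("times and values must have equal length")
    if len(values) < MIN_SERIES_LENGTH:
        raise ValueError(f"series too short (< {MIN_SERIES_LENGTH} points)")
    if not 0 < fraction < 1:
        raise ValueError("filter fraction must lie in (0, 1)")
    if interpolate:
        grid, data, interp_mask, cens = _regular_grid(times, values, censored)
    else:
        steps = np.diff(times)
        if not np.allclose(steps, np.median(steps), rtol=0.01,
                           atol=float(np.median(steps)) * 0.01):
            raise ValueError("irregular time grid; enable interpolation")
        grid, data = times, values
        interp_mask = np.zeros(len(times), dtype=bool)
        cens = (np.zeros(len(times), dtype=bool) if censored is None
                else np.asarray(censored, dtype=bool))
    n = len(data)
    spec = np.fft.rfft(data)
    kmax = int(np.floor(fraction * (n / 2.0)))        # highest retained bin index
    keep = np.zeros(len(spec), dtype=bool)
    keep[: kmax + 1] = True                           # DC always kept
    # count of full-spectrum coefficients zeroed (conjugate pairs count twice)
    removed = 0
    for j in range(1, len(spec)):
        if not keep[j]:
            removed += 1 if (n % 2 == 0 and j == n // 2) else 2
    signal = np.fft.irfft(np.where(keep, spec, 0.0), n=n)
    noise = data - signal
    return NoiseDecomposition(
        times=grid, data=data, signal=signal, noise=noise,
        filter_fraction=fraction, interpolated=interp_mask,
        removed_bin_fraction=removed / n, taxon=taxon,
        participant_id=participant_id, censored=cens)


def decompose_cohort(qpcr_table, fraction=DEFAULT_FILTER_FRACTION,
                     include_total_load=True,
                     exclude_censored_runs=False) -> list[NoiseDecomposition]:
    """Decompose every (participant, assay) log10 series of a qPCR table.

    ``exclude_censored_runs`` drops series in which more than half of the
    values sit at the detection threshold (a sensitivity toggle; censored
    values otherwise enter the filter at the threshold, flagged).
    """
    out = []
    assays = (["total_load"] if include_total_load else []) + list(qpcr_table.species)
    for pid, grp in qpcr_table.data.groupby("participant_id", sort=False):
        t = grp["time_h"].to_numpy(dtype=float)
        if len(t) < MIN_SERIES_LENGTH:
            continue
        for assay in assays:
            vals = np.log10(np.maximum(grp[assay].to_numpy(dtype=float),
                                       qpcr_table.detection_threshold))
            if assay == "total_load":
                cens = np.zeros(len(t), dtype=bool)
            else:
                idx = grp.index
                cens = qpcr_table.below_threshold.loc[idx, assay].to_numpy(dtype=bool)
            if exclude_censored_runs and cens.mean() > 0.5:
                continue
            out.append(lowpass_decompose(t, vals, fraction, censored=cens,
                                         taxon=assay, participant_id=pid))
    return out


def summarize_noise(decompositions) -> pd.DataFrame:
    """Pooled noise mean and variance per taxon across participants.

    Interpolated grid points are excluded. Raises if the input is empty.
    """
    if not decompositions:
        raise ValueError("no decompositions to summarize")
    rows = {}
    for d in decompositions:
        rows.setdefault(d.taxon, []).append(d.noise[~d.interpolated])
    recs = []
    for taxon, chunks in rows.items():
        pooled = np.concatenate(chunks)
        corr = [d.removed_bin_fraction for d in decompositions if d.taxon == taxon]
        mean_removed = float(np.mean(corr))
        var = float(pooled.var())
        recs.append({
            "taxon": taxon, "n": len(pooled),
            "noise_mean": float(pooled.mean()),
            "noise_variance": var,
            "noise_variance_corrected": var / mean_removed if mean_removed > 0 else np.nan,
        })
    return pd.DataFrame(recs)
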
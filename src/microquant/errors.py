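"""IC-error statistics, call classification, attribution and kinetic rates.

The validation of inferred concentrations (IC) against targeted-qPCR
absolute concentrations (AC) rests on:

* the IC error, ``log10(AC) - log10(IC)`` on mapped values, positive when
  the inference underestimates;
* a four-way call classification from the raw (unmapped) values:
  false positive (IC > 0 while AC at/below the detection threshold),
  false negative (IC = 0 while AC above threshold), double negative
  (both negative), true positive otherwise;
* attribution of large errors (|IC error| > 0.5 log10) to relative-
  abundance bins, with and without double negatives;
* a flag for samples whose broad-range total load falls below the sum of
  the targeted species concentrations (total-load underestimates);
* per-day rates of change between consecutive samples 18-36 h apart, the
  rIC error (rate(AC) - rate(IC)) and transition classes from the IC-zero
  flags of the two endpoints.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DETECTION_THRESHOLD
from .inference import log_map_concentration, threshold_floor_qpcr

__all__ = [
    "ic_error", "classify_call", "ra_bin", "build_error_records",
    "attribute_large_errors", "flag_tbl_underestimate", "RatePair",
    "compute_rate_pairs", "rate_pair_table", "sign_error_rate",
]

RA_BIN_LABELS = ["<1%", "1-10%", ">=10%"]
CALL_CLASSES = ["true_positive", "false_positive", "false_negative", "double_negative"]

RATE_WINDOW_H = (18.0, 36.0)


def ic_error(ac, ic, threshold=DETECTION_THRESHOLD, depth=None):
    """IC error = log10(AC) - log10(IC) on mapped values, in log10 copies/swab.

    AC is floored at the detection threshold; zero IC maps to 1 copy/swab.
    Positive values mean the inferred concentration underestimates.
    """
    out = threshold_floor_qpcr(ac, threshold) - log_map_concentration(ic)
    return out


def classify_call(ic, ac, threshold=DETECTION_THRESHOLD):
    """Four-way call class from raw (unmapped) IC and AC values."""
    ic = np.asarray(ic, dtype=float)
    ac = np.asarray(ac, dtype=float)
    ic_pos = ic > 0
    ac_pos = ac > threshold
    out = np.where(ic_pos & ac_pos, "true_positive",
          np.where(ic_pos & ~ac_pos, "false_positive",
          np.where(~ic_pos & ac_pos, "false_negative", "double_negative")))
    return str(out) if out.ndim == 0 else out


def ra_bin(ra):
    """Half-open relative-abundance bins [0,1%), [1%,10%), [10%,100%]."""
    ra = np.asarray(ra, dtype=float)
    out = np.where(ra < 0.01, RA_BIN_LABELS[0],
          np.where(ra < 0.10, RA_BIN_LABELS[1], RA_BIN_LABELS[2]))
    return str(out) if out.ndim == 0 else out


def build_error_records(inferred: pd.DataFrame) -> pd.DataFrame:
    """Per (sample, species) error records from an inferred-concentration table.

    Keeps only rows with a targeted-qPCR value (``ac`` present); adds
    ``ic_error``, ``call``, ``ra_bin`` and the total-load-underestimate flag.
    """
    df = inferred.dropna(subset=["ac"]).copy()
    thr = df["detection_threshold"].to_numpy()
    df["ic_error"] = ic_error(df["ac"].to_numpy(), df["ic"].to_numpy(), thr)
    df["call"] = classify_call(df["ic"].to_numpy(), df["ac"].to_numpy(), thr)
    df["ra_bin"] = ra_bin(df["rel_abund"].to_numpy())
    ac_sum = df.groupby(["participant_id", "time_h"])["ac"].transform("sum")
    df["tbl_underestimate"] = df["total_load"].to_numpy() < ac_sum.to_numpy()
    return df.reset_index(drop=True)


def attribute_large_errors(records: pd.DataFrame, cutoff=0.5,
                           include_double_negatives=True) -> pd.Series:
    """Fraction of large IC errors (|error| > cutoff) per relative-abundance bin.

    ``include_double_negatives=False`` drops samples that were negative by
    both assays before attributing.
    """
    df = records
    if not include_double_negatives:
        df = df[df["call"] != "double_negative"]
    big = df[df["ic_error"].abs() > cutoff]
    if len(big) == 0:
        warnings.warn("no IC errors exceed the cutoff; empty attribution")
        return pd.Series(dtype=float, name="fraction")
    frac = big["ra_bin"].value_counts(normalize=True)
    return frac.reindex(RA_BIN_LABELS, fill_value=0.0).rename("fraction")


def flag_tbl_underestimate(total_load, species_conc) -> bool:
    """True iff the broad-range total load is strictly below the species sum."""
    species_conc = np.asarray(list(species_conc.values())
                              if isinstance(species_conc, dict) else species_conc,
                              dtype=float)
    return bool(float(total_load) < species_conc.sum())


# ---------------------------------------------------------------------------
# Rates of change
# ---------------------------------------------------------------------------

@dataclass
class RatePair:
    """Two time-adjacent samples of one species with per-day rates of change."""

    participant_id: str
    taxon: str
    t1_h: float
    t2_h: float
    rate_ac: float          # log10 per day, on mapped values
    rate_ic: float
    rate_ra: float
    ric_error: float        # rate_ac - rate_ic
    transition: str         # double_positive | single_positive | double_negative

    @property
    def gap_h(self) -> float:
        return self.t2_h - self.t1_h


def _select_consecutive(times, min_gap, max_gap):
    """Index pairs for rate computation: one step per pair, nearest to 24 h.

    From each starting sample the future sample inside the gap window whose
    gap is closest to 24 h is paired; other in-window candidates are
    skipped, and the walk continues from the paired sample.
    """
    pairs = []
    i, n = 0, len(times)
    while i < n - 1:
        gaps = times[i + 1:] - times[i]
        cand = np.where((gaps >= min_gap) & (gaps <= max_gap))[0]
        if len(cand) == 0:
            i += 1
            continue
        j = i + 1 + cand[np.argmin(np.abs(gaps[cand] - 24.0))]
        pairs.append((i, j))
        i = j
    return pairs


def compute_rate_pairs(records: pd.DataFrame,
                       min_gap_h=RATE_WINDOW_H[0],
                       max_gap_h=RATE_WINDOW_H[1]) -> list[RatePair]:
    """Per-day rates of change between consecutive samples 18-36 h apart.

    ``records`` is the per-(sample, species) error-record table (it carries
    the mapped log10 values and IC-zero flags). Rates are differences of
    mapped log10 values divided by the gap in days; the rIC error is
    rate(AC) - rate(IC). Transition classes come from the IC-zero flags of
    the two endpoints.
    """
    out: list[RatePair] = []
    for (pid, taxon), grp in records.groupby(["participant_id", "taxon"], sort=False):
        t = grp["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            raise ValueError(f"series for ({pid}, {taxon}) is not time-sorted")
        log_ac = grp["log10_ac"].to_numpy(dtype=float)
        log_ic = grp["log10_ic"].to_numpy(dtype=float)
        log_ra = grp["log10_ra"].to_numpy(dtype=float)
        zero = grp["ic_was_zero"].to_numpy(dtype=bool)
        for i, j in _select_consecutive(t, min_gap_h, max_gap_h):
            dt_days = (t[j] - t[i]) / 24.0
            r_ac = (log_ac[j] - log_ac[i]) / dt_days
            r_ic = (log_ic[j] - log_ic[i]) / dt_days
            r_ra = (log_ra[j] - log_ra[i]) / dt_days
            n_zero = int(zero[i]) + int(zero[j])
            transition = ("double_positive", "single_positive", "double_negative")[n_zero]
            out.append(RatePair(pid, taxon, float(t[i]), float(t[j]),
                                r_ac, r_ic, r_ra, r_ac - r_ic, transition))
    return out


def rate_pair_table(pairs: list[RatePair]) -> pd.DataFrame:
    return pd.DataFrame([{
        "participant_id": p.participant_id, "taxon": p.taxon,
        "t1_h": p.t1_h, "t2_h": p.t2_h, "gap_h": p.gap_h,
        "rate_ac": p.rate_ac, "rate_ic": p.rate_ic, "rate_ra": p.rate_ra,
        "ric_error": p.ric_error, "transition": p.transition,
    } for p in pairs])


def sign_error_rate(pairs, which="ic", include_single_positive=True) -> float:
    """Fraction of rate pairs whose inferred and qPCR rates have opposite signs.

    Zero rates never count as opposite; only strict sign opposition
    contributes (quadrant membership excludes the axes). ``which`` selects
    the inferred-side rate ("ic" or "ra").
    """
    df = pairs if isinstance(pairs, pd.DataFrame) else rate_pair_table(pairs)
    if len(df) == 0:
        return float("nan")
    if not include_single_positive:
        df = df[df["transition"] != "single_positive"]
        if len(df) == 0:
            return float("nan")
    other = df["rate_ic"] if which == "ic" else df["rate_ra"]
    opposite = np.sign(df["rate_ac"]) * np.sign(other) < 0
    return float(opposite.mean())
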
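"""Inferred concentrations and the log-scale zero mappings.

The central estimator: a species' absolute concentration can be inferred
from sequencing alone as

    IC = RA x TBL

where RA is the taxon's relative abundance (a fraction) and TBL the total
bacterial load from broad-range qPCR (16S rRNA gene copies per swab).
Because RA is a fraction, the inferred concentrations of a sample's taxa
sum exactly to the measured total load.

Working on a log10 scale requires mapping zeros to finite values:

* zero relative abundance maps to 1/depth (one read's worth), the smallest
  fraction the sequencing run could have resolved;
* zero inferred concentration maps to 1 copy/swab (log10 = 0);
* targeted-qPCR values are floored at the assay detection threshold.

A ``was_zero`` flag is carried alongside mapped values so that call
classification never has to guess whether a mapped value was a true zero.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DETECTION_THRESHOLD, PairedSample

__all__ = [
    "infer_concentration", "log_map_abundance", "log_map_concentration",
    "threshold_floor_qpcr", "InferredProfile", "infer_profile", "infer_table",
]


def infer_concentration(ra, tbl):
    """Inferred concentration IC = RA x TBL, in copies/swab.

    ``ra`` is a fraction in [0, 1] (scalar or array); ``tbl`` the total
    bacterial load in 16S copies/swab.
    """
    ra = np.asarray(ra, dtype=float)
    tbl = np.asarray(tbl, dtype=float)
    if np.any(ra < 0) or np.any(ra > 1 + 1e-12):
        raise ValueError("relative abundance must lie in [0, 1]")
    if np.any(tbl < 0):
        raise ValueError("total load must be non-negative")
    out = ra * tbl
    return float(out) if out.ndim == 0 else out


def log_map_abundance(ra, depth):
    """log10 relative abundance with zeros mapped to 1/depth."""
    depth = np.asarray(depth, dtype=float)
    if np.any(depth <= 0):
        raise ValueError("sequencing depth must be positive")
    ra = np.asarray(ra, dtype=float)
    out = np.where(ra > 0, np.log10(np.where(ra > 0, ra, 1.0)), -np.log10(depth))
    return float(out) if out.ndim == 0 else out


def log_map_concentration(ic):
    """log10 inferred concentration with zeros mapped to 1 copy/swab (log10 = 0)."""
    ic = np.asarray(ic, dtype=float)
    if np.any(ic < 0):
        raise ValueError("concentration must be non-negative")
    out = np.where(ic > 0, np.log10(np.where(ic > 0, ic, 1.0)), 0.0)
    return float(out) if out.ndim == 0 else out


def threshold_floor_qpcr(ac, threshold=DETECTION_THRESHOLD):
    """log10 targeted-qPCR value floored at the detection threshold."""
    threshold = np.asarray(threshold, dtype=float)
    if np.any(threshold <= 0):
        raise ValueError("threshold must be positive")
    ac = np.asarray(ac, dtype=float)
    out = np.log10(np.maximum(ac, threshold))
    return float(out) if out.ndim == 0 else out


@dataclass
class InferredProfile:
    """Per-taxon inferred concentrations for one sample, with mapped logs."""

    participant_id: str
    time_h: float
    total_load: float
    depth: float
    taxa: list[str]
    ic: np.ndarray
    ic_was_zero: np.ndarray        # boolean; true where RA (hence IC) was exactly 0
    log10_ic: np.ndarray
    log10_ra: np.ndarray
    log10_ac: dict[str, float]     # floored, only for taxa with a targeted assay


def infer_profile(pair: PairedSample) -> InferredProfile:
    ic = infer_concentration(pair.rel_abund, pair.total_load)
    was_zero = pair.rel_abund == 0
    return InferredProfile(
        participant_id=pair.participant_id,
        time_h=pair.time_h,
        total_load=pair.total_load,
        depth=pair.depth,
        taxa=list(pair.taxa),
        ic=np.atleast_1d(ic),
        ic_was_zero=was_zero,
        log10_ic=np.atleast_1d(log_map_concentration(ic)),
        log10_ra=np.atleast_1d(log_map_abundance(pair.rel_abund, pair.depth)),
        log10_ac={sp: threshold_floor_qpcr(v, pair.detection_threshold)
                  for sp, v in pair.abs_conc.items()},
    )


def infer_table(pairs: list[PairedSample]) -> pd.DataFrame:
    """Long-format inferred-concentration table over a list of paired samples.

    One row per (sample, taxon) with the raw and log-mapped quantities; the
    ``ac`` columns are NaN for taxa observed only by sequencing.
    """
    rows = []
    for pair in pairs:
        prof = infer_profile(pair)
        for k, taxon in enumerate(prof.taxa):
            ac = pair.abs_conc.get(taxon, np.nan)
            rows.append({
                "participant_id": prof.participant_id,
                "time_h": prof.time_h,
                "taxon": taxon,
                "total_load": prof.total_load,
                "depth": prof.depth,
                "count": np.nan if pair.counts is None else pair.counts[k],
                "rel_abund": pair.rel_abund[k],
                "ic": prof.ic[k],
                "ic_was_zero": bool(prof.ic_was_zero[k]),
                "log10_ic": prof.log10_ic[k],
                "log10_ra": prof.log10_ra[k],
                "ac": ac,
                "ac_censored": pair.ac_censored.get(taxon, np.nan),
                "log10_ac": prof.log10_ac.get(taxon, np.nan),
                "detection_threshold": pair.detection_threshold,
            })
    return pd.DataFrame(rows)
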
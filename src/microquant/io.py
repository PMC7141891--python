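"""Readers, writers and the paired data model for qPCR and amplicon abundance tables.

Two measurement tables underlie every analysis in this package:

* a qPCR table holding, per participant and sampling time, the total
  bacterial load measured by broad-range 16S qPCR (``total_load``) and the
  absolute concentration of each assayed species (16S rRNA gene copies per
  swab);
* an abundance table holding per-sample amplicon read counts (or relative
  abundances) for every taxon observed by sequencing.

The two are joined on (participant, time) into :class:`PairedSample`
records, the analysis-ready unit consumed by the inference and validation
modules.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("microquant")

# Censoring floor used throughout the error analyses, in 16S copies/swab.
DETECTION_THRESHOLD = 93.8
# Assay limits of quantification, kept as metadata only (not used as floors).
LOQ_TARGETED_QPCR = 2.5
LOQ_BROAD_RANGE_QPCR = 10.0

DEFAULT_JOIN_TOLERANCE_H = 1.0

_PARTICIPANT_ALIASES = {"participant", "participant_id", "subject", "subject_id", "pid"}
_TIME_H_ALIASES = {"time_h", "time_hours", "hour", "hours", "h"}
_TIME_D_ALIASES = {"time_d", "time_days", "day", "days", "d"}
_TBL_ALIASES = {"total_load", "tbl", "br16s", "total", "total_bacterial_load"}
_TAXON_ALIASES = {"taxon", "species", "otu", "asv"}
_COUNT_ALIASES = {"count", "counts", "reads"}
_RA_ALIASES = {"rel_abund", "relative_abundance", "ra", "fraction"}
_RA_PCT_ALIASES = {"rel_abund_pct", "percent", "ra_pct", "relative_abundance_pct"}


class SchemaError(ValueError):
    """A required column or header is missing or the file is empty."""


class ValidationError(ValueError):
    """Parsed values violate a table invariant."""


class AmbiguousJoinError(ValueError):
    """More than one row of one table matches a row of the other within tolerance."""


def _find_column(columns, aliases, what, required=True):
    hits = [c for c in columns if c.strip().lower() in aliases]
    if len(hits) > 1:
        raise SchemaError(f"multiple candidate columns for {what}: {hits}")
    if not hits:
        if required:
            raise SchemaError(f"no column naming {what} (expected one of {sorted(aliases)})")
        return None
    return hits[0]


def _read_delimited(path, dialect):
    sep = {"csv": ",", "tsv": "\t", None: None}.get(dialect, dialect)
    import csv as _csv
    try:
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    except (pd.errors.EmptyDataError, _csv.Error):
        raise SchemaError(f"{path}: empty or undelimited file") from None
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df


def _extract_time_h(df):
    """Return times in hours; day-indexed inputs are converted on read."""
    col_h = _find_column(df.columns, _TIME_H_ALIASES, "time in hours", required=False)
    if col_h is not None:
        return pd.to_numeric(df[col_h], errors="raise").astype(float)
    col_d = _find_column(df.columns, _TIME_D_ALIASES, "time in days", required=False)
    if col_d is not None:
        return pd.to_numeric(df[col_d], errors="raise").astype(float) * 24.0
    raise SchemaError("no time column (hours or days)")


# ---------------------------------------------------------------------------
# qPCR table
# ---------------------------------------------------------------------------

@dataclass
class QPCRTable:
    """Per-sample broad-range total load and targeted per-species concentrations.

    Attributes
    ----------
    data
        Tidy frame with columns ``participant_id``, ``time_h``, ``total_load``
        and one column per assayed species, all concentrations in 16S rRNA
        gene copies per swab.
    species
        Names of the per-species assay columns.
    detection_threshold
        Censoring floor in copies/swab; stored values at or below it are
        flagged in :attr:`below_threshold`.
    """

    data: pd.DataFrame
    species: list[str]
    detection_threshold: float = DETECTION_THRESHOLD
    loq_targeted: float = LOQ_TARGETED_QPCR
    loq_broad_range: float = LOQ_BROAD_RANGE_QPCR
    below_threshold: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        df = self.data
        for col in ("participant_id", "time_h", "total_load"):
            if col not in df.columns:
                raise SchemaError(f"qPCR table missing column {col!r}")
        conc = df[["total_load", *self.species]]
        if (conc.to_numpy(dtype=float) < 0).any():
            raise ValidationError("negative concentration in qPCR table")
        for pid, grp in df.groupby("participant_id", sort=False):
            t = grp["time_h"].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ValidationError(f"time_h not strictly increasing for participant {pid!r}")
        if self.below_threshold is None:
            self.below_threshold = df[self.species] <= self.detection_threshold
        self.data = df.reset_index(drop=True)
        self.below_threshold = self.below_threshold.reset_index(drop=True)


def read_qpcr_table(path, dialect=None, species=None,
                    detection_threshold=DETECTION_THRESHOLD) -> QPCRTable:
    """Parse a wide delimited qPCR table.

    The header must name the participant, the sampling time (hours, or days —
    converted to hours), and the broad-range total-load column; every other
    numeric column is treated as a species assay unless ``species`` names
    them explicitly.
    """
    df = _read_delimited(path, dialect)
    pid_col = _find_column(df.columns, _PARTICIPANT_ALIASES, "participant id")
    tbl_col = _find_column(df.columns, _TBL_ALIASES, "total bacterial load")
    time_h = _extract_time_h(df)
    known = {pid_col, tbl_col} | {
        c for c in df.columns if c.strip().lower() in (_TIME_H_ALIASES | _TIME_D_ALIASES)
    }
    if species is None:
        species = [c for c in df.columns if c not in known]
    out = pd.DataFrame({
        "participant_id": df[pid_col].astype(str),
        "time_h": time_h,
        "total_load": pd.to_numeric(df[tbl_col], errors="raise").astype(float),
    })
    for sp in species:
        if sp not in df.columns:
            raise SchemaError(f"species column {sp!r} not present")
        out[sp] = pd.to_numeric(df[sp], errors="raise").astype(float)
    out = out.sort_values(["participant_id", "time_h"], kind="stable")
    return QPCRTable(out, list(species), detection_threshold=detection_threshold)


def write_qpcr_table(table: QPCRTable, path, dialect="csv") -> None:
    sep = "\t" if dialect == "tsv" else ","
    df = table.data.copy()
    # repr-level float formatting so a write/read cycle is lossless
    df.to_csv(path, sep=sep, index=False, float_format=None)


# ---------------------------------------------------------------------------
# Abundance table
# ---------------------------------------------------------------------------

@dataclass
class AbundanceTable:
    """Per-sample taxon read counts with depth and derived relative abundances.

    ``counts`` may be absent when the source supplied relative abundances
    directly (long-format fractional input); ``rel_abund`` is then the stored
    fractions and ``depth`` whatever the source recorded.
    """

    data: pd.DataFrame            # participant_id, time_h + taxon count columns (or NaN)
    taxa: list[str]
    depth: pd.Series = field(default=None)        # type: ignore[assignment]
    rel_abund: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    from_counts: bool = True

    def __post_init__(self):
        df = self.data.reset_index(drop=True)
        if self.from_counts:
            counts = df[self.taxa].to_numpy()
            if not np.all(counts >= 0):
                raise ValidationError("negative count")
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("non-integer count")
            depth = counts.sum(axis=1)
            if np.any(depth <= 0):
                bad = df.loc[depth <= 0, ["participant_id", "time_h"]]
                raise ValidationError(f"all-zero sample(s); depth must be positive:\n{bad}")
            self.depth = pd.Series(depth.astype(float), name="depth")
            self.rel_abund = df[self.taxa].div(self.depth.to_numpy(), axis=0)
        else:
            ra = self.rel_abund.to_numpy(dtype=float)
            if np.any(ra < 0) or np.any(ra > 1 + 1e-9):
                raise ValidationError("relative abundance outside [0, 1]")
            sums = ra.sum(axis=1)
            if np.any(sums > 1 + 1e-6):
                raise ValidationError("relative abundances sum to > 1")
            self.rel_abund = self.rel_abund.reset_index(drop=True)
            if self.depth is None:
                raise ValidationError("fraction-based table requires a depth per sample")
            self.depth = self.depth.reset_index(drop=True).astype(float)
        self.data = df


def read_abundance_table(path, dialect=None) -> AbundanceTable:
    """Parse a taxon count matrix (wide) or long-format counts/abundances.

    Long format requires columns for participant, time, taxon and one of
    count / fraction / percent; percent values are divided by 100 on read.
    Wide format treats every non-key numeric column as a taxon count column.
    """
    df = _read_delimited(path, dialect)
    taxon_col = _find_column(df.columns, _TAXON_ALIASES, "taxon", required=False)
    pid_col = _find_column(df.columns, _PARTICIPANT_ALIASES, "participant id")
    time_h = _extract_time_h(df)
    df = df.assign(__time_h=time_h)
    if taxon_col is None:
        known = {pid_col, "__time_h"} | {
            c for c in df.columns if c.strip().lower() in (_TIME_H_ALIASES | _TIME_D_ALIASES)
        }
        taxa = [c for c in df.columns if c not in known]
        if not taxa:
            raise SchemaError("wide abundance table has no taxon columns")
        out = pd.DataFrame({
            "participant_id": df[pid_col].astype(str),
            "time_h": df["__time_h"],
        })
        for t in taxa:
            out[t] = pd.to_numeric(df[t], errors="raise")
        out = out.sort_values(["participant_id", "time_h"], kind="stable")
        return AbundanceTable(out, taxa)
    # long format
    count_col = _find_column(df.columns, _COUNT_ALIASES, "count", required=False)
    ra_col = _find_column(df.columns, _RA_ALIASES, "fraction", required=False)
    pct_col = _find_column(df.columns, _RA_PCT_ALIASES, "percent", required=False)
    keys = df[pid_col].astype(str) + "\x00" + df["__time_h"].astype(str)
    if count_col is not None:
        wide = df.pivot_table(index=[pid_col, "__time_h"], columns=taxon_col,
                              values=count_col, fill_value=0, aggfunc="sum")
        wide = wide.reset_index().rename(columns={pid_col: "participant_id",
                                                  "__time_h": "time_h"})
        wide["participant_id"] = wide["participant_id"].astype(str)
        taxa = [c for c in wide.columns if c not in ("participant_id", "time_h")]
        wide = wide.sort_values(["participant_id", "time_h"], kind="stable")
        return AbundanceTable(wide, taxa)
    if ra_col is None and pct_col is None:
        raise SchemaError("long abundance table needs a count, fraction or percent column")
    values = (pd.to_numeric(df[pct_col], errors="raise") / 100.0 if ra_col is None
              else pd.to_numeric(df[ra_col], errors="raise"))
    depth_col = _find_column(df.columns, {"depth", "total_reads", "library_size"},
                             "depth", required=False)
    df = df.assign(__ra=values)
    wide = df.pivot_table(index=[pid_col, "__time_h"], columns=taxon_col,
                          values="__ra", fill_value=0.0, aggfunc="sum")
    wide = wide.reset_index().rename(columns={pid_col: "participant_id",
                                              "__time_h": "time_h"})
    wide["participant_id"] = wide["participant_id"].astype(str)
    taxa = [c for c in wide.columns if c not in ("participant_id", "time_h")]
    wide = wide.sort_values(["participant_id", "time_h"], kind="stable").reset_index(drop=True)
    if depth_col is not None:
        depths = (df.groupby([pid_col, "__time_h"])[depth_col].first()
                    .reset_index(drop=True).astype(float))
        depth = depths
    else:
        depth = pd.Series(np.full(len(wide), np.nan), name="depth")
    keys_order = wide[["participant_id", "time_h"]]
    if depth_col is not None:
        lut = df.groupby([df[pid_col].astype(str), df["__time_h"]])[depth_col].first()
        depth = pd.Series(
            [float(lut.loc[(p, t)]) for p, t in zip(keys_order["participant_id"],
                                                    keys_order["time_h"])],
            name="depth",
        )
    return AbundanceTable(wide[["participant_id", "time_h"]].join(wide[taxa]), taxa,
                          depth=depth, rel_abund=wide[taxa], from_counts=False)


def write_abundance_table(table: AbundanceTable, path, dialect="csv") -> None:
    sep = "\t" if dialect == "tsv" else ","
    table.data.to_csv(path, sep=sep, index=False)


def read_abundance_triplets(path) -> AbundanceTable:
    """Parse a sparse triplet-text count matrix.

    Plain-text layout: two header lines ``#samples<TAB>p1:t1<TAB>p2:t2...``
    (participant:time_h) and ``#taxa<TAB>name1<TAB>name2...`` followed by
    one ``sample_index<TAB>taxon_index<TAB>count`` triplet per line
    (0-based indices). Absent entries are zero.
    """
    samples, taxa, triplets = None, None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if parts[0] == "#samples":
                samples = parts[1:]
            elif parts[0] == "#taxa":
                taxa = parts[1:]
            else:
                i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
                triplets.append((i, j, c))
    if not samples or not taxa:
        raise SchemaError("triplet file missing #samples or #taxa header")
    counts = np.zeros((len(samples), len(taxa)))
    for i, j, c in triplets:
        counts[i, j] += c
    pids, times = zip(*(s.split(":") for s in samples))
    wide = pd.DataFrame({"participant_id": [str(p) for p in pids],
                         "time_h": [float(t) for t in times]})
    for k, t in enumerate(taxa):
        wide[t] = counts[:, k]
    return AbundanceTable(wide, list(taxa))


# ---------------------------------------------------------------------------
# Paired samples
# ---------------------------------------------------------------------------

@dataclass
class PairedSample:
    """One participant/time point joining qPCR and sequencing measurements."""

    participant_id: str
    time_h: float
    total_load: float
    depth: float
    taxa: list[str]
    rel_abund: np.ndarray          # fraction per taxon, aligned with ``taxa``
    counts: np.ndarray | None      # None for fraction-based input
    abs_conc: dict[str, float]     # taxon -> targeted-qPCR copies/swab
    ac_censored: dict[str, bool]
    detection_threshold: float


@dataclass
class JoinResult:
    pairs: list[PairedSample]
    unmatched_qpcr: pd.DataFrame
    unmatched_abundance: pd.DataFrame


def join_tables(qpcr: QPCRTable, abund: AbundanceTable,
                tolerance_h: float = DEFAULT_JOIN_TOLERANCE_H) -> JoinResult:
    """Pair qPCR and abundance rows by participant and time within tolerance.

    Every unmatched row of either table is reported (and logged), never
    silently dropped; two candidate rows within the tolerance raise
    :class:`AmbiguousJoinError`.
    """
    pairs: list[PairedSample] = []
    q = qpcr.data
    a = abund.data
    matched_q = np.zeros(len(q), dtype=bool)
    matched_a = np.zeros(len(a), dtype=bool)
    a_by_pid = {pid: grp for pid, grp in a.groupby("participant_id", sort=False)}
    for qi, qrow in q.iterrows():
        grp = a_by_pid.get(qrow["participant_id"])
        if grp is None:
            continue
        dt = (grp["time_h"] - qrow["time_h"]).abs()
        cand = grp.index[dt <= tolerance_h]
        if len(cand) > 1:
            raise AmbiguousJoinError(
                f"participant {qrow['participant_id']!r}: {len(cand)} sequencing rows "
                f"within ±{tolerance_h} h of t={qrow['time_h']}")
        if len(cand) == 0:
            continue
        ai = cand[0]
        if matched_a[a.index.get_loc(ai)]:
            raise AmbiguousJoinError(
                f"participant {qrow['participant_id']!r}: sequencing row at "
                f"t={a.loc[ai, 'time_h']} matches multiple qPCR rows within ±{tolerance_h} h")
        matched_q[q.index.get_loc(qi)] = True
        matched_a[a.index.get_loc(ai)] = True
        pos = abund.data.index.get_loc(ai)
        ra = abund.rel_abund.iloc[pos].to_numpy(dtype=float)
        counts = (abund.data.loc[ai, abund.taxa].to_numpy(dtype=float)
                  if abund.from_counts else None)
        censored = qpcr.below_threshold.iloc[q.index.get_loc(qi)]
        pairs.append(PairedSample(
            participant_id=str(qrow["participant_id"]),
            time_h=float(qrow["time_h"]),
            total_load=float(qrow["total_load"]),
            depth=float(abund.depth.iloc[pos]),
            taxa=list(abund.taxa),
            rel_abund=ra,
            counts=counts,
            abs_conc={sp: float(qrow[sp]) for sp in qpcr.species},
            ac_censored={sp: bool(censored[sp]) for sp in qpcr.species},
            detection_threshold=qpcr.detection_threshold,
        ))
    un_q = q.loc[~matched_q]
    un_a = a.loc[~matched_a, ["participant_id", "time_h"]]
    for _, row in un_q.iterrows():
        logger.warning("unmatched qPCR row: participant=%s t=%.1f h",
                       row["participant_id"], row["time_h"])
    for _, row in un_a.iterrows():
        logger.warning("unmatched sequencing row: participant=%s t=%.1f h",
                       row["participant_id"], row["time_h"])
    return JoinResult(pairs, un_q.reset_index(drop=True), un_a.reset_index(drop=True))
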
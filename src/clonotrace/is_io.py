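"""Integration-site table I/O, cross-patient collision filtering and the
abundance matrix.

An integration site (IS) is identified by its genomic coordinate
``(chrom, pos, strand)`` and serves as a heritable clonal barcode.  Tables
are plain TSV with one row per IS observation per sample; the in-memory
representation is a typed :class:`pandas.DataFrame`.  The abundance matrix
``M`` has one row per IS and one column per (patient, compartment,
timepoint) sample, entries being summed sequencing reads.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

IS_COLUMNS = ["patient", "compartment", "timepoint_months", "chrom", "pos", "strand", "reads"]

VALID_STRANDS = {"+", "-"}


class ISRecord(NamedTuple):
    """One integration site observed in one sample."""

    patient: str
    compartment: str
    timepoint_months: int
    chrom: str
    pos: int
    strand: str
    reads: int


class ISTableFormatError(ValueError):
    """Raised when an IS table is structurally malformed."""


def is_key(chrom: str, pos: int, strand: str) -> str:
    """Canonical string identity of an IS: ``chrom:pos:strand``."""
    return f"{chrom}:{pos}:{strand}"


def _chrom_sort_key(chrom: str) -> tuple:
    """Natural chromosome ordering: chr1 < chr2 < chr10 < chrX."""
    m = re.match(r"(?:chr)?(\d+)$", str(chrom))
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, str(chrom))


def read_is_table(path) -> pd.DataFrame:
    """Read an IS TSV into a validated DataFrame.

    The file must carry the header columns ``patient, compartment,
    timepoint_months, chrom, pos, strand, reads`` (an optional
    ``nearest_gene`` column is passed through).  Malformed rows are rejected
    with their 1-based file line number.

    Raises
    ------
    ISTableFormatError
        If a required column is missing or a row fails validation
        (``reads < 1``, ``timepoint_months < 0``, bad strand).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in IS_COLUMNS if c not in df.columns]
    if missing:
        raise ISTableFormatError(f"IS table {path} missing required column(s): {missing}")
    return _validate_is_frame(df, source=str(path))


def _validate_is_frame(df: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
    out = df.copy()
    for col, typ in [("timepoint_months", int), ("pos", int), ("reads", int)]:
        try:
            out[col] = out[col].astype(typ)
        except (ValueError, TypeError) as exc:
            raise ISTableFormatError(f"{source}: column {col!r} is not integer-typed: {exc}") from exc
    # header is line 1, first data row line 2
    for cond, msg in [
        (out["reads"] < 1, "reads must be >= 1"),
        (out["timepoint_months"] < 0, "timepoint_months must be >= 0"),
        (~out["strand"].isin(VALID_STRANDS), "strand must be + or -"),
    ]:
        if cond.any():
            lines = [int(i) + 2 for i in np.flatnonzero(cond.to_numpy())[:5]]
            raise ISTableFormatError(f"{source}: {msg} (line(s) {lines})")
    for col in ("patient", "compartment", "chrom", "strand"):
        out[col] = out[col].astype(str)
    return out


def write_is_table(df: pd.DataFrame, path) -> None:
    """Write an IS DataFrame as TSV (round-trips through :func:`read_is_table`)."""
    df.to_csv(path, sep="\t", index=False)


@dataclass
class CollisionReport:
    """Outcome of the cross-patient collision filter.

    ``table`` holds one row per IS identity observed in more than one
    patient: the involved patients, their per-patient read totals, and the
    outcome (``assigned:<patient>`` or ``dropped``).
    """

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["is_key", "patients", "read_totals", "outcome"])
    )

    @property
    def n_assigned(self) -> int:
        return int(self.table["outcome"].str.startswith("assigned").sum()) if len(self.table) else 0

    @property
    def n_dropped(self) -> int:
        return int((self.table["outcome"] == "dropped").sum()) if len(self.table) else 0

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def collision_filter(
    df: pd.DataFrame, fold: float = 10.0, basis: str = "reads"
) -> tuple[pd.DataFrame, CollisionReport]:
    """Resolve cross-patient IS collisions with the fold-rule.

    The same integration coordinate seen in more than one patient is
    presumed cross-sample contamination.  For each such IS the per-patient
    totals are compared: if the top patient's total is at least ``fold``
    times every other patient's total, the IS is kept only in the top
    patient; otherwise it is dropped from all patients.  Within-patient
    sharing across compartments and timepoints is biological signal and is
    never altered.

    Parameters
    ----------
    df : IS DataFrame (as from :func:`read_is_table`).
    fold : ratio threshold, must be > 1.  Ties at exactly ``fold x`` keep
        the IS in the top patient (the comparison is ``>=``).
    basis : ``"reads"`` compares per-patient summed read counts over all
        samples (default); ``"relabund"`` compares the per-patient maximum
        per-sample relative abundance of the IS.
    """
    if fold <= 1:
        raise ValueError(f"fold must be > 1, got {fold}")
    if basis not in ("reads", "relabund"):
        raise ValueError(f"basis must be 'reads' or 'relabund', got {basis!r}")
    if df.empty or df["patient"].nunique() <= 1:
        return df.copy(), CollisionReport()

    work = df.copy()
    work["_key"] = work["chrom"].astype(str) + ":" + work["pos"].astype(str) + ":" + work["strand"].astype(str)
    if basis == "reads":
        weight = work["reads"].astype(float)
    else:
        sample_tot = work.groupby(["patient", "compartment", "timepoint_months"])["reads"].transform("sum")
        weight = work["reads"] / sample_tot * 100.0
    work["_w"] = weight

    if basis == "reads":
        totals = work.groupby(["_key", "patient"])["_w"].sum()
    else:
        totals = work.groupby(["_key", "patient"])["_w"].max()
    n_pat = totals.groupby(level="_key").size()
    shared_keys = n_pat.index[n_pat > 1]

    rows = []
    drop_mask = pd.Series(False, index=work.index)
    for key in shared_keys:
        per_pat = totals.loc[key].sort_values(ascending=False)
        top_patient, top = per_pat.index[0], per_pat.iloc[0]
        others = per_pat.iloc[1:]
        read_totals = ";".join(f"{p}={v:g}" for p, v in per_pat.items())
        in_key = work["_key"] == key
        if (top >= fold * others).all():
            drop_mask |= in_key & (work["patient"] != top_patient)
            outcome = f"assigned:{top_patient}"
        else:
            drop_mask |= in_key
            outcome = "dropped"
        rows.append({"is_key": key, "patients": ";".join(per_pat.index), "read_totals": read_totals, "outcome": outcome})

    kept = work.loc[~drop_mask].drop(columns=["_key", "_w"]).reset_index(drop=True)
    report = CollisionReport(pd.DataFrame(rows, columns=["is_key", "patients", "read_totals", "outcome"]))
    return kept, report


@dataclass
class AbundanceMatrix:
    """IS x sample read-count matrix.

    ``df`` is indexed by IS identity string ``chrom:pos:strand`` and has a
    3-level column MultiIndex ``(patient, compartment, timepoint_months)``.
    Rows are ordered genomically, columns lexicographically by patient and
    compartment then numerically by timepoint.
    """

    df: pd.DataFrame

    @property
    def n_is(self) -> int:
        return self.df.shape[0]

    @property
    def n_samples(self) -> int:
        return self.df.shape[1]

    def patients(self) -> list[str]:
        return sorted(set(self.df.columns.get_level_values("patient")))

    def compartments(self) -> list[str]:
        return sorted(set(self.df.columns.get_level_values("compartment")))

    def timepoints(self, patient: str | None = None, compartment: str | None = None) -> list[int]:
        cols = self.df.columns
        if patient is not None:
            cols = cols[cols.get_level_values("patient") == patient]
        if compartment is not None:
            cols = cols[cols.get_level_values("compartment") == compartment]
        return sorted(set(cols.get_level_values("timepoint_months")))

    def select(self, patient=None, compartment=None, timepoint=None) -> pd.DataFrame:
        """Column subset by any combination of patient/compartment/timepoint."""
        mask = np.ones(self.df.shape[1], dtype=bool)
        lv = self.df.columns
        if patient is not None:
            mask &= lv.get_level_values("patient") == patient
        if compartment is not None:
            comps = [compartment] if isinstance(compartment, str) else list(compartment)
            mask &= lv.get_level_values("compartment").isin(comps)
        if timepoint is not None:
            mask &= lv.get_level_values("timepoint_months") == timepoint
        return self.df.loc[:, mask]

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out.columns = [f"{p}|{c}|{t}" for p, c, t in out.columns]
        out.index.name = "is_key"
        out.to_csv(path, sep="\t")


def build_matrix(df: pd.DataFrame) -> AbundanceMatrix:
    """Assemble the abundance matrix M from (collision-filtered) IS records.

    Duplicate rows for the same IS and sample have their reads summed.
    Empty input yields an empty matrix.  Row/column ordering is
    deterministic, so the matrix is invariant to input row order.
    """
    if df.empty:
        empty = pd.DataFrame(
            index=pd.Index([], name="is_key"),
            columns=pd.MultiIndex.from_arrays([[], [], []], names=["patient", "compartment", "timepoint_months"]),
        )
        return AbundanceMatrix(empty)
    work = df.copy()
    work["is_key"] = work["chrom"].astype(str) + ":" + work["pos"].astype(str) + ":" + work["strand"].astype(str)
    mat = work.pivot_table(
        index="is_key",
        columns=["patient", "compartment", "timepoint_months"],
        values="reads",
        aggfunc="sum",
        fill_value=0,
    )
    # genomic row order
    coords = {k: (_chrom_sort_key(k.split(":")[0]), int(k.split(":")[1]), k.split(":")[2]) for k in mat.index}
    mat = mat.loc[sorted(mat.index, key=coords.get)]
    mat = mat.sort_index(axis=1)
    return AbundanceMatrix(mat.astype(int))


def relative_abundance(m: AbundanceMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-column relative abundance in percent.

    Each column is scaled to percent of its read total; empty (all-zero)
    columns stay all-zero.
    """
    df = m.df if isinstance(m, AbundanceMatrix) else m
    totals = df.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = df.div(totals.where(totals > 0), axis=1) * 100.0
    return out.fillna(0.0)
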
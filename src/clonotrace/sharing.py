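"""IS sharing, recapture-over-time fractions and Pearson sharing networks.

"Shared" means detected at any read count >= 1 after collision filtering;
no abundance floor is applied.  Pearson correlations between sample pairs
are computed on relative-abundance vectors over the union of IS present in
either sample (absences count as zero); a binary-incidence variant is
available.  Only positive correlations are retained as network edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from clonotrace.is_io import AbundanceMatrix, relative_abundance


@dataclass
class SharingResult:
    focal: str
    comparators: tuple
    n_focal: int
    n_shared: int
    percent: float


def _detected_keys(df: pd.DataFrame) -> set:
    if df.shape[1] == 0:
        return set()
    return set(df.index[(df > 0).any(axis=1)])


def sharing_fraction(
    m: AbundanceMatrix,
    focal_compartment: str,
    comparator_compartments,
    patient: str | None = None,
) -> SharingResult:
    """Percent of focal-compartment IS also seen in any comparator sample.

    The focal set is the union of the compartment's IS over all its
    timepoints (within ``patient`` if given).
    """
    focal_df = m.select(patient=patient, compartment=focal_compartment)
    focal = _detected_keys(focal_df)
    if not focal:
        raise ValueError(f"no IS detected for focal compartment {focal_compartment!r}")
    comp_df = m.select(patient=patient, compartment=list(comparator_compartments))
    shared = focal & _detected_keys(comp_df)
    return SharingResult(
        focal=focal_compartment,
        comparators=tuple(comparator_compartments),
        n_focal=len(focal),
        n_shared=len(shared),
        percent=100.0 * len(shared) / len(focal),
    )


def recapture_fraction(m: AbundanceMatrix, compartment: str, patient: str | None = None) -> float:
    """Percent of a compartment's IS detected at two or more distinct timepoints."""
    sub = m.select(patient=patient, compartment=compartment)
    tps = sorted(set(sub.columns.get_level_values("timepoint_months")))
    if len(tps) < 2:
        raise ValueError(f"compartment {compartment!r} observed at {len(tps)} timepoint(s); need >= 2")
    detected = (sub > 0).T.groupby(level="timepoint_months").any().T  # IS x timepoint booleans
    n_tp = detected.sum(axis=1)
    n_is = int((n_tp >= 1).sum())
    if n_is == 0:
        raise ValueError(f"no IS detected for compartment {compartment!r}")
    return 100.0 * float((n_tp >= 2).sum()) / n_is


def pairwise_pearson(
    m: AbundanceMatrix, basis: str = "relabund"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r between samples on their IS sharing profile.

    For each column pair, r is computed over the union of IS present in at
    least one of the two samples, with absences as zeros, on relative
    abundances (``basis="relabund"``) or 0/1 incidence
    (``basis="incidence"``).  A constant vector makes r undefined; such
    pairs are reported as missing (NaN), never as 0.

    Returns the full correlation matrix and an edge-list DataFrame
    (source, target, r, retained) where ``retained`` marks r > 0.
    """
    df = m.df
    if df.shape[1] < 2:
        raise ValueError("need >= 2 sample columns for pairwise correlation")
    if basis == "relabund":
        vals = relative_abundance(m)
    elif basis == "incidence":
        vals = (df > 0).astype(float)
    else:
        raise ValueError(f"basis must be 'relabund' or 'incidence', got {basis!r}")

    cols = list(df.columns)
    n = len(cols)
    corr = np.full((n, n), np.nan)
    present = df.to_numpy() > 0
    x = vals.to_numpy()
    for i in range(n):
        corr[i, i] = 1.0
        for j in range(i + 1, n):
            union = present[:, i] | present[:, j]
            if union.sum() < 2:
                continue
            a, b = x[union, i], x[union, j]
            if a.std() == 0 or b.std() == 0:
                continue  # undefined, left NaN
            r = float(np.corrcoef(a, b)[0, 1])
            corr[i, j] = corr[j, i] = r
    names = [f"{p}|{c}|{t}" for p, c, t in cols]
    corr_df = pd.DataFrame(corr, index=names, columns=names)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            r = corr[i, j]
            if np.isnan(r):
                continue
            edges.append({"source": names[i], "target": names[j], "r": r, "retained": bool(r > 0)})
    return corr_df, pd.DataFrame(edges, columns=["source", "target", "r", "retained"])


T_COMPARTMENTS = ("TN", "TSCM", "TCM", "TEM", "TEMRA", "Twhole")


def nk_t_sharing(
    m: AbundanceMatrix,
    patient: str | None = None,
    independent_timepoints_only: bool = True,
) -> tuple[SharingResult, SharingResult]:
    """NK IS sharing with naive T cells and with any T-cell subtype.

    Returns (NK vs TN, NK vs any-T).  With
    ``independent_timepoints_only`` (default), an NK IS counts as shared
    only when found in a comparator sample taken at a timepoint different
    from every NK timepoint at which that IS was detected — i.e. samples
    isolated and sequenced independently.
    """
    nk_df = m.select(patient=patient, compartment="NK")
    nk_keys = _detected_keys(nk_df)
    if not nk_keys:
        raise ValueError("no NK IS present in matrix")

    def _count_shared(comparators) -> int:
        comp_df = m.select(patient=patient, compartment=list(comparators))
        if comp_df.shape[1] == 0:
            return 0
        if not independent_timepoints_only:
            return len(nk_keys & _detected_keys(comp_df))
        nk_tp = (nk_df > 0).T.groupby(level="timepoint_months").any().T
        comp_tp = (comp_df > 0).T.groupby(level="timepoint_months").any().T
        shared = 0
        for key in nk_keys:
            seen_nk = set(nk_tp.columns[nk_tp.loc[key]]) if key in nk_tp.index else set()
            if key not in comp_tp.index:
                continue
            seen_comp = set(comp_tp.columns[comp_tp.loc[key]])
            if seen_comp - seen_nk:
                shared += 1
        return shared

    present_t = [c for c in T_COMPARTMENTS if c in m.compartments()]
    res = []
    for comps in (("TN",), tuple(present_t)):
        n_shared = _count_shared(comps)
        res.append(
            SharingResult(
                focal="NK",
                comparators=comps,
                n_focal=len(nk_keys),
                n_shared=n_shared,
                percent=100.0 * n_shared / len(nk_keys),
            )
        )
    return res[0], res[1]
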
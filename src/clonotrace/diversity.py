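"""Clonal diversity indices over abundance-matrix columns.

Shannon entropy (nats by default), Simpson concentration D = sum p_i^2 and
its inverse are computed on read counts: each clone's probability is its
read share within the sample.  ``diversity_timecourse`` tracks a
compartment's diversity across timepoints; ``top_clones`` lists clones
above a relative-abundance threshold for bubble-style views.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from clonotrace.is_io import AbundanceMatrix, relative_abundance


@dataclass
class DiversityResult:
    patient: str
    compartment: str
    timepoint_months: int
    n_clones: int
    shannon: float
    simpson: float
    inverse_simpson: float


def _proportions(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("diversity undefined for all-zero counts")
    return c / c.sum()


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i (natural log by default).

    Zero counts are ignored.  ``base`` rebases the logarithm (e.g. 2 for
    bits); the default is nats, the convention of entropy-based repertoire
    diversity reporting.
    """
    p = _proportions(counts)
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def simpson(counts) -> float:
    """Simpson concentration D = sum p_i^2 (1 = monoclonal)."""
    p = _proportions(counts)
    return float((p * p).sum())


def inverse_simpson(counts) -> float:
    """Inverse Simpson 1/D, the effective number of equally-sized clones."""
    return 1.0 / simpson(counts)


def sample_diversity(m: AbundanceMatrix) -> pd.DataFrame:
    """Per-sample diversity table (sample key, S, Shannon, Simpson, InverseSimpson)."""
    rows = []
    for col in m.df.columns:
        counts = m.df[col].to_numpy()
        if counts.sum() == 0:
            continue
        p, c, t = col
        rows.append(
            {
                "patient": p,
                "compartment": c,
                "timepoint_months": t,
                "n_clones": int((counts > 0).sum()),
                "shannon": shannon(counts),
                "simpson": simpson(counts),
                "inverse_simpson": inverse_simpson(counts),
            }
        )
    return pd.DataFrame(rows)


def diversity_timecourse(m: AbundanceMatrix, compartment: str, patient: str | None = None) -> list[DiversityResult]:
    """Time-ordered diversity of one compartment (optionally one patient)."""
    if compartment not in m.compartments():
        raise ValueError(f"compartment {compartment!r} not present in matrix")
    sub = m.select(patient=patient, compartment=compartment)
    results = []
    for col in sorted(sub.columns, key=lambda c: (c[0], c[2])):
        counts = sub[col].to_numpy()
        if counts.sum() == 0:
            continue
        p, c, t = col
        results.append(
            DiversityResult(
                patient=p,
                compartment=c,
                timepoint_months=int(t),
                n_clones=int((counts > 0).sum()),
                shannon=shannon(counts),
                simpson=simpson(counts),
                inverse_simpson=inverse_simpson(counts),
            )
        )
    return results


def top_clones(
    m: AbundanceMatrix,
    compartment: str,
    timepoint: int,
    threshold_pct: float = 0.01,
    patient: str | None = None,
) -> pd.DataFrame:
    """Clones contributing strictly more than ``threshold_pct`` percent.

    Returns a DataFrame (is_key, relative abundance percent) in descending
    abundance, pooled over the matching sample columns.  The comparison is
    strict (> threshold), so a clone exactly at the threshold is excluded.
    """
    sub = m.select(patient=patient, compartment=compartment, timepoint=timepoint)
    if sub.shape[1] == 0:
        return pd.DataFrame(columns=["is_key", "abundance_pct"])
    rel = relative_abundance(sub)
    best = rel.max(axis=1)
    keep = best[best > threshold_pct].sort_values(ascending=False)
    return pd.DataFrame({"is_key": keep.index, "abundance_pct": keep.to_numpy()})
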
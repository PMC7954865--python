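"""Nearest-gene assignment, proto-oncogene flagging and clone tracking.

Gene annotations come in as BED6 (0-based half-open, as BED specifies);
IS coordinates are 1-based and converted only at this boundary.  An IS is
assigned the single nearest gene within 1 Mb, measured from the IS
position to the gene's transcription start site (TSS); an IS inside a
gene body short-circuits to distance 0.  Equidistant ties break by
lexicographic gene name.

Proto-oncogene surveillance flags every IS whose nearest gene is in a
watch list (LMO2, MECOM and CCND2 by default, the loci historically
involved in insertional-mutagenesis events in gamma-retroviral gene
therapy) together with its maximum relative abundance and a threshold
class: "<1%", "1-10%" (1 exclusive through 10 inclusive) or ">10%".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from clonotrace.is_io import AbundanceMatrix, relative_abundance

DEFAULT_ONCOGENES = ("LMO2", "MECOM", "CCND2")

DEFAULT_MAX_DISTANCE = 1_000_000

# heatmap colour breaks (relative abundance %) for bit-exact recolouring of exports
HEATMAP_COLOR_BREAKS = (
    0, 0.0001, 0.01, 0.1, 1, 5, 10, 20, 30, 50, 70, 100,
)


@dataclass
class GeneModel:
    """One gene: BED-style 0-based half-open coordinates plus its TSS."""

    name: str
    chrom: str
    strand: str
    start: int
    end: int

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def read_gene_bed(path) -> pd.DataFrame:
    """Read a BED6 gene annotation into a gene table with TSS coordinates."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6), dtype={"chrom": str, "name": str, "strand": str},
    )
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: BED intervals must satisfy start < end")
    if (~df["strand"].isin(["+", "-"])).any():
        raise ValueError(f"{path}: strand must be + or -")
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return df


def write_gene_bed(genes: pd.DataFrame, path) -> None:
    out = genes[["chrom", "start", "end", "name"]].copy()
    out["score"] = genes["score"] if "score" in genes else 0
    out["strand"] = genes["strand"]
    out.to_csv(path, sep="\t", header=False, index=False)


def nearest_gene(
    chrom: str, pos: int, genes: pd.DataFrame, max_distance: int = DEFAULT_MAX_DISTANCE
) -> tuple[str, int] | None:
    """Single nearest gene within ``max_distance`` of a 1-based IS position.

    Returns ``(gene name, signed distance IS - TSS)``; distance is 0 when
    the IS falls inside a gene body.  ``None`` when the chromosome is
    absent from the annotation or no TSS lies within range.
    """
    sub = genes[genes["chrom"] == str(chrom)]
    if sub.empty:
        return None
    pos0 = int(pos) - 1  # convert to 0-based at the BED boundary
    inside = sub[(sub["start"] <= pos0) & (pos0 < sub["end"])]
    if not inside.empty:
        name = sorted(inside["name"])[0]
        return name, 0
    dist = pos0 - sub["tss"].to_numpy()
    absd = np.abs(dist)
    within = absd <= max_distance
    if not within.any():
        return None
    best = absd[within].min()
    cand = sub.loc[within].loc[absd[within] == best]
    cand = cand.sort_values("name")
    row = cand.iloc[0]
    return str(row["name"]), int(pos0 - row["tss"])


def annotate_matrix(m: AbundanceMatrix, genes: pd.DataFrame, max_distance: int = DEFAULT_MAX_DISTANCE) -> pd.Series:
    """Nearest-gene name per IS row of the matrix (NaN if unassigned)."""
    out = {}
    for key in m.df.index:
        chrom, pos, _strand = key.rsplit(":", 2)
        hit = nearest_gene(chrom, int(pos), genes, max_distance=max_distance)
        out[key] = hit[0] if hit else np.nan
    return pd.Series(out, name="nearest_gene")


def abundance_class(pct: float) -> str:
    """Threshold class of a relative abundance: <1%, 1-10% or >10%.

    Boundaries are inclusive on the lower class: exactly 1.0 belongs to
    "<1%" and exactly 10.0 to "1-10%".
    """
    if pct <= 1.0:
        return "<1%"
    if pct <= 10.0:
        return "1-10%"
    return ">10%"


def flag_oncogenes(
    m: AbundanceMatrix,
    genes: pd.DataFrame,
    loci: tuple = DEFAULT_ONCOGENES,
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> pd.DataFrame:
    """Flag IS whose nearest gene is a watched proto-oncogene locus.

    One row per flagged IS: its identity, locus, maximum relative
    abundance over all samples (percent) and threshold class.
    """
    nearest = annotate_matrix(m, genes, max_distance=max_distance)
    rel = relative_abundance(m)
    rows = []
    for key, gene in nearest.items():
        if pd.isna(gene) or gene not in loci:
            continue
        max_pct = float(rel.loc[key].max())
        rows.append(
            {
                "is_key": key,
                "locus": gene,
                "max_abundance_pct": max_pct,
                "threshold_class": abundance_class(max_pct),
            }
        )
    return pd.DataFrame(rows, columns=["is_key", "locus", "max_abundance_pct", "threshold_class"])


NOISE_FLOOR_PCT = 0.0001


def track_clone(m: AbundanceMatrix, is_key: str, noise_floor: float = NOISE_FLOOR_PCT) -> pd.DataFrame:
    """Longitudinal relative-abundance trajectory of one IS.

    One row per sample column: relative abundance (percent) and a
    detection class — ``undetected`` (0), ``sub-noise`` (positive but at
    or below the sequencing-noise floor, 0.0001% by default) or
    ``detected``.
    """
    if is_key not in m.df.index:
        raise KeyError(f"IS {is_key!r} not present in matrix")
    rel = relative_abundance(m).loc[is_key]
    rows = []
    for (patient, comp, months), pct in rel.items():
        if pct == 0:
            cls = "undetected"
        elif pct <= noise_floor:
            cls = "sub-noise"
        else:
            cls = "detected"
        rows.append(
            {
                "patient": patient,
                "compartment": comp,
                "timepoint_months": months,
                "abundance_pct": float(pct),
                "detection": cls,
            }
        )
    return pd.DataFrame(rows)
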
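"""TCR repertoire analysis: QC filtering, diversity, sharing, recapture and
CDR3-window distances.

A clone is one V(D)J rearrangement; its identity key is
``(locus, CDR3 nucleotide sequence, V, J)`` by default, with a CDR3-only
option for callers that do not trust V/J assignments.  Sequence distance
between clones is the per-position mismatch (Hamming) count over a 50-bp
window centred on the CDR3; shorter windows are centre-padded with a
neutral symbol that never matches a nucleotide, keeping the distance a
metric without inventing sequence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from clonotrace.diversity import shannon
from clonotrace.sim import window50

TCR_COLUMNS = [
    "patient", "compartment", "timepoint_months", "locus",
    "v_gene", "j_gene", "cdr3_nt", "window50", "reads", "qc_label",
]

NO_CDR3_LABEL = "no CD3 detected"

PAD = "."


class TCRTableFormatError(ValueError):
    pass


def read_tcr_table(path) -> pd.DataFrame:
    """Read a TCR rearrangement TSV (V(D)J-caller export dialect).

    Rows without a CDR3 sequence are rejected with their line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TCR_COLUMNS if c not in df.columns]
    if missing:
        raise TCRTableFormatError(f"TCR table {path} missing required column(s): {missing}")
    bad = df["cdr3_nt"].str.strip() == ""
    if bad.any():
        lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())[:5]]
        raise TCRTableFormatError(f"{path}: missing CDR3 sequence (line(s) {lines})")
    out = df.copy()
    for col, typ in [("timepoint_months", int), ("reads", int)]:
        out[col] = out[col].astype(typ)
    if (out["reads"] < 1).any():
        raise TCRTableFormatError(f"{path}: reads must be >= 1")
    return out


def write_tcr_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def filter_qc(df: pd.DataFrame, label: str = NO_CDR3_LABEL) -> pd.DataFrame:
    """Drop rearrangements carrying the excluded QC label (exact match)."""
    keep = df["qc_label"] != label
    return df.loc[keep].reset_index(drop=True)


def clone_key(df: pd.DataFrame, cdr3_only: bool = False) -> pd.Series:
    """Clone identity keys; default (locus, CDR3, V, J), optionally CDR3 only."""
    if cdr3_only:
        return df["locus"] + "|" + df["cdr3_nt"]
    return df["locus"] + "|" + df["cdr3_nt"] + "|" + df["v_gene"] + "|" + df["j_gene"]


def tcr_diversity(df: pd.DataFrame) -> pd.DataFrame:
    """Shannon diversity of clone read counts per (patient, compartment, timepoint)."""
    rows = []
    for (patient, comp, months), grp in df.groupby(["patient", "compartment", "timepoint_months"]):
        counts = grp.groupby(clone_key(grp))["reads"].sum()
        rows.append(
            {
                "patient": patient,
                "compartment": comp,
                "timepoint_months": months,
                "n_clones": len(counts),
                "shannon": shannon(counts.to_numpy()),
            }
        )
    return pd.DataFrame(rows)


def tcr_sharing_network(df: pd.DataFrame) -> pd.DataFrame:
    """Per-timepoint pairwise Pearson r of clone abundances between subtypes.

    For each (patient, timepoint) with >= 2 compartments, correlates
    read-count vectors over the union of clone identities present in
    either compartment (absent = 0).  Positive correlations are the
    retained network edges.
    """
    edges = []
    for (patient, months), grp in df.groupby(["patient", "timepoint_months"]):
        comps = sorted(grp["compartment"].unique())
        if len(comps) < 2:
            continue
        vectors = {
            comp: sub.groupby(clone_key(sub))["reads"].sum()
            for comp, sub in grp.groupby("compartment")
        }
        for i, a in enumerate(comps):
            for b in comps[i + 1 :]:
                va, vb = vectors[a], vectors[b]
                union = va.index.union(vb.index)
                if len(union) < 2:
                    continue
                x = va.reindex(union, fill_value=0).to_numpy(dtype=float)
                y = vb.reindex(union, fill_value=0).to_numpy(dtype=float)
                if x.std() == 0 or y.std() == 0:
                    continue
                r = float(np.corrcoef(x, y)[0, 1])
                edges.append(
                    {
                        "patient": patient,
                        "timepoint_months": months,
                        "source": a,
                        "target": b,
                        "r": r,
                        "retained": bool(r > 0),
                    }
                )
    return pd.DataFrame(edges, columns=["patient", "timepoint_months", "source", "target", "r", "retained"])


def tcr_recapture(
    df: pd.DataFrame,
    compartment: str,
    patient: str | None = None,
    symmetric: bool = False,
    cdr3_only: bool = False,
) -> float:
    """Percent of clone identities recaptured across two timepoints.

    Directional (default): percent of timepoint-1 identities re-detected
    at timepoint 2.  ``symmetric=True`` uses the Jaccard form
    ``100 * |A ∩ B| / |A ∪ B|`` which is exchangeable in the two
    occasions.
    """
    sub = df[df["compartment"] == compartment]
    if patient is not None:
        sub = sub[sub["patient"] == patient]
    tps = sorted(sub["timepoint_months"].unique())
    if len(tps) < 2:
        raise ValueError(f"compartment {compartment!r} has {len(tps)} timepoint(s); need 2")
    first = sub[sub["timepoint_months"] == tps[0]]
    second = sub[sub["timepoint_months"] == tps[-1]]
    a = set(clone_key(first, cdr3_only=cdr3_only))
    b = set(clone_key(second, cdr3_only=cdr3_only))
    if symmetric:
        return 100.0 * len(a & b) / len(a | b)
    if not a:
        raise ValueError("no clones at the first timepoint")
    return 100.0 * len(a & b) / len(a)


def cdr3_distance_matrix(df: pd.DataFrame, pad: str = PAD) -> tuple[np.ndarray, pd.DataFrame]:
    """Pairwise Hamming distance over 50-bp CDR3-centred windows.

    Windows shorter than 50 are centre-padded; the pad symbol matches
    only itself, never a nucleotide.  Rows with no window and no CDR3 to
    rebuild one from are omitted from the returned clone frame.

    Returns ``(D, clones)`` with D symmetric, zero-diagonal, aligned with
    the retained clone rows.
    """
    work = df.copy()
    windows = []
    keep = []
    for i, row in work.iterrows():
        w = str(row.get("window50", "") or "")
        if len(w) != 50:
            src = w if w else str(row.get("cdr3_nt", "") or "")
            if not src:
                keep.append(False)
                windows.append(None)
                continue
            w = window50(src, pad=pad)
        keep.append(True)
        windows.append(w)
    kept = work.loc[np.array(keep, dtype=bool)].reset_index(drop=True)
    seqs = [w for w in windows if w is not None]
    if not seqs:
        return np.zeros((0, 0), dtype=int), kept
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), 50)
    d = (arr[:, None, :] != arr[None, :, :]).sum(axis=2).astype(int)
    return d, kept
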
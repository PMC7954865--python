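"""Synthetic clonal-hematopoiesis cohort generator with known ground truth.

Simulates a fixed pool of N vector-marked progenitor clones per patient,
each carrying a unique integration site.  At every sampling timepoint a
clone is captured in a compartment with a probability that combines the
occasion's baseline capture probability with the clone's own output rate,

    p_ct = 1 - (1 - p_t) ** rate,      rate ~ LogNormal(0, sigma^2),

which induces the between-clone capture heterogeneity targeted by the
Chao lower-bound estimators while keeping probabilities in (0, 1).  Naive
T cells carry freshly generated CDR3 rearrangements at every timepoint
(the thymic-turnover signature), while memory compartments re-observe IS
(and earlier CDR3s) of previously seen naive clones.  NK rows are drawn
only from the bipotent clone subset.  Read counts are negative binomial
around ``read_depth * rate`` (LAM-PCR-like overdispersion) and a small
contamination rate copies IS rows into other patients at <= 1/10 of the
source reads so the cross-patient collision filter is exercisable.

All draws flow from a single seeded generator: identical configs and
seeds yield byte-identical tables.  The generator produces tables, never
sequencing reads; vector-genome junctions and thymic-selection biology
are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

# toy genome for IS coordinates: collisions only arise from injected contamination
GENOME = {"chr1": 100_000_000, "chr2": 100_000_000, "chr3": 100_000_000}

MEMORY_COMPARTMENTS = ("TSCM", "TCM", "TEM")

# probability a captured memory clone is observed in each memory subtype;
# memory clones are large populations spanning phenotypes, so joint detection
# across TSCM/TCM/TEM is common
MEMORY_SUBTYPE_SPREAD = 0.7

# log-normal sigma of the per-clone memory expansion factor: a clone's
# persisted memory population has one (heavy-tailed) size that drives its
# read counts in every memory subtype, coupling abundances across TSCM/TCM/TEM
MEMORY_EXPANSION_SIGMA = 1.0

DEFAULT_SEED = 20210312


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the clinical regime the analysis targets: a pool of
    3000 long-term lymphoid progenitor clones per patient (mid-range of a
    few-thousand-clone population), three sampling timepoints spanning
    roughly eight years, moderate clone-output heterogeneity, and dual
    T/NK potential for a subset of clones.
    """

    n_patients: int = 2
    n_clones_per_patient: int = 3000
    bipotent_fraction: float = 0.3
    output_rate_dispersion: float = 0.4
    timepoints: tuple = (60, 108, 156)
    capture_prob_per_timepoint: tuple = (0.15, 0.20, 0.25)
    compartments: tuple = ("TN", "TSCM", "TCM", "TEM", "NK")
    memory_carryover: float = 0.3
    tcr_per_clone_per_timepoint: int = 1
    contamination_rate: float = 0.002
    read_depth: float = 50.0
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        for name in ("bipotent_fraction", "memory_carryover", "contamination_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for p in self.capture_prob_per_timepoint:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"capture probabilities must be in [0, 1], got {p}")
        if len(self.capture_prob_per_timepoint) != len(self.timepoints):
            raise ValueError("capture_prob_per_timepoint must match timepoints in length")
        for name in ("n_patients", "n_clones_per_patient", "tcr_per_clone_per_timepoint"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.output_rate_dispersion < 0:
            raise ValueError("output_rate_dispersion must be >= 0")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be > 0")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("timepoints", "capture_prob_per_timepoint", "compartments"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SimTruth:
    """Ground truth: one row per simulated clone."""

    clones: pd.DataFrame  # patient, clone_id, chrom, pos, strand, bipotent, rate

    def n_clones(self, patient: str) -> int:
        return int((self.clones["patient"] == patient).sum())

    def to_tsv(self, path) -> None:
        self.clones.to_csv(path, sep="\t", index=False)


def _unique_coordinates(rng: np.random.Generator, n: int, taken: set) -> list[tuple]:
    """Draw n IS coordinates unique within a patient (rejection sampling)."""
    chroms = list(GENOME)
    out: list[tuple] = []
    seen = set(taken)
    while len(out) < n:
        chrom = chroms[rng.integers(len(chroms))]
        pos = int(rng.integers(1, GENOME[chrom] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        key = (chrom, pos, strand)
        if key in seen:
            continue
        seen.add(key)
        out.append(key)
    return out


def _nb_reads(rng: np.random.Generator, mean: float, size: int, dispersion: float = 2.0) -> np.ndarray:
    """Negative-binomial reads with the given mean, floored at 1."""
    p = dispersion / (dispersion + mean)
    draws = rng.negative_binomial(dispersion, p, size=size)
    return np.maximum(draws, 1)


def _random_cdr3(rng: np.random.Generator) -> str:
    length = int(rng.integers(45, 61))
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def window50(seq: str, pad: str = ".") -> str:
    """Central 50-character window of a sequence, centre-padded if shorter."""
    if len(seq) >= 50:
        start = (len(seq) - 50) // 2
        return seq[start : start + 50]
    left = (50 - len(seq)) // 2
    return pad * left + seq + pad * (50 - len(seq) - left)


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate IS and TCR tables plus ground truth for a patient cohort.

    Returns ``(is_table, tcr_table, truth)`` where the tables follow the
    TSV dialects of :mod:`clonotrace.is_io` and :mod:`clonotrace.tcr`.
    Deterministic: same config and seed give byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    patients = [f"P{i + 1}" for i in range(config.n_patients)]
    sigma = config.output_rate_dispersion

    truth_rows = []
    per_patient_clones = {}
    for patient in patients:
        coords = _unique_coordinates(rng, config.n_clones_per_patient, set())
        rates = (
            rng.lognormal(mean=0.0, sigma=sigma, size=config.n_clones_per_patient)
            if sigma > 0
            else np.ones(config.n_clones_per_patient)
        )
        bipotent = rng.random(config.n_clones_per_patient) < config.bipotent_fraction
        clones = pd.DataFrame(
            {
                "patient": patient,
                "clone_id": [f"{patient}_c{i}" for i in range(config.n_clones_per_patient)],
                "chrom": [c[0] for c in coords],
                "pos": [c[1] for c in coords],
                "strand": [c[2] for c in coords],
                "bipotent": bipotent,
                "rate": rates,
            }
        )
        per_patient_clones[patient] = clones
        truth_rows.append(clones)
    truth = SimTruth(pd.concat(truth_rows, ignore_index=True))

    is_rows = []
    tcr_rows = []
    memory_comps = [c for c in config.compartments if c in MEMORY_COMPARTMENTS]
    has_tn = "TN" in config.compartments
    has_nk = "NK" in config.compartments

    for patient in patients:
        clones = per_patient_clones[patient]
        n = len(clones)
        rates = clones["rate"].to_numpy()
        bipotent = clones["bipotent"].to_numpy()
        tn_seen_before = np.zeros(n, dtype=bool)  # clones with a TN detection at <= current t
        clone_cdr3_history: dict[int, list[tuple]] = {}
        memory_rearr: dict[int, tuple] = {}  # persisted rearrangement once a clone enters memory
        mem_factor = rng.lognormal(0.0, MEMORY_EXPANSION_SIGMA, size=n)

        for t_idx, (months, p_t) in enumerate(zip(config.timepoints, config.capture_prob_per_timepoint)):
            p_clone = 1.0 - (1.0 - p_t) ** rates

            if has_tn:
                captured = rng.random(n) < p_clone
                tn_seen_before |= captured
                idx = np.flatnonzero(captured)
                # reads scale with clone output rate
                reads = _nb_reads(rng, config.read_depth, idx.size)
                reads = np.maximum((reads * rates[idx]).astype(int), 1)
                for j, ci in enumerate(idx):
                    row = clones.iloc[ci]
                    is_rows.append((patient, "TN", months, row["chrom"], row["pos"], row["strand"], int(reads[j])))
                    for _ in range(config.tcr_per_clone_per_timepoint):
                        # fresh rearrangement every timepoint; V/J are part of its identity
                        rearr = (
                            _random_cdr3(rng),
                            f"TRBV{int(rng.integers(1, 31))}",
                            f"TRBJ{int(rng.integers(1, 8))}",
                        )
                        clone_cdr3_history.setdefault(ci, []).append(rearr)
                        cdr3, v, j = rearr
                        tcr_rows.append(
                            (
                                patient, "TN", months, "TRB", v, j,
                                cdr3, window50(cdr3), int(_nb_reads(rng, config.read_depth, 1)[0]), "",
                            )
                        )

            # memory detection is clone-level: a persisted clone spans the
            # memory subtypes, so one capture event spreads across them
            mem_captured = tn_seen_before & (rng.random(n) < config.memory_carryover * p_clone)
            for comp in memory_comps:
                captured = mem_captured & (rng.random(n) < MEMORY_SUBTYPE_SPREAD)
                idx = np.flatnonzero(captured)
                reads = _nb_reads(rng, config.read_depth, idx.size)
                reads = np.maximum((reads * rates[idx] * mem_factor[idx]).astype(int), 1)
                for j, ci in enumerate(idx):
                    row = clones.iloc[ci]
                    is_rows.append((patient, comp, months, row["chrom"], row["pos"], row["strand"], int(reads[j])))
                    history = clone_cdr3_history.get(ci)
                    if history:
                        # a memory clone is one long-lived rearrangement, fixed
                        # when the clone first seeds the memory pool
                        if ci not in memory_rearr:
                            memory_rearr[ci] = history[int(rng.integers(len(history)))]
                        cdr3, v, j = memory_rearr[ci]
                        mem_reads = max(1, int(_nb_reads(rng, config.read_depth, 1)[0] * mem_factor[ci]))
                        tcr_rows.append(
                            (
                                patient, comp, months, "TRB", v, j,
                                cdr3, window50(cdr3), mem_reads, "",
                            )
                        )

            if has_nk:
                captured = bipotent & (rng.random(n) < p_clone)
                idx = np.flatnonzero(captured)
                reads = _nb_reads(rng, config.read_depth, idx.size)
                reads = np.maximum((reads * rates[idx]).astype(int), 1)
                for j, ci in enumerate(idx):
                    row = clones.iloc[ci]
                    is_rows.append((patient, "NK", months, row["chrom"], row["pos"], row["strand"], int(reads[j])))

    is_table = pd.DataFrame(
        is_rows, columns=["patient", "compartment", "timepoint_months", "chrom", "pos", "strand", "reads"]
    )

    # cross-patient contamination: copy a row into another patient at low reads
    if config.contamination_rate > 0 and config.n_patients > 1 and len(is_table):
        hit = rng.random(len(is_table)) < config.contamination_rate
        contam_rows = []
        for i in np.flatnonzero(hit):
            src = is_table.iloc[i]
            others = [p for p in patients if p != src["patient"]]
            target = others[int(rng.integers(len(others)))]
            reads = max(1, int(np.floor(src["reads"] / 10.0 * rng.random())))
            contam_rows.append(
                (target, src["compartment"], src["timepoint_months"], src["chrom"], src["pos"], src["strand"], reads)
            )
        if contam_rows:
            is_table = pd.concat(
                [is_table, pd.DataFrame(contam_rows, columns=is_table.columns)], ignore_index=True
            )

    tcr_table = pd.DataFrame(
        tcr_rows,
        columns=[
            "patient", "compartment", "timepoint_months", "locus",
            "v_gene", "j_gene", "cdr3_nt", "window50", "reads", "qc_label",
        ],
    )
    return is_table, tcr_table, truth
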
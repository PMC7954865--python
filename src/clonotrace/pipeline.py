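"""End-to-end orchestration: simulate or load tables, run every analysis
stage, and write TSV artefacts plus a machine-readable run manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import clonotrace
from clonotrace import annotation, capture_recapture, diversity, is_io, sharing, sim, tcr

log = logging.getLogger("clonotrace")


@dataclass
class RunConfig:
    """Pipeline configuration: inputs, output directory, stage thresholds."""

    out_dir: str
    is_table: str | None = None
    tcr_table: str | None = None
    gene_bed: str | None = None
    sim_config: sim.SimConfig | None = None
    collision_fold: float = 10.0
    bubble_threshold_pct: float = 0.01
    noise_floor_pct: float = annotation.NOISE_FLOOR_PCT
    oncogene_loci: tuple = annotation.DEFAULT_ONCOGENES
    estimate_compartment: str = "TN"
    run_annotation: bool = False
    seed: int = sim.DEFAULT_SEED

    def validate(self) -> None:
        if self.is_table is None and self.sim_config is None:
            raise ValueError("RunConfig needs either is_table or sim_config")
        if self.run_annotation and self.gene_bed is None:
            raise ValueError("annotation stage enabled but gene_bed is not set")
        for fld in ("is_table", "tcr_table", "gene_bed"):
            path = getattr(self, fld)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{fld}: {path} does not exist")
        if self.collision_fold <= 1:
            raise ValueError("collision_fold must be > 1")


def run_pipeline(config: RunConfig) -> dict:
    """Run every enabled stage, writing artefacts under ``config.out_dir``.

    Returns the manifest dict (also written as ``manifest.json``): inputs,
    parameters, package version, seed, and a list of all written
    artefacts keyed by stage.  The pipeline is a pure function of
    (inputs, config, seed): repeated runs produce identical files.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artefacts: dict[str, list[str]] = {}

    def save(stage: str, name: str, writer) -> None:
        path = out / name
        writer(path)
        artefacts.setdefault(stage, []).append(name)
        log.info("%s: wrote %s", stage, path)

    # --- input stage -------------------------------------------------
    if config.sim_config is not None:
        sim_cfg = config.sim_config
        is_df, tcr_df, truth = sim.simulate_cohort(sim_cfg)
        save("simulate", "is_table.tsv", lambda p: is_io.write_is_table(is_df, p))
        save("simulate", "tcr_table.tsv", lambda p: tcr.write_tcr_table(tcr_df, p))
        save("simulate", "truth.tsv", truth.to_tsv)
        save("simulate", "sim_config.json", sim_cfg.to_json)
    else:
        is_df = is_io.read_is_table(config.is_table)
        tcr_df = tcr.read_tcr_table(config.tcr_table) if config.tcr_table else None
    log.info("input: %d IS rows, %d patients", len(is_df), is_df["patient"].nunique())

    # --- collision filter + matrix -----------------------------------
    filtered, report = is_io.collision_filter(is_df, fold=config.collision_fold)
    log.info(
        "collision_filter: %d -> %d rows (%d IS assigned, %d dropped)",
        len(is_df), len(filtered), report.n_assigned, report.n_dropped,
    )
    save("filter", "is_table.filtered.tsv", lambda p: is_io.write_is_table(filtered, p))
    save("filter", "collision_report.tsv", report.to_tsv)
    m = is_io.build_matrix(filtered)
    save("matrix", "abundance_matrix.tsv", m.to_tsv)

    # --- diversity ----------------------------------------------------
    div = diversity.sample_diversity(m)
    save("diversity", "diversity.tsv", lambda p: div.to_csv(p, sep="\t", index=False))

    # --- sharing ------------------------------------------------------
    corr, edges = sharing.pairwise_pearson(m)
    save("sharing", "pearson_matrix.tsv", lambda p: corr.to_csv(p, sep="\t"))
    save("sharing", "network_edges.tsv", lambda p: edges.to_csv(p, sep="\t", index=False))
    sharing_rows = []
    for patient in m.patients():
        comps = set(m.select(patient=patient).columns.get_level_values("compartment"))
        memory = [c for c in ("TSCM", "TCM", "TEM", "TEMRA") if c in comps]
        if "TN" in comps and memory:
            res = sharing.sharing_fraction(m, "TN", memory, patient=patient)
            sharing_rows.append(
                {"patient": patient, "focal": "TN", "comparators": "+".join(memory),
                 "n_focal": res.n_focal, "n_shared": res.n_shared, "percent": res.percent}
            )
        if "NK" in comps and "TN" in comps:
            nk_tn, nk_t = sharing.nk_t_sharing(m, patient=patient)
            for res in (nk_tn, nk_t):
                sharing_rows.append(
                    {"patient": patient, "focal": "NK", "comparators": "+".join(res.comparators),
                     "n_focal": res.n_focal, "n_shared": res.n_shared, "percent": res.percent}
                )
    if sharing_rows:
        sh_df = pd.DataFrame(sharing_rows)
        save("sharing", "sharing_fractions.tsv", lambda p: sh_df.to_csv(p, sep="\t", index=False))
    recap_rows = []
    for patient in m.patients():
        if len(m.timepoints(patient=patient, compartment="TN")) >= 2:
            recap_rows.append(
                {"patient": patient, "compartment": "TN",
                 "recapture_pct": sharing.recapture_fraction(m, "TN", patient=patient)}
            )
    if recap_rows:
        rc_df = pd.DataFrame(recap_rows)
        save("sharing", "recapture.tsv", lambda p: rc_df.to_csv(p, sep="\t", index=False))

    # --- capture-recapture -------------------------------------------
    estimates = capture_recapture.estimate_ltlp(m, compartment=config.estimate_compartment)
    est_df = capture_recapture.estimates_table(estimates)
    if len(est_df):
        save("estimate", "abundance_estimates.tsv", lambda p: est_df.to_csv(p, sep="\t", index=False))
    refusals = {p: e.refused for p, e in estimates.items() if e.refused}
    for patient, reason in refusals.items():
        log.info("estimate: %s refused (%s)", patient, reason)

    # --- TCR branch ---------------------------------------------------
    if tcr_df is not None and len(tcr_df):
        tcr_kept = tcr.filter_qc(tcr_df)
        log.info("tcr filter_qc: %d -> %d rows", len(tcr_df), len(tcr_kept))
        tdiv = tcr.tcr_diversity(tcr_kept)
        save("tcr", "tcr_diversity.tsv", lambda p: tdiv.to_csv(p, sep="\t", index=False))
        tnet = tcr.tcr_sharing_network(tcr_kept)
        save("tcr", "tcr_network_edges.tsv", lambda p: tnet.to_csv(p, sep="\t", index=False))

    # --- annotation ---------------------------------------------------
    if config.run_annotation:
        genes = annotation.read_gene_bed(config.gene_bed)
        flags = annotation.flag_oncogenes(m, genes, loci=tuple(config.oncogene_loci))
        save("annotate", "oncogene_flags.tsv", lambda p: flags.to_csv(p, sep="\t", index=False))

    manifest = {
        "package": "clonotrace",
        "version": clonotrace.__version__,
        "seed": config.seed,
        "parameters": {
            "collision_fold": config.collision_fold,
            "bubble_threshold_pct": config.bubble_threshold_pct,
            "noise_floor_pct": config.noise_floor_pct,
            "oncogene_loci": list(config.oncogene_loci),
            "estimate_compartment": config.estimate_compartment,
        },
        "inputs": {
            "is_table": config.is_table,
            "tcr_table": config.tcr_table,
            "gene_bed": config.gene_bed,
            "simulated": config.sim_config is not None,
        },
        "refusals": refusals,
        "artefacts": artefacts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
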
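# clonotrace

Clonal tracking of gene-modified lymphoid progenitors from integration-site
and TCR repertoire data.

In retroviral gene therapy, every transduced progenitor clone carries its
vector integration site (IS) as a heritable genomic barcode. Years after
treatment, sequencing the IS repertoire of sorted blood populations — naïve
T cells (TN), memory subsets (TSCM/TCM/TEM), NK cells — lets one ask how
many progenitor clones are still producing cells, whether the same clones
feed the T and NK lineages, and whether any clone near a proto-oncogene is
expanding. `clonotrace` implements that analysis chain for researchers
working with longitudinal IS/TCR tables:

- **IS ingestion and contamination filtering** — a cross-patient *10-fold
  collision rule*: an IS coordinate seen in several patients is assigned to
  the patient whose summed reads exceed every other patient's by ≥ 10×,
  otherwise discarded everywhere.
- **Abundance matrix M** — IS × (patient, compartment, timepoint) read
  counts, with a per-column relative-abundance view in percent.
- **Diversity** — Shannon H = −Σ pᵢ ln pᵢ, Simpson D = Σ pᵢ², inverse
  Simpson, per sample and over time.
- **Sharing and recapture** — fractions of IS shared between compartments,
  recaptured across timepoints, and Pearson-correlation sharing networks.
- **Closed-population capture–recapture** — each timepoint is a capture
  occasion; the counts n_ω of the 2ᵗ−1 observable detection histories ω
  are fit with Poisson log-linear models (M0, Mt, and the Chao lower-bound
  heterogeneity models Mh/Mth with η_k ≥ 0), giving the number of active
  clones N̂ = n_obs + exp(β̂0) with a delta-method standard error. The
  most conservative estimate among the lowest-BIC fits is selected.
- **TCR repertoire** — QC filtering, per-sample diversity, cross-subtype
  sharing networks, longitudinal recapture, and Hamming distances over a
  50-bp window centred on the CDR3.
- **Proto-oncogene surveillance** — nearest-gene (TSS within 1 Mb)
  annotation from BED, flags for watched loci (LMO2, MECOM, CCND2) with
  1%/10% abundance classes, and per-clone trajectories with a 0.0001%
  sequencing-noise floor.
- **Synthetic cohort simulator** — a ground-truth generator of IS/TCR
  tables (fixed clone pool, heterogeneous output rates, bipotent T/NK
  clones, fresh TN rearrangements per timepoint, persisted memory clones,
  cross-patient contamination) for validation and parameter-recovery
  testing.

## Worked example

Simulate a two-patient cohort (3000 clones per patient, three sampling
timepoints) and estimate the number of active clones from the naïve-T
recapture pattern:

```sh
clonotrace simulate --out-dir demo
clonotrace estimate demo/is_table.tsv --out demo/estimates.tsv
```

```
wrote 5934 IS rows, 4760 TCR rows to demo
P1: Mt N_hat=2677 SE=90
P2: Mt N_hat=2590 SE=92
```

Each patient's TN compartment observed ~1500 distinct IS over three
occasions; the detection-history fit infers ~2600–2700 active clones
against a true pool of 3000 — the estimate is a lower bound in the
presence of clone-output heterogeneity. `demo/estimates.tsv` lists every
fitted model with N̂, SE, deviance, AIC/BIC and the selected flag.

The same analyses run on real exported tables: TSV with columns
`patient, compartment, timepoint_months, chrom, pos, strand, reads` for
IS, and `patient, compartment, timepoint_months, locus, v_gene, j_gene,
cdr3_nt, window50, reads, qc_label` for TCR rearrangements. See
`clonotrace run --help` for the all-in-one pipeline (collision filter →
matrix → diversity → sharing → estimation → annotation) which writes TSV
artefacts plus a JSON run manifest.

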
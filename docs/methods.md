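# Methods

## The estimation problem

A transduced progenitor clone is identified by its vector integration site
(IS), a genomic coordinate `(chrom, pos, strand)` inherited by all of the
clone's progeny. Sampling a blood compartment at a timepoint detects a
random subset of the active clones. Treating timepoints as capture
occasions on a closed population (the pool of clones active throughout the
observation window), the number of active clones can be estimated from how
often the same IS is recaptured across occasions. The package's central
output is this abundance estimate for the naïve T (TN) compartment, whose
continuous production of short-lived cells makes it a surrogate readout of
progenitor activity; the surrounding statistics (diversity, sharing,
recapture, oncogene proximity) characterise the clone pool's stability and
safety.

## Closed-population log-linear models

Let t be the number of occasions and n_ω the number of clones with
detection history ω ∈ {0,1}^t \ {0}. The n_ω are modelled as independent
Poisson counts with

    log μ_ω = β0 + Σ_j β_j ω_j + η_{k(ω)} · 1{k(ω) ≥ 3},   k(ω) = Σ_j ω_j

and the estimate of the unobserved cell is exp(β̂0), so N̂ = n_obs +
exp(β̂0). Model structures:

| model    | occasion terms        | heterogeneity terms | min t |
|----------|-----------------------|---------------------|-------|
| M0       | β·k(ω) (single slope) | —                   | 2     |
| Mt       | β_j per occasion      | —                   | 2     |
| Mh_Chao  | β·k(ω)                | η_k ≥ 0, k ≥ 3      | 3     |
| Mth_Chao | β_j per occasion      | η_k ≥ 0, k ≥ 3      | 3     |

The non-negativity constraint on η is what makes the Chao variants *lower
bounds* under between-clone capture heterogeneity. Two exact reductions
anchor the implementation and serve as test oracles:

- at t = 2, the Mt fit is saturated and N̂ equals the Lincoln–Petersen
  estimator n₁·n₂/m, and the delta-method SE equals the classical
  Lincoln–Petersen variance n₁n₂(n₁−m)(n₂−m)/m³;
- at t = 3 with the η constraint inactive, the Mh_Chao fit equals the
  analytic Chao bound S + ((t−1)/t)·f1²/(2·f2), where f_k counts clones
  captured exactly k times.

**Uncertainty.** SE(N̂)² = exp(2β̂0)·Var(β̂0) + exp(β̂0): the first term is
the delta-method variance of the unseen-cell prediction (Var(β̂0) from the
inverse observed Fisher information of the free parameters), the second
the Poisson variance of the unseen cell itself.

**Selection.** BIC = −2ℓ̂ + k·ln(n_obs). Among converged fits within a
BIC tolerance band (default 0, i.e. the strict minimum set) the *smallest*
N̂ is reported — a deliberately conservative tie-break.

**Numerical choices.** The constrained Poisson likelihood is maximised
with bounded L-BFGS-B followed by a projected-Newton polish to
stationarity (step tolerance 1e−13), so the saturated reductions above
hold to near machine precision. Active η constraints are dropped from the
information matrix and returned to the residual degrees of freedom.
Degenerate geometries are reported, not hidden: zero overlap at t = 2
yields N̂ = ∞ flagged `infinite_estimate`; f2 = 0 in a Chao model (where
the log-linear fit diverges) falls back to the bias-corrected bound
S + ((t−1)/t)·f1(f1−1)/(2(f2+1)) with flag `f2_zero_bias_corrected` and no
SE. Estimation is refused, with an explicit reason, for patients with
fewer than three timepoints: heterogeneity models are not identifiable
there, so estimates would not be comparable across patients.

## Filtering and matrix conventions

- **Collision rule.** An IS observed in more than one patient is presumed
  cross-contamination. Per-patient totals are summed reads over *all* of a
  patient's samples (the most conservative reading of a fold-rule);
  comparing per-sample maximum relative abundances is available via
  `basis="relabund"`. Ties at exactly fold× keep the IS in the top patient
  (≥, not >). Within-patient sharing across compartments/timepoints is
  biological signal and never filtered. IS identity is exact
  (chrom, pos, strand) — no fuzzy merging.
- **Coordinates.** IS tables are 1-based; BED gene annotations are 0-based
  half-open; conversion happens only at the BED boundary.
- **Diversity** is computed on read counts (the matrix entries), natural
  log; an incidence-weighted variant amounts to passing the binarised
  counts. Bubble/threshold comparisons are strict (> threshold).
- **Pearson sharing networks** correlate relative-abundance vectors over
  the union of IS present in either sample of a pair, zeros for absences;
  a 0/1-incidence basis is an option and the choice is recorded in output
  metadata. Constant vectors give an undefined r, reported as missing
  rather than 0. Only r > 0 edges are retained.
- **"Independent timepoint" sharing** (NK vs T): an NK IS counts as shared
  only if found in a T sample at a timepoint different from every NK
  timepoint where that IS was seen — the comparator was isolated and
  sequenced independently.
- **TCR identity** is (locus, CDR3 nucleotide sequence, V, J) by default,
  with a CDR3-only option. The QC filter removes rearrangements labelled
  "no CD3 detected" by the upstream caller (exact label, configurable).
  CDR3 distances are Hamming counts over the 50-bp CDR3-centred window;
  shorter windows are centre-padded with "." which matches only itself,
  keeping the distance a metric without inventing sequence.
- **Oncogene classes** partition abundance at 1% and 10%, inclusive on the
  lower class (1.0 → "<1%", 10.0 → "1–10%"). The noise floor for clone
  trajectories is 0.0001% relative abundance.
- **Nearest gene**: the single gene whose TSS is closest to the IS within
  1 Mb; an IS inside a gene body short-circuits to distance 0; equidistant
  ties break by lexicographic gene name.

## The synthetic cohort generator

The simulator produces IS/TCR tables with the statistical structure the
analysis assumes, plus ground truth, so estimator behaviour can be checked
against a known clone count. Per patient, N clones each receive a unique
coordinate on a toy genome (3 chromosomes × 10⁸ bp; uniqueness by
rejection, so cross-patient coincidences arise only from injected
contamination) and an output rate λ ~ LogNormal(0, σ²). Detection in a
compartment at occasion t is Bernoulli with

    p_ct = 1 − (1 − p_t)^λ,

which induces the Mh-type heterogeneity the Chao models target while
keeping probabilities valid. Read counts are negative binomial
(dispersion 2) with mean `read_depth`, scaled by λ — the overdispersion
typical of LAM-PCR quantification. TN clones emit freshly generated
CDR3 rearrangements (random 45–60 nt, V/J drawn once per rearrangement)
at every timepoint; once a TN-seen clone seeds the memory pool, one of its
rearrangements persists, memory detection happens at clone level
(carryover × p_ct) and spreads across TSCM/TCM/TEM with probability 0.7
each, and a per-clone log-normal memory expansion factor (σ = 1) couples
the clone's read counts across memory subtypes. NK rows are drawn only
from the bipotent clone subset. Contamination copies a row into another
patient with reads ≤ 1/10 of the source row, exercising the collision
filter. All draws come from one seeded generator; identical configs give
byte-identical tables.

### Study conditions (defaults)

| parameter | default | rationale |
|---|---|---|
| n_patients | 2 | abundance estimation needs ≥ 3 timepoints, available for two patients |
| n_clones_per_patient | 3000 | mid-range of a few-thousand-clone progenitor pool |
| timepoints (months) | 60, 108, 156 | three samplings spanning ~8 years of follow-up |
| capture_prob_per_timepoint | 0.15, 0.20, 0.25 | a few hundred–1500 distinct IS per compartment, as in deep longitudinal IS datasets |
| output_rate_dispersion σ | 0.4 | moderate clone-output heterogeneity: visible Mh structure without degenerate dominance |
| bipotent_fraction | 0.3 | a minority of clones feed both T and NK lineages |
| memory_carryover | 0.3 | memory detection less likely than naïve for the same clone |
| tcr_per_clone_per_timepoint | 1 | one tracked rearrangement per clone-occasion |
| contamination_rate | 0.002 | low-level cross-sample carry-over |
| read_depth | 50 | mean reads per captured IS |
| seed | 20210312 | documented default; every draw flows from it |

### What the generator does and does not emulate

It reproduces: a fixed clone pool with heterogeneous output, dual T/NK
potential, naïve TCR turnover vs memory persistence, per-occasion capture,
read-count overdispersion, and low-level contamination. It does **not**
simulate sequencing reads, vector–genome junctions, PCR amplification
bias, restriction-site accessibility, clonal expansion dynamics in time,
or thymic selection. Passing recovery tests therefore demonstrates that
the estimation chain is correct *under its stated sampling model* — not
that real LAM-PCR data satisfy that model.

## Known limitations

- The Chao-type estimates are lower bounds. In recovery runs at the study
  conditions the selected model underestimates the true pool by ~10% on
  average (see `ltlp_nhat_recovery_error_pct` in the acceptance output);
  since the delta-method relative SE is ~3–4%, the interval N̂ ± 2·SE
  frequently excludes the true N under heterogeneity. The point estimate
  stays comfortably within ±20% of truth; the SE quantifies sampling
  noise around the *bound*, not the heterogeneity bias.
- The collision rule's comparison basis (reads vs relative abundance) is
  a convention; both are implemented, reads-based is the default.
- With two occasions only Lincoln–Petersen-type estimation is possible
  and is deliberately refused in the per-patient pipeline (no
  heterogeneity control); the model functions remain callable directly.
- The genome assembly of real IS coordinates must match the supplied BED
  annotation; no annotation is bundled.
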
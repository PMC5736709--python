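# Methods

This note records the models implemented in `sbs`, the conventions and
defaults chosen where several are in circulation, and what the synthetic
data does and does not emulate.

## Profile HMMs (`sbs.hmm`)

**Architecture.** A local-alignment profile with match states
`M_1..M_k`, insert states `I_j` between consecutive matches, and interior
delete states.  Entry is uniform over match states (probability `1/k`);
every match state can end the alignment, with a constant per-state exit
probability (default `1/k`; the final match state always exits).
Leading/trailing deletions and flanking inserts are absorbed by local
entry/exit; flanking residues are emitted by the background null, so they
contribute zero log-odds.  This is deliberately simpler than a full
Plan7 profile: there is no multihit wing retraction and no E-value
calibration — classification rests on bit-score comparison only.

**Estimation.** Columns with gap fraction `< match_fraction` (default
0.5) become match states.  Emissions are residue counts plus
background-proportional pseudocounts of total weight `pseudocount_weight`
(default 1.0); insert emissions pool all insert columns.  Transitions are
counted from the per-sequence state paths with Laplace pseudocounts of
the same weight.  With weight 0 the model degenerates to observed
frequencies (useful for exact hand-checks; forbidden transitions then
have probability 0).

**Scoring.** Forward and Viterbi run in natural-log odds space and report
log₂-odds bits against an i.i.d. background null (Robinson & Robinson
frequencies).  On tiny models the forward value is verified against
exhaustive enumeration of every local path to 1e-9.  Ambiguity codes
(B, Z, X, U, O, J) score as background — zero log-odds — rather than
receiving invented penalties; unknown characters raise an error naming
the character and position.

**Scanning.** Candidate envelopes are found by running Viterbi, removing
the envelope, and recursing on both flanks; candidates are enumerated
down to a 0-bit floor and then filtered by the reporting threshold
(default 10 bits), which makes hit lists monotone in the threshold.
Envelopes from different models overlapping by more than half of the
shorter envelope are resolved in favour of the higher forward score.
Reported scores are forward bits over the envelope, recomputed for every
supplied model, so cross-model comparison always refers to the same
residue span.

**Typing.** A hit is labelled with the higher-scoring of the
canonical/Vibrio models when that score beats every decoy by at least
`margin_bits` (default 0) and reaches the reporting threshold; otherwise
it is rejected as a related non-CBM40 domain.  An exact score tie is
labelled canonical and flagged.  The recorded margin is the best CBM40
score minus the best competing score (other type or decoy).

## Survey (`sbs.survey`)

Sialidase (GH33) co-occurrence is decided by scanning the full protein
with a user-built GH33 profile; an Asp-box motif screen (two or more
`S-x-D-x-G-x-T-W` occurrences) exists as an optional fallback and is off
by default.  Redundancy reduction is greedy incremental clustering:
sequences ordered by descending length (ties by id) join the first
representative at ≥ 80% identity, else found a cluster.  Identity is
computed over a BLOSUM62 global alignment (gap open −11 / extend −1) with
gap-against-residue columns counted as mismatches in the denominator —
the conservative convention; an `aligned_columns` mode scores rows of an
existing alignment instead.  Taxa come from a caller-supplied TSV; there
are no remote lookups.  Tabulation is representative-level.

## Phylogeny (`sbs.phylo`)

**Rate model.** General time-reversible amino-acid model from a
symmetric exchangeability matrix `S` and frequencies `π`:
`Q_ab = S_ab π_b`, diagonal fixed by zero row sums, scaled so
`−Σ_a π_a Q_aa = 1` (distances in substitutions/site).  `P(t) = e^{Qt}`
is evaluated via the symmetrised eigendecomposition, making the
thousands of evaluations in a bootstrap cheap.  Any PAML-format `.dat`
matrix loads through `load_paml`; the bundled default is the published
WAG matrix.  The model slot is deliberately pluggable so other published
empirical matrices (e.g. PMB, distributed with PHYLIP/EMBOSS as
`pmb.dat`) drop in without code changes; all algorithms and tests are
model-generic.

**Distances.** `t̂ = argmax_{t≥0} Σ_sites log(π_a P_ab(t))` with pairwise
deletion of gapped/ambiguous columns and a uniform rate across sites (no
gamma).  Optimisation is bounded scalar minimisation with an expanding
bracket, verified against a brute-force grid (1e-5 steps) to 1e-4 and
against an independent reference implementation (phangorn `dist.ml`) on a
frozen fixture.  Saturated pairs (likelihood still rising at the bound)
are capped at 10 substitutions/site so matrices stay finite.

**Trees.** Standard neighbour joining with the rate-corrected Q
criterion; ties broken deterministically by the lowest flattened index;
negative branch-length estimates clamped to 0 with the clamped deficit
recorded on the tree (`clamped_negative_length`).  NJ reconstructs
additive matrices exactly — tested on random binary trees of up to 12
taxa against a path-sum oracle.  Bootstrap resamples alignment columns
with replacement, recomputes distances and NJ per replicate, and reports
each internal bipartition's replicate percentage on the full-data NJ
tree; a majority-rule consensus (extended by default, plain by flag) is
returned alongside, since either presentation is common.  Replicates in
which some pair shares no comparable site are dropped, counted and
warned about.

## STD NMR (`sbs.biophys.std`)

Build-ups are fit by unweighted least squares to `y = a(1 − e^{−bt})`.
The rate constant is reported positive with the decaying exponential
written explicitly; magnitudes are unchanged relative to writing the
exponent with a negative `b`.  Initialisation `a₀ = max(y)`, `b₀` from
inverting the model at the first time point, with geometric restarts.
Epitope maps divide initial slopes `a·b` by the reference proton's slope
(H7 of the sialic-acid ring by default — a parameter, since Neu5Gc
ligands may warrant a different reference) and assign display bins on
the rounded percentage: blue 0–24, yellow 25–50, red 51–100, `over100`
beyond.  The reference entry is exactly 100 by construction.  Maps are
invariant under uniform intensity rescaling because `a` is linear in the
data and `b` is scale-free.

## ITC (`sbs.biophys.itc`)

Total concentrations after cumulative injected volume `dV` follow the
overfill displacement convention `Mt = M0(1 − dV/2V0)`,
`Xt = X0 (dV/V0)(1 − dV/2V0)`; bound ligand from the single-site
quadratic; injection heats `ΔQ_i = Q_i − Q_{i−1} + (v_i/V0)(Q_i+Q_{i−1})/2`
plus a fitted per-injection baseline (fixable to 0).  Buffer-control
heats are subtracted before fitting when supplied; a first-injection
discard flag exists and is off by default.  The fit runs over
`(log K_d, ΔH, baseline)` — log-K_d for conditioning — with N fixed at
1.0 by default (a free-N mode exists); standard errors come from the
Jacobian, K_d's by the delta method.  Titrations with Wiseman
`c = M0·N/K_d < 0.01` are flagged "unreliable (low c-value)": the fitted
K_d is then an estimate only, mirroring how very weak monosaccharide
affinities (~tens of mM) must be read.  Derived quantities:
`ΔG = RT ln K_d` (K_d in molar), `−TΔS = ΔG − ΔH`, an identity that holds
exactly as stored.  Note the saturating-titration cumulative heat exceeds
the naive `M0·V0·ΔH` by the first-order displacement term for the
schedule used; tests account for this.

## Assays (`sbs.assays`)

Array ranks are `mean/max·100` over replicate means (sample SD, n−1 —
the replicate count is 4 by convention); division precedes scaling so
the top glycan is exactly 100.  Sialylation fraction is the area share
of sialylated peaks among assigned O-glycan peaks.  ELISA readings are
blank-subtracted and scaled so the reference preparation is exactly
100%.  r² is the squared Pearson correlation.  Heat-map plotting of
ranks is intentionally not implemented; the tables are the product.
ANOVA/Tukey significance testing is out of scope.

## Synthetic data (`sbs.simulate`)

Families evolve without indels along a two-clade tree under the same
rate-model machinery the phylogeny uses (one matrix-exponential
implementation, tested once).  Identity targets (within-family 45%,
between-family 17% by default — the canonical-vs-Vibrio regime) are
converted to branch lengths via the model's expected-identity curve and
enforced by rejection resampling (≤ 50 draws, ±10 percentage points).
Proteomes are background-residue linkers with planted domain instances
(family members evolved by 0.1 substitutions/site); co-occurrence,
decoy and type rates are Bernoulli per protein; default co-occurrence is
0.92.  STD/ITC/RFU generators add Gaussian noise to the exact forward
models.  Every generator is byte-deterministic under `(config, seed)`
and emits a truth record.

What this does **not** emulate: insertions/deletions and alignment
uncertainty, compositional bias and low-complexity linkers, real
taxonomic breadth, O-acetylation lability on arrays, or instrument
drift.  Passing tests therefore demonstrate algorithmic correctness and
parameter recovery under the stated noise models, not robustness to
every artefact of real data.

## Problem sizes in tests

The default suite runs desk-scale versions of each analysis: 8+8-taxon
two-family bootstraps with 100 replicates, 200-protein proteome scans,
50-seed NJ additivity checks, and 50-titration Monte-Carlo recovery —
sizes chosen so the entire suite completes in a couple of minutes on one
CPU while still exercising every code path at meaningful scale.
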
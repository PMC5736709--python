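# sbs — sialic-acid binding suite

`sbs` is a Python toolkit for studying how gut bacteria recognise sialic
acid through the carbohydrate-binding modules (CBM40) appended to their
sialidases.  The motivating system is the mucin-foraging gut symbiont
*Ruminococcus gnavus*, whose intramolecular *trans*-sialidase carries a
CBM40 that binds sialylated mucin glycans (3′-/6′-sialyllactose,
sialyl-LacNAc, Neu5Gc variants) with millimolar affinity and thereby acts
as a mucus adhesin.  The package is aimed at computational glycobiologists
and microbiologists who want to (a) find and type CBM40 domains in
protein sequence collections, (b) place them on a phylogeny, and (c)
quantify the underlying binding data (STD NMR, ITC, glycan arrays, ELISA,
MS) with transparent, tested code.

Everything runs from synthetic data with planted ground truth — no
downloads are needed to exercise or validate any stage.

## What it computes

**Domain discovery and typing** (`sbs.hmm`, `sbs.survey`).  Profile HMMs
are built from seed alignments (match columns by gap fraction,
background-proportional pseudocounts, local alignment with uniform entry
over match states).  Sequences are scored in log₂-odds bits by the
forward algorithm, `bits = log2 Σ_paths P(path) / P(null)`, domains
located by Viterbi, and each hit typed canonical / *Vibrio* / reject by
cross-model score comparison against decoy models.  Surveys screen hits
for a co-occurring sialidase catalytic domain (GH33), reduce to a
non-redundant set by greedy clustering at 80% global identity, and
tabulate counts by phylum/class/genus.

**Phylogeny** (`sbs.phylo`).  Pairwise maximum-likelihood distances under
an empirical amino-acid model: `t̂ = argmax_t Σ_sites log π_a P_ab(t)`
with `P(t) = exp(Qt)` and the generator scaled to one expected
substitution per site per unit time.  Trees by neighbour joining;
supports by column-resampling bootstrap with majority-rule (extended)
consensus.  Any PAML-format matrix plugs in; the bundled default is WAG.

**Binding biophysics** (`sbs.biophys`).  STD-NMR build-up curves are fit
to `y = a(1 − e^{−bt})`; binding epitopes are mapped by normalising the
initial slopes `a·b` to the sialic-acid H7 proton (≡ 100%).  ITC
titrations are fit to the single-site isotherm (bound fraction from the
Wiseman quadratic, overfill displacement correction, N fixed at 1.0),
yielding K_d, ΔH, and the derived ΔG = RT ln K_d and −TΔS = ΔG − ΔH.

**Assay quantification** (`sbs.assays`).  Glycan-array rank
normalisation (100·mean RFU / max mean RFU), MS sialylation fraction
(area share of sialylated peaks), ELISA normalisation to a reference
mucin (≡ 100%), Pearson r², internal-standard quantification.

## Worked example

Simulate an ITC titration of a CBM40 binding 3′-sialyllactose
(19 × 2 µl injections, 200 µl cell, 115 µM protein, 10 mM ligand,
K_d = 0.57 mM, ΔH = −40 kJ/mol) and fit it:

```bash
sbs simulate itc --seed 3 --out run/
sbs itc fit --csv run/itc.csv --v0 200 --m0 115 --x0 10 --out run/fit.json
# Kd = 0.57 mM, dH = -40 kJ/mol, dG = -18.5, -TdS = 21.5 kJ/mol
```

The fitted K_d reproduces the planted value; the positive −TΔS says the
binding is enthalpy-driven with an entropic penalty, the signature of
CBM–sugar recognition.  The same pattern from the library:

```python
from sbs.simulate import gen_itc, gen_std
from sbs.biophys import fit_isotherm, fit_buildup, epitope_map

tit, truth = gen_itc(0.57, -40.0, cell_conc_uM=115.0, syringe_conc_mM=10.0)
fit = fit_isotherm(tit, fix_N=True)
print(fit.Kd_mM)               # 0.57

curves, _ = gen_std({"H7": (2.0, 0.5), "H3ax": (1.2, 0.6), "H8": (0.35, 0.8)})
for c in curves:
    fit_buildup(c)
emap = epitope_map(curves, reference="H7")
print(emap.entries["H7"])      # (1.0, 100.0, 'red')
print(emap.entries["H8"])      # (0.28, 28.0, 'yellow')
```

A full sequence survey — simulate two divergent CBM40 families, build
models, scan a proteome and bootstrap the tree:

```bash
sbs simulate families --seed 1 --out fams/
sbs hmm build --msa fams/canonical.afa --out canonical.shm
sbs hmm build --msa fams/vibrio.afa --out vibrio.shm
sbs hmm scan --models canonical.shm,vibrio.shm --fasta proteome.fa \
    --threshold 10 --tsv hits.tsv
sbs tree bootstrap --msa fams/pooled.afa --reps 1000 --seed 1 --out tree.nwk
```

On such two-family data the canonical-vs-*Vibrio* split is recovered with
100% bootstrap support.

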
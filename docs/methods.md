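# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations behind `calproscreen`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Sequence identity

Pairwise identities come from optimal global alignment with affine gaps
(Gotoh three-state dynamic program). A gap of length *k* costs
`gap_open + (k − 1)·gap_extend`; switching gap direction re-opens a gap;
end gaps are penalized like internal ones. Defaults are BLOSUM62 with gap
open 10 and extend 0.5 — standard global-protein-alignment practice. The
traceback prefers diagonal over up over left on ties, so results are
deterministic.

Percent identity divides identical columns by the **full alignment length**
(gap columns included). For two length-111 sequences differing at 14
positions this gives 100·97/111 ≈ 87.4 %, consistent with how paralog pairs
of this family are usually quoted; `denominator="aligned"` switches to
columns where both rows carry a residue. Identities between genuinely
distant family members (20–40 %) depend mildly on aligner and gap settings;
a ±2-percentage-point band is the right way to compare values across
aligners.

Consensus profiles count a column's residues over **all** rows (gaps count
in the denominator): a consensus letter requires that residue in ≥ 50 % of
the sequences, otherwise '.'. Frequency ties break alphabetically.

The identity matrix aligns each unordered pair independently rather than
reading identities off a multiple alignment; for close pairs the two
approaches agree exactly, for distant pairs the difference is well inside
the ±2-point band.

## Superposition and the metal-site screen

Cα atoms are paired chain-by-chain via sequence alignment of the one-letter
chain sequences, then fitted by the Kabsch algorithm: SVD of the covariance
of the centered point sets, with the smallest singular direction
sign-corrected so the result is always a proper rotation (det +1), never a
reflection. Point sets whose second singular value vanishes (collinear) are
rejected as degenerate. An iterative trim loop (≤ 5 cycles) drops pairs
with residual > 2 × the current RMSD and refits, approximating the
refinement step of common structure viewers; `all_pairs=True` disables it.
For two-chain models both chain-pairing assignments are fitted and the
lower-RMSD one kept (heterodimers do not announce which chain matches which
reference subunit); the choice is logged.

The census counts histidine **Cα** atoms within the cutoff of the reference
metal position, inclusive (d ≤ 9.0 Å). 9 Å is deliberately generous: it
admits any histidine that a modest conformational change could bring into
the site. Models are moved into the reference frame and censused against
the reference's own Zn coordinate, so the question asked is "could this
dimer assemble a site where calprotectin has one". A flag switches the
census to nearest-any-atom distances. Coordination detection lists residues
with a standard donor atom (ND1, NE2, OD1, OD2, OE1, OE2, SG, backbone O)
within 3.0 Å of the metal.

Dimer enumeration defaults to ordered pairs — n² complexes for n monomers
(196 for 14), counting A·B and B·A as distinct predictions, which matches
how ensemble model generators treat chain order. Unordered mode
(n(n+1)/2) is available.

## Growth-curve analysis

OD600 series live on the plate reader's 15-minute grid over 0–13 h.
Background subtraction uses the matching protein-in-buffer blank wells at
the same concentration — preferring blanks recorded under the same
biological replicate (each replicate is typically its own plate and day),
pooling otherwise. Technical wells are averaged within a biological
replicate before any statistics; negative subtracted values are retained
(clipping would bias the AUC); an isolated missing timepoint is linearly
interpolated, two consecutive ones are an error.

AUC is the composite trapezoid rule on the observed grid (no smoothing);
window endpoints must be grid points. ΔAUC subtracts the same replicate's
own 0 µM control; pooling controls across replicates is refused. SEM is
sd/√n (ddof = 1) over biological replicates, reported as 0 with n = 1
flagged.

The dose-level ANOVA is two-way additive (protein + strain) by default,
because both factors plausibly shift ΔAUC; a one-way mode drops the strain
term. Tukey–Kramer comparisons on the protein factor use the fitted model's
residual mean square and degrees of freedom with the studentized-range
distribution. Zero residual variance (all observations identical) is an
error, not a p-value.

## Reporter analysis

Firefly background is the mean firefly of same-complex vehicle wells (so
vehicle groups average exactly 0 after subtraction); Renilla background is
the mean Renilla of same-treatment empty-vector wells. Wells with
non-positive background-subtracted Renilla indicate failed transfection and
are excluded with a logged warning rather than producing negative or
infinite ratios. Every ratio is divided by the mean ratio of the reference
condition (human TLR4 + endotoxin by default, configurable), making the
reference group's mean exactly 1 and the whole readout invariant to the
firefly channel's units.

Welch t-tests (two-sided, Welch–Satterthwaite df) compare groups of
biological-replicate means (technical wells averaged first). p-values are
reported unadjusted — the convention for this assay — with an optional Holm
adjustment.

## Synthetic data

Each generator draws from its own `numpy` stream derived from the user seed
via `SeedSequence(seed, spawn_key=(k,))` (growth 0, structure 1, reporter 2,
sequences 3, stand-ins 4), so generators never perturb one another and
every output is bit-reproducible.

**Growth**: od(t) = blank + s(c)·K / (1 + exp(−s(c)·r·(t − t_lag))) +
N(0, σ²), with Hill inhibition s(c) = 1 − effect·c^h/(c^h + IC50^h).
Defaults: K = 1 OD, r = 0.8 /h, t_lag = 4 h, IC50 = 20 µM, h = 2,
effect = 1, σ = 0.01 OD, doses 0–100 µM, 3 biological × 3 technical
replicates on the 15-min/13-h grid — a realistic overnight plate for a
susceptible strain under a potent metal chelator. Matching blank wells are
emitted per biological replicate. The truth record stores the noiseless
curves and the exact ΔAUC per dose from the closed-form logistic integral
(K/r)·[ln(1+e^{a(T−t₀)}) − ln(1+e^{−a·t₀})], a = s·r.

**Structure fixtures** use one atom per analysed role (Cα, plus NE2 in
donor mode): full backbone geometry would change no tested quantity.
Histidine Cα sit at planted radii from a Zn at the origin (random
directions, or deterministic axes in `axis_aligned` mode so radii survive
the 0.001 Å PDB quantization exactly); decoy residues at 12–25 Å give each
chain a superposable scaffold. The mobile copy applies the planted or
random rigid motion in full precision, so noiseless fits can reach RMSD
≈ 1e-15.

**Reporter plates**: per-well Renilla is lognormal transfection efficiency
(σ = 0.2) plus instrument background; firefly is
L·baseline_ff·fold(complex, treatment)·(1 + ε) plus a complex-matched
additive background; vehicle wells carry fold 0 (pure background). The
expected pipeline output for a condition is fold/fold(reference). Default
folds (reference 20, a second endotoxin responder 10, one agonist-activated
condition 15, all else 0) emulate a strongly responding positive control
against silent receptors, in 3 biological × 3 technical replicates.

**Sequence families** apply exactly the planted number of substitutions per
descendant (replacement always differs from the ancestor) and record
realized pairwise differences; with few substitutions and these gap
penalties the optimal alignment is gap-free, so planted counts are
recovered exactly.

### Synthetic stand-ins for external reference objects

Two reference objects live in external databases and are represented here
by labelled synthetic constructions:

- `synthetic_calprotectin_reference()` — a geometric emulation of a
  Zn-bound calprotectin-like heterodimer: six NE2 donors 2.2 Å from an
  octahedral Zn with the published chain/residue assignments (chain A His17
  and His27; chain C His87, His91, His99 and His101), one non-coordinating
  histidine (chain C, 95) with Cα at 8.5 Å, decoy alanines and two Ca ions.
  Exactly seven His Cα fall within 9 Å.
- `synthetic_icn_like_pair()` — two length-111 proteins differing at
  exactly 14 positions, 8 of them terminal, emulating a recently duplicated
  paralog pair at ≈ 87.4 % identity.

Both are arithmetic/geometric emulations of the published descriptions, not
the database entries; tests passing on them validate the pipeline's
computations, not properties of the real structures or sequences.

## Calibration checks and their designs

Two long-run checks verify statistical calibration across 200 seeds each:

- *Null growth calibration* uses 8 biological replicates at 3 doses: a
  sharper design than the default triplicate so the 4·SEM band has the
  intended coverage (with only three replicates the t₂ tails alone exceed
  the tolerated failure rate, regardless of implementation).
- *Fold recovery* compares each recovered group mean against the planted
  relative fold within 3 × the propagated SEM
  √(SEM_group² + (mean·SEM_reference)²); the reference term is needed
  because normalization divides every well by the same noisy reference
  mean, a component invisible to the within-group SEM.

## What passing tests do and do not show

The generators share the analysis pipeline's structural assumptions
(logistic growth, lognormal transfection efficiency, Gaussian plate noise,
rigid models). Passing tests demonstrates that the computations are correct
and well-calibrated under those assumptions; they say nothing about, e.g.,
diauxic growth, luminescence crosstalk, flexible-loop model error, or any
property of the real crystal structures and database sequences the
stand-ins emulate. The screen histograms over real predicted-model
ensembles additionally depend on an external model generator and are out of
scope here.

## Problem sizes

Default problem sizes (53-point growth grids, ≤ 30-residue fixture chains,
135-well reporter plates, 200-seed calibration loops) were chosen so the
whole suite and the acceptance script each run in well under a few minutes
on one CPU while keeping every statistical check adequately powered.
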
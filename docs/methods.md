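# Methods

This note records the models, defaults and numerical choices behind
`mtsprofile`, and what the synthetic-data experiments do and do not
establish.

## Sequence model and variables

A record is a species-labelled pair (MTS, mature sequence), the two
parts of a precursor split at the last residue of the targeting signal
(1-based `cleavage_pos`; mature numbering starts immediately after it).
Sequences are uppercase over the 20 standard residues; the unknown codes
X/B/Z/U/O/J are accepted up to a 5% per-part budget (configurable) but
excluded from all chemistry — they count toward length (a positional
property) and toward nothing else. Records violating these invariants
are rejected on load with per-record reasons rather than aborting the
dataset.

Each part is summarised by 12 variables: length; net charge at a
working pH (default 7.5); isoelectric point; and the fractions of nine
residue groups — non-polar aliphatic `a`={G,A,V,I,L}, non-polar aromatic
`f`={F,W}, non-polar cyclic `p`={P}, polar sulphur `c`={C,M}, polar
hydroxyl `s`={S,T}, polar aromatic `y`={Y}, polar acidic-amide
`n`={N,Q}, acidic `d`={D,E}, basic `b`={R,H,K}. The groups partition the
alphabet, so fractions sum to 1 over classified residues.

## Charge and pI

Net charge is the Henderson–Hasselbalch sum over ionizable side chains
(D, E, C, Y acidic; R, H, K basic) and, by default, the free N-terminal
amine and C-terminal carboxyl. Termini are ionized for both parts
because the mature N-terminus is free after cleavage; the flag is
configurable. The default pKa set is the simplified Bjellqvist table
(the set behind the common pI web calculators, with a generic N-terminal
7.5 in place of residue-specific values); EMBOSS and Lehninger sets ship
alongside, and the YAML resource is user-extensible. Because downstream
statistics are rank-based, the choice of set shifts absolute charges but
barely moves Spearman correlations; the active set name is echoed into
every output header.

The pI is the root of q(pH) on (0, 14). q is strictly decreasing in pH
and the termini guarantee a sign change, so bisection converges to the
unique root. The guaranteed tolerance is 1e-3 pH units, but the
implementation always runs its full iteration budget (60 halvings,
interval ~1e-17), which keeps |q(pI)| < 1e-3 even for sequences dense in
ionizable residues, where the titration curve is steep.

## Correlation analysis

Spearman's ρ is the product-moment correlation of mid-ranks (ties
handled), with a two-tailed p from t = ρ·√((n−2)/(1−ρ²)) on n−2 df —
the behaviour of the general statistics packages used for datasets in
the n = 35–85 per-species range. An exact permutation p (full
enumeration) is available for n ≤ 10. Cells with fewer than 5 pairs
(after pairwise deletion of missing values) or zero variance are
reported as not-computed rather than failing the grid. Significance
classes are p<0.05 and p<0.01 on the raw p, mirroring how such grids are
conventionally reported; Benjamini–Hochberg q-values over the computed
cells are emitted in the long-format output for transparency but never
alter the class.

## PCA

PCA operates on the sample correlation matrix (columns standardized), so
eigenvalues sum to the number of non-constant variables and percent
variance is eigenvalue/p·100. Constant columns are dropped with a
warning. Components are unrotated; loadings are eigenvector ×
√eigenvalue with the sign convention that each component's
largest-magnitude loading is positive. Default retention is the Kaiser
rule (eigenvalue strictly > 1); a fixed count is available. The pooled
MTS-only PCA, per-species MTS PCAs and a combined 24-variable
MTS+mature PCA are all emitted.

## Windows and secondary structure

Window coordinates are 1-based inclusive, counted from the first mature
residue. The windowed correlation table fixes the MTS side to {length,
charge at pH 7.5} and the mature side to the acidic-group fraction of
each window (defaults 1–40 and 41–80). Records whose mature chain does
not span a window are excluded from that window's statistics
(`require_full`): a truncated 41–80 window on a 60-residue chain is not
comparable to a full one. A `truncate` policy exists for exploratory
runs and is the default for the secondary-structure windows (1–50 and
51–100), where proportions over the available residues are meaningful
and the effective window length is recorded.

Secondary structure is consumed, never predicted: a per-residue string
over {H, E, L} plus a parallel disorder mask, length-checked against the
mature sequence. Finer state alphabets from upstream predictors must be
collapsed to these three before loading. Extreme-MTS groups are the k
shortest- and k longest-MTS records of a species, ties broken by
record_id so the selection is deterministic; k defaults to 10 for
species with ≥ 80 records and 5 otherwise. When annotations cover only
part of a dataset, groups are selected among annotated records. Group
differences use the tie-corrected Kruskal–Wallis H with a chi-square p
(df = groups − 1); the degenerate all-identical case returns H = 0,
p = 1 by definition rather than an error.

## Synthetic-data generator

The generator emulates the shape of a curated five-species
mitochondrial-matrix dataset; its defaults are the study conditions for
every self-contained experiment:

- species counts 85/84/56/35/36 (Hsap/Mmus/Scer/Atha/Osat);
- MTS length = 10 + negative binomial (mean 45, dispersion 3), capped
  at 120 — right-skewed lengths in the ~10–120 range;
- mature length = 70 + negative binomial (mean 380, dispersion 4),
  typical of matrix enzymes and long enough that the 41–80 window is
  nearly always present;
- MTS composition ~ Dirichlet (concentration 25) around means enriched
  in basic (0.24) and hydroxyl (0.18) groups and nearly devoid of
  acidics (0.02); mature composition ~ Dirichlet (concentration 80)
  around proteome-average group frequencies. The concentrations set the
  across-record spread to roughly what inter-protein composition
  variation looks like, looser for the short variable signals;
- segmental H/E/L annotations with geometric segment lengths (means
  10/5/6), state probabilities 0.40/0.25/0.35 and a 12% per-segment
  disorder probability.

Cross-part dependence is induced with a Gaussian copula over one latent
dimension per involved property. A target Spearman ρ_S maps to the
latent Pearson scale through the closed form ρ = 2·sin(π·ρ_S/6); an
infeasible combination of targets surfaces as a non-positive-definite
latent matrix and raises. Latent uniforms drive the margins
monotonically: the length margin through the negative-binomial quantile
function, a fraction margin through the Beta quantile of that group's
Dirichlet marginal (the remaining groups are rescaled to fill the
simplex). A record's composition **is** its Dirichlet draw: group counts
are apportioned deterministically (largest remainder) from
length × weight and only residue identity within a group is random, so
a realized fraction equals its latent weight up to 1/(2L) rounding and
the rank correlation measured in emitted sequences matches the request
without attenuation corrections. Supported target properties are length
and the nine group fractions on either side; charge and pI cannot be
margin-targeted directly (they emerge from composition), though they
inherit correlation through the basic/acidic fractions.

What the generator does **not** emulate: positional composition
structure along the chain (residues are exchangeable within a record,
so windowed fractions carry hypergeometric dilution of any whole-chain
signal), amphipathic helix periodicity, cleavage-site motifs,
phylogenetic correlation between species, and any coupling between MTS
length and secondary-structure annotations. Passing tests therefore
show the measurement and inference machinery is calibrated — not that
real MTSs behave like the simulation.

## Calibration experiments

Two stack-level experiments (in `mtsprofile.experiments`, reported by
`scripts/acceptance.py` and asserted in the test suite):

- **Parameter recovery.** 100 seeded replicates of n = 300 records with
  a single induced target (MTS length, mature acidic fraction,
  ρ* = 0.4); each replicate re-measures ρ̂ from the emitted sequences.
  The mean recovered ρ̂ sits within 0.01 of the target. Note that the
  classical finite-n expectation of Spearman's ρ under a Gaussian
  copula is slightly below the population value (≈ 0.399 here), and
  that the ±0.1 recovery band spans only ~2 asymptotic standard errors
  at this n, so per-replicate band coverage is intrinsically ~95%, not
  higher.
- **Type-I calibration.** 15 replicates of n = 300 under the null
  configuration (no induced targets): the pooled fraction of the
  144 × 15 cross-part cells with p < 0.05 must lie in [0.02, 0.08] — a
  conservative ±3σ binomial band that allows for the dependence among
  cells induced by composition closure. Observed: ~5.1–5.4%.

Problem sizes (100 × 300, 15 × 300) keep the full suite and the
reproduction script to roughly a minute each on one CPU while leaving
the Monte-Carlo error well inside the stated bands.

## Known limitations

- The windowed analysis fixes the mature-side variable to the acidic
  fraction (the scientifically motivated contrast); a generic
  window × variable crossing is a small extension of
  `windowed_group_fraction` but is not wired into the pipeline output.
- The Bjellqvist set here uses a generic N-terminal pKa rather than
  residue-specific values; absolute pI can differ from web calculators
  by a few hundredths of a pH unit.
- Exact permutation p-values enumerate up to 10! permutations and are
  meant for spot checks, not for grids.
- Pooled correlations mix species; with real data, species-level
  confounding (different length and composition baselines) can inflate
  or mask pooled associations relative to the per-species matrices,
  which is why both are always emitted.
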
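# mtsprofile

Physicochemical profiling and correlation analysis of N-terminal
mitochondrial targeting signals (MTSs) and the mature proteins they
import.

Matrix-destined precursor proteins carry an N-terminal presequence that
is removed after import. These signals share almost no sequence homology
and vary enormously in length, yet they are loosely characterised by a
positive net charge, enrichment in basic (R/H/K) and hydroxyl (S/T)
residues and a near-absence of acidic (D/E) residues. `mtsprofile` asks
a quantitative question about that diversity: **which properties of the
mature sequence co-vary with the properties of its targeting signal?**
It is a library (plus a thin CLI) for bench scientists and
bioinformaticians who have a curated set of species-labelled
(MTS, mature) sequence pairs — or who want to simulate one — and need
the complete statistical workup.

## What it computes

Every sequence part is summarised by 12 variables: length, net charge at
pH 7.5, isoelectric point, and the fractions of nine physicochemical
residue groups (a reduced amino-acid alphabet: non-polar
aliphatic/aromatic/cyclic, polar sulphur/hydroxyl/aromatic/acidic-amide,
acidic, basic). On top of these:

- **Charge model.** Net charge is a Henderson–Hasselbalch sum over
  ionizable side chains and free termini,
  `q(pH) = Σ_basic 1/(1+10^(pH−pKa)) − Σ_acidic 1/(1+10^(pKa−pH))`;
  the pI is its unique root, found by bisection. pKa sets (Bjellqvist
  default, EMBOSS, Lehninger) ship as an editable YAML resource.
- **Correlation grids.** 12×12 Spearman ρ matrices between MTS and
  mature variables, per species and pooled, with two-tailed p from the
  t approximation (exact permutation p optional at small n),
  significance classes p<0.05 / p<0.01, and Benjamini–Hochberg q-values
  reported alongside.
- **PCA.** Eigendecomposition of the correlation matrix of a property
  table, percent variance per component, Kaiser retention
  (eigenvalue > 1), and component loadings (eigenvector × √eigenvalue).
- **Windowed N-terminal analysis.** MTS length and charge correlated
  against the acidic fraction of fixed mature-sequence windows
  (default 1–40 and 41–80 residues after the cleavage site).
- **Secondary-structure comparison.** Given per-residue H/E/L +
  disorder annotations (from any upstream predictor), helix/strand/
  disorder proportions over the first and second 50 mature residues are
  compared between the shortest- and longest-MTS groups with a
  Kruskal–Wallis test.
- **Synthetic data.** A generator that emulates a curated five-species
  dataset (85/84/56/35/36 records, MTS lengths ~10–120, basic/hydroxyl-
  rich MTS composition, proteome-like mature composition) and can induce
  chosen rank correlations between MTS and mature properties through a
  Gaussian copula — so the whole pipeline is testable with no download.

## Worked example

```python
from mtsprofile import generate_dataset
from mtsprofile.pipeline import properties_table
from mtsprofile.stats import correlation_matrix

dataset, annotations = generate_dataset(seed=42)   # 296 records, 5 species
matrix = correlation_matrix(
    properties_table(dataset, "mts"),
    properties_table(dataset, "mature"),
)
cell = matrix.cell("length", "frac_d")
print(f"rho={cell.rho:+.3f}  p={cell.p:.2e}  [{cell.sig_class}]  n={cell.n}")
```

prints

```
rho=+0.425  p=2.01e-14  [p<0.01]  n=296
```

The generator induced a rank correlation of 0.4 between MTS length and
the mature acidic-residue fraction; the analysis recovers it from the
emitted sequences (ρ̂ = 0.425 on this seed) and flags it at p < 0.01.
Of the 144 grid cells, 24 reach p < 0.05 on this run — the induced
signal, its echoes through composition closure (fractions sum to one),
and a few chance hits. The `examples/` directory walks through each
capability the same way (`python examples/02_correlation_matrix.py`, …).

From the shell:

```bash
mtsprofile simulate --seed 42 --out sim/
mtsprofile analyze --dataset sim/dataset.tsv --annotations sim/annotations.tsv --out report/
```

`report/` then holds per-record property tables, per-species and pooled
correlation matrices (wide and long form), PCA summaries and loadings,
the windowed correlation table, the secondary-structure comparison and a
manifest recording every tunable. Real datasets use the same TSV layout
(`record_id`, `species`, `gene_id`, `accession`, `mts_seq`,
`mature_seq`) or a FASTA dialect with `cleavage=<k>` in the header.

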
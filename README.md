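# stabscan

Rapid prediction of protein stability changes (ΔΔG, kcal/mol) for single
amino-acid substitutions, directly from structure, with the saturation-scan
and variant-analysis machinery needed to use such predictions at scale.

Changes in folding free energy are a major mechanism by which missense
variants cause disease: a destabilized protein is degraded, and its
function is lost. Physics-based estimators (Rosetta, FoldX) are accurate
but far too slow for proteome-scale scans. `stabscan` implements the
two-stage machine-learning shortcut:

1. **Representation model** — a self-supervised 3D convolutional network
   sees the voxelized atomic environment within 9 Å of a residue's Cα
   (the residue's own atoms masked out; six element channels C, N, O, H,
   S, P on a 1 Å³ grid, Gaussian-blurred) and is trained to classify the
   missing wild-type amino acid. Its 100-dimensional hidden layer becomes
   a reusable description of the structural context. Architecture: three
   conv(3³)→batch-norm→leaky-ReLU→max-pool(2³) blocks with 16/32/64
   filters, then fully connected layers of 100 and 20 nodes; trained with
   Adam (lr 3·10⁻⁴, batches of 100 residues), split strictly by protein.
2. **Downstream regressor** — for a substitution wt→mut, the
   142-dimensional vector [environment representation | one-hot wt |
   one-hot mut | background frequencies of wt and mut] passes through
   fully connected layers of 128/64/16 nodes to a sigmoid scalar.
   Targets are ΔΔG values compressed by the Fermi (logistic switching)
   function

   F(ΔΔG) = 1 / (1 + e^{−β(ΔΔG−α)}),  β = 0.4 (mol/kcal), α = 3.0 kcal/mol,

   which focuses learning on the −1…7 kcal/mol range; the loss is the
   mean absolute error in this transformed space (MAE_F), with Adam
   (lr 5·10⁻⁴, batches of 40 variants). Predictions are the **median of a
   10-replica ensemble** (independently seeded), inverted back to
   kcal/mol. Training tables in Rosetta energy units are converted to
   kcal/mol by dividing by 2.9. Variants at disulfide-bonded cystines are
   removed from training and flagged at prediction time.

On top of this sit: saturation scanning (all 20 substitutions at every
resolvable position of a chain), burial annotation by relative
solvent-accessible surface area (Shrake–Rupley SASA over Sander–Rost
maxima, exposed iff ≥ 0.2), variant-table joining with wild-type
consistency checks, allele-frequency binning, and a bootstrap estimator
(10⁴ resamples) for the difference in median ΔΔG between variant classes.

Everything is testable offline: `stabscan.fixtures` generates seeded toy
structures with ideal backbone geometry and identity-correlated pseudo
side chains, plus synthetic ΔΔG landscapes that are a known deterministic
function of (wild type, mutant, burial) with Gaussian noise. The neural
networks are implemented in numpy (exact gradients, verified by
central-difference tests; deterministic given seeds).

## Worked example

The Fermi algebra in two lines:

```python
>>> from stabscan import fermi_transform, inverse_fermi
>>> fermi_transform(3.0)        # at the midpoint alpha
0.5
>>> inverse_fermi(0.5)
3.0
```

A complete toy pipeline from the shell (generate fixtures, train both
stages small, scan a protein, annotate variants):

```sh
stabscan make-fixtures --out fx --n-proteins 4 --n-residues 16 --seed 3
stabscan train-repr --pdb-dir fx --out repr.npz --reduced --max-epochs 2 --seed 0
stabscan train-ddg  --pdb-dir fx --table fx/training_ddg.csv \
                    --repr repr.npz --out ens.npz --ensemble-size 2 --max-epochs 2
stabscan scan --pdb fx/toy_ideal_helix_3.pdb --repr repr.npz \
              --ensemble ens.npz --out scan.csv
stabscan annotate --scan scan.csv --variants fx/variants.tsv --out ann.tsv
```

which prints (numbers from the run above):

```
320 predictions (16 sites) -> scan.csv
matched 45, rejected 8 wild-type mismatches, 147 without coverage
benign: n=25 median=1.61 central95=(0.53, 2.72) kcal/mol
pathogenic: n=20 median=2.39 central95=(0.63, 3.52) kcal/mol
pathogenic - benign median difference: 0.79 kcal/mol (95% CI 0.02 - 1.37, 10000 resamples)
```

The scan CSV has one row per (position, mutant amino acid) — 20 per site,
the wild-type "self" row flagged with ΔΔG = 0.0 — with Fermi-space scores
and ΔΔG in kcal/mol. The annotate step rejects variant rows whose stated
wild type disagrees with the structure (8 decoys above were planted by the
fixture generator) and reports, per variant class, the median ΔΔG, the
central 95% range, and the bootstrap difference of medians: pathogenic
variants are systematically more destabilizing than benign ones.

## Layout

| module | contents |
|---|---|
| `stabscan.structure` | PDB parsing/validation, element channels, residue sites |
| `stabscan.voxel` | local frames, masked environments, voxel grids, blurring |
| `stabscan.representation` | the 3D-CNN wild-type classifier and its training |
| `stabscan.ddg` | Fermi algebra, features, cystine filter, ensemble regressor |
| `stabscan.scan` | saturation scans, SASA burial, scan CSV format |
| `stabscan.analysis` | variant joins, AF binning, bootstrap statistics |
| `stabscan.fixtures` | seeded toy structures, ΔΔG landscapes, variant tables |

See `docs/methods.md` for the modelling choices, defaults and known
limitations.
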
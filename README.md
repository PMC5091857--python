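# delimkit

Integrative DNA-barcoding species delimitation for regional biodiversity
surveys. `delimkit` is aimed at the situation faced by taxonomists working
on poorly sampled, species-rich groups (the motivating system is Amazonian
*Scinax* treefrogs barcoded with 16S rRNA): single-locus sequences delimit
*putative* units, and morphology, advertisement calls and prior
multi-locus work decide which of those units deserve candidate-species
status.

The package provides, as a library and a `delimkit` command line tool:

- **K2P distances** with pairwise deletion. For transition and transversion
  proportions P, Q over pairwise-complete sites,
  `d = -½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q)`; pairs with
  `1 − 2P − Q ≤ 0` or `1 − 2Q ≤ 0` are flagged saturated, never silently
  numeric.
- **Barcode-gap delimitation** (ABGD-style): ranks pairwise distances,
  skips ranks up to a prior intraspecific limit *P* (default 3%), finds the
  first gap exceeding *X* (default 1.0) times the local gap scale, splits by
  single linkage at the gap midpoint, and recurses within groups (up to 10
  rounds).
- **Single-threshold GMYC**: on an ultrametric gene tree, a threshold time
  *T* separates Yule-like speciation branching (rate `λ_S·k^{p_S}`) from
  within-entity neutral coalescence (rate `λ_C·Σ_j [n_j(n_j−1)]^{p_C}`);
  the interval log-likelihood `Σ_i (ln b_i − b_i x_i)` is maximized over a
  scan of inter-node-height midpoints and tested against the one-process
  null by a likelihood-ratio test (χ², df 3 by default). A UPGMA fallback
  builds a tree when no time-calibrated genealogy is supplied.
- **Reconciliation and classification**: where the two methods disagree,
  the more conservative grouping (fewer units) wins unless morphology,
  calls, or a prior reference delimitation support the finer split; final
  units are classified as nominal species (NS), confirmed candidate species
  (CCS), unconfirmed candidate species (UCS), or deep conspecific lineages
  (DCL), and cryptic-diversity percentages are computed as
  `100·U/(U+D)` (undescribed share) and `100·U/D` (increase), with
  `U = |CCS| + |UCS|`.
- **A synthetic-data generator** (Yule species tree → multispecies
  coalescent → K2P sequence evolution → stochastic evidence) with known
  ground truth, used throughout the test suite.

## Worked example

The package ships a lineage-level encoding of an integrative delimitation
of *Scinax* treefrogs from the Purus–Madeira region (two molecular
delimitations, the differentiability evidence between lineages, and a
focal-region flag). Running

```sh
python analysis/04_integrate_case_study.py
```

prints

```
encoded delimitations (focal region): 13 distance-based, 12 tree-based units
consensus: 12 focal units — 2 NS, 7 CCS, 2 UCS, 1 DCL
baseline regional (D=2): 82% undescribed, +450% over the described richness
baseline amazonia_unassigned (D=21): 30% undescribed, +43% over the described richness
```

Reading: the two molecular methods disagree on three lineage sets; after
conservative reconciliation (with one reference-evidence override) 12 focal
units remain, of which 9 (7 CCS + 2 UCS) are undescribed species-level
taxa. Against the two described species recorded in the region that is an
82% undescribed share and a 4.5-fold increase; against the 21 unassigned
Amazonian congeners, 30% and a 43% increase.

The synthetic end-to-end run works the same way from sequences:

```sh
python analysis/01_simulate_dataset.py   # 8 species × 4 specimens, 550 bp
python analysis/02_distance_delimitation.py
python analysis/03_tree_delimitation.py
```

which reports exact recovery of the 8 simulated species by the barcode-gap
partitioner and by the GMYC fit (`entities: 8`, LR = 47.8, p ≈ 2e-10 on the
bundled seed).

Equivalent CLI entry points: `delimkit simulate|distances|abgd|gmyc|classify|run`
(see `delimkit --help`).

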
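# bfhc

Topological **B**ay / **F**jord / **H**arbor / **C**anyon (BFHC) indices and
fused-ring topology classification for polycyclic aromatic hydrocarbons
(PAHs), computed directly from Cartesian coordinates.

Given a C/H-only structure (plain XYZ or Gaussian-input Cartesian block) the
pipeline:

1. perceives bonds from covalent-radii thresholds (`rC = 0.76`, `rH = 0.31`,
   tolerance `0.40` Å by default; H–H bonds are never formed);
2. assigns degree-based atom types (`H`, `sp`, `sp2`, `sp2-H`, `sp3`);
3. finds a minimum cycle basis of the carbon skeleton (rings of size ≤ 7),
   builds the inner dual graph, and traces the perimeter walk of each fused
   component;
4. scans the perimeter for maximal runs of junction carbons (ring membership
   ≥ 2).  A run of length *k* flanked by rim carbons gives a
   **fissure** (k = 1), **bay** (k = 2, 4-atom path), **fjord** (k = 3,
   5-atom path), **harbor** (k = 4, 6-atom path) or **canyon** (k = 5,
   7-atom path); longer runs are reported as *extended*.  An optional
   geometry filter (endpoint distance ≤ 4.5 Å, endpoints non-bonded) marks
   structurally invalid candidates;
5. classifies the fused-ring topology as **linear** (acene-type),
   **angular** (cata-condensed, bent/branched) or **peri-condensed**
   (some carbon in ≥ 3 rings).

It also models the accompanying metadata table (BFHC counts, topology class,
the seven-level carcinogenicity vocabulary `-, ±, L, LM, M, HM, H`, log P,
log Iball), with CSV/XLSX ingest, ordinal encoding, summaries, and
cross-validation of recorded values against recomputation from structures.
A benzenoid builder generates idealized fixtures (acenes, kinked
cata-condensed systems, peri-condensed systems, nonplanar helicenes via
spiral z-offsets) with ground-truth connectivity for testing.

## CLI

```sh
bfhc generate --compound phenanthrene -o phen.xyz   # built-in fixtures
bfhc generate --random --cells 6 --seed 3 -o r.xyz  # random polyhex
bfhc compute phen.xyz                               # motif table to stdout
bfhc compute *.xyz -o table.csv                     # metadata CSV
bfhc validate --table table.csv --structures dir/   # recompute + diff
bfhc summarize --table table.csv                    # dataset counts
```

`bfhc compute` accepts `--no-geometry-filter`, `--geometry-max-distance`,
`--endpoint-policy any|hydrogen-only` and `--tolerance`.

## Python API

```python
import bfhc

built = bfhc.canonical("hexahelicene")      # fixture + ground-truth bonds
result = bfhc.analyze(built.molecule)
result.bfhc()          # (0, 0, 0, 1)  -> one canyon
result.topology        # "angular"
print(bfhc.report_motifs(result.motifs))
```

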
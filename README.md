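# synergyscreen

Ligand-based virtual screening with strategies for combining 2D
fingerprint similarity and 3D shape similarity.

Similarity-based virtual screening ranks a compound library by its
similarity to one or more known active molecules (the *queries*). 2D
methods compare hashed circular fingerprints; 3D methods compare
molecular shape and pharmacophoric features. The two channels retrieve
largely different active chemotypes, so combining them can recover more
— and more diverse — actives than either channel alone. This package
implements the full strategy stack for exploiting that synergy, plus the
evaluation machinery to measure it, for computational chemists running
or benchmarking ligand-based screens:

- **Library preparation** (`synergyscreen.libprep`): salt stripping,
  molecular-weight window (250–1500 Da), element filter, activity
  labelling from potency records (active < 10,000 nM in Kd / AC50 /
  IC50 / Ki / EC50 / Potency; inactive > 20,000 nM), stereo-completeness
  filter for active candidates, Bemis–Murcko scaffold extraction.
- **2D screening** (`screen2d`): Morgan fingerprints (radius 2,
  1024 bits) with Tanimoto ranking, `T(a,b) = c / (|a| + |b| − c)`.
- **3D screening** (`screen3d`): a pluggable shape channel with the
  two-component score contract `total = shape + color ∈ [0, 2]`
  (each component in [0, 1]). Ships an alignment-free,
  rotation/translation-invariant reference scorer based on USR-style
  distance-distribution moments with pharmacophore-class sub-moments;
  scores from any external shape engine can be loaded instead.
- **Fusion** (`fusion`): the three combination strategies —
  1. *MAX fusion* of multi-query hit lists: each compound gets the best
     score it obtained with any query;
  2. *parallel selection* of two methods' hit lists at a chosen ratio
     (1:1 balanced, 9:1, ...), transferring the next not-yet-included
     compounds from each list in turn, duplicates replaced by the next
     unique entry;
  3. the *integrated* strategy: balanced parallel selection of the
     MAX-fused multi-query 2D and 3D lists.
- **Metrics** (`metrics`): ROC AUC (exact Mann–Whitney pair counting),
  enrichment factors EFk% for k ∈ {1, 3, 5, 10}, scaffold recovery rate
  SRRk% (fraction of distinct active scaffolds found among the actives
  in the top k%), the two-list scaffold-overlap decomposition, and the
  paired Wilcoxon signed-rank test (exact for small samples).
- **Benchmark** (`benchmark`): a synthetic deck generator with planted
  scaffold families and two partially overlapping similarity channels,
  a SMILES fixture generator for end-to-end chemistry tests, and an
  experiment runner implementing the multi-query protocol (nested query
  sets of sizes 1–5, 30 repeats, queries removed from the deck).

## Worked example

Generate the synthetic chemistry deck (3 active scaffold families × 5
R-group analogs + 50 decoys), prepare it, screen with one query per
family, MAX-fuse and evaluate:

```
$ synergyscreen fixtures --out raw.csv
wrote 65 compounds
$ synergyscreen prep --in raw.csv --out lib.csv
kept 65 compounds, rejected 0
$ synergyscreen screen2d --queries queries.smi --library lib.csv --out scores2d.csv
scored 3 queries x 62 compounds
$ synergyscreen fuse --scores scores2d.csv --out ranks2d.csv
wrote 62 ranked compounds (fused2d)
$ synergyscreen evaluate --ranks ranks2d.csv --labels lib.csv --k 1,5,10 --out report.json
AUC 1.000; EF1% 5.17; EF5% 5.17; EF10% 5.17
```

Here `queries.smi` holds one active per family (the three queries are
removed from the evaluated deck, leaving 12 actives among 62
compounds). AUC 1.0 means every remaining active outranks every decoy —
expected, since each query's family analogs are highly fingerprint-
similar to it. EF1% = 5.17 is the maximum attainable on this deck: the
top 1% holds a single compound, and it is active, so the active rate in
the top list (1.0) is 5.17× the deck's base rate (12/62). The report
also gives SRR values: one of the three scaffold families is recovered
within the top 1% (SRR1% = 0.33).

Python API equivalent:

```python
from synergyscreen import benchmark as bm, fusion, metrics, screen_2d

df = bm.generate_smiles_fixture(n_families=3, r_groups_per_family=5, n_decoys=50)
...
ranking = fusion.max_fuse(screen_2d(queries, library))
report = metrics.evaluate(ranking, labels, scaffolds, k_list=(1, 10))
```

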
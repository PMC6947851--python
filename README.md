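# groupsep

Group-separation statistics for multi-locus bacterial sequence
collections — built for the kind of question rhizobium population
studies ask: do isolates from one host plant form a genetically
distinct group relative to reference biovars, how deep is the
separation, and how much of the diversity is explained by geography?

Given pre-aligned per-locus FASTA files (typically a core set of
housekeeping genes, *hkg*, and an accessory set of symbiotic genes,
*sym*) plus a strain table with group labels and sampling coordinates,
the package computes, per gene and per category concatenate:

- **p-distance matrices** with pairwise deletion (plus JC69 and K2P
  corrected distances), and great-circle geographic distance matrices;
- **nucleotide differentiation** N<sub>st</sub> = (R<sub>t</sub> −
  R<sub>s</sub>)/R<sub>t</sub>, where R<sub>t</sub> is the mean pairwise
  p-distance over the pooled pair of groups and R<sub>s</sub> the
  within-group diversity, with a seeded bootstrap over alignment
  columns for confidence intervals;
- **jackknife (JK) group assignment**: each sequence is removed and
  assigned to the group with the highest mean similarity
  100·(1 − p-distance) among the remaining sequences, giving an
  (asymmetric) assignment-percentage matrix and the coefficient of
  average divergence CAD = 100 − within-group JK similarity;
- **Mantel tests** of genetic-vs-geographic distance correlation with a
  seeded permutation null (one-sided, add-one p-value);
- **neighbour-joining trees** with column-bootstrap bipartition
  supports, written as Newick;
- a **hkg/sym diversity-ratio** comparison with a hierarchical
  bootstrap (loci and strains-within-locus).

A synthetic-data generator produces multi-locus collections with
controllable between/within-group divergence, per-category divergence
multipliers, group "coherence" (how star-like a group's ancestry is),
and isolation-by-distance coupling to geography — so every stage of the
pipeline is testable without any sequence downloads.

## Worked example

```python
import numpy as np
from groupsep import (simulate, scenario_config, groups_from_metadata,
                      concatenate, distance_matrix, nst_bootstrap, jk_assign)

alns, meta, truth = simulate(scenario_config("paperlike", seed=7))
groups = groups_from_metadata(meta)
sym = concatenate([a for a in alns if a.category == "sym"], "sym")
hkg = concatenate([a for a in alns if a.category == "hkg"], "hkg")

pair = {"Vaf": groups["Vaf"], "Rlv": groups["Rlv"]}
for name, cc in [("hkg", hkg), ("sym", sym)]:
    res = nst_bootstrap(cc, pair, n_boot=1000, seed=7)
    print(f"{name} concatenate: R_s={res.R_s:.4f} R_t={res.R_t:.4f} "
          f"N_st={res.N_st:.3f} 95% CI=({res.ci95[0]:.3f}, {res.ci95[1]:.3f})")

jk = jk_assign(distance_matrix(sym), groups, seed=7)
print(jk.groups, np.round(jk.assignment_pct, 1), sep="\n")
```

prints

```
hkg concatenate: R_s=0.0299 R_t=0.0340 N_st=0.119 95% CI=(0.079, 0.161)
sym concatenate: R_s=0.0377 R_t=0.0464 N_st=0.187 95% CI=(0.145, 0.227)
['Vaf', 'Rlv', 'Rlt']
[[100.   0.   0.]
 [  0. 100.   0.]
 [  0.   0. 100.]]
```

The focal group (here labelled `Vaf`) differentiates from the related
reference group (`Rlv`) about 1.6× more strongly on the symbiotic
concatenate than on the housekeeping one (N<sub>st</sub> 0.187 vs
0.119, non-overlapping bootstrap CIs), while the leave-one-out
classifier assigns every strain to its own group on the sym
concatenate — the signature of host-associated divergence of the
accessory genes.

## Command line

```bash
groupsep simulate --fixture paperlike --seed 1 -o data/
groupsep run -c config.yaml          # full pipeline -> TSVs + Newick + manifest
groupsep nst  --fasta data/nodD.fasta --metadata data/metadata.csv \
              --group-a Vaf --group-b Rlv --seed 1
groupsep jk   --fasta data/nodD.fasta --metadata data/metadata.csv --seed 1
groupsep mantel --fasta data/gltA.fasta --metadata data/metadata.csv --seed 1
groupsep tree --fasta data/nodD.fasta --seed 1 -o nodD.nwk
```

`groupsep run` takes a YAML config naming the per-locus FASTA files
(with categories), the metadata table, the analyses to run, bootstrap
and permutation sizes, and one seed; it writes per-analysis TSVs,
Newick trees, and a manifest echoing the configuration and collecting
any per-locus errors.

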
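# motifkey

Network-motif detection and key-regulator ranking in directed pathway
graphs, with hypergeometric enrichment statistics for ranked gene lists.

## The problem

Disease pathways (colorectal cancer being the motivating case) are sparse
directed graphs over genes. Their regulatory logic concentrates in *network
motifs*: small connected subgraph classes — chains, single/multiple input
modules, bifans — that occur far more often than in degree-matched random
networks. Once the over-represented classes are known, the question a
systems biologist actually cares about is *which genes carry them*: a class
whose many instances keep reusing the same few genes points at key
regulators.

`motifkey` implements that whole chain of reasoning as a library + CLI for
anyone who has a pathway as an edge list and wants candidate key genes out:

1. **Enumeration** — every connected induced k-node subgraph (3 ≤ k ≤ 8) is
   visited exactly once (ESU); a sampling variant (RAND-ESU) gives unbiased
   count estimates on large graphs. Classes are identified by a canonical
   row-major adjacency bitstring.
2. **Null statistics** — R degree-preserving edge-switching randomizations
   give, per class, z = (N_real − mean_rand)/sd_rand, an add-one empirical
   p-value, and the significance profile SP(m_i) = z(m_i)/√(Σ_j z(m_j)²);
   classes with z > 2 and p < 0.05 are significant.
3. **Key-gene parameters** — per class, with freq(g) the number of
   instances containing gene g:
   FN = #distinct genes, FTN = Σ freq(g) = k·#instances, FT = FN/FTN.
   Low FT ⇔ few genes recur across many instances. The minimal-FT class
   among significant classes is selected and its genes ranked by frequency.
4. **Enrichment** — the exact hypergeometric upper tail
   P(X ≥ a | N, A, n) and the minimum-hypergeometric score
   mHG(λ) = min_n HGT(N, K, n, k_n) over all prefix cutoffs of a ranked 0/1
   label vector, calibrated by a permutation p-value.

A synthetic-data module generates sparse pathway-like graphs with planted
motif copies (optionally overlapping, so a small regulator set recurs
across instances) and ranked label vectors with planted top-enrichment, so
every stage is testable end to end without any database access.

The package also ships a published reference table of 55 motif classes
with their (FN, FTN, FT) values as a packaged fixture; `motifkey
replay-table1` recomputes every FT and selects the key class from it.

## Worked example

```python
import motifkey as mk

# a synthetic 60-gene pathway; five overlapping bifan copies planted on a
# 70-edge sparse background
bundle = mk.synthesize(mk.SyntheticConfig(seed=7, overlap_fraction=1.0))
graph = bundle["graph"]

from motifkey.cli import PipelineConfig, run_pipeline
out = run_pipeline(
    PipelineConfig(k_min=4, k_max=4, ensemble_size=100, seed=7),
    graph=graph,
)
key = out["key_record"]
print(key.motif.bits, f"FT={key.ft_display:.3f}")
for gene, freq in out["key_genes"][:4]:
    print(gene, freq)
```

prints

```
0000000011001100 FT=0.082
g0017 45
g0059 45
g0006 13
g0005 12
```

The selected class is the planted bifan (two regulators × two targets,
written as its canonical 16-bit adjacency string). Its FT of 0.082 is the
minimum over all significant 4-node classes. The two genes with frequency
45 are the planted shared regulators — they sit in every instance of the class, which is
exactly the signature the FT parameter is designed to expose; the ranked
list below them are the rotating target genes.

Replaying the packaged reference table:

```bash
$ motifkey replay-table1 | tail -1
# key motif: 7n (FT=0.171), 55/55 rows match
```

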
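# omicsmap

Hyperbolic mapping of a lipid–metabolite–protein network, for researchers
who need to move between omics layers: given a set of molecules from one
layer (say, proteins dysregulated in a disease), find the lipids and
metabolites most functionally associated with them.

The package builds a three-layer molecular network (a confidence-filtered
protein–protein interaction core with lipids and metabolites attached via
enzymatic-reaction and GWAS edges), embeds it in the two-dimensional
hyperbolic plane under the popularity–similarity model, and turns the
resulting coordinate table into answers:

* **Embedding** (LaBNE + HyperMap): angles from the first two non-trivial
  eigenvectors of the symmetric normalized graph Laplacian, radii from the
  degree ranking r_i = 2β ln i + 2(1−β) ln N with β = 1/(γ−1), refined by a
  windowed maximum-likelihood search under the Fermi–Dirac connection
  probability p(x) = 1/(1 + e^{(x−R)/2T}).
* **Distances**: d(s,t) = acosh[cosh r_s cosh r_t − sinh r_s sinh r_t cos Δθ]
  with Δθ = π − |π − |θ_s − θ_t||.
* **Clustering**: circular sectors cut at the largest angular gaps, subject
  to a minimum of 10 protein members per sector, annotated by a
  hypergeometric over-representation test with Benjamini–Hochberg
  correction.
* **Ranking**: each target molecule t of a non-input layer scores
  score(t) = 1/Σ_{i=1..n} d_i, the reciprocal sum of its n smallest
  distances to the input subset (n = 3 by default), with an evidence trail
  of the contributing molecules.
* **Simulation**: a popularity–similarity model generator with known
  ground-truth coordinates, used as fixture source and embedding-validation
  oracle.

## Worked example

Simulate a toy three-layer map, embed it, and rank lipids against a protein
subset:

```sh
omicsmap simulate --n 300 --m 3 --gamma 2.5 --temp 0.2 --seed 1 \
    --lipids 15 --metabolites 10 --out-prefix toy
# wrote toy.nodes.tsv / .edges.tsv / .truth.tsv (317 nodes, 946 edges)

omicsmap embed --network-prefix toy --gamma 2.5 --temp 0.2 \
    --window 0.785 --grid 90 --out coords.tsv
# wrote coordinates for 317 nodes to coords.tsv

printf 'P001\nP002\nP003\nP004\nP005\n' > subset.txt
omicsmap rank --coords coords.tsv --input subset.txt \
    --input-type protein --n-nearest 3 --out-prefix cvd
# wrote 15 ranked lipids to cvd.lipid.csv
# wrote 10 ranked metabolites to cvd.metabolite.csv

head -4 cvd.lipid.csv
# rank,id,score,evidence,distance_sum
# 1,SLM:000000003,0.027399623942809318,P001:10.086736;P005:10.237060;P002:16.173055,36.49685127384521
# 2,SLM:000000005,0.026517326295854,P002:11.157983;P004:11.486448;P001:15.066761,37.71119263092338
# 3,SLM:000000004,0.02350881768325393,P002:13.738520;P003:13.853742;P001:14.944969,42.537230645687956
```

Reading the output: the top-ranked lipid `SLM:000000003` sits a summed
hyperbolic distance of 36.5 from its three nearest input proteins
(P001, P005, P002 — the evidence column, nearest first), giving the score
1/36.5 ≈ 0.0274.  Higher scores mean stronger association; scores are only
comparable within one run of one map.

The same coordinate table feeds `omicsmap cluster` (angular sectors),
`omicsmap enrich` (sector annotation against a `term<TAB>id` file) and
`omicsmap plot` (disk scatter).  To build a map from real data instead,
start from `omicsmap build --ppi hippie.tsv --cross lipids.tsv --cross
metabolites.tsv --score-threshold 0.71 --out-prefix net`, then `omicsmap
embed --network-prefix net` (defaults γ = 2.98, T = 0.84, w = 2π).  File
schemas are documented in `docs/formats.md`, the model and its validation
in `docs/methods.md`.

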
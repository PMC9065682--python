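# polyreco

Automatic labeling of collinear regions on Ks dotplots and recognition of
polyploidy events (whole-genome duplication vs. triplication).

## The problem

When a target genome is compared with a reference genome, each homologous
gene pair is a point on the *Ks dotplot*: x = the gene's order rank on its
target chromosome, y = the rank on the reference chromosome, coloured by
the synonymous substitution rate Ks (a proxy for the age of the
duplication that separated the two copies). Segments descending from a
common ancestral segment keep their gene order, so they appear as diagonal
runs. A genome that went through a whole-genome duplication (WGD) retains
two collinear copies of every reference segment; a triplication (WGT)
retains three. Reading the multiplication level off such a plot by eye is
slow and subjective; `polyreco` does it algorithmically:

1. **Cluster** — within each *comparison unit* (one target chromosome ×
   one reference chromosome cell of the plot), dots in the displayed Ks
   range 0–2 are clustered with DBSCAN (Euclidean distance on rank
   coordinates, defaults eps = 50, MinPts = 3). Each cluster becomes a
   labeled bounding box with corners (l_x, l_y)/(r_x, r_y), gene count
   `num`, length Δy = l_y − r_y and width Δx = r_x − l_x → `cluster.csv`.
2. **Merge** — boxes of a unit are fused into collinear regions when their
   axis gaps are small: for disjoint boxes, 0 ≤ y_gap ≤ *gap* and
   0 ≤ x_gap ≤ *Slen*; for boxes overlapping in y, 0 ≤ x_gap < *Slen*; for
   boxes overlapping in x, 0 ≤ y_gap ≤ *gap* (*gap* = mean vertical gap
   between adjacent boxes of the unit, *Slen* = 1/6 of the target
   chromosome length) → `combine.csv`.
3. **Combine** — per reference chromosome *i*, regions are grouped into
   *combination rounds*: seed on the longest remaining region, add the
   y-disjoint set of shorter regions that maximises the round's total
   length `sumy` (exhaustive search), repeat until no region is left.
   Each round is scored with the collinearity evaluation index

   &nbsp;&nbsp;&nbsp;&nbsp;MI = Σₘ Δyₘ / lenᵢ

   — the fraction of reference chromosome *i* covered by the round
   → `result.csv` and the MI line chart.
4. **Call** — MI stays high for as many rounds as there are retained
   copies, then collapses; the round with the largest MI drop (the
   inflection) is the chromosome's multiplication level, and the modal
   level across reference chromosomes is the genome-wide call
   (2 → WGD, 3 → WGT).

A synthetic-dotplot generator (`polyreco.simulate`) plants k-fold
polyploidy structure with gene loss, fragmentation and background noise,
so the whole pipeline is testable without any genome download.

## Worked example

The package bundles the labeled-region table a willow genome leaves on
grape chromosome 13 (six merged regions; `polyreco.examples`). Combining
them:

```sh
polyreco recognize --boxes grape13_combine.csv --ref-len grape.len -o out --no-figures
# multiplier 2 (whole-genome duplication); report in out/report.json
cat out/result.csv
# chr1,chr2,id,l_x,l_y,num,r_x,r_y,Sumy,Δy,Δx,Comro
# 8,13,2,78,1089,239,605,446,947,643,527,1
# 16,13,1,1163,283,42,1235,91,947,192,72,1
# 8,13,1,592,1267,56,671,1155,947,112,79,1
# 10,13,2,1419,1088,276,1934,457,909,631,515,2
# 9,13,1,378,257,63,478,89,909,168,100,2
# 10,13,1,1327,1267,65,1426,1157,909,110,99,2
cat out/mi.csv
# comro,13
# 1,73.93
# 2,70.96
```

Round 1 (willow chromosomes 8 and 16, sumy = 947, MI = 73.93 %) and round
2 (willow 9 and 10, sumy = 909, MI = 70.96 %) each tile almost three
quarters of grape chromosome 13; there is no comparable third round, so
the inflection sits at round 2: one recent whole-genome duplication.

The same end to end on synthetic data:

```sh
polyreco simulate -k 3 --seed 42 -o dots.tsv \
    --ref-len-out ref.len --target-len-out target.len --truth-out truth.json
# wrote 5413 dots to dots.tsv
polyreco recognize dots.tsv --target-len target.len --ref-len ref.len -o out
# multiplier 3 (whole-genome triplication); report in out/report.json
```

with `out/mi.csv` showing three ~99 % rounds per reference chromosome
before the collapse — the planted triplication.

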
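# zonemap

Quantitative mapping of spatial expression zones of olfactory receptor
genes from serial-section cell positions.

Olfactory sensory neurons expressing a given receptor gene are scattered
across a shared sensory surface, yet different genes occupy statistically
distinct, broadly overlapping spatial domains.  `zonemap` is for
researchers who label such cells by in situ hybridization on complete
series of horizontal sections of a cup-shaped (rosette) olfactory organ
and want to turn per-cell measurements into defensible statements about
expression zones.

The pipeline:

1. **Normalize** each labeled soma into three relative coordinates —
   laminar height `h_rel = h_soma/thickness` (0 basal → 1 apical),
   relative radius `r_rel = r_soma/lamella_length` (0 innermost → 1
   outermost), and organ height `z_rel = section/(total−1)` (0 top → 1
   bottom) — excluding the radial value on the short-lamella top sections.
2. **Describe** each gene's distribution per coordinate by its unbinned
   ECDF, quartiles, and half-width `hw = Q3 − Q1`.
3. **Compare** all gene pairs with the two-sample Kolmogorov–Smirnov test,
   `D = sup_x |F_a(x) − F_b(x)|`, significance at raw `p < 0.01`.
4. **Partition** genes into zones: per coordinate, the maximal cliques of
   the indistinguishability graph (possibly overlapping); combined over
   all three coordinates, the connected components (disjoint zones).

A seeded synthetic organ generator (logit-normal coordinate laws, Poisson
section counts, 40–60 sections/organ, 5 organs/gene) makes every stage
testable without access to raw microscope data, and a curation module
implements the acceptance filters for candidate receptor-family sequences
(gap-column stripping, >98%-identity allele collapse, distributed-difference
rule, unique-locus check, >80% clade-support filter).

## Worked example

```python
import zonemap as zm

raw = zm.make_fixture(seed=11)          # synthetic raw measurement table
res = zm.ZoneModel.from_raw(raw).fit(seed=11)
print(res.summary())
```

prints (abridged):

```
Spatial expression-zone analysis
================================================
cells: 18493   genes: 9   sparse genes: 6
KS method: asymptotic   significance cutoff: p < 0.01

Distribution descriptors (pooled over organs)
 gene coordinate    n    q1  median    q3  half_width
   g1    laminar  425 0.650   0.714 0.767       0.117
   j1    laminar  539 0.499   0.603 0.692       0.193
   n1    laminar  449 0.592   0.673 0.729       0.137
 ...
   u1     radial  500 0.324   0.427 0.561       0.237
   u1          z  505 0.164   0.291 0.455       0.291

laminar median range: 0.600-0.714 (spread 11% of layer height)

laminar groups (maximal cliques): g1 | j1,t1 | n1,q1,u1
radial groups (maximal cliques): g1,n1,q1 | j1,u1 | t1
z groups (maximal cliques): g1,j1,n1,q1,t1 | u1
combined zones (5): g1 | j1 | n1,q1 | t1 | u1
```

Reading this: the six sparsely expressed receptor genes fall into three
groups by laminar height (`g1` most apical; `n1`,`q1`,`u1` intermediate;
`j1`,`t1` most basal, the extreme medians 11% of layer height apart), the
radial coordinate further separates `j1` from `t1`, and the organ-height
axis isolates `u1` (shifted toward the organ opening) — so combining all
three coordinates distinguishes **five expression zones for six genes**,
with only `n1` and `q1` sharing a zone.  The marker contrasts (in the full
output) show every receptor distribution significantly more apical than
the `omp`-expressing population, while only the intermediate receptors
blend into the `trpc2` distribution.

The same pipeline runs from the shell:

```sh
zonemap simulate --seed 11 --out raw.tsv
zonemap normalize --in raw.tsv --out cells.tsv
zonemap stats --in cells.tsv --out descriptors.tsv --plots figs/
zonemap zones --in cells.tsv --out zones.json --seed 11
# or end to end, with matrices, manifest and summary:
zonemap run --seed 11 --out-dir results/
```

For real data, point `normalize` at your own tab-separated measurement
table (columns: organ_id, gene, section_index, total_sections, side,
soma_height_um, layer_thickness_um, radial_distance_um, lamella_length_um).

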
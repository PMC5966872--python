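# Methods

## The problem

In the olfactory epithelium, neurons expressing the same receptor gene are
scattered across a shared sensory surface rather than confined to a
compartment, yet different genes occupy statistically distinct, broadly
overlapping *expression zones*.  `zonemap` quantifies such zones from
serial horizontal sections of a cup-shaped olfactory organ (a rosette of
lamellae radiating from a median raphe, as in teleost fish).  The input is
one row per labeled cell: which organ and gene, which section, and the raw
micrometer measurements of the soma against local tissue landmarks.

## Coordinates

Each cell is reduced to three dimensionless positions:

- **Laminar height** `h_rel = h_soma / thickness`, the shortest distance
  from the basal border of the sensory layer to the soma center, over the
  layer thickness at that position.  0 is basal, 1 is apical (at the
  lumen).
- **Relative radius** `r_rel = r_soma / lamella_length`, the distance from
  the lamellar apex (nearest the median raphe) to the soma, over the length
  of that lamella.  0 is innermost, 1 is outermost.
- **Organ height** `z_rel = section_index / (total_sections − 1)`, the
  horizontal section number over the section count.  0 is the top section
  (organ opening), 1 the bottommost.  The `−1` in the denominator makes
  both endpoints attainable, matching the stated range of the coordinate;
  with a single section the value is 0.

**Radial exclusion.**  On the topmost sections the sensory surface has not
yet extended toward the median raphe, so the lamella is too short to carry
a meaningful radial scale.  Cells on lamellae shorter than `min_length`
(default 50 µm, configurable) keep their laminar and organ-height values
but are flagged as radially excluded.  The threshold is a normalization
detail, not a biological constant: any value that removes the degenerate
first sections without touching formed lamellae (roughly 20–100 µm under
the packaged geometry) gives the same downstream results.

Left and right sides of the organ are pooled (no side asymmetry is
expected or modeled).  Malformed rows abort the run by default, naming the
row; a lenient mode skips and reports them.

## Descriptors

All statistics are computed on the unbinned sample.  The ECDF is the
right-continuous step function `F(x) = #{values ≤ x}/n`, ties merged into
single steps.  Location is the median; broadness is the **half-width**
`Q3 − Q1`, with quartiles by linear interpolation between order statistics
(the common default; fixed so tables are reproducible).  Distributions are
pooled over organs — per-organ curves are kept only for display, since
per-organ cell counts (~100) make them noisy.  Histograms (20 equal bins
on [0, 1] by default) are display-only.  Percentages in reports are
rounded half away from zero to one decimal, except the median-spread
headline, which is quoted as a whole percent.

## Comparison and zoning

Two genes' distributions along one coordinate are compared with the
two-sample Kolmogorov–Smirnov test.  The statistic
`D = sup_x |F_a(x) − F_b(x)|` is evaluated exactly on the union of step
points.  The default p-value uses the Kolmogorov limit distribution at
`√(en)·D` with effective size `en = n_a·n_b/(n_a+n_b)`; a seeded
permutation mode (default 10⁴ label shuffles, add-one estimator) serves as
the small-sample route and as the verification oracle for the asymptotic
formula.  Ties are handled by the step-point evaluation; nothing is
jittered.

Significance is raw `p < α` with `α = 0.01` and **no multiple-testing
correction** — at the pooled sample sizes involved (n > 100) the test is
sensitive, and the stricter cutoff plays that role; Bonferroni can be
applied by passing a smaller `α`.

- **Per-coordinate groups** are the *maximal cliques* of the
  indistinguishability graph (edge ⇔ `p ≥ α`).  Cliques may overlap: a
  distribution can be intermediate between two otherwise-distinct
  neighbours and belong to both groups.
- **Combined zones** connect two genes only if *no* coordinate separates
  them; the zones are the connected components of that graph, a disjoint
  partition.  This is the only graph reading under which six genes with one
  indistinguishable pair yield five zones.

Both outputs are deterministically ordered (members sorted, then groups),
so results are invariant to gene ordering and organ relabeling.

## Synthetic organ generator

No per-cell measurements for this kind of study are publicly deposited, so
the package ships a seeded generator that emulates the sampling regime and
serves as the test bed.

- **Geometry.**  Each organ has `n_sections ~ U{40..60}` horizontal
  sections; layer thickness per section `U(30, 60)` µm; lamella length
  `U(200, 400)` µm, ramping linearly from 0 over the first 5 sections
  (the lamella forms below the organ opening).  Absolute scales are
  arbitrary — only relative coordinates survive normalization — but are
  chosen so the radial exclusion engages exactly on the topmost sections.
- **Coordinate laws.**  Laminar and radial positions are drawn
  independently per cell (preferred radius and height are treated as
  independently specified) from **logit-normal** laws: `X = expit(Z)`,
  `Z ~ N(µ, σ)`, parameterized by the median (`expit(µ)`) and the
  interquartile width, with σ recovered by a monotone root solve.  The
  logit-normal is bounded on (0, 1) and unimodal, matching observed
  coordinate histograms; width 0 degenerates to a spike at the median.
- **Organ axis.**  z is observed only as a section index, so the gene's
  z-law is discretized into per-section masses (CDF increments over equal
  slabs), mixed with a 5% uniform background — labeled cells are found
  scattered over the whole axis, and this keeps the first short-lamella
  sections populated so the exclusion path is always exercised.  Section
  cell counts are Poisson with rate `mean_cells_per_section · n_sections ·
  weight_s`, so the expected organ total is `rate × n_sections`.
- **De-normalization.**  Relative draws are multiplied by the section's
  thickness and lamella length, producing raw µm measurements that the
  coordinates module must exactly invert.

**Packaged calibration.**  The default profiles encode six sparse receptor
genes (2 cells/section), a broadly expressed co-receptor `c1` and two
cell-type markers `omp`/`trpc2` (20 cells/section each; `omp` marks the
other, more basal neuron type):

| gene  | laminar (median, IQR) | radial | z | cells/section |
|-------|----------------------|--------|-----|----|
| g1    | 0.714, 0.12 | 0.500, 0.24 | 0.50, 0.30 | 2 |
| n1    | 0.660, 0.14 | 0.500, 0.24 | 0.50, 0.30 | 2 |
| q1    | 0.660, 0.14 | 0.505, 0.24 | 0.50, 0.30 | 2 |
| u1    | 0.660, 0.14 | 0.435, 0.24 | 0.30, 0.30 | 2 |
| j1    | 0.603, 0.20 | 0.440, 0.24 | 0.50, 0.30 | 2 |
| t1    | 0.603, 0.20 | 0.570, 0.24 | 0.50, 0.30 | 2 |
| c1    | 0.660, 0.14 | 0.580, 0.24 | 0.50, 0.30 | 20 |
| omp   | 0.450, 0.15 | 0.500, 0.24 | 0.50, 0.30 | 20 |
| trpc2 | 0.660, 0.14 | 0.500, 0.24 | 0.50, 0.30 | 20 |

Laminar medians span exactly 0.603–0.714 (an 11% spread of layer height)
in three width classes; radial medians stay within ~14% of each other with
every IQR at 0.24; all genes sit mid-organ in z except `u1`, shifted toward
the opening.  The calibration satisfies a separation contract, verified
numerically against the logit-normal CDFs: every gene pair meant to be
distinguishable has **population KS distance ≥ 0.15** in its separating
coordinate (e.g. g1–n1 laminar 0.221, j1–t1 radial 0.277, u1–q1 radial
0.153, u1 z 0.334), while within-zone pairs (n1/q1, trpc2 vs n1) share
identical laws.  With ~500 cells per sparse gene and α = 0.01 (critical
D ≈ 0.10), separated pairs are detected with high power and the intended
structure — three laminar groups, five combined zones for six genes —
emerges in the packaged replicates.

**What the generator does not emulate:** lamellar curvature and its
measurement error, per-organ biological heterogeneity (organs differ only
by sampling noise), section-thickness irregularities, probe sensitivity
differences, and any correlation between coordinates.  Passing tests
therefore validate the pipeline's statistics, not the biological values of
real measurements — the study's real per-gene descriptor values cannot be
reproduced because the underlying cell coordinates were never deposited.

## Family curation filters

Candidate receptor sequences from homology searches are accepted as bona
fide unique family members only if they pass, in order:

1. **Gap stripping**: alignment columns with *strictly more than* 90% gaps
   removed (a column at exactly 90% stays).  Idempotent.
2. **Allele collapse**: pairwise identity computed over mutually ungapped
   positions; sequences > 98% identical are allelic variants, clustered by
   single linkage; the representative is the longest ungapped sequence
   (ties by name).
3. **Distributed difference**: a pair must differ by ≥ 2% *and* the
   variable positions must span ≥ 50% of the alignment length (span = last
   − first variable column + 1).  Differences concentrated in one stretch
   indicate a chimeric or mis-assembled prediction; such pairs are merged
   like alleles.  The span formalization is this package's choice — no
   standard formula exists — and both thresholds are configurable.
4. **Unique locus**: candidates whose 0-based half-open intervals overlap
   on the same chromosome and strand are flagged as conflicts (abutting
   intervals do not overlap).
5. **Clade support**: the family clade is the smallest clade containing
   the anchor taxa; a candidate inside it is accepted if the smallest
   clade containing it and an anchor has branch support *strictly over*
   80, is reported unresolved at or below that, and is rejected outside
   the family clade.

All "over X%" boundaries are read strictly, uniformly.  Alignment and tree
inference themselves are out of scope; the filters consume their outputs.
A fully synthetic family with planted alleles, an overlapping locus pair
and a low-support interloper (`zonemap.curation.synthetic_family`) pins
down the chain's behavior exactly.

## Numerical and reproducibility choices

- Quantiles: linear interpolation; KS distance: exact step-point sup.
- Tabular outputs: TSV, floats at 6 significant digits; identical seed and
  configuration give byte-identical files; every run writes a manifest
  (seed, config hash, version).
- All randomness flows through `numpy.random.default_rng(seed)`; the five
  packaged replicate seeds live in `zonemap.simulate.PACKAGED_SEEDS`.
- Degenerate inputs: empty samples, zero rates, zero widths, single
  sections and single-gene tables raise or short-circuit explicitly rather
  than propagating NaNs.

## Problem sizes

The test suite and the acceptance script run the default fixture (9 genes,
5 organs/gene, ~18,000 cells of which ~500 per sparse gene) in a few
seconds.  Statistical guarantees are checked at the sizes they are stated
for: type-I error over 1000 null replicates at n = 500 (rate within
[0.004, 0.02] at α = 0.01), power ≥ 0.95 over 200 replicates at population
D = 0.15 and n = 600, asymptotic-vs-permutation agreement within 0.02 at
10⁴ shuffles, and parameter recovery within 0.03 on a dense fixture
(~5,000 cells/gene) where sampling noise cannot mask systematic bias.

## Known limitations

- The asymptotic p-value is slightly conservative below n ≈ 50 per sample;
  use the permutation method there.
- Zone partitions are sensitive to single borderline pairs by
  construction (a raw-cutoff decision rule); replicate seeds are the
  intended way to judge stability.
- The maximal-clique enumeration is exponential in the worst case; it is
  intended for the small gene panels (≲ 20) this analysis targets.
- Radial exclusion uses a single length threshold; organs whose lamellae
  form over many more than ~5 sections would need a recalibrated
  `min_length`.
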
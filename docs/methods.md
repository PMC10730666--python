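# Methods

## The model

polyqnet treats a protein–protein interaction network (PIN) as a geometric
object: every protein occupies a point of the two-dimensional hyperbolic
plane H² (curvature −1), written in polar coordinates (r, θ).  The radial
coordinate encodes *popularity* — hubs sit near the origin — and the angular
coordinate encodes *similarity*: proteins participating in related
processes occupy nearby angles.  Under the popularity–similarity (PS)
model, two nodes at hyperbolic distance

    x = arccosh( cosh r₁ cosh r₂ − sinh r₁ sinh r₂ cos Δθ )

are connected with the Fermi–Dirac probability

    p(x) = 1 / (1 + exp((x − R) / (2T))),

where R is the connection radius and the temperature T ∈ [0, 1) controls
clustering: T → 0 gives a hard distance cutoff (maximal clustering), larger
T blurs it.  A network grown under this model has a power-law degree
distribution with exponent γ = 1 + 1/β, where β ∈ (0, 1] is the popularity
fading of old nodes.

The analysis pipeline embeds a confidence-filtered PIN into H², builds a
disease-specific subnetwork around seed genes (products of transcripts
enriched in protein aggregates), partitions it into angular sectors, and
asks which functional gene sets are over-represented in each sector.
Transcript-side stages (windowed fragmentation, PWM log-odds scanning) and
small assay quantifications (2^−ΔCt, reporter ratios, Welch comparisons)
complete the toolkit.

## Embedding: LaBNE + HM

**LaBNE (spectral initialisation).**  The symmetric normalized graph
Laplacian L = I − D^(−1/2) A D^(−1/2) is diagonalised and the eigenvectors
of its two smallest strictly positive eigenvalues serve as a planar layout;
a node's initial angle is the polar angle of its row in that plane.  The
symmetric normalized form (rather than the unnormalized Laplacian) is used
because PINs have heavy-tailed degrees, which dominate the unnormalized
spectrum.  Radii are fixed purely by degree rank,

    r_i = 2β ln i + 2(1 − β) ln N       (rank i = 1 for the largest hub),

and are never refined — in the PS model the radial order is the degree
order, and refining radii would conflate the two coordinates.  The
connection radius uses the PS closed form

    R = 2 ln N − 2 ln( (2T / sin πT) · (1 − N^−(1−β)) / (m (1 − β)) ),

with the limits 2T/sin πT → 2/π as T → 0 and (1 − N^−(1−β))/(1−β) → ln N as
β → 1.  m (links per new node, half the mean degree) is estimated from the
data as max(1, round(mean degree / 2)) when not supplied.  Note R grows
with m: attaching more links per node requires a larger reach.

**HM (likelihood refinement).**  Nodes are visited in decreasing degree
order; each node's angle moves to the maximizer of its local Bernoulli
log-likelihood (its full adjacency row — edges *and* non-edges — under the
Fermi–Dirac kernel) over a deterministic grid of candidate angles spanning
a window w around the incumbent, incumbent included.  Because the incumbent
is always a candidate, the total log-likelihood is non-decreasing across
sweeps; the trace is recorded and asserted.

Defaults: window w = 2π (global search), one sweep, 360 candidate angles.
The grid density matters more than one might expect: with a global window,
100 candidates quantize angles to 3.6°, which is *coarser* than the
spectral estimate being refined, and measurably degrades distance recovery
even while the likelihood rises.  A 1° grid (360 candidates) improves or
ties the spectral solution on every PS benchmark we generate; finer grids
buy little and cost linearly.  Determinism is guaranteed by canonicalizing
eigenvector signs (largest-magnitude entry positive), sorting node visits
by (degree, id), and placing the incumbent first so argmax ties keep it.

Reference parameters for embedding a human PIN follow published hyperbolic
maps of the human interactome: γ = 2.97, T = 0.83, w = 2π, interaction
confidence ≥ 0.71, largest connected component only.

## Subnetwork, sectors, enrichment

**Seed neighborhood.**  The disease subnetwork contains the matched seeds,
their first neighbors, and exactly the seed-incident edges (seed–seed and
seed–neighbor); neighbor–neighbor edges are excluded.  This convention
yields the near-tree-like edge/node ratios reported for aggregate-derived
seed sets; the full induced subgraph is available behind `induced=True`.
Subnetwork coordinates are always those inferred on the full network —
re-embedding a subnetwork would distort its geometry.

**Angular sectors.**  Nodes sorted by angle are cut at every consecutive
gap exceeding a threshold g; the wrap-around gap participates like any
other (the circle has no privileged origin), and a single cut merely opens
the circle (one sector).  Ties in θ are broken by node id; sector ids
increase with θ starting just after the largest cut gap.  Undersized
sectors (< min_size, default 5 members) are either kept with a warning
(default) or repeatedly merged across the smaller adjacent gap.  The tuner
returns the g maximizing the sector count subject to every sector reaching
min_size, evaluating candidate thresholds at the observed gap values and
just below each of them (the cut rule is strictly >, so cutting a gap
requires g slightly below it); ties go to the larger g.  When isolated
nodes sit between large gaps, no multi-sector partition may satisfy the
size constraint and the tuner honestly returns a single sector — this is
the documented worst case, and it occurs for one of the synthetic
benchmark seeds.

**Enrichment.**  Each sector is tested against every gene set it overlaps
with the hypergeometric upper tail P(X ≥ k), computed by log-space
summation of log-pmf terms.  Benjamini–Hochberg correction is applied
across terms *within* each sector, matching the per-cluster reporting of
such analyses; both raw p and q are emitted.  The universe defaults to all
proteins of the full embedded network.  Note the test is discrete: under a
null of random sectors and sets its achievable level just below 0.05 is
strictly smaller than 0.05 (about 0.032 at the sizes our calibration
simulation uses), so the observed null rejection rate is compared against
the exactly computed discrete level, not the nominal one.

## Transcript scanning and quantifications

Sequences are RNA ({A, C, G, U}; DNA T is normalized on input).  Long
transcripts are split into overlapping 100 nt windows with a 50 nt step;
the final window is anchored to the sequence end so every window is full
length and every base is covered.  The 100 nt window is the conventional
fragment size for this kind of motif pre-processing; no standard step
exists, so 50% overlap was chosen, and any published fragment total is
treated as dataset-specific rather than a contract.  PWM scanning scores offset o as

    score(o) = Σ_j log2( (f_j(s[o+j]) + c) / (1 + 4c) / b ),

bits-scale log-odds against a uniform background b = 0.25 with pseudocount
c = 10⁻³ (c = 0 reproduces textbook log-odds exactly; a width-3
single-base-certain PWM then scores a perfect match at exactly 6 bits, the
standard reporting threshold).  N scores as background (0 bits).  Scanning
is single-strand — RNA has no reverse complement to search.

Assay helpers: relative expression 2^−(Ct_target − Ct_reference); plain
signal ratios (reporter activity, signal/background, cytoplasmic/total);
and a two-sided Welch t-test for two replicate groups reported as
mean ± SD per group.  Welch rather than Student is the default because
triplicate designs give no power to verify equal variances.  For qPCR
replicates, Cts are averaged per condition before ΔCt (the alternative —
per-replicate ΔCt then averaging — is a one-line change and noted in the
API docs).

## Synthetic data: what it emulates and what it does not

The generators produce inputs with the statistical structure the analysis
assumes, with recorded ground truth:

- **PS networks** grown node by node: θ_t uniform, birth radius 2 ln t,
  fading r_s(t) = βr_s + (1−β)r_t; the first m+1 nodes form a clique; later
  nodes attach to the m hyperbolically nearest nodes (T = 0) or to m
  weighted draws without replacement under the Fermi–Dirac kernel at the
  running radius R_t.  Exactly m draws (not independent Bernoulli trials)
  keep the edge budget fixed at m(N−m−1) + C(m+1, 2), which makes edge
  counts assertable.  Every new node attaches to at least one earlier node,
  so connectivity is structural.
- **Gene sets** planted on equal contiguous angular arcs (membership =
  arc nodes, plus optional uniform noise), alongside uniform random terms.
- **Transcripts** with background bases i.i.d. uniform (matching the
  scanner's default background) and one PWM-sampled word per planted
  sequence at a recorded offset.
- **DE tables** from a z-model: null log2FC ~ N(0, 1), planted
  log2FC ~ N(effect, 1), two-sided z p-values, BH adjustment.  The pipeline
  consumes DE results as a table, so only the table's statistical shape
  matters; count-model internals are deliberately out of scope.

Benchmark conditions are fixed once: embedding recovery uses N = 500,
m = 4, γ = 2.5, T = 0.1 (strongly geometric, desk-scale); degree-exponent
recovery uses N = 2000; DE calibration uses 5000 null genes and effect
size 6 for power; motif recovery uses near-deterministic 6–8 nt PWMs at
threshold 6.  Passing these tests shows the machinery is correct and
well-calibrated on data satisfying the model's assumptions.  It does *not*
show that a real PIN is well described by the PS model, that real inclusion
transcriptomes have planted-arc functional structure, or that real DE
p-values follow a z-model — those are properties of the biology and of
upstream tools, not of this package.

## Numerical choices

- Hyperbolic distance switches to the asymptotic form
  x ≈ r₁ + r₂ + 2 ln sin(Δθ/2) when r₁ + r₂ > 40 (cosh overflows near 710;
  at 40 the branches agree far below 1e-6), floored at |r₁ − r₂|, which
  also handles Δθ → 0.
- Fermi–Dirac probabilities entering likelihoods are clipped to
  [1e-12, 1 − 1e-12]; the T = 0 kernel returns the exact step function.
- PWM rows must sum to 1 within 1e-3 (then renormalized); widths 1–30.
- Output TSVs serialize floats with Python's shortest round-trip
  representation, so write→read reproduces values bit-exactly (readers use
  pandas' round-trip float parser).
- Degenerate inputs fail loudly with positional context: parse errors name
  line numbers, missing coordinates name the node, pipeline stage failures
  name the stage and input file.

## Problem sizes and runtime

All tests and the acceptance script are desk-scale by design: networks of
120–2000 nodes, 2000 sampled distance pairs, 5000-gene DE tables, 200
planted transcripts.  The full suite runs in well under a minute and the
acceptance script in under half a minute on one CPU.  The embedding is the
only stage with nontrivial cost (dense eigendecomposition up to 3000 nodes,
then a sparse shift-invert solver; HM refinement is O(N² · candidates) per
sweep), which is why the pipeline caches coordinates and reuses them when
supplied.

## Known limitations

- The PS connection-radius formula is the standard closed form of the
  model family; analyses built on other embedders may use different R
  conventions, so R is overridable.
- The curvature is fixed (ζ = 1) and the space is 2-D; no 3-D embedding.
- Motif *discovery* (finding enriched patterns against shuffled controls)
  is out of scope; only scanning with externally supplied PWMs is
  implemented.
- Identifier mapping between gene symbols and protein accessions is the
  caller's responsibility (symbol collapse is the default for raw
  interaction tables, numeric-id keying is a flag).
- The gap tuner inherits the brittleness of hard size constraints: one
  isolated embedded node can force the single-sector solution; the merge
  policy is provided as the pragmatic alternative.
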
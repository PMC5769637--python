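# Methods

## The model

`pctopo` treats a planar epithelium purely topologically: cells are nodes,
shared walls are edges, and — because four-way cell junctions are excluded,
as they are both biophysically avoided and measure-zero in real tissues —
the number of a cell's neighbours n equals its number of sides. A bare
graph is not enough to divide a cell, though: a division wall splits the
mother's boundary into two *contiguous* runs of neighbours, and contiguity
is not a graph property. The tissue is therefore stored as a rotation
system: for every cell, the counter-clockwise cyclic order of its
neighbours. This is the minimal structure that fixes an embedding of the
graph on an orientable surface.

A division of an n-sided mother works as follows. A starting wall is drawn
uniformly among the n interfaces; the new wall's two endpoints cut two
interfaces, whose owner cells (the *junction neighbours*) become adjacent
to both daughters. The remaining n − 2 neighbours split into two
contiguous arcs of a and n − 2 − a cells, so the daughters have a + 3 and
(n − 2 − a) + 3 neighbours. Three rules fix the law of a:

- **Equal split** — a = (n−2)/2; for odd n the two nearest integers are
  chosen with probability 1/2 each (the unordered daughter pair is the same
  either way).
- **Random split** — a uniform on {0, …, n−2}: every split ratio equally
  likely.
- **Pascal split** — the binomially weighted division in which the new
  wall never cuts two adjacent walls, so each daughter keeps at least one
  intact wall: per-daughter law P(k | n) = C(n−4, k−4) / 2^(n−4) on
  k ∈ [4, n], i.e. a = 1 + Binomial(n−4, 1/2). Mothers with n = 3 (where
  this law is undefined) take the only possible split {3, 4}; n = 4 forces
  {4, 4}. We adopted this form, the one originally derived for
  proliferating epithelia, after finding that the plain
  a ~ Binomial(n−2, 1/2) variant — each non-junction neighbour siding with
  either daughter independently — produces a steady-state neighbour-number
  variance of ≈ 3.86, incompatible with the ≈ 2.69 that the tissue-level
  simulations of this model family are known to produce, whereas the
  adjacent-wall-excluded form reproduces it.

Every division satisfies two conservation laws, asserted on every logged
event: deg(d1) + deg(d2) = n + 4, and the summed neighbour count over the
mother's former neighbours rises by exactly 2 (the two junction neighbours
gain one wall each; nobody else changes).

Two schedulers are provided. *Without replacement*: every cell present at
the start of a round divides exactly once, in uniformly shuffled order,
asynchronously (each division sees the updated graph); the population
doubles per round. *With replacement*: each event divides a uniformly
drawn cell, so lineages accumulate different division counts.

### Initial condition and orientation bookkeeping

Simulations start from a hexagonal lattice wrapped on a torus (default
8×8): boundary-free, so Euler's relation for trivalent maps makes the mean
neighbour number exactly 6 at all times. Lattices with fewer than 3 rows
or columns are rejected — wrap-around would duplicate walls or make a cell
its own neighbour.

The insertion positions of the new edges in the junction neighbours'
cyclic orders are chosen to preserve the global counter-clockwise
orientation. This is verified by face tracing: in a consistently oriented
rotation system of a tissue without four-way junctions, every face of the
embedded graph is a triangle (one per tricellular junction). The
`validate(faces=True)` check traces all faces and is exercised after
division sequences in the tests; it would catch any insertion-order error
immediately.

## Statistics

- **P(n), μ1, μ2** — frequencies, mean and population variance (ddof 0) of
  the neighbour-number distribution.
- **α** — the single parameter linking the hexagon frequency to the
  spread: α = μ2 · P(6)². The steady state of the equal rule gives
  α ≈ 0.156.
- **Division matrices** — per-daughter laws P(k | n), analytic per rule and
  empirical from events (each event contributes two daughter observations;
  rows with no events are undefined/NaN, not zero; daughters outside
  [3, n+1] are kept but flagged as anomalies, since in tracked data they
  indicate a neighbour dividing within the imaging interval).
- **Aboav–Weaire** — m_n, the mean neighbour number of the neighbours of
  n-sided cells, with the classical reference m_n = 5 + 8/n (default) or
  the Weaire form (6 − a) + (6a + μ2)/n with a = 1 selectable; the printed
  reference form in the source material is not recoverable, so both common
  forms are exposed.
- **Lewis** — mean area of n-sided cells against the reference
  Ā_n = (A0/N)(n−2)/4; for already-normalised areas the scale A0/N is
  replaced by the mean normalised area so the reference passes through the
  data's own scale at n = 6 (both conventions available, same caveat).
- **Normalised areas** — area over the mean area of the cell's neighbours;
  the neighbour-mean normalised area excludes the central cell from each
  neighbour's own normalisation. Regressions are plain ordinary least
  squares; zero-variance inputs are flagged degenerate rather than fitted.

## Image topology

Adjacency in label images uses 4-connectivity: corner-only contact is not a
wall, which keeps the extractor consistent with the model's exclusion of
four-way junctions. Areas are pixel counts (optionally scaled by a pixel
size); axes come from the second central moments of the pixel coordinates,
so a w×h rectangle has anisotropy √((w²−1)/(h²−1)) under the discrete
convention. Validity tiers are nested: interior (touches neither image
border nor background), neighbour-complete (all neighbours interior;
required for m_n and normalised areas), second-order-complete (all
neighbours neighbour-complete; required for neighbour-of-neighbour
statistics). Segmentations with one-pixel background membranes are handled
by an optional bridging mode (off by default). Statistics are invariant
under image transposition and 90° rotation (tested).

## Synthetic data

The generator emulates the two inputs the pipeline consumes.

*Frames*: rasterised Voronoi tessellations of uniformly random seeds
(default 150 seeds on 400×400, two Lloyd relaxation iterations to round the
cells; an optional linear density gradient grades cell sizes). Ground
truth ships with every frame: per-label pixel counts, and adjacency built
with an independent region-adjacency-graph implementation. Walls present
in the raster but absent from the Delaunay graph of the seeds — the
signature of a near-degenerate four-cell junction, where the raster must
pick one diagonal — are reported as `degenerate_walls`.

*Time-lapses*: a fraction (default 0.2) of neighbour-complete cells divide
by a straight wall through the centroid at a uniform random angle, the
geometric rule topologically equivalent to the equal split under isotropic
conditions. Base mothers are chosen mutually non-adjacent so every
division is isolated; co-dividing neighbour pairs ("contamination", which
broadens empirical division matrices) are injected only deliberately, at a
per-mother probability calibrated so the expected flagged-event fraction
equals the requested rate. Cuts that would produce a daughter below 4
pixels, a disconnected daughter, or (for isolated divisions) a
junction-degenerate topology violating the n + 4 law are re-drawn at a
fresh angle, up to 30 attempts, then the mother is skipped — the generator's
contract is clean division geometry, and deviations from it are injected
explicitly, never left to rasterisation accidents.

What the synthetic tissue does **not** emulate: lobed (jigsaw) cell
outlines, mechanical relaxation, growth, T1 transitions, and anisotropic
domains. Convex tessellations suffice because every implemented statistic
is a function of adjacency and area only; passing tests certify the
estimators and the extraction pipeline, not the biology of lobe formation.

## Numerical and protocol choices

- Steady-state protocol: 10 without-replacement rounds from the 8×8 torus,
  replicates pooled until ≥ 50,000 final cells (one replicate yields
  65,536), matching the scale of the reference analyses; the heavy-tailed
  random rule is pooled to ≥ 100,000. Convergence is fast — the
  total-variation distance between consecutive rounds of the equal rule
  falls below 0.01 within ~8 rounds (regression-tested).
- RNG: one `numpy` generator per replicate, seeded `seed + replicate`;
  every stochastic routine takes an explicit seed and reruns are
  bit-identical (tested at the CLI level via output checksums).
- On a torus μ1 is exactly 6 by Euler's relation; reference analyses on
  bounded tissue report 5.999, the difference being their boundary
  sampling, which this package deliberately avoids.
- Empirical-vs-analytic matrix checks use ≥ 20,000 isolated divisions per
  mother degree (rows 3–8), giving row-wise total-variation distances
  comfortably below the 0.01 test threshold.

## Known limitations

- The simulated tissue has no geometry: Lewis-law and area statistics
  apply only to segmented or synthetic frames, not to simulation output.
- The Aboav and Lewis *reference curves* implement the classical closed
  forms; where the source material's exact printed equation differs, the
  alternative form is selectable but defaults may not coincide with it.
- The label-image adjacency definition (4-connected wall contact) is
  internally consistent and oracle-tested, but other segmentation
  pipelines may define adjacency differently at degenerate junctions.
- The tracking-event validity requirement (mother and both daughters
  neighbour-complete) is stricter than strictly necessary; it guarantees
  fully defined neighbour counts at the cost of discarding some usable
  border events.
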
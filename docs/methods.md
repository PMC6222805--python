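# Methods

## Graph model

Each trajectory frame is converted into an undirected intermolecular graph.
Vertices are *named interaction-site atoms*: the solute's oxygen (and
optionally hydroxyl-hydrogen) sites and the water O/H1/H2 atoms. Using
atom-level rather than molecule-level vertices is deliberate: the degree
bookkeeping counts a water's two hydrogens separately, so a water that
presents both hydrogens to one site contributes two edges (raw degree 2).
Molecule-level views are derived downstream, never assumed.

Two geometric hydrogen-bond criteria are implemented:

- **Distance-only rule** (`build_frame_graph`, default): an edge between a
  site oxygen and a water hydrogen (or a site hydrogen and the water
  oxygen) whenever r(O···H) < 0.30 nm, with no angle test — every mutual
  orientation is accepted. Strict `<` is the default; both the cutoff and
  the strictness are configurable.
- **Donor–acceptor rule** (`build_gmx_graph`): an edge between a donor
  oxygen (an O with at least one covalently bonded H, known from the
  topology's bond list) and an acceptor oxygen when r(DA) ≤ 0.35 nm and the
  H–D–A angle of some donor hydrogen is ≤ 30°; at most one edge per
  (donor hydrogen, acceptor) pair, with the mediating hydrogen recorded on
  the edge. The angle convention (H–D–A at the donor, or D–H···A at the
  hydrogen) is selectable.

Periodic boundaries: all pair distances use the minimum-image convention in
a cubic box, and the integer image shift used is stored on each edge, so
graphs cross the box boundary. Whether the original graph-analysis software
used minimum images or explicit ghost atoms is not documented anywhere we
could verify; minimum image is chosen and stated here. Translating every
coordinate by a lattice vector provably leaves the graph unchanged (tested).

Neighbor search is a vectorized site-against-solvent pair scan. With a
handful of solute sites this is already linear in the number of waters, so
no cell list is used; the optional water–water scan is an all-pairs
vectorized block, adequate for the system sizes the package targets
(hundreds of waters). An independent O(N²) brute-force scan is kept in the
test suite as the oracle for both builders.

## Degree census and mean degree

For every requested site, `degree_census` tallies N(i) — the number of
frames in which the site has raw degree i. Conservation (Σᵢ N(i) = frame
count, per site) is enforced by a validator. The weighted mean degree is
Σᵢ i·N(i)/Σᵢ N(i); with `halve=True` it is divided by two to convert the
hydrogen-resolved count into a per-water-molecule degree. The halved value
equals the exact count of interacting water molecules precisely when every
bound water engages both hydrogens (tested on synthetic frames generated in
that mode); with single-hydrogen binding it is a convention, not an
identity.

## Geodesics

`geodesic_matrix` computes all-pairs shortest edge counts with the
Floyd–Warshall algorithm on the unweighted adjacency matrix. Updates are
strict improvements with intermediates scanned in ascending vertex order,
giving a deterministic predecessor matrix; the single reconstructed path
per pair is canonical but arbitrary among equal-length paths. Unreachable
pairs carry the sentinel −1 and are excluded from averages. Equivalence
with per-vertex breadth-first search is asserted exactly on hundreds of
random graphs in the test suite.

A hydrogen-bond *pathway* should be able to pass through a bridging water,
but at the atom-site level a water's own O and H vertices share no edge.
`project_to_molecules` therefore collapses each solvent molecule to a
single vertex (solute sites stay resolved; parallel edges merge, keeping
the shortest realized distance) before geodesic analysis; the CLI applies
this projection by default. `geodesic_persistence` reports the per-frame
gd(u, v) series of a site pair and its maximal runs of constant finite gd,
with durations in ps.

## Persistence and residence times

A *continuous persistence* event is a maximal uninterrupted run of frames
during which a specific site–partner contact exists. "Uninterrupted" means
zero gap tolerance by default — a single absent frame terminates the run —
with a configurable tolerance because the comparison between counting
conventions hinges on exactly this choice. Partners are keyed either by
the individual water hydrogen (*hydrogen mode*) or by the water molecule
index (*molecule mode*, which survives hydrogen swaps). Events touching
the first or last frame are flagged censored; they are included in means by
default (naive run-averaging) with a flag to exclude them, since trajectory-
edge handling is otherwise an unstated convention.

The residence time is the mean event duration times the frame interval,
which is algebraically identical to the duration-histogram formulation
Σₜ t·P(t) — both phrasings are one estimator, and the identity is asserted
on random event sets. In hydrogen mode the mean is doubled by default
(`correction="auto"`): a bound water spends, on average, half its stay with
each hydrogen pointing at the site, so hydrogen-label runs are half as long
as the true residence. The doubling is exact only when the expected
hydrogen-run length is exactly half the molecule-run length; the synthetic
generator's default swap rate realizes that regime (below), and the
agreement is verified to sampling error, not assumed.

## Correlation-function lifetime

The intermittent correlation function is
C_HB(t) = Σ s(t₀)s(t₀+t) / Σ s(t₀)², summed over pairs and over every valid
time origin — a pair bonded at t₀ counts at t₀+t even if the bond broke in
between. Normalizing by the bonded origins valid for each lag makes
C_HB(0) = 1 exactly and a permanent bond give C_HB ≡ 1. The numerator is
evaluated with FFT autocorrelation (checked against the literal double loop
in tests). `integrate_lifetime` returns the trapezoidal integral over the
available lags together with the truncation lag; the default maximum lag is
half the trajectory. On any series with rebinding the continuous-
persistence lifetime is at most the intermittent one (tested inequality).

## Distance distributions

`distance_distribution` histograms minimum-image O(site)···H(water)
distances below a collection cutoff (default 0.35 nm, bin width 0.005 nm).
The covalent O–H of the water itself never enters (only intermolecular
pairs are formed), so the first hydration shell appears near 0.18 nm rather
than the 0.28 nm donor–acceptor distance. Raw counts are emitted (no
shell-volume normalization), with a normalized view available; the
collection cutoff is recorded on the histogram because a second-shell peak
truncated by the collection window looks artificially sharp.
`suggest_cutoff` locates the first two peaks (scipy `find_peaks` with a 5%
prominence floor) and returns the centre of the lowest-count bin strictly
between them — for ties, the middle bin of the lowest run. A distribution
without two separated peaks raises an error instead of guessing.

## Synthetic generator

The generator emulates, at toy scale, a fixed-composition solvated-solute
box: a rigid scaffold with six oxygen sites (two hydroxyl-like, O9/O9′,
with bonded hydrogens; four methoxy-like) at 0.35 nm from the centre of a
cubic box (default edge 5.2 nm), plus rigid 3-site waters (O–H 0.0957 nm,
H–O–H 104.52°; a 4-site water's virtual site is irrelevant to O/H distance
criteria and is omitted). Defaults: 200 waters, 500 frames at 0.5 ps.

Site occupancy is a per-site two-state Markov chain: unbind probability
p = 0.2 per frame, rebind probability b = 0.2, giving stationary occupancy
b/(b+p) = 0.5 and geometric bound durations with mean 1/p = 5 frames
(2.5 ps). A bound water swaps its active hydrogen with per-frame
probability q, default q = p/(1−p), chosen so the expected hydrogen-label
run is exactly half the molecule run — the idealized regime in which the
doubling convention is exact.

Geometry: the bound water's near hydrogen sits at the shell radius
(0.18 nm, σ = 0.003 nm, clipped to [0.172, 0.20] nm) from the site oxygen
along the site's outward axis jittered within a 15° cone; the O–H···site
axis carries an additional librational tilt (half-Gaussian, σ = 15°, capped
at 30°), rejection-sampled so the far hydrogen always stays outside the
0.30 nm cutoff. Without the tilt the far hydrogen forms an artificially
sharp distance spike near 0.314 nm. An option places both hydrogens inside
the cutoff (symmetric geometry, both at ≈0.234 nm) to exercise the
degree-2 convention. Optional second-shell waters put a hydrogen at
0.30 nm (σ = 0.012 nm, floor 0.26 nm); the two-shell study configuration
uses 48 of them against 6 permanently bound first-shell waters, reflecting
that real second shells are more populous than first shells. All remaining
waters are resampled uniformly each frame outside an exclusion radius
(0.45 nm plus one O–H bond) of every site, so they can never form spurious
edges nor enter the distance-collection window.

Because of this construction, pushing the rendered frames through the
0.30 nm rule reproduces the Markov state sequence's edge pattern *exactly*
(asserted frame by frame), and `graphs_from_states` can build the same
graphs directly from the states for long statistical runs without
geometry. What the generator does **not** emulate: forces and energetics,
water–water network structure, box fluctuations, correlated site
occupancies, or realistic bulk density. Passing tests therefore validate
the *bookkeeping and estimators* against known statistics, not force-field
physics.

## Problem sizes and tolerances

Statistical tests use 15000-frame state-level simulations (six sites,
p = 0.2, b = 0.4 → ≈12 000 complete events), where the 1/p recovery is
asserted within 5% and the hydrogen-×2 vs molecule-mode agreement within
7% (≈1% standard error observed). The geometry pipeline is exercised on
500-frame, 200-water systems, which run end to end in seconds and
byte-identically for a fixed seed. Exponential-integral recovery is
asserted within 2% at 0.01 ps sampling. Exact (non-statistical) properties
— oracle equivalences, conservation laws, round-trips — are asserted with
no tolerance beyond float printing precision.

## File formats

Multi-frame XYZ (nm; no box information — the box edge comes from the
`.gro` or the topology config and is held constant), single-frame
fixed-column `.gro` (cubic boxes only; velocities ignored), a line-oriented
topology config (`molecule`/`atoms`/`bond`/`site`/`end`/`layout`/`box`
directives, 1-based indices in files), `.graph` edge lists (one undirected
edge per line: molecule index, site label, atom serial of both endpoints,
distance; ascending endpoint order, byte-reproducible), `.geopath` geodesic
records (pair, distance, one canonical path), and CSV for all tabular
output. The `.graph`/`.geopath` column layouts are documented here but not
claimed byte-compatible with any other software's files. Atom-to-molecule
assignment is positional — templates are consumed in declared layout order
— matching fixed-composition simulation boxes; no distance-based inference
is attempted.
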
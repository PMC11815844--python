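# Methods

`cppkit` implements the desk-scale analysis layer of a staged steered-pull
study of cell-penetrating peptides (CPPs) crossing lipid bilayers: the
free-energy machinery that turns nonequilibrium pulling work into a
potential of mean force (PMF), and the membrane-disruption metrics applied
to relaxation trajectories.  Because production molecular dynamics at this
scale needs GPU-months, the package pairs every estimator with a synthetic
generator whose ground truth is known exactly; the estimators are validated
by recovery, not by re-simulation.

## Steered-pull engine

The reaction coordinate is the membrane-normal distance z between the
peptide's Cα center of mass and the lower-leaflet headgroup center of mass;
the toy engine abstracts it to a single scalar.  A particle obeys
overdamped Langevin dynamics (Euler–Maruyama, no inertia) on a ground-truth
potential `U(x)` built as a sum of Gaussian components over a flat baseline:

    γ dx = [ −U'(x) + k (λ(t) − x) ] dt + √(2 γ k_B T dt) ξ

with a harmonic guide of stiffness `k` dragged at constant velocity,
`λ(t) = start + v t`.  External work follows the stiff-spring convention,
`dW = k (λ_t − x_t) v dt`, evaluated at the same-time state, which makes
two closed-form anchors exact to O(dt): at T = 0 on a flat potential the
steady-state lag is `γ v / k` and the work rate `γ v²`; in the quasi-static
limit `W(final) → U(end) − U(start)`.  For a flat potential the work is
Gaussian and mean dissipation equals `β Var(W)/2`, which the suite checks
directly — a sharp test of the bookkeeping.

Parameters with units, defaults, rationale:

| parameter | default | unit | why |
|---|---|---|---|
| spring_constant k | 10 | kcal·mol⁻¹·Å⁻² | stiff-spring guide of the emulated protocol |
| velocity v | 1 | Å·ns⁻¹ | production pulling speed of the emulated protocol |
| temperature T | 310.15 | K | physiological |
| friction γ | 0.05 | kcal·mol⁻¹·ns·Å⁻² | low-dissipation regime: mean dissipated work ≈ k_BT/2 per 5 Å stage, where a 25-replica Jarzynski average is well converged |
| timestep dt | 10⁻³ | ns | k·dt/γ = 0.2, safely inside the explicit-Euler stability bound k·dt/γ < 2 (enforced) |

Replica `i` of an ensemble draws its noise from `default_rng([seed, i])`,
so every replica is individually reproducible and identical seeds give
bit-identical traces.

## Jarzynski estimation and staged assembly

The free-energy difference over a stage is the Jarzynski average

    ΔF = −(1/β) ln ⟨ exp(−β W) ⟩ ,   β = 1/(k_B T),

with k_B = 0.0019872041 kcal·mol⁻¹·K⁻¹.  All exponentials go through a
shifted log-sum-exp, so ensembles with works of hundreds of kT neither
underflow nor overflow; the shifted form equals the naive evaluation to
10⁻¹⁰ kcal/mol wherever the naive form is finite, and satisfies the exact
inequalities ΔF ≤ ⟨W⟩ (Jensen) and ΔF ≤ min W + k_BT ln N.

The staged protocol splits the span into contiguous windows (default
8 × 5 Å), runs N = 25 replicas per stage, computes the stage profile
pointwise (each replica's accumulated work linearly interpolated at the
guide position — traces are densely sampled, so higher-order interpolation
is unwarranted), then selects the replica whose final work is closest to
the stage ΔF (ties to the lowest replica id) and starts the next stage
from its final particle position.  Stage segments are concatenated with
offset matching, so the assembled profile is continuous at boundaries by
construction.  Both the final-work scalar estimate and the pointwise
profile are exposed, since either reading of "the Jarzynski average per
stage" may be wanted.

Forward/backward calibration: the backward pull estimates F(z) − F(end);
`hysteresis` maps it onto the forward grid, re-anchors both at the forward
start and reports the max and mean absolute discrepancy.  At one-tenth of
the production velocity the discrepancy stays below 5% of a 5 kcal/mol
test barrier.

## Synthetic bilayers

`generate_bilayer_trajectory` builds labeled bead trajectories with exactly
known ground truth: one headgroup bead per lipid pinned (up to jitter) to
its leaflet plane (default ±19.25 Å, i.e. 38.5 Å thickness), tail chains of
8 beads at 1.5 Å spacing tilted by Gaussian noise, single-ring sterol
species, bulk water slabs beyond the membrane, and an optional
transmembrane channel whose radius profile r(z) is prescribed.  Channel
waters are drawn uniformly in the disk of radius r(z) per 1 Å sub-slab
with count proportional to disk area (default 0.5 waters/Å³ — deliberately
denser than physical water so a 1 Å slab at r = 6 Å holds ≥50 waters and
the bottleneck is well sampled).  Static beads get fresh per-frame jitter;
waters are resampled each frame, so pore statistics fluctuate while the
seed keeps everything bit-reproducible.

What the generator does *not* emulate: lipid diffusion and undulations,
peptide conformational dynamics, water permeation kinetics, periodic-image
molecule wrapping, and any coupling between peptide and membrane.  Passing
recovery tests therefore demonstrates estimator correctness on known
geometry, not agreement with real trajectories.

## Membrane metrics

* **Leaflets** — lipids split by mean headgroup z against the per-frame
  median; z ≥ median goes upper, so planar edge cases are deterministic.
* **Thickness** — mean upper minus mean lower headgroup z per frame.
* **Area per lipid** — box cross-section over leaflet count (APL × count =
  Lx·Ly exactly); Voronoi tessellation is deliberately out of scope.
* **Order parameter** — S = ⟨(3 cos²θ − 1)/2⟩ with θ against z, bounded in
  [−0.5, 1].  The coarse model has no hydrogens, so the trajectory helper
  uses successive-bead segment vectors as pseudo-bonds (a straight chain
  along the normal scores exactly 1); explicit bond vectors can be passed
  to compute the conventional C–H form exactly.
* **Pore radius** — the membrane span is cut into z slabs (default 1 Å,
  bounds defaulting to the headgroup planes); a slab's radius is the
  maximum lateral distance of its waters from their centroid (the
  half-max-pairwise-distance reading is available via
  `method="pairwise"`); an empty slab yields 0 (no continuous pathway);
  the frame value is the minimum over slabs — the bottleneck.  Trailing
  statistics default to the last 0.8 of frames, mirroring an
  80-of-100 ns relaxation window.
* **Fate classification** — over the trailing window, median peptide COM z
  below (lower plane + margin) ⇒ lower-leaflet equilibrium; above
  (upper plane − margin) ⇒ return; otherwise mid-membrane, split by
  whether the bottleneck radius exceeds `pore_threshold` in more than
  `persistence` of frames: pore formation vs insertion.  Defaults
  margin 5 Å, threshold 1 Å, persistence 0.5 — the source taxonomy is
  qualitative, so all three are configuration-exposed.  The margins keep
  the three z-regions disjoint for any bilayer thicker than 2 × margin.

## Contacts

Residue occupancy is the percentage of analyzed frames in which any bead
of a peptide residue lies within the cutoff (default 4.0 Å, a common
heavy-atom contact distance; the emulated study never states its value, so
it is exposed and echoed in outputs) of any bead of the selected lipid
group (headgroups, optionally per species; tails; sterol) and leaflet.
Distances are minimum-image under the orthorhombic box via MDAnalysis.
Occupancy is exactly monotone in the cutoff and obeys the union bound over
groups; a brute-force all-pairs scan reproduces it exactly on small frames.

## Descriptors

GRAVY is the mean Kyte–Doolittle hydropathy over residues (rounded to two
decimals only for display).  Net charge uses integer formal charges at
neutral pH: +1 Lys/Arg, −1 Asp/Glu, His neutral, zwitterionic termini
cancelling — the only model reproducing all declared study charges;
fractional pKa-based charge is deliberately excluded.  The bundled registry
carries the five study peptides; declared and recomputed values are
cross-checked, and the one inconsistency in the source table (K-FGF
declared length 17 vs its printed 16-residue sequence) is flagged, not
silently corrected.

## Numerical choices and limitations

Degenerate inputs raise rather than coerce: empty ensembles, non-finite
works, zero-length bond vectors, inverted leaflet planes, channels wider
than the half-box, unstable integrator settings.  Work-trace CSVs,
multi-model PDB and GRO series round-trip through MDAnalysis at format
precision (10⁻³ Å for PDB, 10⁻² Å for GRO).  The demo pipeline writes a
manifest with seed, parameters and SHA-256 checksums; reruns are
byte-identical.

Test and demo problem sizes (8 × 5 Å stages × 25 replicas at dt = 10⁻³ ns;
bilayers of tens-to-hundreds of lipids over ≤10 frames) are the package's
validation scale: large enough for the stated statistical bounds, small
enough to run in seconds.  The 1-D engine cannot, by design, show membrane
deformation, the defect-assisted dragging of headgroups, or absolute
translocation barriers; those require the full molecular simulations this
package analyzes.
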
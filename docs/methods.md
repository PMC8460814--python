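# Methods

This note documents the models, parameters, numerical choices, and known
limitations of `wayvis`, in the package's own terms.

## Environments

Two two-storey buildings are generated parametrically (`BuildingParams`),
identical except for the atria layout. Coordinates are right-handed, z-up,
in metres, with the origin at the entrance and the fixed initial heading
along +x; yaw is degrees counterclockwise from +x, pitch degrees upward.

The study design constrains only a few quantities: the total atria void
area (288 m², conserved exactly per variant and asserted at construction),
the destination layout (eight doors, four per floor, two
entrance-forward-facing and two entrance-backwards-facing each), an
identical first floor across variants, a fixed entrance pose, and the
avatar kinematics. All other dimensions are this package's defaults, chosen
so the constrained elements fit a plausible hall: 36 m × 18 m floors, 3 m
floor-to-floor, a 3 m-deep ring of enclosed perimeter rooms on the first
floor, a fence confining second-floor movement to a perimeter walkway, and
an escalator whose base sits ≈ 10.6 m from the entrance with a slab cutout
at its landing (the cutout is an escalator well, not an atrium, and is not
counted in the 288 m² budget). Defaults are config-overridable and are not
claimed faithful to the original scenes, whose dimensions are unpublished.

Occluders are axis-aligned rectangles (walls, slabs, roof, fence) with
rectangular holes for glass doors and voids. Destination doors are one-sided
1 m × 2 m rectangles flush with their walls: rays reaching the back face
count as blocked. Glass doors are transparent to destination rays but are
treated as bounding surfaces for isovists (glass still delimits the visible
volume of a space; zone boundaries include doors). The fence is modelled as
a 1 m parapet that occludes rays crossing its height band. The escalator
ramp itself is not an occluder (an open stair with see-through railings)
and blocks movement only through its first-floor footprint.

## Visibility

*Destination visibility* casts a uniform k × k grid of rays (default
10 × 10 = 100) from the eye to the door surface. A ray counts as reaching
when its target lies inside the view cone — azimuth within half the
horizontal angle of yaw, elevation within half the vertical angle of pitch,
distance within range — and no opaque rectangle intersects the segment.
The human-side post-processing FOV default is 91° × 60° with 100 m range (a
16:9 desktop camera with a 60° vertical angle); the agent FOV is 150°
horizontal, 100 m range, with the vertical angle defaulting to 60° (the
vertical extent is not constrained by the study and is a parameter).

*Isovists* are 2D visibility polygons in a horizontal slice at eye height
(1.7 m above the floor). They are computed by an angular sweep (default 1°)
augmented with rays aimed at and just past every wall endpoint, which
recovers polygonal scenes essentially exactly; the 100 m range circle is
discretised at the sweep resolution. *Drift* is the distance from the cast
point to the polygon's area centroid. The *drift field* precomputes drift
for every walkable navigation cell (1 m default resolution) at 2° sweep
resolution; a compositional test asserts the field equals per-cell isovist
drift exactly.

## Behavioural measures

The analysis window is the trajectory prefix up to the first sample within
`arrival_radius` (default 0.5 m — the bottom step is a point, a radius is
required) of the escalator base. Measures over the window:

- **Time to Escalator** — window duration (s).
- **Average Vertical Head Movement** — mean *absolute* pitch change between
  consecutive samples (degrees). A signed mean would telescope to
  (pitch_end − pitch_start)/n and could not indicate visual search; the
  absolute-difference reading is documented as an interpretation. Note this
  measure is per-sample and therefore depends on the sampling rate; it is
  comparable across trials logged at one rate (as in the emulated design)
  but is excluded from the resampling-invariance test.
- **Average Cosine Similarity** — mean cosine between the heading and the
  direction to the escalator base. Both vectors are projected to the
  horizontal plane by default so that a level gaze aimed at the base scores
  exactly 1 (the base is a floor point; a 3D cosine can never reach 1 with
  a level gaze); `cosine_plane="3d"` compares full 3D vectors instead.
  Heading means camera forward (desktop mouse-look), not movement
  direction.
- **Average Destination Visibility** — mean ray-cast visible fraction over
  the window; an optional stride subsamples poses for speed (convergence in
  the stride is asserted in tests).

Trials with exactly zero average visibility form the NV condition, all
others V. The original matched NV/V design implies a matching rule that is
not published; the default keeps all trials and reports counts, and an
optional random stratified matcher (per participant × block) can equalise
the counts. Neither is claimed canonical.

## Statistics

The three response forms are fitted by closed-form group means (threshold),
ordinary least squares (linear), and nonlinear least squares with a
log-linear start (exponential; a non-converged fit is flagged and ranked
last). Information criteria use a Gaussian likelihood with the error
variance profiled out and k = 3 ({a, b, σ}) for every form, so the AIC/BIC
comparison is on equal footing; the likelihood family is this package's
choice. An extrapolation report flags where the smooth forms leave the
physically admissible range beyond the observed visibility values.

Mixed models are random-intercept fits (statsmodels MixedLM), REML by
default with an ML option for information-criterion comparisons. The
coefficient table reports Wald z statistics, two-sided normal p-values and
coef ± 1.96 SE intervals. Encoding in the study-style model: NV is the
reference level of the visibility condition (the coefficient is the V − NV
effect), block is numeric 0-based (the intercept refers to non-visible
trials in the first block), atria type and session are 0/1 indicators.
Bonferroni correction is α/m; a stricter declared threshold (the study used
0.001 < 0.05/21) is accepted, a looser one rejected.

## Agents

Both agents share the avatar kinematics: height 1.8 m, eye height 1.7 m,
shoulder width 0.25 m, forward speed 1.3 m/s, lateral/backward 0.6 m/s.
Motion realisation (unconstrained by the study, documented as defaults):
the agent turns toward its current waypoint at 90°/s and advances only when
aligned within 45°, with an internal 0.1 s step, logging poses every 0.2 s.
Navigation uses an 8-connected grid (diagonal cost √2, corner-cutting
disallowed, 0.2 m wall clearance) with a single inter-floor edge along the
escalator; A* uses the straight-line 3D distance heuristic, which is
admissible because every edge weight is at least its endpoint displacement.

The cognitive agent's controller: from the spawn state it moves to the
escalator if the destination is in its 3D FOV, else it explores. Exploring
means walking to the visible cell with minimal drift whose convex zone has
not been traversed (ties: nearest, then lowest cell index); traversed zones
are a growing short-term memory and are never re-targeted. If no visible
cell qualifies, any unvisited zone may be targeted; once no unvisited zone
remains, the first floor counts as *sufficiently explored* and the agent
heads for the escalator (on the second floor this situation flags a failed
trial instead). Catching sight of the destination during first-floor
exploration triggers the move-to-escalator state; sight during that state
does not replan. The in-sight check is re-evaluated after the floor switch
(at the escalator top): if positive the agent plans a shortest path to the
door, otherwise it keeps following minimal-drift cells on the second floor.
Escalator riding happens at forward speed along the ramp; a catch-up phase
walks the agent onto the base first so no logged step exceeds the speed
cap. The shortest-path baseline plans entrance → base, rides, then top →
door, which is the A* path through the single inter-floor link; its
pre-escalator leg is shared across destinations, making its Time to
Escalator exactly invariant to the destination. Both agent types spend
time rotating from their random initial heading, for fairness.

Zone decomposition splits each floor's walkable polygon at reflex vertices
(recursively, cutting along an incident edge; polygons with holes are first
split through the hole centroid), yielding convex zones that tile the floor
exactly; an optional maximum span subdivides large zones further.

## Monte-Carlo experiments and comparison

A simulation experiment draws one uniform initial heading per agent and
runs every destination in the configured set with it, the study's 1600
samples thus being 400 agents × 4 second-floor destinations. This
organisation identifies the per-agent random intercept of the difference
model. Per-trial L1 differences are taken against the per-destination human
benchmark (mean by default, median optional — the aggregation the study
used before its difference model is unpublished). KDE rasters use a
Gaussian kernel with Scott's rule bandwidth by default and are renormalised
to integrate to one over their extent. DTW is the classic unconstrained
dynamic program on 2D positions with Euclidean local cost.

## Synthetic study generator

The generator emulates the deposited data's *structure*: 69 participants,
atria type and session between subjects, 3 blocks × 8 destinations in
randomised order, a pose sample every 0.1 s. Target measure values per
trial follow a linear mixed model whose defaults are the study's reported
effects (time intercept 34.765 s, visibility effect −4.935 s, block effect
−2.095 s; head movement 0.041/−0.025/−0.002°; cosine 0.723/+0.107/+0.039;
participant SDs near the reported random-intercept variances; residual SDs
5 s / 0.008° / 0.06, chosen to give z magnitudes of the same order as the
reported tables since residual variances are not printed). Targets are
realised geometrically: time via a hesitation phase at the entrance (the
avatar paces slowly along its dwell heading, so longer hesitation also
means a longer walked path and time/distance stay concordant); head
movement via an alternating pitch step equal to the target; cosine via the
dwell heading angle solved against the fixed walk's contribution and
clamped to the feasible range (the clamp slightly attenuates extreme cosine
targets, visible as a small attenuation of the recovered cosine effect).
The visibility condition follows the door's facing by construction of the
geometry: forward-facing doors are visible through the atria during the
walk, backwards-facing doors are occluded by the slab from everywhere the
synthetic avatar goes.

What the generator does *not* emulate: genuine visual search (pitch is a
micro-oscillation, not gaze), collision avoidance, within-trial speed
variation, or any dependence of the path shape on the atria variant.
Passing recovery tests therefore shows the *pipeline* (measures →
segmentation → mixed models) is unbiased under the emulated design, not
that real human data would yield the same coefficients.

## Problem sizes in the checked runs

The test suite and the acceptance script run everything at desk scale as
this package's own defaults for verification runs: the full 69-participant
synthetic design (828 analysed trials) per replicate, 50 replicates for
effect-recovery coverage, 100 replicates (n = 400) for threshold-form
identification, 200 Monte-Carlo trials per agent condition, visibility
scored with a 3 × 3 ray grid at a stride of 5–6 samples in bulk runs (the
stride/ray-count convergence is asserted separately).

## Known limitations

- The cosine-similarity signature of the cognitive agent does not match
  human-like benchmarks: during exploration the agent's heading points at
  drift targets across the hall, giving backward-trial cosines near 0.2
  where the emulated humans sit near 0.72, so in cosine the cognitive agent
  deviates *more* from those benchmarks than the shortest-path baseline.
  The time-measure pattern — the one the agents reproduce robustly — is the
  one asserted in the always-run suite; the cosine direction depends on the
  real human benchmark data. No agent parameters were tuned against any
  benchmark.
- Failed second-floor explorations (all zones visited, door never seen) are
  flagged, not retried; they do not occur in the default environments.
- The per-sample head-movement measure is sampling-rate dependent (see
  above).
- Only two floors and a single escalator are supported; isovists are 2D
  slices, not 3D volumes.
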
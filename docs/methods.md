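# Methods

## Model overview

`lotcrt` simulates ventricular electrical activation as a first-arrival
(Eikonal) problem on a tetrahedral biventricular anatomy coupled to a 1-D
His-Purkinje tree, and uses it to study how the programmed
ventriculo-ventricular delay (VVD) between a left-bundle-area lead and an LV
epicardial lead shapes left-ventricular synchrony under different conduction
substrates. Only local activation times are computed; membrane kinetics,
repolarization and body-surface potentials are outside the model. All the
synchrony metrics and optimal-VVD logic consume activation times alone, so a
pure Eikonal formulation carries the full analysis; this is a deliberate
fidelity simplification relative to reaction-Eikonal electrophysiology.

Units are fixed package-wide: mm, ms, and m/s (1 m/s = 1 mm/ms).

## Synthetic anatomies

The generator builds idealized two-ventricle geometries from implicit
surfaces: the LV is a thick shell between two confocal-ish ellipsoids
truncated at a basal plane, and the RV is a thinner crescent shell from a
second, laterally offset ellipsoid pair that wraps the LV's septal side. The
septum is the part of the LV wall facing the RV cavity, so the RV septal
endocardium coincides with the "epicardial" level surface of the septal
wall, and the transmural coordinate runs 0 → 1 from the LV endocardium to
the RV septal endocardium there — which is what makes the even transmural
septal split well defined.

Default dimensions (all configurable, mm): LV endocardial long axis 42,
equatorial radius 20, LV wall 9, RV wall 4, RV wrap ~150°, basal truncation
at 0.8 of the long axis. The truncation level matters mechanistically: it
leaves a genuine Purkinje-free basal band (the Purkinje network only covers
the apical 70% of the apicobasal range, see below) whose late activation is
precisely the territory an epicardial lead can rescue. Cohorts are built by
seeded multiplicative jitter (default ±10%) of the main dimensions; the
same parameters and seed reproduce a mesh bit-for-bit.

Meshing snaps a regular lattice (default 1.5 mm, a compromise between
oracle accuracy and desk-scale runtime) onto the nearest implicit surface,
jitters interior points slightly to avoid degenerate Delaunay
configurations, tessellates, and keeps tetrahedra whose centroid lies in
the wall, followed by a largest-connected-component filter. Surface
triangles are tagged by probing just outside each boundary face (LV endo,
RV septal/free endo, epicardium, base). The jagged-boundary error this
introduces is below the lattice spacing and irrelevant next to the
first-order solver error.

Fibers follow a rule-based transmural helix: the angle interpolates
linearly from +60° (endocardium) to −60° (epicardium) about the local
circumferential direction in the wall tangent plane. The conduction model
only requires transverse isotropy about some fiber field; this is the
standard rule used when imaging-derived fibers are unavailable.

## His-Purkinje network

The tree is generated on the endocardial surfaces: a His trunk above the
basal septum, left and right bundles, three LV fascicles (anterior,
posterior, septal) and two RV fascicles (septal, moderator band — the
latter crossing the cavity as a chord, as the anatomical structure does).
Fascicle paths are geodesics on the endocardial surface graph; Purkinje
arborizations are unions of geodesic branches from each fascicle terminus
to seeded junction sites (default 1.5 PMJ/cm², apical 70% of the
endocardium). Building branches as predecessor paths of a single
shortest-path computation, grafted leaf-to-root onto the existing network,
guarantees the graph is exactly a tree — which in turn makes fascicle
calibration closed-form, because arrival paths are unique.

Every terminal couples to its nearest endocardial mesh vertex through a
Purkinje-myocardial junction with anterograde delay 10 ms and retrograde
delay 5 ms (literature-typical values; both configurable — the source
model does not state them).

**Fascicle CV calibration.** The His/bundle/Purkinje segments conduct at
3 m/s. Per-fascicle CVs are set in closed form so that a sinus beat reaches
all three LV fascicle ends at a common time T and both RV fascicle ends at
T + 10 ms, matching classical human sinus activation sequences. T is
anchored at the latest unconstrained LV arrival, so every calibrated CV is
≤ the trunk CV; infeasible targets (an RV fascicle that cannot be slowed
enough) raise a calibration error rather than silently clipping.

## Activation solvers

*Tree*: earliest arrival by Dijkstra over conductive edges, edge time =
length / segment CV.

*Myocardium*: anisotropic Eikonal first arrival with the elliptical
travel-time metric `t(d) = sqrt(d^T M d)`,
`M = vf⁻² f fᵀ + vt⁻² (I − f fᵀ)`, `vt = 0.4 · vf`, `vf = 0.6 m/s`
scaled per element by region multipliers (disease scenarios) and any scar
scale. Sheet and normal-to-sheet speeds are equal (transverse isotropy).
The solver is a numba-compiled label-correcting fast-iterative method whose
local step minimizes arrival over each adjacent tetrahedron face, with
closed-form face/edge/vertex sub-solutions. The update threshold (default
0.05 ms) bounds a path-dependent wobble of a few tenths of a millisecond;
the dominant error is first-order mesh discretization — exact along
lattice-aligned directions, up to ~10% in oblique directions at 1 mm and
anisotropy 0.4, shrinking under refinement. Tests cross-check the solver
against an independent chord-graph shortest-path oracle and closed-form
point-source solutions.

*Coupling*: tree and tissue interact bidirectionally through the PMJs
(anterograde into muscle, retrograde into the network). The coupled system
is iterated to a fixed point; every operation is min-plus linear, so the
iteration is monotone non-increasing and the fixed point from several
stimuli equals the element-wise minimum of single-stimulus fixed points.
The VVD sweep exploits exactly this: one coupled solve per lead, then a
`min(U₁ + onset₁, U₂ + onset₂)` combination per grid point, which makes a
21-point sweep cost two solves instead of 21. Retrograde coupling can be
disabled; unreached tissue carries +inf and is excluded from metrics with
a warning.

## Conduction substrates

Three mechanisms, applied to copies of the tree/model:

* proximal left bundle branch block — the first left-bundle edge below the
  His bifurcation is made non-conductive; the distal left bundle survives
  as the LBBP pacing target;
* diffuse LV conduction-system delay — left bundle, LV fascicles and LV
  Purkinje CVs scaled by a factor (His trunk and all right-sided segments
  untouched);
* LV intra-myocardial delay — CV multiplier of the LV free wall *and the
  LV half of the septum* scaled (consistent with the transmural septal
  attribution used by the metrics).

Scenario codes: A = block + slow LV HPS, B = block + slow LV myocardium
(mild/severe = 60%/40% of healthy CV), C and D = the respective slowing
alone without block (mild/severe = 40%/20%, because milder slowing without
block barely prolongs LV activation). A spherical lateral-wall scar with
its own CV scale (0 = non-conductive) and optional Purkinje involvement is
available for regional-disease experiments.

## Pacing protocols and VVD

Supported modalities: sinus; His-bundle pacing (targets the node distal to
the block, so it corrects proximal block); selective LBBP (left bundle
only); non-selective LBBP (bundle + septal myocardium within a 2 mm capture
radius); LV septal pacing (myocardium only); LV epicardial pacing at the
latest-activated baseline epicardial site (free wall, valve band excluded,
ties to the lowest node index); RV apical pacing; and the two-lead
combinations BVP, LOT-CRT (selective / non-selective / septal-capture) and
HOT-CRT. Negative VVD fires the conduction-system/RV lead first, positive
the epicardial lead first; onsets are normalized so the earliest stimulus
is t = 0; paced protocols contain no sinus source (pacing is assumed to
override intrinsic rhythm). AVD-optimized fusion with intrinsic conduction
is deliberately out of scope.

## Synchrony metrics

All interval metrics are *shortest time interval taken to activate q% of a
region*: the narrowest time window containing q% of the element-volume-
weighted activation mass (element-centroid times; surface variants are
face-area-weighted). q = 100 gives the total activation time; q = 95 the
AT95 family. The sliding window is the substantive choice: up to 5% of
early-activating volume (for example a small pre-excited epicardial patch)
does not stretch LVAT95, which is what lets a large positive VVD pay off
under intra-myocardial delay instead of being charged for its head start.
A min-anchored percentile suppresses that mechanism entirely. One
consequence worth knowing: a shortest-window metric is not strictly
monotone under added stimuli (earlier activation of some tissue can spread
a previously tight distribution), although nodal activation times are.

The basal valve band (apicobasal > 0.9) is always excluded; the septum
counts toward the ventricle of its transmural half; the LV epicardium for
surface metrics is the set of epicardial faces owned by LV free-wall
elements (the septum has no epicardial exposure). Responses are paced −
baseline (negative = improvement). The optimal VVD minimizes LVAT95 over
the −100…+100 ms grid in 10 ms steps; ties prefer the smaller |VVD|, then
the negative candidate; a boundary optimum is flagged, not extrapolated.

## Cohorts and statistics

Cohorts derive per-anatomy seeds from one master seed via a SeedSequence
split, run the requested scenario × modality × VVD cells, and emit a tidy
table (one row per cell per VVD plus per-scenario baselines). Summaries are
mean ± sample SD (n−1). Two-group comparisons follow a normality-gated
protocol: Shapiro-Wilk per group at α = 0.05, then a two-sided t-test if
both groups pass, otherwise Mann-Whitney U, with Bonferroni correction over
the comparison family (default N = 10). The printed clinical
electrocardiographic-imaging constants from the original validation are
embedded verbatim and only ever *juxtaposed* with synthetic-cohort numbers
in a labelled report — never asserted against — because the idealized
anatomies are not the imaged patients.

## Problem sizes and what the tests show

The default test suite runs slab verifications at 1 mm resolution
(seconds) and a three-anatomy cohort at the default 1.5 mm resolution
(~250k tetrahedra per heart; the cohort takes on the order of ten minutes).
On that cohort the package reproduces the qualitative programming
guidance: optimal VVD negative (conduction-system lead first) for diffuse
conduction-system delay, positive (epicardial lead first) for
intra-myocardial delay under selective capture, always negative for
septal-capture hybrids, |optimal VVD| non-decreasing with severity, hybrid
CRT no worse than biventricular pacing in mixed substrates, and marginal
(≤ 10 ms) epicardial benefit in pure proximal block.

What passing tests do *not* show: agreement of absolute cohort-level
magnitudes with the published patient cohort. Those depend on 24 CT-derived
heart-failure anatomies and a patient-adapted conduction-system generator
that are not reproducible from parameters. The soft comparison against the
published mean ± 2 SD windows is reported per cell; on the default cohort
most cells land inside their windows, but substrates with nearly flat
LVAT95-vs-VVD profiles here deviate: the no-block conduction-system cell
overshoots toward more negative VVDs, the biventricular-pacing optimum in
the mixed conduction-system scenario sits slightly RV-first instead of
slightly epicardial-first (both "near simultaneous"), and the mild
intra-myocardial cell optimizes at exactly simultaneous rather than
epicardial-first. The corresponding assertions are left strict and fail
loudly rather than being widened. Synthetic anatomies also idealize away
wall-thickness heterogeneity, trabeculation, papillary muscles and real
scar distributions.

## Numerical choices and degenerate inputs

* Eikonal update tolerance 0.05 ms; coupling tolerance 0.01 ms with a
  20-iteration cap (a cap hit raises with the residual, it never returns a
  half-converged map silently).
* Septal mid-surface ties (transmural depth exactly 0.5) go to the LV half.
* Zero-CV regions are excluded from updates; a stimulus inside one is an
  error; tissue enclosed by one stays at +inf.
* Degenerate Delaunay slivers below 10⁻⁹ mm³ are dropped; all elements are
  reoriented to positive volume.
* Mesh/tree determinism is bit-exact for fixed parameters and seed.
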
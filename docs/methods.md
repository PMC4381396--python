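# Methods

## Problem and approach

Given a receptor structure and the docked poses of a screening library,
`somsite` locates candidate binding sites as regions where poses accumulate
densely and homogeneously.  The pose-atom point cloud (all heavy atoms of
all retained poses, up to the 20 lowest-energy poses per ligand) is
summarised by a 3D self-organizing map (SOM); consensual clusters of the
map are candidate sites; grid-detected cavities characterise them against
the receptor; and a circular-substructure decomposition of the library
scores chemical moieties for active-site enrichment.

## Cavity detection

Space around the receptor is discretised at 0.5 Å.  A grid point is
*accessible* to a probe of radius `r` when its distance to every atom
centre is at least `vdW + r` (Lee–Richards solvent-accessible convention;
Bondi vdW radii by default, overridable per element).  Two probes are used:

* solvent probe, 1.4 Å — accessibility including interior voids;
* bulk probe, 10 Å — bulk solvent.

Bulk solvent is operationalised as the *volume swept* by bulk probes whose
centres sit in the boundary-connected component of the 10 Å valid-centre
mask: valid centres are flood-filled from the grid faces (26-connectivity)
and dilated by the probe radius with an exact Euclidean distance transform.
Subtracting only the valid-*centre* mask would misclassify the entire
3.1–11.7 Å shell around any structure as cavity; sweeping the probe volume
is what "not accessible to bulk solvent" means physically.

Cavity points (solvent-accessible, outside bulk volume) are clustered by
26-connectivity; clusters under 96 points (12 Å³, about one water molecule)
are discarded; survivors are labelled 1..n by decreasing volume, which is
exactly `voxel_count x spacing³`.  The grid origin is snapped to multiples
of the spacing so detection is invariant under translations by grid
multiples.  A neuron lies in a cavity when any of the 8 corners of its
enclosing grid cell carries the cavity label (ties to the smallest id);
neuron density is neurons-in-cavity over cavity volume.

Per-cavity absolute volumes depend on the vdW radius table, which is a free
choice here; comparisons across runs should hold the table fixed.

## Self-organizing map

PCA of the pose-atom cloud gives orthonormal components `V1..V3` with
lengths `S1>=S2>=S3` (square roots of the covariance eigenvalues).  Map
dimensions are `round(c * S_i)` with `c = (target / (S1*S2*S3))^(1/3)`,
target 15³ = 3375 neurons, every dimension floored at 2 and degenerate
lengths floored at `S1/100`.  The lattice is initialised regularly spaced
along the principal axes spanning the projection range `[V-, V+]` of the
data, offset by the cloud mean.

Training presents every point once per cycle in a seeded random order.
Within a phase, radius and learning rate decay as
`(x0 - xf) * exp(-t/lambda) + xf` with `lambda = cycles*n/10` and `t`
counted continuously across the phase's cycles.  Defaults: phase 1, one
cycle with `(r, alpha)` from `(7.5, 1.0)` to `(3.75, 0.5)`; phase 2, ten
cycles from `(3.75, 0.5)` to `(1.0, 0.1)`.  After each presentation the
best-matching unit (BMU; Euclidean, ties to the smallest flat index with k
fastest) is found and every neuron moves by
`alpha * exp(-d²/(2 r²)) * (x - w)` where `d` is the lattice-index distance
to the BMU.  The Gaussian neighbourhood is the conventional choice where
only the radii are prescribed; a hard-cutoff kernel (`d <= r`) is available
behind `kernel="cutoff"`.  All randomness flows from one integer seed, so
identical seeds give bit-identical maps.  Acuity is summarised by the
quantization error (distance of each input to its BMU).

## Consensual clusters

The U-matrix assigns each neuron the mean distance to its existing direct
lattice neighbours (up to 26; fewer at the non-periodic borders).  The
threshold `t_U = mu + sigma` of the largest-weight component of a Gaussian
mixture fitted to the U-values, with the component count (1–10) chosen by
BIC (ties prefer fewer components; fits are seeded with 5 restarts).  A
near-zero-variance distribution short-circuits to the common value.

Neurons with `U <= t_U` are aggregated by 26-connectivity into consensual
clusters (CCs), ranked by decreasing neuron count; ties break by lower mean
U, then smallest member flat index.  Each CC's overlap radius `r_CC` is
`mu + sigma` of the dominant component of a 2-component mixture over
intra-cluster nearest-neighbour distances, collected between axis
neighbours (±1 along one lattice index) that are both members.  On a
perfectly regular lattice all distances coincide and `r_CC` is the spacing;
clusters with fewer than 4 such distances fall back to mean + sd; clusters
with no intra-cluster neighbour pair (single neurons) have no radius and
are excluded from precision scoring.

Precision of a CC against a reference ligand is the fraction of ligand
atoms within `r_CC` of any CC neuron ("within" is `<=`).  Evaluation
reports per-CC precisions, the lowest-rank CC exceeding the precision
threshold (0.25 default) as the hit, Top1/Top3 success flags, and a
stringent occurrence flag that marks failure when the ligand overlaps
(precision > 0) zero or two-plus CCs.  Fixed radii of 1.6 Å and 2.0 Å and a
heavy-atoms-only mode support comparisons with the conventions of other
site-prediction tools.

## Chemical features and enrichment

Each molecule (hydrogens removed) is decomposed into the circular Morgan
environments of every heavy atom for radii 0–3 bonds; the canonical
environment hash is the feature identity (stable across atom orderings and
shared across molecules), and occurrences outside 3–7 heavy atoms are
filtered out.  The 3–7 window realises the "small moiety" size range; the
radius-3 cap bounds environment diameter at 6 bonds.  A feature occurrence's
position in a pose is the arithmetic mean of its member-atom coordinates.

Feature sets: `F_EGFd` all features of docked compounds; `F_AS` those with
at least one occurrence centre within `r_CC` of the active-site CC (a
per-centre rule, applied occurrence by occurrence); `F_AS_bar` its
complement in `F_EGFd`; `F_A = F_EGFd ∩ features(actives)`.  Enrichments,
sensitivity `Se = |F_A ∩ F_AS|/|F_A|` and specificity
`Sp = |(F_EGFd \ F_A) ∩ F_AS_bar|/|F_EGFd \ F_A|` follow; undefined
denominators are reported as absent rather than zero, and `Se/(1-Sp)` is
+inf when `Sp = 1` with `Se > 0`.

Significance uses a randomization null: `F_AS` (resp. `F_AS_bar`) is
redrawn uniformly without replacement from `F_EGFd` preserving its size —
implemented as chunked row permutations of a membership indicator, a
genuine resampling whose overlap counts are hypergeometric — and the
Z-score is the observed statistic's distance from the null mean in null
sds.  |Z| > 4 is flagged strongly significant.  The production default is
10⁶ draws; tests and the acceptance script use 10⁴–10⁵, which already pins
the null moments to three significant figures at these set sizes.

## Synthetic data

The generators produce the fixtures every stage is tested on:

* **Hollow shells** — carbon-like pseudo-atoms (r = 1.7 Å) tile concentric
  spherical layers 1 Å apart; the interior void is an analytically known
  cavity.  A flood-fill self-check rejects leaky tilings.  An optional
  mouth cone converts the void to a surface pocket; note a 10 Å bulk probe
  genuinely cannot wash out an open bowl much narrower than itself, so
  destroying the enclosure requires a bowl wider than the probe.
* **Pose clouds** — each ligand is a rigid random chain cluster (3–8 heavy
  atoms, 1.5 Å steps); each of its 20 poses independently lands in a
  Gaussian pocket or a uniform background box, with scores normal around
  per-pocket means (favoured pocket lowest).  The planted-pocket study
  condition is 50 ligands x 20 poses with weights 0.8/0.15/0.05
  (major/minor/background) and 1.5 Å pocket spread, plus an 8-atom probe
  ligand sampled in the major pocket for evaluation.
* **Toy libraries** — random connected C/N/O graphs of 4–12 heavy atoms
  with valid valences, emitted as SMILES.

What these fixtures do *not* emulate: conformational flexibility, real
docking energetics, chemistry-dependent pose preferences, and receptor
shape around the pockets.  Passing tests therefore demonstrate the
correctness of the clustering/consensus machinery under known ground
truth, not docking accuracy on real targets.

The acceptance script's enrichment scene scatters non-active molecules
over a few shallow decoy sites rather than uniformly in space.  This
mirrors real docking, where poses always land on surface sites — and it
matters for the method: the U-value threshold takes the *largest-weight*
mixture component, so the input cloud must be dominated by site-bound
poses.  A mostly-diffuse cloud makes the background mode dominant and the
threshold meaningless; that regime is outside the method's operating
conditions.

## Numerical choices and edge cases

* BMU and CC rank ties break deterministically (smallest flat index /
  lower mean U) so reports are byte-stable.
* GMM fits: seeded, 5 restarts, BIC ties to fewer components.
* Grid memory is capped (configurable); exceeding it raises an error that
  suggests a larger spacing.
* Pose-score ties at the `max_poses` cutoff keep file order.
* PCA component signs are fixed (largest-magnitude entry positive) so
  initialisation is deterministic.
* Problem sizes in tests and the acceptance script: 1000-pose clouds,
  3375-neuron maps, 20-seed repetitions, 10⁵ randomization draws — chosen
  as the smallest sizes at which the statistics stabilise.

## Known limitations

* Training is a per-presentation Python/NumPy loop (~10 s for 5600 points
  on a 3375-neuron map); very large pose sets benefit from down-sampling.
* Cavity volumes inherit the vdW-table choice; no table calibration is
  attempted.
* Score-based CC re-ranking (using the projected mean docking score to
  promote the active site when it ranks second) is exposed as data
  (`neuron_mean_scores`) but not automated.
* mol2 ingestion requires a sidecar score table; PDBQT scores are read
  from Vina result remarks only.
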
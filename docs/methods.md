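# Methods

This note documents the models and procedures implemented in `fibrilmod`,
the parameters that matter and their defaults, the statistical structure
the synthetic generators emulate, and the numerical choices made where the
design was genuinely open.

## Contact definition and units

All coordinates are handled internally in nm, times in ns; Angstrom-based
formats are converted on read, and hydrogens declared in inputs are
dropped, so every analysis operates on heavy (non-hydrogen) atoms.

Two residues are *in contact* in a frame when the minimum distance over
their heavy-atom pairs is below the contact cutoff, 0.45 nm by default.
Only pairs separated by at least three intervening residues are
considered; "at least three other residues" is read strictly as
|i−j| ≥ 4, applied identically to simulation ensembles and to fibril
structures, and recorded in every output header. Under periodic
boundaries, distances use the general triclinic minimum-image convention
(fractional coordinates wrapped to [−½, ½)), which is exact for the
rectangular and modestly skewed boxes used in practice.

Contact maps are stored sparsely: only pairs with P<sub>ij</sub> > 0,
together with the pair-universe size. Absence of a pair means "no frames
in contact" — a real observation, not missing data — and downstream code
(contact deltas, modulation regression) treats it as P = 0. Contact
deltas are therefore computed over the union of stored pairs within the
shared pair universe.

## Periodic-image QC

Before analysis, frames in which any protein atom approaches any protein
atom of the nearest periodic image within 0.3 nm are flagged; the
reference behaviour enumerates all 26 neighbour cells explicitly. The
filter removes flagged frames individually (per-frame removal is the
default; the violation fraction is always reported). Frame exclusion
never alters per-frame values of retained frames.

## Fibril-native contacts and polymorph clustering

One monomer is extracted per deposited structure. The default chain
policy, `central`, picks the chain whose centroid lies nearest the
assembly centroid — an interior protofilament layer, avoiding stack-edge
effects; `first` and explicit chain ids are available. Residue numbers
are shifted by an explicit `renumber_offset` into full-length isoform
numbering (no automatic sequence alignment). Residues with some atoms
unresolved keep their resolved heavy atoms; fully unresolved residues
drop out of the pair universe.

The native-contact cutoff reuses the ensemble contact definition
(0.45 nm, |i−j| ≥ 4) so fibril-native pairs and ensemble pairs live in
one universe. Structures are clustered on a graph with an edge whenever
two structures share at least one contact (a Jaccard-index threshold is
available for sensitivity analysis); clusters are connected components,
which makes "a structure sharing no contact with any other is a
singleton" hold by construction and yields exact membership counts.

## Modulation coefficients

For each fibril-native pair, k<sub>ij</sub> is the ordinary-least-squares
slope of P<sub>ij</sub> against the *numeric* molar ratio (0, 1, 5, 10,
50, …), not the condition rank. Unweighted OLS is the default; weighting
by per-condition frame counts is a switch. The intercept, r² (reported
as NaN for a flat response, which has no variance to explain) and point
count are retained per pair. With exactly two conditions the slope
reduces algebraically to ΔP<sub>ij</sub>/Δratio. Classification into
promoted / suppressed / unchanged uses a symmetric slope threshold
(default 0: any nonzero slope is classified by sign); region annotations
are supplied by configuration, never hard-coded.

## Twin-cutoff contact dynamics

Binary contact trajectories use hysteresis: a contact forms when the
heavy-atom distance drops below r<sub>on</sub> = 0.45 nm and breaks only
when it exceeds r<sub>off</sub> = 0.6 nm; distances in the dead zone
retain the previous state, which suppresses spurious boundary
recrossings. A series starting in the dead zone is back-filled from the
first unambiguous state by default (dropping the ambiguous prefix is a
switch).

The relaxation time comes from fitting C(t) = exp(−t/τ) to the
normalised fluctuation autocorrelation of the state series (computed via
FFT), over lags from 1 until C first drops below 0.05 or 10% of the
series length, whichever is smaller. The one-parameter fit is performed
in *linear* space, initialised from the log-linear slope: near the 0.05
floor the statistical noise on C is comparable to C itself, so least
squares on log C is dominated by the ill-determined tail (observed
errors up to ~20% on telegraph series of 10⁶ steps), whereas the
linear-space fit weights the well-determined early decay and recovers
1/(k_on+k_off) to a few percent under the same conditions. Windows too
short to fit, or non-decaying autocorrelations (e.g. strictly periodic
state series), are rejected and flagged through `fit_quality = inf`
rather than raising.

## Ligand binding and residence kinetics

N<sub>ligand</sub>(i) is the mean over frames of the number of distinct
ligand molecules with any heavy atom within 0.45 nm of residue *i*.
Ligand-mediated contacts P<sub>i,s,j</sub> use a 0.6 nm cutoff on both
legs and require the *same* ligand molecule; pairs in direct contact are
not excluded — direct versus mediated attribution is done downstream by
comparing against the plain contact map.

Binding events are tracked per (ligand, residue) pair independently — a
ligand may be bound to several residues at once. An event begins when
the ligand enters r<sub>on</sub> of a residue while previously unbound
there and ends at the first frame its distance exceeds r<sub>off</sub>
(τ<sub>residue</sub>) or its distance to *all* residues exceeds
r<sub>off</sub> (τ<sub>protein</sub>, which therefore dominates
τ<sub>residue</sub> event by event). Events still bound at trajectory
end are censored: reported, but excluded from means, so short
trajectories cannot silently bias residence times downward. The exchange
rate is completed dissociation events divided by the analysed time
(frames × spacing), so rate × time is an integer by construction.

Residence estimates assume the output cadence resolves the unbound
intervals: an unbound excursion shorter than the frame spacing is
invisible and merges two events, biasing mean τ upward (~2% when the
mean unbound dwell is 25 frames, growing quickly below ~10). The
synthetic test conditions keep mean unbound dwells at ≥ 40 frames for
this reason; with real trajectories the same consideration governs the
choice of output cadence, and coarse cadences are flagged as a caveat
rather than corrected.

## Chain metrics

*Radius of gyration.* Mass weighting is the default for all-atom inputs
(atom elements are not declared in the bead topology, so a
carbon-dominated uniform mass is used, which reduces to uniform
weighting for single-bead residues); explicit uniform weighting is the
natural choice for synthetic bead chains. Errors are the SEM of four
contiguous block means — the standard estimate for correlated series.

*Radial distribution function.* g(r) between protein Cα atoms and ligand
heavy atoms, minimum-image distances, normalised per frame by pair
count, shell volume and the instantaneous box volume (NPT-compatible),
so an uncorrelated uniform system gives g ≈ 1. r<sub>max</sub> must not
exceed half the smallest box extent.

*Flory exponent.* Root-mean-square Cα–Cα distances R(s) per sequence
separation s are fitted to R(s) = b·s<sup>ν</sup> with the prefactor
fixed at b = 0.55 nm, i.e. a one-parameter least-squares fit of
log(R/b) = ν·log s. The default fit range starts at s = 5 to skip
local-stiffness separations and runs to the chain end; both the range
and the Cα selection are configuration-exposed because reasonable
alternatives exist. Noiseless power laws invert to machine precision and
ideal Gaussian chains (where R(s) = b√s exactly in expectation) give
ν = 0.50.

*Secondary structure.* The package aggregates per-frame assignment codes
(it does not implement the assignment algorithm): the conventional
3-state reduction maps H, G, I → helix; E, B → sheet; everything else →
coil. The grouping is recorded in output headers; fractions sum to 1
per residue. Unknown codes without a grouping entry are an error, not
silently coil.

## ThT kinetics

The replicate-mean trace is fitted to
F(t) = F₀ + (F<sub>max</sub> − F₀)/(1 + exp[−k(t − t<sub>1/2</sub>)])
by bounded nonlinear least squares. Initialisation is deterministic:
F₀ = min, F<sub>max</sub> = max, t<sub>1/2</sub> from the half-rise
crossing, k = 4/(t₉₀ − t₁₀). Bounds keep k > 0 and t<sub>1/2</sub>
within the observed range ± 50%; a fit with F<sub>max</sub> < F₀ is
flagged `poor_fit` rather than raised. The lag time is
t<sub>1/2</sub> − 2/k, the tangent-intersection identity, and holds
exactly for every successful fit (it is computed, never re-fitted).

Traces whose total rise (mean of the last three points minus mean of the
first three) does not exceed 5× the baseline noise SD (SD of the
linearly detrended first tenth of the trace) are flagged
`no_aggregation` and not fitted — the behaviour expected of
highest-ligand conditions that abolish aggregation.

Uncertainties come from residual resampling around the fitted curve with
a fixed seed (replicate-level case resampling is a switch); 2.5/97.5
percentiles of each parameter and of the propagated lag form the 95%
intervals. On simulated curves with 2% Gaussian noise the intervals
cover the true k and t<sub>1/2</sub> at close to nominal rate.

## Synthetic generators

The generators target the statistical structure the analyses assume, not
force-field thermodynamics:

- **Bead chains.** One bead (= one heavy atom = Cα) per residue, fresh
  random walk per frame with a 0.38 nm virtual bond. Programmed contact
  pairs draw an independent Bernoulli state per frame with occupancy
  a + b·ratio and are realised geometrically at 0.40 nm (formed) or
  0.80 nm (broken); programmed pairs must use disjoint residues so the
  realisations cannot interfere. The box is auto-sized to at least twice
  the chain extent, so generated ensembles pass the 0.3 nm
  periodic-image QC by construction.
- **Ligands.** Continuous-time telegraph processes with the specified
  on/off rates, sampled at the frame spacing; bound frames place the
  ligand bead 0.40 nm from its site residue, unbound frames uniformly in
  the box but ≥ 0.7 nm from every bead (so an unbound frame is
  unambiguously beyond r<sub>off</sub>).
- **Fibril-like structures.** A designed contact set is realised by
  gradient descent from an extended chain on a soft potential (bonds at
  0.38 nm, designed pairs pulled to 0.40 nm with weight 10, all other
  |i−j| ≥ 4 pairs repelled below a 0.60 nm buffer with weight 4 — the
  buffer keeps residual penalty violations on the correct side of the
  0.45 nm cutoff). The result is verified against the design; failures
  retry with fresh jitter and finally raise, naming the design. Block
  overlaps between designed sets define a known ground-truth clustering.
- **ThT curves.** Exact logistic curves at the plate cadence (7 min)
  plus seeded Gaussian noise per replicate.

Every generator is a pure function of (spec, ratio): a fixed seed
reproduces identical bytes (per-purpose substreams keep partial
regeneration stable; string-tagged substreams use CRC32, not Python's
randomised `hash`).

What passing tests on these generators do *not* show: real ensembles have
correlated frames, excluded volume, multi-atom side chains and
concentration-dependent ligand crowding; the generators validate the
estimators' statistical correctness, not the physics of any particular
system.

## Problem sizes used in the checks

The automated checks run at desk scale: 50 random ensembles up to 20
residues × 100 frames for exact oracle equivalence; 2000 frames per
ratio for slope recovery (errors bounded by 3 binomial SE); 1.8×10⁵
frames (≥ 1000 events) for residence times; 5×10⁵-step telegraph series
for relaxation times; 10⁴ Gaussian chains for the Flory exponent; 10⁶
pair samples per RDF bin; 200 simulated plates × 200 bootstrap
replicates for CI coverage. These sizes make the statistical tolerances
(10% on kinetic means, ±0.02 on ν, 5% on g(r)) comfortable without
being excessive.

## Known limitations

- Analyses are strictly intrachain/monomeric; no inter-chain contacts.
- No trajectory alignment or PBC re-wrapping beyond minimum-image
  distances (all observables are rotation/translation invariant).
- Fibril-to-construct residue mapping is by explicit offset only.
- No binding free energies, and no mechanistic
  (nucleation–elongation) aggregation models — the logistic form only.
- XTC/DCD atom order is assumed to follow sorted topology atom ids;
  mismatched orders must be expressed in the topology sidecar.
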
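# Methods

## The model

The adult muscle-type acetylcholine receptor switches spontaneously between
a closed-channel/low-affinity conformation (C_L) and an
open-channel/high-affinity conformation (O_H). With two approximately
equivalent and independent neurotransmitter sites, microscopic reversibility
constrains the gating equilibrium constants:

    L2 / L0 = (K_H / K_L)^2,    ΔG = −RT ln K,    P_O = L / (1 + L)

`holdscan.thermo` implements this cycle exactly. R is fixed at
1.9872×10⁻³ kcal/(mol·K) and 0 °C = 273.15 K, so RT at 23 °C evaluates to
0.5885 and prints as 0.59 kcal/mol. All energies are kcal/mol throughout;
probabilities and energies are rounded only at the reporting layer (two
decimals by default), never internally. Agonist efficiency is
η = 1 − ΔG_L/ΔG_H; per site, efficacy is ΔG_H − ΔG_L.

The trajectory side of the package identifies the low- and high-affinity
conformations of the site in MD data. Frames are Cα-superposed (Kabsch, via
scipy's SVD solver; proper rotations only; collinear point sets rejected),
the 3N×3N positional covariance is diagonalized, and the PC-1/PC-2
projection histogram is Boltzmann-inverted into a free-energy landscape
whose basins — labeled m1/m2/m3 by temporal order of first occupancy — are
the candidate states. Within each basin, ligand orientations are clustered
under a ≤1.0 Å site-superposed heavy-atom RMSD rule and the top three
clusters define the frames whose energies fingerprint the state.

## Parameter defaults

| parameter | default | units | rationale |
|---|---|---|---|
| RT (thermo) | 0.59 | kcal/mol | 23 °C, the electrophysiology temperature |
| kT (landscape) | 0.59 | kcal/mol | same; 300 K would give 0.596 (<1% difference); configurable |
| landscape bins | 50×50 | — | resolves well-separated basins at a few hundred frames |
| count smoothing σ | 2 | bins | see "numerical choices" below |
| basin depth cut | 2.0 | kcal/mol | minima higher than this are not wells |
| merge prominence | 0.5 | kcal/mol | a minimum less than this below its lowest saddle is histogram noise |
| basin min. occupancy | 2% | frames | isolated outlier bins are not metastable |
| well-bottom window | 0.5 | kcal/mol | "bottom of the well" frames for clustering |
| pose RMSD threshold | 1.0 | Å | the shared-orientation rule |
| top clusters kept | 3 | — | frames outside are disregarded |
| site selection | Cα within 12 Å of the ligand head | — | binding energy is set locally (~12 Å) |
| H-bond criterion | D–A ≤ 3.5 Å, D–H…A ≥ 120° | Å, ° | conventional; angle used only when hydrogens exist |
| pocket-water cutoff | 8 | Å | from the aromatic-box centroid |
| pocket grid | radius 10, spacing 0.5 | Å | inclusion-sphere convention |
| LJ/Coulomb scorer | ε(r)=4r, cutoff 12 Å, k=332.0637 | — | surrogate; see limitations |
| CompositeScore weight | 5 | — | comp = pose − 5·pers; lower = more stable |
| cis / trans bands | <60° / >120° | ° | pivot-angle classification |

Residue identities (the aromatic box, loop tips, salt-bridge partners) are
configuration entries, never hard-coded, so any numbering scheme works.

## The synthetic generator

`holdscan.synth` emulates the statistical structure the analysis assumes,
not protein physics. A stylized two-domain toy — 40 fixed "core" Cα sites,
10 "loop" atoms that translate 0/2/4 Å along a fixed vector per state, a
6-atom ligand whose tail pivots 0°/75°/150° about a fixed head atom, and 16
single-oxygen waters of which 12/8/4 sit inside the pocket per state — is
propagated through a 150/60/90-frame m1→m2→m3 dwell schedule with isotropic
0.3 Å Gaussian jitter and 20 ps frame spacing. Interaction energies are
Gaussian per frame with state-dependent means (−20/−24/−30 kcal/mol,
SD 3.0). A single seeded RNG stream makes every run byte-reproducible.

What passing tests on this generator show: the pipeline recovers planted
basins, temporal labels, pose classes, descriptor schedules and energy means
under realistic noise. What they do not show: performance on real
trajectories with anharmonic basins, overlapping states, slow drift,
correlated water motion, or ambiguous intermediates. The generator's states
are isotropic Gaussian clouds — deliberately the easy case the published
defaults are calibrated to resolve.

The four-agonist experimental table fixture (ACh, CCh, Ebt, Ebx) encodes the
measured efficiencies 0.50/0.52/0.42/0.46 exactly through its ΔG_L/ΔG_H
ratios; the absolute ΔG_H magnitudes in that fixture are package choices,
not measured values.

## Numerical choices

* **Superposition reference.** The "average coordinates" reference is
  circular (the mean depends on the fit); we iterate fit-to-mean →
  recompute-mean twice, which converges to well below coordinate noise.
* **Eigenvector signs** are fixed by orienting each mode so its
  largest-magnitude component is positive; overlaps and landscapes are
  sign-free, projections become deterministic.
* **PCA is per run**; replicate agreement is quantified by the k×k matrix
  of absolute inner products of the top modes (`subspace_overlap`).
* **Landscape smoothing and basin merging.** Local minima are found on a
  surface built from Gaussian-smoothed *counts* (smoothing G directly would
  bleed NaN from empty bins). At the default 50×50 binning with a few
  hundred frames the raw histogram is sparse, and σ=1 bin leaves spurious
  minima; σ=2 bins resolves the planted three-state system in 50/50 seeded
  replicates with ≥97.7% frame-assignment accuracy, so σ=2 is the default.
  The "keep a minimum only if it is ≥0.5 kcal/mol below its lowest saddle"
  rule is implemented as a persistence watershed: shallow minima are merged
  into their deeper neighbor (not discarded), so their frames stay
  assigned. Basins holding <2% of frames are dropped as outliers. A basin
  whose minimum lies in the upper half of the depth window is flagged
  `shallow` (the weakly-occupied-intermediate case).
* **Pose clustering** is leader clustering in frame order with one
  medoid-refinement/reassignment pass; all ties resolve to the earlier
  frame, making partitions byte-deterministic. The ≤1 Å rule is
  member-to-medoid (complete linkage would be stricter; the choice is
  configurable via the threshold only).
* **Unsigned-angle and distance bias.** The pivot angle and tip
  displacement fold coordinate noise at zero (folded-normal / chi bias,
  ≈σ√(8/π) for a distance). Per-state displacement is therefore also
  offered as the displacement of the state-mean tip position
  (`state_tip_displacement`), which is unbiased; the pivot angle accepts an
  external noise-free reference structure.
* **Pocket volume** counts grid points inside the inclusion sphere farther
  than r_vdw from every *protein* heavy atom — waters and ligand are
  stripped first, since the pocket is a property of the protein. No
  flood-fill/contiguity pruning is applied; consequences: occlusion is
  monotone (adding an atom never grows the volume) and grid refinement
  converges (<1% on halving the spacing), which is the tested surface.
* **Degenerate inputs** are rejected with messages: zero-variance
  projections, collinear superposition targets, empty frame sets, missing
  force-field parameters (named per atom), non-physical temperatures.

## Design choices on open ground

* The landscape temperature: the cycle algebra uses the experimental 23 °C
  (RT=0.59); simulation analyses conventionally use 300 K. The difference
  is under 1% and the parameter is exposed; 0.59 is the single default so
  that thermodynamic and landscape energies share a scale.
* Unliganded P_O from ΔG0=+8.3 and RT=0.59 evaluates to 7.8×10⁻⁷ (a less
  rounded ΔG0 would give 7.4×10⁻⁷); the package computes, it does not
  reconcile rounding.
* The energy scorer is a surrogate: pairwise Lennard-Jones plus Coulomb
  with a distance-dependent dielectric ε(r)=4r and a 12 Å cutoff. It is
  *not* a Poisson–Boltzmann or generalized-Born model and is never
  presented as one. The pipeline's claims rest on the ratio η, which is
  invariant to any uniform scale error in the state energies — this
  cancellation is a tested property, and the acceptance script plants a
  deliberate 1.45× overestimation to exercise it end to end.
* TΔS defaults to 0 (no normal-mode analysis); the StateEnergy record
  carries the term so supplied tables can populate it.

## Problem sizes

Tests and the acceptance script run the synthetic system at 300 frames and
~70 atoms, with 50 (tests) / 25 (script) seeded replicates for the
state-recovery rates and all well-bottom frames per basin for the
efficiency chain. These sizes put multinomial and SEM sampling bounds well
inside the asserted tolerances while keeping a full run in tens of seconds.

## Known limitations

* No kinetics: no rates, committors, Markov-state estimation, or
  reweighting; basins are occupancy objects only.
* The surrogate scorer has no solvation, polarization, or entropy terms;
  absolute ΔG values are fingerprints, not affinity predictions.
* Only multi-model PDB input is supported (no binary trajectory formats,
  no mmCIF); element inference from atom names covers organic elements.
* The pivot angle is unsigned — clockwise and counterclockwise flips are
  indistinguishable (handedness would need a reference plane convention).
* The landscape defaults are calibrated for well-separated basins; heavily
  overlapping states will merge under the prominence rule.
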
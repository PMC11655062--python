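# holdscan

Conformational-state analysis of a nicotinic acetylcholine receptor (AChR)
neurotransmitter site from molecular-dynamics trajectories.

Agonists activate the muscle-type AChR by binding weakly to the resting,
low-affinity conformation of the orthosteric site (free energy ΔG_L) and
strongly to the activated, high-affinity conformation (ΔG_H). The local
L→H rearrangement ("hold") is the event that starts the global gating
isomerization. `holdscan` implements the trajectory-analysis pipeline that
identifies the metastable conformations of the site visited during this
transition and fingerprints them energetically:

1. **Superposition + PCA** — Cα least-squares fitting removes rigid-body
   motion; the 3N×3N positional covariance matrix
   C_ij = ⟨(X_i−⟨X_i⟩)(X_j−⟨X_j⟩)⟩ is diagonalized and frames are projected
   onto PC-1/PC-2.
2. **Free-energy landscape** — the 2D projection histogram is
   Boltzmann-inverted, G_i = −kT ln(N_i/N_max), and its minima are grown
   into basins (a prominence-filtered watershed). Basins are labeled
   m1 / m2 / m3 by the temporal order the trajectory visits them
   (m1 = low-affinity end state, m2 = intermediate, m3 = high-affinity).
3. **Pose clustering** — within each basin, ligand orientations are
   clustered under the ≤1.0 Å site-superposed heavy-atom RMSD rule; the top
   three clusters supply the frames used for energy fingerprinting.
4. **Energy fingerprints and efficiency** — per-state interaction energies
   (surrogate Lennard-Jones + Coulomb scorer with ε(r)=4r, or a supplied
   per-frame table) give ΔG(m1) and ΔG(m3), whence the agonist efficiency

       η = 1 − ΔG_L/ΔG_H ≈ 1 − ΔG(m1)/ΔG(m3),

   a ratio that cancels any uniform scale error in the computed energies.
5. **Geometry and pocket descriptors** — agonist pivot ("flip") angle about
   its cationic head group, loop-C tip displacement ("flop"), residue-pair
   distances, pocket hydration and grid-based pocket volume ("fix").
6. **Gating thermodynamics** — the allosteric cycle algebra: ΔG = −RT ln K,
   microscopic reversibility L₂/L₀ = (K_H/K_L)², open probability
   P_O = L/(1+L).

A synthetic-trajectory generator (`holdscan.synth`) produces toy systems
with full ground truth — three metastable basins visited m1→m2→m3, a staged
cis→trans ligand pivot (0°/75°/150°), loop displacement (0/2/4 Å),
state-dependent pocket hydration (12/8/4 waters) and state-dependent
interaction energies — so every stage is testable against planted values.

## Worked example

```python
>>> import json, holdscan as hs
>>> # gating thermodynamics of acetylcholine at the adult receptor
>>> rt = hs.rt_at_temperature(23.0)          # 0.5885 kcal/mol
>>> ach = hs.AgonistEnergetics("ACh", dG_L=-5.1, dG_H=-10.2)
>>> coupling = hs.coupling_energy(ach, n_sites=2)
>>> net = hs.net_gating_energy(8.3, coupling)
>>> print(f"eta={ach.eta:.2f} coupling={coupling:.1f} "
...       f"net={net:.1f} P_O={hs.popen(net, 0.59):.2f}")
eta=0.50 coupling=-10.2 net=-1.9 P_O=0.96
```

Two bound ACh molecules deliver −10.2 kcal/mol of L→H binding free energy,
which overcomes the +8.3 kcal/mol unliganded gating penalty to give a net
−1.9 kcal/mol and an open probability of 0.96 — a channel switched from
essentially silent to essentially always open.

End-to-end on a synthetic trajectory:

```python
>>> import numpy as np
>>> traj, truth, schedule = hs.generate_system(hs.SyntheticSpec(seed=7))
>>> model = hs.fit_pca(traj, "name CA")
>>> proj = hs.project(traj, model, k=2)
>>> fel = hs.build_fel(proj)                       # kT = 0.59 kcal/mol
>>> basins = hs.find_minima(fel)
>>> idx = hs.assign_frames(proj, fel, basins)
>>> basins = hs.label_basins_temporal(basins, traj.times)
>>> labels = np.array([basins[i].label if i >= 0 else None for i in idx], dtype=object)
>>> sorted((b.label, round(b.occupancy, 2)) for b in basins)
[('m1', 0.5), ('m2', 0.19), ('m3', 0.29)]
>>> round(float((labels == truth).mean()), 3)
0.977
```

The same stages are exposed on the command line
(`holdscan simulate|pca|fel|clusters|geometry|pocket|energy|thermo|compare|run-all`):

```sh
holdscan run-all --seed 7 --out results/
holdscan thermo --dgl -5.1 --dgh -10.2 --dg0 8.3
```

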
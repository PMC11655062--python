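"""Binding-energy fingerprinting of states and pose-stability scoring.

The per-state binding energies here are *fingerprints for identifying
states*, not quantitative affinity predictions.  The interaction scorer is a
classical pairwise surrogate — Lennard-Jones plus Coulomb with a
distance-dependent dielectric eps(r) = 4r — evaluated over ligand-receptor
pairs within a cutoff.  Per-frame energies may equally be supplied as a CSV
(``frame,energy_kcal``), which decouples the fingerprinting bookkeeping from
any particular scorer.

What carries the physics is the ratio: agonist efficiency

    eta = 1 - dG(m1) / dG(m3)

cancels any uniform scale error in the state energies, which is why
approximate energies can reproduce experimentally exact efficiencies.

Pose stability (metadynamics-style scoring layer): PoseScore is the mean
ligand RMSD drift from the segment start, PersScore the persistence of the
initial ligand-receptor contacts over the final stretch of the segment, and
CompositeScore = PoseScore - 5 * PersScore (lower = more stable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .poses import ligand_rmsd
from .traj import Topology, Trajectory

__all__ = [
    "COULOMB_K",
    "DEFAULT_LJ_TABLE",
    "EnergyParams",
    "StateEnergy",
    "PoseStability",
    "interaction_energy",
    "state_energy",
    "binding_dg",
    "efficiency_from_states",
    "compare_to_experiment",
    "pose_scores",
    "read_energy_csv",
]

#: Coulomb constant in kcal*A/(mol*e^2).
COULOMB_K = 332.0637

#: Per-element Lennard-Jones well depth (kcal/mol) and zero-crossing radius
#: sigma (A); generic organic-element values for the surrogate scorer.
DEFAULT_LJ_TABLE = {
    "C": (0.10, 3.40),
    "N": (0.17, 3.25),
    "O": (0.21, 2.96),
    "S": (0.25, 3.56),
    "H": (0.015, 2.50),
    "P": (0.20, 3.74),
}


@dataclass
class EnergyParams:
    """Parameters of the surrogate pairwise scorer."""

    charges: np.ndarray                      # e, one per atom
    lj_table: dict = field(default_factory=lambda: dict(DEFAULT_LJ_TABLE))
    cutoff: float = 12.0                     # A
    coulomb_k: float = COULOMB_K

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float)
        for el, (eps, sigma) in self.lj_table.items():
            if eps < 0 or sigma <= 0:
                raise ValueError(f"invalid LJ parameters for element {el!r}")
        sigma_max = max(s for _, s in self.lj_table.values())
        if self.cutoff <= sigma_max:
            raise ValueError("cutoff must exceed the largest LJ sigma")


@dataclass
class StateEnergy:
    """Binding-energy fingerprint of one basin."""

    label: str
    dH: float                 # mean interaction enthalpy surrogate, kcal/mol
    TdS: float = 0.0          # entropy term, kcal/mol (0 unless supplied)
    sd: float = 0.0
    sem: float = 0.0
    n_frames: int = 1

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("a state energy needs at least one frame")
        if self.sem < 0:
            raise ValueError("SEM cannot be negative")

    @property
    def dG(self) -> float:
        return self.dH - self.TdS


@dataclass
class PoseStability:
    pose_score: float     # A, mean ligand RMSD drift
    pers_score: float     # fraction of initial contacts persisting
    comp_score: float

    def __post_init__(self) -> None:
        if self.pose_score < 0:
            raise ValueError("PoseScore cannot be negative")
        if not 0.0 <= self.pers_score <= 1.0:
            raise ValueError("PersScore must lie in [0, 1]")


def interaction_energy(coords: np.ndarray, top: Topology, ligand_idx,
                       receptor_idx, params: EnergyParams) -> float:
    """Pairwise ligand-receptor interaction energy (kcal/mol) of one frame.

    Sum over cross pairs within the cutoff of LJ(eps, sigma) with
    Lorentz-Berthelot combination plus Coulomb under eps(r) = 4r, i.e.
    ``k q_i q_j / (4 r^2)``.  Symmetric under swapping the two selections.
    """
    lig = np.asarray(ligand_idx)
    rec = np.asarray(receptor_idx)
    for group in (lig, rec):
        for a in group:
            el = top.element[a]
            if el not in params.lj_table:
                raise ValueError(
                    f"no LJ parameters for atom serial {top.serial[a]} "
                    f"({top.name[a]}, element {el!r})"
                )
            if not np.isfinite(params.charges[a]):
                raise ValueError(
                    f"missing charge for atom serial {top.serial[a]} ({top.name[a]})"
                )
    eps_arr = np.array([params.lj_table[el][0] for el in top.element])
    sig_arr = np.array([params.lj_table[el][1] for el in top.element])

    diff = coords[lig][:, None, :] - coords[rec][None, :, :]
    r = np.sqrt((diff**2).sum(axis=2))
    within = (r <= params.cutoff) & (r > 0)
    if not np.any(within):
        return 0.0
    eps_ij = np.sqrt(np.outer(eps_arr[lig], eps_arr[rec]))[within]
    sig_ij = (0.5 * (sig_arr[lig][:, None] + sig_arr[rec][None, :]))[within]
    qq = np.outer(params.charges[lig], params.charges[rec])[within]
    rr = r[within]
    sr6 = (sig_ij / rr) ** 6
    e_lj = 4.0 * eps_ij * (sr6**2 - sr6)
    e_coul = params.coulomb_k * qq / (4.0 * rr**2)
    return float(e_lj.sum() + e_coul.sum())


def state_energy(label: str, energies: np.ndarray, frames=None,
                 TdS: float = 0.0) -> StateEnergy:
    """Mean/SD/SEM of per-frame energies over the accepted frames only."""
    energies = np.asarray(energies, dtype=float)
    if frames is not None:
        energies = energies[np.asarray(frames, dtype=int)]
    if energies.size == 0:
        raise ValueError(f"state {label!r} has no accepted frames")
    n = energies.size
    sd = float(energies.std(ddof=1)) if n > 1 else 0.0
    return StateEnergy(
        label=label,
        dH=float(energies.mean()),
        TdS=TdS,
        sd=sd,
        sem=sd / np.sqrt(n),
        n_frames=n,
    )


def binding_dg(complex_E: float, protein_E: float, ligand_E: float) -> float:
    """dG_bind = dG_complex - dG_protein - dG_ligand."""
    return complex_E - protein_E - ligand_E


def efficiency_from_states(dG_m1: float, dG_m3: float) -> float:
    """Efficiency from state energies, with m1 as L and m3 as H.

    eta = 1 - dG(m1)/dG(m3); invariant under uniform scaling of both.
    """
    if dG_m3 == 0:
        raise ValueError("dG(m3) must be nonzero")
    return 1.0 - dG_m1 / dG_m3


def compare_to_experiment(state_energies: dict, experimental) -> pd.DataFrame:
    """Tabulate computed vs experimental energetics per agonist.

    ``state_energies`` maps agonist id -> (dG_m1, dG_m3) in kcal/mol;
    ``experimental`` is a list of :class:`holdscan.thermo.AgonistEnergetics`.
    Reports per-agonist dG ratios, % overestimation, and the efficiency gap.
    """
    by_id = {e.agonist_id: e for e in experimental}
    rows = []
    for agonist, (dg_m1, dg_m3) in state_energies.items():
        if agonist not in by_id:
            raise KeyError(f"agonist {agonist!r} missing from the experimental table")
        exp = by_id[agonist]
        eta_calc = efficiency_from_states(dg_m1, dg_m3)
        rows.append({
            "agonist": agonist,
            "dG_m1": dg_m1,
            "dG_L_exp": exp.dG_L,
            "dG_m3": dg_m3,
            "dG_H_exp": exp.dG_H,
            "ratio_m1": dg_m1 / exp.dG_L,
            "ratio_m3": dg_m3 / exp.dG_H,
            "pct_over_m1": 100.0 * (dg_m1 / exp.dG_L - 1.0),
            "pct_over_m3": 100.0 * (dg_m3 / exp.dG_H - 1.0),
            "eta_calc": eta_calc,
            "eta_exp": exp.eta,
            "eta_diff": eta_calc - exp.eta,
        })
    return pd.DataFrame(rows)


def pose_scores(traj: Trajectory, frames, ligand_sel, site_sel, contacts,
                contact_cutoff: float = 4.0, comp_weight: float = 5.0,
                tail_fraction: float = 0.2) -> PoseStability:
    """Pose-stability scores over a trajectory segment.

    PoseScore: mean ligand RMSD (site-superposed) of every segment frame
    versus the segment start.  PersScore: over the final ``tail_fraction`` of
    the segment, the mean fraction of the listed contacts — (atom_i, atom_j)
    index pairs, "present" when within ``contact_cutoff`` — that were present
    at the segment start and still are.  CompositeScore = PoseScore -
    ``comp_weight`` * PersScore; lower means a more stable pose.
    """
    frames = np.asarray(frames, dtype=int)
    if frames.size < 2:
        raise ValueError("pose scoring needs a segment of at least 2 frames")
    lig = traj.select(ligand_sel) if isinstance(ligand_sel, str) else np.asarray(ligand_sel)
    site = traj.select(site_sel) if isinstance(site_sel, str) else np.asarray(site_sel)
    start = frames[0]
    rmsds = np.array([
        ligand_rmsd(traj.coords[start], traj.coords[f], lig, site) for f in frames
    ])
    pose = float(rmsds.mean())

    contacts = [(int(i), int(j)) for i, j in contacts]

    def present(frame):
        c = traj.coords[frame]
        return np.array([
            np.linalg.norm(c[i] - c[j]) <= contact_cutoff for i, j in contacts
        ])

    initial = present(start)
    if not initial.any():
        pers = 0.0
    else:
        n_tail = max(1, int(np.ceil(tail_fraction * frames.size)))
        tail_frames = frames[-n_tail:]
        fracs = [
            (present(f) & initial).sum() / initial.sum() for f in tail_frames
        ]
        pers = float(np.mean(fracs))
    return PoseStability(pose, pers, pose - comp_weight * pers)


def read_energy_csv(path: str | Path) -> pd.DataFrame:
    """Read a per-frame energy table with columns ``frame,energy_kcal``."""
    df = pd.read_csv(path)
    missing = {"frame", "energy_kcal"} - set(df.columns)
    if missing:
        raise ValueError(f"energy CSV missing columns: {sorted(missing)}")
    return df
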
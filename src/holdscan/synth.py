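"""Synthetic trajectories with the statistical structure the analysis assumes.

The generator emulates, with full ground truth, the features the pipeline is
built to detect at a neurotransmitter site:

* three metastable conformations visited in temporal order m1 -> m2 -> m3,
  realized as staged displacements of a "loop" atom group along a fixed
  vector (default 0 / 2 / 4 A) on top of isotropic thermal jitter;
* a ligand whose cationic head atom stays fixed in the pocket while the tail
  pivots about it per state (default 0 / 75 / 150 degrees — the cis ->
  intermediate -> trans flip);
* state-dependent pocket hydration (default 12 / 8 / 4 waters inside the
  pocket — de-wetting), with the remaining waters parked in bulk;
* state-dependent ligand-receptor interaction energies (Gaussian per frame).

The geometry is a stylized two-domain toy (core + loop + ligand + waters),
not a protein model; but atoms carry ordinary names/residues/chains so the
same selection expressions used on real structures drive every test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .thermo import AgonistEnergetics
from .traj import VDW_RADII, Topology, Trajectory

__all__ = [
    "STATE_NAMES",
    "SyntheticSpec",
    "generate_system",
    "generate_apo_reference",
    "generate_energy_table",
    "generate_experimental_table",
]

STATE_NAMES = ("m1", "m2", "m3")

#: Fixed direction of the staged loop displacement ("flop": downward).
_LOOP_SHIFT_DIR = np.array([0.0, 0.0, -1.0])
#: Axis of the ligand-tail pivot about the fixed head group.
_FLIP_AXIS = np.array([0.0, 0.0, 1.0])

_POCKET_RADIUS = 6.0      # waters "in the pocket" are placed within this (A)
_BULK_RADIUS = 28.0       # bulk waters parked on a shell at this distance (A)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic system; defaults are the study conditions.

    ``dwell_frames`` (150/60/90 of 300 total) gives basin occupancies
    0.5/0.2/0.3 — two prominent end states and a sparser intermediate, as on
    real landscapes.  ``noise_sigma`` of 0.3 A approximates Calpha thermal
    jitter in an equilibrated run.  Frame spacing is 20 ps.
    """

    seed: int = 0
    n_core_atoms: int = 40
    n_loop_atoms: int = 10
    n_ligand_atoms: int = 6
    n_waters: int = 16
    dwell_frames: tuple = (150, 60, 90)
    noise_sigma: float = 0.3
    flip_angles: tuple = (0.0, 75.0, 150.0)       # degrees per state
    loop_shift: tuple = (0.0, 2.0, 4.0)           # A per state
    waters_in_pocket: tuple = (12, 8, 4)          # count per state
    energy_mean: tuple = (-20.0, -24.0, -30.0)    # kcal/mol per state
    energy_sd: float = 3.0
    frame_dt_ps: float = 20.0

    def __post_init__(self) -> None:
        for name in ("n_core_atoms", "n_loop_atoms", "n_ligand_atoms", "n_waters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        for name in ("dwell_frames", "flip_angles", "loop_shift",
                     "waters_in_pocket", "energy_mean"):
            if len(getattr(self, name)) != 3:
                raise ValueError(f"{name} must have one entry per state (3)")
        if any(d < 1 for d in self.dwell_frames):
            raise ValueError("each state must dwell for at least one frame")
        if max(self.waters_in_pocket) > self.n_waters:
            raise ValueError("waters_in_pocket cannot exceed n_waters")

    @property
    def n_frames(self) -> int:
        return int(sum(self.dwell_frames))


def _rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()


def _base_geometry(spec: SyntheticSpec, rng: np.random.Generator):
    """State-independent site positions of every atom group."""
    # Aromatic-box stand-in: the first three core atoms ring the pocket center
    # at fixed positions so "resid 1 2 3" is a deterministic pocket-center
    # selection.
    box = 4.0 * np.array([
        [1.0, 0.0, 0.0],
        [-0.5, np.sqrt(3) / 2, 0.0],
        [-0.5, -np.sqrt(3) / 2, 0.0],
    ])
    n_rest = spec.n_core_atoms - 3
    # Remaining core atoms on a shell 6-14 A out (rejection-free radial draw).
    u = rng.random(n_rest)
    radii = (6.0**3 + u * (14.0**3 - 6.0**3)) ** (1.0 / 3.0)
    vec = rng.normal(size=(n_rest, 3))
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    core = np.vstack([box, radii[:, None] * vec])

    # Loop atoms clustered above the pocket; they carry the staged shift.
    loop = np.array([8.0, 8.0, 6.0]) + rng.normal(scale=1.5, size=(spec.n_loop_atoms, 3))

    # Ligand: cationic head at the pocket center, tail extending +x.
    lig = np.zeros((spec.n_ligand_atoms, 3))
    lig[1:, 0] = 1.4 * np.arange(1, spec.n_ligand_atoms)

    # Water sites: pocket slots inside _POCKET_RADIUS, bulk slots far away.
    u = rng.random(spec.n_waters)
    radii = _POCKET_RADIUS * 0.8 * u ** (1.0 / 3.0)
    vec = rng.normal(size=(spec.n_waters, 3))
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    pocket_sites = radii[:, None] * vec
    vec = rng.normal(size=(spec.n_waters, 3))
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    bulk_sites = _BULK_RADIUS * vec
    return core, loop, lig, pocket_sites, bulk_sites


def _topology(spec: SyntheticSpec) -> Topology:
    n_prot = spec.n_core_atoms + spec.n_loop_atoms
    n = n_prot + spec.n_ligand_atoms + spec.n_waters
    name = np.array(
        ["CA"] * n_prot
        + ["N1"] + [f"C{i}" for i in range(2, spec.n_ligand_atoms + 1)]
        + ["O"] * spec.n_waters, dtype="U5",
    )
    resname = np.array(
        ["ALA"] * spec.n_core_atoms + ["GLY"] * spec.n_loop_atoms
        + ["LIG"] * spec.n_ligand_atoms + ["HOH"] * spec.n_waters, dtype="U5",
    )
    chain = np.array(
        ["A"] * n_prot + ["L"] * spec.n_ligand_atoms + ["W"] * spec.n_waters,
        dtype="U4",
    )
    resid = np.concatenate([
        np.arange(1, n_prot + 1),
        np.full(spec.n_ligand_atoms, 1),
        np.arange(1, spec.n_waters + 1),
    ])
    element = np.array(
        ["C"] * n_prot + ["N"] + ["C"] * (spec.n_ligand_atoms - 1)
        + ["O"] * spec.n_waters, dtype="U2",
    )
    is_water = np.array([False] * (n_prot + spec.n_ligand_atoms) + [True] * spec.n_waters)
    is_ligand = np.array(
        [False] * n_prot + [True] * spec.n_ligand_atoms + [False] * spec.n_waters
    )
    return Topology(
        serial=np.arange(1, n + 1),
        name=name,
        resname=resname,
        chain=chain,
        resid=resid,
        element=element,
        vdw_radius=np.array([VDW_RADII[el] for el in element]),
        charge=np.zeros(n),
        is_water=is_water,
        is_ligand=is_ligand,
    )


def _state_coords(spec: SyntheticSpec, geometry, state: int) -> np.ndarray:
    """Noiseless atom positions of one state."""
    core, loop, lig, pocket_sites, bulk_sites = geometry
    loop_s = loop + spec.loop_shift[state] * _LOOP_SHIFT_DIR
    R = _rotation(_FLIP_AXIS, spec.flip_angles[state])
    lig_s = lig.copy()
    lig_s[1:] = (lig[1:] - lig[0]) @ R.T + lig[0]
    n_in = spec.waters_in_pocket[state]
    waters = np.where(
        (np.arange(spec.n_waters) < n_in)[:, None], pocket_sites, bulk_sites
    )
    return np.vstack([core, loop_s, lig_s, waters])


def generate_system(spec: SyntheticSpec):
    """Build the synthetic trajectory.

    Returns ``(trajectory, labels, schedule)`` where ``labels`` is the
    per-frame ground-truth state name and ``schedule`` records the planted
    per-state values of every descriptor.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    geometry = _base_geometry(spec, rng)
    top = _topology(spec)
    state_xyz = [_state_coords(spec, geometry, s) for s in range(3)]

    labels = np.concatenate([
        np.full(d, STATE_NAMES[s], dtype=object)
        for s, d in enumerate(spec.dwell_frames)
    ])
    coords = np.empty((spec.n_frames, top.n_atoms, 3))
    state_idx = np.concatenate([
        np.full(d, s) for s, d in enumerate(spec.dwell_frames)
    ])
    for f in range(spec.n_frames):
        noise = rng.normal(scale=spec.noise_sigma, size=(top.n_atoms, 3)) \
            if spec.noise_sigma > 0 else 0.0
        coords[f] = state_xyz[state_idx[f]] + noise
    times = np.arange(spec.n_frames) * spec.frame_dt_ps
    traj = Trajectory(top, coords, times)
    schedule = {
        "flip_angles": dict(zip(STATE_NAMES, spec.flip_angles)),
        "loop_shift": dict(zip(STATE_NAMES, spec.loop_shift)),
        "waters_in_pocket": dict(zip(STATE_NAMES, spec.waters_in_pocket)),
        "energy_mean": dict(zip(STATE_NAMES, spec.energy_mean)),
        "dwell_fraction": dict(zip(
            STATE_NAMES, np.asarray(spec.dwell_frames) / spec.n_frames
        )),
    }
    return traj, labels, schedule


def generate_apo_reference(spec: SyntheticSpec) -> Trajectory:
    """Noiseless single-frame reference in the m1 geometry (loop unshifted)."""
    rng = np.random.default_rng(spec.seed)
    geometry = _base_geometry(spec, rng)
    top = _topology(spec)
    return Trajectory(top, _state_coords(spec, geometry, 0)[None, :, :],
                      np.array([0.0]))


def generate_energy_table(spec: SyntheticSpec, labels,
                          seed: int | None = None) -> pd.DataFrame:
    """Per-frame Gaussian interaction energies with state-dependent means."""
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    labels = np.asarray(labels, dtype=object)
    means = dict(zip(STATE_NAMES, spec.energy_mean))
    energies = np.array([
        rng.normal(means[l], spec.energy_sd) if spec.energy_sd > 0 else means[l]
        for l in labels
    ])
    return pd.DataFrame({
        "frame": np.arange(len(labels)),
        "energy_kcal": energies,
        "state": labels,
    })


#: (dG_L, dG_H) fixture magnitudes per agonist, kcal/mol.  The ratios
#: reproduce the experimental efficiencies 0.50 / 0.52 / 0.42 / 0.46; the
#: absolute dG_H magnitudes are fixture choices, not measured values.
_EXPERIMENTAL_FIXTURE = {
    "ACh": (-5.10, -10.20),
    "CCh": (-4.80, -10.00),
    "Ebt": (-6.96, -12.00),
    "Ebx": (-5.94, -11.00),
}


def generate_experimental_table() -> pd.DataFrame:
    """Four-agonist experimental-energetics fixture (``agonist,dG_L,dG_H``)."""
    rows = []
    for agonist, (dg_l, dg_h) in _EXPERIMENTAL_FIXTURE.items():
        rec = AgonistEnergetics(agonist, dg_l, dg_h)  # validates invariants
        rows.append({"agonist": agonist, "dG_L": rec.dG_L, "dG_H": rec.dG_H})
    return pd.DataFrame(rows)
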
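"""Geometric observables of the L->H ("flip-flop-fix") rearrangement.

Descriptors follow the three hallmark events at the neurotransmitter site:

* **flip** — the agonist pivots about its cationic head group (N+), held in
  the aromatic box, from the cis orientation (tail toward the alpha subunit)
  to trans (tail away); measured as the angle between the head->tail vector
  and its reference orientation after binding-site superposition.
* **flop** — staged downward displacement of the loop C tip (Calpha of
  alphaC192) relative to its apo position.
* **fix** — pocket compaction and de-wetting: residue-pair distances
  (e.g. alphaK145-alphaD200), pocket water counts, and the water-mediated
  hydrogen bond between the agonist tail and the loop E backbone
  (deltaN109 carbonyl / deltaL121 amine).

Residue identities are configuration, not code: every function takes
selections, so any numbering scheme works.
"""

from __future__ import annotations

import numpy as np

from .pca import apply_transform, kabsch_superpose
from .traj import Topology, Trajectory

__all__ = [
    "DescriptorSeries",
    "pivot_angle",
    "classify_orientation",
    "loop_displacement",
    "pair_distance",
    "count_pocket_waters",
    "water_mediated_hbond",
    "state_summaries",
]


class DescriptorSeries:
    """A named per-frame series with per-state summaries."""

    def __init__(self, name: str, values: np.ndarray, units: str):
        self.name = name
        self.values = np.asarray(values, dtype=float)
        self.units = units
        self.per_state: dict[str, tuple[float, float]] = {}

    def summarize(self, labels) -> dict[str, tuple[float, float]]:
        """Mean and SD keyed by state label; frames labeled None are skipped."""
        labels = np.asarray(labels, dtype=object)
        if len(labels) != len(self.values):
            raise ValueError("labels length does not match series length")
        out = {}
        for state in sorted({l for l in labels if l is not None}):
            vals = self.values[labels == state]
            out[str(state)] = (float(vals.mean()), float(vals.std()))
        self.per_state = out
        return out


def _single_index(idx, what: str) -> int:
    idx = np.atleast_1d(np.asarray(idx))
    if idx.size != 1:
        raise ValueError(f"{what} selection must resolve to exactly one atom, got {idx.size}")
    return int(idx[0])


def _resolve(traj: Trajectory, sel):
    return traj.select(sel) if isinstance(sel, str) else np.asarray(sel)


def pivot_angle(traj: Trajectory, head_sel, tail_sel, site_sel,
                reference_frame: int = 0,
                reference_traj: Trajectory | None = None) -> DescriptorSeries:
    """Per-frame pivot angle (degrees) of the head->tail vector vs reference.

    Binding-site atoms are superposed onto the reference frame first, so the
    angle reports reorientation of the ligand within the site, not drift of
    the whole complex.  Range [0, 180]; unsigned (no handedness).

    The reference orientation is frame ``reference_frame`` of
    ``reference_traj`` when given (e.g. a noise-free starting structure),
    else of the trajectory itself.
    """
    head = _single_index(_resolve(traj, head_sel), "head")
    tail = _single_index(_resolve(traj, tail_sel), "tail")
    if head == tail:
        raise ValueError("head and tail atoms must differ")
    site = _resolve(traj, site_sel)
    ref = reference_traj if reference_traj is not None else traj
    ref_site = ref.coords[reference_frame, site, :]
    v_ref = ref.coords[reference_frame, tail] - ref.coords[reference_frame, head]
    v_ref = v_ref / np.linalg.norm(v_ref)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        R, t, _ = kabsch_superpose(traj.coords[f, site, :], ref_site)
        pts = apply_transform(traj.coords[f, [head, tail], :], R, t)
        v = pts[1] - pts[0]
        v = v / np.linalg.norm(v)
        out[f] = np.degrees(np.arccos(np.clip(v @ v_ref, -1.0, 1.0)))
    return DescriptorSeries("pivot_angle", out, "degrees")


def classify_orientation(angle: float, cis_max: float = 60.0,
                         trans_min: float = 120.0) -> str:
    """cis / trans / intermediate classification of a pivot angle."""
    if angle < cis_max:
        return "cis"
    if angle > trans_min:
        return "trans"
    return "intermediate"


def loop_displacement(traj: Trajectory, apo: Trajectory, tip_sel, anchor_sel,
                      apo_frame: int = 0) -> DescriptorSeries:
    """Displacement (A) of a loop tip atom relative to its apo position.

    Core (anchor) atoms of each frame are superposed onto the apo reference
    before measuring the Euclidean tip displacement, so rigid motion of the
    whole domain does not register.
    """
    tip = _single_index(_resolve(traj, tip_sel), "tip")
    anchors = _resolve(traj, anchor_sel)
    apo_tip_idx = _single_index(_resolve(apo, tip_sel), "apo tip")
    apo_anchors = _resolve(apo, anchor_sel)
    if len(anchors) != len(apo_anchors):
        raise ValueError("anchor selections differ between trajectory and apo reference")
    apo_anchor_xyz = apo.coords[apo_frame, apo_anchors, :]
    apo_tip_xyz = apo.coords[apo_frame, apo_tip_idx]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        R, t, _ = kabsch_superpose(traj.coords[f, anchors, :], apo_anchor_xyz)
        tip_xyz = apply_transform(traj.coords[f, tip][None, :], R, t)[0]
        out[f] = np.linalg.norm(tip_xyz - apo_tip_xyz)
    return DescriptorSeries("loop_displacement", out, "A")


def state_tip_displacement(traj: Trajectory, apo: Trajectory, tip_sel,
                           anchor_sel, labels, apo_frame: int = 0) -> dict:
    """Per-state loop-tip displacement from the state-mean structure.

    Each frame is anchor-superposed onto the apo reference; the tip positions
    are averaged within each state and the displacement of that mean position
    from the apo tip is reported.  Unlike the per-frame series mean, this is
    unbiased at zero displacement (per-frame distances fold coordinate noise
    into a positive offset).
    """
    tip = _single_index(_resolve(traj, tip_sel), "tip")
    anchors = _resolve(traj, anchor_sel)
    apo_tip_idx = _single_index(_resolve(apo, tip_sel), "apo tip")
    apo_anchors = _resolve(apo, anchor_sel)
    apo_anchor_xyz = apo.coords[apo_frame, apo_anchors, :]
    apo_tip_xyz = apo.coords[apo_frame, apo_tip_idx]
    labels = np.asarray(labels, dtype=object)
    tips = np.empty((traj.n_frames, 3))
    for f in range(traj.n_frames):
        R, t, _ = kabsch_superpose(traj.coords[f, anchors, :], apo_anchor_xyz)
        tips[f] = apply_transform(traj.coords[f, tip][None, :], R, t)[0]
    return {
        str(state): float(np.linalg.norm(tips[labels == state].mean(axis=0) - apo_tip_xyz))
        for state in sorted({l for l in labels if l is not None})
    }


def pair_distance(traj: Trajectory, sel_a, sel_b,
                  mode: str = "atom") -> DescriptorSeries:
    """Per-frame distance (A) between two atom groups.

    Modes: ``atom`` (both selections must be single atoms),
    ``ring-centroid`` (unweighted centroid of each selection; a ring needs
    >= 3 atoms), ``closest-heavy`` (minimum over all cross pairs).
    """
    a = _resolve(traj, sel_a)
    b = _resolve(traj, sel_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("pair_distance selections must be non-empty")
    if mode == "atom":
        ia = _single_index(a, "sel_a")
        ib = _single_index(b, "sel_b")
        out = np.linalg.norm(traj.coords[:, ia] - traj.coords[:, ib], axis=1)
    elif mode == "ring-centroid":
        if max(a.size, b.size) < 3:
            raise ValueError("ring-centroid mode needs a ring selection of >= 3 atoms")
        ca = traj.coords[:, a, :].mean(axis=1)
        cb = traj.coords[:, b, :].mean(axis=1)
        out = np.linalg.norm(ca - cb, axis=1)
    elif mode == "closest-heavy":
        heavy = traj.topology.is_heavy
        ah = a[heavy[a]]
        bh = b[heavy[b]]
        if ah.size == 0 or bh.size == 0:
            raise ValueError("closest-heavy mode found no heavy atoms in a selection")
        diff = traj.coords[:, ah, None, :] - traj.coords[:, None, bh, :]
        out = np.sqrt((diff**2).sum(axis=3)).min(axis=(1, 2))
    else:
        raise ValueError(f"unknown pair_distance mode {mode!r}")
    return DescriptorSeries(f"pair_distance[{mode}]", out, "A")


def count_pocket_waters(traj: Trajectory, center_sel, cutoff: float = 8.0) -> DescriptorSeries:
    """Number of water oxygens within ``cutoff`` A of the pocket center.

    The center is the centroid of ``center_sel`` (typically the aromatic-box
    Calpha atoms), recomputed per frame.
    """
    top = traj.topology
    center_idx = _resolve(traj, center_sel)
    if center_idx.size == 0:
        raise ValueError("pocket center selection is empty")
    wat_o = np.flatnonzero(top.is_water & (top.element == "O"))
    counts = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        center = traj.coords[f, center_idx, :].mean(axis=0)
        if wat_o.size == 0:
            counts[f] = 0
        else:
            d = np.linalg.norm(traj.coords[f, wat_o, :] - center, axis=1)
            counts[f] = int((d <= cutoff).sum())
    return DescriptorSeries("pocket_waters", counts, "count")


def water_mediated_hbond(coords: np.ndarray, top: Topology, ligand_sel,
                         partner_sel, d_max: float = 3.5,
                         angle_min: float = 120.0):
    """Detect a water bridging the ligand tail group and a backbone partner.

    A bridge is present when one water oxygen is simultaneously within
    ``d_max`` (heavy-atom donor-acceptor distance) of at least one ligand
    group atom and one backbone partner atom.  When the water carries
    hydrogens, the O-H...X angle toward each side must also be at least
    ``angle_min`` degrees.  Returns ``(present, water_serial_or_None)``;
    with several candidate waters, the smallest summed distance wins.
    """
    lig = np.asarray(ligand_sel)
    partner = np.asarray(partner_sel)
    wat_o = np.flatnonzero(top.is_water & (top.element == "O"))
    best = None
    best_sum = np.inf
    for o in wat_o:
        d_lig = np.linalg.norm(coords[lig] - coords[o], axis=1).min()
        d_par = np.linalg.norm(coords[partner] - coords[o], axis=1).min()
        if d_lig > d_max or d_par > d_max:
            continue
        hyd = np.flatnonzero(
            top.is_water & (top.element == "H") & (top.resid == top.resid[o])
            & (top.chain == top.chain[o])
        )
        if hyd.size:
            targets = (lig[np.argmin(np.linalg.norm(coords[lig] - coords[o], axis=1))],
                       partner[np.argmin(np.linalg.norm(coords[partner] - coords[o], axis=1))])
            ok = True
            for tgt in targets:
                angles = [_dha_angle(coords[o], coords[h], coords[tgt]) for h in hyd]
                if max(angles) < angle_min:
                    ok = False
                    break
            if not ok:
                continue
        if d_lig + d_par < best_sum:
            best_sum = d_lig + d_par
            best = o
    if best is None:
        return False, None
    return True, int(top.serial[best])


def _dha_angle(donor: np.ndarray, hydrogen: np.ndarray, acceptor: np.ndarray) -> float:
    v1 = donor - hydrogen
    v2 = acceptor - hydrogen
    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def state_summaries(series_list, labels) -> dict[str, dict[str, tuple[float, float]]]:
    """Summaries for several descriptor series under one state labeling."""
    return {s.name: s.summarize(labels) for s in series_list}
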
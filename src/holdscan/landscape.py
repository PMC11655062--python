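"""Free-energy landscape over PC-1/PC-2 and metastable basin identification.

The 2D projection histogram is Boltzmann-inverted,

    G_i = -kT ln(N_i / N_max),

so the most populated bin sits at G = 0 and empty bins are masked (never 0).
Local minima of the (count-smoothed) landscape are grown into basins by
steepest-descent bin assignment; basins are labeled m1/m2/m3 by the temporal
order in which the trajectory visits them, following the observation that
runs start in the low-affinity state (m1), pass an intermediate (m2), and end
high-affinity (m3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "DEFAULT_KT",
    "FreeEnergyLandscape",
    "Basin",
    "build_fel",
    "find_minima",
    "assign_frames",
    "label_basins_temporal",
    "well_bottom_frames",
]

#: kT in kcal/mol; 0.59 corresponds to 23 C (the experimental temperature);
#: 300 K would give 0.596 — the difference is <1% and the value is configurable.
DEFAULT_KT = 0.59

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class FreeEnergyLandscape:
    """Binned 2D free-energy surface over the top two principal components."""

    xedges: np.ndarray
    yedges: np.ndarray
    counts: np.ndarray          # nbins x nbins
    G: np.ndarray               # kcal/mol; NaN on empty bins
    kT: float
    mask: np.ndarray            # True where the bin is empty

    @property
    def nbins(self) -> tuple[int, int]:
        return self.counts.shape

    def bin_of(self, point: np.ndarray) -> tuple[int, int]:
        """Bin indices of a PC-space point (edge bins absorb boundary values)."""
        i = int(np.clip(np.searchsorted(self.xedges, point[0], side="right") - 1,
                        0, self.counts.shape[0] - 1))
        j = int(np.clip(np.searchsorted(self.yedges, point[1], side="right") - 1,
                        0, self.counts.shape[1] - 1))
        return i, j

    def bin_centers(self, i: int, j: int) -> np.ndarray:
        return np.array([
            0.5 * (self.xedges[i] + self.xedges[i + 1]),
            0.5 * (self.yedges[j] + self.yedges[j + 1]),
        ])


@dataclass
class Basin:
    """A metastable basin of the landscape."""

    label: str | None
    minimum: np.ndarray                 # PC-space location of the minimum bin
    min_bin: tuple[int, int]
    g_min: float                        # kcal/mol, relative to the global 0
    depth: float                        # prominence: boundary saddle G - g_min
    member_bins: set = field(default_factory=set)
    frames: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    occupancy: float = 0.0
    positional_variance: float = 0.0    # pose-fluctuation measure in PC space
    shallow: bool = False


def build_fel(proj: np.ndarray, nbins: int = 50, kT: float = DEFAULT_KT,
              range=None) -> FreeEnergyLandscape:
    """Boltzmann-invert the 2D histogram of an F x 2 projection series.

    ``range`` optionally fixes the bin extent as ((x0, x1), (y0, y1));
    by default the bins span the data.
    """
    proj = np.asarray(proj, dtype=float)
    if proj.ndim != 2 or proj.shape[1] != 2:
        raise ValueError(f"projection must be F x 2, got {proj.shape}")
    if kT <= 0:
        raise ValueError(f"kT must be positive, got {kT}")
    if np.any(proj.std(axis=0) == 0):
        raise ValueError("degenerate projection: a component has zero variance")
    if proj.shape[0] < nbins:
        warnings.warn(
            f"only {proj.shape[0]} frames for {nbins} bins: landscape will be sparse",
            stacklevel=2,
        )
    counts, xedges, yedges = np.histogram2d(proj[:, 0], proj[:, 1], bins=nbins,
                                            range=range)
    mask = counts == 0
    G = np.full_like(counts, np.nan)
    nmax = counts.max()
    occupied = ~mask
    G[occupied] = -kT * np.log(counts[occupied] / nmax)
    return FreeEnergyLandscape(xedges, yedges, counts, G, kT, mask)


def _smoothed_g(fel: FreeEnergyLandscape, smooth_sigma: float) -> np.ndarray:
    """Landscape from Gaussian-smoothed counts (avoids smoothing across NaN)."""
    sm = gaussian_filter(fel.counts, sigma=smooth_sigma, mode="constant")
    sm = np.where(sm <= 0, np.nan, sm)
    return -fel.kT * np.log(sm / np.nanmax(sm))


def find_minima(
    fel: FreeEnergyLandscape,
    smooth_sigma: float = 2.0,
    max_depth_cut: float = 2.0,
    min_prominence: float = 0.5,
    min_occupancy: float = 0.02,
) -> list[Basin]:
    """Locate basins of the landscape by prominence-filtered watershed.

    Bins of the smoothed surface are flooded in order of increasing G.  When
    two growing basins meet, the saddle level decides their fate: a basin
    whose minimum lies less than ``min_prominence`` kcal/mol below its lowest
    saddle is merged into its deeper neighbor (this absorbs the spurious
    minima that histogram noise produces on sparse landscapes); deeper basins
    survive as separate metastable states.  Only basins whose minimum G is
    below ``max_depth_cut`` are returned, sorted by depth (lowest G first).
    A surviving basin whose minimum sits in the upper half of the depth
    window (G > max_depth_cut / 2, i.e. weakly occupied in the -kT ln(rho)
    sense) is kept but flagged ``shallow``.  A surviving basin must also
    hold at least ``min_occupancy`` of all frames — isolated outlier bins
    are not metastable states.
    """
    Gs = _smoothed_g(fel, smooth_sigma)
    nx, ny = Gs.shape
    finite = np.isfinite(Gs)

    cells = sorted(
        ((i, j) for i in range(nx) for j in range(ny) if finite[i, j]),
        key=lambda c: (Gs[c], c),
    )
    parent: dict[tuple[int, int], tuple[int, int]] = {}   # union-find over minima
    birth: dict[tuple[int, int], float] = {}              # G at each minimum
    saddle: dict[tuple[int, int], float] = {}             # merge/contact level
    owner: dict[tuple[int, int], tuple[int, int]] = {}    # bin -> minimum root

    def find(m):
        while parent[m] != m:
            parent[m] = parent[parent[m]]
            m = parent[m]
        return m

    for cell in cells:
        i, j = cell
        g = Gs[i, j]
        roots = []
        for di, dj in _NEIGHBORS:
            a, b = i + di, j + dj
            if 0 <= a < nx and 0 <= b < ny and (a, b) in owner:
                r = find(owner[(a, b)])
                if r not in roots:
                    roots.append(r)
        if not roots:
            parent[cell] = cell
            birth[cell] = g
            owner[cell] = cell
            continue
        roots.sort(key=lambda r: (birth[r], r))
        deepest = roots[0]
        owner[cell] = deepest
        for r in roots[1:]:
            # Saddle between r and a deeper basin at level g.
            if g - birth[r] < min_prominence:
                parent[r] = deepest           # merge the shallow one away
            else:
                saddle[r] = min(saddle.get(r, np.inf), g)
    survivors = sorted({find(m) for m in parent}, key=lambda m: (birth[m], m))
    survivors = [m for m in survivors if birth[m] <= max_depth_cut]
    members: dict[tuple[int, int], set] = {m: set() for m in survivors}
    for cell, m in owner.items():
        root = find(m)
        if root in members:
            members[root].add(cell)
    total = fel.counts.sum()
    survivors = [
        m for m in survivors
        if sum(fel.counts[c] for c in members[m]) / total >= min_occupancy
    ]
    if not survivors:
        warnings.warn("no landscape minimum below the depth cut", stacklevel=2)
        return []

    basins = []
    for m in survivors:
        prominence = float(saddle.get(m, np.inf) - birth[m])
        basins.append(
            Basin(
                label=None,
                minimum=fel.bin_centers(*m),
                min_bin=m,
                g_min=float(birth[m]),
                depth=prominence,
                member_bins=members[m],
                shallow=birth[m] > max_depth_cut / 2,
            )
        )
    basins.sort(key=lambda b: b.g_min)
    return basins


def assign_frames(proj: np.ndarray, fel: FreeEnergyLandscape, basins: list[Basin]):
    """Assign each frame to the basin owning its bin (or None).

    Fills each basin's ``frames``, ``occupancy`` and ``positional_variance``
    in place and returns the per-frame array of basin indices (-1 unassigned).
    """
    proj = np.asarray(proj, dtype=float)
    owner = {}
    for b_idx, basin in enumerate(basins):
        for cell in basin.member_bins:
            owner[cell] = b_idx
    labels = np.full(proj.shape[0], -1, dtype=int)
    for f in range(proj.shape[0]):
        cell = fel.bin_of(proj[f])
        if not fel.mask[cell]:
            labels[f] = owner.get(cell, -1)
    for b_idx, basin in enumerate(basins):
        frames = np.flatnonzero(labels == b_idx)
        basin.frames = frames
        basin.occupancy = len(frames) / proj.shape[0]
        if len(frames) > 1:
            basin.positional_variance = float(proj[frames].var(axis=0).sum())
    return labels


def label_basins_temporal(basins: list[Basin], times: np.ndarray) -> list[Basin]:
    """Label basins m1..m3 by the order the trajectory visits them.

    m1 has the earliest median member time and m3 the latest; any basins in
    between are intermediates (a single one is labeled m2).  Ties are broken
    by occupancy (larger first).
    """
    times = np.asarray(times, dtype=float)
    populated = [b for b in basins if len(b.frames) > 0]
    if not populated:
        raise ValueError("no basin has assigned frames; run assign_frames first")
    order = sorted(populated, key=lambda b: (np.median(times[b.frames]), -b.occupancy))
    n = len(order)
    for rank, basin in enumerate(order):
        if rank == 0:
            basin.label = "m1"
        elif rank == n - 1 and n > 1:
            basin.label = "m3"
        elif n == 3 or rank == 1:
            basin.label = "m2" if n <= 3 else f"m2_{rank}"
        else:
            basin.label = f"m2_{rank}"
    return basins


def well_bottom_frames(basin: Basin, fel: FreeEnergyLandscape, proj: np.ndarray,
                       window: float = 0.5) -> np.ndarray:
    """Frames in bins within ``window`` kcal/mol of the basin minimum.

    These "bottom of the well" frames are the inputs to pose clustering and
    binding-energy fingerprinting.
    """
    finite = [cell for cell in basin.member_bins if np.isfinite(fel.G[cell])]
    if not finite:
        return np.array([], dtype=int)
    g_ref = min(fel.G[cell] for cell in finite)
    keep_bins = {cell for cell in finite if fel.G[cell] <= g_ref + window}
    proj = np.asarray(proj, dtype=float)
    return np.array(
        [f for f in basin.frames if fel.bin_of(proj[f]) in keep_bins], dtype=int
    )
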
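"""Allosteric gating thermodynamics of the muscle-type acetylcholine receptor.

The receptor switches spontaneously between a closed-channel/low-affinity
conformation (C_L) and an open-channel/high-affinity conformation (O_H).
Agonists bind weakly to C_L (association constant K_L, binding free energy
dG_L) and strongly to O_H (K_H, dG_H).  Because the two adult neurotransmitter
sites are approximately equivalent and independent, microscopic reversibility
ties the diliganded and unliganded gating equilibrium constants together:

    L2 / L0 = (K_H / K_L) ** n_sites        (n_sites = 2 for adult receptors)

Everything in this module is algebra on that four-state cycle: free energies
from equilibrium constants (dG = -RT ln K), the per-site L->H coupling energy,
the net diliganded gating energy, open probability, and agonist efficiency

    eta = 1 - dG_L / dG_H

which is the fraction of agonist binding free energy converted into receptor
activation.  All energies are kcal/mol; rounding happens only at reporting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "R_KCAL",
    "CELSIUS_OFFSET",
    "AgonistEnergetics",
    "GatingCycle",
    "rt_at_temperature",
    "dg_from_K",
    "K_from_dg",
    "coupling_energy",
    "net_gating_energy",
    "popen",
    "diliganded_constant",
    "efficiency",
    "read_energetics_csv",
]

#: Gas constant in kcal/(mol K).
R_KCAL = 1.9872e-3
#: 0 degrees Celsius in kelvin.
CELSIUS_OFFSET = 273.15


@dataclass(frozen=True)
class AgonistEnergetics:
    """Experimental site energetics of one agonist.

    Parameters
    ----------
    agonist_id:
        Short name, e.g. ``"ACh"``.
    dG_L, dG_H:
        Binding free energies (kcal/mol) to the low- and high-affinity
        conformations of the site.  Both must be negative and the
        high-affinity energy must be the more negative of the two.
    """

    agonist_id: str
    dG_L: float
    dG_H: float
    eta: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.dG_L < 0 and self.dG_H < 0):
            raise ValueError(
                f"{self.agonist_id}: binding free energies must be negative "
                f"(got dG_L={self.dG_L}, dG_H={self.dG_H})"
            )
        if not self.dG_H < self.dG_L:
            raise ValueError(
                f"{self.agonist_id}: expected dG_H < dG_L "
                f"(got dG_L={self.dG_L}, dG_H={self.dG_H})"
            )
        object.__setattr__(self, "eta", efficiency(self.dG_L, self.dG_H))


@dataclass(frozen=True)
class GatingCycle:
    """The four-state binding/gating cycle of a two-site receptor.

    ``L0`` is derived from the unliganded gating free energy ``dG0`` and
    ``L2`` follows from microscopic reversibility given the association
    constant ratio ``K_H / K_L``.
    """

    RT: float
    dG0: float
    K_ratio: float
    n_sites: int = 2
    L0: float = field(init=False)
    L2: float = field(init=False)

    def __post_init__(self) -> None:
        if self.RT <= 0:
            raise ValueError(f"RT must be positive, got {self.RT}")
        if self.n_sites < 1:
            raise ValueError(f"n_sites must be >= 1, got {self.n_sites}")
        if self.K_ratio <= 0:
            raise ValueError(f"K_H/K_L ratio must be positive, got {self.K_ratio}")
        object.__setattr__(self, "L0", math.exp(-self.dG0 / self.RT))
        object.__setattr__(
            self, "L2", diliganded_constant(self.L0, self.K_ratio, self.n_sites)
        )

    @property
    def popen_unliganded(self) -> float:
        return self.L0 / (1.0 + self.L0)

    @property
    def popen_diliganded(self) -> float:
        return self.L2 / (1.0 + self.L2)


def rt_at_temperature(T_celsius: float) -> float:
    """RT in kcal/mol at a temperature given in Celsius (0.59 at 23 C)."""
    if T_celsius <= -CELSIUS_OFFSET:
        raise ValueError(
            f"temperature {T_celsius} C is at or below absolute zero"
        )
    return R_KCAL * (T_celsius + CELSIUS_OFFSET)


def dg_from_K(K: float, RT: float) -> float:
    """Free energy (kcal/mol) of an equilibrium constant: dG = -RT ln K."""
    if K <= 0:
        raise ValueError(f"equilibrium constant must be positive, got {K}")
    if RT <= 0:
        raise ValueError(f"RT must be positive, got {RT}")
    return -RT * math.log(K)


def K_from_dg(dG: float, RT: float) -> float:
    """Inverse of :func:`dg_from_K`: K = exp(-dG/RT)."""
    if RT <= 0:
        raise ValueError(f"RT must be positive, got {RT}")
    return math.exp(-dG / RT)


def coupling_energy(e: AgonistEnergetics, n_sites: int = 2) -> float:
    """Total L->H binding free energy change over ``n_sites`` sites.

    Per site this is the efficacy, dG_H - dG_L; for two bound neurotransmitter
    molecules it is the energy source that drives the otherwise unfavorable
    gating isomerization (-10.2 kcal/mol for ACh at the adult receptor).
    """
    return n_sites * (e.dG_H - e.dG_L)


def net_gating_energy(dG0: float, coupling: float) -> float:
    """Net diliganded gating free energy: unliganded dG0 plus agonist coupling."""
    return dG0 + coupling


def popen(dG_net: float, RT: float) -> float:
    """Open probability from a net gating free energy.

    L = exp(-dG_net/RT) and P_O = L/(1+L); strictly decreasing in dG_net.
    """
    if RT <= 0:
        raise ValueError(f"RT must be positive, got {RT}")
    # Work with log-odds to stay finite for strongly negative dG_net.
    x = -dG_net / RT
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    return math.exp(x) / (1.0 + math.exp(x))


def diliganded_constant(L0: float, K_ratio: float, n_sites: int = 2) -> float:
    """Diliganded gating constant by microscopic reversibility.

    L2 = L0 * (K_H/K_L)**n_sites; for the adult receptor the two independent
    L->H rearrangements multiply the gating equilibrium constant by 5680**2.
    """
    if L0 <= 0:
        raise ValueError(f"L0 must be positive, got {L0}")
    if K_ratio <= 0:
        raise ValueError(f"K_H/K_L must be positive, got {K_ratio}")
    if n_sites < 1:
        raise ValueError(f"n_sites must be >= 1, got {n_sites}")
    return L0 * K_ratio**n_sites


def efficiency(dG_L: float, dG_H: float) -> float:
    """Agonist efficiency eta = 1 - dG_L/dG_H.

    The ratio of binding free energies makes eta immune to any uniform scale
    error in the two energies, which is what lets it be computed from
    approximate in-silico energies.
    """
    if dG_H == 0:
        raise ValueError("dG_H must be nonzero for efficiency")
    if not (dG_L < 0 and dG_H < dG_L):
        warnings.warn(
            f"efficiency computed outside the physical regime "
            f"(expected dG_H < dG_L < 0; got dG_L={dG_L}, dG_H={dG_H})",
            stacklevel=2,
        )
    return 1.0 - dG_L / dG_H


def read_energetics_csv(path: str | Path) -> list[AgonistEnergetics]:
    """Read an experimental table ``agonist,dG_L,dG_H`` (kcal/mol).

    Efficiency is computed on read and every record is validated against the
    sign invariants (dG_H < dG_L < 0).
    """
    df = pd.read_csv(path)
    required = {"agonist", "dG_L", "dG_H"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"energetics CSV missing columns: {sorted(missing)}")
    return [
        AgonistEnergetics(str(row.agonist), float(row.dG_L), float(row.dG_H))
        for row in df.itertuples(index=False)
    ]
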
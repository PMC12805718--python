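"""Parameter containers for the chemostat model.

An *ecology* is the set of environmental constants describing one chemostat
habitat: nutrient and virus supply, dilution, uptake, viral replication and
lysis kinetics, and the cap on immunity investment.  A *strategy* is the pair
of heritable defense investments a genotype carries: the programmed-cell-death
(PCD) threshold parameter ``a`` and the immunity (virus clearance) rate ``r``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

__all__ = ["EcologyParams", "StrategyParams", "rescale_volume", "REFERENCE_RANGES"]

#: Reference ranges explored in the sensitivity survey of the model.  Values
#: outside these ranges are legal but trigger a warning, because the model's
#: qualitative behaviour has only been mapped within them.
REFERENCE_RANGES = {
    "B": (0.05, 0.2),
    "C": (1e-7, 1e-5),
    "psi0": (1e7, 1e12),
    "E": (0.0125, 0.05),
    "F": (0.8, 8.0),
    "G": (1.0, 2.0),
    "T": (0.2, 1.0),
}


@dataclass(frozen=True)
class EcologyParams:
    """Environmental constants of a single well-mixed chemostat.

    Parameters
    ----------
    A : float
        Baseline growth-rate scale (per unit nutrient per unit time).  Cell
        volume advances from bin ``p`` to ``p+1`` at rate ``A*(1-r/E)*phi*p``.
    B : float
        Chemostat dilution rate (fraction of the vessel volume per unit time).
    C : float
        Per-unit-cell-volume media uptake rate.  Governs both nutrient
        consumption and virion encounter; ``1/C`` is proportional to the
        carrying capacity of the vessel.
    E : float
        Maximum immunity investment.  ``r/E`` is the fractional growth cost of
        immunity; growth stops as ``r`` approaches ``E``.
    F : float
        Intracellular virus replication rate (per virion per unit time).
    G : float
        Exponent of the lysis-rate curve below the lethal threshold.
    T : float
        Lethal intracellular virus concentration: at ``rho >= T`` the cell
        lyses deterministically (within one step).
    phi0 : float
        Nutrient concentration of the influent media (growth scale is ``A``
        at ``phi = 1``).
    psi0 : float
        Virion count of the influent media (extrinsic viral pressure).
    Q : int
        Maximum absolute number of virions inside one cell.
    P0 : int
        Number of volume bins; a newborn cell has volume index ``P0``, and
        division occurs on leaving the top bin ``2*P0 - 1``.
    """

    A: float
    B: float
    C: float
    E: float
    F: float
    G: float
    T: float
    psi0: float
    phi0: float = 1.0
    Q: int = 1000
    P0: int = 10

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError("A must be positive")
        if not self.B > 0:
            raise ValueError("B must be positive")
        if not self.C > 0:
            raise ValueError("C must be positive")
        if not self.E > 0:
            raise ValueError("E must be positive")
        if self.F < 0:
            raise ValueError("F must be non-negative")
        if self.G < 1:
            raise ValueError("G must be >= 1")
        if not 0 < self.T <= 1:
            raise ValueError("T must lie in (0, 1]")
        if self.phi0 < 0 or self.psi0 < 0:
            raise ValueError("phi0 and psi0 must be non-negative")
        if int(self.Q) != self.Q or self.Q < 1:
            raise ValueError("Q must be an integer >= 1")
        if int(self.P0) != self.P0 or self.P0 < 2:
            raise ValueError("P0 must be an integer >= 2")
        for name, (lo, hi) in REFERENCE_RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                warnings.warn(
                    f"{name}={v:g} lies outside the surveyed range [{lo:g}, {hi:g}]",
                    stacklevel=3,
                )

    @property
    def extrinsic_moi(self) -> float:
        """Extrinsic multiplicity of infection, the product ``C * psi0``."""
        return self.C * self.psi0

    def replace(self, **kw) -> "EcologyParams":
        """Return a copy with the given fields substituted."""
        return replace(self, **kw)


@dataclass(frozen=True)
class StrategyParams:
    """Heritable defense investments of one genotype.

    ``a`` sets the PCD trigger: a cell self-destructs (without virion release)
    as soon as its intracellular virus concentration exceeds ``1 - a``.  At
    ``a = 0`` PCD never fires; at ``a = 1`` a single virion triggers it.
    ``r`` is the immunity clearance rate per unit cell volume; it carries the
    multiplicative growth cost ``1 - r/E``.
    """

    a: float
    r: float

    def __post_init__(self) -> None:
        if not 0 <= self.a <= 1:
            raise ValueError("a must lie in [0, 1]")
        if self.r < 0:
            raise ValueError("r must be non-negative")

    def validate_against(self, eco: EcologyParams) -> None:
        if self.r > eco.E:
            raise ValueError(f"r={self.r:g} exceeds the immunity cap E={eco.E:g}")


def rescale_volume(eco: EcologyParams, factor: float) -> EcologyParams:
    """Shrink the chemostat vessel by ``factor`` without changing per-capita dynamics.

    The model has an exact volume symmetry: mapping ``C -> C*factor`` and
    ``psi0 -> psi0/factor`` rescales every population variable (cell counts
    and the virion pool) by ``1/factor`` while leaving per-cell rates, the
    nutrient trajectory, the extrinsic MOI ``C*psi0`` and therefore the whole
    fitness landscape (including the optimal strategy) unchanged.  This is the
    sanctioned way to obtain small populations for stochastic runs.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    return eco.replace(C=eco.C * factor, psi0=eco.psi0 / factor)
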
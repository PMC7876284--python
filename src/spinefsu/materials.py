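"""Material parameter sets for FSU finite-element models.

All moduli in MPa.  The healthy set is the standard lumbar FSU
parameterization: orthotropic elastic cortical bone, neo-Hookean trabecular
bone / endplates / nucleus pulposus / facet cartilage, a compressible
Holmes-Mow annulus matrix reinforced by two exponential-power-law fiber
families, and nonlinear tension-only ligaments (curves live with the
ligament elements, not here).

Degenerated discs are represented by automatic material corrections keyed to
the Pfirrmann grade, reflecting the stiffening and fluid loss of progressing
degeneration:

* grade 4 — nucleus E 1.0 -> 1.4 MPa, nu 0.49 -> 0.42; annulus E 1.0 -> 4.5 MPa
* grade 5 — nucleus E 1.0 -> 2.2 MPa, nu 0.49 -> 0.32; annulus E 1.0 -> 5.5 MPa

Everything else stays at the healthy values.  Grades 1-3 are close enough to
healthy that no correction is defined; requesting them is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "IsotropicElastic",
    "OrthotropicElastic",
    "HolmesMowParams",
    "FiberParams",
    "MaterialSet",
    "materials_for_grade",
]


@dataclass(frozen=True)
class IsotropicElastic:
    """Neo-Hookean solid parameterized by small-strain E (MPa) and nu."""

    E: float
    nu: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0.0 < self.nu < 0.5:
            raise ValueError("Poisson's ratio must lie in (0, 0.5)")

    @property
    def lame(self) -> tuple[float, float]:
        lam = self.E * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))
        mu = self.E / (2 * (1 + self.nu))
        return lam, mu


@dataclass(frozen=True)
class OrthotropicElastic:
    """Orthotropic elasticity (cortical bone); shear moduli are package
    defaults — the canonical parameter tables stop at E and nu."""

    E1: float = 8000.0
    E2: float = 8000.0
    E3: float = 12000.0
    nu12: float = 0.4
    nu23: float = 0.3
    nu31: float = 0.35
    G12: float = 3500.0
    G23: float = 3500.0
    G31: float = 3500.0


@dataclass(frozen=True)
class HolmesMowParams:
    """Compressible Holmes-Mow solid: E, nu plus exponential stiffening beta."""

    E: float
    nu: float
    beta: float

    @property
    def lame(self) -> tuple[float, float]:
        lam = self.E * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))
        mu = self.E / (2 * (1 + self.nu))
        return lam, mu


@dataclass(frozen=True)
class FiberParams:
    """Tension-only exponential-power-law fiber family:
    W = xi/(alpha*beta) * (exp(alpha*(I_n - 1)**beta) - 1) for I_n > 1."""

    alpha: float = 65.0
    beta: float = 2.0
    xi: float = 0.296


@dataclass(frozen=True)
class MaterialSet:
    """Complete FSU material assignment for one degeneration grade."""

    grade: str  # 'healthy' | 'PG4' | 'PG5'
    cortical: OrthotropicElastic
    trabecular: IsotropicElastic
    endplate: IsotropicElastic
    nucleus: IsotropicElastic
    annulus: HolmesMowParams
    fiber: FiberParams
    facet_cartilage: IsotropicElastic


_HEALTHY = MaterialSet(
    grade="healthy",
    cortical=OrthotropicElastic(),
    trabecular=IsotropicElastic(E=100.0, nu=0.2),
    endplate=IsotropicElastic(E=1000.0, nu=0.3),
    nucleus=IsotropicElastic(E=1.0, nu=0.49),
    annulus=HolmesMowParams(E=1.0, nu=0.4, beta=3.4),
    fiber=FiberParams(alpha=65.0, beta=2.0, xi=0.296),
    facet_cartilage=IsotropicElastic(E=30.0, nu=0.4),
)


def materials_for_grade(grade) -> MaterialSet:
    """Material set for 'healthy' or Pfirrmann grade 4 / 5.

    Pure and total on its domain; nucleus stiffness is strictly increasing
    with degeneration grade.
    """
    if grade in ("healthy", None, 0):
        return _HEALTHY
    if grade in (4, "4", "PG4"):
        return replace(
            _HEALTHY,
            grade="PG4",
            nucleus=IsotropicElastic(E=1.4, nu=0.42),
            annulus=HolmesMowParams(E=4.5, nu=0.4, beta=3.4),
        )
    if grade in (5, "5", "PG5"):
        return replace(
            _HEALTHY,
            grade="PG5",
            nucleus=IsotropicElastic(E=2.2, nu=0.32),
            annulus=HolmesMowParams(E=5.5, nu=0.4, beta=3.4),
        )
    raise ValueError(
        f"unsupported degeneration grade {grade!r}: material corrections are "
        "defined for 'healthy' and Pfirrmann grades 4 and 5 only"
    )
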
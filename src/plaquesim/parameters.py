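"""Model constants, unit conversion, regime validation and initial conditions.

The model tracks live and apoptotic macrophages in an early atherosclerotic
plaque, structured by the lipid content ``a`` of each cell.  Lipid is measured
in units of the endogenous membrane lipid ``a0`` and time in units of the mean
macrophage lifespan ``1/beta`` (``beta`` is the apoptosis rate).  All analysis
is carried out on the dimensionless system; dimensional quantities exist only
at the conversion boundary provided here.

Dimensionless groups (pure numbers):

====== =====================  ==============================================
field  definition             meaning
====== =====================  ==============================================
rho    ``rho / beta``          proliferation rate per mean lifespan
gamma  ``gamma / beta``        emigration rate per mean lifespan
nu     ``nu / beta``           secondary-necrosis rate per mean lifespan
eta    ``alpha*eta / beta^2``  efferocytosis (apoptotic-cell uptake) rate
theta  ``alpha*theta/beta^2``  necrotic-lipid uptake rate
lam    ``lam / (a0*alpha)``    net LDL/HDL lipid influx
kappa  ``kappa*beta/(a0*alpha)`` internalised lipid at half-maximal recruitment
a_sigma ``a_sigma / a0``       scale of the initial half-normal spread
====== =====================  ==============================================

A bounded macrophage population requires ``rho < 1 + gamma``: above that
threshold division outpaces apoptosis plus emigration and the cell number
grows without limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, asdict
from typing import TYPE_CHECKING

import numpy as np
import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .grid import LipidGrid
    from .ode import ODEState

SQRT_2PI = math.sqrt(2.0 * math.pi)

__all__ = [
    "DimensionalParameters",
    "DimensionlessParameters",
    "Violation",
    "ValidationReport",
    "nondimensionalise",
    "redimensionalise",
    "validate",
    "initial_ode_state",
    "initial_state",
    "time_in_hours",
    "time_in_days",
    "load_parameters",
    "dump_parameters",
]


def _check_positive(obj, allow_zero: tuple[str, ...] = ()) -> None:
    for f in fields(obj):
        value = getattr(obj, f.name)
        ok = value >= 0 if f.name in allow_zero else value > 0
        if not ok:
            raise ValueError(
                f"{type(obj).__name__}.{f.name} must be "
                f"{'non-negative' if f.name in allow_zero else 'strictly positive'}, "
                f"got {value!r}"
            )


@dataclass(frozen=True)
class DimensionalParameters:
    """Dimensional model constants.

    Rates are per unit time (hours in the default parameterisation), lipid
    quantities in the same unit as ``a0``, and ``alpha`` — the maximal
    monocyte recruitment rate — in cells per unit time.
    """

    a0: float        # endogenous (membrane) lipid per cell
    beta: float      # apoptosis rate
    rho: float       # proliferation rate
    gamma: float     # emigration rate
    nu: float        # secondary necrosis rate
    eta: float       # efferocytosis rate coefficient, 1/(cells*time)
    theta: float     # necrotic lipid uptake coefficient, 1/(cells*time)
    lam: float       # net LDL/HDL lipid influx, lipid/time
    kappa: float     # internalised lipid at half-maximal recruitment
    alpha: float     # maximal recruitment rate, cells/time
    a_sigma: float   # scale of the initial lipid spread

    def __post_init__(self) -> None:
        _check_positive(self, allow_zero=("rho", "eta"))


@dataclass(frozen=True)
class DimensionlessParameters:
    """Dimensionless model constants (see the module docstring for the map)."""

    rho: float
    gamma: float
    nu: float
    eta: float
    theta: float
    lam: float
    kappa: float
    a_sigma: float

    def __post_init__(self) -> None:
        # rho = 0 (no proliferation) and eta = 0 (no efferocytosis) are
        # meaningful limiting models; the other rates must be positive.
        _check_positive(self, allow_zero=("rho", "eta"))

    @property
    def bounded(self) -> bool:
        """True when the macrophage population admits a finite steady state."""
        return self.rho < 1.0 + self.gamma

    def replace(self, **kwargs) -> "DimensionlessParameters":
        data = asdict(self)
        data.update(kwargs)
        return DimensionlessParameters(**data)


@dataclass(frozen=True)
class Violation:
    name: str
    message: str
    hard: bool


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[Violation, ...]

    @property
    def is_valid(self) -> bool:
        return not self.violations

    @property
    def hard_violations(self) -> tuple[Violation, ...]:
        return tuple(v for v in self.violations if v.hard)


def nondimensionalise(dim: DimensionalParameters) -> DimensionlessParameters:
    """Convert dimensional constants to the dimensionless groups."""
    return DimensionlessParameters(
        rho=dim.rho / dim.beta,
        gamma=dim.gamma / dim.beta,
        nu=dim.nu / dim.beta,
        eta=dim.alpha * dim.eta / dim.beta**2,
        theta=dim.alpha * dim.theta / dim.beta**2,
        lam=dim.lam / (dim.a0 * dim.alpha),
        kappa=dim.kappa * dim.beta / (dim.a0 * dim.alpha),
        a_sigma=dim.a_sigma / dim.a0,
    )


def redimensionalise(
    nd: DimensionlessParameters, a0: float, beta: float, alpha: float
) -> DimensionalParameters:
    """Invert :func:`nondimensionalise` given the three dimensional scales."""
    if not (a0 > 0 and beta > 0 and alpha > 0):
        raise ValueError("a0, beta and alpha must be strictly positive")
    return DimensionalParameters(
        a0=a0,
        beta=beta,
        rho=nd.rho * beta,
        gamma=nd.gamma * beta,
        nu=nd.nu * beta,
        eta=nd.eta * beta**2 / alpha,
        theta=nd.theta * beta**2 / alpha,
        lam=nd.lam * a0 * alpha,
        kappa=nd.kappa * a0 * alpha / beta,
        alpha=alpha,
        a_sigma=nd.a_sigma * a0,
    )


def time_in_hours(t: float, beta_per_hour: float) -> float:
    """Dimensional time (hours) of ``t`` macrophage lifespans."""
    return t / beta_per_hour


def time_in_days(t: float, beta_per_hour: float) -> float:
    """Dimensional time (days) of ``t`` macrophage lifespans."""
    return time_in_hours(t, beta_per_hour) / 24.0


def validate(nd: DimensionlessParameters) -> ValidationReport:
    """Check the modelling regime.

    Hard constraints are mathematical requirements (bounded growth, positive
    initial population); advisory constraints are biological modelling
    assumptions (efferocytosis more efficient than necrotic uptake, recruitment
    half-saturation above the initial spread) whose violation still yields a
    well-posed problem.
    """
    violations: list[Violation] = []
    if nd.rho >= 1.0 + nd.gamma:
        violations.append(
            Violation(
                "unbounded-growth",
                f"rho={nd.rho} >= 1 + gamma={1 + nd.gamma}: proliferation "
                "outpaces apoptosis plus emigration; no bounded steady state",
                hard=True,
            )
        )
    if nd.a_sigma * SQRT_2PI <= 2.0 * nd.lam:
        violations.append(
            Violation(
                "nonpositive-initial-population",
                f"a_sigma*sqrt(2*pi)={nd.a_sigma * SQRT_2PI:.4g} <= "
                f"2*lam={2 * nd.lam:.4g}: the initial population M(0) would "
                "be non-positive",
                hard=True,
            )
        )
    if nd.eta <= nd.theta:
        violations.append(
            Violation(
                "efferocytosis-not-dominant",
                f"eta={nd.eta} <= theta={nd.theta}: apoptotic-cell uptake is "
                "assumed more efficient than necrotic-lipid uptake",
                hard=False,
            )
        )
    if nd.kappa <= nd.a_sigma:
        violations.append(
            Violation(
                "recruitment-halfmax-below-spread",
                f"kappa={nd.kappa} <= a_sigma={nd.a_sigma}: significant "
                "recruitment would occur even without LDL influx",
                hard=False,
            )
        )
    return ValidationReport(tuple(violations))


def initial_ode_state(nd: DimensionlessParameters, p0_ratio: float = 0.5) -> "ODEState":
    """Aggregate initial condition consistent with the recruitment boundary.

    The initial lipid distribution is a half-normal with scale ``a_sigma``,
    and the initial population size is pinned by requiring the boundary flux
    relation to hold at ``t = 0``:

        M(0) = kappa*lam*sqrt(2*pi) / (a_sigma*(a_sigma*sqrt(2*pi) - 2*lam))

    ``p0_ratio`` sets P(0)/M(0) (< 1: fewer apoptotic than live cells).  The
    plaque starts with no necrotic lipid, N(0) = 0.
    """
    from .ode import ODEState

    denom = nd.a_sigma * SQRT_2PI - 2.0 * nd.lam
    if denom <= 0:
        raise ValueError(
            "initial condition requires a_sigma*sqrt(2*pi) > 2*lam "
            f"(got {nd.a_sigma * SQRT_2PI:.4g} <= {2 * nd.lam:.4g})"
        )
    if not (0.0 < p0_ratio < 1.0):
        raise ValueError("p0_ratio must lie in (0, 1)")
    M0 = nd.kappa * nd.lam * SQRT_2PI / (nd.a_sigma * denom)
    # first moment of the half-normal: 1 + a_sigma*sqrt(2/pi)
    AM0 = M0 * (1.0 + 2.0 * nd.a_sigma / SQRT_2PI)
    return ODEState(M=M0, P=p0_ratio * M0, A_M=AM0, A_P=p0_ratio * AM0, N=0.0)


def half_normal_density(a: np.ndarray, a_sigma: float) -> np.ndarray:
    """Half-normal lipid density on ``a >= 1`` with scale ``a_sigma``."""
    return (2.0 / (a_sigma * SQRT_2PI)) * np.exp(-((a - 1.0) ** 2) / (2.0 * a_sigma**2))


def initial_state(
    nd: DimensionlessParameters, grid: "LipidGrid", p0_ratio: float = 0.5
):
    """Initial densities ``(m0, p0)`` on ``grid`` plus the aggregate state.

    The half-normal is sampled on the truncated domain without renormalising:
    for the default scales the mass beyond ``a_max`` is utterly negligible.
    """
    report = validate(nd)
    if report.hard_violations:
        names = ", ".join(v.name for v in report.hard_violations)
        raise ValueError(f"hard parameter-regime violations: {names}")
    m0 = half_normal_density(grid.nodes, nd.a_sigma)
    return m0, m0.copy(), initial_ode_state(nd, p0_ratio=p0_ratio)


def dump_parameters(nd: DimensionlessParameters, path) -> None:
    """Write dimensionless parameters as a flat YAML mapping."""
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(nd), fh, sort_keys=True)


def load_parameters(path) -> DimensionlessParameters:
    """Read dimensionless parameters from a flat YAML mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return DimensionlessParameters(**data)
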
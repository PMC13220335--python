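"""Dimensional bookkeeping between lattice and physical units.

A lattice Boltzmann run is carried out in dimensionless lattice units
(grid spacing = time step = 1, outlet density = 1).  Dynamic similitude
with the physical flow is guaranteed by matching the Reynolds number;
the scale factors for length (``delta_x``) and kinematic viscosity
(``delta_nu``) then fix the time scale ``delta_t = delta_x**2 / delta_nu``
by dimensional analysis, and the outlet density fixes the mass scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "UnitScaling",
    "FlowRegime",
    "derive_time_scale",
    "inlet_speed",
    "ballistic_cross_time",
    "SEAWATER_NU",
    "SEAWATER_RHO",
]

#: kinematic viscosity of cold deep-sea water, m^2/s
SEAWATER_NU = 1.75e-6
#: mass density of seawater, kg/m^3 (configurable in UnitScaling)
SEAWATER_RHO = 1025.0


def derive_time_scale(delta_x: float, delta_nu: float) -> float:
    """Time scale factor delta_t implied by length and viscosity scales.

    Viscosity has dimension L^2/T, hence ``delta_t = delta_x**2 / delta_nu``.
    Attaching the result to a :class:`UnitScaling` makes the Reynolds number
    identical in lattice and physical units.

    Raises
    ------
    ValueError
        If either scale is not strictly positive.
    """
    if delta_x <= 0 or delta_nu <= 0:
        raise ValueError(
            f"scale factors must be > 0, got delta_x={delta_x}, delta_nu={delta_nu}"
        )
    return delta_x * delta_x / delta_nu


@dataclass(frozen=True)
class UnitScaling:
    """Scale factors mapping lattice units to physical (SI) units.

    Parameters
    ----------
    delta_x : float
        Metres per lattice spacing.
    delta_nu : float
        m^2/s per lattice viscosity unit.
    rho_out : float
        Reference lattice density at the outlet; fixed at 1.
    rho_phys : float
        Physical mass density of the working fluid, kg/m^3.
    """

    delta_x: float
    delta_nu: float
    rho_out: float = 1.0
    rho_phys: float = SEAWATER_RHO

    def __post_init__(self) -> None:
        if self.delta_x <= 0 or self.delta_nu <= 0:
            raise ValueError("delta_x and delta_nu must be > 0")
        if self.rho_out != 1.0:
            raise ValueError("lattice outlet density is fixed at 1")

    @property
    def delta_t(self) -> float:
        """Seconds per lattice time step (derived, delta_x^2/delta_nu)."""
        return derive_time_scale(self.delta_x, self.delta_nu)

    # -- lattice -> physical ------------------------------------------------
    def length(self, x_lat: float) -> float:
        return x_lat * self.delta_x

    def time(self, t_lat: float) -> float:
        return t_lat * self.delta_t

    def velocity(self, u_lat: float) -> float:
        return u_lat * self.delta_x / self.delta_t

    def viscosity(self, nu_lat: float) -> float:
        return nu_lat * self.delta_nu

    def force(self, f_lat: float) -> float:
        # mass scale from rho_phys/rho_out * delta_x^3; force = M L / T^2
        return f_lat * (self.rho_phys / self.rho_out) * self.delta_x**4 / self.delta_t**2

    def volume_rate(self, q_lat: float) -> float:
        """Volumetric flow rate, lattice -> m^3/s."""
        return q_lat * self.delta_x**3 / self.delta_t

    # -- physical -> lattice ------------------------------------------------
    def length_to_lattice(self, x_phys: float) -> float:
        return x_phys / self.delta_x

    def time_to_lattice(self, t_phys: float) -> float:
        return t_phys / self.delta_t

    def velocity_to_lattice(self, u_phys: float) -> float:
        return u_phys * self.delta_t / self.delta_x

    def viscosity_to_lattice(self, nu_phys: float) -> float:
        return nu_phys / self.delta_nu

    def force_to_lattice(self, f_phys: float) -> float:
        return f_phys / ((self.rho_phys / self.rho_out) * self.delta_x**4 / self.delta_t**2)

    def header_lines(self) -> list[str]:
        """Comment lines embedding the scaling in output file headers."""
        return [
            f"delta_x_m = {self.delta_x!r}",
            f"delta_nu_m2_s = {self.delta_nu!r}",
            f"delta_t_s = {self.delta_t!r}",
            f"rho_out_lattice = {self.rho_out!r}",
            f"rho_phys_kg_m3 = {self.rho_phys!r}",
        ]


@dataclass(frozen=True)
class FlowRegime:
    """Physical flow regime: Re = u_in * D / nu.

    The inlet speed is derived from the Reynolds number, the body-cavity
    inner diameter ``D_phys`` and the kinematic viscosity ``nu_phys``.
    """

    Re: float
    D_phys: float = 0.040
    nu_phys: float = SEAWATER_NU

    def __post_init__(self) -> None:
        if self.Re <= 0 or self.D_phys <= 0 or self.nu_phys <= 0:
            raise ValueError("Re, D_phys and nu_phys must all be > 0")

    @property
    def u_in_phys(self) -> float:
        return inlet_speed(self)

    @property
    def t_cross(self) -> float:
        return ballistic_cross_time(self)


def inlet_speed(regime: FlowRegime) -> float:
    """Inlet speed u_in = Re * nu / D in m/s."""
    if regime.D_phys == 0:
        raise ValueError("D_phys must be nonzero")
    return regime.Re * regime.nu_phys / regime.D_phys


def ballistic_cross_time(regime: FlowRegime) -> float:
    """Reference 'ballistic' cross time t_cross = D / u_in in seconds.

    The time a fluid particle would take to traverse the cavity diameter
    at the inlet speed; residence times are reported against it.
    """
    u = inlet_speed(regime)
    if u == 0:
        raise ValueError("inlet speed is zero")
    return regime.D_phys / u


def scaling_for_regime(
    regime: FlowRegime,
    d_lattice: float,
    u_in_lattice: float,
    rho_phys: float = SEAWATER_RHO,
) -> UnitScaling:
    """Build the UnitScaling that maps a lattice run onto a physical regime.

    ``d_lattice`` is the cavity diameter in lattice nodes and
    ``u_in_lattice`` the chosen lattice inlet speed (kept well below the
    speed of sound).  The lattice viscosity follows from matching Re:
    ``nu_lat = u_lat * D_lat / Re``.
    """
    if d_lattice <= 0 or u_in_lattice <= 0:
        raise ValueError("d_lattice and u_in_lattice must be > 0")
    delta_x = regime.D_phys / d_lattice
    nu_lat = u_in_lattice * d_lattice / regime.Re
    delta_nu = regime.nu_phys / nu_lat
    return UnitScaling(delta_x=delta_x, delta_nu=delta_nu, rho_phys=rho_phys)
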
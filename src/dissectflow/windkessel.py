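"""Three-element Windkessel (RCR) outlet model.

The distal vasculature past each outlet is lumped into a proximal resistance
``R_p`` in series with a parallel pair of compliance ``C`` and distal
resistance ``R_d``, grounded at a distal reference pressure ``P_d``:

    P         = R_p * Q + P_c
    C dP_c/dt = Q - (P_c - P_d) / R_d

where ``P`` is the interface pressure seen by the network, ``Q`` the outlet
flow and ``P_c`` the mid (capacitor) pressure — the model's single state.
``P_d`` defaults to zero ground.  The state update is backward Euler, which
is unconditionally stable and consistent with the implicit network solve.

The module also carries the tuned per-outlet parameter registry for the
18 branches of the aortic model (carotid/subclavian, visceral, renal, sacral
and iliac outlets) as packaged CSV, in canonical g-mm-s units.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .waveform import Waveform

__all__ = [
    "WindkesselParams",
    "WindkesselState",
    "wk_interface_pressure",
    "wk_step",
    "wk_periodic_mean_identity",
    "load_rcr_registry",
    "RegistryError",
]

#: number of outlets in the packaged aortic registry
REGISTRY_SIZE = 18


class RegistryError(ValueError):
    """Raised when an outlet registry fails its integrity checks."""


@dataclass(frozen=True)
class WindkesselParams:
    """RCR parameters: resistances g/(mm^4 s), compliance mm^4 s^2/g."""

    Rp: float
    C: float
    Rd: float
    Pd: float = 0.0

    def __post_init__(self) -> None:
        if self.Rp <= 0 or self.Rd <= 0 or self.C <= 0:
            raise ValueError(
                f"Rp, C, Rd must be strictly positive, got "
                f"({self.Rp}, {self.C}, {self.Rd})"
            )
        if self.Pd < 0:
            raise ValueError(f"Pd must be non-negative, got {self.Pd}")

    @property
    def total_resistance(self) -> float:
        return self.Rp + self.Rd

    def scaled(self, factor: float) -> "WindkesselParams":
        """Return a copy with both resistances scaled (afterload experiments)."""
        return WindkesselParams(self.Rp * factor, self.C, self.Rd * factor, self.Pd)


@dataclass
class WindkesselState:
    """Instantaneous capacitor pressure ``P_c`` (canonical units)."""

    Pc: float = 0.0


def wk_interface_pressure(params: WindkesselParams, state: WindkesselState,
                          Q: float) -> float:
    """Interface pressure seen by the network: ``P = R_p Q + P_c``."""
    return params.Rp * Q + state.Pc


def wk_step(params: WindkesselParams, state: WindkesselState, Q: float,
            dt: float) -> WindkesselState:
    """Advance ``P_c`` by one backward-Euler step of length ``dt``.

    Solves  C (Pc' - Pc)/dt = Q - (Pc' - Pd)/Rd  for Pc'.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    a = dt / (params.Rd * params.C)
    pc_new = (state.Pc + (dt / params.C) * Q + a * params.Pd) / (1.0 + a)
    return WindkesselState(Pc=pc_new)


def wk_periodic_mean_identity(params: WindkesselParams, Q: Waveform) -> float:
    """Cycle-mean interface pressure for a periodic inflow.

    At cyclic convergence the capacitor stores no net charge over a period, so
    the mean obeys the purely resistive identity
    ``P_mean = Q_mean (R_p + R_d) + P_d``.  Used as an analytic oracle against
    the time-stepped solution.
    """
    return Q.mean() * (params.Rp + params.Rd) + params.Pd


def steady_state(params: WindkesselParams, Q: float) -> WindkesselState:
    """Exact equilibrium state under constant flow: ``P_c = P_d + Q R_d``."""
    return WindkesselState(Pc=params.Pd + Q * params.Rd)


def load_rcr_registry(path=None) -> dict[str, WindkesselParams]:
    """Load an outlet registry (``name,Rp,C,Rd[,Pd]`` CSV) as an ordered map.

    With no ``path`` the packaged 18-outlet aortic registry is returned and
    its row count is enforced.
    """
    if path is None:
        src = resources.files("dissectflow.data") / "outlet_rcr.csv"
        with resources.as_file(src) as p:
            table = pd.read_csv(p)
        enforce = REGISTRY_SIZE
    else:
        table = pd.read_csv(path)
        enforce = None
    required = {"name", "Rp", "C", "Rd"}
    if not required.issubset(table.columns):
        raise RegistryError(f"registry must have columns {sorted(required)}")
    if table["name"].duplicated().any():
        dupes = table.loc[table["name"].duplicated(), "name"].tolist()
        raise RegistryError(f"duplicate outlet names: {dupes}")
    registry: dict[str, WindkesselParams] = {}
    for _, row in table.iterrows():
        pd_val = float(row["Pd"]) if "Pd" in table.columns else 0.0
        registry[str(row["name"])] = WindkesselParams(
            Rp=float(row["Rp"]), C=float(row["C"]), Rd=float(row["Rd"]), Pd=pd_val
        )
    if enforce is not None and len(registry) != enforce:
        raise RegistryError(
            f"packaged registry must contain exactly {enforce} outlets, "
            f"found {len(registry)}"
        )
    return registry
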
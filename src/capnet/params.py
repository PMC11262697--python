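"""Model parameters and simulation configuration.

All defaults are the typical values of the calibrated parameter set for
HUVEC incubation on an air-dried type-I collagen gel.  Units follow the
conventions used throughout the package: lengths in micrometres (um),
time in seconds, concentrations and densities in ng/um^3, stresses in Pa,
and Hamiltonian terms in arbitrary energy units (a.e.u.).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class PottsParams:
    """Cellular Potts model parameters.

    The interface energies ``J[tau, tau']`` are per unit boundary length
    (a.e.u./um); a lattice edge of length ``dx`` therefore contributes
    ``J * dx``.  Second-order (diagonal) neighbour pairs are down-weighted
    by ``neighbor_weight_order2`` both in the Hamiltonian and in the
    proposal kernel.
    """

    J11: float = 0.12      # cell-cell interface energy, a.e.u./um
    J10: float = 0.06      # cell-empty
    J01: float = 0.06      # empty-cell
    J00: float = 0.0       # empty-empty
    lambda_a: float = 1.0e-4   # area restraint, a.e.u./um^4
    lambda_p: float = 1.0e-2   # perimeter restraint, a.e.u./um
    lambda_l: float = 5.0e3    # length restraint, a.e.u.*um
    a0: float = 1960.0         # target area, um^2 (50 um diameter disk)
    mu_m: float = 1.3e8        # morphology-change strength, um^3/ng
    mu_h: float = 1.5e14       # haptotaxis strength, a.e.u.*um^3/ng
    temperature: float = 1.0   # a.e.u.; fixed, no fluctuation parameter
    neighbor_weight_order2: float = 0.5  # energy + proposal down-weight

    def validate(self) -> None:
        for name in ("lambda_a", "lambda_p", "lambda_l", "mu_m", "mu_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.temperature != 1.0:
            raise ValueError("acceptance rule is defined at fixed unit temperature")

    @property
    def j_matrix(self):
        import numpy as np

        return np.array([[self.J00, self.J01], [self.J10, self.J11]], dtype=float)


@dataclass
class GelParams:
    """Viscoelastic biogel parameters."""

    E: float = 2.0e4        # Young's modulus, Pa
    nu: float = 0.48        # Poisson ratio
    mu1: float = 7.4e5      # shear viscosity, Pa*s
    mu2: float = 1.0e7      # bulk viscosity, Pa*s
    beta1: float = 1.0e4    # 1st long-range elastic coefficient, um^2
    beta2: float = 1.0e4    # 2nd long-range elastic coefficient, um^2
    kappa: float = 4.0e9    # cell traction strength, Pa*um^3/ng
    rho0: float = 1.0e-5    # initial gel density, ng/um^3
    h0: float = 3.0e2       # initial gel thickness, um
    h_min: float = 1.0      # thickness floor, um (the thickness relation is
                            # a linearization; the friction term divides by h^2)

    def validate(self) -> None:
        if self.E <= 0:
            raise ValueError("E must be positive")
        if not 0.0 < self.nu < 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5)")
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValueError("long-range coefficients must be non-negative")
        if self.h_min <= 0 or self.h0 <= 0 or self.rho0 <= 0:
            raise ValueError("h0, h_min, rho0 must be positive")


@dataclass
class VegfParams:
    """Two-species VEGF transport and binding kinetics.

    ``gamma`` is the mass ratio of binding sites (fibronectin) to gel, and
    ``mw_ratio`` the fibronectin-to-VEGF molecular-weight ratio M_FN/M_VEGF
    entering the free-binding-site term ``gamma*rho - mw_ratio*b``.  The
    default uses M_FN = 440 kDa and M_VEGF = 45 kDa.

    The default ``gamma`` follows the calibration criterion that roughly
    10% of the VEGF dose is gel-bound at the initial well-mixed
    equilibrium; the haptotaxis feedback that drives network formation
    needs bound-VEGF gradients of that magnitude.
    """

    D_c: float = 5.9e1      # soluble VEGF diffusivity, um^2/s
    k_on: float = 8.6e5     # binding rate, um^3/(ng*s)
    k_off: float = 3.6e-3   # unbinding rate, 1/s
    gamma: float = 4.8e-5   # binding-site mass ratio in the gel
    c0: float = 2.0e-11     # initial soluble concentration, ng/um^3
    mw_ratio: float = 440.0 / 45.0  # M_FN / M_VEGF

    def validate(self) -> None:
        for name in ("D_c", "k_on", "k_off", "gamma", "c0", "mw_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimConfig:
    """Full configuration of a coupled run.

    One Monte-Carlo step (MCS) represents ``mcs_minutes`` simulated
    minutes; the continuum fields advance by the same interval once per
    MCS.  The morphology and haptotaxis mechanisms can be toggled
    independently, reproducing the four factorial conditions
    (off/off, off/on, on/off, on/on).
    """

    nx: int = 170
    ny: int = 170
    dx: float = 10.0            # um
    mcs_minutes: float = 2.0
    n_cells: int = 400
    duration: int = 720         # MCS (24 h)
    seed: int = 0
    morphology_on: bool = True
    haptotaxis_on: bool = True
    snapshot_every: int = 30    # MCS (1 h)
    potts: PottsParams = field(default_factory=PottsParams)
    gel: GelParams = field(default_factory=GelParams)
    vegf: VegfParams = field(default_factory=VegfParams)

    @property
    def dt(self) -> float:
        """Physical duration of one MCS in seconds."""
        return self.mcs_minutes * 60.0

    def mcs_at_hours(self, hours: float) -> int:
        """Number of MCS corresponding to ``hours`` of incubation."""
        mcs = hours * 60.0 / self.mcs_minutes
        imcs = int(round(mcs))
        if abs(mcs - imcs) > 1e-9:
            raise ValueError(f"{hours} h is not a whole number of MCS")
        return imcs

    def validate(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.nx < 8 or self.ny < 8:
            raise ValueError("grid too small")
        if self.dx <= 0 or self.mcs_minutes <= 0:
            raise ValueError("dx and mcs_minutes must be positive")
        self.potts.validate()
        self.gel.validate()
        self.vegf.validate()

    # -- flat key-value serialization ------------------------------------

    _SYMBOLS = {
        # Potts
        "J_11": ("potts", "J11"), "J_10": ("potts", "J10"),
        "J_01": ("potts", "J01"), "J_00": ("potts", "J00"),
        "lambda_a": ("potts", "lambda_a"), "lambda_p": ("potts", "lambda_p"),
        "lambda_l": ("potts", "lambda_l"), "a_0": ("potts", "a0"),
        "mu_m": ("potts", "mu_m"), "mu_h": ("potts", "mu_h"),
        "neighbor_weight_order2": ("potts", "neighbor_weight_order2"),
        # gel
        "E": ("gel", "E"), "nu": ("gel", "nu"),
        "mu_1": ("gel", "mu1"), "mu_2": ("gel", "mu2"),
        "beta_1": ("gel", "beta1"), "beta_2": ("gel", "beta2"),
        "kappa": ("gel", "kappa"), "rho_0": ("gel", "rho0"),
        "h_0": ("gel", "h0"), "h_min": ("gel", "h_min"),
        # VEGF
        "D_c": ("vegf", "D_c"), "k_on": ("vegf", "k_on"),
        "k_off": ("vegf", "k_off"), "gamma": ("vegf", "gamma"),
        "c_0": ("vegf", "c0"), "mw_ratio": ("vegf", "mw_ratio"),
    }
    _TOP = ("nx", "ny", "dx", "mcs_minutes", "n_cells", "duration", "seed",
            "morphology_on", "haptotaxis_on", "snapshot_every")

    def get_symbol(self, symbol: str) -> float:
        """Look up a parameter by its flat config-file symbol name."""
        if symbol in self._SYMBOLS:
            group, attr = self._SYMBOLS[symbol]
            return getattr(getattr(self, group), attr)
        if symbol in self._TOP:
            return getattr(self, symbol)
        raise KeyError(f"unknown parameter symbol {symbol!r}")

    def set_symbol(self, symbol: str, value) -> None:
        if symbol in self._SYMBOLS:
            group, attr = self._SYMBOLS[symbol]
            setattr(getattr(self, group), attr, value)
        elif symbol in self._TOP:
            cur = getattr(self, symbol)
            setattr(self, symbol, type(cur)(value))
        else:
            raise KeyError(f"unknown parameter symbol {symbol!r}")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self._TOP}
        for sym in self._SYMBOLS:
            d[sym] = self.get_symbol(sym)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def save(self, path: str | Path) -> None:
        lines = [f"{k} = {v}" for k, v in self.to_dict().items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SimConfig":
        cfg = cls()
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if val in ("True", "true"):
                parsed = True
            elif val in ("False", "false"):
                parsed = False
            else:
                parsed = float(val)
            cfg.set_symbol(key, parsed)
        cfg.validate()
        return cfg

    def copy(self) -> "SimConfig":
        return dataclasses.replace(
            self,
            potts=dataclasses.replace(self.potts),
            gel=dataclasses.replace(self.gel),
            vegf=dataclasses.replace(self.vegf),
        )
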
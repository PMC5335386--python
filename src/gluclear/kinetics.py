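"""Ligand-driven Markov schemes: transporter kinetics, Q10 scaling, well-mixed propagation.

The astrocytic glutamate transporter is represented by a three-state cyclic
carrier: outward-facing free (T), outward-facing bound (TG) and
inward-facing (T_in).  Binding consumes a free glutamate (k_on, bimolecular),
unbinding releases it (k_off), translocation sequesters it permanently
(k_trans) and reorientation returns the empty carrier (k_reorient).
Receptor schemes use the same representation and are loaded from editable
YAML files so literature rate sets can be swapped in without code changes.

Rates are s⁻¹ (unimolecular) or M⁻¹s⁻¹ (bimolecular); temperatures in °C;
concentrations in M; integration times in ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.integrate import solve_ivp
from scipy.linalg import expm

__all__ = [
    "SchemeError",
    "Transition",
    "KineticScheme",
    "TransporterParams",
    "q10_scale",
    "build_transporter_scheme",
    "apparent_km",
    "integrate_wellmixed",
    "steady_state",
    "transporter_cycle_flux",
    "sealed_box_binding_ode",
    "AVOGADRO",
]

AVOGADRO = 6.02214076e23


class SchemeError(ValueError):
    """Invalid kinetic scheme or integration settings."""


@dataclass(frozen=True)
class Transition:
    """One edge of the state graph.

    ``rate`` is s⁻¹ for unimolecular transitions and M⁻¹s⁻¹ when ``ligand``
    names the species whose concentration multiplies the rate.  ``effect``
    is None, 'consume' (binding removes one free ligand) or 'release'.
    """

    source: str
    target: str
    rate: float
    ligand: str | None = None
    effect: str | None = None

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise SchemeError(f"negative rate on {self.source}->{self.target}")
        if self.effect not in (None, "consume", "release"):
            raise SchemeError(f"unknown effect {self.effect!r}")
        if self.effect == "consume" and self.ligand is None:
            raise SchemeError("'consume' requires a ligand")


@dataclass
class KineticScheme:
    """States plus unimolecular/bimolecular transitions with side effects."""

    states: list[str]
    transitions: list[Transition]
    conducting: list[str] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise SchemeError("duplicate state names")
        idx = {s: i for i, s in enumerate(self.states)}
        for t in self.transitions:
            if t.source not in idx or t.target not in idx:
                raise SchemeError(f"transition references unknown state: {t}")
        for s in self.conducting:
            if s not in idx:
                raise SchemeError(f"conducting state {s!r} not in states")
        # connectivity (undirected)
        adj: dict[str, set[str]] = {s: set() for s in self.states}
        for t in self.transitions:
            adj[t.source].add(t.target)
            adj[t.target].add(t.source)
        seen = {self.states[0]}
        stack = [self.states[0]]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if seen != set(self.states):
            raise SchemeError("state graph is not connected")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, name: str) -> int:
        return self.states.index(name)

    def ligands(self) -> list[str]:
        return sorted({t.ligand for t in self.transitions if t.ligand})

    def rate_matrix(self, concentrations: dict[str, float] | None = None) -> np.ndarray:
        """Generator matrix Q (s⁻¹): Q[i, j] is the i→j rate, rows sum to 0."""
        conc = concentrations or {}
        n = self.n_states
        q = np.zeros((n, n))
        idx = {s: i for i, s in enumerate(self.states)}
        for t in self.transitions:
            r = t.rate
            if t.ligand is not None:
                c = conc.get(t.ligand)
                if c is None:
                    raise SchemeError(
                        f"no concentration supplied for ligand {t.ligand!r}"
                    )
                r = r * c
            q[idx[t.source], idx[t.target]] += r
        np.fill_diagonal(q, q.diagonal() - q.sum(axis=1))
        return q

    def scaled(self, q10: float, t_ref: float, t_target: float,
               scale_bimolecular: bool = True) -> "KineticScheme":
        """Return a copy with all rates Q10-adjusted from t_ref to t_target."""
        new = []
        for t in self.transitions:
            if t.ligand is not None and not scale_bimolecular:
                new.append(t)
            else:
                new.append(
                    Transition(t.source, t.target,
                               q10_scale(t.rate, q10, t_ref, t_target),
                               t.ligand, t.effect)
                )
        return KineticScheme(list(self.states), new, list(self.conducting), self.name)

    # -- YAML round trip ----------------------------------------------------

    _ALLOWED_KEYS = {"name", "states", "transitions", "conducting"}
    _ALLOWED_TKEYS = {"from", "to", "rate", "ligand", "effect"}

    @classmethod
    def from_yaml(cls, path) -> "KineticScheme":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise SchemeError("scheme file must be a mapping")
        unknown = set(doc) - cls._ALLOWED_KEYS
        if unknown:
            raise SchemeError(f"unknown scheme keys: {sorted(unknown)}")
        trans = []
        for i, t in enumerate(doc.get("transitions", [])):
            bad = set(t) - cls._ALLOWED_TKEYS
            if bad:
                raise SchemeError(f"transition {i}: unknown keys {sorted(bad)}")
            trans.append(
                Transition(t["from"], t["to"], float(t["rate"]),
                           t.get("ligand"), t.get("effect"))
            )
        return cls(list(doc["states"]), trans,
                   list(doc.get("conducting", [])), doc.get("name", ""))

    def to_yaml(self, path) -> None:
        doc = {
            "name": self.name,
            "states": list(self.states),
            "transitions": [
                {k: v for k, v in (
                    ("from", t.source), ("to", t.target), ("rate", t.rate),
                    ("ligand", t.ligand), ("effect", t.effect),
                ) if v is not None}
                for t in self.transitions
            ],
            "conducting": list(self.conducting),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass(frozen=True)
class TransporterParams:
    """Rate constants of the simplified cyclic glutamate-transporter carrier.

    Defaults are the room-temperature base values; ``q10`` applied from
    ``t_ref`` to ``t_sim`` approximates physiological temperature.  ``km``
    is the independently printed apparent steady-state affinity and is kept
    as its own entry (see :func:`apparent_km` for the value the cyclic
    steady state actually implies).
    """

    k_on: float = 6e6          # M^-1 s^-1
    k_off: float = 601.0       # s^-1
    k_trans: float = 2000.0    # s^-1
    k_reorient: float = 50.0   # s^-1
    km: float = 13e-6          # M
    q10: float = 3.0
    t_ref: float = 25.0        # deg C
    t_sim: float = 35.0        # deg C

    def validate(self) -> None:
        for name in ("k_on", "k_off", "k_trans", "k_reorient", "km"):
            if getattr(self, name) < 0:
                raise SchemeError(f"{name} must be >= 0")
        if self.q10 < 1:
            raise SchemeError("q10 must be >= 1")


def q10_scale(rate: float, q10: float, t_ref: float, t_target: float) -> float:
    """Temperature-adjust a rate: rate × q10^((t_target − t_ref)/10)."""
    if q10 <= 0:
        raise SchemeError("q10 must be > 0")
    return rate * q10 ** ((t_target - t_ref) / 10.0)


def build_transporter_scheme(
    params: TransporterParams | None = None,
    apply_q10: bool = False,
    scale_bimolecular: bool = True,
) -> KineticScheme:
    """Three-state transporter scheme: T ⇌ TG → T_in → T.

    Glutamate binding consumes a free molecule; unbinding releases it;
    translocation sequesters it permanently.  With ``apply_q10`` all rates
    (optionally excluding the bimolecular k_on) are scaled from ``t_ref``
    to ``t_sim``.
    """
    p = params or TransporterParams()
    p.validate()
    scheme = KineticScheme(
        states=["T", "TG", "Tin"],
        transitions=[
            Transition("T", "TG", p.k_on, ligand="glutamate", effect="consume"),
            Transition("TG", "T", p.k_off, effect="release"),
            Transition("TG", "Tin", p.k_trans),
            Transition("Tin", "T", p.k_reorient),
        ],
        name="glutamate_transporter",
    )
    if apply_q10:
        scheme = scheme.scaled(p.q10, p.t_ref, p.t_sim, scale_bimolecular)
    return scheme


def apparent_km(params: TransporterParams | None = None) -> float:
    """Steady-state half-saturation of the cyclic carrier, in M.

    K_m = (k_off + k_trans)·k_reorient / (k_on·(k_reorient + k_trans)):
    the glutamate concentration at which the steady-state translocation
    flux is half its saturating value.  With k_trans → 0 this reduces to
    the equilibrium dissociation constant k_off/k_on.
    """
    p = params or TransporterParams()
    p.validate()
    denom = p.k_on * (p.k_reorient + p.k_trans)
    if denom == 0:
        raise SchemeError("zero denominator in apparent Km")
    return (p.k_off + p.k_trans) * p.k_reorient / denom


def steady_state(scheme: KineticScheme,
                 concentrations: dict[str, float] | None = None) -> np.ndarray:
    """Stationary occupancy vector of the scheme at fixed ligand levels."""
    q = scheme.rate_matrix(concentrations)
    n = scheme.n_states
    a = np.vstack([q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return sol


def transporter_cycle_flux(params: TransporterParams, glutamate: float) -> float:
    """Steady-state translocation flux per transporter (s⁻¹) at fixed [glu]."""
    scheme = build_transporter_scheme(params)
    occ = steady_state(scheme, {"glutamate": glutamate})
    return params.k_trans * occ[scheme.state_index("TG")]


def integrate_wellmixed(
    scheme: KineticScheme,
    ligand_timecourse: dict[str, np.ndarray | float],
    dt_ms: float,
    n_steps: int,
    y0: np.ndarray | None = None,
    method: str = "expm",
) -> tuple[np.ndarray, np.ndarray]:
    """Propagate state occupancies under (possibly time-varying) ligands.

    ``ligand_timecourse`` maps species to a scalar (held constant) or an
    array of per-step concentrations (length ≥ n_steps).  Returns
    ``(times_ms, occ)`` with ``occ`` of shape (n_steps + 1, n_states); the
    occupancy vector stays a probability vector at every step.

    method='expm' uses the per-step matrix exponential (unconditionally
    stable; exact for piecewise-constant ligand); 'rk4' is classical
    Runge–Kutta and raises a step-size error when k·dt is too large.
    """
    n = scheme.n_states
    if y0 is None:
        y0 = np.zeros(n)
        y0[0] = 1.0
    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (n,) or np.any(y0 < -1e-12) or abs(y0.sum() - 1) > 1e-9:
        raise SchemeError("y0 must be a probability vector over the states")

    tracks: dict[str, np.ndarray] = {}
    for sp, val in ligand_timecourse.items():
        arr = np.asarray(val, dtype=float)
        if arr.ndim == 0:
            arr = np.full(n_steps, float(arr))
        if len(arr) < n_steps:
            raise SchemeError(f"timecourse for {sp!r} shorter than n_steps")
        tracks[sp] = arr

    dt_s = dt_ms * 1e-3
    occ = np.empty((n_steps + 1, n))
    occ[0] = y0
    y = y0.copy()

    constant = all(np.ptp(a) == 0 for a in tracks.values())
    if method == "expm" and constant:
        q = scheme.rate_matrix({sp: a[0] for sp, a in tracks.items()})
        prop = expm(q.T * dt_s)
        for i in range(n_steps):
            y = prop @ y
            occ[i + 1] = y
    elif method == "expm":
        for i in range(n_steps):
            q = scheme.rate_matrix({sp: a[i] for sp, a in tracks.items()})
            y = expm(q.T * dt_s) @ y
            occ[i + 1] = y
    elif method == "rk4":
        qmax = 0.0
        for i in range(n_steps):
            q = scheme.rate_matrix({sp: a[i] for sp, a in tracks.items()}).T
            qmax = max(qmax, float(np.abs(np.diag(q)).max()))
            if qmax * dt_s > 2.0:
                raise SchemeError(
                    f"rk4 unstable: max rate {qmax:.3g}/s times dt "
                    f"{dt_s:.3g}s exceeds 2; reduce the step size"
                )
            k1 = q @ y
            k2 = q @ (y + 0.5 * dt_s * k1)
            k3 = q @ (y + 0.5 * dt_s * k2)
            k4 = q @ (y + dt_s * k3)
            y = y + dt_s / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            occ[i + 1] = y
    else:
        raise SchemeError(f"unknown method {method!r}")

    sums = occ.sum(axis=1)
    if np.any(np.abs(sums - 1) > 1e-6) or np.any(occ < -1e-6):
        raise SchemeError("occupancies left the probability simplex")
    times = np.arange(n_steps + 1) * dt_ms
    return times, occ


def sealed_box_binding_ode(
    n_glu: int,
    n_transporters: int,
    volume_um3: float,
    k_on: float,
    k_off: float,
    t_ms: np.ndarray,
) -> np.ndarray:
    """Deterministic bound-count time course in a sealed well-mixed box.

    Mass-action ODE for reversible binding with depletion of both pools
    (no translocation); the independent oracle for the particle engine's
    bimolecular calibration.  Returns bound counts at ``t_ms``.
    """
    vol_l = volume_um3 * 1e-15
    kon_count = k_on / (AVOGADRO * vol_l)  # per-pair rate, s^-1

    def rhs(t, y):
        b = y[0]
        return [kon_count * (n_glu - b) * (n_transporters - b) - k_off * b]

    sol = solve_ivp(rhs, (0.0, float(t_ms[-1]) * 1e-3), [0.0],
                    t_eval=np.asarray(t_ms) * 1e-3, rtol=1e-8, atol=1e-10)
    return sol.y[0]
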
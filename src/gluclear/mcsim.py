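"""Particle-based 3D Monte Carlo reaction-diffusion engine.

Simulates Brownian motion of glutamate molecules released from a point
source in the synaptic cleft of a simplified scene.  Molecules carry a
region-dependent diffusion coefficient (free cleft value inside the cleft
cylinder, tortuosity-reduced apparent value outside), reflect specularly
off every surface, and react stochastically with glutamate transporters on
the astrocytic processes (binding on collision, unbinding or permanent
translocation while bound, carrier reorientation).  Receptor pools on the
PSD can optionally participate as reversible surface buffers.

Collision geometry uses the exact parametric solids of the scene builder
(truncated spheres, rectangular slabs, world box) rather than the
measurement meshes, so reflections are exact and mass conservation holds
to the integer count at every step.

Units: lengths μm, time ms internally (configuration uses the customary
μs time step and cm²/s diffusion coefficients).
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
from numba import njit

from .geometry import Scene, SceneSolids
from .kinetics import AVOGADRO, KineticScheme, TransporterParams

__all__ = [
    "SimConfig",
    "TortuosityBudget",
    "SimResult",
    "SeedAggregate",
    "SimulationError",
    "run_simulation",
    "run_calibration_box",
    "estimate_free_diffusion_msd",
    "compute_concentration_timecourse",
    "aggregate_seeds",
    "count_centroid",
]


class SimulationError(RuntimeError):
    """Configuration or runtime failure of the particle engine."""


@dataclass(frozen=True)
class TortuosityBudget:
    """Decomposition of the neuropil tortuosity λ into geometric, viscous
    and occupancy-correction components.  Stored as provenance metadata:
    the engine takes the printed cleft/extracellular diffusion coefficients
    literally and never recombines these factors."""

    lambda_total: float = 1.6
    lambda_g: float = 1.48
    lambda_v: float = 1.38
    lambda_x: float = 1.11
    occupied_fraction: float = 0.18

    def validate(self) -> None:
        for name in ("lambda_total", "lambda_g", "lambda_v", "lambda_x"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be >= 1")
        if not 0 <= self.occupied_fraction <= 1:
            raise SimulationError("occupied_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Engine settings.

    dt_us × n_iterations spans the simulated window (defaults: 10 μs ×
    5,000 = 50 ms).  Diffusion coefficients are given in cm²/s as is
    customary; the cleft uses the free-solution value and everywhere else
    the apparent (tortuosity-corrected) value applies.
    """

    dt_us: float = 10.0
    n_iterations: int = 5000
    n_molecules: int = 2000
    n_seeds: int = 300
    d_cleft_cm2s: float = 3.3e-6
    d_extra_cm2s: float = 1.41e-6
    record_stride: int = 1
    release_offset_nm: float = 1.0
    apply_q10: bool = True
    include_receptors: bool = False
    max_reflections: int = 10
    tortuosity: TortuosityBudget = field(default_factory=TortuosityBudget)

    def validate(self) -> None:
        if min(self.dt_us, self.n_iterations, self.n_molecules) <= 0:
            raise SimulationError("dt, iterations and molecules must be > 0")
        if self.d_cleft_cm2s <= 0 or self.d_extra_cm2s <= 0:
            raise SimulationError("diffusion coefficients must be > 0")
        if self.record_stride < 1:
            raise SimulationError("record_stride must be >= 1")
        self.tortuosity.validate()

    @property
    def dt_ms(self) -> float:
        return self.dt_us * 1e-3

    @property
    def d_cleft_um2_ms(self) -> float:
        return self.d_cleft_cm2s * 1e5

    @property
    def d_extra_um2_ms(self) -> float:
        return self.d_extra_cm2s * 1e5

    @property
    def span_ms(self) -> float:
        return self.dt_ms * self.n_iterations

    def content_hash(self, scene_spec=None) -> str:
        payload = repr(asdict(self))
        if scene_spec is not None:
            payload += repr(scene_spec)
        return hashlib.sha1(payload.encode()).hexdigest()[:16]


@dataclass
class SimResult:
    """Per-timestep species counts and cumulative reaction tallies.

    At every recorded step ``cleft_free + extra_free + bound +
    receptor_bound + translocated == n_molecules``.
    """

    time_ms: np.ndarray
    cleft_free: np.ndarray
    extra_free: np.ndarray
    bound: np.ndarray
    receptor_bound: np.ndarray
    translocated: np.ndarray
    cum_bind: np.ndarray
    cum_unbind: np.ndarray
    cum_transloc: np.ndarray
    n_molecules: int
    seed: int
    config_hash: str
    clamped_steps: int = 0

    def free_total(self) -> np.ndarray:
        return self.cleft_free + self.extra_free

    def check_conservation(self) -> None:
        total = (self.cleft_free + self.extra_free + self.bound
                 + self.receptor_bound + self.translocated)
        if not np.all(total == self.n_molecules):
            bad = int(np.argmax(total != self.n_molecules))
            raise SimulationError(
                f"mass conservation violated at record {bad}: {total[bad]} "
                f"!= {self.n_molecules}"
            )
        for cum in (self.cum_bind, self.cum_unbind, self.cum_transloc):
            if np.any(np.diff(cum) < 0):
                raise SimulationError("cumulative tallies must be non-decreasing")

    _SERIES = ("time_ms", "cleft_free", "extra_free", "bound",
               "receptor_bound", "translocated",
               "cum_bind", "cum_unbind", "cum_transloc")

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            ts = fh.create_group("timeseries")
            for name in self._SERIES:
                ts.create_dataset(name, data=getattr(self, name))
            meta = fh.create_group("meta")
            meta.attrs["n_molecules"] = self.n_molecules
            meta.attrs["seed"] = self.seed
            meta.attrs["config_hash"] = self.config_hash
            meta.attrs["clamped_steps"] = self.clamped_steps

    @classmethod
    def from_hdf5(cls, path) -> "SimResult":
        with h5py.File(path, "r") as fh:
            kw = {name: fh["timeseries"][name][...] for name in cls._SERIES}
            meta = fh["meta"].attrs
            return cls(**kw, n_molecules=int(meta["n_molecules"]),
                       seed=int(meta["seed"]),
                       config_hash=str(meta["config_hash"]),
                       clamped_steps=int(meta["clamped_steps"]))


@dataclass
class SeedAggregate:
    """Pointwise mean ± SEM of recorded series across seeds."""

    time_ms: np.ndarray
    mean: dict[str, np.ndarray]
    sem: dict[str, np.ndarray]
    n_seeds: int
    config_hash: str


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

_EPS = 1e-7   # push-off distance from surfaces after reflection, μm
_TINY = 1e-12


@njit(cache=False)
def _simulate_kernel(
    seed,
    n_steps,
    stride,
    n_mol,
    sig_cleft,
    sig_extra,
    world_half,
    cleft_hh,
    cleft_r2,
    has_terminals,
    pre_cz, pre_r, pre_a2,
    post_cz, post_r, post_a2,
    astro_cos, astro_sin,
    rho_in, thick, half_w, half_h,
    nt, p_bind,
    p_evt, frac_off, p_reorient,
    psd_r2, pool_sites, pool_pbind, pool_poff,
    init_mode, release_z,
    max_refl,
    counts, cums,
):
    np.random.seed(seed)
    n_astro = astro_cos.shape[0]
    n_pools = pool_sites.shape[0]

    x = np.empty(n_mol)
    y = np.empty(n_mol)
    z = np.empty(n_mol)
    state = np.zeros(n_mol, dtype=np.int64)   # 0 free, 1 bound, 2 transloc, 3 rbound
    bproc = np.full(n_mol, -1, dtype=np.int64)
    bx = np.zeros(n_mol)
    by = np.zeros(n_mol)
    bz = np.zeros(n_mol)
    bnx = np.zeros(n_mol)
    bny = np.zeros(n_mol)
    bnz = np.zeros(n_mol)

    n_bound = np.zeros(max(n_astro, 1), dtype=np.int64)
    t_in = np.zeros(max(n_astro, 1), dtype=np.int64)
    pool_bound = np.zeros(max(n_pools, 1), dtype=np.int64)

    if init_mode == 0:
        for i in range(n_mol):
            x[i] = 0.0
            y[i] = 0.0
            z[i] = release_z
    else:
        # uniform over the box, rejecting solid interiors (slabs only in
        # calibration mode; terminals are disabled there)
        for i in range(n_mol):
            while True:
                px = (np.random.random() * 2.0 - 1.0) * world_half
                py = (np.random.random() * 2.0 - 1.0) * world_half
                pz = (np.random.random() * 2.0 - 1.0) * world_half
                inside = False
                for k in range(n_astro):
                    lx = astro_cos[k] * px + astro_sin[k] * py
                    ly = -astro_sin[k] * px + astro_cos[k] * py
                    if (rho_in < lx < rho_in + thick and -half_w < ly < half_w
                            and -half_h < pz < half_h):
                        inside = True
                        break
                if not inside:
                    x[i] = px
                    y[i] = py
                    z[i] = pz
                    break

    cum_bind = 0
    cum_unbind = 0
    cum_transloc = 0
    clamps = 0
    leak = -1

    n_rec = counts.shape[0]
    rec = 0
    # record initial state
    ncf = 0
    nef = 0
    for i in range(n_mol):
        if z[i] * z[i] <= cleft_hh * cleft_hh and x[i] * x[i] + y[i] * y[i] <= cleft_r2:
            ncf += 1
        else:
            nef += 1
    counts[0, 0] = ncf
    counts[0, 1] = nef
    rec = 1

    for step in range(n_steps):
        # --- bound-molecule events -------------------------------------
        for i in range(n_mol):
            s = state[i]
            if s == 1:
                if np.random.random() < p_evt:
                    k = bproc[i]
                    if np.random.random() < frac_off:
                        state[i] = 0
                        x[i] = bx[i] + 1e-3 * bnx[i]
                        y[i] = by[i] + 1e-3 * bny[i]
                        z[i] = bz[i] + 1e-3 * bnz[i]
                        n_bound[k] -= 1
                        cum_unbind += 1
                    else:
                        state[i] = 2
                        n_bound[k] -= 1
                        t_in[k] += 1
                        cum_transloc += 1
            elif s == 3:
                k = bproc[i]
                if np.random.random() < pool_poff[k]:
                    state[i] = 0
                    x[i] = bx[i] + 1e-3 * bnx[i]
                    y[i] = by[i] + 1e-3 * bny[i]
                    z[i] = bz[i] + 1e-3 * bnz[i]
                    pool_bound[k] -= 1

        # --- carrier reorientation -------------------------------------
        for k in range(n_astro):
            if t_in[k] > 0:
                n_re = np.random.binomial(t_in[k], p_reorient)
                t_in[k] -= n_re

        # --- diffusion with reflections and surface binding ------------
        for i in range(n_mol):
            if state[i] != 0:
                continue
            in_cleft = (z[i] * z[i] <= cleft_hh * cleft_hh
                        and x[i] * x[i] + y[i] * y[i] <= cleft_r2)
            sig = sig_cleft if in_cleft else sig_extra
            dx = sig * np.random.normal()
            dy = sig * np.random.normal()
            dz = sig * np.random.normal()
            px = x[i]
            py = y[i]
            pz = z[i]

            done = False
            for bounce in range(max_refl):
                best_t = 2.0
                nx = 0.0
                ny = 0.0
                nz = 0.0
                surf = -1       # 0 world, 1 pre-sph, 2 pre-disc, 3 post-sph,
                                # 4 post-disc, 10+k astro slab k
                hit_proc = -1

                # world box
                if dx > 0.0 and px + dx > world_half:
                    t = (world_half - px) / dx
                    if _TINY < t < best_t:
                        best_t = t; nx = -1.0; ny = 0.0; nz = 0.0; surf = 0
                elif dx < 0.0 and px + dx < -world_half:
                    t = (-world_half - px) / dx
                    if _TINY < t < best_t:
                        best_t = t; nx = 1.0; ny = 0.0; nz = 0.0; surf = 0
                if dy > 0.0 and py + dy > world_half:
                    t = (world_half - py) / dy
                    if _TINY < t < best_t:
                        best_t = t; nx = 0.0; ny = -1.0; nz = 0.0; surf = 0
                elif dy < 0.0 and py + dy < -world_half:
                    t = (-world_half - py) / dy
                    if _TINY < t < best_t:
                        best_t = t; nx = 0.0; ny = 1.0; nz = 0.0; surf = 0
                if dz > 0.0 and pz + dz > world_half:
                    t = (world_half - pz) / dz
                    if _TINY < t < best_t:
                        best_t = t; nx = 0.0; ny = 0.0; nz = -1.0; surf = 0
                elif dz < 0.0 and pz + dz < -world_half:
                    t = (-world_half - pz) / dz
                    if _TINY < t < best_t:
                        best_t = t; nx = 0.0; ny = 0.0; nz = 1.0; surf = 0

                if has_terminals:
                    a2 = dx * dx + dy * dy + dz * dz
                    # presynaptic sphere portion (z <= -cleft_hh)
                    cx = px
                    cy = py
                    cz = pz - pre_cz
                    b2 = 2.0 * (cx * dx + cy * dy + cz * dz)
                    c2 = cx * cx + cy * cy + cz * cz - pre_r * pre_r
                    if a2 > 0.0 and c2 > 0.0:
                        disc = b2 * b2 - 4.0 * a2 * c2
                        if disc > 0.0:
                            t = (-b2 - math.sqrt(disc)) / (2.0 * a2)
                            if _TINY < t < best_t:
                                hz = pz + t * dz
                                if hz <= -cleft_hh + 1e-9:
                                    hx = px + t * dx
                                    hy = py + t * dy
                                    best_t = t
                                    nx = hx / pre_r
                                    ny = hy / pre_r
                                    nz = (hz - pre_cz) / pre_r
                                    surf = 1
                    # presynaptic flat face (disc at z = -cleft_hh, from above)
                    if dz < 0.0 and pz >= -cleft_hh and pz + dz < -cleft_hh:
                        t = (-cleft_hh - pz) / dz
                        if _TINY < t < best_t:
                            hx = px + t * dx
                            hy = py + t * dy
                            if hx * hx + hy * hy <= pre_a2:
                                best_t = t; nx = 0.0; ny = 0.0; nz = 1.0; surf = 2
                    # postsynaptic sphere cap (z >= cleft_hh)
                    cz = pz - post_cz
                    b2 = 2.0 * (cx * dx + cy * dy + cz * dz)
                    c2 = cx * cx + cy * cy + cz * cz - post_r * post_r
                    if a2 > 0.0 and c2 > 0.0:
                        disc = b2 * b2 - 4.0 * a2 * c2
                        if disc > 0.0:
                            t = (-b2 - math.sqrt(disc)) / (2.0 * a2)
                            if _TINY < t < best_t:
                                hz = pz + t * dz
                                if hz >= cleft_hh - 1e-9:
                                    hx = px + t * dx
                                    hy = py + t * dy
                                    best_t = t
                                    nx = hx / post_r
                                    ny = hy / post_r
                                    nz = (hz - post_cz) / post_r
                                    surf = 3
                    # postsynaptic flat face (disc at z = +cleft_hh, from below)
                    if dz > 0.0 and pz <= cleft_hh and pz + dz > cleft_hh:
                        t = (cleft_hh - pz) / dz
                        if _TINY < t < best_t:
                            hx = px + t * dx
                            hy = py + t * dy
                            if hx * hx + hy * hy <= post_a2:
                                best_t = t; nx = 0.0; ny = 0.0; nz = -1.0; surf = 4

                # astrocytic slabs
                for k in range(n_astro):
                    ck = astro_cos[k]
                    sk = astro_sin[k]
                    lx = ck * px + sk * py
                    ly = -sk * px + ck * py
                    ldx = ck * dx + sk * dy
                    ldy = -sk * dx + ck * dy
                    t_en = 0.0
                    t_ex = 1.0e30
                    ax_hit = -1
                    ax_sign = 0.0
                    ok = True
                    # local x axis
                    if ldx != 0.0:
                        t1 = (rho_in - lx) / ldx
                        t2 = (rho_in + thick - lx) / ldx
                        if t1 > t2:
                            tmp = t1; t1 = t2; t2 = tmp
                        if t1 > t_en:
                            t_en = t1
                            ax_hit = 0
                            ax_sign = -1.0 if ldx > 0.0 else 1.0
                        if t2 < t_ex:
                            t_ex = t2
                    elif lx < rho_in or lx > rho_in + thick:
                        ok = False
                    if ok:
                        if ldy != 0.0:
                            t1 = (-half_w - ly) / ldy
                            t2 = (half_w - ly) / ldy
                            if t1 > t2:
                                tmp = t1; t1 = t2; t2 = tmp
                            if t1 > t_en:
                                t_en = t1
                                ax_hit = 1
                                ax_sign = -1.0 if ldy > 0.0 else 1.0
                            if t2 < t_ex:
                                t_ex = t2
                        elif ly < -half_w or ly > half_w:
                            ok = False
                    if ok:
                        if dz != 0.0:
                            t1 = (-half_h - pz) / dz
                            t2 = (half_h - pz) / dz
                            if t1 > t2:
                                tmp = t1; t1 = t2; t2 = tmp
                            if t1 > t_en:
                                t_en = t1
                                ax_hit = 2
                                ax_sign = -1.0 if dz > 0.0 else 1.0
                            if t2 < t_ex:
                                t_ex = t2
                        elif pz < -half_h or pz > half_h:
                            ok = False
                    if (ok and ax_hit >= 0 and t_en > _TINY and t_en <= 1.0
                            and t_en < t_ex and t_en < best_t):
                        best_t = t_en
                        surf = 10 + k
                        hit_proc = k
                        if ax_hit == 0:
                            nx = ck * ax_sign
                            ny = sk * ax_sign
                            nz = 0.0
                        elif ax_hit == 1:
                            nx = -sk * ax_sign
                            ny = ck * ax_sign
                            nz = 0.0
                        else:
                            nx = 0.0
                            ny = 0.0
                            nz = ax_sign

                if best_t > 1.0:
                    px += dx
                    py += dy
                    pz += dz
                    done = True
                    break

                hx = px + best_t * dx
                hy = py + best_t * dy
                hz = pz + best_t * dz

                if surf >= 10:
                    k = hit_proc
                    if nt[k] > 0:
                        free = nt[k] - n_bound[k] - t_in[k]
                        if free > 0:
                            pb = p_bind[k] * free / nt[k]
                            if np.random.random() < pb:
                                state[i] = 1
                                bproc[i] = k
                                bx[i] = hx
                                by[i] = hy
                                bz[i] = hz
                                bnx[i] = nx
                                bny[i] = ny
                                bnz[i] = nz
                                n_bound[k] += 1
                                cum_bind += 1
                                done = True
                                break
                elif surf == 4 and n_pools > 0:
                    if hx * hx + hy * hy <= psd_r2:
                        bound_here = False
                        for q in range(n_pools):
                            freeq = pool_sites[q] - pool_bound[q]
                            if freeq > 0:
                                pb = pool_pbind[q] * freeq / pool_sites[q]
                                if np.random.random() < pb:
                                    state[i] = 3
                                    bproc[i] = q
                                    bx[i] = hx
                                    by[i] = hy
                                    bz[i] = hz
                                    bnx[i] = nx
                                    bny[i] = ny
                                    bnz[i] = nz
                                    pool_bound[q] += 1
                                    bound_here = True
                                    break
                        if bound_here:
                            done = True
                            break

                # specular reflection of the residual displacement
                rx = (1.0 - best_t) * dx
                ry = (1.0 - best_t) * dy
                rz = (1.0 - best_t) * dz
                dot = rx * nx + ry * ny + rz * nz
                dx = rx - 2.0 * dot * nx
                dy = ry - 2.0 * dot * ny
                dz = rz - 2.0 * dot * nz
                px = hx + _EPS * nx
                py = hy + _EPS * ny
                pz = hz + _EPS * nz

            if not done and state[i] == 0:
                clamps += 1  # reflection budget exhausted: keep last valid pos

            if state[i] == 0:
                if (px < -world_half - 1e-6 or px > world_half + 1e-6
                        or py < -world_half - 1e-6 or py > world_half + 1e-6
                        or pz < -world_half - 1e-6 or pz > world_half + 1e-6):
                    leak = i
                x[i] = px
                y[i] = py
                z[i] = pz

        # --- record -----------------------------------------------------
        if (step + 1) % stride == 0 and rec < n_rec:
            ncf = 0
            nef = 0
            nb = 0
            nrb = 0
            ntr = 0
            for i in range(n_mol):
                s = state[i]
                if s == 0:
                    if (z[i] * z[i] <= cleft_hh * cleft_hh
                            and x[i] * x[i] + y[i] * y[i] <= cleft_r2):
                        ncf += 1
                    else:
                        nef += 1
                elif s == 1:
                    nb += 1
                elif s == 2:
                    ntr += 1
                else:
                    nrb += 1
            counts[rec, 0] = ncf
            counts[rec, 1] = nef
            counts[rec, 2] = nb
            counts[rec, 3] = nrb
            counts[rec, 4] = ntr
            cums[rec, 0] = cum_bind
            cums[rec, 1] = cum_unbind
            cums[rec, 2] = cum_transloc
            rec += 1
        if leak >= 0:
            break

    return leak, clamps


@njit(cache=False)
def _msd_kernel(seed, n_particles, n_steps, sigma, box_half, stride, msd_out):
    np.random.seed(seed)
    x = np.zeros(n_particles)
    y = np.zeros(n_particles)
    z = np.zeros(n_particles)
    rec = 0
    for step in range(n_steps):
        for i in range(n_particles):
            x[i] += sigma * np.random.normal()
            y[i] += sigma * np.random.normal()
            z[i] += sigma * np.random.normal()
            if box_half > 0.0:
                # reflective box via folding
                for _ in range(100):
                    moved = False
                    if x[i] > box_half:
                        x[i] = 2 * box_half - x[i]; moved = True
                    elif x[i] < -box_half:
                        x[i] = -2 * box_half - x[i]; moved = True
                    if y[i] > box_half:
                        y[i] = 2 * box_half - y[i]; moved = True
                    elif y[i] < -box_half:
                        y[i] = -2 * box_half - y[i]; moved = True
                    if z[i] > box_half:
                        z[i] = 2 * box_half - z[i]; moved = True
                    elif z[i] < -box_half:
                        z[i] = -2 * box_half - z[i]; moved = True
                    if not moved:
                        break
        if (step + 1) % stride == 0:
            acc = 0.0
            for i in range(n_particles):
                acc += x[i] * x[i] + y[i] * y[i] + z[i] * z[i]
            msd_out[rec] = acc / n_particles
            rec += 1
    return rec


# ---------------------------------------------------------------------------
# Python drivers
# ---------------------------------------------------------------------------


def _transporter_rates(scheme_or_params) -> tuple[float, float, float, float]:
    """Extract (k_on, k_off, k_trans, k_reorient) from params or a scheme."""
    if scheme_or_params is None:
        scheme_or_params = TransporterParams()
    if isinstance(scheme_or_params, TransporterParams):
        p = scheme_or_params
        return p.k_on, p.k_off, p.k_trans, p.k_reorient
    scheme: KineticScheme = scheme_or_params
    k_on = k_off = k_trans = k_reorient = 0.0
    for t in scheme.transitions:
        if t.ligand is not None:
            k_on = t.rate
        elif t.effect == "release":
            k_off = t.rate
        elif t.source == "TG":
            k_trans = t.rate
        else:
            k_reorient = t.rate
    return k_on, k_off, k_trans, k_reorient


def _binding_probability(k_on: float, density: float, d_um2_ms: float,
                         dt_ms: float) -> float:
    """Per-collision binding probability for a transporter-covered wall.

    Matches the mass-action on-rate in the well-mixed limit: the wall
    collision flux of Brownian particles is c·sqrt(D/(π·dt)) per area, so
    p = k_on'·σ·sqrt(π·dt/D) with k_on' the per-pair rate in μm³/s.
    """
    kon_um3_s = k_on * 1e15 / AVOGADRO
    d_um2_s = d_um2_ms * 1e3
    dt_s = dt_ms * 1e-3
    return kon_um3_s * density * math.sqrt(math.pi * dt_s / d_um2_s)


def _event_probs(k_off, k_trans, k_reorient, dt_ms):
    dt_s = dt_ms * 1e-3
    k_tot = k_off + k_trans
    p_evt = 1.0 - math.exp(-k_tot * dt_s) if k_tot > 0 else 0.0
    frac_off = k_off / k_tot if k_tot > 0 else 0.0
    p_re = 1.0 - math.exp(-k_reorient * dt_s)
    return p_evt, frac_off, p_re


def run_simulation(
    scene: Scene,
    config: SimConfig | None = None,
    seed: int = 0,
    transporter: KineticScheme | TransporterParams | None = None,
    transporter_density: float | None = None,
) -> SimResult:
    """Run one seed of the reaction–diffusion simulation on a scene.

    Deterministic for a fixed (scene, config, seed).  ``transporter_density``
    overrides the scene's surface density (e.g. the reduced-uptake 5,400
    μm⁻² condition) without rebuilding the scene.  Raises
    :class:`SimulationError` on a leak or an unstable binding probability.
    """
    config = config or SimConfig()
    config.validate()
    params = transporter if isinstance(transporter, TransporterParams) else None
    if params is None and transporter is None:
        params = TransporterParams()
    if params is not None:
        k_on, k_off, k_trans, k_reorient = (params.k_on, params.k_off,
                                            params.k_trans, params.k_reorient)
        if config.apply_q10:
            f = params.q10 ** ((params.t_sim - params.t_ref) / 10.0)
            k_on, k_off, k_trans, k_reorient = (k_on * f, k_off * f,
                                                k_trans * f, k_reorient * f)
    else:
        k_on, k_off, k_trans, k_reorient = _transporter_rates(transporter)

    s = scene.solids
    dt = config.dt_ms
    n_astro = s.n_astro
    astro_meshes = scene.meshes.get("astrocyte", [])
    nt = np.zeros(max(n_astro, 1), dtype=np.int64)
    p_bind = np.zeros(max(n_astro, 1))
    density = (transporter_density if transporter_density is not None
               else scene.spec.transporter_density)
    for k in range(n_astro):
        from .geometry import mesh_surface_area
        area = mesh_surface_area(astro_meshes[k])
        nt[k] = int(round(density * area))
        sigma_eff = nt[k] / area if area > 0 else 0.0
        p_bind[k] = _binding_probability(k_on, sigma_eff,
                                         config.d_extra_um2_ms, dt)
        if p_bind[k] > 1.0:
            raise SimulationError(
                f"binding probability {p_bind[k]:.3f} > 1 on process {k}; "
                "reduce dt or the transporter density"
            )
    p_evt, frac_off, p_re = _event_probs(k_off, k_trans, k_reorient, dt)

    pools_sites = np.zeros(0, dtype=np.int64)
    pools_pbind = np.zeros(0)
    pools_poff = np.zeros(0)
    if config.include_receptors:
        sites = []
        pbs = []
        poffs = []
        psd_area = math.pi * s.psd_radius**2
        for dens, r_kon, r_koff in (
            (scene.spec.glua_psd_density, 1e7, 5000.0),
            (scene.spec.glun_psd_density, 1e7, 50.0),
        ):
            n_sites = int(round(dens * psd_area))
            if n_sites > 0:
                sites.append(n_sites)
                pbs.append(_binding_probability(r_kon, n_sites / psd_area,
                                                config.d_cleft_um2_ms, dt))
                poffs.append(1.0 - math.exp(-r_koff * dt * 1e-3))
        pools_sites = np.array(sites, dtype=np.int64)
        pools_pbind = np.array(pbs)
        pools_poff = np.array(poffs)

    sig_cleft = math.sqrt(2.0 * config.d_cleft_um2_ms * dt)
    sig_extra = math.sqrt(2.0 * config.d_extra_um2_ms * dt)
    release_z = -s.cleft_hh + config.release_offset_nm * 1e-3

    n_rec = config.n_iterations // config.record_stride + 1
    counts = np.zeros((n_rec, 5), dtype=np.int64)
    cums = np.zeros((n_rec, 3), dtype=np.int64)

    leak, clamps = _simulate_kernel(
        seed, config.n_iterations, config.record_stride, config.n_molecules,
        sig_cleft, sig_extra,
        s.world_half, s.cleft_hh, s.cleft_radius**2,
        True,
        s.pre_center_z, s.pre_radius, s.apposition_radius**2,
        s.post_center_z, s.post_radius, s.apposition_radius**2,
        np.array([math.cos(a) for a in s.astro_angles]),
        np.array([math.sin(a) for a in s.astro_angles]),
        s.astro_rho_in, s.astro_thickness, s.astro_half_width,
        s.astro_half_height,
        nt[:n_astro] if n_astro else nt[:1] * 0,
        p_bind[:n_astro] if n_astro else p_bind[:1] * 0,
        p_evt, frac_off, p_re,
        s.psd_radius**2, pools_sites, pools_pbind, pools_poff,
        0, release_z,
        config.max_reflections,
        counts, cums,
    )
    if leak >= 0:
        raise SimulationError(f"particle {leak} escaped the world box")

    time_ms = np.arange(n_rec) * config.record_stride * dt
    result = SimResult(
        time_ms=time_ms,
        cleft_free=counts[:, 0].copy(),
        extra_free=counts[:, 1].copy(),
        bound=counts[:, 2].copy(),
        receptor_bound=counts[:, 3].copy(),
        translocated=counts[:, 4].copy(),
        cum_bind=cums[:, 0].copy(),
        cum_unbind=cums[:, 1].copy(),
        cum_transloc=cums[:, 2].copy(),
        n_molecules=config.n_molecules,
        seed=seed,
        config_hash=config.content_hash(scene.spec),
        clamped_steps=clamps,
    )
    result.check_conservation()
    return result


def run_calibration_box(
    n_molecules: int,
    n_transporters: int,
    k_on: float,
    k_off: float,
    config: SimConfig | None = None,
    seed: int = 0,
    box_edge: float = 1.0,
    slab_area: float = 0.5,
) -> SimResult:
    """Sealed-box binding calibration: one transporter-covered slab, no uptake.

    Molecules start uniformly distributed; transporters bind and unbind
    with no translocation (k_trans = 0).  The deterministic reference is
    :func:`gluclear.kinetics.sealed_box_binding_ode` with the same counts.
    """
    config = config or SimConfig(n_molecules=n_molecules, apply_q10=False)
    config.validate()
    dt = config.dt_ms
    half_w = math.sqrt(slab_area) / 2.0
    half_h = math.sqrt(slab_area) / 2.0
    thick = 0.05
    # two large faces dominate; effective density over total slab area
    area_total = 2 * slab_area + 2 * thick * (2 * half_w + 2 * half_h)
    sigma = n_transporters / area_total
    p_bind = _binding_probability(k_on, sigma, config.d_extra_um2_ms, dt)
    if p_bind > 1.0:
        raise SimulationError(f"binding probability {p_bind:.3f} > 1")
    p_evt, frac_off, p_re = _event_probs(k_off, 0.0, 1.0, dt)

    n_rec = config.n_iterations // config.record_stride + 1
    counts = np.zeros((n_rec, 5), dtype=np.int64)
    cums = np.zeros((n_rec, 3), dtype=np.int64)
    leak, clamps = _simulate_kernel(
        seed, config.n_iterations, config.record_stride, n_molecules,
        math.sqrt(2.0 * config.d_extra_um2_ms * dt),
        math.sqrt(2.0 * config.d_extra_um2_ms * dt),
        box_edge / 2.0, 0.0, 0.0,
        False,
        0.0, 0.1, 0.0, 0.0, 0.1, 0.0,
        np.array([1.0]), np.array([0.0]),
        -thick / 2.0, thick, half_w, half_h,
        np.array([n_transporters], dtype=np.int64),
        np.array([p_bind]),
        p_evt, frac_off, p_re,
        0.0, np.zeros(0, dtype=np.int64), np.zeros(0), np.zeros(0),
        1, 0.0,
        config.max_reflections,
        counts, cums,
    )
    if leak >= 0:
        raise SimulationError(f"particle {leak} escaped the box")
    time_ms = np.arange(n_rec) * config.record_stride * dt
    result = SimResult(
        time_ms=time_ms,
        cleft_free=counts[:, 0].copy(),
        extra_free=counts[:, 1].copy(),
        bound=counts[:, 2].copy(),
        receptor_bound=counts[:, 3].copy(),
        translocated=counts[:, 4].copy(),
        cum_bind=cums[:, 0].copy(),
        cum_unbind=cums[:, 1].copy(),
        cum_transloc=cums[:, 2].copy(),
        n_molecules=n_molecules,
        seed=seed,
        config_hash=config.content_hash(),
        clamped_steps=clamps,
    )
    result.check_conservation()
    return result


def estimate_free_diffusion_msd(
    d_um2_ms: float,
    n_particles: int = 10_000,
    n_steps: int = 1000,
    dt_ms: float = 0.01,
    seed: int = 0,
    box_half: float = 0.0,
    stride: int = 10,
) -> float:
    """Recover D from the Einstein relation ⟨r²⟩ = 6·D·t in an empty world.

    ``box_half`` > 0 encloses the walk in a reflective box (used to check
    that a box much larger than the diffusion length does not bias the
    estimate).  Returns the fitted D in μm²/ms.
    """
    if d_um2_ms < 0:
        raise SimulationError("D must be >= 0")
    if d_um2_ms == 0:
        return 0.0
    sigma = math.sqrt(2.0 * d_um2_ms * dt_ms)
    n_rec = n_steps // stride
    msd = np.zeros(n_rec)
    _msd_kernel(seed, n_particles, n_steps, sigma, box_half, stride, msd)
    t = (np.arange(1, n_rec + 1) * stride) * dt_ms
    # regression through the origin
    slope = float(np.dot(t, msd) / np.dot(t, t))
    return slope / 6.0


def compute_concentration_timecourse(counts: np.ndarray,
                                     region_volume_um3: float) -> np.ndarray:
    """Convert molecule counts to molar concentration: n / (N_A · V)."""
    if region_volume_um3 <= 0:
        raise SimulationError("region volume must be > 0")
    vol_l = region_volume_um3 * 1e-15
    return np.asarray(counts, dtype=float) / (AVOGADRO * vol_l)


def count_centroid(time_ms: np.ndarray, counts: np.ndarray) -> float:
    """First temporal moment ⟨t⟩ = Σ t·n(t) / Σ n(t) of a count time course."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise SimulationError("zero total count; centroid undefined")
    return float(np.dot(time_ms, counts) / total)


def aggregate_seeds(results: list[SimResult]) -> SeedAggregate:
    """Pointwise mean and SEM (sample SD / √n) of recorded series."""
    if not results:
        raise SimulationError("no results to aggregate")
    h0 = results[0].config_hash
    if any(r.config_hash != h0 for r in results):
        raise SimulationError("results carry mixed config hashes")
    t0 = results[0].time_ms
    if any(len(r.time_ms) != len(t0) for r in results):
        raise SimulationError("results have mismatched time bases")
    n = len(results)
    mean = {}
    sem = {}
    for name in ("cleft_free", "extra_free", "bound", "receptor_bound",
                 "translocated", "cum_bind", "cum_unbind", "cum_transloc"):
        stack = np.stack([getattr(r, name) for r in results]).astype(float)
        mean[name] = stack.mean(axis=0)
        if n == 1:
            warnings.warn("single seed: SEM reported as 0")
            sem[name] = np.zeros_like(mean[name])
        else:
            sem[name] = stack.std(axis=0, ddof=1) / math.sqrt(n)
    return SeedAggregate(time_ms=t0.copy(), mean=mean, sem=sem,
                         n_seeds=n, config_hash=h0)
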
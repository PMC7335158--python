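"""Strings-and-binders (SBS) polymer model and equilibrium sampler.

The SBS model represents a chromatin locus as a self-avoiding bead chain
carrying typed ("colored") binding sites.  Diffusing binder particles of the
same types bridge cognate sites; above a threshold binder concentration the
chain undergoes a coil -> globule phase-separation transition, the central
physical phenomenon this package models.

The equilibrium ensembles are produced by a Metropolis Monte Carlo sampler of
the canonical (Boltzmann) distribution on a classical coarse-grained polymer
energy function:

* consecutive beads: FENE bonds, ``U = -0.5 k R0^2 ln(1 - (r/R0)^2)``
  with ``k = 30 kBT/sigma^2`` and ``R0 = 1.5 sigma``;
* every particle pair: purely repulsive WCA (truncated-shifted Lennard-Jones,
  cutoff ``2^(1/6) sigma``);
* binder-bead: an attractive square well of range ``1.5 sigma`` with depth
  ``e_specific`` when binder type equals the bead color and ``e_unspecific``
  (for any bead) otherwise.

All lengths are in units of the bead diameter sigma and energies in kBT
(kBT = 1 in reduced units).  The binders live in a periodic cubic box whose
default edge equals the gyration radius of the corresponding self-avoiding
walk (SAW); chain coordinates are kept unwrapped and binder-bead separations
use the minimum-image convention.

Move set per sweep: one attempted local displacement per bead and per binder
(a fraction of binder moves are box-uniform teleports, a symmetric proposal
that accelerates binder diffusion), plus a small number of chain pivot moves.
Pivot moves greatly accelerate equilibration of open conformations and can be
disabled when a diffusive, local-move-only dynamics is wanted (time series).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

__all__ = [
    "PolymerModel",
    "SimulationParams",
    "Conformation",
    "Ensemble",
    "PhaseScanResult",
    "gyration_radius",
    "saw_reference_rg",
    "binding_energy",
    "simulate_ensemble",
    "simulate_trajectory",
    "phase_scan",
]

# engine constants (reduced units); the original study defers these to the
# classical polymer-physics literature, so they are package configuration
FENE_K = 30.0
FENE_R0 = 1.5
WCA_CUT2 = 2.0 ** (1.0 / 3.0)  # squared cutoff of the WCA repulsion
WELL_RANGE2 = 1.5 ** 2  # squared range of the binder-bead attractive well

# Particle core sizes.  A bead is a 30-kb chromatin window - itself a
# polymer blob that can partially interpenetrate a neighbour - so its
# repulsive core is softer than its nominal diameter; a binder stands for a
# protein complex, much smaller than a bead.  Core diameters scale the WCA
# repulsion (bead-bead BEAD_CORE, binder-bead mixed, binder-binder
# BINDER_DIAMETER); the attractive well keeps its 1.5 sigma range and bonds
# their nominal length.
BEAD_CORE = 0.8
BINDER_DIAMETER = 0.5
_CC2 = BEAD_CORE**2  # squared bead-bead core scale
_BB2 = ((BEAD_CORE + BINDER_DIAMETER) / 2.0) ** 2  # squared binder-bead core
_PP2 = BINDER_DIAMETER**2  # squared binder-binder core scale

# Default box edge as a multiple of the SAW gyration radius.  The box must
# comfortably exceed the open-coil extent (~sqrt(6) Rg): binder-bead
# interactions use the minimum-image convention, and a box smaller than the
# coil lets one binder bridge beads through periodic images, which distorts
# the coil branch of the transition.
BOX_FACTOR = 2.5

AVOGADRO = 6.02214076e23


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class PolymerModel:
    """Bead-level coloring of a chain partitioned into genomic windows.

    ``colors[b] == 0`` marks a bead with only unspecific affinity; values
    ``1..n`` are the specific binding-site types.  Bead ``b`` belongs to
    window ``b // r`` (0-based, half-open genomic bins).
    """

    colors: np.ndarray
    n: int
    r: int = 1
    resolution_bp: int = 30_000
    origin_bp: int = 0
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        self.colors = np.asarray(self.colors, dtype=np.int64)
        if self.colors.ndim != 1 or self.colors.size == 0:
            raise ValueError("colors must be a non-empty 1-D sequence")
        if self.colors.size % self.r:
            raise ValueError("len(colors) must be a multiple of r")
        if self.n < 0 or self.r < 1:
            raise ValueError("need n >= 0 and r >= 1")
        if self.colors.min() < 0 or self.colors.max() > self.n:
            raise ValueError("color values must lie in [0, n]")

    @property
    def n_beads(self) -> int:
        return int(self.colors.size)

    @property
    def n_windows(self) -> int:
        return self.n_beads // self.r

    def window_of(self, bead: int) -> int:
        return bead // self.r

    def color_counts(self) -> np.ndarray:
        """(n_windows, n+1) matrix of per-window bead counts per color."""
        out = np.zeros((self.n_windows, self.n + 1), dtype=np.int64)
        for b, c in enumerate(self.colors):
            out[b // self.r, c] += 1
        return out

    def window_starts_bp(self) -> np.ndarray:
        return self.origin_bp + self.resolution_bp * np.arange(self.n_windows)


@dataclass
class SimulationParams:
    """Monte Carlo run parameters.

    ``concentration`` is the molar binder concentration (mol/l, the study
    scans 0-0.5 umol/l); affinities are in kBT with the study's weak
    biochemical ranges 3.1-8.0 (specific) and 0-2.7 (unspecific).  The binder
    count is ``round(c * V * NA)`` with the box volume ``V`` obtained from
    ``box_edge`` (sigma units) and ``sigma_nm``.
    """

    concentration: float = 0.0
    e_specific: float = 8.0
    e_unspecific: float = 0.5
    box_edge: float | None = None  # None -> BOX_FACTOR * SAW reference Rg
    n_steps: int = 4000
    equilibration_steps: int = 1500
    seed: int = 0
    dt: float = 0.01  # nominal MD time (tau units) represented by one sweep
    sigma_nm: float = 45.0
    bead_step: float = 0.25
    binder_step: float = 0.5
    teleport_fraction: float = 0.3
    pivots_per_sweep: int | None = None  # None -> max(2, n_beads // 25)
    samples_per_chain: int = 1
    decorrelation_sweeps: int = 200
    # Overshoot-and-relax equilibration: run the first part of the
    # equilibration at strengthened affinities (overshoot_factor) to push
    # the chain over the nucleation barrier of the first-order-like
    # collapse, then relax at the target affinities.  Where the coil is the
    # stable phase the overshoot globule dissolves quickly (verified by
    # compact-start control runs), so sub-threshold points are not biased.
    anneal_equilibration: bool = True
    overshoot_factor: float = 1.5
    overshoot_fraction: float = 0.3
    # Initial chain configuration: "open" (SAW-like random walk) or
    # "compact" (confined walk inside a globule-sized ball).  The collapse
    # is first-order-like and both phases are long-lived at desk-scale
    # sampling, so state-labeled ensembles are prepared in the basin of the
    # phase being sampled; unbiased scans keep open starts.
    initial_state: str = "open"

    def validate(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.box_edge is not None and self.box_edge <= 0:
            raise ValueError("box_edge must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1 or self.equilibration_steps < 0:
            raise ValueError("invalid step counts")
        if self.e_specific < self.e_unspecific:
            raise ValueError("e_specific must be >= e_unspecific")


@dataclass
class Conformation:
    """A single-molecule 3D configuration (sigma units)."""

    coords: np.ndarray  # (n_beads, 3)
    time_stamp: int = 0
    binder_coords: np.ndarray | None = None
    binder_types: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_beads, 3)")


@dataclass
class Ensemble:
    """A statistical ensemble of single-molecule conformations."""

    conformations: list[Conformation]
    params: SimulationParams
    model: PolymerModel
    state_label: str = "unlabeled"  # {coil, globule, unlabeled}
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.conformations)

    def coords_stack(self) -> np.ndarray:
        return np.stack([c.coords for c in self.conformations])


@dataclass
class PhaseScanResult:
    """Order parameters along a binder-concentration scan."""

    concentrations: np.ndarray
    rg_norm: np.ndarray  # mean Rg / SAW reference Rg
    binding_energy: np.ndarray  # mean total binder-polymer energy (kBT)
    mean_separation_score: np.ndarray
    threshold: float | None  # midpoint of the max-drop interval, or None
    threshold_interval: tuple[float, float] | None = None
    ensembles: list[Ensemble] | None = None

    @property
    def has_transition(self) -> bool:
        return self.threshold is not None


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _wca(r2: float) -> float:
    if r2 >= WCA_CUT2:
        return 0.0
    inv6 = 1.0 / (r2 * r2 * r2)
    return 4.0 * (inv6 * inv6 - inv6) + 1.0


@njit(cache=True, fastmath=True)
def _fene(r2: float) -> float:
    if r2 >= FENE_R0 * FENE_R0:
        return 1.0e30
    return -0.5 * FENE_K * FENE_R0 * FENE_R0 * math.log(1.0 - r2 / (FENE_R0 * FENE_R0))


@njit(cache=True, fastmath=True)
def _min_image_d2(dx: float, dy: float, dz: float, L: float) -> float:
    dx -= L * round(dx / L)
    dy -= L * round(dy / L)
    dz -= L * round(dz / L)
    return dx * dx + dy * dy + dz * dz


@njit(cache=True)
def _bead_energy(i, pos, beads, colors, binders, btypes, L, e_s, e_u):
    """Energy of bead i at position pos against everything else."""
    n = beads.shape[0]
    e = 0.0
    # bonds
    for j in (i - 1, i + 1):
        if 0 <= j < n:
            dx = pos[0] - beads[j, 0]
            dy = pos[1] - beads[j, 1]
            dz = pos[2] - beads[j, 2]
            e += _fene(dx * dx + dy * dy + dz * dz)
            if e > 1.0e29:
                return e
    # excluded volume vs all other beads (unwrapped chain coordinates)
    for j in range(n):
        if j == i:
            continue
        dx = pos[0] - beads[j, 0]
        dy = pos[1] - beads[j, 1]
        dz = pos[2] - beads[j, 2]
        e += _wca((dx * dx + dy * dy + dz * dz) / _CC2)
    # binder wells + cores (minimum image)
    ci = colors[i]
    for p in range(binders.shape[0]):
        d2 = _min_image_d2(
            pos[0] - binders[p, 0], pos[1] - binders[p, 1], pos[2] - binders[p, 2], L
        )
        e += _wca(d2 / _BB2)
        if d2 < WELL_RANGE2:
            e -= e_s if btypes[p] == ci else e_u
    return e


@njit(cache=True)
def _binder_energy(p, pos, beads, colors, binders, btypes, L, e_s, e_u):
    e = 0.0
    for q in range(binders.shape[0]):
        if q == p:
            continue
        d2 = _min_image_d2(
            pos[0] - binders[q, 0], pos[1] - binders[q, 1], pos[2] - binders[q, 2], L
        )
        e += _wca(d2 / _PP2)
    tp = btypes[p]
    for i in range(beads.shape[0]):
        d2 = _min_image_d2(
            pos[0] - beads[i, 0], pos[1] - beads[i, 1], pos[2] - beads[i, 2], L
        )
        e += _wca(d2 / _BB2)
        if d2 < WELL_RANGE2:
            e -= e_s if colors[i] == tp else e_u
    return e


@njit(cache=True)
def _binding_energy_kernel(beads, colors, binders, btypes, L, e_s, e_u):
    """Sum of the active attractive well terms (non-positive)."""
    e = 0.0
    for p in range(binders.shape[0]):
        tp = btypes[p]
        for i in range(beads.shape[0]):
            d2 = _min_image_d2(
                binders[p, 0] - beads[i, 0],
                binders[p, 1] - beads[i, 1],
                binders[p, 2] - beads[i, 2],
                L,
            )
            if d2 < WELL_RANGE2:
                e -= e_s if colors[i] == tp else e_u
    return e


@njit(cache=True)
def _rg_kernel(beads):
    n = beads.shape[0]
    cx = beads[:, 0].mean()
    cy = beads[:, 1].mean()
    cz = beads[:, 2].mean()
    s = 0.0
    for i in range(n):
        dx = beads[i, 0] - cx
        dy = beads[i, 1] - cy
        dz = beads[i, 2] - cz
        s += dx * dx + dy * dy + dz * dz
    return math.sqrt(s / n)


@njit(cache=True)
def _pivot_delta(lo, hi, rot, pivot, beads, colors, binders, btypes, L, e_s, e_u):
    """Energy change of rigidly rotating beads [lo, hi) about bead `pivot`.

    Bond lengths inside the moved block and the bond at the pivot are
    invariant under the rotation, so only non-bonded terms are evaluated.
    """
    n = beads.shape[0]
    de = 0.0
    px, py, pz = beads[pivot, 0], beads[pivot, 1], beads[pivot, 2]
    for i in range(lo, hi):
        ox = beads[i, 0] - px
        oy = beads[i, 1] - py
        oz = beads[i, 2] - pz
        nx = rot[0, 0] * ox + rot[0, 1] * oy + rot[0, 2] * oz + px
        ny = rot[1, 0] * ox + rot[1, 1] * oy + rot[1, 2] * oz + py
        nz = rot[2, 0] * ox + rot[2, 1] * oy + rot[2, 2] * oz + pz
        ci = colors[i]
        for j in range(n):
            if lo <= j < hi or j == pivot:
                continue
            dxo = beads[i, 0] - beads[j, 0]
            dyo = beads[i, 1] - beads[j, 1]
            dzo = beads[i, 2] - beads[j, 2]
            dxn = nx - beads[j, 0]
            dyn = ny - beads[j, 1]
            dzn = nz - beads[j, 2]
            de += _wca((dxn * dxn + dyn * dyn + dzn * dzn) / _CC2) - _wca(
                (dxo * dxo + dyo * dyo + dzo * dzo) / _CC2
            )
            if de > 1.0e29:
                return de
        for p in range(binders.shape[0]):
            d2o = _min_image_d2(
                beads[i, 0] - binders[p, 0],
                beads[i, 1] - binders[p, 1],
                beads[i, 2] - binders[p, 2],
                L,
            )
            d2n = _min_image_d2(
                nx - binders[p, 0], ny - binders[p, 1], nz - binders[p, 2], L
            )
            de += _wca(d2n / _BB2) - _wca(d2o / _BB2)
            dep = e_s if btypes[p] == ci else e_u
            if d2n < WELL_RANGE2:
                de -= dep
            if d2o < WELL_RANGE2:
                de += dep
    return de


@njit(cache=True)
def _apply_pivot(lo, hi, rot, pivot, beads):
    px, py, pz = beads[pivot, 0], beads[pivot, 1], beads[pivot, 2]
    for i in range(lo, hi):
        ox = beads[i, 0] - px
        oy = beads[i, 1] - py
        oz = beads[i, 2] - pz
        beads[i, 0] = rot[0, 0] * ox + rot[0, 1] * oy + rot[0, 2] * oz + px
        beads[i, 1] = rot[1, 0] * ox + rot[1, 1] * oy + rot[1, 2] * oz + py
        beads[i, 2] = rot[2, 0] * ox + rot[2, 1] * oy + rot[2, 2] * oz + pz


@njit(cache=True)
def _random_rotation(angle_scale):
    """Rotation about a random axis, angle uniform in angle_scale*(-pi, pi]."""
    # axis from two uniforms (Marsaglia), angle from the third
    while True:
        a = 2.0 * np.random.random() - 1.0
        b = 2.0 * np.random.random() - 1.0
        s = a * a + b * b
        if s < 1.0:
            break
    ux = 2.0 * a * math.sqrt(1.0 - s)
    uy = 2.0 * b * math.sqrt(1.0 - s)
    uz = 1.0 - 2.0 * s
    th = angle_scale * (2.0 * np.random.random() - 1.0) * math.pi
    c = math.cos(th)
    si = math.sin(th)
    one_c = 1.0 - c
    rot = np.empty((3, 3))
    rot[0, 0] = c + ux * ux * one_c
    rot[0, 1] = ux * uy * one_c - uz * si
    rot[0, 2] = ux * uz * one_c + uy * si
    rot[1, 0] = uy * ux * one_c + uz * si
    rot[1, 1] = c + uy * uy * one_c
    rot[1, 2] = uy * uz * one_c - ux * si
    rot[2, 0] = uz * ux * one_c - uy * si
    rot[2, 1] = uz * uy * one_c + ux * si
    rot[2, 2] = c + uz * uz * one_c
    return rot


@njit(cache=True)
def _run_sweeps(
    beads,
    colors,
    binders,
    btypes,
    L,
    e_s,
    e_u,
    n_sweeps,
    bead_step,
    binder_step,
    teleport_fraction,
    pivots_per_sweep,
    record_every,
    seed,
):
    """Run Metropolis sweeps in place; return (rg_trace, be_trace)."""
    np.random.seed(seed)
    n = beads.shape[0]
    npart = binders.shape[0]
    n_rec = n_sweeps // record_every + 1
    rg_trace = np.empty(n_rec)
    be_trace = np.empty(n_rec)
    rec = 0
    cand = np.empty(3)
    for sweep in range(n_sweeps):
        for _ in range(n):
            i = np.random.randint(0, n)
            cand[0] = beads[i, 0] + bead_step * (2.0 * np.random.random() - 1.0)
            cand[1] = beads[i, 1] + bead_step * (2.0 * np.random.random() - 1.0)
            cand[2] = beads[i, 2] + bead_step * (2.0 * np.random.random() - 1.0)
            e_old = _bead_energy(i, beads[i], beads, colors, binders, btypes, L, e_s, e_u)
            e_new = _bead_energy(i, cand, beads, colors, binders, btypes, L, e_s, e_u)
            de = e_new - e_old
            if de <= 0.0 or np.random.random() < math.exp(-de):
                beads[i, 0] = cand[0]
                beads[i, 1] = cand[1]
                beads[i, 2] = cand[2]
        for _ in range(npart):
            p = np.random.randint(0, npart)
            if np.random.random() < teleport_fraction:
                cand[0] = L * np.random.random()
                cand[1] = L * np.random.random()
                cand[2] = L * np.random.random()
            else:
                cand[0] = binders[p, 0] + binder_step * (2.0 * np.random.random() - 1.0)
                cand[1] = binders[p, 1] + binder_step * (2.0 * np.random.random() - 1.0)
                cand[2] = binders[p, 2] + binder_step * (2.0 * np.random.random() - 1.0)
            e_old = _binder_energy(
                p, binders[p], beads, colors, binders, btypes, L, e_s, e_u
            )
            e_new = _binder_energy(p, cand, beads, colors, binders, btypes, L, e_s, e_u)
            de = e_new - e_old
            if de <= 0.0 or np.random.random() < math.exp(-de):
                binders[p, 0] = cand[0] % L
                binders[p, 1] = cand[1] % L
                binders[p, 2] = cand[2] % L
        n_piv = pivots_per_sweep if n > 2 else 0
        for _ in range(n_piv):
            pivot = np.random.randint(1, n - 1)
            # most pivots use small angles: full-angle pivots are almost
            # never accepted in collapsed states, while small rotations let
            # whole globules approach, merge and rearrange
            scale = 1.0 if np.random.random() < 0.3 else 0.08
            rot = _random_rotation(scale)
            # rotate the shorter tail for efficiency
            if pivot < n // 2:
                lo, hi = 0, pivot
            else:
                lo, hi = pivot + 1, n
            de = _pivot_delta(
                lo, hi, rot, pivot, beads, colors, binders, btypes, L, e_s, e_u
            )
            if de <= 0.0 or (de < 1.0e29 and np.random.random() < math.exp(-de)):
                _apply_pivot(lo, hi, rot, pivot, beads)
        if sweep % record_every == 0:
            rg_trace[rec] = _rg_kernel(beads)
            be_trace[rec] = _binding_energy_kernel(
                beads, colors, binders, btypes, L, e_s, e_u
            )
            rec += 1
    return rg_trace[:rec], be_trace[:rec]


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------


def gyration_radius(conf: Conformation | np.ndarray) -> float:
    """Root-mean-square distance of the beads from their centroid."""
    coords = conf.coords if isinstance(conf, Conformation) else np.asarray(conf, float)
    if coords.size == 0:
        raise ValueError("empty conformation")
    centred = coords - coords.mean(axis=0)
    return float(np.sqrt((centred**2).sum(axis=1).mean()))


def binding_energy(
    conf: Conformation,
    model: PolymerModel,
    params: SimulationParams,
) -> float:
    """Total binder-polymer attractive energy of one configuration (kBT)."""
    if conf.binder_coords is None or len(conf.binder_coords) == 0:
        return 0.0
    L = (
        params.box_edge
        if params.box_edge
        else BOX_FACTOR * saw_reference_rg(model.n_beads)
    )
    return float(
        _binding_energy_kernel(
            np.ascontiguousarray(conf.coords),
            model.colors,
            np.ascontiguousarray(conf.binder_coords, dtype=np.float64),
            np.ascontiguousarray(conf.binder_types, dtype=np.int64),
            float(L),
            params.e_specific,
            params.e_unspecific,
        )
    )


# ---------------------------------------------------------------------------
# simulation drivers
# ---------------------------------------------------------------------------


def _child_seeds(seed: int, k: int) -> np.ndarray:
    """k reproducible independent sub-seeds, each < 2**31."""
    return np.random.SeedSequence(seed).generate_state(k, dtype=np.uint32) % (2**31 - 1)


def _initial_chain(
    n_beads: int, rng: np.random.Generator, compact: bool = False
) -> np.ndarray:
    """Chain start with ~unit bonds: open random walk or confined ball."""
    if not compact:
        steps = rng.normal(size=(n_beads - 1, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        steps *= 0.97
        coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        return np.ascontiguousarray(coords)
    radius = max(1.6, 0.62 * n_beads ** (1.0 / 3.0) * 1.15)
    coords = np.zeros((n_beads, 3))
    pos = np.zeros(3)
    for i in range(1, n_beads):
        while True:
            step = rng.normal(size=3)
            step *= 0.97 / np.linalg.norm(step)
            cand = pos + step
            if np.linalg.norm(cand) < radius:
                coords[i] = cand
                pos = cand
                break
    return np.ascontiguousarray(coords)


def binder_count_for(params: SimulationParams, n_beads: int) -> tuple[int, float]:
    """(binder count P, box edge in sigma) implied by the parameters."""
    L = params.box_edge if params.box_edge else BOX_FACTOR * saw_reference_rg(n_beads)
    volume_l = (L * params.sigma_nm * 1e-9) ** 3 * 1e3  # m^3 -> litres
    P = int(round(params.concentration * volume_l * AVOGADRO))
    return P, float(L)


def _stationary(trace: np.ndarray, scale_floor: float) -> bool:
    """Split-half plateau check: halves' means within 5% of the trace scale."""
    if trace.size < 4:
        return True
    h = trace.size // 2
    m1, m2 = trace[:h].mean(), trace[h:].mean()
    scale = max(abs(trace.mean()), scale_floor)
    return abs(m1 - m2) <= 0.05 * scale


def _run_one_chain(
    model: PolymerModel,
    params: SimulationParams,
    seed: int,
    n_samples: int,
    L: float,
    P: int,
    pivots: int,
) -> tuple[list[Conformation], np.ndarray, np.ndarray, bool]:
    rng = np.random.default_rng(seed)
    beads = _initial_chain(model.n_beads, rng, compact=params.initial_state == "compact")
    binders = np.ascontiguousarray(rng.uniform(0.0, L, size=(P, 3)))
    # binder types cycle through the specific colors present in the model
    present = [c for c in range(1, model.n + 1)] or [0]
    btypes = np.ascontiguousarray(
        np.array([present[p % len(present)] for p in range(P)], dtype=np.int64)
    )
    record_every = 10
    if params.anneal_equilibration and params.equilibration_steps >= 100:
        n_over = int(params.overshoot_fraction * params.equilibration_steps)
        n_relax = params.equilibration_steps - n_over
        eq_seeds = _child_seeds(seed + 555, 2)
        rg_a, be_a = _run_sweeps(
            beads,
            model.colors,
            binders,
            btypes,
            L,
            params.overshoot_factor * params.e_specific,
            params.overshoot_factor * params.e_unspecific,
            n_over,
            params.bead_step,
            params.binder_step,
            params.teleport_fraction,
            pivots,
            record_every,
            int(eq_seeds[0]),
        )
        rg_b, be_b = _run_sweeps(
            beads,
            model.colors,
            binders,
            btypes,
            L,
            params.e_specific,
            params.e_unspecific,
            n_relax,
            params.bead_step,
            params.binder_step,
            params.teleport_fraction,
            pivots,
            record_every,
            int(eq_seeds[1]),
        )
        eq_rg = np.concatenate([rg_a, rg_b])
        eq_be = np.concatenate([be_a, be_b])
    else:
        eq_rg, eq_be = _run_sweeps(
            beads,
            model.colors,
            binders,
            btypes,
            L,
            params.e_specific,
            params.e_unspecific,
            params.equilibration_steps,
            params.bead_step,
            params.binder_step,
            params.teleport_fraction,
            pivots,
            record_every,
            int(seed),
        )
    confs: list[Conformation] = []
    rg_tr = [eq_rg]
    be_tr = [eq_be]
    sample_sweeps = max(params.n_steps - params.equilibration_steps, 1)
    gap = max(params.decorrelation_sweeps, sample_sweeps // max(n_samples, 1))
    sub = _child_seeds(seed + 1, n_samples)
    for s in range(n_samples):
        rg_b, be_b = _run_sweeps(
            beads,
            model.colors,
            binders,
            btypes,
            L,
            params.e_specific,
            params.e_unspecific,
            gap,
            params.bead_step,
            params.binder_step,
            params.teleport_fraction,
            pivots,
            record_every,
            int(sub[s]),
        )
        rg_tr.append(rg_b)
        be_tr.append(be_b)
        confs.append(
            Conformation(
                coords=beads.copy(),
                time_stamp=params.equilibration_steps + (s + 1) * gap,
                binder_coords=binders.copy(),
                binder_types=btypes.copy(),
            )
        )
    rg_trace = np.concatenate(rg_tr)
    be_trace = np.concatenate(be_tr)
    post = rg_trace[len(eq_rg) :] if len(rg_trace) > len(eq_rg) + 3 else rg_trace
    post_be = be_trace[len(eq_be) :] if len(be_trace) > len(eq_be) + 3 else be_trace
    ok = _stationary(post, 1.0) and _stationary(post_be, 1.0)
    return confs, rg_trace, be_trace, ok


def simulate_ensemble(
    model: PolymerModel,
    params: SimulationParams,
    n_molecules: int,
    use_pivot: bool = True,
) -> Ensemble:
    """Sample an equilibrium ensemble of single-molecule conformations.

    ``n_molecules`` conformations are drawn after equilibration from
    ``ceil(n_molecules / params.samples_per_chain)`` independent chains, each
    with its own seed derived from ``params.seed``.  Gyration-radius and
    binding-energy traces are recorded and a split-half plateau check flags
    runs that did not reach stationarity (``metadata['stationarity_ok']``).
    """
    params.validate()
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    P, L = binder_count_for(params, model.n_beads)
    pivots = (
        params.pivots_per_sweep
        if params.pivots_per_sweep is not None
        else max(2, model.n_beads // 10)
    )
    if not use_pivot:
        pivots = 0
    per_chain = max(1, params.samples_per_chain)
    n_chains = math.ceil(n_molecules / per_chain)
    seeds = _child_seeds(params.seed, n_chains)
    confs: list[Conformation] = []
    rg_traces, be_traces = [], []
    all_ok = True
    for ci in range(n_chains):
        want = min(per_chain, n_molecules - len(confs))
        chain_confs, rg_tr, be_tr, ok = _run_one_chain(
            model, params, int(seeds[ci]), want, L, P, pivots
        )
        confs.extend(chain_confs)
        rg_traces.append(rg_tr)
        be_traces.append(be_tr)
        all_ok = all_ok and ok
    if not all_ok:
        warnings.warn(
            "stationarity check failed on at least one chain; "
            "increase n_steps/equilibration_steps",
            RuntimeWarning,
            stacklevel=2,
        )
    ens = Ensemble(conformations=confs, params=params, model=model)
    ens.metadata.update(
        {
            "binder_count": P,
            "box_edge": L,
            "rg_traces": rg_traces,
            "binding_energy_traces": be_traces,
            "stationarity_ok": all_ok,
        }
    )
    return ens


def simulate_trajectory(
    model: PolymerModel,
    params: SimulationParams,
    n_frames: int,
    frame_every: int = 50,
    use_pivot: bool = False,
) -> tuple[list[Conformation], float]:
    """Steady-state time series of one molecule.

    Local-displacement dynamics only by default (pivot moves scramble the
    physical, diffusive relaxation the time correlations measure).  Returns
    the frames and the frame spacing in nominal MD time units
    (``frame_every * params.dt``).
    """
    params.validate()
    P, L = binder_count_for(params, model.n_beads)
    rng = np.random.default_rng(params.seed)
    beads = _initial_chain(model.n_beads, rng, compact=params.initial_state == "compact")
    binders = np.ascontiguousarray(rng.uniform(0.0, L, size=(P, 3)))
    present = [c for c in range(1, model.n + 1)] or [0]
    btypes = np.ascontiguousarray(
        np.array([present[p % len(present)] for p in range(P)], dtype=np.int64)
    )
    seeds = _child_seeds(params.seed, n_frames + 1)
    # overshoot-and-relax equilibration (pivots allowed here: only the
    # steady state matters, not the approach to it)
    if params.anneal_equilibration and params.equilibration_steps >= 100:
        n_over = int(params.overshoot_fraction * params.equilibration_steps)
        phases = [
            (params.overshoot_factor, n_over),
            (1.0, params.equilibration_steps - n_over),
        ]
    else:
        phases = [(1.0, params.equilibration_steps)]
    eq_seeds = _child_seeds(params.seed + 555, len(phases))
    for ci, (f, n_sw) in enumerate(phases):
        if n_sw < 1:
            continue
        _run_sweeps(
            beads,
            model.colors,
            binders,
            btypes,
            L,
            f * params.e_specific,
            f * params.e_unspecific,
            n_sw,
            params.bead_step,
            params.binder_step,
            params.teleport_fraction,
            max(2, model.n_beads // 10),
            n_sw,
            int(eq_seeds[ci]),
        )
    pivots = max(2, model.n_beads // 25) if use_pivot else 0
    frames = [
        Conformation(
            coords=beads.copy(),
            time_stamp=0,
            binder_coords=binders.copy(),
            binder_types=btypes.copy(),
        )
    ]
    for f in range(1, n_frames):
        _run_sweeps(
            beads,
            model.colors,
            binders,
            btypes,
            L,
            params.e_specific,
            params.e_unspecific,
            frame_every,
            params.bead_step,
            params.binder_step,
            params.teleport_fraction,
            pivots,
            frame_every,
            int(seeds[f]),
        )
        frames.append(
            Conformation(
                coords=beads.copy(),
                time_stamp=f * frame_every,
                binder_coords=binders.copy(),
                binder_types=btypes.copy(),
            )
        )
    return frames, frame_every * params.dt


# ---------------------------------------------------------------------------
# SAW reference
# ---------------------------------------------------------------------------

_SAW_CACHE: dict[int, float] = {}


def saw_reference_rg(
    n_beads: int, n_samples: int = 300, seed: int = 20_201_703
) -> float:
    """Mean gyration radius of the binder-free (self-avoiding) chain.

    Estimated once per chain length by a pivot-accelerated simulation of the
    chain with zero binders and cached.  Used both as the normalization of
    the order parameter ``Rg / Rg_SAW`` and as the default box edge.
    """
    if n_beads < 2:
        raise ValueError("need at least 2 beads")
    if n_beads in _SAW_CACHE:
        return _SAW_CACHE[n_beads]
    rng = np.random.default_rng(seed + n_beads)
    beads = _initial_chain(n_beads, rng)
    binders = np.zeros((0, 3))
    btypes = np.zeros(0, dtype=np.int64)
    colors = np.zeros(n_beads, dtype=np.int64)
    pivots = max(4, n_beads // 4)
    # equilibration: a few hundred accepted pivots fully decorrelate a SAW
    _run_sweeps(
        beads, colors, binders, btypes, 1.0e6, 0.0, 0.0,
        200, 0.25, 0.5, 0.0, pivots, 200, int(seed % (2**31 - 1)),
    )
    vals = np.empty(n_samples)
    sub = _child_seeds(seed + 7 * n_beads, n_samples)
    for s in range(n_samples):
        _run_sweeps(
            beads, colors, binders, btypes, 1.0e6, 0.0, 0.0,
            20, 0.25, 0.5, 0.0, pivots, 20, int(sub[s]),
        )
        vals[s] = _rg_kernel(beads)
    out = float(vals.mean())
    _SAW_CACHE[n_beads] = out
    return out


def saw_ensemble(n_beads: int, n_molecules: int, seed: int = 0) -> Ensemble:
    """Equilibrium SAW (binder-free) conformations, pivot-sampled."""
    model = PolymerModel(colors=np.zeros(n_beads, dtype=np.int64), n=0, r=1)
    gap = max(20, n_beads // 4)
    params = SimulationParams(
        concentration=0.0,
        seed=seed,
        n_steps=graceful_total(n_beads, n_molecules, gap),
        equilibration_steps=max(300, n_beads),
        samples_per_chain=max(1, n_molecules // 8),
        decorrelation_sweeps=gap,
        anneal_equilibration=False,
    )
    return simulate_ensemble(model, params, n_molecules)


def graceful_total(n_beads: int, n_molecules: int, gap: int) -> int:
    per_chain = max(1, n_molecules // 8)
    return max(300, n_beads) + per_chain * gap + 10


# ---------------------------------------------------------------------------
# phase scan
# ---------------------------------------------------------------------------


def phase_scan(
    model: PolymerModel,
    concentration_grid: Sequence[float],
    params: SimulationParams,
    n_molecules: int = 30,
    su: int = 5,
    sl: int = 5,
    min_drop: float = 0.3,
    keep_ensembles: bool = False,
) -> PhaseScanResult:
    """Scan binder concentrations and locate the coil -> globule transition.

    A transition is reported when the SAW-normalized gyration radius
    decreases by at least ``min_drop`` over the scan; its threshold is the
    midpoint of the grid interval of maximal decrease.  Otherwise the
    threshold is reported absent (None), never fabricated.
    """
    from .metrics import distance_matrix, separation_score

    grid = np.asarray(list(concentration_grid), dtype=float)
    if grid.size < 4:
        raise ValueError("need at least 4 grid points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("concentration grid must be strictly increasing")
    rg_saw = saw_reference_rg(model.n_beads)
    seeds = _child_seeds(params.seed, grid.size)
    rg_norm = np.empty(grid.size)
    be = np.empty(grid.size)
    sep = np.empty(grid.size)
    ensembles = []
    for gi, c in enumerate(grid):
        p = replace(params, concentration=float(c), seed=int(seeds[gi]))
        ens = simulate_ensemble(model, p, n_molecules)
        rgs = [gyration_radius(cf) for cf in ens.conformations]
        rg_norm[gi] = np.mean(rgs) / rg_saw
        be[gi] = np.mean([binding_energy(cf, model, p) for cf in ens.conformations])
        scores = []
        for cf in ens.conformations:
            prof = separation_score(distance_matrix(cf, model), su=su, sl=sl)
            scores.append(np.nanmean(prof))
        sep[gi] = float(np.mean(scores))
        if keep_ensembles:
            ensembles.append(ens)
    drops = rg_norm[:-1] - rg_norm[1:]
    k = int(np.argmax(drops))
    if np.max(rg_norm) - np.min(rg_norm) >= min_drop:
        threshold = float(0.5 * (grid[k] + grid[k + 1]))
        interval = (float(grid[k]), float(grid[k + 1]))
    else:
        threshold, interval = None, None
    return PhaseScanResult(
        concentrations=grid,
        rg_norm=rg_norm,
        binding_energy=be,
        mean_separation_score=sep,
        threshold=threshold,
        threshold_interval=interval,
        ensembles=ensembles if keep_ensembles else None,
    )
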
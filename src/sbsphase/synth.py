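"""Synthetic ground truths and emulated datasets.

Every pipeline stage is testable without external data: this module builds
ground-truth colorings with controlled between-domain overlap, Poisson-noised
contact maps standing in for bulk Hi-C counts, and imaging-like single-cell
distance matrices with localization noise and probe dropout.  All generators
are deterministic per seed and carry their parameters as provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence
import warnings

import numpy as np

from .core import Ensemble, PolymerModel, SimulationParams, simulate_ensemble
from .metrics import DistanceMatrix, _window_centroids
from .prismr import (
    ContactMatrix,
    between_color_overlap,
    forward_contact_map,
    get_templates,
)

__all__ = [
    "SyntheticTruth",
    "ImagingEmulation",
    "RecoveryFixture",
    "generate_coloring",
    "generate_block_copolymer_control",
    "synthesize_hic",
    "synthesize_imaging",
    "bootstrap_binding_sites",
    "bootstrap_track",
    "make_recovery_fixture",
]


@dataclass
class SyntheticTruth:
    model: PolymerModel
    overlap_target: float | None
    realized_overlap: float
    generator_params: dict = field(default_factory=dict)


@dataclass
class ImagingEmulation:
    matrices: list[DistanceMatrix]
    nan_rate: float
    realized_nan_rate: float
    localization_noise_nm: float
    sigma_nm: float
    seed: int


@dataclass
class RecoveryFixture:
    truth: SyntheticTruth
    clean_map: ContactMatrix
    noisy_map: ContactMatrix
    coil: Ensemble
    globule: Ensemble
    imaging: ImagingEmulation
    manifest: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# colorings
# ---------------------------------------------------------------------------


def _enriched_colors(
    n_windows: int, n: int, r: int, tail: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample bead colors from successive trapezoidal color profiles.

    Color c has weight 1 inside its own region and a linear tail of width
    ``tail`` windows spilling into the neighbouring regions; overlapping
    tails make windows carry beads of several colors (for r > 1).
    """
    edges = np.linspace(0, n_windows, n + 1)
    centers = np.arange(n_windows) + 0.5
    weights = np.zeros((n_windows, n))
    for c in range(n):
        lo, hi = edges[c], edges[c + 1]
        inside = (centers >= lo) & (centers < hi)
        weights[inside, c] = 1.0
        if tail > 0:
            left = (centers < lo) & (centers >= lo - tail)
            weights[left, c] = np.maximum(
                weights[left, c], 1.0 - (lo - centers[left]) / tail
            )
            right = (centers >= hi) & (centers < hi + tail)
            weights[right, c] = np.maximum(
                weights[right, c], 1.0 - (centers[right] - hi) / tail
            )
    colors = np.zeros(n_windows * r, dtype=np.int64)
    for w in range(n_windows):
        p = weights[w]
        tot = p.sum()
        if tot <= 0:
            continue
        probs = p / tot
        colors[w * r : (w + 1) * r] = rng.choice(n, size=r, p=probs) + 1
    return colors


def generate_coloring(
    n_windows: int,
    n: int,
    r: int = 1,
    layout: str = "successive-enriched",
    overlap_target: float | None = None,
    seed: int = 0,
    custom_colors: Sequence[int] | None = None,
) -> SyntheticTruth:
    """Ground-truth coloring with colors enriched in successive regions.

    ``overlap_target`` (percent) tunes the mean window-overlap between
    different colors by widening the tails of each color's genomic profile;
    the realized overlap must land within +-10 points of the target or the
    generator raises with the feasible range.  ``layout='random'`` draws iid
    bead colors (the high-overlap control regime); ``layout='custom'`` wraps
    a user-provided coloring.
    """
    rng = np.random.default_rng(seed)
    params = {
        "n_windows": n_windows,
        "n": n,
        "r": r,
        "layout": layout,
        "overlap_target": overlap_target,
        "seed": seed,
    }
    if layout == "custom":
        if custom_colors is None:
            raise ValueError("layout='custom' requires custom_colors")
        model = PolymerModel(colors=np.asarray(custom_colors, np.int64), n=n, r=r)
        return SyntheticTruth(model, None, between_color_overlap(model), params)
    if layout == "random":
        colors = rng.integers(1, n + 1, size=n_windows * r).astype(np.int64)
        model = PolymerModel(colors=colors, n=n, r=r)
        return SyntheticTruth(model, None, between_color_overlap(model), params)
    if layout != "successive-enriched":
        raise ValueError(f"unknown layout {layout!r}")
    target = 0.0 if overlap_target is None else float(overlap_target)
    max_tail = 2.0 * n_windows / n
    best = None
    for tail in np.linspace(0.0, max_tail, 25):
        colors = _enriched_colors(n_windows, n, r, tail, np.random.default_rng(seed))
        model = PolymerModel(colors=colors, n=n, r=r)
        got = between_color_overlap(model)
        if best is None or abs(got - target) < abs(best[1] - target):
            best = (model, got, tail)
    model, got, tail = best
    if overlap_target is not None and abs(got - target) > 10.0:
        lo = between_color_overlap(
            PolymerModel(
                colors=_enriched_colors(n_windows, n, r, 0.0, np.random.default_rng(seed)),
                n=n, r=r,
            )
        )
        hi = between_color_overlap(
            PolymerModel(
                colors=_enriched_colors(
                    n_windows, n, r, max_tail, np.random.default_rng(seed)
                ),
                n=n, r=r,
            )
        )
        raise ValueError(
            f"overlap_target {target:.0f}% infeasible for n_windows={n_windows}, "
            f"n={n}, r={r}; feasible range is about [{lo:.0f}%, {hi:.0f}%]"
        )
    params["tail"] = float(tail)
    return SyntheticTruth(model, overlap_target, got, params)


def generate_block_copolymer_control(
    n_windows: int, n: int, r: int = 1, seed: int = 0
) -> SyntheticTruth:
    """Contiguous equal blocks, zero between-color overlap by construction."""
    truth = generate_coloring(
        n_windows, n, r, layout="successive-enriched", overlap_target=None, seed=seed
    )
    truth.generator_params["layout"] = "block-copolymer"
    return truth


# ---------------------------------------------------------------------------
# emulated datasets
# ---------------------------------------------------------------------------


def synthesize_hic(
    source: ContactMatrix, depth: float, seed: int = 0
) -> ContactMatrix:
    """Poisson-noised raw-count contact map from a probability map.

    Each upper-triangle element is drawn as Poisson(depth * probability) and
    mirrored, emulating finite sequencing depth; symmetry is exact.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    p = source.values
    W = p.shape[0]
    counts = np.zeros((W, W))
    iu = np.triu_indices(W, k=0)
    counts[iu] = rng.poisson(depth * p[iu])
    counts = np.triu(counts) + np.triu(counts, k=1).T
    return ContactMatrix(
        values=counts,
        resolution_bp=source.resolution_bp,
        origin_bp=source.origin_bp,
        chrom=source.chrom,
        normalization="raw",
    )


def synthesize_imaging(
    ens: Ensemble,
    nan_rate: float = 0.15,
    noise_nm: float = 50.0,
    sigma_nm: float = 45.0,
    seed: int = 0,
) -> ImagingEmulation:
    """Chromatin-tracing-like distance matrices from a simulated ensemble.

    Window centroids are scaled to nm, perturbed by isotropic Gaussian
    localization noise, and whole probes (rows/columns) are dropped to NaN
    independently per molecule at ``nan_rate``, the way tracing experiments
    lose probes.
    """
    if not 0 <= nan_rate < 1:
        raise ValueError("nan_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    matrices = []
    dropped = 0
    total = 0
    for conf in ens.conformations:
        cent = _window_centroids(conf, ens.model) * sigma_nm
        if noise_nm > 0:
            cent = cent + rng.normal(scale=noise_nm, size=cent.shape)
        d = np.sqrt(((cent[:, None] - cent[None]) ** 2).sum(-1))
        drop = rng.random(cent.shape[0]) < nan_rate
        d[drop, :] = np.nan
        d[:, drop] = np.nan
        dropped += int(drop.sum())
        total += cent.shape[0]
        matrices.append(
            DistanceMatrix(
                values=d,
                units="nm",
                resolution_bp=ens.model.resolution_bp,
                origin_bp=ens.model.origin_bp,
            )
        )
    return ImagingEmulation(
        matrices=matrices,
        nan_rate=nan_rate,
        realized_nan_rate=dropped / total if total else 0.0,
        localization_noise_nm=noise_nm,
        sigma_nm=sigma_nm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# bootstrap controls
# ---------------------------------------------------------------------------


def bootstrap_binding_sites(
    model: PolymerModel, n_reps: int = 1000, seed: int = 0
) -> list[np.ndarray]:
    """Randomized binding-domain replicates by position bootstrap.

    Per replicate and per color, the window positions of that color's sites
    are resampled with replacement; per-color site counts are preserved
    exactly.  Replicates are returned as (n_windows, n+1) occupancy-count
    matrices (resampling ignores the r-sites-per-window capacity, so they
    are profiles, not chain colorings).
    """
    rng = np.random.default_rng(seed)
    counts = model.color_counts()
    W, ncol1 = counts.shape
    reps = []
    for _ in range(n_reps):
        new = np.zeros_like(counts)
        for c in range(1, ncol1):
            positions = np.repeat(np.arange(W), counts[:, c])
            if positions.size:
                resampled = rng.choice(positions, size=positions.size, replace=True)
                np.add.at(new[:, c], resampled, 1)
        new[:, 0] = np.maximum(model.r - new[:, 1:].sum(axis=1), 0)
        reps.append(new)
    return reps


def bootstrap_track(track: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Position-bootstrap of a per-window site-count track (sum preserved)."""
    t = np.asarray(track, dtype=float)
    W = t.size
    n_sites = int(round(np.nansum(t)))
    if n_sites <= 0:
        return t.copy()
    weights = np.where(np.isfinite(t) & (t > 0), t, 0.0)
    probs = weights / weights.sum()
    out = np.zeros(W)
    np.add.at(out, rng.choice(W, size=n_sites, replace=True, p=probs), 1.0)
    return out


# ---------------------------------------------------------------------------
# end-to-end fixture
# ---------------------------------------------------------------------------


def make_recovery_fixture(
    n_windows: int = 60,
    n: int = 3,
    r: int = 1,
    depth: float = 1e4,
    n_molecules: int = 100,
    coil_concentration: float = 0.01e-6,
    globule_concentration: float = 0.5e-6,
    nan_rate: float = 0.15,
    noise_nm: float = 50.0,
    sigma_nm: float = 45.0,
    seed: int = 0,
    samples_per_chain: int = 10,
) -> RecoveryFixture:
    """One-call synthetic study: truth, noisy map, labeled ensembles, imaging.

    The ground truth is a successive-enriched coloring; its forward map plus
    Poisson noise is the inference input, and coil/globule ensembles of the
    truth chain are simulated at sub-/supra-threshold binder concentrations
    and labeled accordingly.  Fully seeded and byte-reproducible.
    """
    ss = np.random.SeedSequence(seed)
    s_truth, s_hic, s_coil, s_glob, s_img = (
        int(v) for v in ss.generate_state(5) % (2**31 - 1)
    )
    truth = generate_coloring(n_windows, n, r, seed=s_truth)
    templates = get_templates(n_windows, r)
    clean = forward_contact_map(truth.model, templates)
    noisy = synthesize_hic(clean, depth=depth, seed=s_hic)
    base = SimulationParams(
        n_steps=9000,
        equilibration_steps=5000,
        samples_per_chain=samples_per_chain,
        decorrelation_sweeps=150,
        sigma_nm=sigma_nm,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        coil = simulate_ensemble(
            truth.model,
            replace(base, concentration=coil_concentration, seed=s_coil),
            n_molecules,
        )
        globule = simulate_ensemble(
            truth.model,
            replace(base, concentration=globule_concentration, seed=s_glob),
            n_molecules,
        )
    coil.state_label = "coil"
    globule.state_label = "globule"
    imaging = synthesize_imaging(
        globule, nan_rate=nan_rate, noise_nm=noise_nm, sigma_nm=sigma_nm, seed=s_img
    )
    manifest = {
        "n_windows": n_windows,
        "n": n,
        "r": r,
        "depth": depth,
        "n_molecules": n_molecules,
        "coil_concentration": coil_concentration,
        "globule_concentration": globule_concentration,
        "nan_rate": nan_rate,
        "noise_nm": noise_nm,
        "sigma_nm": sigma_nm,
        "seed": seed,
    }
    return RecoveryFixture(
        truth=truth,
        clean_map=clean,
        noisy_map=noisy,
        coil=coil,
        globule=globule,
        imaging=imaging,
        manifest=manifest,
    )
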
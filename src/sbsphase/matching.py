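"""Optimal-rotation (Kabsch) RMSD comparison of conformation ensembles.

Each query 3D structure is associated to the reference structure of least
RMSD after centering, per-axis z-score normalization and optimal proper
rotation (no reflections: chirality is physical).  The matched-RMSD
distribution is compared against a null of all query-query pairs, matched
references carry thermodynamic state labels (coil / globule) used to
classify queries, and coil/globule mixture weights are fitted by resampling
mixture median distance matrices against a target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import Conformation, Ensemble
from .metrics import (
    DistanceMatrix,
    distance_corrected_r,
    median_distance_matrix,
    _window_centroids,
)

__all__ = [
    "RMSDAssignment",
    "MixtureFit",
    "kabsch_rmsd",
    "least_rmsd_assignment",
    "classify_states",
    "fit_mixture_weight",
]


@dataclass
class RMSDAssignment:
    pairs: list  # (query index, reference index, rmsd)
    matched_rmsd: np.ndarray
    null_rmsd: np.ndarray  # all query-query pairs
    coverage: float  # fraction of references matched by >= 1 query
    fraction_above_null_q1: float
    mw_pvalue: float
    skipped_queries: list = field(default_factory=list)


@dataclass
class MixtureFit:
    weight_coil: float
    grid: np.ndarray
    objective: np.ndarray  # r' of the mixture median matrix vs target
    ambiguous: bool = False
    rmsd_state_fractions: dict | None = None


# ---------------------------------------------------------------------------
# Kabsch
# ---------------------------------------------------------------------------


def _zscore(x: np.ndarray, per_axis: bool = False) -> np.ndarray:
    """Center and normalize one structure to unit scale.

    Isotropic by default (divide by the RMS radius): scale-free while
    keeping the comparison exactly invariant under rigid rotations.
    Per-axis standardization is also available but shears the structure and
    then a rigid copy no longer reaches RMSD 0.
    """
    c = x - x.mean(axis=0)
    if per_axis:
        sd = c.std(axis=0)
        sd[sd == 0] = 1.0
        return c / sd
    rms = np.sqrt((c**2).sum(axis=1).mean())
    return c / rms if rms > 0 else c


def kabsch_rmsd(
    X: np.ndarray,
    Y: np.ndarray,
    min_points: int = 3,
    per_axis: bool = False,
    scale_normalize: bool = True,
) -> tuple[float, np.ndarray | None]:
    """Least RMSD between two structures over proper rotations.

    Rows with NaN in either structure are dropped pairwise; both structures
    are centered and normalized to unit scale (see ``_zscore``), and the
    optimal rotation is the SVD (Kabsch) solution constrained to det = +1.
    Returns (rmsd, rotation); with fewer than ``min_points`` common defined
    points the comparison is undefined and (nan, None) is returned with a
    warning.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("need two equally shaped (n, 3) structures")
    ok = np.isfinite(X).all(axis=1) & np.isfinite(Y).all(axis=1)
    if ok.sum() < max(min_points, 3):
        warnings.warn("too few common defined points for RMSD", RuntimeWarning)
        return float("nan"), None
    if scale_normalize:
        A = _zscore(X[ok], per_axis)
        B = _zscore(Y[ok], per_axis)
    else:
        # same-unit comparison: keep the physical size (it is the main
        # order parameter separating coil from globule structures)
        A = X[ok] - X[ok].mean(axis=0)
        B = Y[ok] - Y[ok].mean(axis=0)
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = A @ R.T - B
    rmsd = float(np.sqrt((diff**2).sum(axis=1).mean()))
    return rmsd, R


def _coords_of(obj) -> list[np.ndarray]:
    if isinstance(obj, Ensemble):
        return [_window_centroids(c, obj.model) for c in obj.conformations]
    out = []
    for c in obj:
        out.append(c.coords if isinstance(c, Conformation) else np.asarray(c, float))
    return out


def _rmsd_matrix(
    A: list[np.ndarray], B: list[np.ndarray], min_frac: float, scale_normalize=True
):
    n = A[0].shape[0]
    min_pts = max(3, int(np.ceil(min_frac * n)))
    out = np.full((len(A), len(B)), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i, x in enumerate(A):
            for j, y in enumerate(B):
                out[i, j], _ = kabsch_rmsd(
                    x, y, min_points=min_pts, scale_normalize=scale_normalize
                )
    return out


def least_rmsd_assignment(
    queries, references, min_common_fraction: float = 0.2, scale_normalize: bool = True
) -> RMSDAssignment:
    """Associate every query to its least-RMSD reference.

    The null distribution holds all query-query RMSDs; the report includes
    the fraction of matched RMSDs above the null's first quartile and the
    two-sided Mann-Whitney p comparing matched vs null (a significant
    association has a matched distribution well below the null).
    ``scale_normalize=True`` (z-scored coordinates) is for cross-modality
    comparison (imaging nm vs model sigma); pass False when both sets share
    physical units and molecular size should count.
    """
    qs, rs = _coords_of(queries), _coords_of(references)
    if not qs or not rs:
        raise ValueError("empty query or reference set")
    rm = _rmsd_matrix(qs, rs, min_common_fraction, scale_normalize)
    pairs, matched, skipped = [], [], []
    hit = np.zeros(len(rs), dtype=bool)
    for i in range(len(qs)):
        row = rm[i]
        if not np.isfinite(row).any():
            skipped.append(i)
            continue
        j = int(np.nanargmin(row))
        pairs.append((i, j, float(row[j])))
        matched.append(row[j])
        hit[j] = True
    qq = _rmsd_matrix(qs, qs, min_common_fraction, scale_normalize)
    iu = np.triu_indices(len(qs), k=1)
    null = qq[iu]
    null = null[np.isfinite(null)]
    matched = np.asarray(matched)
    q1 = np.percentile(null, 25) if null.size else float("nan")
    frac = float((matched > q1).mean()) if matched.size and np.isfinite(q1) else float("nan")
    if matched.size >= 3 and null.size >= 3:
        p = float(
            stats.mannwhitneyu(matched, null, alternative="two-sided").pvalue
        )
    else:
        p = float("nan")
    return RMSDAssignment(
        pairs=pairs,
        matched_rmsd=matched,
        null_rmsd=null,
        coverage=float(hit.mean()),
        fraction_above_null_q1=frac,
        mw_pvalue=p,
        skipped_queries=skipped,
    )


def classify_states(
    assignment: RMSDAssignment, reference_state_labels
) -> dict:
    """Fraction of queries matched to references of each thermodynamic state."""
    labels = list(reference_state_labels)
    if any(lbl in (None, "", "unlabeled") for lbl in labels):
        raise ValueError("all references must carry a state label")
    counts: dict = {}
    for _, j, _ in assignment.pairs:
        counts[labels[j]] = counts.get(labels[j], 0) + 1
    total = max(sum(counts.values()), 1)
    return {k: v / total for k, v in sorted(counts.items())}


# ---------------------------------------------------------------------------
# mixture decomposition
# ---------------------------------------------------------------------------


def fit_mixture_weight(
    coil_ens,
    globule_ens,
    target_median_distance: DistanceMatrix,
    grid_step: float = 0.05,
    n_sample: int = 600,
    n_rep: int = 5,
    seed: int = 0,
    query_ensemble=None,
) -> MixtureFit:
    """Coil fraction of a two-state mixture explaining a median distance map.

    For each coil weight w on the grid a mixture of single-molecule distance
    matrices is drawn by molecule resampling (w-proportional, fixed seed),
    its median matrix formed, and scored by the distance-corrected
    correlation r' against the target; the fitted weight is the argmax.
    Medians do not mix linearly, hence resampling rather than averaging the
    two state medians.  With ``query_ensemble`` given, an independent RMSD
    state classification of the queries is reported as a cross-check.
    """
    from .metrics import ensemble_distance_matrices

    coil_ms = [m.values for m in ensemble_distance_matrices(coil_ens)]
    glob_ms = [m.values for m in ensemble_distance_matrices(globule_ens)]
    tgt = target_median_distance
    if coil_ms[0].shape != tgt.values.shape:
        raise ValueError("target shape mismatch")
    rng = np.random.default_rng(seed)
    grid = np.round(np.arange(0.0, 1.0 + 1e-9, grid_step), 10)
    obj = np.empty(grid.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for k, w in enumerate(grid):
            n_coil = int(round(w * n_sample))
            reps = []
            for _ in range(max(1, n_rep)):
                pick_c = rng.integers(0, len(coil_ms), size=n_coil)
                pick_g = rng.integers(0, len(glob_ms), size=n_sample - n_coil)
                stack = [coil_ms[i] for i in pick_c] + [glob_ms[i] for i in pick_g]
                med = median_distance_matrix(
                    [DistanceMatrix(values=v) for v in stack]
                )
                reps.append(distance_corrected_r(med, tgt))
            obj[k] = float(np.nanmean(reps))
    # the objective is a noisy unimodal curve; a short moving average
    # stabilizes its argmax against resampling noise
    kernel = np.ones(3)
    finite = np.isfinite(obj)
    smooth = np.convolve(np.where(finite, obj, 0.0), kernel, mode="same")
    norm = np.convolve(finite.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        obj_s = smooth / norm
    best = int(np.nanargmax(obj_s))
    # flat objective: neither end of the weight axis nor the interior wins
    # (judged on the smoothed curve, which suppresses resampling noise)
    k5 = max(1, grid.size // 5)
    lo_m, hi_m = np.nanmean(obj_s[:k5]), np.nanmean(obj_s[-k5:])
    ambiguous = bool(
        abs(lo_m - hi_m) < 0.05 and np.nanmax(obj_s) - max(lo_m, hi_m) < 0.05
    )
    fractions = None
    if query_ensemble is not None:
        refs = list(coil_ens.conformations) + list(globule_ens.conformations)
        labels = ["coil"] * len(coil_ens.conformations) + ["globule"] * len(
            globule_ens.conformations
        )
        ref_model = coil_ens.model if isinstance(coil_ens, Ensemble) else None
        ref_ens = Ensemble(
            conformations=refs, params=coil_ens.params, model=ref_model
        )
        assignment = least_rmsd_assignment(
            query_ensemble, ref_ens, scale_normalize=False
        )
        fractions = classify_states(assignment, labels)
    if ambiguous:
        warnings.warn(
            "mixture objective is flat; weight is ill-determined", RuntimeWarning
        )
    return MixtureFit(
        weight_coil=float(grid[best]),
        grid=grid,
        objective=obj,
        ambiguous=ambiguous,
        rmsd_state_fractions=fractions,
    )
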
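"""Ensemble and single-molecule observables.

Everything here works on window-level matrices: bead conformations are
reduced to one centroid per genomic window before distances are taken,
mirroring probe-level chromatin-tracing data.  Distance matrices may contain
NaN (missing probes); every operation is pairwise-complete and the main
diagonal is excluded from all correlations.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats
from scipy.spatial.distance import squareform, pdist, cdist

from .core import Conformation, Ensemble, PolymerModel

__all__ = [
    "DistanceMatrix",
    "BoundaryParams",
    "BoundaryProfile",
    "distance_matrix",
    "median_distance_matrix",
    "contact_map_from_ensemble",
    "pearson_r",
    "distance_corrected_r",
    "separation_score",
    "call_boundaries",
    "boundary_probability",
    "filter_cells",
    "gaussian_smooth",
    "variability_distributions",
    "mw_protocol",
    "track_correlation_significance",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise spatial distance matrix with NaN for missing probes."""

    values: np.ndarray
    units: str = "sigma"  # {"sigma", "nm"}
    resolution_bp: int = 30_000
    origin_bp: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if np.isfinite(v).any():
            with np.errstate(invalid="ignore"):
                asym = np.abs(v - v.T)
                if np.isfinite(asym).any() and np.nanmax(asym) > 1e-9:
                    raise ValueError("distance matrix must be symmetric")
                if np.nanmin(v) < -1e-12:
                    raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def nan_fraction(self) -> float:
        return float(np.isnan(self.values).mean())


@dataclass
class BoundaryParams:
    """Separation-score / boundary-calling settings.

    The experimental-data settings of the imaging analysis are
    ``gb=1, valley=1, su=10, sl=6``; the model-ensemble settings are
    ``gb=1, valley=4, su=5, sl=5``.  ``gb`` excludes edge bins, ``valley``
    is the minimum spacing (bins) between called minima and ``su``/``sl``
    the upstream/downstream segment sizes entering the score.
    """

    gb: int = 1
    valley: int = 4
    su: int = 5
    sl: int = 5
    prominence: float = 0.2

    def __post_init__(self) -> None:
        if self.su < 1 or self.sl < 1 or self.gb < 0 or self.valley < 0:
            raise ValueError("invalid boundary parameters")


EXPERIMENTAL_BOUNDARY_PARAMS = BoundaryParams(gb=1, valley=1, su=10, sl=6)
MODEL_BOUNDARY_PARAMS = BoundaryParams(gb=1, valley=4, su=5, sl=5)


@dataclass
class BoundaryProfile:
    """Per-window boundary statistics over an ensemble of molecules."""

    boundary_probability: np.ndarray  # smoothed, in [0, 1]
    raw_probability: np.ndarray
    strengths: np.ndarray  # pooled over all calls of all molecules
    mean_boundary_probability: float
    sem_boundary_probability: float
    mean_strength: float
    sd_strength: float
    calls_per_molecule: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# matrices from conformations
# ---------------------------------------------------------------------------


def _window_centroids(conf: Conformation, model: PolymerModel) -> np.ndarray:
    coords = conf.coords
    if model.r == 1:
        return coords
    return coords.reshape(model.n_windows, model.r, 3).mean(axis=1)


def distance_matrix(conf: Conformation, model: PolymerModel) -> DistanceMatrix:
    """Window-level pairwise Euclidean distance matrix of one molecule."""
    cent = _window_centroids(conf, model)
    return DistanceMatrix(values=squareform(pdist(cent)))


def median_distance_matrix(matrices: list[DistanceMatrix | np.ndarray]) -> DistanceMatrix:
    """Element-wise NaN-ignoring median of single-molecule distance matrices."""
    if not matrices:
        raise ValueError("empty matrix list")
    stack = np.stack([_values(m) for m in matrices])
    units = matrices[0].units if isinstance(matrices[0], DistanceMatrix) else "sigma"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        med = np.nanmedian(stack, axis=0)
    return DistanceMatrix(values=med, units=units)


def ensemble_distance_matrices(ens: Ensemble) -> list[DistanceMatrix]:
    return [distance_matrix(c, ens.model) for c in ens.conformations]


def contact_map_from_ensemble(ens: Ensemble, A: float = 3.0, stat: str = "mean"):
    """Window-level contact frequency map at bead-distance threshold ``A`` sigma.

    Two windows are in contact in a molecule when any bead pair across them
    is closer than ``A`` sigma (any-contact rule); the map is the per-element
    mean (or median) of the single-molecule 0/1 contact matrices.  Contact
    frequency is monotone non-decreasing in ``A``.
    """
    from .prismr import ContactMatrix

    if len(ens) == 0:
        raise ValueError("empty ensemble")
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    model = ens.model
    W, r = model.n_windows, model.r
    maps = np.empty((len(ens), W, W))
    for k, conf in enumerate(ens.conformations):
        d = cdist(conf.coords, conf.coords)
        contact = d < A
        if r > 1:
            contact = (
                contact.reshape(W, r, W, r).any(axis=(1, 3))
            )
        maps[k] = contact
    vals = maps.mean(axis=0) if stat == "mean" else np.median(maps, axis=0)
    np.fill_diagonal(vals, 1.0)
    return ContactMatrix(
        values=vals,
        resolution_bp=model.resolution_bp,
        origin_bp=model.origin_bp,
        normalization="model-probability",
    )


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def _values(m) -> np.ndarray:
    if isinstance(m, DistanceMatrix):
        return m.values
    if hasattr(m, "values") and isinstance(getattr(m, "values"), np.ndarray):
        return m.values
    return np.asarray(m, dtype=float)


def _offdiag_mask(W: int) -> np.ndarray:
    iu = np.triu_indices(W, k=1)
    return iu


def pearson_r(M1, M2, min_n: int = 3) -> float:
    """Pearson correlation over upper-triangle elements defined in both."""
    a, b = _values(M1), _values(M2)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    iu = _offdiag_mask(a.shape[0])
    x, y = a[iu], b[iu]
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < min_n:
        warnings.warn("fewer than %d common defined elements" % min_n, RuntimeWarning)
        return float("nan")
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance in correlation input", RuntimeWarning)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def subtract_diagonal_means(M) -> np.ndarray:
    """Subtract from each element the NaN-aware mean of its diagonal."""
    a = _values(M).copy()
    W = a.shape[0]
    for k in range(W):
        idx = (np.arange(W - k), np.arange(k, W))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mu = np.nanmean(a[idx])
        a[idx] -= mu
        if k:
            a[(idx[1], idx[0])] -= mu
    return a


def distance_corrected_r(M1, M2, min_n: int = 3) -> float:
    """Genomic-distance-corrected Pearson correlation r'.

    Each matrix has its own per-diagonal mean subtracted element-wise, which
    removes the generic decay of contact/distance with genomic separation;
    the Pearson correlation of the residuals (off-diagonal, pairwise
    complete) is r'.  r' is invariant under adding any per-diagonal constant
    field to either matrix.
    """
    a = subtract_diagonal_means(M1)
    b = subtract_diagonal_means(M2)
    return pearson_r(a, b, min_n=min_n)


# ---------------------------------------------------------------------------
# separation score and boundaries
# ---------------------------------------------------------------------------


def _decay_normalize(d: np.ndarray) -> np.ndarray:
    """Divide each element by the matrix's own diagonal median (NaN-aware).

    Removes the generic growth of spatial distance with genomic separation,
    so segment comparisons are not dominated by the unequal genomic spans of
    intra- vs cross-segment pairs.
    """
    W = d.shape[0]
    out = d.copy()
    for k in range(1, W):
        idx = (np.arange(W - k), np.arange(k, W))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(d[idx])
        if np.isfinite(med) and med > 0:
            out[idx] = d[idx] / med
            out[(idx[1], idx[0])] = out[idx]
        else:
            out[idx] = np.nan
            out[(idx[1], idx[0])] = np.nan
    return out


def separation_score(
    D, su: int = 5, sl: int = 5, gb: int = 0, decay_correct: bool = True
) -> np.ndarray:
    """Spatial-separation profile along the genomic coordinate.

    At window ``i`` the upstream segment L holds windows ``[i-su, i)`` and
    the downstream segment R holds ``[i, i+sl)``; positions whose segments
    would be clipped by the locus ends are undefined (clipped segments score
    systematically low and would fake boundaries at the edges).
    The score is the median of all intra-segment pairwise distances divided
    by the median of the cross-segment distances, computed by default on
    decay-normalized distances (each element divided by its diagonal's
    median): about 1 everywhere for a random coil, and well below 1 where
    the two flanks fold into separate globules.  ``decay_correct=False``
    uses raw distances.
    """
    d = _values(D)
    if decay_correct:
        d = _decay_normalize(d)
    W = d.shape[0]
    out = np.full(W, np.nan)
    for i in range(W):
        lo = i - su
        hi = i + sl
        if lo < 0 or hi > W:
            continue
        L = np.arange(lo, i)
        R = np.arange(i, hi)
        intra = []
        for seg in (L, R):
            if len(seg) > 1:
                ii, jj = np.triu_indices(len(seg), k=1)
                intra.append(d[seg[ii], seg[jj]])
        cross = d[np.ix_(L, R)].ravel()
        intra = np.concatenate(intra) if intra else np.array([])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mi = np.nanmedian(intra) if intra.size else np.nan
            mc = np.nanmedian(cross) if cross.size else np.nan
        if np.isfinite(mi) and np.isfinite(mc) and mc > 0:
            out[i] = mi / mc
    if gb > 0:
        out[:gb] = np.nan
        out[-gb:] = np.nan
    return out


def call_boundaries(D, params: BoundaryParams | None = None):
    """Domain-boundary calls of one molecule.

    Boundaries are local minima of the separation-score profile (edge bins
    within ``gb`` excluded, at least ``valley`` bins between calls, minimum
    prominence ``params.prominence``).  The strength of a call is the mean
    of the two flanking profile maxima divided by the profile value at the
    call, hence always >= 1.
    """
    p = params or BoundaryParams()
    prof = separation_score(D, su=p.su, sl=p.sl, gb=p.gb)
    return _calls_from_profile(prof, p)


def _calls_from_profile(prof: np.ndarray, p: BoundaryParams):
    W = prof.size
    if not np.isfinite(prof).any():
        return [], np.array([]), prof
    # undefined bins are filled by nearest-neighbour padding: a constant
    # extension can never add a minimum, and (unlike a high or infinite
    # sentinel) it creates no artificial cliff lending fake prominence to
    # dips near the defined-region edges
    idx = np.arange(W)
    finite_idx = idx[np.isfinite(prof)]
    filled = prof.copy()
    nearest = finite_idx[
        np.argmin(np.abs(idx[:, None] - finite_idx[None, :]), axis=1)
    ]
    filled[~np.isfinite(prof)] = prof[nearest[~np.isfinite(prof)]]
    minima, _ = signal.find_peaks(
        -filled, distance=p.valley + 1, prominence=p.prominence
    )
    minima = minima[np.isfinite(prof[minima])]
    minima = minima[(minima >= p.gb) & (minima < W - p.gb)]
    strengths = []
    finite = np.where(np.isfinite(prof))[0]
    for k, m in enumerate(minima):
        left_stop = minima[k - 1] if k > 0 else (finite[0] if finite.size else 0)
        right_stop = minima[k + 1] if k + 1 < len(minima) else (
            finite[-1] if finite.size else W - 1
        )
        left = prof[left_stop : m + 1]
        right = prof[m : right_stop + 1]
        lmax = np.nanmax(left) if np.isfinite(left).any() else prof[m]
        rmax = np.nanmax(right) if np.isfinite(right).any() else prof[m]
        strengths.append(0.5 * (lmax + rmax) / prof[m])
    return list(map(int, minima)), np.asarray(strengths, dtype=float), prof


def boundary_probability(
    matrices: list,
    params: BoundaryParams | None = None,
) -> BoundaryProfile:
    """Boundary probability and strength over an ensemble of molecules.

    The per-window fraction of molecules with a boundary call there is
    smoothed with a two-point running average; the profile mean is reported
    with the standard error of the mean over windows.
    """
    p = params or BoundaryParams()
    if not matrices:
        raise ValueError("empty ensemble")
    W = _values(matrices[0]).shape[0]
    counts = np.zeros(W)
    strengths = []
    calls_all = []
    for D in matrices:
        calls, s, _ = call_boundaries(D, p)
        counts[calls] += 1
        strengths.extend(s)
        calls_all.append(calls)
    raw = counts / len(matrices)
    smoothed = raw.copy()
    smoothed[:-1] = 0.5 * (raw[:-1] + raw[1:])
    strengths = np.asarray(strengths, dtype=float)
    return BoundaryProfile(
        boundary_probability=smoothed,
        raw_probability=raw,
        strengths=strengths,
        mean_boundary_probability=float(smoothed.mean()),
        sem_boundary_probability=float(smoothed.std(ddof=1) / np.sqrt(W)),
        mean_strength=float(strengths.mean()) if strengths.size else float("nan"),
        sd_strength=float(strengths.std(ddof=1)) if strengths.size > 1 else 0.0,
        calls_per_molecule=calls_all,
    )


# ---------------------------------------------------------------------------
# single-cell filtering and smoothing
# ---------------------------------------------------------------------------


def filter_cells(
    matrices: list, nan_threshold: float = 0.8, r_threshold: float = 0.01
) -> tuple[list, dict]:
    """Quality-filter single-molecule distance matrices.

    Drops matrices with more than ``nan_threshold`` NaN entries, then
    iteratively drops matrices whose mean Pearson correlation with the rest
    of the set falls below ``r_threshold`` (outliers); iteration to a fixed
    point makes the filter idempotent.  Returns the kept matrices and the
    per-rule removal counts.
    """
    report = {"nan_removed": 0, "correlation_removed": 0, "kept": 0}
    kept = []
    for m in matrices:
        if np.isnan(_values(m)).mean() > nan_threshold:
            report["nan_removed"] += 1
        else:
            kept.append(m)
    changed = True
    while changed and len(kept) > 1:
        rs = np.zeros(len(kept))
        for i, j in itertools.combinations(range(len(kept)), 2):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                r = pearson_r(kept[i], kept[j])
            if np.isfinite(r):
                rs[i] += r
                rs[j] += r
        rs /= max(len(kept) - 1, 1)
        bad = np.where(rs < r_threshold)[0]
        changed = bad.size > 0
        if changed:
            report["correlation_removed"] += int(bad.size)
            kept = [m for k, m in enumerate(kept) if k not in set(bad)]
    report["kept"] = len(kept)
    return kept, report


def gaussian_smooth(D, kernel_sd: float = 1.0) -> DistanceMatrix:
    """NaN-aware 2-D Gaussian smoothing (normalized by defined-weight mass).

    Missing entries contribute zero weight so their absence does not bias the
    normalization of neighbouring defined cells; originally-NaN cells remain
    NaN.  Symmetry is preserved.
    """
    a = _values(D)
    nanmask = np.isnan(a)
    filled = np.where(nanmask, 0.0, a)
    weights = (~nanmask).astype(float)
    num = ndimage.gaussian_filter(filled, kernel_sd, mode="nearest")
    den = ndimage.gaussian_filter(weights, kernel_sd, mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den < 1e-12] = np.nan
    out[nanmask] = np.nan
    out = 0.5 * (out + out.T)
    return DistanceMatrix(
        values=out,
        units=D.units if isinstance(D, DistanceMatrix) else "sigma",
        resolution_bp=getattr(D, "resolution_bp", 30_000),
        origin_bp=getattr(D, "origin_bp", 0),
    )


# ---------------------------------------------------------------------------
# variability statistics
# ---------------------------------------------------------------------------


def bootstrap_diagonals(D, rng: np.random.Generator) -> np.ndarray:
    """Resample each diagonal's defined entries with replacement (control)."""
    a = _values(D).copy()
    W = a.shape[0]
    for k in range(1, W):
        idx = (np.arange(W - k), np.arange(k, W))
        vals = a[idx]
        ok = np.isfinite(vals)
        if ok.sum() > 0:
            pool = vals[ok]
            new = vals.copy()
            new[ok] = rng.choice(pool, size=int(ok.sum()), replace=True)
            a[idx] = new
            a[(idx[1], idx[0])] = new
    return a


def _pairwise_rprime(ms1, ms2=None, smooth_sd: float | None = 1.0):
    """r' values (and the matrix-index pairs) within one or across two sets."""
    def prep(ms):
        if smooth_sd:
            return [gaussian_smooth(m, smooth_sd) for m in ms]
        return list(ms)

    A = prep(ms1)
    vals, pairs = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if ms2 is None:
            for i, j in itertools.combinations(range(len(A)), 2):
                vals.append(distance_corrected_r(A[i], A[j]))
                pairs.append((i, j))
        else:
            B = prep(ms2)
            for i in range(len(A)):
                for j in range(len(B)):
                    vals.append(distance_corrected_r(A[i], B[j]))
                    pairs.append((i, j))
    return np.asarray(vals), pairs


def variability_distributions(
    exp_matrices: list,
    model_matrices: list,
    seed: int = 0,
    smooth_sd: float = 1.0,
) -> dict:
    """The four r' distributions quantifying single-molecule variability.

    Returns a dict with keys ``exp_exp``, ``model_model``, ``model_exp`` and
    ``control`` (pairs of diagonal-bootstrapped experimental matrices), each
    holding ``values`` and the contributing matrix-index ``pairs``.
    """
    rng = np.random.default_rng(seed)
    ee, ee_pairs = _pairwise_rprime(exp_matrices, smooth_sd=smooth_sd)
    mm, mm_pairs = _pairwise_rprime(model_matrices, smooth_sd=smooth_sd)
    me, me_pairs = _pairwise_rprime(model_matrices, exp_matrices, smooth_sd=smooth_sd)
    ctrl_ms = [
        DistanceMatrix(values=bootstrap_diagonals(m, rng)) for m in exp_matrices
    ]
    cc, cc_pairs = _pairwise_rprime(ctrl_ms, smooth_sd=smooth_sd)
    return {
        "exp_exp": {"values": ee, "pairs": ee_pairs},
        "model_model": {"values": mm, "pairs": mm_pairs},
        "model_exp": {"values": me, "pairs": me_pairs},
        "control": {"values": cc, "pairs": cc_pairs},
    }


def _independent_pair_sample(pairs, rng):
    """Random maximal set of pairs sharing no matrix index."""
    order = rng.permutation(len(pairs))
    used: set = set()
    out = []
    for k in order:
        i, j = pairs[k]
        if i not in used and j not in used:
            used.update((i, j))
            out.append(k)
    return np.asarray(out, dtype=int)


def mw_protocol(
    dist_a,
    dist_b,
    pairs_a=None,
    pairs_b=None,
    n_resamples: int = 10,
    seed: int = 0,
) -> float:
    """Averaged two-sided Mann-Whitney test between two r' distributions.

    Only independent pairs (no matrix used twice within a sample) enter each
    test, both samples are forced to a common size, and the p-value is the
    average over ``n_resamples`` independent draws.
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    a = a[np.isfinite(a)] if pairs_a is None else a
    b = b[np.isfinite(b)] if pairs_b is None else b
    ps = []
    for _ in range(n_resamples):
        if pairs_a is not None:
            ia = _independent_pair_sample(pairs_a, rng)
            xa = a[ia]
        else:
            xa = a
        if pairs_b is not None:
            ib = _independent_pair_sample(pairs_b, rng)
            xb = b[ib]
        else:
            xb = b
        xa = xa[np.isfinite(xa)]
        xb = xb[np.isfinite(xb)]
        m = min(len(xa), len(xb))
        if m < 3:
            raise ValueError("not enough independent pairs for the test")
        xa = rng.choice(xa, size=m, replace=False)
        xb = rng.choice(xb, size=m, replace=False)
        ps.append(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
    return float(np.mean(ps))


# ---------------------------------------------------------------------------
# binding-domain vs genomic-track correlation
# ---------------------------------------------------------------------------


def track_correlation_significance(
    domain_tracks: np.ndarray,
    feature_tracks: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    upper_pct: float = 90.0,
    lower_pct: float = 10.0,
) -> dict:
    """Bootstrap-calibrated correlations between binding domains and tracks.

    ``domain_tracks``: (n_domains, W) per-window binding-site counts;
    ``feature_tracks``: (n_tracks, W) binned genomic signals.  For each pair
    the Pearson r is compared against the distribution of correlations of
    ``n_boot`` position-bootstrapped domain profiles with the same track:
    positive correlations are significant above ``upper_pct``, negative ones
    below ``lower_pct``.
    """
    from .synth import bootstrap_track

    rng = np.random.default_rng(seed)
    D = np.atleast_2d(np.asarray(domain_tracks, dtype=float))
    F = np.atleast_2d(np.asarray(feature_tracks, dtype=float))
    if D.shape[1] != F.shape[1]:
        raise ValueError("track lengths differ")
    nd, nt = D.shape[0], F.shape[0]
    corr = np.full((nd, nt), np.nan)
    signif = np.zeros((nd, nt), dtype=bool)
    for di in range(nd):
        boots = np.stack([bootstrap_track(D[di], rng) for _ in range(n_boot)])
        for ti in range(nt):
            r = _track_r(D[di], F[ti])
            corr[di, ti] = r
            null = np.array([_track_r(bp, F[ti]) for bp in boots])
            null = null[np.isfinite(null)]
            if not np.isfinite(r) or null.size == 0:
                continue
            hi = np.percentile(null, upper_pct)
            lo = np.percentile(null, lower_pct)
            signif[di, ti] = (r > 0 and r > hi) or (r < 0 and r < lo)
    return {"correlation": corr, "significant": signif}


def _track_r(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
        return float("nan")
    return float(np.corrcoef(x[ok], y[ok])[0, 1])
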
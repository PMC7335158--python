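"""Inference of SBS binding domains from a contact matrix.

Given a bulk contact map of one locus, find the minimal bead coloring whose
physics-predicted contact map best explains it.  The search is a simulated
annealing (SA) over colorings with a distance-scaled mean-squared-error cost

    H0 = < (predicted_ij - target_ij)^2 / dbar(|i-j|) >_masked elements

(dbar(k) is the target's mean over diagonal k, which stops the strong
near-diagonal signal from dominating the fit), plus a chemical-potential
penalty ``H_lambda = lambda * (number of beads with color != 0)`` that
favours sparse models.  Hyperparameters (number of colors n, penalty lambda,
beads-per-window r) are selected by a 70/30 train/test split of matrix
elements: the test-set cost is U-shaped in n and its argmin is the selected
n*, the point of best predictive power before overfitting sets in.

The forward map from a coloring to a contact matrix is a mean-field template
superposition calibrated on the simulator once per chain-length class:
``P(i,j) = clip(p0(|i-j|) + s(i,j) * phi(|i-j|), 0, 1)`` where ``p0`` is the
colorless (SAW) contact decay, ``phi`` the excess contact of a fully bound
single-color chain in the globule state, and ``s(i,j)`` the fraction of
shared-color bead pairs between windows i and j.  This approximation is the
module's core simplification and is validated against direct simulation in
the test suite.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import linear_sum_assignment

from .core import (
    PolymerModel,
    SimulationParams,
    saw_ensemble,
    simulate_ensemble,
)

__all__ = [
    "ContactMatrix",
    "SAConfig",
    "InferenceResult",
    "ModelSelection",
    "ForwardTemplates",
    "get_templates",
    "forward_contact_map",
    "cost_h0",
    "cost_total",
    "sa_optimize",
    "select_hyperparameters",
    "domain_overlap",
    "matched_bead_agreement",
    "robustness_of_minima",
]


@dataclass
class ContactMatrix:
    """Symmetric non-negative contact matrix at fixed bin resolution."""

    values: np.ndarray
    resolution_bp: int = 30_000
    origin_bp: int = 0
    chrom: str = "chrS"
    normalization: str = "raw"  # {raw, KR-like, model-probability}

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("contact matrix must be square")
        if np.isnan(v).any():
            raise ValueError("contact matrix must not contain NaN")
        if np.abs(v - v.T).max() > 1e-9:
            raise ValueError("contact matrix must be symmetric (tol 1e-9)")
        if v.min() < 0:
            raise ValueError("contact matrix must be non-negative")
        self.values = 0.5 * (v + v.T)

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


@dataclass
class SAConfig:
    """Simulated-annealing and model-selection settings."""

    n: int = 2
    r: int = 1
    lambda_: float = 0.0
    train_fraction: float = 0.70
    t0: float | None = None  # None -> set so initial acceptance is ~50%
    cooling: float = 0.97
    sweeps: int = 400
    n_runs: int = 20
    seed: int = 0
    normalize_target: bool = True

    def validate(self) -> None:
        if not (0.5 <= self.train_fraction <= 0.8):
            raise ValueError("train_fraction must be in [0.5, 0.8]")
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        if self.n < 0 or self.r < 1 or self.sweeps < 1:
            raise ValueError("invalid SA configuration")


@dataclass
class InferenceResult:
    coloring: PolymerModel
    h0_train: float
    h0_test: float
    h_total: float
    cost_trace: np.ndarray
    split_mask: np.ndarray  # boolean (W, W), True = training element
    improved: bool = True


@dataclass
class ModelSelection:
    n_star: int | None
    lambda_star: float | None
    r_star: int | None
    curves: dict = field(default_factory=dict)
    ambiguous: bool = False
    tie_set: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# forward model templates
# ---------------------------------------------------------------------------


@dataclass
class ForwardTemplates:
    """Distance-decay templates for the mean-field forward contact map."""

    p0: np.ndarray  # colorless contact probability vs genomic distance k
    phi: np.ndarray  # excess contact of the fully bound single-color chain
    n_windows: int
    r: int
    A: float


_TEMPLATE_CACHE: dict[tuple, ForwardTemplates] = {}


def get_templates(
    n_windows: int,
    r: int = 1,
    A: float = 3.0,
    n_molecules: int = 120,
    seed: int = 77_001,
) -> ForwardTemplates:
    """Simulate (once, cached) the forward-map templates for a chain class."""
    from .metrics import contact_map_from_ensemble

    key = (n_windows, r, A)
    if key in _TEMPLATE_CACHE:
        return _TEMPLATE_CACHE[key]
    n_beads = n_windows * r
    coil = saw_ensemble(n_beads, n_molecules, seed=seed)
    coil.model = PolymerModel(
        colors=np.zeros(n_beads, dtype=np.int64), n=0, r=r
    )
    p0_map = contact_map_from_ensemble(coil, A=A).values
    bound_model = PolymerModel(colors=np.ones(n_beads, dtype=np.int64), n=1, r=r)
    params = SimulationParams(
        concentration=0.5e-6,
        seed=seed + 1,
        n_steps=12_000,
        equilibration_steps=8_000,
        samples_per_chain=max(1, n_molecules // 8),
        decorrelation_sweeps=200,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        glob = simulate_ensemble(bound_model, params, n_molecules)
    p1_map = contact_map_from_ensemble(glob, A=A).values
    p0 = _diagonal_means(p0_map)
    phi = np.maximum(_diagonal_means(p1_map) - p0, 0.0)
    tpl = ForwardTemplates(p0=p0, phi=phi, n_windows=n_windows, r=r, A=A)
    _TEMPLATE_CACHE[key] = tpl
    return tpl


def _diagonal_means(m: np.ndarray) -> np.ndarray:
    W = m.shape[0]
    return np.array([np.mean(np.diagonal(m, k)) for k in range(W)])


def _shared_color_fraction(counts: np.ndarray, r: int) -> np.ndarray:
    """s(i,j): shared-color bead-pair fraction between windows (W, W)."""
    spec = counts[:, 1:].astype(float)  # drop color 0
    return spec @ spec.T / float(r * r)


def forward_contact_map(
    model: PolymerModel, templates: ForwardTemplates
) -> ContactMatrix:
    """Mean-field predicted contact map of a coloring (deterministic)."""
    if templates.n_windows != model.n_windows or templates.r != model.r:
        raise ValueError("template / chain length mismatch")
    W = model.n_windows
    k = np.abs(np.arange(W)[:, None] - np.arange(W)[None, :])
    s = _shared_color_fraction(model.color_counts(), model.r)
    vals = np.clip(templates.p0[k] + s * templates.phi[k], 0.0, 1.0)
    np.fill_diagonal(vals, 1.0)
    return ContactMatrix(
        values=vals,
        resolution_bp=model.resolution_bp,
        origin_bp=model.origin_bp,
        normalization="model-probability",
    )


# ---------------------------------------------------------------------------
# cost functions
# ---------------------------------------------------------------------------


def _dbar_weights(target: np.ndarray) -> tuple[np.ndarray, int]:
    """Per-element weights 1/dbar(|i-j|); zero-mean diagonals are excluded."""
    W = target.shape[0]
    dbar = _diagonal_means(target)
    excluded = 0
    wk = np.zeros(W)
    for k in range(1, W):
        if dbar[k] > 0:
            wk[k] = 1.0 / dbar[k]
        else:
            excluded += 1
    if excluded:
        warnings.warn(
            f"{excluded} zero-mean diagonals excluded from the cost",
            RuntimeWarning,
            stacklevel=3,
        )
    kmat = np.abs(np.arange(W)[:, None] - np.arange(W)[None, :])
    return wk[kmat], excluded


def cost_h0(predicted, target, mask: np.ndarray | None = None) -> float:
    """Distance-scaled MSE between contact maps on the masked elements.

    The prediction is first multiplied by the least-squares scalar aligning
    it to the target on the mask (model probabilities and raw counts live on
    different scales); the main diagonal is always excluded.
    """
    p = predicted.values if isinstance(predicted, ContactMatrix) else np.asarray(predicted, float)
    t = target.values if isinstance(target, ContactMatrix) else np.asarray(target, float)
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    W = t.shape[0]
    sel = np.triu(np.ones((W, W), dtype=bool), k=1)
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    wgt, _ = _dbar_weights(t)
    sel &= wgt > 0
    pw, tw, ww = p[sel], t[sel], wgt[sel]
    denom = np.sum(ww * pw * pw)
    a = np.sum(ww * pw * tw) / denom if denom > 0 else 0.0
    a = max(a, 0.0)
    return float(np.mean(ww * (a * pw - tw) ** 2))


def cost_total(h0: float, coloring: PolymerModel | np.ndarray, lambda_: float) -> float:
    """Total cost H = H0 + lambda * (number of colored beads)."""
    if lambda_ < 0:
        raise ValueError("lambda_ must be >= 0")
    colors = coloring.colors if isinstance(coloring, PolymerModel) else np.asarray(coloring)
    return float(h0 + lambda_ * int(np.count_nonzero(colors)))


# ---------------------------------------------------------------------------
# simulated annealing
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sa_run(
    target,
    wtrain,
    p0m,
    phim,
    colors,
    window_of,
    n_colors,
    r2,
    lam,
    t0,
    alpha,
    sweeps,
    seed,
):
    """Anneal one coloring in place; returns (best_colors, trace, best_H)."""
    np.random.seed(seed)
    W = target.shape[0]
    B = colors.shape[0]
    ncol1 = n_colors + 1
    m = np.zeros((W, ncol1), dtype=np.int64)
    for b in range(B):
        m[window_of[b], colors[b]] += 1
    pred = np.empty((W, W))
    for i in range(W):
        for j in range(W):
            cnt = 0.0
            for c in range(1, ncol1):
                cnt += m[i, c] * m[j, c]
            v = p0m[i, j] + cnt / r2 * phim[i, j]
            pred[i, j] = min(max(v, 0.0), 1.0)
    # masked sums over unordered pairs i<j
    s_pp = 0.0
    s_pt = 0.0
    s_tt = 0.0
    count = 0
    for i in range(W):
        for j in range(i + 1, W):
            w = wtrain[i, j]
            if w > 0.0:
                s_pp += w * pred[i, j] * pred[i, j]
                s_pt += w * pred[i, j] * target[i, j]
                s_tt += w * target[i, j] * target[i, j]
                count += 1
    n_colored = 0
    for b in range(B):
        if colors[b] != 0:
            n_colored += 1

    # H0 under the optimal (non-negative) least-squares scale of `pred`:
    # H0 = (S_tt - S_pt^2 / S_pp) / count, falling back to S_tt/count when
    # the optimal scale would be <= 0.
    if s_pp > 0.0 and s_pt > 0.0:
        h0 = (s_tt - s_pt * s_pt / s_pp) / count
    else:
        h0 = s_tt / count
    h = h0 + lam * n_colored
    best_h = h
    best_colors = colors.copy()
    trace = np.empty(sweeps)
    T = t0
    old_row = np.empty(W)
    for sweep in range(sweeps):
        for _ in range(B):
            b = np.random.randint(0, B)
            c_old = colors[b]
            c_new = np.random.randint(0, ncol1)
            if c_new == c_old:
                continue
            wi = window_of[b]
            d_pp = 0.0
            d_pt = 0.0
            for j in range(W):
                old_row[j] = pred[wi, j]
                if j == wi:
                    continue
                # change of the shared-color pair count between windows wi, j
                dcnt = 0.0
                if c_old != 0:
                    dcnt -= m[j, c_old]
                if c_new != 0:
                    dcnt += m[j, c_new]
                if dcnt != 0.0:
                    cnt_new = dcnt
                    for c in range(1, ncol1):
                        cnt_new += m[wi, c] * m[j, c]
                    v_new = p0m[wi, j] + cnt_new / r2 * phim[wi, j]
                    p_new = min(max(v_new, 0.0), 1.0)
                    if p_new != pred[wi, j]:
                        w = wtrain[wi, j]
                        if w > 0.0:
                            d_pp += w * (p_new * p_new - pred[wi, j] * pred[wi, j])
                            d_pt += w * target[wi, j] * (p_new - pred[wi, j])
                        pred[wi, j] = p_new
                        pred[j, wi] = p_new
            d_col = 0
            if c_old == 0 and c_new != 0:
                d_col = 1
            elif c_old != 0 and c_new == 0:
                d_col = -1
            spp_n = s_pp + d_pp
            spt_n = s_pt + d_pt
            if spp_n > 0.0 and spt_n > 0.0:
                h0_new = (s_tt - spt_n * spt_n / spp_n) / count
            else:
                h0_new = s_tt / count
            h_new = h0_new + lam * (n_colored + d_col)
            dh = h_new - h
            if dh <= 0.0 or np.random.random() < np.exp(-dh / T):
                s_pp += d_pp
                s_pt += d_pt
                n_colored += d_col
                m[wi, c_old] -= 1
                m[wi, c_new] += 1
                colors[b] = c_new
                h0 = h0_new
                h = h_new
                if h < best_h:
                    best_h = h
                    best_colors[:] = colors
            else:
                for j in range(W):
                    if pred[wi, j] != old_row[j]:
                        pred[wi, j] = old_row[j]
                        pred[j, wi] = old_row[j]
        trace[sweep] = h
        T *= alpha
        if sweep % 50 == 49:
            # refresh sums against float drift
            s_pp = 0.0
            s_pt = 0.0
            for i in range(W):
                for j in range(i + 1, W):
                    w = wtrain[i, j]
                    if w > 0.0:
                        s_pp += w * pred[i, j] * pred[i, j]
                        s_pt += w * pred[i, j] * target[i, j]
            if s_pp > 0.0 and s_pt > 0.0:
                h0 = (s_tt - s_pt * s_pt / s_pp) / count
            else:
                h0 = s_tt / count
            h = h0 + lam * n_colored
    return best_colors, trace, best_h


def make_split_mask(
    W: int, train_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (W, W) mask, True on training elements (upper triangle only).

    The split is over unique off-diagonal upper-triangle elements; symmetry
    is handled by construction (only i < j elements are ever evaluated).
    """
    iu = np.triu_indices(W, k=1)
    n_el = iu[0].size
    n_train = int(round(train_fraction * n_el))
    choice = np.zeros(n_el, dtype=bool)
    choice[rng.permutation(n_el)[:n_train]] = True
    mask = np.zeros((W, W), dtype=bool)
    mask[iu] = choice
    return mask


def _prepare_target(target: ContactMatrix, normalize: bool) -> np.ndarray:
    t = target.values.copy()
    if normalize:
        iu = np.triu_indices(t.shape[0], k=1)
        mu = t[iu].mean()
        if mu > 0:
            t = t / mu
    return t


def _estimate_t0(
    target, wtrain, p0m, phim, window_of, n, r2, lam, seed
) -> float:
    """Temperature giving ~50% initial uphill acceptance (mean |dH| / ln 2)."""
    rng = np.random.default_rng(seed)
    W = target.shape[0]
    B = window_of.size
    colors = rng.integers(0, n + 1, size=B).astype(np.int64)
    base = _eval_h0(colors, target, wtrain, p0m, phim, window_of, n, r2)
    dhs = []
    for _ in range(64):
        b = int(rng.integers(0, B))
        old = colors[b]
        colors[b] = int(rng.integers(0, n + 1))
        dhs.append(
            abs(
                _eval_h0(colors, target, wtrain, p0m, phim, window_of, n, r2)
                - base
            )
        )
        colors[b] = old
    scale = float(np.mean(dhs)) + 1e-15
    return scale / np.log(2.0)


def _eval_h0(colors, target, wgt, p0m, phim, window_of, n, r2) -> float:
    W = target.shape[0]
    m = np.zeros((W, n + 1))
    np.add.at(m, (window_of, colors), 1)
    spec = m[:, 1:]
    pred = np.clip(p0m + (spec @ spec.T) / r2 * phim, 0.0, 1.0)
    iu = np.where(np.triu(wgt, k=1) > 0)
    pw, tw, ww = pred[iu], target[iu], wgt[iu]
    spp = np.sum(ww * pw * pw)
    spt = np.sum(ww * pw * tw)
    stt = np.sum(ww * tw * tw)
    if spp > 0 and spt > 0:
        return float((stt - spt**2 / spp) / pw.size)
    return float(stt / pw.size)


def sa_optimize(
    target: ContactMatrix,
    config: SAConfig,
    templates: ForwardTemplates | None = None,
    split_mask: np.ndarray | None = None,
) -> InferenceResult:
    """Anneal a bead coloring against a contact matrix (one SA run).

    Deterministic given ``config.seed``.  ``split_mask`` restricts the cost
    to training elements; the returned result carries both the train and the
    held-out test cost of the best-ever coloring.
    """
    config.validate()
    W = target.n_windows
    tpl = templates or get_templates(W, config.r)
    rng = np.random.default_rng(config.seed)
    if split_mask is None:
        split_mask = make_split_mask(W, config.train_fraction, rng)
    t = _prepare_target(target, config.normalize_target)
    wgt, _ = _dbar_weights(t)
    wtrain = np.where(split_mask, wgt, 0.0)
    # the kernel indexes pair weights from either side of the diagonal
    wtrain_sym = wtrain + wtrain.T
    wtest = np.where(np.triu(~split_mask, k=1), wgt, 0.0)
    kmat = np.abs(np.arange(W)[:, None] - np.arange(W)[None, :])
    p0m = tpl.p0[kmat]
    phim = tpl.phi[kmat]
    window_of = (np.arange(W * config.r) // config.r).astype(np.int64)
    r2 = float(config.r * config.r)
    t0 = config.t0 or _estimate_t0(
        t, wtrain, p0m, phim, window_of, config.n, r2, config.lambda_,
        int(rng.integers(2**31 - 1)),
    )
    init_colors = rng.integers(0, config.n + 1, size=W * config.r).astype(np.int64)
    h0_init = _eval_h0(
        init_colors, t, wtrain, p0m, phim, window_of, config.n, r2
    )
    h_init = h0_init + config.lambda_ * int(np.count_nonzero(init_colors))
    best_colors, trace, best_h = _sa_run(
        t,
        wtrain_sym,
        p0m,
        phim,
        init_colors.copy(),
        window_of,
        config.n,
        r2,
        config.lambda_,
        t0,
        config.cooling,
        config.sweeps,
        int(rng.integers(2**31 - 1)),
    )
    h0_train = _eval_h0(
        best_colors, t, wtrain, p0m, phim, window_of, config.n, r2
    )
    h0_test = _eval_h0(
        best_colors, t, wtest, p0m, phim, window_of, config.n, r2
    )
    improved = best_h < h_init - 1e-15
    if not improved:
        warnings.warn("SA run did not improve on its initial coloring", RuntimeWarning)
    model = PolymerModel(
        colors=best_colors,
        n=config.n,
        r=config.r,
        resolution_bp=target.resolution_bp,
        origin_bp=target.origin_bp,
        chrom=target.chrom,
    )
    return InferenceResult(
        coloring=model,
        h0_train=h0_train,
        h0_test=h0_test,
        h_total=float(best_h),
        cost_trace=trace,
        split_mask=split_mask,
        improved=improved,
    )


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


def _runs_at(
    target, n, lam, r, config, templates, seeds
) -> list[InferenceResult]:
    out = []
    for s in seeds:
        cfg = SAConfig(
            n=n,
            r=r,
            lambda_=lam,
            train_fraction=config.train_fraction,
            t0=config.t0,
            cooling=config.cooling,
            sweeps=config.sweeps,
            seed=int(s),
            normalize_target=config.normalize_target,
        )
        out.append(sa_optimize(target, cfg, templates=templates))
    return out


def select_hyperparameters(
    target: ContactMatrix,
    n_grid,
    lambda_grid,
    r_grid,
    config: SAConfig,
    r_tolerance: float = 0.05,
    tie_tolerance: float = 0.10,
) -> ModelSelection:
    """Train/test selection of (n*, lambda*, r*).

    For every n the held-out cost is averaged over ``config.n_runs``
    independent SA runs (fresh random 70/30 splits and initial colorings):
    the curve first falls with n, reaches a minimum at n* and rises again as
    overfitting sets in.  lambda* is then the test-cost argmin at fixed n*,
    and r* the smallest r whose best cost is within ``r_tolerance`` of the
    largest-r plateau.  Statistical ties (means within ``tie_tolerance`` of
    the minimum, the run-to-run noise scale of the SA) break toward smaller
    n, larger lambda and smaller r (parsimony); any tie is flagged as
    ambiguous with the tie set.  Curves are normalized by the colorless-model
    cost H0(0).
    """
    config.validate()
    n_grid = sorted(int(v) for v in n_grid)
    lambda_grid = sorted(float(v) for v in lambda_grid)
    r_grid = sorted(int(v) for v in r_grid)
    master = np.random.SeedSequence(config.seed)
    curves: dict = {"n": {}, "lambda": {}, "r": {}}

    def mean_test(results):
        return float(np.mean([x.h0_test for x in results]))

    # H0 of the colorless model for normalization, averaged over fresh splits
    tpl0 = get_templates(target.n_windows, r_grid[0])
    rng0 = np.random.default_rng(config.seed + 1)
    h00 = []
    t = _prepare_target(target, config.normalize_target)
    wgt, _ = _dbar_weights(t)
    for _ in range(max(10, config.n_runs // 2)):
        mask = make_split_mask(target.n_windows, config.train_fraction, rng0)
        wtest = np.where(np.triu(~mask, k=1), wgt, 0.0)
        W = target.n_windows
        kmat = np.abs(np.arange(W)[:, None] - np.arange(W)[None, :])
        h00.append(
            _eval_h0(
                np.zeros(W * r_grid[0], dtype=np.int64),
                t, wtest, tpl0.p0[kmat], tpl0.phi[kmat],
                (np.arange(W * r_grid[0]) // r_grid[0]).astype(np.int64),
                1, float(r_grid[0] ** 2),
            )
        )
    h0_zero = float(np.mean(h00))

    seeds_by_n = {
        n: s.generate_state(config.n_runs) % (2**31 - 1)
        for n, s in zip(n_grid, master.spawn(len(n_grid)))
    }
    test_means = []
    for n in n_grid:
        tpl = get_templates(target.n_windows, r_grid[0])
        res = _runs_at(target, n, 0.0, r_grid[0], config, tpl, seeds_by_n[n])
        mtest = mean_test(res)
        test_means.append(mtest)
        curves["n"][n] = {
            "test": mtest / h0_zero,
            "train": float(np.mean([x.h0_train for x in res])) / h0_zero,
            "test_sd": float(np.std([x.h0_test for x in res], ddof=1)) / h0_zero,
        }
    test_means = np.asarray(test_means)
    # Parsimony tie-break: several n whose mean test costs differ by less
    # than the run-to-run SA noise are one plateau, and the smallest such n
    # is selected (one-standard-error-style rule with a 10% relative band).
    tie = [
        n
        for k, n in enumerate(n_grid)
        if test_means[k] <= test_means.min() * (1.0 + tie_tolerance)
    ]
    n_star = int(min(tie))
    ambiguous = len(tie) > 1

    lam_master = np.random.SeedSequence(config.seed + 101)
    lam_means = []
    for lam, s in zip(lambda_grid, lam_master.spawn(len(lambda_grid))):
        tpl = get_templates(target.n_windows, r_grid[0])
        res = _runs_at(
            target, n_star, lam, r_grid[0], config, tpl,
            s.generate_state(config.n_runs) % (2**31 - 1),
        )
        mtest = mean_test(res)
        lam_means.append(mtest)
        curves["lambda"][lam] = {"test": mtest / h0_zero}
    lam_means = np.asarray(lam_means)
    # same tie rule, toward larger lambda (sparser models)
    lam_tie = [
        lam
        for k, lam in enumerate(lambda_grid)
        if lam_means[k] <= lam_means.min() * (1.0 + tie_tolerance)
    ]
    lambda_star = float(max(lam_tie))

    r_best = []
    r_master = np.random.SeedSequence(config.seed + 202)
    for r, s in zip(r_grid, r_master.spawn(len(r_grid))):
        tpl = get_templates(target.n_windows, r)
        res = _runs_at(
            target, n_star, lambda_star, r, config, tpl,
            s.generate_state(max(5, config.n_runs // 2)) % (2**31 - 1),
        )
        best = float(np.min([x.h0_train for x in res]))
        r_best.append(best)
        curves["r"][r] = {"best_train": best / h0_zero}
    plateau = r_best[-1]
    r_star = r_grid[-1]
    for r, v in zip(r_grid, r_best):
        if v <= plateau * (1.0 + r_tolerance):
            r_star = r
            break
    return ModelSelection(
        n_star=n_star,
        lambda_star=lambda_star,
        r_star=int(r_star),
        curves=curves,
        ambiguous=ambiguous,
        tie_set=tie,
    )


# ---------------------------------------------------------------------------
# overlap and robustness statistics
# ---------------------------------------------------------------------------


def _window_sets(model) -> list[set]:
    """Per specific color, the set of windows holding >= 1 site of it."""
    counts = model.color_counts() if isinstance(model, PolymerModel) else np.asarray(model)
    return [set(np.where(counts[:, c] > 0)[0]) for c in range(1, counts.shape[1])]


def domain_overlap(a, b, matched: bool = False) -> dict:
    """Window-level overlap (%) between the binding domains of two models.

    ``pairwise[ca, cb] = 100 * |windows(ca) & windows(cb)| / |windows union|``.
    With ``matched=True`` the colors of ``b`` are optimally permuted
    (assignment problem) to maximize the mean same-color overlap.
    """
    ca = a.color_counts() if isinstance(a, PolymerModel) else np.asarray(a)
    cb = b.color_counts() if isinstance(b, PolymerModel) else np.asarray(b)
    if ca.shape[0] != cb.shape[0]:
        raise ValueError("models cover different window counts")
    sa_, sb_ = _window_sets(ca), _window_sets(cb)
    na, nb = len(sa_), len(sb_)
    pairwise = np.zeros((na, nb))
    for i in range(na):
        for j in range(nb):
            union = sa_[i] | sb_[j]
            pairwise[i, j] = (
                100.0 * len(sa_[i] & sb_[j]) / len(union) if union else 100.0
            )
    out = {"pairwise": pairwise}
    if matched:
        k = min(na, nb)
        ri, cj = linear_sum_assignment(-pairwise)
        out["permutation"] = dict(zip((ri + 1).tolist(), (cj + 1).tolist()))
        out["matched_mean"] = float(pairwise[ri, cj].sum() / k) if k else 100.0
    return out


def between_color_overlap(model) -> float:
    """Mean window overlap (%) between different colors of one model."""
    res = domain_overlap(model, model)["pairwise"]
    n = res.shape[0]
    if n < 2:
        return 0.0
    iu = np.triu_indices(n, k=1)
    return float(res[iu].mean())


def matched_bead_agreement(a: PolymerModel, b: PolymerModel) -> float:
    """Fraction of beads with equal color after optimal color permutation.

    Color 0 (no specific site) is fixed; only specific colors of ``b`` are
    permuted, by maximizing the bead-level confusion-matrix trace.
    """
    if a.n_beads != b.n_beads:
        raise ValueError("bead counts differ")
    n = max(a.n, b.n)
    conf = np.zeros((n + 1, n + 1))
    for ca, cb in zip(a.colors, b.colors):
        conf[ca, cb] += 1
    sub = conf[1:, 1:]
    ri, cj = linear_sum_assignment(-sub)
    agree = conf[0, 0] + sub[ri, cj].sum()
    return float(agree / a.n_beads)


def robustness_of_minima(results: list[InferenceResult], fraction: float = 0.10) -> dict:
    """Similarity among the lower-``fraction`` cost minima of an SA battery."""
    if not results:
        raise ValueError("no results")
    if len(results) == 1:
        return {"n_models": 1, "mean_overlap": float("nan"), "min_overlap": float("nan")}
    order = np.argsort([x.h_total for x in results])
    k = max(2, int(np.ceil(fraction * len(results))))
    chosen = [results[i].coloring for i in order[:k]]
    vals = [
        domain_overlap(x, y, matched=True)["matched_mean"]
        for x, y in itertools.combinations(chosen, 2)
    ]
    return {
        "n_models": k,
        "mean_overlap": float(np.mean(vals)),
        "min_overlap": float(np.min(vals)),
    }
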
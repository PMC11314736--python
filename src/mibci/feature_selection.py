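"""Five feature-ranking algorithms for CSP feature tables.

- ``relieff_scores``   — Relief-F, distance-weighted nearest hits/misses.
- ``inffs_scores``     — Inf-FS, unsupervised graph power-series ranking.
- ``ilfs_scores``      — ILFS, the same power-series machinery on an
                          adjacency learned from token/label statistics.
- ``fsv_rank``         — FSV, weights from a successively-linearized
                          concave-minimization margin separation program.
- ``sd_scores``        — Statistical Dependency of quantized features on
                          the labels (1 = independent, larger = dependent).

Every ranking is returned as a :class:`RankingResult` with a deterministic
descending-score order (ties broken by lower feature index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import linprog

from .io import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class RankingResult:
    """Per-feature scores and the induced descending-order ranking."""

    scores: np.ndarray
    order: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.order = np.asarray(self.order, dtype=int)

    @property
    def n_features(self) -> int:
        return len(self.scores)


def _rank_order(scores: np.ndarray) -> np.ndarray:
    """Indices sorted by descending score; ties keep the lower index first.

    Scores are snapped to 12 relative digits first so that values equal up
    to numerical noise (e.g. duplicated columns through a matrix inverse)
    tie deterministically.
    """
    s = np.asarray(scores, dtype=float)
    scale = np.max(np.abs(s)) if np.any(s) else 1.0
    snapped = np.round(s / scale, 12)
    # stable sort on negated scores preserves original index order for ties
    return np.argsort(-snapped, kind="stable")


def select_top(ranking: RankingResult, n: int) -> list[int]:
    """First ``n`` feature indices of the ranking."""
    if not (1 <= n <= ranking.n_features):
        raise ValueError(f"n must be in [1, {ranking.n_features}], got {n}")
    return ranking.order[:n].tolist()


# --------------------------------------------------------------------------
# Relief-F
# --------------------------------------------------------------------------

@dataclass
class ReliefFParams:
    """Relief-F knobs: neighbors k, rank-decay scale sigma, iterations m.

    ``n_iterations=None`` iterates over every instance (deterministic).
    """

    n_neighbors: int = 10
    sigma: float = 50.0
    n_iterations: int | None = None
    miss_prior: str = "quotient"  # "quotient" (canonical) or "product" (as printed)

    def __post_init__(self) -> None:
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.miss_prior not in ("quotient", "product"):
            raise ValueError("miss_prior must be 'quotient' or 'product'")


def relieff_scores(table: FeatureTable, params: ReliefFParams | None = None) -> RankingResult:
    """Relief-F feature weights with exponential rank-decay neighbor weighting.

    For each instance r, the k nearest hits (same class) and k nearest misses
    (per other class) update every feature weight: hits subtract the
    range-normalized feature difference, misses add it scaled by the prior
    quotient P(miss class) / (1 - P(class of r)).  Neighbor q's contribution
    is weighted by d(r,q) = exp(-(rank(r,q)/sigma)^2) normalized over the k
    neighbors of its group, and the whole update is averaged over the m
    sampled instances.  Constant features (zero range) score exactly 0.
    """
    if params is None:
        params = ReliefFParams()
    X, y = table.values, table.labels
    n, p = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("Relief-F needs at least two classes")
    for c, cnt in zip(classes, counts):
        if cnt < 2:
            raise ValueError(f"need >= 2 instances of class {c}")
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    rng_j = X.max(axis=0) - X.min(axis=0)
    ok = rng_j > 0  # constant features contribute Delta = 0
    safe_range = np.where(ok, rng_j, 1.0)

    # pairwise Manhattan distances on range-normalized features (constant
    # features are excluded from the metric — they carry no information)
    Xn = (X / safe_range)[:, ok]
    D = np.abs(Xn[:, None, :] - Xn[None, :, :]).sum(axis=2)
    np.fill_diagonal(D, np.inf)

    if params.n_iterations is None or params.n_iterations >= n:
        sample = np.arange(n)
    else:
        sample = np.arange(params.n_iterations)  # deterministic prefix
    m = len(sample)
    W = np.zeros(p)
    for r in sample:
        order = np.argsort(D[r], kind="stable")
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(1, n + 1)
        for c in classes:
            mask = y == c
            mask_idx = np.flatnonzero(mask & (np.arange(n) != r))
            if len(mask_idx) == 0:
                continue
            near = mask_idx[np.argsort(D[r, mask_idx], kind="stable")][: params.n_neighbors]
            decay = np.exp(-((ranks[near] / params.sigma) ** 2))
            tot = decay.sum()
            if tot <= 0:
                continue
            w_q = decay / tot
            delta = np.abs(X[near] - X[r]) / safe_range  # (k, p)
            delta[:, ~ok] = 0.0
            contrib = (w_q[:, None] * delta).sum(axis=0) / m
            if c == y[r]:
                W -= contrib
            else:
                if params.miss_prior == "quotient":
                    prior = priors[c] / (1.0 - priors[y[r]])
                else:
                    prior = priors[c] * (1.0 - priors[y[r]])
                W += prior * contrib
    return RankingResult(W, _rank_order(W), "relieff", vars(params).copy())


# --------------------------------------------------------------------------
# Inf-FS / ILFS power-series machinery
# --------------------------------------------------------------------------

@dataclass
class GraphFSParams:
    """Graph-ranking knobs shared by Inf-FS and ILFS.

    ``lam`` mixes dispersion against rank-correlation distance in the Inf-FS
    adjacency; ``r_factor`` sets the geometric-series damping as a fraction
    of 1/spectral-radius.
    """

    lam: float = 0.5
    r_factor: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lam must be in [0, 1]")
        if not (0.0 < self.r_factor < 1.0):
            raise ValueError("r_factor must be in (0, 1)")


def power_series_scores(A: np.ndarray, r_factor: float = 0.9) -> np.ndarray:
    """Row sums of S = (I - rA)^-1 - I with r = r_factor / spectral_radius(A).

    S sums the energies of all paths of every length through the feature
    graph, each length-l path damped by r^l; the row sum is the total energy
    flowing out of a feature.  A zero adjacency yields all-zero scores.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    rho = np.max(np.abs(np.linalg.eigvals(A)))
    if rho == 0:
        return np.zeros(n)
    r = r_factor / rho
    S = np.linalg.inv(np.eye(n) - r * A) - np.eye(n)
    return S @ np.ones(n)


def truncated_path_scores(A: np.ndarray, r_factor: float = 0.9, max_len: int = 50) -> np.ndarray:
    """Independent check of :func:`power_series_scores` by explicit path sums.

    Accumulates row sums of (rA)^l for l = 1..max_len; (A^l)_ij enumerates
    the energies of all length-l paths from i to j.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    rho = np.max(np.abs(np.linalg.eigvals(A)))
    if rho == 0:
        return np.zeros(n)
    rA = (r_factor / rho) * A
    term = np.eye(n)
    total = np.zeros((n, n))
    for _ in range(max_len):
        term = term @ rA
        total += term
    return total @ np.ones(n)


def _inffs_adjacency(X: np.ndarray, lam: float) -> np.ndarray:
    """Inf-FS adjacency a_ij = lam * max(sigma_i, sigma_j) + (1-lam) * (1 - Spearman_ij).

    The pairwise-max dispersion matrix is min-max normalized to [0, 1] so
    the two energy terms are commensurate and no single feature's scale
    dominates the blend.
    """
    n, p = X.shape
    sig = X.std(axis=0, ddof=1)
    disp = np.maximum(sig[:, None], sig[None, :])
    span = disp.max() - disp.min()
    disp = (disp - disp.min()) / (span if span > 0 else 1.0)
    if p >= 2 and n >= 3:
        rho_s = stats.spearmanr(X, axis=0).statistic
        rho_s = np.atleast_2d(rho_s)
        rho_s = np.where(np.isfinite(rho_s), rho_s, 0.0)
    else:
        rho_s = np.ones((p, p))
    corr_dist = 1.0 - rho_s
    np.fill_diagonal(corr_dist, 0.0)
    A = lam * disp + (1.0 - lam) * corr_dist
    return 0.5 * (A + A.T)


def inffs_scores(table: FeatureTable, params: GraphFSParams | None = None) -> RankingResult:
    """Inf-FS: rank features by total damped path energy in the feature graph."""
    if params is None:
        params = GraphFSParams()
    X = table.values
    if X.shape[1] < 2:
        raise ValueError("Inf-FS needs at least two features")
    if X.shape[0] < 3:
        raise ValueError("Inf-FS needs at least three instances (Spearman undefined)")
    A = _inffs_adjacency(X, params.lam)
    s = power_series_scores(A, params.r_factor)
    return RankingResult(s, _rank_order(s), "inf_fs", vars(params).copy())


def _equal_frequency_tokens(x: np.ndarray, tt: int) -> np.ndarray:
    """Quantize a feature into <= tt roughly equal-count integer tokens."""
    qs = np.quantile(x, np.linspace(0, 1, tt + 1)[1:-1])
    tokens = np.searchsorted(qs, x, side="right")
    return tokens


def _token_class_separation(X: np.ndarray, y: np.ndarray, tt: int) -> np.ndarray:
    """Per-feature total-variation distance between class-conditional token laws."""
    classes = np.unique(y)
    p = X.shape[1]
    sep = np.zeros(p)
    for j in range(p):
        tok = _equal_frequency_tokens(X[:, j], tt)
        d1 = np.bincount(tok[y == classes[0]], minlength=tt).astype(float)
        d2 = np.bincount(tok[y == classes[1]], minlength=tt).astype(float)
        d1 /= d1.sum()
        d2 /= d2.sum()
        sep[j] = 0.5 * np.abs(d1 - d2).sum()
    return sep


def _two_class_mixture_em(s: np.ndarray, n_iter: int = 200, tol: float = 1e-8) -> np.ndarray:
    """Posterior P(relevant | s) from a two-component 1-D Gaussian mixture.

    Deterministic initialization: component means at the lower/upper quartile
    of s, equal weights, shared variance.  Returns the responsibility of the
    higher-mean ("relevant") component.
    """
    s = np.asarray(s, dtype=float)
    if np.ptp(s) < 1e-12:
        return np.full(len(s), 0.5)
    mu = np.array([np.quantile(s, 0.25), np.quantile(s, 0.75)])
    if mu[0] == mu[1]:
        mu = np.array([s.min(), s.max()])
    var = np.full(2, max(s.var(), 1e-12))
    pi = np.array([0.5, 0.5])
    gamma = np.zeros((len(s), 2))
    for _ in range(n_iter):
        log_like = -0.5 * ((s[:, None] - mu) ** 2 / var + np.log(2 * np.pi * var))
        log_post = np.log(pi) + log_like
        log_post -= log_post.max(axis=1, keepdims=True)
        new_gamma = np.exp(log_post)
        new_gamma /= new_gamma.sum(axis=1, keepdims=True)
        if np.abs(new_gamma - gamma).max() < tol:
            gamma = new_gamma
            break
        gamma = new_gamma
        nk = gamma.sum(axis=0) + 1e-12
        mu = (gamma * s[:, None]).sum(axis=0) / nk
        var = ((gamma * (s[:, None] - mu) ** 2).sum(axis=0) / nk) + 1e-12
        pi = nk / len(s)
    hi = int(np.argmax(mu))
    return gamma[:, hi]


def ilfs_scores(
    table: FeatureTable,
    params: GraphFSParams | None = None,
    tt: int = 6,
    labels: np.ndarray | None = None,
) -> RankingResult:
    """ILFS: power-series ranking on an adjacency learned from the labels.

    Features are discretized into ``tt`` equal-frequency tokens; the
    separation of each feature's class-conditional token distributions feeds
    a two-latent-class Gaussian mixture (EM, deterministic init) whose
    posterior gives a per-feature relevance probability p(i).  The adjacency
    a_ij = p(i) p(j) then goes through the same damped geometric series as
    Inf-FS.
    """
    if params is None:
        params = GraphFSParams()
    if tt < 2:
        raise ValueError("token count tt must be >= 2")
    X = table.values
    y = table.labels if labels is None else np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValueError("ILFS requires binary labels")
    if X.shape[1] < 2:
        raise ValueError("ILFS needs at least two features")
    sep = _token_class_separation(X, y, tt)
    prob = _two_class_mixture_em(sep)
    # blend posterior with the raw separation so ordering inside a latent
    # class is still resolved by the evidence itself
    rel = prob * (1.0 + sep)
    A = np.outer(rel, rel)
    s = power_series_scores(A, params.r_factor)
    return RankingResult(s, _rank_order(s), "ilfs", {**vars(params), "tt": tt})


# --------------------------------------------------------------------------
# FSV — feature selection via successive linear programming
# --------------------------------------------------------------------------

def fsv_rank(
    table: FeatureTable,
    labels: np.ndarray | None = None,
    max_iter: int = 20,
    alpha: float = 0.3,
    beta: float = 5.0,
    tol: float = 1e-6,
) -> RankingResult:
    """FSV: margin-separation weights from iterated linear programs.

    Solves the concave-minimization feature-selection program by successive
    linearization: each step is the LP

        min  (1-alpha) * (avg slack class 1 + avg slack class 2)
             + alpha * sum_j beta * exp(-beta * v_j_prev) * v_j
        s.t. class-1 rows:  x.w - g + y_i >= 1,   y_i >= 0
             class-2 rows: -(x.w - g) + z_i >= 1, z_i >= 0
             -v <= w <= v

    where the exponential term is the gradient of the concave penalty
    sum_j (1 - exp(-beta v_j)) suppressing unneeded features.  Features are
    ranked by |w| descending.
    """
    X = table.values
    y = table.labels if labels is None else np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("FSV requires binary labels")
    span = X.max(axis=0) - X.min(axis=0)
    if np.all(span == 0):
        raise ValueError("all features constant")
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    Xs = (X - mu) / np.where(sd > 0, sd, 1.0)
    A1 = Xs[y == classes[0]]
    A2 = Xs[y == classes[1]]
    m1, m2 = len(A1), len(A2)
    if m1 == 0 or m2 == 0:
        raise ValueError("need at least one instance per class")
    p = X.shape[1]
    # variable layout: [w (p), g (1), y (m1), z (m2), v (p)]
    nvar = p + 1 + m1 + m2 + p

    def solve_lp(v_prev: np.ndarray) -> np.ndarray | None:
        c = np.zeros(nvar)
        c[p + 1 : p + 1 + m1] = (1.0 - alpha) / m1
        c[p + 1 + m1 : p + 1 + m1 + m2] = (1.0 - alpha) / m2
        c[p + 1 + m1 + m2 :] = alpha * beta * np.exp(-beta * v_prev)
        # margin constraints, as A_ub x <= b_ub
        ub_rows, ub_b = [], []
        for i in range(m1):  # -(a.w) + g - y_i <= -1
            row = np.zeros(nvar)
            row[:p] = -A1[i]
            row[p] = 1.0
            row[p + 1 + i] = -1.0
            ub_rows.append(row)
            ub_b.append(-1.0)
        for i in range(m2):  # a.w - g - z_i <= -1
            row = np.zeros(nvar)
            row[:p] = A2[i]
            row[p] = -1.0
            row[p + 1 + m1 + i] = -1.0
            ub_rows.append(row)
            ub_b.append(-1.0)
        for j in range(p):  # w_j - v_j <= 0 and -w_j - v_j <= 0
            row = np.zeros(nvar)
            row[j] = 1.0
            row[p + 1 + m1 + m2 + j] = -1.0
            ub_rows.append(row)
            ub_b.append(0.0)
            row = np.zeros(nvar)
            row[j] = -1.0
            row[p + 1 + m1 + m2 + j] = -1.0
            ub_rows.append(row)
            ub_b.append(0.0)
        bounds = (
            [(None, None)] * p + [(None, None)] + [(0, None)] * (m1 + m2) + [(0, None)] * p
        )
        res = linprog(c, A_ub=np.array(ub_rows), b_ub=np.array(ub_b), bounds=bounds, method="highs")
        return res.x if res.success else None

    v = np.zeros(p)
    w = np.zeros(p)
    converged = False
    for it in range(max_iter):
        sol = solve_lp(v)
        if sol is None:
            raise RuntimeError("FSV linear program failed to solve")
        w_new, v_new = sol[:p], sol[p + 1 + m1 + m2 :]
        if np.abs(v_new - v).max() < tol:
            w, v = w_new, v_new
            converged = True
            break
        w, v = w_new, v_new
    if not converged:
        logger.info("FSV reached max_iter=%d without v-convergence", max_iter)
    scores = np.abs(w)
    return RankingResult(
        scores,
        _rank_order(scores),
        "fsv",
        {"max_iter": max_iter, "alpha": alpha, "beta": beta, "converged": converged},
    )


# --------------------------------------------------------------------------
# FSV validation measures (ADM / FDM / GDM)
# --------------------------------------------------------------------------

@dataclass
class GDMResult:
    """Pointwise amplitude (ADM), shape (FDM) and global (GDM) differences."""

    adm: np.ndarray
    fdm: np.ndarray
    gdm: np.ndarray

    @property
    def gdm_total(self) -> float:
        return float(self.gdm.sum())


def _dc_lo_hi_split(x: np.ndarray, nb: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a series into DC, low- and high-frequency parts in the DFT domain.

    The break index Ib is where the cumulative magnitude spectrum (excluding
    DC) reaches 40% of its total; a linear taper over ``nb`` bins blends the
    two sides so the split is smooth.  The split is linear in x.
    """
    n = len(x)
    spec = np.fft.rfft(x)
    mag = np.abs(spec)
    dc_spec = np.zeros_like(spec)
    dc_spec[0] = spec[0]
    body = mag[1:]
    total = body.sum()
    if total == 0:
        zero = np.zeros(n)
        return np.fft.irfft(dc_spec, n), zero, zero
    cum = np.cumsum(body) / total
    ib = 1 + int(np.searchsorted(cum, 0.4))
    k = np.arange(len(spec))
    lo_gain = np.clip((ib + nb / 2.0 - k) / max(nb, 1), 0.0, 1.0)
    lo_gain[0] = 0.0
    hi_gain = (1.0 - lo_gain)
    hi_gain[0] = 0.0
    lo = np.fft.irfft(spec * lo_gain, n)
    hi = np.fft.irfft(spec * hi_gain, n)
    return np.fft.irfft(dc_spec, n), lo, hi


def fsv_gdm(series_a: np.ndarray, series_b: np.ndarray, nb: int = 4) -> GDMResult:
    """Amplitude/feature/global difference measures between two data vectors.

    Both series are decomposed into DC + low + high frequency portions.  The
    amplitude measure compares pointwise intensities of the low portions; the
    feature (shape) measure compares first derivatives of the low and high
    portions; both use the intensity-ratio normalization c so that a globally
    scaled copy of a series registers zero difference.  Pointwise
    GDM_i = sqrt(ADM_i^2 + FDM_i^2).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be equal-length 1-D vectors")
    if len(a) < 4:
        raise ValueError("series length must be >= 4")
    denom_b = np.abs(b).mean()
    if np.abs(a).mean() == 0 or denom_b == 0:
        raise ValueError("zero-energy input series")
    c = np.abs(a).mean() / denom_b

    dc_a, lo_a, hi_a = _dc_lo_hi_split(a, nb)
    dc_b, lo_b, hi_b = _dc_lo_hi_split(b, nb)

    amp_a, amp_b = dc_a + lo_a, dc_b + lo_b
    norm_amp = (np.abs(amp_a) + c * np.abs(amp_b)).mean()
    adm = np.abs(amp_a - c * amp_b) / (norm_amp if norm_amp > 0 else 1.0)

    d_lo = np.gradient(lo_a) - c * np.gradient(lo_b)
    d_hi = np.gradient(hi_a) - c * np.gradient(hi_b)
    norm_f = (
        np.abs(np.gradient(lo_a)).mean()
        + c * np.abs(np.gradient(lo_b)).mean()
        + np.abs(np.gradient(hi_a)).mean()
        + c * np.abs(np.gradient(hi_b)).mean()
    )
    fdm = (np.abs(d_lo) + np.abs(d_hi)) / (norm_f if norm_f > 0 else 1.0)

    gdm = np.sqrt(adm**2 + fdm**2)
    return GDMResult(adm=adm, fdm=fdm, gdm=gdm)


# --------------------------------------------------------------------------
# Statistical Dependency
# --------------------------------------------------------------------------

def sd_statistic(tokens: np.ndarray, labels: np.ndarray) -> float:
    """Dependency of a discrete feature on the labels.

    Computed as sum_{y,z} p(y,z)^2 / (p(y) p(z)) over the empirical joint;
    equals exactly 1 when the joint factorizes (independence) and grows with
    dependence, up to min(|Y|, |Z|) for a deterministic relation.
    """
    tokens = np.asarray(tokens)
    labels = np.asarray(labels)
    ys, zs = np.unique(tokens), np.unique(labels)
    n = len(tokens)
    sd = 0.0
    for yv in ys:
        py = (tokens == yv).mean()
        for zv in zs:
            pyz = ((tokens == yv) & (labels == zv)).sum() / n
            if pyz > 0:
                pz = (labels == zv).mean()
                sd += pyz * pyz / (py * pz)
    return float(sd)


def sd_scores(table: FeatureTable, labels: np.ndarray | None = None, qs: int = 4) -> RankingResult:
    """Statistical Dependency score per feature after adaptive quantization.

    Each feature is quantized into ``qs`` equal-frequency bins (fewer when
    the feature has fewer distinct values; merges are logged) and scored by
    :func:`sd_statistic` against the class labels.
    """
    if qs < 2:
        raise ValueError("qs must be >= 2")
    X = table.values
    y = table.labels if labels is None else np.asarray(labels)
    if X.shape[0] < qs:
        raise ValueError("need at least qs instances")
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        tok = _equal_frequency_tokens(X[:, j], qs)
        n_bins = len(np.unique(tok))
        if n_bins < qs:
            logger.debug("feature %d: only %d distinct bins (requested %d)", j, n_bins, qs)
        scores[j] = sd_statistic(tok, y)
    return RankingResult(scores, _rank_order(scores), "sd", {"qs": qs})


_METHODS = {
    "relieff": lambda t, **kw: relieff_scores(t, kw.get("relieff_params")),
    "inf_fs": lambda t, **kw: inffs_scores(t, kw.get("graph_params")),
    "ilfs": lambda t, **kw: ilfs_scores(t, kw.get("graph_params"), tt=kw.get("tt", 6)),
    "fsv": lambda t, **kw: fsv_rank(t, max_iter=kw.get("max_iter", 20)),
    "sd": lambda t, **kw: sd_scores(t, qs=kw.get("qs", 4)),
}


def rank_features(table: FeatureTable, method: str, **kwargs) -> RankingResult:
    """Dispatch to one of the five selectors by name."""
    if method not in _METHODS:
        raise ValueError(f"unknown selector '{method}'; valid: {sorted(_METHODS)}")
    return _METHODS[method](table, **kwargs)
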
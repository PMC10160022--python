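"""Cell-state dynamics in the embedded landscape.

Quantities computed on embedded trajectories (time-ordered snippet
coordinates per cell history, giving T - n_tau single-step transitions):

* overlap coefficient between per-treatment state distributions,
  sum_bins min(p, q) on a shared grid (1 identical, 0 disjoint);
* locality ratio: RMS single-step displacement divided by the RMS
  displacement between random population pairs, so fully random trajectories
  score 1, deterministic frozen trajectories 0, and a stationary AR(1)
  process with coefficient phi scores sqrt(1 - phi);
* force-field: per-bin mean single-step displacement, proportional to the
  effective drift of a Markovian diffusion;
* microstate Markov model: k-means microbins (k = 100 by default), row-
  normalized transition matrix T_ij = C_ij / C_i from observed transition
  counts, and the mean per-step validation log-likelihood <L> = mean log T_ij;
* metastable-state extraction: per-treatment KDE density peaks merged across
  treatments, kinetically grouped into macrostates by spectral clustering of
  the symmetrized transition matrix, with coarse transition networks;
* Bayesian bootstrap (Dirichlet(1,...,1) weights over replicates) for 95%
  confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.stats import gaussian_kde

__all__ = [
    "LandscapeGrid",
    "TransitionMatrix",
    "ForceField",
    "StateNetwork",
    "MarkovStateModel",
    "make_shared_grid",
    "histogram_on_grid",
    "overlap_coefficient",
    "mean_pairwise_overlap",
    "locality_ratio",
    "force_field",
    "fit_microstates",
    "estimate_transition_matrix",
    "trajectory_log_likelihood",
    "find_density_peaks",
    "coarse_grain_states",
    "bayesian_bootstrap_ci",
]


# ---------------------------------------------------------------------------
# shared grid and overlap


@dataclass
class LandscapeGrid:
    """Shared 2-D histogram bin edges over pooled embedded coordinates."""

    edges: tuple[np.ndarray, np.ndarray]

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.edges[0]) - 1, len(self.edges[1]) - 1


def make_shared_grid(
    pooled: np.ndarray, bins: int = 100, pct: tuple[float, float] = (1.0, 99.0)
) -> LandscapeGrid:
    """Grid spanning the given percentile box of the pooled coordinates."""
    pooled = np.asarray(pooled, dtype=float)
    lo = np.percentile(pooled, pct[0], axis=0)
    hi = np.percentile(pooled, pct[1], axis=0)
    edges = tuple(np.linspace(lo[d], hi[d], bins + 1) for d in range(pooled.shape[1]))
    return LandscapeGrid(edges=edges)


def histogram_on_grid(coords: np.ndarray, grid: LandscapeGrid) -> np.ndarray:
    """Normalized occupancy histogram of coordinates on a shared grid.

    Points outside the grid are clipped into the border bins so every
    treatment's histogram sums to exactly 1.
    """
    coords = np.asarray(coords, dtype=float)
    clipped = np.column_stack(
        [
            np.clip(coords[:, d], grid.edges[d][0], grid.edges[d][-1])
            for d in range(coords.shape[1])
        ]
    )
    h, _ = np.histogramdd(clipped, bins=grid.edges)
    total = h.sum()
    if total == 0:
        raise ValueError("no points fall on the grid")
    return h / total


def overlap_coefficient(p: np.ndarray, q: np.ndarray) -> float:
    """Sum of the pointwise minimum of two probability distributions.

    1 for identical distributions, 0 for disjoint supports.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must live on the same grid")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("distributions must be nonnegative")
    for name, arr in (("p", p), ("q", q)):
        if not np.isclose(arr.sum(), 1.0, atol=1e-8):
            raise ValueError(f"{name} must sum to 1 (got {arr.sum():.6g})")
    return float(np.minimum(p, q).sum())


def mean_pairwise_overlap(
    coords_by_treatment: dict[str, np.ndarray],
    grid: LandscapeGrid | None = None,
    bins: int = 100,
) -> tuple[float, dict[tuple[str, str], float]]:
    """Average overlap coefficient over all unordered treatment pairs.

    Histograms are built on a shared grid (constructed from the pooled
    coordinates if not given).  Empty treatments are excluded with a warning.
    """
    coords_by_treatment = {
        k: np.asarray(v, dtype=float) for k, v in coords_by_treatment.items()
    }
    empty = [k for k, v in coords_by_treatment.items() if v.size == 0]
    for k in empty:
        warnings.warn(f"treatment {k!r} has no coordinates; excluded from overlap")
        del coords_by_treatment[k]
    names = sorted(coords_by_treatment)
    if len(names) < 2:
        raise ValueError("need at least 2 nonempty treatments")
    if grid is None:
        pooled = np.vstack([coords_by_treatment[k] for k in names])
        grid = make_shared_grid(pooled, bins=bins)
    hists = {k: histogram_on_grid(coords_by_treatment[k], grid) for k in names}
    pair: dict[tuple[str, str], float] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pair[(a, b)] = overlap_coefficient(hists[a], hists[b])
    return float(np.mean(list(pair.values()))), pair


# ---------------------------------------------------------------------------
# locality ratio and force field


def _stack_transitions(trajectories: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All points, transition start points, and displacement vectors."""
    pts, starts, disps = [], [], []
    for tr in trajectories:
        tr = np.atleast_2d(np.asarray(tr, dtype=float))
        pts.append(tr)
        if tr.shape[0] >= 2:
            starts.append(tr[:-1])
            disps.append(np.diff(tr, axis=0))
    if not pts:
        raise ValueError("no trajectories given")
    points = np.vstack(pts)
    if not disps:
        raise ValueError("no transitions available")
    return points, np.vstack(starts), np.vstack(disps)


def locality_ratio(trajectories: list[np.ndarray]) -> float:
    """Predictability of embedded trajectories.

    numerator: RMS single-step displacement over all trajectories and
    timepoints, summed over embedding dimensions before the square root;
    denominator: RMS displacement between two random draws from the pooled
    population, i.e. sqrt(2) times the population RMS deviation from the
    mean.  Fully random (i.i.d.-position) trajectories give 1; frozen
    trajectories give 0; a stationary AR(1) with coefficient phi gives
    sqrt(1 - phi).
    """
    points, _, disps = _stack_transitions(trajectories)
    var_total = np.sum(np.var(points, axis=0))
    if var_total == 0:
        raise ValueError("zero population variance: locality ratio undefined")
    num = np.sqrt(np.mean(np.sum(disps**2, axis=1)))
    den = np.sqrt(2.0 * var_total)
    return float(num / den)


@dataclass
class ForceField:
    """Per-bin mean single-step displacement (effective drift) and occupancy."""

    grid: LandscapeGrid
    mean_displacement: np.ndarray  # (nbins_x, nbins_y, d); NaN where undefined
    occupancy: np.ndarray  # (nbins_x, nbins_y) transition start counts
    min_count: int


def force_field(
    trajectories: list[np.ndarray], grid: LandscapeGrid, min_count: int = 5
) -> ForceField:
    """Mean single-step displacement of all transitions starting in each bin."""
    _, starts, disps = _stack_transitions(trajectories)
    nb = grid.shape
    d = starts.shape[1]
    idx = []
    for dim in range(2):
        i = np.digitize(starts[:, dim], grid.edges[dim]) - 1
        idx.append(np.clip(i, 0, nb[dim] - 1))
    flat = idx[0] * nb[1] + idx[1]
    occ = np.bincount(flat, minlength=nb[0] * nb[1]).astype(float)
    mean = np.full((nb[0] * nb[1], d), np.nan)
    for dim in range(d):
        s = np.bincount(flat, weights=disps[:, dim], minlength=nb[0] * nb[1])
        ok = occ >= min_count
        mean[ok, dim] = s[ok] / occ[ok]
    return ForceField(
        grid=grid,
        mean_displacement=mean.reshape(nb[0], nb[1], d),
        occupancy=occ.reshape(nb),
        min_count=min_count,
    )


# ---------------------------------------------------------------------------
# microstate Markov model


def fit_microstates(
    coordinates: np.ndarray, k: int = 100, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """k-means microbins over embedded coordinates.

    Returns (centers, assignments); assignment is by nearest center (the
    k-means Voronoi partition).
    """
    from sklearn.cluster import KMeans

    X = np.asarray(coordinates, dtype=float)
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} points, got {X.shape[0]}")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(X)
    return km.cluster_centers_, km.labels_.astype(int)


def assign_microstates(coordinates: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Nearest-center microstate assignment."""
    X = np.atleast_2d(np.asarray(coordinates, dtype=float))
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


@dataclass
class TransitionMatrix:
    """Row-stochastic microstate transition matrix with raw counts retained."""

    counts: np.ndarray  # (k, k) integer counts C_ij
    probabilities: np.ndarray  # T_ij = C_ij / C_i where C_i > 0
    centers: np.ndarray | None = None
    empty_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def k(self) -> int:
        return self.counts.shape[0]


def estimate_transition_matrix(
    assignment_trajectories: list[np.ndarray],
    k: int,
    centers: np.ndarray | None = None,
) -> TransitionMatrix:
    """Count single-step microstate transitions along each trajectory.

    Rows with outgoing transitions are normalized to probabilities; rows with
    no observed transitions are left as zeros and flagged in ``empty_rows``.
    Birth/death of cells is deliberately not modeled: the matrix conditions
    on observed consecutive pairs only.
    """
    C = np.zeros((k, k), dtype=np.int64)
    n_trans = 0
    for a in assignment_trajectories:
        a = np.asarray(a, dtype=int)
        if a.size >= 2:
            np.add.at(C, (a[:-1], a[1:]), 1)
            n_trans += a.size - 1
    if n_trans == 0:
        raise ValueError("no transitions observed")
    row = C.sum(axis=1)
    P = np.zeros_like(C, dtype=float)
    nz = row > 0
    P[nz] = C[nz] / row[nz, None]
    return TransitionMatrix(
        counts=C,
        probabilities=P,
        centers=centers,
        empty_rows=np.flatnonzero(~nz),
    )


def trajectory_log_likelihood(
    tm: TransitionMatrix,
    validation_trajectories: list[np.ndarray],
    pseudocount: float | None = None,
) -> float:
    """Mean log-likelihood per step of validation trajectories, <L> = mean log T_ij.

    ``pseudocount`` (default 1/k) is added to every count before
    normalization so unseen validation transitions have finite likelihood;
    pass ``pseudocount=0`` for the strict estimator, which raises if a
    validation transition has zero training probability.
    """
    k = tm.k
    alpha = 1.0 / k if pseudocount is None else float(pseudocount)
    if alpha > 0:
        C = tm.counts + alpha
        P = C / C.sum(axis=1, keepdims=True)
    else:
        P = tm.probabilities
    logs = []
    for a in validation_trajectories:
        a = np.asarray(a, dtype=int)
        if a.size < 2:
            continue
        p = P[a[:-1], a[1:]]
        if alpha <= 0 and np.any(p == 0):
            raise ValueError("validation transition with zero training probability")
        logs.append(np.log(p))
    if not logs:
        raise ValueError("empty validation set")
    return float(np.mean(np.concatenate(logs)))


class MarkovStateModel:
    """Microstate Markov model of embedded cell-state dynamics.

    fit() clusters the training coordinates into k microbins and estimates
    the transition matrix from the training trajectories; score() assigns
    validation trajectories to the fitted microbins and returns the mean
    per-step log-likelihood.
    """

    def __init__(self, k: int = 100, seed: int = 0, pseudocount: float | None = None):
        self.k = k
        self.seed = seed
        self.pseudocount = pseudocount
        self.centers_: np.ndarray | None = None
        self.transition_matrix_: TransitionMatrix | None = None

    def fit(self, trajectories: list[np.ndarray]) -> "MarkovStateModel":
        pooled = np.vstack([np.atleast_2d(t) for t in trajectories])
        self.centers_, _ = fit_microstates(pooled, k=self.k, seed=self.seed)
        assigns = [assign_microstates(t, self.centers_) for t in trajectories]
        self.transition_matrix_ = estimate_transition_matrix(
            assigns, k=self.k, centers=self.centers_
        )
        return self

    def score(self, trajectories: list[np.ndarray]) -> float:
        if self.transition_matrix_ is None:
            raise RuntimeError("model not fitted")
        assigns = [assign_microstates(t, self.centers_) for t in trajectories]
        return trajectory_log_likelihood(
            self.transition_matrix_, assigns, pseudocount=self.pseudocount
        )


# ---------------------------------------------------------------------------
# metastable states and coarse graining


def find_density_peaks(
    coords_by_treatment: dict[str, np.ndarray],
    grid: LandscapeGrid,
    bandwidth: str | float = "scott",
    min_density_frac: float = 0.05,
    merge_radius: float | None = None,
) -> list[dict]:
    """Fine-grained metastable locations: per-treatment KDE density maxima.

    A kernel-density estimate is evaluated on the shared grid per treatment;
    local maxima above ``min_density_frac`` of that treatment's peak density
    are kept, then peaks within ``merge_radius`` (default: one mean KDE
    bandwidth) are deduplicated across treatments.  Returns a list of
    ``{"location": (x, y), "treatment": name, "density": value}``.

    The default bandwidth is 1.5x Scott's rule: at exactly Scott scale the
    flat top of a sampled density mode carries noise-induced spurious local
    maxima, and mild oversmoothing suppresses them without displacing
    well-separated peaks.
    """
    cx = 0.5 * (grid.edges[0][:-1] + grid.edges[0][1:])
    cy = 0.5 * (grid.edges[1][:-1] + grid.edges[1][1:])
    XX, YY = np.meshgrid(cx, cy, indexing="ij")
    eval_pts = np.vstack([XX.ravel(), YY.ravel()])

    candidates = []
    bws = []
    for name in sorted(coords_by_treatment):
        pts = np.asarray(coords_by_treatment[name], dtype=float)
        if pts.shape[0] < 3:
            continue
        bw = (lambda k: k.scotts_factor() * 1.5) if bandwidth == "scott" else bandwidth
        kde = gaussian_kde(pts.T, bw_method=bw)
        bws.append(float(np.sqrt(np.trace(kde.covariance) / 2.0)))
        dens = kde(eval_pts).reshape(XX.shape)
        local_max = ndi.maximum_filter(dens, size=3, mode="nearest") == dens
        thr = min_density_frac * dens.max()
        for i, j in zip(*np.nonzero(local_max & (dens > thr))):
            candidates.append(
                {
                    "location": (float(cx[i]), float(cy[j])),
                    "treatment": name,
                    "density": float(dens[i, j]),
                }
            )
    if merge_radius is None:
        merge_radius = float(np.mean(bws)) if bws else 1.0
    # greedy dedupe: keep the densest representative of each neighborhood
    candidates.sort(key=lambda c: -c["density"])
    peaks: list[dict] = []
    for c in candidates:
        loc = np.array(c["location"])
        if all(np.linalg.norm(loc - np.array(p["location"])) > merge_radius for p in peaks):
            peaks.append(c)
    return peaks


@dataclass
class StateNetwork:
    """Fine-grained peaks grouped into coarse metastable states."""

    peaks: list[dict]
    micro_to_macro: np.ndarray  # (k,) macrostate index of each microstate
    peak_to_macro: np.ndarray  # (n_peaks,) macrostate index of each peak
    coarse_counts: np.ndarray  # (n_macro, n_macro)
    coarse_probabilities: np.ndarray  # rows with counts sum to 1


def coarse_grain_states(
    tm: TransitionMatrix,
    peaks: list[dict],
    n_macro: int,
    seed: int = 0,
    manual_map: np.ndarray | None = None,
) -> StateNetwork:
    """Group microstates into kinetic basins and build the coarse network.

    Microstates are grouped by spectral (PCCA-style) clustering: k-means on
    the leading ``n_macro`` eigenvectors of the symmetrized transition
    matrix.  ``manual_map`` (a microstate -> macrostate index array)
    overrides the unsupervised grouping, supporting manually refined state
    definitions.  Peaks are assigned the macrostate of their nearest
    microstate center.
    """
    if n_macro > len(peaks) and peaks:
        raise ValueError("n_macro exceeds the number of fine-grained peaks")
    k = tm.k
    if manual_map is not None:
        micro_to_macro = np.asarray(manual_map, dtype=int)
    elif n_macro >= k:
        micro_to_macro = np.arange(k)
    else:
        from sklearn.cluster import KMeans

        P = tm.probabilities.copy()
        empty = tm.counts.sum(axis=1) == 0
        P[empty, empty] = 1.0  # absorbing placeholder for unvisited bins
        S = 0.5 * (P + P.T)
        S = S / S.sum(axis=1, keepdims=True)
        vals, vecs = np.linalg.eig(S)
        order = np.argsort(-np.real(vals))
        emb = np.real(vecs[:, order[:n_macro]])
        micro_to_macro = KMeans(n_clusters=n_macro, random_state=seed, n_init=10).fit_predict(emb)

    n_m = int(micro_to_macro.max()) + 1
    onehot = np.zeros((k, n_m))
    onehot[np.arange(k), micro_to_macro] = 1.0
    coarse = onehot.T @ tm.counts @ onehot
    row = coarse.sum(axis=1)
    probs = np.zeros_like(coarse)
    nz = row > 0
    probs[nz] = coarse[nz] / row[nz, None]

    if peaks and tm.centers is not None:
        locs = np.array([p["location"] for p in peaks])
        nearest = assign_microstates(locs, tm.centers)
        peak_to_macro = micro_to_macro[nearest]
    else:
        peak_to_macro = np.array([], dtype=int)
    return StateNetwork(
        peaks=peaks,
        micro_to_macro=micro_to_macro,
        peak_to_macro=peak_to_macro,
        coarse_counts=coarse,
        coarse_probabilities=probs,
    )


# ---------------------------------------------------------------------------
# bootstrap


def bayesian_bootstrap_ci(
    values, n_draws: int = 10_000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Bayesian bootstrap mean and 95% interval over replicate values.

    Each draw reweights the replicates with Dirichlet(1, ..., 1) weights; the
    interval is the 2.5/97.5 percentile range of the weighted means.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 replicate values")
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.ones(v.size), size=n_draws)
    means = w @ v
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(v.mean()), (float(lo), float(hi))
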
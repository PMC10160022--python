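"""Synthetic data generation: hidden-state feature trajectories and rendered movies.

Two independent generators feed the test surface of the pipeline:

* :func:`simulate_feature_trajectories` produces per-cell feature time series
  governed by a hidden Markov chain with discrete-time Ornstein--Uhlenbeck
  relaxation toward the current state mean.  These trajectories stand in for
  the PCA-reduced features of real cells, so the embedding and dynamics layers
  can be exercised against known ground-truth dynamics without any imaging.
* :func:`render_movie` draws textured elliptical cells moving (and optionally
  dividing) over a noisy background, returning the image stack, exact label
  masks, and the true frame-to-frame links, so preprocessing, featurization
  and tracking can be scored against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "HiddenStateSimSpec",
    "MovieSimSpec",
    "GroundTruth",
    "simulate_feature_trajectories",
    "render_movie",
    "save_movie",
    "save_ground_truth",
    "trajectories_to_frame",
]


@dataclass
class HiddenStateSimSpec:
    """Specification of a hidden-Markov-state feature-trajectory simulation.

    Each cell carries a hidden state s_t evolving by ``transition_matrix``;
    its feature vector relaxes toward the mean of the current state:

        x_{t+1} = x_t + relaxation_rate * (mu_{s_{t+1}} - x_t) + eps,
        eps ~ N(0, noise_sd^2 I).

    ``observed_dims`` selects which feature dimensions are exposed downstream;
    withholding an informative dimension emulates partial observation of cell
    state, the regime where temporal context carries extra information.
    """

    n_states: int
    state_means: np.ndarray  # (n_states, n_features)
    relaxation_rate: float
    noise_sd: float
    transition_matrix: np.ndarray  # (n_states, n_states), row-stochastic
    n_cells: int
    n_frames: int
    observed_dims: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.state_means = np.atleast_2d(np.asarray(self.state_means, dtype=float))
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)

    @property
    def n_features(self) -> int:
        return self.state_means.shape[1]

    def validate(self) -> None:
        if self.state_means.shape[0] != self.n_states:
            raise ValueError("state_means must have one row per state")
        T = self.transition_matrix
        if T.shape != (self.n_states, self.n_states):
            raise ValueError("transition_matrix must be n_states x n_states")
        if np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition_matrix rows must be nonnegative and sum to 1")
        if not (0.0 < self.relaxation_rate <= 1.0):
            raise ValueError("relaxation_rate must lie in (0, 1]")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.observed_dims is not None:
            dims = tuple(self.observed_dims)
            if len(dims) == 0 or any(d < 0 or d >= self.n_features for d in dims):
                raise ValueError("observed_dims must be a nonempty subset of feature indices")


@dataclass
class MovieSimSpec:
    """Specification of a rendered synthetic movie with ground-truth masks."""

    image_size: tuple[int, int] = (128, 128)
    n_cells: int = 5
    cell_radius_mean: float = 8.0
    cell_radius_sd: float = 1.0
    motion_sd_px: float = 2.0
    drift_px: tuple[float, float] = (0.0, 0.0)
    division_prob: float = 0.0
    background_noise_sd: float = 0.05
    n_frames: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.division_prob <= 1.0):
            raise ValueError("division_prob must be in [0, 1]")
        if self.cell_radius_mean <= 0:
            raise ValueError("cell radius must be positive")
        h, w = self.image_size
        if min(h, w) < 4 * self.cell_radius_mean:
            raise ValueError("image too small to hold one cell")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass
class GroundTruth:
    """Ground truth emitted by the simulators.

    ``true_links`` holds directed frame-to-frame correspondences as tuples
    ``(t, label_t, t+1, label_t1)`` using the per-frame mask labels.  For the
    feature-trajectory simulator labels are cell indices and every cell spans
    all frames; for movies, daughters of a division receive fresh labels, both
    linked back to the parent.
    """

    hidden_states: np.ndarray | None = None  # (n_cells, n_frames) int
    true_links: set[tuple[int, int, int, int]] = field(default_factory=set)
    true_masks: np.ndarray | None = None  # (T, H, W) uint16 label images


def _stationary_distribution(T: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_feature_trajectories(
    spec: HiddenStateSimSpec,
) -> tuple[np.ndarray, GroundTruth]:
    """Simulate feature trajectories with hidden Markov-state dynamics.

    Returns
    -------
    trajectories : ndarray, shape (n_cells, n_frames, n_observed)
        Observed feature time series (restricted to ``observed_dims``).
    truth : GroundTruth
        Hidden state labels per cell per frame and the trivial chain links.

    Notes
    -----
    Initial states are drawn from the chain's stationary distribution and the
    initial feature vector is the state mean plus one noise draw, so short
    simulations start in (approximate) stationarity.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_c, n_f, n_feat = spec.n_cells, spec.n_frames, spec.n_features

    pi = _stationary_distribution(spec.transition_matrix)
    states = np.empty((n_c, n_f), dtype=np.int64)
    states[:, 0] = rng.choice(spec.n_states, size=n_c, p=pi)
    # cumulative rows for vectorized categorical sampling
    cum_T = np.cumsum(spec.transition_matrix, axis=1)
    for t in range(1, n_f):
        u = rng.random(n_c)
        states[:, t] = (u[:, None] > cum_T[states[:, t - 1]]).sum(axis=1)

    x = np.empty((n_c, n_f, n_feat), dtype=float)
    x[:, 0] = spec.state_means[states[:, 0]] + rng.normal(0.0, spec.noise_sd, (n_c, n_feat))
    a = spec.relaxation_rate
    for t in range(1, n_f):
        mu = spec.state_means[states[:, t]]
        eps = rng.normal(0.0, spec.noise_sd, (n_c, n_feat))
        x[:, t] = x[:, t - 1] + a * (mu - x[:, t - 1]) + eps

    links = {(t, c, t + 1, c) for c in range(n_c) for t in range(n_f - 1)}
    dims = tuple(range(n_feat)) if spec.observed_dims is None else tuple(spec.observed_dims)
    return x[:, :, dims], GroundTruth(hidden_states=states, true_links=links)


# ---------------------------------------------------------------------------
# movie rendering


def _render_cell(
    img: np.ndarray,
    mask: np.ndarray,
    label: int,
    center: np.ndarray,
    radii: tuple[float, float],
    angle: float,
    speckle_seed: int,
) -> None:
    """Draw one textured ellipse; mask pixels are overwritten by this label."""
    h, w = img.shape
    ry, rx = radii
    rmax = max(ry, rx)
    r0 = max(int(np.floor(center[0] - rmax - 1)), 0)
    r1 = min(int(np.ceil(center[0] + rmax + 2)), h)
    c0 = max(int(np.floor(center[1] - rmax - 1)), 0)
    c1 = min(int(np.ceil(center[1] + rmax + 2)), w)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = yy - center[0]
    dx = xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dy + sa * dx) / ry
    v = (-sa * dy + ca * dx) / rx
    rho2 = u**2 + v**2
    inside = rho2 <= 1.0
    if not inside.any():
        return
    # radial intensity gradient + seeded speckle so texture features are
    # non-degenerate on synthetic cells
    srng = np.random.default_rng(speckle_seed)
    speckle = srng.normal(0.0, 0.15, rho2.shape)
    intensity = 1.0 + 0.8 * (1.0 - rho2) + speckle
    img[r0:r1, c0:c1][inside] = intensity[inside]
    mask[r0:r1, c0:c1][inside] = label


def render_movie(spec: MovieSimSpec) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render a synthetic movie of moving, optionally dividing, textured cells.

    Returns the image stack (float32, T x H x W), exact label masks
    (uint16), and ground truth with true per-frame links.  Divisions replace
    one ellipse by two half-area daughters straddling the parent centroid.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    T = spec.n_frames
    margin = 2.0 * spec.cell_radius_mean

    # live cell registry: label -> dict(center, radii, angle)
    cells: dict[int, dict] = {}
    next_label = 1
    for _ in range(spec.n_cells):
        r = max(1.5, rng.normal(spec.cell_radius_mean, spec.cell_radius_sd))
        ecc = rng.uniform(0.7, 1.0)
        cells[next_label] = {
            "center": np.array(
                [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
            ),
            "radii": (r, r * ecc),
            "angle": rng.uniform(0, np.pi),
        }
        next_label += 1

    images = np.zeros((T, h, w), dtype=np.float32)
    masks = np.zeros((T, h, w), dtype=np.uint16)
    links: set[tuple[int, int, int, int]] = set()
    drift = np.asarray(spec.drift_px, dtype=float)

    for t in range(T):
        frame = np.zeros((h, w), dtype=float)
        if spec.background_noise_sd > 0:
            frame += rng.normal(0.0, spec.background_noise_sd, (h, w))
        lab_img = np.zeros((h, w), dtype=np.uint16)
        for lab in sorted(cells):
            c = cells[lab]
            _render_cell(
                frame, lab_img, lab, c["center"], c["radii"], c["angle"],
                speckle_seed=(spec.seed * 100003 + lab * 1009 + t) % (2**31),
            )
        images[t] = frame
        masks[t] = lab_img

        if t == T - 1:
            break

        # advance: division first, then motion, recording links to t+1
        new_cells: dict[int, dict] = {}
        for lab in sorted(cells):
            c = cells[lab]
            if rng.random() < spec.division_prob:
                r = c["radii"][0] / np.sqrt(2.0), c["radii"][1] / np.sqrt(2.0)
                axis = rng.uniform(0, np.pi)
                off = np.array([np.cos(axis), np.sin(axis)]) * c["radii"][0]
                for sgn in (+1.0, -1.0):
                    new_cells[next_label] = {
                        "center": c["center"] + sgn * off,
                        "radii": r,
                        "angle": rng.uniform(0, np.pi),
                    }
                    links.add((t, lab, t + 1, next_label))
                    next_label += 1
            else:
                new_cells[lab] = dict(c)
                links.add((t, lab, t + 1, lab))
        # motion: random walk + constant drift, reflected at borders
        for lab in sorted(new_cells):
            c = new_cells[lab]
            step = rng.normal(0.0, spec.motion_sd_px, 2) if spec.motion_sd_px > 0 else np.zeros(2)
            pos = c["center"] + step + drift
            pos[0] = np.clip(pos[0], margin, h - margin)
            pos[1] = np.clip(pos[1], margin, w - margin)
            c["center"] = pos
        cells = new_cells

    # a label can be fully occluded by overlap; drop links touching absent cells
    present = [set(np.unique(masks[t])) - {0} for t in range(T)]
    links = {
        (t, a, t1, b) for (t, a, t1, b) in links if a in present[t] and b in present[t1]
    }
    return images, masks, GroundTruth(true_links=links, true_masks=masks)


# ---------------------------------------------------------------------------
# serialization helpers


def save_movie(path: str | Path, images: np.ndarray, masks: np.ndarray) -> None:
    """Write the image stack and label masks as multi-page TIFFs."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path / "images.tif", images.astype(np.float32))
    tifffile.imwrite(path / "masks.tif", masks.astype(np.uint16))


def save_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    """Write links as JSON and masks (if any) as TIFF."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    payload = {"true_links": sorted(map(list, truth.true_links))}
    if truth.hidden_states is not None:
        payload["hidden_states"] = truth.hidden_states.tolist()
    (path / "ground_truth.json").write_text(json.dumps(payload))
    if truth.true_masks is not None:
        tifffile.imwrite(path / "true_masks.tif", truth.true_masks.astype(np.uint16))


def trajectories_to_frame(trajectories: np.ndarray, treatment: str = "sim") -> "pd.DataFrame":
    """Flatten (n_cells, n_frames, n_dims) trajectories to a tidy per-cell-frame table.

    The table uses the same (treatment, stack_id, frame, cell_label) index
    convention as the imaging path, with the cell index doubling as the label,
    so simulated features drop straight into the embedding layer.
    """
    import pandas as pd

    n_c, n_f, n_d = trajectories.shape
    idx = np.indices((n_c, n_f))
    df = pd.DataFrame(
        trajectories.reshape(n_c * n_f, n_d),
        columns=[f"PC{i + 1}" for i in range(n_d)],
    )
    df.insert(0, "treatment", treatment)
    df.insert(1, "stack_id", treatment)
    df.insert(2, "frame", idx[1].ravel())
    df.insert(3, "cell_label", idx[0].ravel())
    return df
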
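"""End-to-end pipeline orchestration with content-hash caching.

Stages run in order (simulate -> preprocess -> features -> track -> embed ->
dynamics) inside a run directory.  Each stage writes its artifacts plus a
key file hashing the stage-relevant configuration and its input artifacts;
rerunning with an unchanged config and inputs is a no-op for that stage,
while deleting an intermediate reruns only the downstream stages.  A single
global seed fans out to per-stage seeds by stable hashing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import dynamics, embedding, features, preprocess, simulate, tracking

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "replicate_splits", "stage_seed"]


@dataclass
class PipelineConfig:
    """Single-file configuration with all pipeline defaults pre-filled.

    Defaults mirror the standard analysis: 3 PCs, trajectory embedding
    length 8, 2-D embedding, 100 microbins, tracking thresholds
    45 / 300 / 10,000 / 10 px, 30-min frame interval.
    """

    treatments: list[str] = field(default_factory=lambda: ["A", "B"])
    stacks_per_treatment: int = 2
    image_size: tuple[int, int] = (128, 128)
    n_cells: int = 4
    n_frames: int = 20
    cell_radius_mean: float = 8.0
    motion_sd_px: float = 2.0
    division_prob: float = 0.0
    background_noise_sd: float = 0.05
    frame_interval: float = 30.0
    n_pc: int = 3
    n_tau: int = 8
    d: int = 2
    k: int = 100
    small_dist_cutoff: float = 45.0
    cluster_dist_cutoff: float = 300.0
    small_cluster_max_area: int = 10_000
    min_overlap_px: int = 10
    reducer: str = "umap"
    overlap_bins: int = 25
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        if cfg.small_dist_cutoff <= 0 or cfg.min_overlap_px <= 0:
            raise ValueError("thresholds must be positive")
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def replicate_splits(
    stack_ids_by_treatment: dict[str, list[str]],
    n_groups: int | None = 3,
    train_val: bool = False,
    seed: int = 0,
) -> dict:
    """Deterministic seeded grouping of stacks per treatment.

    ``n_groups`` mode: split each treatment's stacks into that many replicate
    groups (e.g. 3 groups of 2 from 6 stacks).  ``train_val`` mode: hold out
    one stack per treatment for validation (the 5:1 likelihood protocol).
    Raises naming the treatment when it has too few stacks.
    """
    rng = np.random.default_rng(seed)
    if train_val:
        out = {"train": {}, "validation": {}}
        for tr in sorted(stack_ids_by_treatment):
            ids = sorted(stack_ids_by_treatment[tr])
            if len(ids) < 2:
                raise ValueError(f"treatment {tr!r} needs >= 2 stacks for a train/validation split")
            perm = [ids[i] for i in rng.permutation(len(ids))]
            out["validation"][tr] = [perm[0]]
            out["train"][tr] = sorted(perm[1:])
        return out
    groups: dict[int, dict[str, list[str]]] = {g: {} for g in range(n_groups)}
    for tr in sorted(stack_ids_by_treatment):
        ids = sorted(stack_ids_by_treatment[tr])
        if len(ids) < n_groups:
            raise ValueError(
                f"treatment {tr!r} has {len(ids)} stacks; cannot form {n_groups} replicate groups"
            )
        perm = [ids[i] for i in rng.permutation(len(ids))]
        for i, sid in enumerate(perm):
            groups[i % n_groups].setdefault(tr, []).append(sid)
    return groups


# ---------------------------------------------------------------------------
# caching helpers


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _hash_files(paths: list[Path]) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


class _Stage:
    def __init__(self, run_dir: Path, name: str, key: str):
        self.dir = run_dir / name
        self.name = name
        self.key = key
        self.key_file = self.dir / ".stage_key"

    def is_cached(self, outputs: list[Path] | None = None) -> bool:
        if not (self.key_file.exists() and self.key_file.read_text() == self.key):
            return False
        return all(p.exists() for p in (outputs or []))

    def mark_done(self) -> None:
        self.key_file.write_text(self.key)


def run_pipeline(config: PipelineConfig, run_dir: str | Path) -> dict:
    """Execute all stages on self-simulated movies, with caching.

    Returns a summary dict (also written as ``summary.json``): per-treatment
    landscape overlap, locality ratio, and the microstate-model validation
    log-likelihood.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg = asdict(config)
    (run_dir / "config.yaml").write_text(yaml.safe_dump(cfg))

    # ---- stage 1: simulate movies
    st = _Stage(run_dir, "simulate", _hash_obj({"cfg": cfg, "stage": "simulate"}))
    stack_ids = {
        tr: [f"{tr}_s{i}" for i in range(config.stacks_per_treatment)]
        for tr in config.treatments
    }
    sim_outputs = [st.dir / sid / "images.tif" for _, sid in
                   [(tr, s_) for tr in config.treatments for s_ in stack_ids[tr]]]
    if not st.is_cached(sim_outputs):
        st.dir.mkdir(exist_ok=True)
        for tr in config.treatments:
            for i, sid in enumerate(stack_ids[tr]):
                spec = simulate.MovieSimSpec(
                    image_size=tuple(config.image_size),
                    n_cells=config.n_cells,
                    cell_radius_mean=config.cell_radius_mean,
                    motion_sd_px=config.motion_sd_px,
                    division_prob=config.division_prob,
                    background_noise_sd=config.background_noise_sd,
                    n_frames=config.n_frames,
                    seed=stage_seed(config.seed, f"simulate/{sid}"),
                )
                images, masks, truth = simulate.render_movie(spec)
                simulate.save_movie(st.dir / sid, images, masks)
                simulate.save_ground_truth(st.dir / sid, truth)
        st.mark_done()
        logger.info("simulate: generated %d stacks", sum(map(len, stack_ids.values())))
    else:
        logger.info("simulate: cache hit")

    all_sids = [(tr, sid) for tr in config.treatments for sid in stack_ids[tr]]

    # ---- stage 2: preprocess (z-normalize with supplied masks as foreground)
    sim_files = [p for _, sid in all_sids for p in sorted((run_dir / "simulate" / sid).glob("*.tif"))]
    st = _Stage(run_dir, "preprocess", _hash_obj({"cfg": cfg, "in": _hash_files(sim_files)}))
    if not st.is_cached([st.dir / sid / "normalized.tif" for _, sid in all_sids]):
        st.dir.mkdir(exist_ok=True)
        for tr, sid in all_sids:
            images = tifffile.imread(run_dir / "simulate" / sid / "images.tif")
            masks = tifffile.imread(run_dir / "simulate" / sid / "masks.tif")
            stack = preprocess.FrameStack(
                pixels=images, frame_interval=config.frame_interval, treatment=tr, stack_id=sid
            )
            fg = preprocess.ForegroundMaskStack(masks=masks > 0)
            norm = preprocess.znormalize_stack(stack, fg)
            (st.dir / sid).mkdir(exist_ok=True)
            tifffile.imwrite(st.dir / sid / "normalized.tif", norm.pixels.astype(np.float32))
        st.mark_done()
    else:
        logger.info("preprocess: cache hit")

    # ---- stage 3: features + PCA
    pre_files = [run_dir / "preprocess" / sid / "normalized.tif" for _, sid in all_sids]
    st = _Stage(run_dir, "features", _hash_obj({"cfg": cfg, "in": _hash_files(pre_files)}))
    if not st.is_cached([st.dir / "features.csv"]):
        st.dir.mkdir(exist_ok=True)
        tables = []
        for tr, sid in all_sids:
            norm = tifffile.imread(run_dir / "preprocess" / sid / "normalized.tif")
            masks = tifffile.imread(run_dir / "simulate" / sid / "masks.tif")
            for t in range(norm.shape[0]):
                tables.append(
                    features.featurize_frame(
                        norm[t], masks[t], frame=t, stack_id=sid, treatment=tr
                    )
                )
        table = pd.concat(tables, ignore_index=True)
        fcols = [f"f{i}" for i in range(features.N_FEATURES)]
        model = features.fit_pca(table[fcols].to_numpy(), n_pc=config.n_pc)
        pcs = features.apply_pca(model, table[fcols].to_numpy())
        for j in range(config.n_pc):
            table[f"PC{j + 1}"] = pcs[:, j]
        table.to_csv(st.dir / "features.csv", index=False)
        (st.dir / "feature_blocks.json").write_text(
            json.dumps({k: [v.start, v.stop] for k, v in features.FEATURE_BLOCKS.items()})
        )
        st.mark_done()
    else:
        logger.info("features: cache hit")

    # ---- stage 4: tracking
    st = _Stage(run_dir, "track", _hash_obj({"cfg": cfg, "in": _hash_files(sim_files)}))
    if not st.is_cached([st.dir / f"{sid}_links.jsonl" for _, sid in all_sids]):
        st.dir.mkdir(exist_ok=True)
        for tr, sid in all_sids:
            masks = tifffile.imread(run_dir / "simulate" / sid / "masks.tif")
            graph = tracking.build_linkage_graph(
                masks,
                small_cluster_max_area=config.small_cluster_max_area,
                small_dist_cutoff=config.small_dist_cutoff,
                cluster_dist_cutoff=config.cluster_dist_cutoff,
                min_overlap_px=config.min_overlap_px,
            )
            graph.to_jsonl(st.dir / f"{sid}_links.jsonl")
        st.mark_done()
    else:
        logger.info("track: cache hit")

    # ---- stage 5: snippets + embedding
    feat_file = run_dir / "features" / "features.csv"
    link_files = [run_dir / "track" / f"{sid}_links.jsonl" for _, sid in all_sids]
    st = _Stage(run_dir, "embed", _hash_obj({"cfg": cfg, "in": _hash_files([feat_file] + link_files)}))
    if not st.is_cached([st.dir / "coordinates.csv"]):
        st.dir.mkdir(exist_ok=True)
        table = pd.read_csv(feat_file)
        sup_blocks, idx_blocks = [], []
        for tr, sid in all_sids:
            graph = tracking.LinkageGraph()
            for line in (run_dir / "track" / f"{sid}_links.jsonl").read_text().splitlines():
                e = json.loads(line)
                graph.add_edge(e["t"], e["label_t"], e["label_t1"], e["method"])
            masks = tifffile.imread(run_dir / "simulate" / sid / "masks.tif")
            hists = tracking.leaf_histories(graph, masks)
            sset = embedding.extract_snippets(hists, config.n_tau, stack_id=sid, treatment=tr)
            sub = table[table.stack_id == sid]
            lookup = {
                (int(r.frame), int(r.cell_label)): np.array(
                    [getattr(r, f"PC{j + 1}") for j in range(config.n_pc)]
                )
                for r in sub.itertuples()
            }
            X, kept = embedding.build_supervectors(sset, lookup)
            if X.size:
                sup_blocks.append(X)
                idx_blocks.append(sset.index[kept].reset_index(drop=True))
        X = np.vstack(sup_blocks)
        index = pd.concat(idx_blocks, ignore_index=True)
        model = embedding.fit_embedding(
            X, d=config.d, seed=stage_seed(config.seed, "embed"), reducer=config.reducer
        )
        coords = model.embedding_
        out = index.copy()
        for j in range(config.d):
            out[f"E{j + 1}"] = coords[:, j]
        out.to_csv(st.dir / "coordinates.csv", index=False)
        st.mark_done()
    else:
        logger.info("embed: cache hit")

    # ---- stage 6: dynamics summary
    coord_file = run_dir / "embed" / "coordinates.csv"
    st = _Stage(run_dir, "dynamics", _hash_obj({"cfg": cfg, "in": _hash_files([coord_file])}))
    summary_path = run_dir / "summary.json"
    if not st.is_cached() or not summary_path.exists():
        st.dir.mkdir(exist_ok=True)
        out = pd.read_csv(coord_file)
        ecols = [f"E{j + 1}" for j in range(config.d)]
        coords_by_tr = {
            tr: g[ecols].to_numpy() for tr, g in out.groupby("treatment")
        }
        mean_ov, pair_ov = dynamics.mean_pairwise_overlap(
            coords_by_tr, bins=config.overlap_bins
        )
        trajs = [
            g.sort_values("end_frame")[ecols].to_numpy()
            for _, g in out.groupby(["stack_id", "terminal_label"])
            if len(g) >= 2
        ]
        loc = dynamics.locality_ratio(trajs) if trajs else float("nan")
        k_eff = min(config.k, max(2, sum(len(t) for t in trajs) // 4))
        msm_ll = float("nan")
        if len(trajs) >= 4:
            n_val = max(1, len(trajs) // 6)
            msm = dynamics.MarkovStateModel(
                k=k_eff, seed=stage_seed(config.seed, "dynamics")
            ).fit(trajs[n_val:])
            msm_ll = msm.score(trajs[:n_val])
        summary = {
            "mean_pairwise_overlap": mean_ov,
            "pairwise_overlap": {f"{a}|{b}": v for (a, b), v in pair_ov.items()},
            "locality_ratio": loc,
            "validation_log_likelihood": msm_ll,
            "k_microstates": k_eff,
            "n_snippets": int(len(out)),
            "seed": config.seed,
        }
        summary_path.write_text(json.dumps(summary, indent=2))
        st.mark_done()
    else:
        logger.info("dynamics: cache hit")
        summary = json.loads(summary_path.read_text())
    return summary
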
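"""End-to-end runs: split, transform, project, fit, embed, score, write.

One :func:`run_pipeline` call reproduces the whole protocol on a
similarity matrix plus activity table; :func:`compare_methods` repeats
it for all four projection methods on one shared split.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from . import io as chem_io
from .embed import compute_transform, embed_new
from .errors import PSMAError, ValidationError
from .evaluate import evaluation_report, split_train_test
from .io import ActivityTable, SimilarityMatrix
from .metricspace import DEFAULT_CLAMP_SIM, DEFAULT_K, similarity_to_distance
from .model import PSMAModel, fit_psma, posterior_surface, save_model
from .projection import METHODS, project, shepard

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative description of one pipeline run; defaults replicate
    the reference protocol (convex k=0.382, 20% stratified test split,
    100x100 grid, threshold 0.5)."""

    transform: str = "convex"
    k: float = DEFAULT_K
    clamp_sim: float = DEFAULT_CLAMP_SIM
    method: str = "pcooa"
    dims: int = 2
    perplexity: float = 30.0
    max_iter: int | None = None
    split_seed: int = 0
    tsne_seed: int = 0
    test_fraction: float = 0.2
    stratified: bool = True
    cutoff_nm: float = 10.0
    grid: int = 100
    threshold: float = 0.5
    prior_pos: float | None = None
    outdir: str | None = None

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    model: PSMAModel
    report: dict
    artifacts: chem_io.ArtifactSet | None = None
    train_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PSMAError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc
            log.info("stage %-12s %.3fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(sim: SimilarityMatrix, activity: ActivityTable,
                 cfg: RunConfig | None = None) -> PipelineResult:
    """Split -> distances -> project training -> linear transform ->
    class KDEs + priors -> embed test -> score -> (optionally) write."""
    cfg = cfg or RunConfig()
    missing = set(sim.ids) ^ set(activity.ids)
    if missing:
        raise ValidationError(
            f"similarity matrix and activity table disagree on ids: "
            f"{sorted(missing)[:10]}")

    train_ids, test_ids = _stage("split")(split_train_test)(
        activity, test_fraction=cfg.test_fraction, seed=cfg.split_seed,
        stratified=cfg.stratified)

    sim_train = sim.submatrix(train_ids)
    dist = _stage("distance")(similarity_to_distance)(
        sim_train, method=cfg.transform, k=cfg.k, clamp_sim=cfg.clamp_sim)

    proj = _stage("project")(project)(
        dist, cfg.method, dims=cfg.dims, seed=cfg.tsne_seed,
        perplexity=cfg.perplexity, max_iter=cfg.max_iter)
    shp = shepard(dist, proj.coords)

    transform = _stage("transform")(compute_transform)(dist, proj)
    priors = None
    if cfg.prior_pos is not None:
        priors = (cfg.prior_pos, 1.0 - cfg.prior_pos)
    model = _stage("fit")(fit_psma)(proj, activity, transform=transform,
                                    priors=priors)

    sim_rows = sim.rows(test_ids, train_ids)
    test_coords = _stage("embed")(embed_new)(transform, sim_rows)

    from .model import classify
    pred, scores, in_domain = classify(model, test_coords,
                                       threshold=cfg.threshold)
    truth = activity.label_of(test_ids)
    report = evaluation_report(scores, truth, threshold=cfg.threshold)
    report.update({
        "method": cfg.method,
        "transform": cfg.transform,
        "k": cfg.k,
        "split_seed": cfg.split_seed,
        "tsne_seed": cfg.tsne_seed,
        "n_train": len(train_ids),
        "n_train_pos": int(activity.label_of(train_ids).sum()),
        "prior_pos": model.prior_pos,
        "shepard_r2": shp.r2,
        "stress": proj.stress,
        "n_out_of_domain": int((~in_domain).sum()),
        "embedding_residual_inf": transform.residual_inf,
        "config": cfg.as_dict(),
    })

    artifacts = None
    if cfg.outdir:
        surface = posterior_surface(model, nx=cfg.grid, ny=cfg.grid)
        all_ids = train_ids + test_ids
        all_coords = np.vstack([proj.coords[:, :2], test_coords])
        split_tag = ["train"] * len(train_ids) + ["test"] * len(test_ids)
        meta = {
            "grid": {"nx": cfg.grid, "ny": cfg.grid,
                     "extent": list(surface["extent"])},
            "bandwidths": {"hx": model.kdm_pos.hx, "hy": model.kdm_pos.hy},
            "priors": {"pos": model.prior_pos, "neg": model.prior_neg},
            "method": cfg.method, "transform": cfg.transform, "k": cfg.k,
            "seeds": {"split": cfg.split_seed, "tsne": cfg.tsne_seed},
        }
        artifacts = _stage("write")(chem_io.write_artifacts)(
            cfg.outdir, ids=all_ids, coords=all_coords,
            labels=activity.label_of(all_ids), split=split_tag,
            surface_grid=surface["p_pos"], x_axis=surface["x_axis"],
            y_axis=surface["y_axis"], surface_meta=meta, report=report)
        save_model(model, f"{cfg.outdir}/model.json")

    return PipelineResult(model=model, report=report, artifacts=artifacts,
                          train_ids=train_ids, test_ids=test_ids)


def compare_methods(sim: SimilarityMatrix, activity: ActivityTable,
                    cfg: RunConfig | None = None) -> dict[str, dict]:
    """Run all four projection methods on one shared split.

    Returns a method -> report table (same split seed throughout, so
    n_test is identical across rows) with AUC, MCC, stress and Shepard
    r-squared per method.
    """
    cfg = cfg or RunConfig()
    table: dict[str, dict] = {}
    for method in METHODS:
        mc = RunConfig(**{**cfg.as_dict(), "method": method, "outdir": None})
        res = run_pipeline(sim, activity, mc)
        table[method] = {key: res.report[key] for key in
                         ("auc", "mcc", "stress", "shepard_r2",
                          "n_test", "n_train")}
    return table
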
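"""Orchestration of the five pipeline stages with reproducible manifests.

Stages: simulate -> preprocess -> fit-movement -> fit-ssf -> validate.
Each stage writes its outputs plus a JSON manifest recording the seeds, the
relevant configuration, and the SHA-256 hashes of its input files.  A stage
is skipped on rerun when its manifest matches the current inputs (staleness
by input hash), so deleting one stage's outputs regenerates only that stage
and the ones downstream of it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .config import PipelineConfig
from .covariates import COVARIATE_NAMES, stack_normalizer
from .movement import compare_classes, pool_and_summarize, run_movement_mcmc
from .preprocess import (
    assemble_datasets,
    filter_observations,
    fit_ctcrw,
    simulate_paths,
    steps_and_angles,
)
from .samples import PosteriorSamples
from .ssf import Cluster, build_clusters, run_ssf_mcmc
from .synthetic import (
    CLASS_LABELS,
    default_class_params,
    observe_argos,
    sample_individual_params,
    simulate_ssf_track,
)
from .covariates import GridSpec
from .synthetic import make_covariate_stack
from .validation import CVConfig, run_cv

log = logging.getLogger("bearmove")

STAGES = ["simulate", "preprocess", "fit-movement", "fit-ssf", "validate"]


class StageError(RuntimeError):
    def __init__(self, stage: str, completed: list[str], cause: Exception):
        super().__init__(f"stage {stage!r} failed after {completed}: {cause}")
        self.stage = stage
        self.completed = completed


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(obj) -> str:
    if dataclasses.is_dataclass(obj):
        obj = dataclasses.asdict(obj)
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _manifest_path(out_dir: Path, stage: str) -> Path:
    return out_dir / f"manifest_{stage.replace('-', '_')}.json"


def _write_manifest(out_dir: Path, stage: str, cfg_hash: str, inputs: list[Path],
                    outputs: list[Path], extra: dict | None = None) -> None:
    man = {
        "stage": stage,
        "config_hash": cfg_hash,
        "inputs": {p.name: _sha256(p) for p in inputs},
        "outputs": [p.name for p in outputs],
    }
    if extra:
        man["extra"] = extra
    _manifest_path(out_dir, stage).write_text(json.dumps(man, indent=1, default=str))


def _stage_fresh(out_dir: Path, stage: str, cfg_hash: str, inputs: list[Path]) -> bool:
    mp = _manifest_path(out_dir, stage)
    if not mp.exists():
        return False
    man = json.loads(mp.read_text())
    if man.get("config_hash") != cfg_hash:
        return False
    for p in inputs:
        if not p.exists() or man["inputs"].get(p.name) != _sha256(p):
            return False
    for name in man.get("outputs", []):
        if not (out_dir / name).exists():
            return False
    return True


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig, out_dir: Path) -> dict:
    rng = np.random.default_rng(cfg.stage_seed("simulate"))
    sc = cfg.simulate
    grid = GridSpec(0.0, 0.0, sc.cell_size, sc.grid_nrows, sc.grid_ncols)
    stack = make_covariate_stack(grid, sc.n_days, rng, start_date=np.datetime64(sc.start_date))
    norm = stack_normalizer(stack, rng)
    params = default_class_params()
    beta = np.asarray(sc.beta_true, float)

    all_obs, truths = [], []
    center = np.array([grid.x0 + grid.width / 2, grid.y0 + grid.height / 2])
    captures = []
    for label in CLASS_LABELS:
        inds = sample_individual_params(params[label], sc.n_per_class, rng)
        for ind in inds:
            start = stack.nearest_ocean(
                (center + rng.uniform(-4, 4, 2) * grid.cell_size)[None, :]
            )[0]
            track = simulate_ssf_track(
                ind,
                beta,
                stack,
                n_candidates=sc.n_candidates,
                n_steps=sc.n_steps[label],
                start=start,
                start_bearing=float(rng.uniform(-np.pi, np.pi)),
                rng=rng,
                interval_days=cfg.step_interval_days,
                normalizer=norm,
                angle_mode=cfg.angle_mode,
            )
            truths.append(track)
            obs = observe_argos(
                track,
                duty_cycle_days=sc.duty_cycle_days[label],
                error_scale=sc.error_scale,
                failure_time=sc.failure_time_days[label],
                rng=rng,
            )
            all_obs.extend(obs)
            captures.append(
                {"animal_id": ind.animal_id, "capture_time": str(pd.Timestamp(track.times[0]))}
            )

    obs_csv = out_dir / "observations.csv"
    truth_csv = out_dir / "true_paths.csv"
    cap_csv = out_dir / "captures.csv"
    stack_nc = out_dir / "stack.nc"
    bio.write_observations(all_obs, obs_csv)
    bio.write_paths(truths, truth_csv)
    pd.DataFrame(captures).to_csv(cap_csv, index=False)
    bio.write_stack_netcdf(stack, stack_nc)
    log.info("simulate: %d animals, %d observations", len(truths), len(all_obs))
    return {"outputs": [obs_csv, truth_csv, cap_csv, stack_nc], "inputs": []}


def stage_preprocess(cfg: PipelineConfig, out_dir: Path) -> dict:
    rng = np.random.default_rng(cfg.stage_seed("preprocess"))
    obs_csv = out_dir / "observations.csv"
    cap_csv = out_dir / "captures.csv"
    obs = bio.read_observations(obs_csv)
    caps = pd.read_csv(cap_csv).set_index("animal_id")["capture_time"].to_dict()

    by_animal: dict[str, list] = {}
    for o in obs:
        by_animal.setdefault(o.animal_id, []).append(o)

    realizations = {}
    exclusions = []
    counts = {}
    for aid in sorted(by_animal):
        res = filter_observations(
            sorted(by_animal[aid], key=lambda o: o.timestamp),
            np.datetime64(pd.Timestamp(caps[aid])),
            cfg.filter,
        )
        counts[aid] = res.counts
        if res.excluded:
            exclusions.append({"animal_id": aid, "reason": res.reason})
            continue
        fit = fit_ctcrw(res.observations)
        if not fit.converged:
            log.warning("CTCRW optimizer flagged non-convergence for %s", aid)
        realizations[aid] = simulate_paths(
            fit, m=cfg.m_imputations, interval_days=cfg.step_interval_days, rng=rng
        )
    if not realizations:
        raise RuntimeError("all animals excluded by filtering")
    datasets = assemble_datasets(realizations, rng)

    outputs = []
    for j, ds in enumerate(datasets, start=1):
        p = out_dir / f"dataset_{j:02d}.csv"
        bio.write_paths(ds, p)
        outputs.append(p)
    exc = out_dir / "exclusions.json"
    exc.write_text(json.dumps(exclusions, indent=1))
    cnt = out_dir / "filter_counts.json"
    cnt.write_text(json.dumps(counts, indent=1))
    outputs += [exc, cnt]
    log.info(
        "preprocess: %d animals retained, %d excluded, %d datasets",
        len(realizations), len(exclusions), len(datasets),
    )
    return {"outputs": outputs, "inputs": [obs_csv, cap_csv]}


def _movement_columns(samples: PosteriorSamples) -> pd.DataFrame:
    meta = samples.meta
    cols = {"dataset_index": samples.dataset_index}
    for c, cn in enumerate(meta["class_names"]):
        cols[f"kappa[{cn}]"] = samples.params["kappa"][:, c]
        cols[f"gamma[{cn}]"] = samples.params["gamma"][:, c]
        cols[f"phi[{cn}]"] = samples.params["phi"][:, c]
    for s in ("sigma_kappa", "sigma_gamma", "sigma_phi"):
        cols[s] = samples.params[s]
    for i, aid in enumerate(meta["animal_ids"]):
        cols[f"k[{aid}]"] = samples.params["k"][:, i]
        cols[f"g[{aid}]"] = samples.params["g"][:, i]
        cols[f"r[{aid}]"] = samples.params["r"][:, i]
    return pd.DataFrame(cols)


def stage_fit_movement(cfg: PipelineConfig, out_dir: Path) -> dict:
    rng = np.random.default_rng(cfg.stage_seed("fit-movement"))
    stack = bio.read_stack_netcdf(out_dir / "stack.nc")
    inputs = sorted(out_dir.glob("dataset_*.csv")) + [out_dir / "stack.nc"]
    per_dataset = []
    frames = []
    for j in range(1, cfg.m_imputations + 1):
        reals = bio.read_realizations(out_dir / f"dataset_{j:02d}.csv", j)
        series = [
            steps_and_angles(r, stack=stack, on_ice=cfg.on_ice_filter) for r in reals
        ]
        s = run_movement_mcmc(
            series,
            cfg.movement_mcmc,
            rng,
            class_names=list(CLASS_LABELS),
            angle_mode=cfg.angle_mode,
            dataset_index=j,
        )
        per_dataset.append(s)
        frames.append(_movement_columns(s))
    summary = pool_and_summarize(per_dataset, class_names=list(CLASS_LABELS))
    overlap = compare_classes(summary)

    samples_csv = out_dir / "movement_samples.csv"
    pd.concat(frames, ignore_index=True).to_csv(samples_csv, index=False)
    summ = out_dir / "movement_summary.json"
    summ.write_text(
        json.dumps(
            {
                "summary": summary.to_dict(orient="records"),
                "overlap": overlap.to_dict(orient="records"),
                "diagnostics": [
                    {k: (v if not isinstance(v, dict) else v)
                     for k, v in s.meta.items() if k in ("acceptance", "split_rhat")}
                    for s in per_dataset
                ],
            },
            indent=1,
            default=float,
        )
    )
    return {"outputs": [samples_csv, summ], "inputs": inputs}


def _clusters_to_frame(clusters: list[Cluster], dataset_index: int) -> pd.DataFrame:
    rows = []
    for ci, c in enumerate(clusters):
        pts = np.vstack([c.used_xy[None, :], c.avail_xy])
        for r in range(c.n_rows):
            rec = {
                "dataset_index": dataset_index,
                "cluster_id": ci,
                "row": r,
                "animal_id": c.animal_id,
                "class": c.class_label,
                "time": str(pd.Timestamp(c.time)),
                "x_m": pts[r, 0],
                "y_m": pts[r, 1],
                "prev_x_m": c.prev_xy[0],
                "prev_y_m": c.prev_xy[1],
                "theta_prev": c.theta_prev,
            }
            for jx, name in enumerate(COVARIATE_NAMES):
                rec[name] = c.x_raw[r, jx]
            rows.append(rec)
    return pd.DataFrame(rows)


def _frame_to_clusters(df: pd.DataFrame) -> list[Cluster]:
    out = []
    for (_, _), grp in df.groupby(["dataset_index", "cluster_id"], sort=True):
        grp = grp.sort_values("row")
        pts = grp[["x_m", "y_m"]].to_numpy(float)
        out.append(
            Cluster(
                animal_id=str(grp.animal_id.iloc[0]),
                class_label=str(grp["class"].iloc[0]),
                time=np.datetime64(pd.Timestamp(grp.time.iloc[0])),
                used_xy=pts[0],
                prev_xy=grp[["prev_x_m", "prev_y_m"]].to_numpy(float)[0],
                theta_prev=float(grp.theta_prev.iloc[0]),
                avail_xy=pts[1:],
                x_raw=grp[COVARIATE_NAMES].to_numpy(float),
            )
        )
    return out


def _load_movement_draws(path) -> dict[int, dict[str, dict[str, np.ndarray]]]:
    """Per-dataset, per-animal {k,g,r} draw arrays from the samples CSV."""
    df = pd.read_csv(path)
    animals = sorted(
        {c[2:-1] for c in df.columns if c.startswith("k[")}
    )
    out: dict[int, dict[str, dict[str, np.ndarray]]] = {}
    for j, grp in df.groupby("dataset_index"):
        out[int(j)] = {
            a: {
                "k": grp[f"k[{a}]"].to_numpy(),
                "g": grp[f"g[{a}]"].to_numpy(),
                "r": grp[f"r[{a}]"].to_numpy(),
            }
            for a in animals
        }
    return out


def stage_fit_ssf(cfg: PipelineConfig, out_dir: Path) -> dict:
    rng = np.random.default_rng(cfg.stage_seed("fit-ssf"))
    stack = bio.read_stack_netcdf(out_dir / "stack.nc")
    draws_by_dataset = _load_movement_draws(out_dir / "movement_samples.csv")
    inputs = sorted(out_dir.glob("dataset_*.csv")) + [
        out_dir / "stack.nc",
        out_dir / "movement_samples.csv",
    ]

    cluster_frames = []
    cluster_datasets = []
    for j in range(1, cfg.m_imputations + 1):
        reals = bio.read_realizations(out_dir / f"dataset_{j:02d}.csv", j)
        clusters = []
        for r in reals:
            ind = draws_by_dataset[j][r.animal_id]
            clusters.extend(
                build_clusters(r, ind, stack, A=cfg.a_available, rng=rng)
            )
        cluster_datasets.append(clusters)
        cluster_frames.append(_clusters_to_frame(clusters, j))

    pooled, summary, _ = run_ssf_mcmc(
        cluster_datasets,
        cfg.ssf_mcmc,
        rng,
        class_names=list(CLASS_LABELS),
        priors=cfg.ssf_priors,
    )
    overlap = compare_classes(summary)

    clusters_csv = out_dir / "clusters.csv"
    pd.concat(cluster_frames, ignore_index=True).to_csv(clusters_csv, index=False)
    beta = pooled.params["beta"]
    samples_csv = out_dir / "ssf_samples.csv"
    cols = {"dataset_index": pooled.dataset_index}
    for c, cn in enumerate(CLASS_LABELS):
        for jx, name in enumerate(COVARIATE_NAMES):
            cols[f"beta[{cn},{name}]"] = beta[:, c, jx]
    for jx, name in enumerate(COVARIATE_NAMES):
        cols[f"sigma[{name}]"] = pooled.params["sigma"][:, jx]
    pd.DataFrame(cols).to_csv(samples_csv, index=False)
    summ = out_dir / "ssf_summary.json"
    summ.write_text(
        json.dumps(
            {
                "summary": summary.to_dict(orient="records"),
                "overlap": overlap.to_dict(orient="records"),
            },
            indent=1,
            default=float,
        )
    )
    return {"outputs": [clusters_csv, samples_csv, summ], "inputs": inputs}


def stage_validate(cfg: PipelineConfig, out_dir: Path) -> dict:
    rng = np.random.default_rng(cfg.stage_seed("validate"))
    clusters_csv = out_dir / "clusters.csv"
    df = pd.read_csv(clusters_csv)
    datasets = []
    for j in sorted(df.dataset_index.unique())[: cfg.cv_n_datasets]:
        datasets.append(_frame_to_clusters(df[df.dataset_index == j]))
    cvc = CVConfig(
        test_frac=cfg.cv_test_frac,
        mcmc=cfg.cv_mcmc,
        priors=cfg.ssf_priors,
        n_rows=cfg.a_available + 1,
    )
    res = run_cv(datasets, cvc, rng, class_names=list(CLASS_LABELS))
    cv_json = out_dir / "cv.json"
    cv_json.write_text(
        json.dumps(
            {
                "rho_median": res["rho_median"],
                "rho_lo": res["rho_lo"],
                "rho_hi": res["rho_hi"],
                "n_datasets": res["n_datasets"],
                "per_dataset": [
                    {
                        "dataset_index": r.dataset_index,
                        "rho": r.rho,
                        "n_test_clusters": r.n_test_clusters,
                        "bin_counts": r.bin_counts.tolist(),
                    }
                    for r in res["per_dataset"]
                ],
            },
            indent=1,
        )
    )
    return {"outputs": [cv_json], "inputs": [clusters_csv]}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "fit-movement": stage_fit_movement,
    "fit-ssf": stage_fit_ssf,
    "validate": stage_validate,
}


def run_stage(stage: str, cfg: PipelineConfig, out_dir, force: bool = False) -> bool:
    """Run one stage unless its manifest shows it is up to date.

    Returns True when the stage actually ran.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash({"cfg": cfg.to_dict(), "stage": stage})
    func = _STAGE_FUNCS[stage]
    # probe freshness using the previous manifest's input list
    mp = _manifest_path(out_dir, stage)
    if not force and mp.exists():
        man = json.loads(mp.read_text())
        inputs = [out_dir / n for n in man.get("inputs", {})]
        if _stage_fresh(out_dir, stage, cfg_hash, inputs):
            log.info("stage %s is up to date; skipping", stage)
            return False
    res = func(cfg, out_dir)
    _write_manifest(out_dir, stage, cfg_hash, res["inputs"], res["outputs"])
    return True


def run_pipeline(cfg: PipelineConfig, out_dir, force: bool = False) -> Path:
    """Execute all stages in order; halts naming the failing stage."""
    out_dir = Path(out_dir)
    completed: list[str] = []
    for stage in STAGES:
        try:
            run_stage(stage, cfg, out_dir, force=force)
        except Exception as e:  # noqa: BLE001 - reported with stage context
            raise StageError(stage, completed, e) from e
        completed.append(stage)

    mov = json.loads((out_dir / "movement_summary.json").read_text())
    ssf = json.loads((out_dir / "ssf_summary.json").read_text())
    cv = json.loads((out_dir / "cv.json").read_text())
    summary = {
        "movement": mov["summary"],
        "movement_overlap": mov["overlap"],
        "ssf": ssf["summary"],
        "cv_rho_median": cv["rho_median"],
        "cv_rho_interval": [cv["rho_lo"], cv["rho_hi"]],
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    return out_dir
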
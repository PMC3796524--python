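"""End-to-end analysis pipeline: load -> superimpose -> shape variables ->
morphospace -> divergence/overlap -> association -> dental metrics.

A single declarative configuration drives the whole analysis; the same
stages run on real TPS+CSV input or on a generated scenario, all randomness
flows from one seed, and a manifest records the configuration, software
version and per-stage log so that identical config+seed reproduces
byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import permutation_test, rv_coefficient, shape_size_regression, two_block_pls
from .dental_metrics import metrics_table
from .geometry_io import (
    LandmarkScheme,
    configs_to_frame,
    default_scheme,
    frame_to_configs,
    read_tps,
    write_tps,
)
from .gpa import SlidingSpec, centroid_size, gpa, procrustes_correlation, slide_gpa
from .morphospace import (
    bca_bootstrap_ci,
    concentration_ellipse,
    distance_from_basal,
    ellipse_overlap,
    pca_covariance,
    rule_of_eye,
    select_pcs,
)
from .synthetic import generate, two_clade_default
from .tps_shape import bending_energy_matrix, shape_variables

__all__ = ["PipelineConfig", "PipelineResult", "run", "compare_sliding_criteria"]

STAGES = (
    "load",
    "superimpose",
    "shape_variables",
    "pca",
    "divergence",
    "overlap",
    "association",
    "dental_metrics",
)

_MEASUREMENT_COLS = (
    "length_mm",
    "width_mm",
    "anterocone_protocone_mm",
    "anterostyle_minor_mm",
    "anterostyle_major_mm",
    "anterostyle_dir_x",
    "anterostyle_dir_y",
    "protocone_x",
    "protocone_y",
    "enterostyle_x",
    "enterostyle_y",
)


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration; defaults follow the standard
    analysis protocol (alpha = 0, 55% ellipses, 95% PC-variance cut,
    9999 randomizations, 95% CIs)."""

    input_tps: str | None = None
    input_csv: str | None = None
    scenario: str | None = "two_clade_default"
    sliding_criterion: str = "bending_energy"
    slide: bool = True
    alpha: float = 0.0
    pc_variance_threshold: float = 0.95
    n_pcs: int | None = None
    ellipse_level: float = 0.55
    n_boot: int = 9999
    n_perm: int = 9999
    ci_level: float = 0.95
    seed: int = 1
    output_dir: str | None = None
    basal_group: str | None = None
    reference_group: str | None = None
    min_group_n: int = 5  # groups below this are flagged in the log, not excluded

    def __post_init__(self):
        for name in ("pc_variance_threshold", "ellipse_level", "ci_level"):
            v = getattr(self, name)
            if not 0 < v < 1 and not (name == "pc_variance_threshold" and v == 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        for name in ("n_boot", "n_perm"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    config: PipelineConfig
    procrustes: object
    scores: object
    pca: object
    n_pcs: int
    divergence: pd.DataFrame
    basal_distances: pd.DataFrame
    overlap: pd.DataFrame
    association: pd.DataFrame
    regression: object
    metrics: pd.DataFrame | None
    meta: pd.DataFrame
    manifest: dict
    diagnostics: pd.DataFrame | None = None


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _load(config: PipelineConfig, scheme: LandmarkScheme):
    if config.input_tps:
        configs = read_tps(config.input_tps, scheme)
        meta = pd.read_csv(config.input_csv) if config.input_csv else None
        if meta is not None:
            by_id = meta.set_index("specimen_id")
            for cfg in configs:
                if cfg.specimen_id in by_id.index:
                    row = by_id.loc[cfg.specimen_id]
                    cfg.species_label = str(row.get("species_label", cfg.species_label))
                    cfg.age_ma = float(row.get("age_Ma", cfg.age_ma))
                    cfg.clade = str(row.get("clade", cfg.clade))
        return configs, meta
    if config.scenario == "two_clade_default":
        scenario = two_clade_default(seed=config.seed)
    else:
        raise PipelineError("load", f"unknown scenario {config.scenario!r}")
    configs, truth = generate(scenario, scheme)
    return configs, truth.frame


def run(config: PipelineConfig, scheme: LandmarkScheme | None = None) -> PipelineResult:
    """Execute the full pipeline; see module docstring for the stage list."""
    scheme = scheme or default_scheme()
    rng = np.random.default_rng(config.seed)
    # deterministic per-stage seeds
    stage_seeds = {name: int(rng.integers(0, 2**31 - 1)) for name in STAGES}
    log: list[dict] = []

    def _log(stage, **info):
        log.append({"stage": stage, **info})

    # -- load ---------------------------------------------------------------
    try:
        configs, meta = _load(config, scheme)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc
    if meta is None:
        meta = configs_to_frame(configs)
    _log("load", specimens=len(configs))

    # -- superimpose --------------------------------------------------------
    try:
        ln_cs = np.log([centroid_size(c) for c in configs])
        if config.slide:
            spec = SlidingSpec(criterion=config.sliding_criterion)
            proc, diagnostics = slide_gpa(configs, scheme, spec)
        else:
            proc = gpa(configs, scheme=scheme)
            diagnostics = None
    except Exception as exc:
        raise PipelineError("superimpose", str(exc)) from exc
    _log(
        "superimpose",
        specimens=proc.n_specimens,
        iterations=proc.iterations,
        converged=bool(proc.converged),
        criterion=config.sliding_criterion if config.slide else "none",
    )

    # -- shape variables ----------------------------------------------------
    try:
        model = bending_energy_matrix(proc.mean_shape, alpha=config.alpha)
        scores = shape_variables(proc, model, alpha=config.alpha)
    except Exception as exc:
        raise PipelineError("shape_variables", str(exc)) from exc
    _log("shape_variables", columns=len(scores.column_labels))

    # -- PCA ----------------------------------------------------------------
    try:
        pca = pca_covariance(scores)
        n_pcs = config.n_pcs or select_pcs(pca, config.pc_variance_threshold)
    except Exception as exc:
        raise PipelineError("pca", str(exc)) from exc
    _log("pca", n_pcs=n_pcs, pc1_pct=float(100 * pca.proportion_variance[0]))

    labels = np.array([c.species_label for c in configs])
    ages = np.array([c.age_ma for c in configs])
    group_sizes = pd.Series(labels).value_counts()
    for g, n_g in group_sizes.items():
        if n_g < config.min_group_n:
            _log("divergence", warning=f"group {g!r} has n={n_g} < {config.min_group_n}")

    # -- divergence ---------------------------------------------------------
    try:
        divergence, basal_distances = _divergence_tables(
            config, pca.scores, labels, ages, n_pcs, stage_seeds["divergence"]
        )
    except Exception as exc:
        raise PipelineError("divergence", str(exc)) from exc
    _log("divergence", rows=len(divergence), low_precision=bool(config.n_boot < 1000))

    # -- overlap ------------------------------------------------------------
    try:
        overlap = _overlap_table(config, pca.scores, labels, ages)
    except Exception as exc:
        raise PipelineError("overlap", str(exc)) from exc
    _log("overlap", rows=len(overlap))

    # -- association --------------------------------------------------------
    try:
        association = _association_table(config, scores, meta, ln_cs, stage_seeds["association"])
        regression = shape_size_regression(scores, ln_cs)
    except Exception as exc:
        raise PipelineError("association", str(exc)) from exc
    _log(
        "association",
        rows=len(association),
        regression_pct=float(regression.percent_variance_predicted),
    )

    # -- dental metrics -----------------------------------------------------
    metrics = None
    if meta is not None and all(c in meta.columns for c in _MEASUREMENT_COLS):
        try:
            metrics = metrics_table(configs, meta, scheme)
        except Exception as exc:
            raise PipelineError("dental_metrics", str(exc)) from exc
    _log("dental_metrics", rows=0 if metrics is None else len(metrics))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "stages": list(STAGES),
        "log": log,
    }
    result = PipelineResult(
        config=config,
        procrustes=proc,
        scores=scores,
        pca=pca,
        n_pcs=n_pcs,
        divergence=divergence,
        basal_distances=basal_distances,
        overlap=overlap,
        association=association,
        regression=regression,
        metrics=metrics,
        meta=meta,
        manifest=manifest,
        diagnostics=diagnostics,
    )
    if config.output_dir:
        _write_outputs(result, configs, Path(config.output_dir))
    return result


def _coexisting(labels: np.ndarray, ages: np.ndarray) -> dict[float, list[str]]:
    out: dict[float, list[str]] = {}
    for age in sorted(set(ages), reverse=True):
        groups = sorted(set(labels[ages == age]))
        if len(groups) >= 2:
            out[float(age)] = groups
    return out


def _basal_label(config: PipelineConfig, labels: np.ndarray, ages: np.ndarray) -> str:
    if config.basal_group:
        return config.basal_group
    oldest = ages.max()
    candidates = sorted(set(labels[ages == oldest]))
    return candidates[0]


def _divergence_tables(config, pc_scores, labels, ages, n_pcs, seed):
    rng = np.random.default_rng(seed)
    x = pc_scores[:, :n_pcs]

    def dist_stat(a, b):
        return float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))

    def ci_about(d, lo, hi):
        # BCa's bias correction can push both percentiles past a strongly
        # biased statistic (distances are chi-like near zero); the reported
        # interval must bracket the observed value
        return min(lo, d), max(hi, d)

    rows = []
    for age, groups in _coexisting(labels, ages).items():
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                ga, gb = groups[i], groups[j]
                xa, xb = x[labels == ga], x[labels == gb]
                d = dist_stat(xa, xb)
                lo, hi = ci_about(
                    d,
                    *bca_bootstrap_ci(
                        (xa, xb),
                        dist_stat,
                        n_boot=config.n_boot,
                        level=config.ci_level,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    ),
                )
                rows.append(
                    {
                        "age_Ma": age, "groupA": ga, "groupB": gb,
                        "distance": d, "ci_low": lo, "ci_high": hi, "n_pcs": n_pcs,
                    }
                )
    divergence = pd.DataFrame(rows)

    basal = _basal_label(config, labels, ages)
    base_table = distance_from_basal(
        x, labels, basal, n_pcs,
        reference_group=config.reference_group
        or _farthest_group(x, labels, basal),
    )
    xb = x[labels == basal]
    brows = []
    for _, r in base_table.iterrows():
        g = r["group"]
        if g == basal:
            lo = hi = 0.0
        else:
            xg = x[labels == g]
            lo, hi = ci_about(
                r["distance"],
                *bca_bootstrap_ci(
                    (xb, xg),
                    dist_stat,
                    n_boot=config.n_boot,
                    level=config.ci_level,
                    seed=int(rng.integers(0, 2**31 - 1)),
                ),
            )
        age_g = float(ages[labels == g][0])
        brows.append(
            {
                "age_Ma": age_g, "group": g, "distance": r["distance"],
                "ci_low": lo, "ci_high": hi,
                "percent_change": r["percent_change"], "n_pcs": n_pcs,
            }
        )
    return divergence, pd.DataFrame(brows).sort_values("age_Ma", ascending=False).reset_index(drop=True)


def _farthest_group(x, labels, basal) -> str:
    basal_mean = x[labels == basal].mean(axis=0)
    best, best_d = None, -1.0
    for g in sorted(set(labels)):
        d = float(np.linalg.norm(x[labels == g].mean(axis=0) - basal_mean))
        if d > best_d:
            best, best_d = g, d
    return best


def _overlap_table(config, pc_scores, labels, ages) -> pd.DataFrame:
    xy = pc_scores[:, :2]
    rows = []
    for age, groups in _coexisting(labels, ages).items():
        usable = [g for g in groups if np.sum(labels == g) >= 3]
        if len(usable) < 2:
            continue
        ellipses = []
        for g in usable:
            try:
                ellipses.append(concentration_ellipse(xy[labels == g], config.ellipse_level))
            except ValueError:
                pass
        if len(ellipses) < 2:
            continue
        prop = ellipse_overlap(ellipses[:3])
        rows.append(
            {"age_Ma": age, "groups": "|".join(usable), "overlap_proportion": prop}
        )
    return pd.DataFrame(rows)


def _association_table(config, scores, meta, ln_cs, seed) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    blocks = {"ln_centroid_size": ln_cs}
    if meta is not None and "vd_index" in meta.columns:
        blocks = {"vd_index": meta["vd_index"].to_numpy(float), **blocks}
    for name, col in blocks.items():
        pls = two_block_pls(scores, col)
        rv = rv_coefficient(scores.matrix, col)
        p_r = permutation_test(
            lambda a, b: two_block_pls(a, b).axis_correlation[0],
            scores.matrix, col, n_perm=config.n_perm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        p_rv = permutation_test(
            rv_coefficient, scores.matrix, col, n_perm=config.n_perm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rows.append(
            {
                "block": name,
                "pls1_r": float(pls.axis_correlation[0]),
                "pls1_pct_covariation": float(pls.percent_covariation[0]),
                "rv": rv,
                "p_perm_r": p_r,
                "p_perm_rv": p_rv,
                "n_perm": config.n_perm,
            }
        )
    return pd.DataFrame(rows)


def _write_outputs(result: PipelineResult, configs, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    proc = result.procrustes
    aligned_cfgs = [
        c.copy_with(points=proc.aligned[i]) for i, c in enumerate(configs)
    ]
    write_tps(aligned_cfgs, outdir / "aligned.tps")
    pd.DataFrame(result.scores.matrix, columns=result.scores.column_labels).assign(
        specimen_id=[c.specimen_id for c in configs]
    ).to_csv(outdir / "shape_scores.csv", index=False)
    pd.DataFrame(
        {
            "eigenvalue": result.pca.eigenvalues,
            "proportion_variance": result.pca.proportion_variance,
        }
    ).to_csv(outdir / "pca.csv", index=False)
    result.divergence.to_csv(outdir / "divergence.csv", index=False)
    result.basal_distances.to_csv(outdir / "distance_from_basal.csv", index=False)
    result.overlap.to_csv(outdir / "overlap.csv", index=False)
    result.association.to_csv(outdir / "association.csv", index=False)
    reg = result.regression
    pd.DataFrame(
        [
            {
                "wilks_lambda": reg.wilks_lambda,
                "p_value": reg.p_value,
                "percent_variance_predicted": reg.percent_variance_predicted,
                "n_components": reg.n_components,
                "rank_deficient": reg.rank_deficient,
            }
        ]
    ).to_csv(outdir / "regression.csv", index=False)
    if result.metrics is not None:
        result.metrics.to_csv(outdir / "dental_metrics.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2, default=str))
    try:
        from .plots import pc_scatter, distance_vs_age

        labels = np.array([c.species_label for c in configs])
        pc_scatter(result.pca.scores, labels, result.config.ellipse_level, outdir / "pc_scatter.png")
        distance_vs_age(result.basal_distances, outdir / "distance_vs_age.png")
    except Exception as exc:  # plotting is cosmetic; never fail the run
        warnings.warn(f"figure generation failed: {exc}")


def compare_sliding_criteria(config: PipelineConfig, scheme: LandmarkScheme | None = None):
    """PCA-score concordance between the two sliding criteria.

    Runs the pipeline under both the minimum-bending-energy and the
    minimum-Procrustes-distance criterion and returns the Procrustes
    correlation (r, p) of the full PCA score matrices.
    """
    scheme = scheme or default_scheme()
    cfg_be = dataclasses.replace(config, sliding_criterion="bending_energy", output_dir=None)
    cfg_pd = dataclasses.replace(config, sliding_criterion="procrustes_distance", output_dir=None)
    res_be = run(cfg_be, scheme)
    res_pd = run(cfg_pd, scheme)
    return procrustes_correlation(
        res_be.pca.scores, res_pd.pca.scores, n_perm=config.n_perm, seed=config.seed
    )
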
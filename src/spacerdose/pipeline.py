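"""End-to-end cohort pipeline.

Per case: synthesize a phantom, iodinate the spacer, build the three
scenario SPR grids, optimize the two-lateral-beam plan on the true-material
(TM) grid, recalculate the fixed plan on the no-override (NM) and
water-override (WM) grids, then quantify TM-NM and TM-WM disagreement with
per-structure gamma passing ratios (1%/1mm, 2%/2mm, 3%/3mm) and dosimetric
index differences. Across the cohort, paired sign-flip permutation tests
and boxplot summaries are computed per (pair, structure, metric).

Everything is reproducible from one master seed; per-case child seeds are
derived arithmetically and recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beam import DepthDoseModel, Plan, compute_dose, optimize_plan
from .core import ImageGrid, ROISet, write_mask, write_volume
from .dosimetry import constraint_report, dose_indices, load_constraints
from .gamma import GammaCriteria, gamma_map, passing_ratio
from .materials import HUCurve, build_spr_grid, spacer_material
from .phantom import PhantomParams, generate_phantom, iodinate_spacer, jitter_params
from .stats import box_summary, paired_permutation_test

log = logging.getLogger("spacerdose")

SCENARIO_PAIRS = (("TM", "NM"), ("TM", "WM"))

DEFAULT_PR_ROIS = (
    "prostate", "seminal_vesicles", "ctv", "rectum", "bladder",
    "nvb", "nvb_left", "nvb_right", "penile_bulb",
)
DEFAULT_INDEX_ROIS = DEFAULT_PR_ROIS


@dataclass
class PipelineConfig:
    """Cohort-study configuration (YAML-loadable)."""

    n_cases: int = 20
    master_seed: int = 1
    grid_preset: str = "default"          # default | reduced | fine
    rx_gy: float = 70.0
    fractions: int = 28
    gamma_criteria: tuple = ((1.0, 1.0), (2.0, 2.0), (3.0, 3.0))
    low_dose_threshold: float = 0.10
    gamma_interp_step: float = 0.2        # fraction of DTA; 0.1 = finest
    pr_rois: tuple = DEFAULT_PR_ROIS
    index_rois: tuple = DEFAULT_INDEX_ROIS
    n_perm: int = 1000
    size_jitter: float = 0.10
    position_jitter_mm: float = 3.0
    save_volumes: bool = False
    phantom_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def base_params(self) -> PhantomParams:
        maker = {
            "default": PhantomParams,
            "reduced": PhantomParams.reduced,
            "fine": PhantomParams.fine,
        }.get(self.grid_preset)
        if maker is None:
            raise ValueError(f"unknown grid preset {self.grid_preset!r}")
        return maker(**self.phantom_overrides)

    def criteria(self) -> list[GammaCriteria]:
        return [
            GammaCriteria(d, r, self.low_dose_threshold, interp_step=self.gamma_interp_step)
            for d, r in self.gamma_criteria
        ]


@dataclass
class CaseResult:
    case_id: str
    seed: int
    pr_rows: list[dict]
    index_rows: list[dict]
    diff_rows: list[dict]
    constraint_rows: pd.DataFrame
    wall_time_s: float


@dataclass
class CohortReport:
    pr_table: pd.DataFrame
    indices: pd.DataFrame
    index_diffs: pd.DataFrame
    permutation_tests: pd.DataFrame
    box_pr: pd.DataFrame
    box_diffs: pd.DataFrame
    constraints: pd.DataFrame
    manifest: dict
    failed_cases: list[str]


def _roi_mask(rois: ROISet, name: str) -> np.ndarray:
    if name == "nvb":
        return rois["nvb_left"] | rois["nvb_right"]
    if name == "ALL":
        return np.ones(rois.grid.shape, dtype=bool)
    return rois[name]


def run_case(
    params: PhantomParams,
    config: PipelineConfig,
    case_id: str,
    model: DepthDoseModel | None = None,
    curve: HUCurve | None = None,
    outdir: Path | None = None,
) -> CaseResult:
    """Run the full single-case analysis: phantom to gamma/DVH comparison."""
    t0 = time.time()
    model = model or DepthDoseModel()
    curve = curve or HUCurve()
    rx_cGy = config.rx_gy * 100.0

    hu, rois = generate_phantom(params)
    hu_iod = iodinate_spacer(
        hu, rois["spacer"], params.iodinated_hu_mean, params.iodinated_hu_sd,
        params.smooth_sigma_voxels, seed=params.seed + 1,
    )
    spr = {sc: build_spr_grid(hu_iod, rois, sc, curve) for sc in ("TM", "NM", "WM")}
    plan = optimize_plan(spr["TM"], rois, rx_cGy, model, fractions=config.fractions)
    dose = {sc: compute_dose(plan, spr[sc], model) for sc in ("TM", "NM", "WM")}

    # gamma passing ratios per pair, criteria, structure
    ref = dose["TM"]
    thresh_mask = ref.values >= config.low_dose_threshold * ref.values.max()
    pr_rows = []
    for _, other in SCENARIO_PAIRS:
        pair = f"TM-{other}"
        for crit in config.criteria():
            gmap = gamma_map(ref, dose[other], crit, where=thresh_mask)
            for roi_name in (*config.pr_rois, "ALL"):
                pr = passing_ratio(gmap, ref, crit, _roi_mask(rois, roi_name))
                pr_rows.append({
                    "case": case_id, "pair": pair, "roi": roi_name,
                    "criteria": crit.label, "PR": pr,
                })

    index_rows, diff_rows = [], []
    for roi_name in config.index_rois:
        mask = _roi_mask(rois, roi_name)
        vals = {sc: dose_indices(dose[sc], mask, roi_name) for sc in ("TM", "NM", "WM")}
        for sc, metrics in vals.items():
            for metric, v in metrics.items():
                index_rows.append({
                    "case": case_id, "scenario": sc, "roi": roi_name,
                    "metric": metric, "value_cGy": v,
                })
        for _, other in SCENARIO_PAIRS:
            for metric in vals["TM"]:
                diff_rows.append({
                    "case": case_id, "pair": f"TM-{other}", "roi": roi_name,
                    "metric": metric,
                    "diff_cGy": vals["TM"][metric] - vals[other][metric],
                })

    constraints = constraint_report(dose, rois, load_constraints())
    constraints.insert(0, "case", case_id)

    if outdir is not None and config.save_volumes:
        case_dir = Path(outdir) / case_id
        case_dir.mkdir(parents=True, exist_ok=True)
        write_volume(hu_iod, case_dir / "hu.nii.gz", {"seed": params.seed})
        plan.save(case_dir / "plan.json")
        for sc in ("TM", "NM", "WM"):
            write_volume(dose[sc], case_dir / f"dose_{sc}.nii.gz")
        masks_dir = case_dir / "masks"
        masks_dir.mkdir(exist_ok=True)
        for name in rois.names():
            write_mask(rois[name], rois.grid, masks_dir / f"{name}.nii.gz")

    return CaseResult(case_id, params.seed, pr_rows, index_rows, diff_rows,
                      constraints, time.time() - t0)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> CohortReport:
    """Run the cohort study and aggregate statistics (optionally write CSVs)."""
    base = config.base_params()
    model = DepthDoseModel()
    curve = HUCurve()
    results: list[CaseResult] = []
    failed: list[str] = []
    for i in range(config.n_cases):
        case_id = f"case{i:03d}"
        params = jitter_params(base, i, config.master_seed,
                               config.size_jitter, config.position_jitter_mm)
        try:
            res = run_case(params, config, case_id, model, curve,
                           Path(outdir) if outdir else None)
            log.info("%s done in %.1f s (seed %d)", case_id, res.wall_time_s, res.seed)
            results.append(res)
        except Exception:
            log.exception("stage failure in %s (phantom/plan/compare)", case_id)
            failed.append(case_id)
    if not results:
        raise RuntimeError("every case failed")

    pr_table = pd.DataFrame([r for res in results for r in res.pr_rows])
    indices = pd.DataFrame([r for res in results for r in res.index_rows])
    index_diffs = pd.DataFrame([r for res in results for r in res.diff_rows])
    constraints = pd.concat([res.constraint_rows for res in results], ignore_index=True)

    # cohort statistics ---------------------------------------------------
    perm_rows, box_diff_rows = [], []
    test_idx = 0
    for (pair, roi, metric), grp in index_diffs.groupby(["pair", "roi", "metric"], sort=True):
        d = grp.sort_values("case")["diff_cGy"].to_numpy()
        if d.size >= 2:
            res = paired_permutation_test(d, config.n_perm,
                                          seed=config.master_seed * 100_000 + test_idx)
            perm_rows.append({
                "pair": pair, "roi": roi, "metric": metric,
                "mean_diff_cGy": res.observed, "p_value": res.p_value,
                "n_perm": res.n_perm, "exhaustive": res.exhaustive,
            })
        bs = box_summary(d)
        box_diff_rows.append({
            "pair": pair, "roi": roi, "metric": metric,
            "median": bs.median, "q25": bs.q25, "q75": bs.q75,
            "whisker_low": bs.whisker_low, "whisker_high": bs.whisker_high,
            "n_outliers": len(bs.outliers),
        })
        test_idx += 1

    box_pr_rows = []
    for (pair, roi, crit), grp in pr_table.groupby(["pair", "roi", "criteria"], sort=True):
        vals = grp["PR"].dropna().to_numpy()
        if vals.size == 0:
            continue
        bs = box_summary(vals)
        box_pr_rows.append({
            "pair": pair, "roi": roi, "criteria": crit,
            "median": bs.median, "q25": bs.q25, "q75": bs.q75,
            "whisker_low": bs.whisker_low, "whisker_high": bs.whisker_high,
            "n_outliers": len(bs.outliers),
        })

    manifest = {
        "package_version": __version__,
        "config": {**dataclasses.asdict(config),
                   "gamma_criteria": [list(c) for c in config.gamma_criteria],
                   "pr_rois": list(config.pr_rois),
                   "index_rois": list(config.index_rois)},
        "spacer_material": dict(spacer_material().weight_fractions),
        "case_seeds": {r.case_id: r.seed for r in results},
        "failed_cases": failed,
        "wall_time_s": {r.case_id: round(r.wall_time_s, 2) for r in results},
    }

    report = CohortReport(
        pr_table=pr_table,
        indices=indices,
        index_diffs=index_diffs,
        permutation_tests=pd.DataFrame(perm_rows),
        box_pr=pd.DataFrame(box_pr_rows),
        box_diffs=pd.DataFrame(box_diff_rows),
        constraints=constraints,
        manifest=manifest,
        failed_cases=failed,
    )
    if outdir is not None:
        write_report(report, outdir)
    return report


def write_report(report: CohortReport, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.pr_table.to_csv(outdir / "pr_table.csv", index=False)
    report.indices.to_csv(outdir / "indices.csv", index=False)
    report.index_diffs.to_csv(outdir / "index_diffs.csv", index=False)
    report.permutation_tests.to_csv(outdir / "permutation_tests.csv", index=False)
    report.box_pr.to_csv(outdir / "box_pr.csv", index=False)
    report.box_diffs.to_csv(outdir / "box_diffs.csv", index=False)
    report.constraints.to_csv(outdir / "constraints_report.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(report.manifest, indent=1))


def plot_pr_boxplots(report: CohortReport, path: str | Path) -> None:
    """Per-structure boxplots of gamma passing ratios (one panel per pair)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pairs = sorted(report.pr_table["pair"].unique())
    fig, axes = plt.subplots(len(pairs), 1, figsize=(10, 4 * len(pairs)), squeeze=False)
    for ax, pair in zip(axes[:, 0], pairs):
        sub = report.pr_table[report.pr_table["pair"] == pair]
        labels, data = [], []
        for (roi, crit), grp in sub.groupby(["roi", "criteria"], sort=True):
            vals = grp["PR"].dropna().to_numpy()
            if vals.size:
                labels.append(f"{roi}\n{crit}")
                data.append(vals)
        ax.boxplot(data, tick_labels=labels)
        ax.axhline(0.9, ls="--", lw=0.8, color="gray")  # clinical PR threshold
        ax.set_ylabel("gamma passing ratio")
        ax.set_title(pair)
        ax.tick_params(axis="x", labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
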
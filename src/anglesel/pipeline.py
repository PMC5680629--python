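"""End-to-end orchestration: simulate/load -> behavior -> morphometrics -> selection.

``run_pipeline`` executes the full analysis and (optionally) writes a report
bundle of plain CSV tables: behavior summaries per period, rank-order
consistency and repeatability per boldness measure, the trait correlation
matrix, captured-vs-uncaught descriptives, the AICc model comparison and the
mean-standardized selection gradients for each fitness horizon.  All outputs
are deterministic for a fixed seed; the seed is recorded in every file
header.  Stage timings go to the module logger.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, behavior, io as aio, morpho, selection, synth
from .config import RunConfig, SimConfig

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineReport"]

_DAY = pd.Timedelta(days=1)


@dataclass
class PipelineReport:
    """All tables produced by one pipeline run."""

    config: RunConfig
    behavior_by_period: pd.DataFrame
    consistency: pd.DataFrame
    correlations: pd.DataFrame
    traits: selection.TraitMatrix
    capture_summaries: pd.DataFrame
    descriptives: dict = field(default_factory=dict)  # horizon -> DataFrame
    model_comparisons: dict = field(default_factory=dict)
    gradients: dict = field(default_factory=dict)
    fits: dict = field(default_factory=dict)

    def tables(self) -> dict:
        t = {
            "behavior_summary": self.behavior_by_period,
            "repeatability": self.consistency,
            "correlations": self.correlations.reset_index(names="trait"),
            "capture_summary": self.capture_summaries,
        }
        for h in sorted(self.descriptives):
            t[f"descriptives_{h}d"] = self.descriptives[h]
            t[f"model_comparison_{h}d"] = self.model_comparisons[h]
            t[f"gradients_{h}d"] = self.gradients[h]
        return t


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **kw)
            except Exception as e:  # annotate with stage context
                raise StageError(name, e) from e
            logger.info("stage %-12s %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


@_stage("simulate")
def _obtain_data(cfg: RunConfig):
    if cfg.data_dir is not None:
        d = Path(cfg.data_dir)
        detections = aio.read_detections(d / "detections.csv")
        captures = aio.read_captures(d / "captures.csv")
        traits_raw = aio.read_traits(d / "traits.csv")
        landmarks = morpho.read_tps(d / "landmarks.tps")
        sim = SimConfig.from_yaml(d / "config.yaml") if (d / "config.yaml").exists() else SimConfig()
        return detections, captures, traits_raw, landmarks, sim
    sim = cfg.simulate
    bundle = synth.simulate_experiment(sim)
    roster = bundle.roster
    keep = set(roster["fish_id"])
    detections = bundle.detections[bundle.detections["fish_id"].isin(keep)].reset_index(drop=True)
    captures = bundle.captures[bundle.captures["fish_id"].isin(keep)].reset_index(drop=True)
    landmarks = [c for c in bundle.landmarks if c.fish_id in keep]
    traits_raw = roster[["fish_id", "pond", "tl_mm", "growth_mm"]].reset_index(drop=True)
    return detections, captures, traits_raw, landmarks, sim


@_stage("behavior")
def _behavior_stage(detections, traits_raw, sim: SimConfig, debounce_s: float):
    base = pd.Timestamp(sim.base_date)
    week1 = (base, base + sim.obs_days * _DAY)
    week2_days = min(7, sim.angling_days)
    week2 = (week1[1], week1[1] + week2_days * _DAY)
    roster = traits_raw
    b1 = behavior.summarize_behavior(detections, week1, debounce_s, roster)
    b2 = behavior.summarize_behavior(detections, week2, debounce_s, roster)
    b1.insert(1, "period", "observation")
    b2.insert(1, "period", "angling_week")
    both = pd.concat([b1, b2], ignore_index=True)

    rows = []
    labels = {"bp_close": "close feeding spot", "bp_distant": "distant feeding spot", "sp": "shelter use"}
    for col, label in labels.items():
        x = b1[col].to_numpy()
        y = b2.set_index("fish_id").loc[b1["fish_id"], col].to_numpy()
        cons = behavior.spearman_consistency(x, y)
        rep = behavior.lessells_boag_repeatability(np.column_stack([x, y]))
        rows.append(
            {
                "measure": label,
                "n": cons.n,
                "spearman_r": cons.spearman_rho,
                "spearman_p": cons.p_value,
                "F": rep.F,
                "F_p": rep.p_value,
                "repeatability": rep.r,
            }
        )
    return both, b1, pd.DataFrame(rows)


@_stage("morpho")
def _morpho_stage(landmarks, traits_raw, gpa_tol: float):
    order = {fid: i for i, fid in enumerate(traits_raw["fish_id"])}
    landmarks = sorted(landmarks, key=lambda c: order[c.fish_id])
    gpa = morpho.generalized_procrustes(landmarks, tol=gpa_tol)
    projector = morpho.BurnabyProjector().fit(gpa)
    body = morpho.shape_pca(projector.transform(gpa.aligned), analysis="body", ids=gpa.ids)
    head_cfg = morpho.head_subset(landmarks)
    gpa_head = morpho.generalized_procrustes(head_cfg, tol=gpa_tol)
    head = morpho.shape_pca(gpa_head.aligned, analysis="head", ids=gpa_head.ids)
    tl = traits_raw["tl_mm"].to_numpy(dtype=float)
    sb = morpho.size_correct(body.scores[:, 0], tl)
    sh = morpho.size_correct(head.scores[:, 0], tl)
    logger.info(
        "morpho: body PC1 %.1f%%, head PC1 %.1f%%, arching dEV %.2f pp",
        100 * body.explained_variance_ratio[0],
        100 * head.explained_variance_ratio[0],
        100 * projector.explained_variance_change_[0],
    )
    return sb, sh, body, head, projector


@_stage("selection")
def _selection_stage(traits: selection.TraitMatrix, captures, traits_raw, horizons, pond_mode,
                     raw_for_tables: pd.DataFrame):
    descriptives, comparisons, gradients, fits_by_h = {}, {}, {}, {}
    summaries = []
    for h in horizons:
        fitness = selection.assign_fitness(captures, h, traits_raw)
        fitness = fitness.loc[traits.fish_id.to_numpy()]
        comp, fits = selection.run_model_set(traits, fitness, horizon=h, pond_mode=pond_mode)
        final = selection.select_final_model(comp, fits)
        grad = selection.selection_gradients(final, traits, null_fit=fits.get(9))
        grad.insert(0, "model_no", final.model_no)
        desc, _ = selection.trait_descriptives(raw_for_tables, fitness)
        cs = behavior.capture_summary(captures, h, population=len(traits_raw))
        summaries.append(
            {
                "horizon_days": h,
                "captured": cs.captured,
                "population": cs.population,
                "fraction_pct": 100.0 * cs.fraction,
                "rod_hours": cs.rod_hours,
                "cpue_fish_per_hr": cs.cpue,
            }
        )
        descriptives[h], comparisons[h], gradients[h], fits_by_h[h] = desc, comp, grad, fits
    return descriptives, comparisons, gradients, fits_by_h, pd.DataFrame(summaries)


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> PipelineReport:
    """Run every stage in order; optionally write the report bundle to disk."""
    detections, captures, traits_raw, landmarks, sim = _obtain_data(cfg)
    behavior_tbl, week1, consistency = _behavior_stage(detections, traits_raw, sim, cfg.debounce_s)

    sb, sh, *_ = _morpho_stage(landmarks, traits_raw, cfg.gpa_tol)

    bp = week1.set_index("fish_id").loc[traits_raw["fish_id"], "bp_distant"].to_numpy()
    sp = week1.set_index("fish_id").loc[traits_raw["fish_id"], "sp"].to_numpy()
    growth_mm = traits_raw["growth_mm"].astype(float)
    raw = pd.DataFrame(
        {
            "fish_id": traits_raw["fish_id"],
            "pond": traits_raw["pond"],
            "BP": bp,
            "TL": traits_raw["tl_mm"].astype(float),
            "G": selection.growth_residuals(growth_mm, bp),
            "SB": sb,
            "SH": sh,
            "SP": sp,
        }
    )
    # "doubling growth" refers to the raw increment, not the residual
    traits = selection.zstandardize(raw, mean_overrides={"G": float(growth_mm.mean())})
    # descriptives and the correlation matrix report the raw growth increment
    # (the residual is uncorrelated with BP by construction)
    raw_for_tables = raw.assign(G=growth_mm.to_numpy())
    _, corr = selection.trait_descriptives(raw_for_tables, pd.Series(1, index=raw["fish_id"]))

    descriptives, comparisons, gradients, fits, capture_tbl = _selection_stage(
        traits, captures, traits_raw, cfg.horizons, cfg.pond_mode, raw_for_tables
    )

    report = PipelineReport(
        config=cfg,
        behavior_by_period=behavior_tbl,
        consistency=consistency,
        correlations=corr,
        traits=traits,
        capture_summaries=capture_tbl,
        descriptives=descriptives,
        model_comparisons=comparisons,
        gradients=gradients,
        fits=fits,
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: PipelineReport, out_dir) -> dict:
    """Write every report table as CSV with a reproducibility header."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# anglesel {__version__} seed={report.config.seed}\n"
    paths = {}
    for name, df in report.tables().items():
        path = out / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")
        paths[name] = path
    summary = out / "summary.txt"
    with open(summary, "w") as fh:
        fh.write(header)
        fh.write(_summary_text(report))
    paths["summary"] = summary
    return paths


def _summary_text(report: PipelineReport) -> str:
    lines = []
    n = report.traits.n
    lines.append(f"fish with complete records: {n}")
    for _, row in report.capture_summaries.iterrows():
        lines.append(
            f"{int(row.horizon_days)}-day angling: {int(row.captured)}/{int(row.population)} captured "
            f"({row.fraction_pct:.1f}%), CPUE {row.cpue_fish_per_hr:.3f} fish/hr"
        )
    for _, row in report.consistency.iterrows():
        lines.append(
            f"repeatability {row.measure}: r = {row.repeatability:.3f} "
            f"(Spearman rho = {row.spearman_r:.3f})"
        )
    for h, grad in sorted(report.gradients.items()):
        comp = report.model_comparisons[h]
        best = comp.sort_values("aicc").iloc[0]
        lines.append(
            f"{h}-day best model: #{int(best.model_no)} [{best.terms}] "
            f"AICc = {best.aicc:.1f}, w = {best.weight:.3f}"
        )
        final_no = int(grad["model_no"].iloc[0])
        final_row = comp.loc[comp.model_no == final_no].iloc[0]
        lines.append(
            f"{h}-day gradients from final model #{final_no} [{final_row.terms}] "
            f"(richest within delta-AICc < 1):"
        )
        for _, g in grad.iterrows():
            bmu = "n/a" if np.isnan(g.beta_mu) else f"{g.beta_mu:.3f}"
            lines.append(
                f"  {g.trait}: alpha = {g.alpha:.3f} (SE {g.se:.2f}, p = {g.p:.3f}), "
                f"beta_SD = {g.beta_sd:.3f}, beta_mu = {bmu}"
            )
    return "\n".join(lines) + "\n"
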
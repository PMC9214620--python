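"""End-to-end pipeline: simulate → cohort → exposure → screen → validate → report.

Each stage reads and writes plain CSV/JSON in one artifact directory and
logs its row counts; a manifest records the configuration, seed and
per-stage counts so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import defaults
from .cohort import DEFAULT_LOOKBACK_DAYS, build_cohort, load_code_lists, summarize_cohort
from .exposure import (DEFAULT_MIN_PATIENTS, DEFAULT_WINDOW, filter_min_patients,
                       map_orders, window_exposure)
from .screening import MWASModel, export_forest
from .synthetic import SimulationConfig, generate_cohort
from .validation import performance_table

logger = logging.getLogger(__name__)

MODELS = ("model1", "model2", "model3")


class PipelineError(RuntimeError):
    """A named stage failed; partial outputs are retained."""


@dataclass
class RunConfig:
    """Configuration of a full run.

    Either ``simulate`` is set (synthetic tables are generated into the
    artifact directory) or the three input paths point at existing CSVs.
    Defaults equal the screen's standard constants: 275–215-day exposure
    window, 315-day diagnosis lookback, ≥5-patient filter, alpha 0.05.
    """

    deliveries: str | None = None
    orders: str | None = None
    diagnoses: str | None = None
    code_lists: str | None = None
    annotations: str | None = None
    gold_standard: str | None = None
    window: tuple[int, int] = DEFAULT_WINDOW
    lookback_days: int = DEFAULT_LOOKBACK_DAYS
    mb_tolerance_days: int = 0
    min_patients: int = DEFAULT_MIN_PATIENTS
    alpha: float = 0.05
    models: tuple[str, ...] = MODELS
    simulate: SimulationConfig | None = None

    def __post_init__(self):
        far, near = self.window
        if far <= near:
            raise ValueError("window must be (far, near) days before delivery with far > near")
        if self.lookback_days <= 0:
            raise ValueError("lookback_days must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: tuple(v) if k in ("window", "models") else v for k, v in raw.items()})
        if sim is not None:
            if "gold_standard_ids" in sim:
                sim["gold_standard_ids"] = tuple(sim["gold_standard_ids"])
            cfg.simulate = SimulationConfig(**sim)
        return cfg

    def to_jsonable(self) -> dict:
        out = dataclasses.asdict(self)
        if self.simulate is not None:
            sim = dataclasses.asdict(self.simulate)
            sim["gold_standard_ids"] = list(sim["gold_standard_ids"])
            if isinstance(sim["exposure_prevalence"], Mapping):
                sim["exposure_prevalence"] = dict(sim["exposure_prevalence"])
            sim["beta_medication"] = dict(sim["beta_medication"])
            sim["exposure_blocks"] = [list(b) for b in sim["exposure_blocks"]]
            out["simulate"] = sim
        out["window"] = list(self.window)
        out["models"] = list(self.models)
        return out


def _stage(name: str, manifest: dict):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def record(self, **counts):
            manifest["stages"][name] = counts
            logger.info("stage %s: %s", name, counts)

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            return False
    return _Ctx()


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute every stage into ``outdir`` and return its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_jsonable(), "stages": {}}

    with _stage("simulate", manifest) as st:
        if config.simulate is not None:
            synthetic = generate_cohort(config.simulate)
            synthetic.write(outdir)
            deliveries_path = outdir / "deliveries.csv"
            orders_path = outdir / "orders.csv"
            diagnoses_path = outdir / "diagnoses.csv"
            st.record(deliveries=len(synthetic.deliveries),
                      orders=len(synthetic.orders),
                      diagnoses=len(synthetic.diagnoses))
        else:
            deliveries_path = Path(config.deliveries)
            orders_path = Path(config.orders)
            diagnoses_path = Path(config.diagnoses)
            st.record(skipped=True)

    with _stage("build-cohort", manifest) as st:
        deliveries = pd.read_csv(deliveries_path, dtype={"patient_id": str, "delivery_id": str})
        diagnoses = pd.read_csv(diagnoses_path, dtype={"patient_id": str, "code": str})
        codes_frame = (pd.read_csv(config.code_lists) if config.code_lists
                       else defaults.default_code_lists())
        code_lists = load_code_lists(codes_frame)
        cohort = build_cohort(deliveries, diagnoses, code_lists,
                              lookback_days=config.lookback_days,
                              mb_tolerance_days=config.mb_tolerance_days)
        cohort.to_csv(outdir / "cohort.csv", index=False)
        st.record(deliveries=len(cohort), mb=int(cohort["mb"].sum()),
                  art=int(cohort["art"].sum()), infertility=int(cohort["infertility"].sum()))

    with _stage("build-exposure", manifest) as st:
        orders = pd.read_csv(orders_path, dtype={"patient_id": str})
        annotations = (pd.read_csv(config.annotations) if config.annotations
                       else defaults.default_annotations(
                           config.simulate.n_medications if config.simulate
                           else defaults.DEFAULT_N_MEDICATIONS))
        mapped = map_orders(orders, annotations)
        matrix = window_exposure(cohort, mapped, window=config.window)
        filtered = filter_min_patients(matrix, config.min_patients)
        matrix.frame.to_csv(outdir / "exposure_matrix.csv")
        filtered.patient_counts().rename_axis("medication_id").to_csv(
            outdir / "medication_counts.csv")
        fertility_ids = sorted(
            annotations.loc[annotations["fertility_flag"] == 1, "medication_id"].unique())
        summary = summarize_cohort(cohort, matrix, fertility_ids)
        summary.to_csv(outdir / "summary.csv", index=False)
        st.record(orders=len(orders), mapped=len(mapped),
                  unmatched=mapped.attrs.get("n_unmatched", 0),
                  medications=matrix.m, retained=filtered.m)

    screens = {}
    for label in config.models:
        with _stage(f"screen-{label}", manifest) as st:
            results = MWASModel(cohort, filtered, model=label, alpha=config.alpha).fit()
            results.frame.to_csv(outdir / f"results_{label}.csv", index=False)
            if label == "model3":
                export_forest(results).to_csv(outdir / "forest_data.csv", index=False)
            screens[label] = results.frame
            st.record(medications=filtered.m,
                      sig_nominal=int(results.frame["sig_nominal"].sum()),
                      sig_bonf=int(results.frame["sig_bonf"].sum()))

    with _stage("validate", manifest) as st:
        if config.gold_standard:
            gold = pd.read_csv(config.gold_standard)["medication_id"].astype(str).tolist()
        elif config.simulate is not None and config.simulate.gold_standard_ids:
            gold = list(config.simulate.gold_standard_ids)
        else:
            gold = defaults.default_gold_standard()
        gold = [g for g in gold if g in set(filtered.medication_ids)]
        if gold:
            perf = performance_table(screens, gold)
            perf.to_csv(outdir / "performance.csv", index=False)
            st.record(gold=len(gold))
        else:
            st.record(gold=0, skipped=True)

    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return outdir


def screen_synthetic(sim_config: SimulationConfig,
                     models: tuple[str, ...] = ("model3",),
                     min_patients: int = DEFAULT_MIN_PATIENTS,
                     alpha: float = 0.05):
    """Generate a synthetic cohort and run the screen in memory.

    Returns (analysis cohort, unfiltered matrix, filtered matrix,
    {model label: MWASResults}).  Convenience wrapper over the same
    stages run_pipeline executes, without file round-trips.
    """
    synthetic = generate_cohort(sim_config)
    code_lists = load_code_lists(defaults.default_code_lists())
    cohort = build_cohort(synthetic.deliveries, synthetic.diagnoses, code_lists)
    mapped = map_orders(synthetic.orders, sim_config.annotations())
    matrix = window_exposure(cohort, mapped)
    filtered = filter_min_patients(matrix, min_patients)
    results = {label: MWASModel(cohort, filtered, model=label, alpha=alpha).fit()
               for label in models}
    return cohort, matrix, filtered, results


def make_report(artifact_dir: str | Path, plot: bool = False) -> str:
    """Render a human-readable run report from stage outputs only.

    Validates the Bonferroni ⊆ nominal invariant on every results file
    and refuses to render from inconsistent artifacts.  With ``plot`` a
    forest plot PNG is written next to the report (requires matplotlib).
    """
    d = Path(artifact_dir)
    required = ["manifest.json", "summary.csv"]
    missing = [f for f in required if not (d / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete artifact directory, missing {missing}")
    manifest = json.loads((d / "manifest.json").read_text())

    lines = ["MWAS run report", "=" * 40, ""]
    lines.append("Stage counts:")
    for stage, counts in manifest["stages"].items():
        lines.append(f"  {stage}: " + ", ".join(f"{k}={v}" for k, v in counts.items()))
    lines.append("")

    summary = pd.read_csv(d / "summary.csv")
    lines += ["Cohort summary (per stratum):", summary.to_string(index=False), ""]

    forest = None
    for label in MODELS:
        path = d / f"results_{label}.csv"
        if not path.exists():
            continue
        res = pd.read_csv(path)
        if ((res["sig_bonf"] == 1) & (res["sig_nominal"] == 0)).any():
            raise ValueError(
                f"invariant violation in {path.name}: Bonferroni-significant "
                "medication without nominal significance")
        lines.append(
            f"{label}: {int(res['sig_nominal'].sum())} nominal / "
            f"{int(res['sig_bonf'].sum())} Bonferroni significant of {len(res)}")
    lines.append("")

    perf_path = d / "performance.csv"
    if perf_path.exists():
        perf = pd.read_csv(perf_path)
        lines += ["Gold-standard performance:", perf.to_string(index=False), ""]

    forest_path = d / "forest_data.csv"
    if forest_path.exists():
        forest = pd.read_csv(forest_path)
        if forest.empty:
            lines.append("Forest set: no significant medications.")
        else:
            lines += ["Forest-plot data (model 3):", forest.to_string(index=False)]
        if plot and not forest.empty:
            _plot_forest(forest, d / "forest.png")
            lines.append(f"Forest plot written to {d / 'forest.png'}")

    report = "\n".join(lines) + "\n"
    (d / "report.txt").write_text(report)
    return report


def _plot_forest(forest: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = forest[forest["term"] == "exposure"].sort_values("or_")
    fig, ax = plt.subplots(figsize=(6, max(2, 0.3 * len(sub))))
    ypos = range(len(sub))
    ax.errorbar(sub["or_"], list(ypos),
                xerr=[sub["or_"] - sub["ci_low"], sub["ci_high"] - sub["or_"]],
                fmt="o", capsize=3)
    ax.axvline(1.0, color="grey", lw=0.8)
    ax.set_yticks(list(ypos), sub["medication_id"])
    ax.set_xscale("log")
    ax.set_xlabel("odds ratio (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
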
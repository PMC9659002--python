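"""Pipeline orchestration and the method-comparison report.

``run_pipeline`` executes the full analysis — ingest (or simulate) →
crude rates → quintile levels → three weight groups → fuzzy nearness
selection → random forest → comparison report — writing every stage
artifact plus a manifest with a structured per-stage log (stage name,
input hash, seed, elapsed seconds).  Given the same configuration and
seed the outputs are identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import ahp as ahp_mod
from . import datasets
from .chisq import chisq_stage
from .fuzzy import NearnessResult, membership_matrix, nearness_analysis, reference_membership
from .ingest import LCM, crude_rates, quintile_classify, read_mortality_table
from .rf import RfConfig, RfReport, fit_and_report, split
from .ridit import ridit_stage
from .synthetic import GroundTruth, SyntheticConfig, generate

logger = logging.getLogger(__name__)

#: Stage artifacts written by a full run, in execution order.
ARTIFACTS = ("data", "levels", "a1", "a2", "a3", "nearness", "rf_report",
             "comparison")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full run.

    Exactly one of ``data`` (path to a long-format mortality CSV) or
    ``simulate`` (synthetic-generator settings) must be provided.  The
    top-level ``seed`` drives both the generator and the random-forest
    stage unless those carry their own.
    """

    data: str | None = None
    schema: Mapping[str, str] | None = None
    simulate: SyntheticConfig | None = None
    unit: str = "country-year"
    ahp_matrix: str | None = None       # None -> packaged Delphi matrix
    ahp_method: str = "column_norm_mean"
    reference: Sequence[float] | None = None  # None -> computed from LCM rates
    rf: RfConfig = field(default_factory=RfConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.data is None) == (self.simulate is None):
            raise ValueError("provide exactly one of 'data' or 'simulate'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        seed = int(raw.get("seed", 0))
        sim = raw.get("simulate")
        if sim is not None:
            sim = SyntheticConfig(**{"seed": seed, **sim})
        rf = RfConfig(**{"seed": seed, **raw.get("rf", {})})
        return cls(
            data=raw.get("data"),
            schema=raw.get("schema"),
            simulate=sim,
            unit=raw.get("unit", "country-year"),
            ahp_matrix=raw.get("ahp_matrix"),
            ahp_method=raw.get("ahp_method", "column_norm_mean"),
            reference=raw.get("reference"),
            rf=rf,
            seed=seed,
        )


@dataclass(frozen=True)
class PipelineResult:
    """All stage outputs of a full run."""

    table: pd.DataFrame
    rates: pd.DataFrame
    levels: pd.DataFrame
    weights: dict[str, pd.Series]       # method -> weight vector
    nearness: NearnessResult
    rf_report: RfReport
    comparison: pd.DataFrame
    truth: GroundTruth | None
    manifest: dict


def _rank(weights: pd.Series) -> pd.Series:
    """Ordinal ranks 1..m, highest weight first, ties alphabetical."""
    order = sorted(weights.index, key=lambda v: (-weights[v], v))
    return pd.Series({v: i + 1 for i, v in enumerate(order)}, name="rank")


def comparison_report(
    weights: Mapping[str, pd.Series], rf_report: RfReport
) -> pd.DataFrame:
    """Per-variable weights and ranks of every method, plus the RF ranking."""
    out = pd.DataFrame(index=sorted(rf_report.importances.index))
    out["rfm_importance"] = rf_report.importances
    out["rfm_rank"] = _rank(rf_report.importances)
    for method, w in weights.items():
        out[f"{method}_weight"] = w
        out[f"{method}_rank"] = _rank(w)
    out.index.name = "variable"
    return out


def topk_overlap(
    ranking_a: Sequence[str], ranking_b: Sequence[str], k: int
) -> tuple[int, set[str]]:
    """Size and members of the intersection of two rankings' top-k sets."""
    if set(ranking_a) != set(ranking_b):
        raise ValueError("rankings cover different variable sets")
    if k > len(ranking_a):
        raise ValueError(f"k={k} exceeds the number of variables")
    common = set(ranking_a[:k]) & set(ranking_b[:k])
    return len(common), common


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig | str | Path, output_dir: str | Path
) -> PipelineResult:
    """Execute every stage and write all artifacts under ``output_dir``.

    On a stage failure the pipeline aborts with the stage name and cause;
    artifacts of completed stages are retained.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "artifacts": {}}
    stage_t0 = time.perf_counter()

    def _record(stage: str, artifact: str | None, path: Path | None) -> None:
        nonlocal stage_t0
        entry = {
            "stage": stage,
            "seed": config.seed,
            "elapsed_s": round(time.perf_counter() - stage_t0, 4),
        }
        if path is not None:
            entry["sha256"] = _sha256(path)
            manifest["artifacts"][artifact] = path.name
        manifest["stages"].append(entry)
        logger.info("stage %s done in %.3fs", stage, entry["elapsed_s"])
        stage_t0 = time.perf_counter()

    def _run(stage, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- data -------------------------------------------------------------
    truth: GroundTruth | None = None
    if config.simulate is not None:
        table, truth = _run("simulate", lambda: generate(config.simulate))
        truth.to_json(out / "ground_truth.json")
    else:
        table = _run(
            "ingest",
            lambda: read_mortality_table(config.data, schema=config.schema),
        )
    data_path = out / "data.csv"
    table.to_csv(data_path, index=False)
    _record("data", "data", data_path)

    # --- rates and levels -------------------------------------------------
    rates = _run("crude_rates", lambda: crude_rates(table, unit=config.unit))
    levels = _run("quintile_classify", lambda: quintile_classify(rates))
    levels_path = out / "levels.csv"
    levels.reset_index().to_csv(levels_path, index=False)
    rates.reset_index().to_csv(out / "rates.csv", index=False)
    _record("classify", "levels", levels_path)

    # --- weight groups ----------------------------------------------------
    _, _, a1 = _run("weights_chisq", lambda: chisq_stage(rates, levels))
    a1_path = out / "a1.csv"
    a1.rename("weight").to_csv(a1_path)
    _record("weights_chisq", "a1", a1_path)

    _, _, a2 = _run("weights_ridit", lambda: ridit_stage(levels))
    a2_path = out / "a2.csv"
    a2.rename("weight").to_csv(a2_path)
    _record("weights_ridit", "a2", a2_path)

    def _ahp():
        if config.ahp_matrix is not None:
            matrix = ahp_mod.read_pairwise_matrix(config.ahp_matrix)
        else:
            matrix = datasets.load_delphi_matrix()
        result = ahp_mod.priority_vector(matrix, method=config.ahp_method)
        return result.weights.reindex(a1.index).fillna(0.0)

    a3 = _run("weights_ahp", _ahp)
    a3 = a3 / a3.sum()
    a3_path = out / "a3.csv"
    a3.rename("weight").to_csv(a3_path)
    _record("weights_ahp", "a3", a3_path)

    # --- fuzzy nearness selection ------------------------------------------
    def _fuzzy():
        R = membership_matrix(levels)
        if config.reference is not None:
            C = pd.Series(list(config.reference), index=range(1, 6))
            C = C / C.sum()
        else:
            C = reference_membership(rates[LCM], levels[LCM])
        return nearness_analysis({"chisq": a1, "ridit": a2, "ahp": a3}, R, C)

    nearness = _run("fuzzy_nearness", _fuzzy)
    nearness_path = out / "nearness.json"
    nearness_path.write_text(json.dumps(nearness.to_dict(), indent=2))
    _record("fuzzy_nearness", "nearness", nearness_path)

    # --- random forest ------------------------------------------------------
    def _rf():
        train, test = split(levels, config.rf)
        return fit_and_report(train, test, config.rf)

    rf_report = _run("rf", _rf)
    rf_path = out / "rf_report.json"
    rf_path.write_text(json.dumps(rf_report.to_dict(), indent=2))
    _record("rf", "rf_report", rf_path)

    # --- comparison ---------------------------------------------------------
    comparison = _run(
        "report",
        lambda: comparison_report({"chisq": a1, "ridit": a2, "ahp": a3}, rf_report),
    )
    comparison_path = out / "comparison.csv"
    comparison.to_csv(comparison_path)
    _record("report", "comparison", comparison_path)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return PipelineResult(
        table=table, rates=rates, levels=levels,
        weights={"chisq": a1, "ridit": a2, "ahp": a3},
        nearness=nearness, rf_report=rf_report, comparison=comparison,
        truth=truth, manifest=manifest,
    )
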
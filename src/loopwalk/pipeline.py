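"""End-to-end pipeline runs: configuration, execution, reports, file I/O.

``run_full_pipeline`` executes encode -> stratify -> fit stage 1 -> LOOCV ->
fit stage 2 -> LOOCV -> enumerate -> stage-1 screen -> stage-2 rank ->
select, and writes three artifacts to the output directory: the candidate
ranking TSV, the stage-2 weight-table TSV, and a JSON run report.  Runs
are deterministic for a fixed seed; a failure in any stage aborts with the
stage name and removes partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field, field_validator

from . import __version__
from .cascade import StratificationConfig, ThermostabilityCascade
from .descriptors import DescriptorTable
from .screening import read_screen_table

logger = logging.getLogger("loopwalk")

__all__ = ["RunConfig", "RunReport", "run_full_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class RunConfig(BaseModel):
    """Configuration of one full pipeline run (JSON-serialisable)."""

    screen_path: str
    descriptor_source: str = "packaged"  # "packaged" or a CSV/AAindex1 path
    top_fraction: float = 0.34
    bottom_fraction: float = 0.34
    lambda_policy: str = "cv5"
    family: str = "logistic"
    n_high: int = Field(default=20, ge=0)
    n_medium: int = Field(default=20, ge=0)
    run_loocv: bool = True
    seed: int = 0
    out_dir: str = "loopwalk_out"

    @field_validator("top_fraction", "bottom_fraction")
    @classmethod
    def _frac(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError("stratification fractions must lie in (0, 1)")
        return v

    def config_hash(self) -> str:
        return hashlib.sha256(
            self.model_dump_json().encode()
        ).hexdigest()[:12]


class RunReport(BaseModel):
    """Machine-readable summary of a completed run.

    ``RunReport.model_json_schema()`` is the packaged schema; a report read
    back from disk is validated by constructing this model from it.
    """

    version: str
    seed: int
    config: RunConfig
    config_hash: str
    n_mutants: int
    label_counts: dict[str, int]
    loocv_accuracy_stage1: Optional[float]
    loocv_accuracy_stage2: Optional[float]
    n_candidates: int
    n_stage1_kept: int
    n_stage1_rejected: int
    selected_high: list[dict]
    selected_medium: list[dict]
    weight_table: dict[str, dict[str, float]]


def _load_descriptors(source: str) -> DescriptorTable:
    if source == "packaged":
        return DescriptorTable.paper_set()
    path = Path(source)
    if path.suffix.lower() == ".csv":
        return DescriptorTable.from_csv(path)
    return DescriptorTable.from_aaindex1(path)


def run_full_pipeline(config: RunConfig) -> RunReport:
    """Run the whole cascade on a screening table and write its artifacts."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = [out_dir / "ranking.tsv", out_dir / "weights.tsv", out_dir / "report.json"]
    stage = "setup"
    try:
        stage = "read_screen_table"
        records, wildtype = read_screen_table(config.screen_path)
        logger.info(
            "run start: seed=%d config_hash=%s n_mutants=%d",
            config.seed, config.config_hash(), len(records),
        )

        stage = "load_descriptors"
        table = _load_descriptors(config.descriptor_source)

        stage = "encode_and_stratify"
        model = ThermostabilityCascade.from_screen(
            records,
            table,
            stratification=StratificationConfig(
                config.top_fraction, config.bottom_fraction
            ),
            lambda_policy=config.lambda_policy,
            family=config.family,
        )

        stage = "fit_and_loocv"
        results = model.fit(seed=config.seed, run_loocv=config.run_loocv)

        stage = "rank_candidates"
        ranking = results.rank_candidates()
        n_candidates = 20 ** 3 - len(set(model.triples))

        stage = "select_candidates"
        high, medium = results.select(ranking, config.n_high, config.n_medium)

        stage = "write_outputs"
        ranking.to_tsv(out_dir / "ranking.tsv")
        wt = results.weight_table()
        wt.to_csv(out_dir / "weights.tsv", sep="\t", float_format="%.10g")
        report = RunReport(
            version=__version__,
            seed=config.seed,
            config=config,
            config_hash=config.config_hash(),
            n_mutants=len(records),
            label_counts=results.label_counts,
            loocv_accuracy_stage1=(
                results.loocv_stage1.accuracy if results.loocv_stage1 else None
            ),
            loocv_accuracy_stage2=(
                results.loocv_stage2.accuracy if results.loocv_stage2 else None
            ),
            n_candidates=n_candidates,
            n_stage1_kept=len(ranking),
            n_stage1_rejected=n_candidates - len(ranking),
            selected_high=high[["rank", "triple", "p_high"]].to_dict(orient="records"),
            selected_medium=medium[["rank", "triple", "p_high"]].to_dict(
                orient="records"
            ),
            weight_table={
                d: {p: float(wt.loc[d, p]) for p in wt.columns} for d in wt.index
            },
        )
        (out_dir / "report.json").write_text(report.model_dump_json(indent=1))
        logger.info("run complete: %d candidates ranked", len(ranking))
        return report
    except Exception as exc:
        for f in outputs:
            f.unlink(missing_ok=True)
        raise PipelineError(f"pipeline stage '{stage}' failed: {exc}") from exc


def read_report(path: str | Path) -> RunReport:
    """Load and validate a run report written by :func:`run_full_pipeline`."""
    return RunReport.model_validate(json.loads(Path(path).read_text()))
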
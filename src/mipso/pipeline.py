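"""End-to-end selection pipeline as a Model / Results pair.

:class:`SelectionPipeline` is constructed from labelled trial tensors and a
:class:`~mipso.config.PipelineConfig`; :meth:`SelectionPipeline.fit` runs
downsampling, MST feature extraction, the configured multilevel-PSO
selection scheme, a final discriminant fit on the surviving mask, and
held-out evaluation.  The returned :class:`PipelineResults` carries the
baseline (no-selection) report, every level's mask and report, the final
model, and a ``summary()`` table with one row per level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .blda import BayesianDiscriminant, BayesianDiscriminantResults
from .config import PipelineConfig
from .containers import TrialTensor
from .metrics import EvaluationReport, confusion
from .multilevel import (
    LevelResult,
    SelectionMask,
    channel_then_feature,
    run_multilevel,
    stratified_split,
)
from .stockwell import downsample, extract_features

__all__ = ["SelectionPipeline", "PipelineResults"]


class SelectionPipeline:
    """Channel/feature-selection pipeline bound to training (and test) data.

    Parameters
    ----------
    train : TrialTensor
        Labelled training trials at any integer multiple of the target rate.
    test : TrialTensor, optional
        Held-out trials for the final evaluation.  When omitted, a seeded
        stratified ``test_fraction`` of the training trials is set aside
        before any fitting.
    config : PipelineConfig, optional
        All stage parameters; defaults are the tuned operating point.
    """

    def __init__(
        self,
        train: TrialTensor,
        test: TrialTensor | None = None,
        config: PipelineConfig | None = None,
    ) -> None:
        self.train = train
        self.test = test
        self.config = config or PipelineConfig()

    def fit(self, seed: int | None = None) -> "PipelineResults":
        """Run the full pipeline; ``seed`` overrides the config's seed."""
        cfg = self.config
        master = int(cfg.seed if seed is None else seed)

        train = self.train
        test = self.test
        if train.fs != cfg.target_fs:
            train = downsample(train, cfg.target_fs)
        if test is not None and test.fs != cfg.target_fs:
            test = downsample(test, cfg.target_fs)

        if test is None:
            rng = np.random.default_rng([master, 42])
            kept, held = stratified_split(train.labels, cfg.test_fraction, rng)
            test = train.subset(held)
            train = train.subset(kept)

        feats = extract_features(train, cfg.mst)
        test_feats = extract_features(test, cfg.mst)

        common = dict(
            eval_features=test_feats,
            val_fraction=cfg.val_fraction,
            fitness_on_eval=cfg.fitness_on_eval,
            use_scores=cfg.use_scores,
            standardize=cfg.standardize,
            target_coding=cfg.target_coding,
        )
        pso = replace(cfg.pso, seed=master)

        baseline_model = BayesianDiscriminant(
            feats.labels,
            feats.values,
            standardize=cfg.standardize,
            target_coding=cfg.target_coding,
        ).fit()
        baseline_report = confusion(
            test_feats.labels, baseline_model.classify(test_feats.values)
        )

        levels: list[LevelResult] = []
        if cfg.scheme == "feature":
            levels = run_multilevel(feats, "feature", pso, cfg.max_level, **common)
        elif cfg.scheme == "channel":
            levels = run_multilevel(feats, "channel", pso, cfg.max_level, **common)
        elif cfg.scheme == "channel-feature":
            pso_ft = replace(cfg.pso_feature or cfg.pso, seed=master)
            ch_levels, ft_levels = channel_then_feature(
                feats,
                pso,
                pso_ft,
                cfg.max_level,
                cfg.max_level_feature or cfg.max_level,
                **common,
            )
            levels = ch_levels + ft_levels

        if levels:
            final_mask = levels[-1].mask
            cols = final_mask.feature_column_mask(feats)
            final_model = BayesianDiscriminant(
                feats.labels,
                feats.values[:, cols],
                standardize=cfg.standardize,
                target_coding=cfg.target_coding,
            ).fit()
            final_model.mask = cols.astype(np.uint8)
            final_report = confusion(
                test_feats.labels, final_model.classify(test_feats.values[:, cols])
            )
        else:  # scheme == "none": the baseline is the result
            final_mask = None
            final_model = baseline_model
            final_report = baseline_report

        return PipelineResults(
            config=cfg,
            seed=master,
            levels=levels,
            baseline_report=baseline_report,
            final_mask=final_mask,
            final_model=final_model,
            final_report=final_report,
            feature_columns=list(feats.columns),
        )


@dataclass
class PipelineResults:
    """Everything the pipeline produced, with summary and persistence."""

    config: PipelineConfig
    seed: int
    levels: list[LevelResult]
    baseline_report: EvaluationReport
    final_mask: SelectionMask | None
    final_model: BayesianDiscriminantResults
    final_report: EvaluationReport
    feature_columns: list

    @property
    def n_selected(self) -> int | None:
        return None if self.final_mask is None else self.final_mask.n_selected

    def selected_channels(self) -> list[int]:
        """Channels surviving in the final mask (all channels if none)."""
        if self.final_mask is None:
            return sorted({c for c, _ in self.feature_columns})
        if self.final_mask.granularity == "channel":
            return [int(c) for c in self.final_mask.selected_provenance]
        return sorted({int(c) for c, _ in self.final_mask.selected_provenance})

    def summary(self) -> str:
        header = "Level\tPhase\tSelected\tACC%\tKappa\tF-score\tSEN\tSPE\tPRE"
        lines = [
            f"Multilevel PSO selection — scheme: {self.config.scheme}, seed: {self.seed}",
            header,
            "0\tbaseline\t"
            + str(len(self.feature_columns))
            + "\t"
            + "\t".join(self.baseline_report.tsv_row().split("\t")[1:]),
        ]
        for lv in self.levels:
            row = (
                lv.evaluation.tsv_row(lv.n_selected)
                if lv.evaluation is not None
                else f"{lv.n_selected}" + "\t-" * 6
            )
            lines.append(f"{lv.level}\t{lv.phase}\t{row}")
        lines.append(
            f"final: {self.final_report.to_dict()['accuracy'] * 100:.2f}% accuracy, "
            f"kappa {self.final_report.kappa:.2f}, "
            f"{self.n_selected if self.n_selected is not None else len(self.feature_columns)} "
            "selected"
        )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Write config, per-level masks/reports, traces and the final model."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.json").write_text(
            json.dumps(self.config.to_dict(), indent=2) + "\n"
        )
        (outdir / "baseline_report.json").write_text(self.baseline_report.to_json() + "\n")
        trace_lines = ["phase\tlevel\titeration\tgbest_fitness\tgbest_popcount"]
        for lv in self.levels:
            lvdir = outdir / f"level_{lv.level}_{lv.phase}"
            lvdir.mkdir(exist_ok=True)
            (lvdir / "mask.txt").write_text(lv.mask.to_text())
            if lv.evaluation is not None:
                (lvdir / "report.json").write_text(lv.evaluation.to_json() + "\n")
            pops = (
                lv.popcount_trace
                if lv.popcount_trace is not None
                else [lv.n_selected] * len(lv.trace)
            )
            for it, (fit, pop) in enumerate(zip(lv.trace, pops)):
                trace_lines.append(f"{lv.phase}\t{lv.level}\t{it}\t{fit}\t{pop}")
        (outdir / "trace.tsv").write_text("\n".join(trace_lines) + "\n")
        (outdir / "final_model.json").write_text(self.final_model.to_json() + "\n")
        (outdir / "final_report.json").write_text(self.final_report.to_json() + "\n")
        (outdir / "summary.txt").write_text(self.summary() + "\n")
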
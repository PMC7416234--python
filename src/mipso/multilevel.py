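"""Multilevel binary-PSO selection over channels and features.

A single PSO run finds a good mask, but a swarm of N particles exploring a
2240-bit space can stall on local optima.  The multilevel scheme re-runs the
optimiser, each level restricted to the coordinates the previous level's
global best retained, so the search space shrinks and the particle-to-
dimension ratio improves.  Levels stop at ``max_level`` or as soon as two
consecutive levels select the same number of coordinates.

Three schemes are provided: channel selection (one bit per channel; a set
bit activates the channel's whole feature block), feature selection (one
bit per column), and channel-then-feature selection (channel phase first,
then feature-granularity levels restricted to the surviving channels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blda import BayesianDiscriminant
from .containers import FeatureMatrix
from .metrics import EvaluationReport, confusion
from .pso import PSOConfig, PSOResult, mse_inverse_fitness, run_pso

__all__ = [
    "SelectionMask",
    "LevelResult",
    "stratified_split",
    "run_multilevel",
    "channel_selection",
    "feature_selection",
    "channel_then_feature",
]


@dataclass
class SelectionMask:
    """Binary mask in the *global* coordinate space of its granularity.

    ``bits[i]`` refers to channel ``provenance[i]`` (channel granularity) or
    feature column ``provenance[i]`` with identity ``(channel, freq)``
    (feature granularity), so masks from successive levels can be compared
    bit for bit.
    """

    bits: np.ndarray
    granularity: str  # "channel" | "feature"
    provenance: list

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.granularity not in ("channel", "feature"):
            raise ValueError("granularity must be 'channel' or 'feature'")
        if len(self.provenance) != len(self.bits):
            raise ValueError("provenance must describe every bit")
        if not self.bits.any():
            raise ValueError("a selection mask must have at least one bit set")

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    @property
    def selected(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    @property
    def selected_provenance(self) -> list:
        return [self.provenance[i] for i in self.selected]

    def feature_column_mask(self, features: FeatureMatrix) -> np.ndarray:
        """Expand to a boolean mask over the feature matrix's columns."""
        out = np.zeros(features.n_features, dtype=bool)
        if self.granularity == "feature":
            out[self.selected] = True
        else:
            for ch in self.selected_provenance:
                out[features.channel_columns(ch)] = True
        return out

    def is_subset_of(self, other: "SelectionMask") -> bool:
        return bool(np.all(other.bits[self.bits.astype(bool)] == 1))

    def to_text(self) -> str:
        lines = [f"# granularity: {self.granularity}"]
        for bit, prov in zip(self.bits, self.provenance):
            lines.append(f"{int(bit)}\t{prov}")
        return "\n".join(lines) + "\n"


@dataclass
class LevelResult:
    """One multilevel stage: its mask, fitness trace and held-out report."""

    level: int
    phase: str  # "channel" | "feature"
    mask: SelectionMask
    fitness: float
    trace: np.ndarray
    n_evaluations: int
    popcount_trace: np.ndarray = None
    evaluation: EvaluationReport | None = None

    @property
    def n_selected(self) -> int:
        return self.mask.n_selected


def stratified_split(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded per-class split; returns (kept_idx, held_out_idx), both sorted."""
    labels = np.asarray(labels)
    held = []
    for cls in (-1, 1):
        idx = np.flatnonzero(labels == cls)
        n_hold = max(int(round(fraction * idx.size)), 2)
        held.append(rng.choice(idx, size=min(n_hold, idx.size - 2), replace=False))
    held_idx = np.sort(np.concatenate(held))
    kept = np.setdiff1d(np.arange(labels.size), held_idx)
    return kept, held_idx


def _evaluate_mask(
    mask: SelectionMask,
    train: FeatureMatrix,
    eval_features: FeatureMatrix,
    *,
    standardize: bool,
    target_coding: str,
) -> EvaluationReport:
    cols = mask.feature_column_mask(train)
    res = BayesianDiscriminant(
        train.labels,
        train.values[:, cols],
        standardize=standardize,
        target_coding=target_coding,
    ).fit()
    pred = res.classify(eval_features.values[:, cols])
    return confusion(eval_features.labels, pred)


def run_multilevel(
    features: FeatureMatrix,
    granularity: str,
    cfg: PSOConfig,
    max_level: int,
    *,
    eval_features: FeatureMatrix | None = None,
    val_fraction: float = 0.25,
    fitness_on_eval: bool = False,
    use_scores: bool = False,
    standardize: bool = True,
    target_coding: str = "label",
    initial_coords: np.ndarray | None = None,
    phase_id: int = 0,
) -> list[LevelResult]:
    """Repeated PSO levels, each restricted to the previous level's selection.

    Fitness for each candidate mask is the inverse squared error of the
    discriminant on a validation set: by default a seeded stratified
    ``val_fraction`` split carved out of ``features``; with
    ``fitness_on_eval=True`` the supplied ``eval_features`` are used
    directly (this leaks evaluation labels into selection and exists only to
    reproduce protocols that score fitness on the test set).

    Every level runs an independently seeded fresh swarm; per-level seeds
    derive from ``cfg.seed`` and the level index.  If ``eval_features`` is
    given, each level's mask is additionally refitted on the full training
    features and scored on it for reporting.
    """
    if max_level < 1:
        raise ValueError("max_level must be at least 1")
    if granularity not in ("channel", "feature"):
        raise ValueError("granularity must be 'channel' or 'feature'")
    if fitness_on_eval and eval_features is None:
        raise ValueError("fitness_on_eval needs explicit eval_features")

    master = 0 if cfg.seed is None else int(cfg.seed)

    if fitness_on_eval:
        fit_train, fit_val = features, eval_features
    else:
        split_rng = np.random.default_rng([master, phase_id, 777])
        kept, held = stratified_split(features.labels, val_fraction, split_rng)
        fit_train = features.subset_trials(kept)
        fit_val = features.subset_trials(held)

    if granularity == "channel":
        global_ids = list(features.channels)
        col_blocks = {c: features.channel_columns(c) for c in global_ids}
    else:
        global_ids = list(range(features.n_features))
    id_pos = {g: i for i, g in enumerate(global_ids)}

    if initial_coords is None:
        coords = np.asarray(global_ids)
    else:
        coords = np.asarray(initial_coords)
        if coords.size == 0:
            raise ValueError("initial coordinate set must be nonempty")

    blda_kwargs = dict(standardize=standardize, target_coding=target_coding)
    results: list[LevelResult] = []
    prev_count = None
    for level in range(1, max_level + 1):
        d = coords.size

        def fitness(bits: np.ndarray) -> float:
            sel = coords[bits]
            if granularity == "channel":
                cols = np.zeros(features.n_features, dtype=bool)
                for ch in sel:
                    cols[col_blocks[ch]] = True
            else:
                cols = np.zeros(features.n_features, dtype=bool)
                cols[sel] = True
            return mse_inverse_fitness(
                cols, fit_train, fit_val, use_scores=use_scores, **blda_kwargs
            )

        rng = np.random.default_rng([master, phase_id, level])
        pso: PSOResult = run_pso(d, cfg, fitness, rng=rng, perfect_fitness=1.0 / 1e-12)
        sel = coords[pso.mask.astype(bool)]
        if sel.size == 0:
            raise RuntimeError(
                "PSO returned an empty selection; every candidate mask was degenerate"
            )

        bits = np.zeros(len(global_ids), dtype=np.uint8)
        bits[[id_pos[g] for g in sel]] = 1
        provenance = (
            global_ids if granularity == "channel" else [features.columns[j] for j in global_ids]
        )
        mask = SelectionMask(bits, granularity, list(provenance))

        evaluation = None
        if eval_features is not None:
            evaluation = _evaluate_mask(
                mask, features, eval_features, **blda_kwargs
            )
        results.append(
            LevelResult(
                level=level,
                phase=granularity,
                mask=mask,
                fitness=pso.fitness,
                trace=pso.trace,
                n_evaluations=pso.n_evaluations,
                popcount_trace=pso.popcount_trace,
                evaluation=evaluation,
            )
        )
        if prev_count is not None and sel.size == prev_count:
            break  # selected count unchanged between consecutive levels
        prev_count = sel.size
        coords = sel
    return results


def channel_selection(
    features: FeatureMatrix, cfg: PSOConfig, max_level: int, **kwargs
) -> list[LevelResult]:
    """Multilevel PSO over channels; a set bit activates the channel's block."""
    return run_multilevel(features, "channel", cfg, max_level, **kwargs)


def feature_selection(
    features: FeatureMatrix, cfg: PSOConfig, max_level: int, **kwargs
) -> list[LevelResult]:
    """Multilevel PSO over individual feature columns."""
    return run_multilevel(features, "feature", cfg, max_level, **kwargs)


def channel_then_feature(
    features: FeatureMatrix,
    cfg_ch: PSOConfig,
    cfg_ft: PSOConfig,
    max_level_ch: int,
    max_level_ft: int,
    **kwargs,
) -> tuple[list[LevelResult], list[LevelResult]]:
    """Channel phase to termination, then feature levels on the survivors."""
    ch_results = run_multilevel(
        features, "channel", cfg_ch, max_level_ch, phase_id=0, **kwargs
    )
    surviving = ch_results[-1].mask.selected_provenance
    cols = np.concatenate([features.channel_columns(c) for c in surviving])
    ft_results = run_multilevel(
        features,
        "feature",
        cfg_ft,
        max_level_ft,
        initial_coords=np.sort(cols),
        phase_id=1,
        **kwargs,
    )
    return ch_results, ft_results
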
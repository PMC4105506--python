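"""Repeated cross-validation, the univariate region scan, and coupled
backward-elimination / forward-addition region ranking.

All models being compared at a given point are evaluated on identical
fold partitions (a shared, seeded fold stream, hashed for audit), with
normalization fitted on the training folds only. The selection criterion
is the median validation C-index; elimination ties are broken by the
fixed canonical region order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ann import AnnConfig, knockout_importance, predict_index, train_ensemble
from .bsi import REGIONS
from .cohort import Cohort
from .concordance import ConcordanceUndefined, c_index
from .cox import fit_cox, predict_risk


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: model family plus named covariate subset."""

    kind: str  # "cox" | "ann"
    covariates: tuple[str, ...]
    ann: AnnConfig | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("cox", "ann"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if not self.covariates:
            raise ValueError("covariate list must be non-empty")


@dataclass
class CvResult:
    """Validation C-indices from repeated k-fold cross-validation."""

    spec: ModelSpec
    entries: np.ndarray  # (repeats, folds)
    partition_hash: str
    notes: list[str] = field(default_factory=list)

    @property
    def median(self) -> float:
        return float(np.median(self.entries))

    @property
    def mean(self) -> float:
        return float(np.mean(self.entries))

    @property
    def sd(self) -> float:
        return float(np.std(self.entries, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        reps, folds = self.entries.shape
        return pd.DataFrame(
            {
                "model": ["+".join(self.spec.covariates)] * (reps * folds),
                "kind": [self.spec.kind] * (reps * folds),
                "repeat": np.repeat(np.arange(reps), folds),
                "fold": np.tile(np.arange(folds), reps),
                "c_index": self.entries.ravel(),
            }
        )


@dataclass
class EliminationStep:
    removed: str
    backward_covariates: tuple[str, ...]  # model after removal (includes age)
    forward_covariates: tuple[str, ...]  # age + regions removed so far
    backward_result: CvResult
    forward_result: CvResult | None = None


@dataclass
class EliminationTrace:
    """Backward-elimination steps with the complementary forward models."""

    initial_result: CvResult  # all regions + age
    steps: list[EliminationStep]
    model_kind: str

    @property
    def removal_order(self) -> list[str]:
        return [s.removed for s in self.steps]

    def validate(self) -> None:
        """Assert the structural invariants of the coupled procedure."""
        all_regions = set(REGIONS)
        for k, step in enumerate(self.steps):
            back = set(step.backward_covariates)
            fwd = set(step.forward_covariates)
            assert "age" in back and "age" in fwd, "age must stay in both directions"
            union = (back | fwd) - {"age"}
            inter = (back & fwd) - {"age"}
            assert union == all_regions, f"step {k}: region sets do not cover all regions"
            assert not inter, f"step {k}: backward/forward region overlap {inter}"
        assert set(self.steps[-1].backward_covariates) == {"age"}
        assert set(self.steps[-1].forward_covariates) == {"age", *REGIONS}


def event_stratified_folds(
    event: np.ndarray, folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Random fold labels balancing events and censorings across folds."""
    n = event.shape[0]
    labels = np.empty(n, dtype=int)
    for grp in (np.nonzero(event == 1)[0], np.nonzero(event == 0)[0]):
        perm = rng.permutation(grp)
        labels[perm] = np.arange(perm.size) % folds
    return labels


class FoldStream:
    """Seeded, model-independent sequence of fold partitions.

    Every model evaluated against the same stream sees identical
    partitions, making paired comparisons fair; the partition hash is
    recorded on each :class:`CvResult`.
    """

    def __init__(self, event: np.ndarray, repeats: int, folds: int, seed: int):
        rng = np.random.default_rng(seed)
        self.folds = folds
        self.repeats = repeats
        self.partitions = [event_stratified_folds(event, folds, rng) for _ in range(repeats)]
        digest = hashlib.sha1()
        for p in self.partitions:
            digest.update(p.astype(np.int64).tobytes())
        self.partition_hash = digest.hexdigest()[:16]


def _fit_predict(
    spec: ModelSpec,
    X_train: np.ndarray,
    t_train: np.ndarray,
    e_train: np.ndarray,
    X_val: np.ndarray,
    seed: int,
) -> np.ndarray:
    if spec.kind == "cox":
        fit = fit_cox(X_train, t_train, e_train, names=spec.covariates)
        return predict_risk(fit, X_val)
    config = spec.ann or AnnConfig()
    model = train_ensemble(X_train, t_train, e_train, replace(config, seed=seed))
    return predict_index(model, X_val)


def repeated_cv(
    spec: ModelSpec,
    cohort: Cohort,
    repeats: int = 20,
    folds: int = 3,
    seed: int = 0,
    fold_stream: FoldStream | None = None,
) -> CvResult:
    """Repeated k-fold cross-validation of one model specification.

    Defaults to the 20x3 scheme. Normalization is fitted per training
    split inside the model fit; the validation C-index is recorded per
    (repeat, fold). A fold without usable pairs voids and redraws the
    repeat (noted on the result).
    """
    stream = fold_stream or FoldStream(cohort.event, repeats, folds, seed)
    X = cohort.covariate_matrix(list(spec.covariates))
    notes: list[str] = []
    entries = np.empty((stream.repeats, stream.folds))
    redraw_rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0FFEE)))
    member_seeds = np.random.SeedSequence(seed).generate_state(stream.repeats * stream.folds)
    for r, labels in enumerate(stream.partitions):
        for attempt in range(5):
            try:
                for f in range(stream.folds):
                    val = labels == f
                    train = ~val
                    risk = _fit_predict(
                        spec,
                        X[train],
                        cohort.time[train],
                        cohort.event[train],
                        X[val],
                        int(member_seeds[r * stream.folds + f] % (2**31)),
                    )
                    entries[r, f] = c_index(risk, cohort.time[val], cohort.event[val]).value
                break
            except ConcordanceUndefined:
                labels = event_stratified_folds(cohort.event, stream.folds, redraw_rng)
                notes.append(f"repeat {r}: fold without usable pairs, partition redrawn")
        else:
            raise ConcordanceUndefined(f"repeat {r}: no usable validation pairs after redraws")
    return CvResult(
        spec=spec, entries=entries, partition_hash=stream.partition_hash, notes=notes
    )


def univariate_region_scan(
    cohort: Cohort,
    model_kind: str = "cox",
    repeats: int = 20,
    folds: int = 3,
    seed: int = 0,
    ann_config: AnnConfig | None = None,
) -> dict[str, CvResult]:
    """One model per region (region + age), plus the age + total-BSI model.

    All thirteen models share a single fold stream so their validation
    C-indices are paired.
    """
    stream = FoldStream(cohort.event, repeats, folds, seed)
    results: dict[str, CvResult] = {}
    for name in (*REGIONS, "total_bsi"):
        spec = ModelSpec(kind=model_kind, covariates=("age", name), ann=ann_config)
        results[name] = repeated_cv(spec, cohort, seed=seed, fold_stream=stream)
    return results


def _rank_removals_ann(
    cohort: Cohort,
    current: tuple[str, ...],
    ann_config: AnnConfig,
    seed: int,
) -> str:
    """ANN removal ranking for one step: knockout importance, no retraining.

    One ensemble is trained on the step's full covariate set; the region
    with the smallest knockout drop (in-sample) is the removal candidate.
    Ties break by canonical region order (the order of ``current``).
    """
    covs = ("age", *current)
    X = cohort.covariate_matrix(list(covs))
    model = train_ensemble(X, cohort.time, cohort.event, replace(ann_config, seed=seed))
    drops = knockout_importance(model, X, cohort.time, cohort.event)
    region_drops = drops[1:]  # skip age
    return current[int(np.argmin(region_drops))]


def backward_elimination(
    cohort: Cohort,
    model_kind: str = "cox",
    repeats: int = 20,
    folds: int = 3,
    seed: int = 0,
    ann_config: AnnConfig | None = None,
) -> EliminationTrace:
    """Iteratively remove the least-useful region until only age remains.

    For Cox, every candidate reduced model is refitted and scored by
    repeated CV on a shared fold stream; the region whose removal leaves
    the highest median validation C (smallest drop) goes. For ANN,
    ranking within a step uses knockout importance on a single ensemble
    (no retraining), and the chosen reduced model is then refitted by
    repeated CV for the step's reported performance.
    """
    ann_config = ann_config or AnnConfig()
    stream = FoldStream(cohort.event, repeats, folds, seed)

    def cv(covs: tuple[str, ...]) -> CvResult:
        spec = ModelSpec(kind=model_kind, covariates=covs, ann=ann_config)
        return repeated_cv(spec, cohort, seed=seed, fold_stream=stream)

    current: tuple[str, ...] = tuple(REGIONS)
    initial = cv(("age", *current))
    steps: list[EliminationStep] = []
    removed_so_far: list[str] = []
    step_seed = np.random.SeedSequence((seed, 0xAB1E)).generate_state(len(REGIONS))
    for k in range(len(REGIONS)):
        if model_kind == "cox":
            best_region, best_result, best_median = None, None, -np.inf
            for region in current:  # canonical order = deterministic tie-break
                reduced = tuple(r for r in current if r != region)
                res = cv(("age", *reduced))
                if res.median > best_median:
                    best_region, best_result, best_median = region, res, res.median
            removal, result = best_region, best_result
        else:
            removal = _rank_removals_ann(
                cohort, current, ann_config, int(step_seed[k] % (2**31))
            )
            result = cv(("age", *tuple(r for r in current if r != removal)))
        current = tuple(r for r in current if r != removal)
        removed_so_far.append(removal)
        steps.append(
            EliminationStep(
                removed=removal,
                backward_covariates=("age", *current),
                forward_covariates=("age", *removed_so_far),
                backward_result=result,
            )
        )
    trace = EliminationTrace(initial_result=initial, steps=steps, model_kind=model_kind)
    trace.validate()
    return trace


def forward_addition(
    trace: EliminationTrace,
    cohort: Cohort,
    repeats: int = 20,
    folds: int = 3,
    seed: int = 0,
    ann_config: AnnConfig | None = None,
) -> EliminationTrace:
    """Score the forward models: age plus regions in backward-removal order.

    Fills ``forward_result`` on every step of ``trace`` using the same
    seeded fold stream geometry as the backward pass.
    """
    stream = FoldStream(cohort.event, repeats, folds, seed)
    for step in trace.steps:
        spec = ModelSpec(
            kind=trace.model_kind, covariates=step.forward_covariates, ann=ann_config
        )
        step.forward_result = repeated_cv(spec, cohort, seed=seed, fold_stream=stream)
    trace.validate()
    return trace


def summarize_trace(trace: EliminationTrace) -> pd.DataFrame:
    """Tidy per-step summary (median/mean/sd for both directions).

    Step 0 is the starting full backward model; the best backward subset
    can be read off as the step with the highest backward median.
    """
    rows = [
        {
            "step": 0,
            "removed": "",
            "direction": "backward",
            "covariates": "+".join(trace.initial_result.spec.covariates),
            "n_regions": len(REGIONS),
            "median": trace.initial_result.median,
            "mean": trace.initial_result.mean,
            "sd": trace.initial_result.sd,
        }
    ]
    for k, step in enumerate(trace.steps, start=1):
        rows.append(
            {
                "step": k,
                "removed": step.removed,
                "direction": "backward",
                "covariates": "+".join(step.backward_covariates),
                "n_regions": len(step.backward_covariates) - 1,
                "median": step.backward_result.median,
                "mean": step.backward_result.mean,
                "sd": step.backward_result.sd,
            }
        )
        if step.forward_result is not None:
            rows.append(
                {
                    "step": k,
                    "removed": step.removed,
                    "direction": "forward",
                    "covariates": "+".join(step.forward_covariates),
                    "n_regions": len(step.forward_covariates) - 1,
                    "median": step.forward_result.median,
                    "mean": step.forward_result.mean,
                    "sd": step.forward_result.sd,
                }
            )
    return pd.DataFrame(rows)
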
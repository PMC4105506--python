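"""Non-linearity screen: univariate linear performance versus multivariate
knockout importance.

Each region is placed on two axes: its validation C-index from a Cox model
using only that region and age (how useful it is alone, linearly), and the
drop in validation C-index when its input is knocked out of an ANN
ensemble trained on all regions plus age (how much a non-linear
multivariate model relies on it). A region that is useless alone but
heavily relied on jointly — the upper-left quadrant — is a candidate for a
non-linear interaction. On a purely additive cohort that quadrant stays
empty.

Cross-validation is not used here; instead the whole procedure is repeated
(default 10 times) on fresh random train/evaluation splits, and means and
standard deviations over the repeats are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ann import AnnConfig, knockout_importance, train_ensemble
from .bsi import REGIONS
from .cohort import Cohort
from .concordance import ConcordanceUndefined, c_index
from .cox import fit_cox, predict_risk


@dataclass
class ScreenResult:
    """Per-region (univariate C, knockout drop) with dispersion and quadrant."""

    univariate_c: np.ndarray  # (repeats, 12)
    knockout_drop: np.ndarray  # (repeats, 12)
    seed: int
    boundaries: tuple[float, float] | None = None  # (vertical=C, horizontal=drop)
    quadrants: dict[str, str] | None = None

    @property
    def univariate_mean(self) -> np.ndarray:
        return self.univariate_c.mean(axis=0)

    @property
    def univariate_sd(self) -> np.ndarray:
        return self.univariate_c.std(axis=0, ddof=1)

    @property
    def drop_mean(self) -> np.ndarray:
        return self.knockout_drop.mean(axis=0)

    @property
    def drop_sd(self) -> np.ndarray:
        return self.knockout_drop.std(axis=0, ddof=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "region": REGIONS,
                "univariate_c_mean": self.univariate_mean,
                "univariate_c_sd": self.univariate_sd,
                "drop_mean": self.drop_mean,
                "drop_sd": self.drop_sd,
            }
        )
        if self.quadrants is not None:
            df["quadrant"] = [self.quadrants[r] for r in REGIONS]
        return df


def screen(
    cohort: Cohort,
    repeats: int = 10,
    seed: int = 0,
    ann_config: AnnConfig | None = None,
    train_fraction: float = 2.0 / 3.0,
) -> ScreenResult:
    """Run the screen: per repeat, one random train/evaluation split.

    The univariate axis comes from Cox (region + age) evaluated on the
    held-out third; the importance axis from knockout on an ANN ensemble
    trained on all regions + age, also evaluated held-out. Deterministic
    given ``seed``.
    """
    ann_config = ann_config or AnnConfig()
    rng = np.random.default_rng(seed)
    n = cohort.n
    n_train = int(round(train_fraction * n))
    uni = np.empty((repeats, len(REGIONS)))
    drops = np.empty((repeats, len(REGIONS)))
    all_covs = ["age", *REGIONS]
    X_all = cohort.covariate_matrix(all_covs)
    member_seeds = np.random.SeedSequence(seed).generate_state(repeats)
    for r in range(repeats):
        perm = rng.permutation(n)
        tr, ev = perm[:n_train], perm[n_train:]
        t_tr, e_tr = cohort.time[tr], cohort.event[tr]
        t_ev, e_ev = cohort.time[ev], cohort.event[ev]
        for j, region in enumerate(REGIONS):
            X = cohort.covariate_matrix(["age", region])
            fit = fit_cox(X[tr], t_tr, e_tr)
            try:
                uni[r, j] = c_index(predict_risk(fit, X[ev]), t_ev, e_ev).value
            except ConcordanceUndefined:
                uni[r, j] = 0.5
        model = train_ensemble(
            X_all[tr], t_tr, e_tr, replace(ann_config, seed=int(member_seeds[r] % (2**31)))
        )
        drops[r] = knockout_importance(model, X_all[ev], t_ev, e_ev)[1:]  # skip age
    return ScreenResult(univariate_c=uni, knockout_drop=drops, seed=seed)


def classify_quadrants(
    result: ScreenResult,
    boundaries: tuple[float, float] | None = None,
) -> ScreenResult:
    """Label each region's quadrant.

    Boundaries default to the midpoint of each axis's observed range —
    the "halves" of the plot. (A per-axis median is unusable as a default:
    it forces half the regions above the importance boundary even when
    their knockout drops are pure noise around zero, so the upper-left
    could never be empty.) Points exactly on a boundary are assigned to
    the lower / left side, so a fully degenerate screen labels everything
    lower-left. Boundaries are stored on the result so labels are
    auditable, and can be overridden.
    """
    if result.univariate_mean.shape[0] < 2:
        raise ValueError("need at least two regions to classify")
    if boundaries is None:
        uni, drop = result.univariate_mean, result.drop_mean
        boundaries = (
            float((uni.min() + uni.max()) / 2.0),
            float((drop.min() + drop.max()) / 2.0),
        )
    vx, hy = boundaries
    quadrants = {}
    for j, region in enumerate(REGIONS):
        right = result.univariate_mean[j] > vx
        upper = result.drop_mean[j] > hy
        quadrants[region] = ("upper" if upper else "lower") + "-" + ("right" if right else "left")
    result.boundaries = boundaries
    result.quadrants = quadrants
    return result
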
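"""Quartile/contour distribution analysis of word PC scores.

Per-participant word PC scores are binned into four *fixed* score ranges
([-4,-2], (-2,0], (0,2], (2,4] -- fixed edges, not data quantiles), counted
per quartile and mapped as bivariate 4x4 proportion grids.  Group mean maps
minus the control mean map give difference maps, tested cellwise with Welch
two-tailed t-tests on participant-level proportions (uncorrected, as is the
convention for these maps; treat cell p-values descriptively).  A mixed
(group x quartile) repeated-measures ANOVA tests distributional shifts.
Scores outside [-4, 4] are clipped into the end bins and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Fixed quartile edges on the PC-score scale.
QUARTILE_EDGES = (-4.0, -2.0, 0.0, 2.0, 4.0)
QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


def _bin_indices(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    n_out = int(np.sum((scores < QUARTILE_EDGES[0]) | (scores > QUARTILE_EDGES[-1])))
    if n_out:
        logger.info("clipping %d scores outside [%g, %g] into end bins", n_out, QUARTILE_EDGES[0], QUARTILE_EDGES[-1])
    clipped = np.clip(scores, QUARTILE_EDGES[0], QUARTILE_EDGES[-1])
    # bins: [-4,-2], (-2,0], (0,2], (2,4]  (right-closed; the lowest closed both sides)
    idx = np.searchsorted(QUARTILE_EDGES[1:-1], clipped, side="left")
    return idx


def quartile_counts(word_scores) -> np.ndarray:
    """Counts of word scores per fixed quartile bin; sums to len(scores)."""
    scores = np.asarray(word_scores, dtype=float)
    if scores.size == 0:
        return np.zeros(4, dtype=int)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    return np.bincount(_bin_indices(scores), minlength=4)


@dataclass
class DistributionMap:
    """Bivariate 4x4 proportion grid of word tokens for one participant/group."""

    axes: tuple[str, str]  # (x component, y component)
    grid: np.ndarray  # 4x4, grid[i, j] = proportion in x-bin i, y-bin j
    n_words: int

    def __post_init__(self):
        assert self.grid.shape == (4, 4)
        if self.n_words > 0:
            assert abs(self.grid.sum() - 1.0) < 1e-10


def proportion_map(x_scores, y_scores, axes: tuple[str, str] = ("PC1", "PC2")) -> DistributionMap:
    """Joint proportion of a participant's words in each 2-D quartile cell."""
    x = np.asarray(x_scores, dtype=float)
    y = np.asarray(y_scores, dtype=float)
    if x.shape != y.shape:
        raise ValueError("score vectors must have equal length")
    if x.size == 0:
        raise ValueError("no words: proportion map undefined")
    grid = np.zeros((4, 4))
    np.add.at(grid, (_bin_indices(x), _bin_indices(y)), 1.0)
    return DistributionMap(axes=axes, grid=grid / x.size, n_words=int(x.size))


def group_mean_map(maps: list[DistributionMap]) -> DistributionMap:
    """Unweighted mean of participant maps (each participant counts equally)."""
    if not maps:
        raise ValueError("no maps to average")
    axes = maps[0].axes
    if any(m.axes != axes for m in maps):
        raise ValueError("maps must share axes")
    grid = np.mean([m.grid for m in maps], axis=0)
    return DistributionMap(axes=axes, grid=grid, n_words=sum(m.n_words for m in maps))


@dataclass
class DifferenceMap:
    """Patient-group mean map minus control mean map, with cellwise tests."""

    axes: tuple[str, str]
    grid: np.ndarray  # 4x4 mean difference; sums to 0
    t: np.ndarray  # 4x4 Welch t statistics (NaN where undefined)
    p: np.ndarray  # 4x4 two-tailed p-values (NaN where undefined)


def difference_map(
    group_maps: list[DistributionMap], control_maps: list[DistributionMap]
) -> DifferenceMap:
    """Welch two-tailed t-test per cell on participant-level proportions.

    Cells with zero variance in both groups get NaN t/p (flagged undefined);
    if the means are also equal the difference there is zero.
    """
    if len(group_maps) < 2 or len(control_maps) < 2:
        raise ValueError("both groups need at least 2 participants")
    axes = group_maps[0].axes
    G = np.stack([m.grid for m in group_maps])  # n_g x 4 x 4
    C = np.stack([m.grid for m in control_maps])
    diff = G.mean(axis=0) - C.mean(axis=0)
    t = np.full((4, 4), np.nan)
    p = np.full((4, 4), np.nan)
    for i in range(4):
        for j in range(4):
            g, c = G[:, i, j], C[:, i, j]
            if g.std(ddof=1) == 0 and c.std(ddof=1) == 0:
                continue  # undefined: flagged as NaN
            res = stats.ttest_ind(g, c, equal_var=False)
            t[i, j], p[i, j] = res.statistic, res.pvalue
    return DifferenceMap(axes=axes, grid=diff, t=t, p=p)


def quartile_count_table(
    scores_by_participant: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Participants x 4 quartile-count table for one PC."""
    rows = {pid: quartile_counts(s) for pid, s in scores_by_participant.items()}
    df = pd.DataFrame(rows, index=QUARTILE_LABELS).T
    df.index.name = "participant_id"
    return df


def quartile_rm_anova(count_table: pd.DataFrame, groups: pd.Series) -> dict:
    """Mixed ANOVA: quartile within-subject, group between-subject.

    Returns F/p for the group, quartile and interaction effects plus Tukey
    HSD post hoc on the quartile factor.
    """
    import pingouin as pg
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if list(count_table.columns) != list(QUARTILE_LABELS):
        raise ValueError(f"count table columns must be {QUARTILE_LABELS}")
    if count_table.isna().any().any():
        raise ValueError("count table must be complete")
    groups = pd.Series(groups, index=count_table.index).astype(str)
    if (groups.value_counts() < 2).any():
        raise ValueError("every group needs at least 2 participants")
    if (count_table.nunique(axis=0) == 1).all():
        # every participant identical: no variance anywhere, all effects null
        return {
            "F_group": 0.0, "p_group": 1.0,
            "F_quartile": 0.0, "p_quartile": 1.0,
            "F_interaction": 0.0, "p_interaction": 1.0,
            "anova_table": None, "tukey_quartile": None,
        }
    count_table = count_table.rename_axis("participant_id")
    long = count_table.reset_index().melt(
        id_vars="participant_id", var_name="quartile", value_name="count"
    )
    long["group"] = long["participant_id"].map(groups)
    long["count"] = long["count"].astype(float)
    aov = pg.mixed_anova(
        data=long, dv="count", within="quartile", subject="participant_id", between="group"
    )
    aov = aov.set_index("Source")
    tukey = pairwise_tukeyhsd(long["count"], long["quartile"])
    tukey_df = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    return {
        "F_group": float(aov.loc["group", "F"]),
        "p_group": float(aov.loc["group", "p_unc"]),
        "F_quartile": float(aov.loc["quartile", "F"]),
        "p_quartile": float(aov.loc["quartile", "p_unc"]),
        "F_interaction": float(aov.loc["Interaction", "F"]),
        "p_interaction": float(aov.loc["Interaction", "p_unc"]),
        "anova_table": aov.reset_index(),
        "tukey_quartile": tukey_df,
    }
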
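"""Two-condition statistics on network metrics, per electrode and window.

Per-trial metric values for the two conditions are compared with a
two-sided Wilcoxon rank-sum (Mann–Whitney) test, independently for every
(electrode, metric, window, link count K).  A difference is called
significant when it meets both of the procedure's criteria:

1. the p-value is below the Bonferroni-corrected level ``alpha / 20``
   (20 electrodes tested simultaneously), and
2. the same electrode/metric/window passes criterion 1 at no fewer than
   ``min_densities`` distinct values of K (robustness to the arbitrary
   choice of link density).

Small samples (pooled n ≤ 12) use exact enumeration of the rank-sum
distribution with midranks for ties; larger samples use the tie-corrected,
continuity-corrected normal approximation.  No further correction is
applied across windows or densities — the family-wise guarantee is over the
20 electrodes within one (metric, window) family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .io import TrialSet
from .netbuild import FunctionalNetwork

__all__ = [
    "ComparisonConfig",
    "SignificanceMap",
    "wilcoxon_rank",
    "rank_sum_p",
    "compare_conditions",
    "first_neighbors",
    "baseline_check",
]

LOCAL_METRICS = ("degree", "clustering", "betweenness")


@dataclass
class ComparisonConfig:
    """Dual significance criterion parameters.

    ``density_grid`` is the set of link counts K at which every comparison
    is repeated (seven densities spanning the 30/50/70 used for the global
    time courses); ``alpha_fw / n_electrodes`` is the Bonferroni per-test
    level; ``min_densities`` is the number of K values at which a local
    difference must hold to count as robust.
    """

    density_grid: tuple[int, ...] = (20, 30, 40, 50, 60, 70, 80)
    alpha_fw: float = 0.05
    n_electrodes: int = 20
    min_densities: int = 3

    def __post_init__(self) -> None:
        self.density_grid = tuple(int(k) for k in self.density_grid)
        if not 0 < self.alpha_fw < 1:
            raise ValueError("alpha_fw must lie in (0, 1)")
        if self.min_densities > len(self.density_grid):
            raise ValueError("min_densities exceeds the density grid size")

    @property
    def bonferroni_alpha(self) -> float:
        return self.alpha_fw / self.n_electrodes


@dataclass
class SignificanceMap:
    """Per-test p-values and flags for local and global comparisons.

    ``local``: one row per (electrode, metric, window_start_ms, k) with
    columns p, bonferroni_pass, robust_pass, direction.  ``global_``: one
    row per (metric, window_start_ms, k), tested at the uncorrected level.
    """

    local: pd.DataFrame
    global_: pd.DataFrame = field(default_factory=pd.DataFrame)
    condition_names: tuple[str, str] = ("A", "B")

    def robust_findings(self) -> pd.DataFrame:
        """Contiguous robust window spans per (electrode, metric)."""
        sig = self.local[self.local["robust_pass"]]
        rows = []
        for (el, metric), grp in sig.groupby(["electrode", "metric"]):
            wins = np.sort(grp["window_start_ms"].unique())
            rows.append(
                {
                    "electrode": el,
                    "metric": metric,
                    "window_start_ms_first": wins[0],
                    "window_start_ms_last": wins[-1],
                    "n_windows": len(wins),
                    "direction": grp["direction"].mode().iloc[0],
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "electrode",
                "metric",
                "window_start_ms_first",
                "window_start_ms_last",
                "n_windows",
                "direction",
            ],
        )


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

EXACT_MAX_N = 12


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration with midranks."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled, method="average")
    n_tot = pooled.size
    n_a = a.size
    mu = n_a * (n_tot + 1) / 2.0
    w_obs = ranks[:n_a].sum()
    dev_obs = abs(w_obs - mu)
    hits = 0
    total = 0
    for subset in combinations(range(n_tot), n_a):
        w = ranks[list(subset)].sum()
        if abs(w - mu) >= dev_obs - 1e-9:
            hits += 1
        total += 1
    return hits / total


def rank_sum_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-sided rank-sum p (normal approximation, tie-corrected).

    ``a`` and ``b`` have samples on the last axis; leading axes broadcast.
    Degenerate strata where every pooled value is identical get p = 1.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    pooled_sd = np.concatenate([a, b], axis=-1).std(axis=-1)
    degenerate = pooled_sd == 0
    if degenerate.all():
        return np.ones(a.shape[:-1]).squeeze()
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", axis=-1)
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(degenerate, 1.0, p)
    return p.squeeze() if p.ndim else float(p)


def wilcoxon_rank(a, b) -> float:
    """Two-sided rank-sum p-value for two independent samples.

    Exact enumeration of all arrangements of the pooled midranks when the
    pooled size is ≤ 12; tie-corrected continuity-corrected normal
    approximation otherwise.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.concatenate([a, b]).std() == 0:
        return 1.0
    if a.size + b.size <= EXACT_MAX_N:
        return _exact_rank_sum_p(a, b)
    return float(rank_sum_p(a, b))


# ---------------------------------------------------------------------------
# condition comparison
# ---------------------------------------------------------------------------


class AlignmentError(ValueError):
    """The two conditions do not cover the same windows / density grid."""


def _pivot(df: pd.DataFrame, value: str) -> tuple[pd.DataFrame, np.ndarray]:
    """(k, window, node) × trial value matrix with a stable row index."""
    wide = df.pivot_table(
        index=["k", "window_start_ms", "node"],
        columns="trial",
        values=value,
        sort=True,
    )
    return wide, wide.to_numpy()


def compare_conditions(
    metrics_a: pd.DataFrame,
    metrics_b: pd.DataFrame,
    cfg: ComparisonConfig | None = None,
    global_a: pd.DataFrame | None = None,
    global_b: pd.DataFrame | None = None,
    condition_names: tuple[str, str] = ("A", "B"),
) -> SignificanceMap:
    """Test every (electrode, metric, window, K) cell between two conditions.

    ``metrics_a`` / ``metrics_b`` are long-format per-node metric tables
    (columns trial, window_start_ms, k, node, degree, clustering,
    betweenness) for the two conditions.  Optional global tables (columns
    trial, window_start_ms, k, l_avg, c_avg, b_avg) are tested per
    (metric, window, K) at the uncorrected level.
    """
    cfg = cfg or ComparisonConfig()
    if metrics_a.empty or metrics_b.empty:
        raise AlignmentError("empty metric table for at least one condition")
    grid_a = set(map(tuple, metrics_a[["k", "window_start_ms"]].drop_duplicates().to_numpy().tolist()))
    grid_b = set(map(tuple, metrics_b[["k", "window_start_ms"]].drop_duplicates().to_numpy().tolist()))
    if grid_a != grid_b:
        raise AlignmentError(
            "conditions cover different (K, window) grids: "
            f"{sorted(grid_a ^ grid_b)[:5]} ..."
        )
    keep_a = metrics_a[metrics_a["k"].isin(cfg.density_grid)]
    keep_b = metrics_b[metrics_b["k"].isin(cfg.density_grid)]
    if keep_a.empty:
        raise AlignmentError(
            f"no rows at the configured density grid {cfg.density_grid}"
        )
    frames = []
    for metric in LOCAL_METRICS:
        wide_a, arr_a = _pivot(keep_a, metric)
        wide_b, arr_b = _pivot(keep_b, metric)
        if not wide_a.index.equals(wide_b.index):
            raise AlignmentError("conditions cover different electrode sets")
        p = np.atleast_1d(rank_sum_p(arr_a, arr_b))
        med_a = np.median(arr_a, axis=1)
        med_b = np.median(arr_b, axis=1)
        direction = np.where(
            med_a > med_b,
            condition_names[0],
            np.where(med_b > med_a, condition_names[1], "none"),
        )
        sub = wide_a.index.to_frame(index=False)
        sub["electrode"] = sub.pop("node")
        sub["metric"] = metric
        sub["p"] = p
        sub["direction"] = direction
        frames.append(sub)
    local = pd.concat(frames, ignore_index=True)
    local["bonferroni_pass"] = local["p"] < cfg.bonferroni_alpha
    n_pass = local.groupby(["electrode", "metric", "window_start_ms"])[
        "bonferroni_pass"
    ].transform("sum")
    local["robust_pass"] = local["bonferroni_pass"] & (n_pass >= cfg.min_densities)
    local = local[
        ["electrode", "metric", "window_start_ms", "k", "p",
         "bonferroni_pass", "robust_pass", "direction"]
    ].sort_values(["metric", "electrode", "window_start_ms", "k"], ignore_index=True)

    global_df = pd.DataFrame()
    if global_a is not None and global_b is not None:
        g_frames = []
        for metric in ("l_avg", "c_avg", "b_avg"):
            wa = global_a.pivot_table(
                index=["k", "window_start_ms"], columns="trial", values=metric, sort=True
            )
            wb = global_b.pivot_table(
                index=["k", "window_start_ms"], columns="trial", values=metric, sort=True
            )
            if not wa.index.equals(wb.index):
                raise AlignmentError("global tables cover different grids")
            p = np.atleast_1d(rank_sum_p(wa.to_numpy(), wb.to_numpy()))
            sub = wa.index.to_frame(index=False)
            sub["metric"] = metric
            sub["p"] = p
            sub["significant"] = sub["p"] < cfg.alpha_fw
            g_frames.append(sub)
        global_df = pd.concat(g_frames, ignore_index=True)

    return SignificanceMap(local=local, global_=global_df,
                           condition_names=condition_names)


def first_neighbors(
    nets: list[FunctionalNetwork], target: str
) -> pd.DataFrame:
    """Count, per condition, how often each electrode links to ``target``.

    One count per network in which the electrode is a first neighbour
    (directly linked) of the target; counts are bounded by the number of
    networks per condition.
    """
    if not nets:
        raise ValueError("no networks supplied")
    labels = nets[0].labels
    if target not in labels:
        raise KeyError(f"unknown target electrode {target!r}")
    t = labels.index(target)
    conditions = sorted({net.condition for net in nets})
    counts = {c: np.zeros(len(labels), dtype=int) for c in conditions}
    totals = {c: 0 for c in conditions}
    for net in nets:
        if net.labels != labels:
            raise ValueError("all networks must share the montage")
        counts[net.condition] += net.adjacency[t]
        totals[net.condition] += 1
    df = pd.DataFrame({"electrode": labels})
    for c in conditions:
        df[f"count_{c}" if c else "count"] = counts[c]
    df = df[df["electrode"] != target].reset_index(drop=True)
    df.attrs["n_networks"] = totals
    return df


def baseline_check(
    pre_a: TrialSet,
    pre_b: TrialSet,
    cfg: ComparisonConfig | None = None,
    window_config=None,
    condition_names: tuple[str, str] = ("A", "B"),
) -> SignificanceMap:
    """Run the identical pipeline on pre-stimulus epochs of both conditions.

    Under a correct setup the pre-stimulus (fixation) period carries no
    condition information, so the returned map should show no robust passes;
    any systematic finding here flags a confound in the acquisition or the
    analysis configuration.
    """
    from .connectivity import WindowConfig
    from .pipeline import metric_table

    cfg = cfg or ComparisonConfig()
    if pre_a.n_trials == 0 or pre_b.n_trials == 0:
        raise AlignmentError("empty pre-stimulus trial set")
    if pre_a.n_samples != pre_b.n_samples:
        raise AlignmentError("pre-stimulus epochs differ in length")
    wc = window_config or WindowConfig(fs=pre_a.fs)
    local_a, global_a = metric_table(pre_a, wc, cfg.density_grid)
    local_b, global_b = metric_table(pre_b, wc, cfg.density_grid)
    return compare_conditions(
        local_a, local_b, cfg, global_a, global_b, condition_names=condition_names
    )
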
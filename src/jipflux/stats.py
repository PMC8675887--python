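"""Pairwise rank-sum comparisons of JIP parameters with FDR control.

Each JIP parameter is compared between pairs of experimental groups
(population × season × period cells) with two-sided Wilcoxon–Mann–Whitney
rank-sum tests; p-values are then adjusted with the Benjamini–Hochberg
step-up procedure, by default within each parameter's family of contrasts.
Significance stars follow the conventional thresholds on the adjusted p:
``*`` < 0.05, ``**`` < 0.01, ``***`` < 0.001, ``****`` < 0.0001.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: largest pooled sample size for which the exact (enumeration) null is used
EXACT_THRESHOLD = 12

_STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))

GroupKey = tuple[str, str, str]


@dataclass(frozen=True)
class Contrast:
    """One pairwise comparison of a parameter between two factor cells."""

    parameter: str
    group_a: GroupKey
    group_b: GroupKey

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("a contrast needs two distinct groups")


@dataclass(frozen=True)
class GroupTestResult:
    contrast: Contrast
    n_a: int
    n_b: int
    statistic: float
    p_raw: float
    p_adj: float
    stars: str


def significance_stars(p_adj: float) -> str:
    for threshold, code in _STAR_THRESHOLDS:
        if p_adj < threshold:
            return code
    return "ns"


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon–Mann–Whitney rank-sum test.

    Returns the Mann–Whitney U statistic of ``x`` and a two-sided p-value:
    exact (full enumeration of the null) when the pooled size is <= 12 and
    tie-free, otherwise the normal approximation with tie and continuity
    corrections.  Two identical samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # all observations identical: no evidence against the null
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_THRESHOLD and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Sort ascending, multiply p_(i) by m/i, enforce monotonicity from the
    largest rank down, cap at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def default_contrasts(
    metadata: pd.DataFrame,
    parameters: Iterable[str],
) -> list[Contrast]:
    """The default bracket-style contrast family for a factorial design.

    For every parameter: day vs night within each population × season,
    summer vs winter within each population × period, and population vs
    population at matched season × period.  Only cells actually present in
    ``metadata`` (columns population, season, period) are used.
    """
    cells = {
        (str(p), str(s), str(d))
        for p, s, d in metadata[["population", "season", "period"]].itertuples(index=False)
    }
    pairs: list[tuple[GroupKey, GroupKey]] = []
    pops = sorted({c[0] for c in cells})
    seasons = sorted({c[1] for c in cells})
    periods = sorted({c[2] for c in cells})
    for pop, season in itertools.product(pops, seasons):
        for d1, d2 in itertools.combinations(periods, 2):
            if (pop, season, d1) in cells and (pop, season, d2) in cells:
                pairs.append(((pop, season, d1), (pop, season, d2)))
    for pop, period in itertools.product(pops, periods):
        for s1, s2 in itertools.combinations(seasons, 2):
            if (pop, s1, period) in cells and (pop, s2, period) in cells:
                pairs.append(((pop, s1, period), (pop, s2, period)))
    for season, period in itertools.product(seasons, periods):
        for p1, p2 in itertools.combinations(pops, 2):
            if (p1, season, period) in cells and (p2, season, period) in cells:
                pairs.append(((p1, season, period), (p2, season, period)))
    return [Contrast(param, a, b) for param in parameters for a, b in pairs]


def pairwise_parameter_tests(
    params: pd.DataFrame,
    metadata: pd.DataFrame,
    contrasts: Iterable[Contrast] | None = None,
    family: str = "per_parameter",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the pairwise rank-sum tests with BH adjustment.

    Parameters
    ----------
    params : DataFrame
        Per-sample parameter table indexed by sample_id.
    metadata : DataFrame
        Indexed by sample_id with columns population, season, period.
    contrasts : iterable of Contrast, optional
        Defaults to :func:`default_contrasts` over all parameter columns.
    family : {"per_parameter", "global"}
        Scope of the BH adjustment: within each parameter's contrasts
        (default, matching per-panel star displays) or across all tests.

    Returns
    -------
    results : DataFrame
        One row per testable contrast with columns parameter, group_a,
        group_b, n_a, n_b, U, p_raw, p_adj, stars.
    skipped : DataFrame
        Contrasts that could not be resolved to >= 2 samples per side.
    """
    if family not in ("per_parameter", "global"):
        raise ValueError(f"unknown adjustment family {family!r}")
    meta = metadata.loc[metadata.index.intersection(params.index)]
    groups: dict[GroupKey, list[str]] = {}
    for sid, row in meta.iterrows():
        groups.setdefault((str(row["population"]), str(row["season"]), str(row["period"])), []).append(sid)
    if contrasts is None:
        contrasts = default_contrasts(meta.reset_index(), list(params.columns))
    rows: list[dict] = []
    skipped: list[dict] = []
    for c in contrasts:
        ids_a = groups.get(c.group_a, [])
        ids_b = groups.get(c.group_b, [])
        xa = params.loc[ids_a, c.parameter].dropna() if ids_a else pd.Series(dtype=float)
        xb = params.loc[ids_b, c.parameter].dropna() if ids_b else pd.Series(dtype=float)
        if len(xa) < 2 or len(xb) < 2:
            skipped.append({
                "parameter": c.parameter,
                "group_a": "/".join(c.group_a), "group_b": "/".join(c.group_b),
                "reason": f"group sizes {len(xa)}/{len(xb)} below 2",
            })
            continue
        u, p = rank_sum_test(xa.to_numpy(), xb.to_numpy())
        rows.append({
            "parameter": c.parameter,
            "group_a": "/".join(c.group_a), "group_b": "/".join(c.group_b),
            "n_a": len(xa), "n_b": len(xb), "U": u, "p_raw": p,
        })
    results = pd.DataFrame(
        rows, columns=["parameter", "group_a", "group_b", "n_a", "n_b", "U", "p_raw"]
    )
    if not results.empty:
        p_adj = np.empty(len(results))
        if family == "global":
            p_adj[:] = bh_adjust(results["p_raw"].to_numpy())
        else:
            for _, idx in results.groupby("parameter").groups.items():
                loc = results.index.get_indexer(idx)
                p_adj[loc] = bh_adjust(results["p_raw"].to_numpy()[loc])
        results["p_adj"] = p_adj
        results["stars"] = [significance_stars(p) for p in p_adj]
    else:
        results["p_adj"] = pd.Series(dtype=float)
        results["stars"] = pd.Series(dtype=str)
    skipped_df = pd.DataFrame(skipped, columns=["parameter", "group_a", "group_b", "reason"])
    if skipped:
        logger.warning("%d contrast(s) skipped (insufficient samples)", len(skipped))
    return results, skipped_df
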
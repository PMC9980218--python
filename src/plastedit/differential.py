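"""Differential editing between conditions.

Per-site editing efficiencies from replicate libraries are compared with a
one-tailed Welch t-test (unequal variances, Satterthwaite degrees of
freedom), the test used for silenced-vs-control comparisons in VIGS editing
studies.  The tail is taken in the direction of the observed difference by
default.  Raw p < alpha is the significance rule (no multiple-testing
correction unless requested), matching the per-site asterisk convention of
the emulated analyses.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats


def welch_one_tailed(
    a: Iterable[float],
    b: Iterable[float],
    direction: str = "auto",
) -> tuple[float, float, float]:
    """Welch t-test of sample b against sample a; returns (t, df, p).

    t is computed for mean(b) - mean(a).  ``direction`` names the alternative
    for b relative to a: "greater", "less", or "auto" (tail in the direction
    of the observed difference).  With zero variance in both samples and equal
    means, (t, p) = (0, 0.5) by convention.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 replicates")
    if direction not in ("auto", "greater", "less"):
        raise ValueError(f"invalid direction {direction!r}")

    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    delta = b.mean() - a.mean()
    se2 = va / na + vb / nb

    if se2 == 0.0:
        df = float(na + nb - 2)
        if delta == 0.0:
            return 0.0, df, 0.5
        t = math.inf if delta > 0 else -math.inf
    else:
        t = delta / math.sqrt(se2)
        df = se2**2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )

    if direction == "auto":
        direction = "greater" if t >= 0 else "less"
    if direction == "greater":
        p = float(stats.t.sf(t, df)) if math.isfinite(t) else (0.0 if t > 0 else 1.0)
    else:
        p = float(stats.t.cdf(t, df)) if math.isfinite(t) else (0.0 if t < 0 else 1.0)
    return float(t), float(df), p


def _pivot(table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Long-format (site_id, efficiency[, ...]) -> site_id -> replicate array."""
    if "site_id" not in table.columns or "efficiency" not in table.columns:
        raise ValueError("condition table needs site_id and efficiency columns")
    out = {}
    for site_id, grp in table.groupby("site_id", sort=False):
        vals = grp["efficiency"].to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"efficiencies outside [0,1] for site {site_id}")
        out[str(site_id)] = vals
    return out


def compare_conditions(
    control: pd.DataFrame,
    test: pd.DataFrame,
    alpha: float = 0.05,
    direction: str = "auto",
    two_tailed: bool = False,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-site differential editing, test condition vs control.

    Both inputs are long-format tables with at least ``site_id`` and
    ``efficiency`` columns (one row per replicate).  Returns one row per
    shared site with means, delta = mean_test - mean_control, the Welch
    statistic, one-tailed p (or two-tailed with ``two_tailed``), significance
    at ``alpha`` and direction.  ``bh_correct`` applies Benjamini-Hochberg to
    the p-values before thresholding.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    ctl = _pivot(control)
    tst = _pivot(test)
    shared = [s for s in ctl if s in tst]
    if not shared:
        raise ValueError("no shared site_ids between conditions")

    rows = []
    for site in shared:
        a, b = ctl[site], tst[site]
        if two_tailed:
            t, df, p_low = welch_one_tailed(a, b, "less")
            p = min(1.0, 2 * min(p_low, 1 - p_low))
        else:
            t, df, p = welch_one_tailed(a, b, direction)
        delta = b.mean() - a.mean()
        rows.append({
            "site_id": site,
            "n_control": a.size,
            "n_test": b.size,
            "mean_control": a.mean(),
            "mean_test": b.mean(),
            "delta": delta,
            "t_stat": t,
            "df": df,
            "p_one_tailed": p,
            "direction": "increased" if delta > 0 else
                         ("decreased" if delta < 0 else "unchanged"),
        })
    df_out = pd.DataFrame(rows)
    pcol = df_out["p_one_tailed"].to_numpy()
    if bh_correct:
        pcol = stats.false_discovery_control(pcol, method="bh")
        df_out["p_adjusted"] = pcol
    df_out["significant"] = pcol < alpha
    return df_out


def summarize(results: pd.DataFrame) -> dict[str, int]:
    """Counts of significant / increased / decreased sites."""
    sig = results[results["significant"]]
    return {
        "n_sites": len(results),
        "n_significant": len(sig),
        "n_decreased": int((sig["direction"] == "decreased").sum()),
        "n_increased": int((sig["direction"] == "increased").sum()),
    }


def age_trend(
    tables: Mapping[int, pd.DataFrame],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Old-vs-young leaf comparison per site.

    ``tables`` maps leaf number to a long-format efficiency table.  Leaves are
    numbered from the bottom of the plant, so the lowest number is the oldest
    leaf; the comparison is oldest vs youngest (old as test condition).
    Adds a per-site trend label: decreased / increased when significant,
    otherwise unaffected.
    """
    if len(tables) < 2:
        raise ValueError("need at least two leaf classes")
    oldest = min(tables)
    youngest = max(tables)
    res = compare_conditions(tables[youngest], tables[oldest], alpha=alpha)
    res["leaf_old"] = oldest
    res["leaf_young"] = youngest
    res["trend"] = np.where(res["significant"], res["direction"], "unaffected")
    return res


def classify_signatures(
    results: Mapping[str, pd.DataFrame],
    stress_control: str | None = None,
) -> pd.DataFrame:
    """Label each site by the specificity of its editing perturbation.

    ``results`` maps condition names to compare_conditions outputs (each vs a
    common non-silenced control); ``stress_control`` names the condition that
    serves as a general-chlorosis control (PDS-like).  Labels: a site
    significant in the stress control is ``general_stress`` (a secondary
    effect of chloroplast dysfunction); significant in exactly one other
    condition, ``specific:<condition>``; in two or more, ``shared``; nowhere,
    ``unaffected``.
    """
    if len(results) < 2:
        raise ValueError("need results for at least two conditions")
    if stress_control is not None and stress_control not in results:
        raise ValueError(f"stress control {stress_control!r} not in results")

    sig_by_cond = {
        cond: set(df.loc[df["significant"], "site_id"])
        for cond, df in results.items()
    }
    all_sites = sorted({s for df in results.values() for s in df["site_id"]})
    rows = []
    for site in all_sites:
        hits = {c for c, s in sig_by_cond.items() if site in s}
        if stress_control is not None and stress_control in hits:
            label = "general_stress"
        else:
            hits = hits - {stress_control}
            if len(hits) == 0:
                label = "unaffected"
            elif len(hits) == 1:
                label = f"specific:{next(iter(hits))}"
            else:
                label = "shared"
        rows.append({"site_id": site, "label": label})
    return pd.DataFrame(rows)


def conservation_compare(
    sites_a: pd.DataFrame,
    sites_b: pd.DataFrame,
    key: tuple[str, str] = ("gene", "offset"),
) -> tuple[int, int, int, pd.DataFrame]:
    """Compare two species' editing-site tables by (gene, within-gene offset).

    Returns (n_conserved, n_unique_a, n_unique_b, joined table); the joined
    table carries a ``status`` column in {conserved, a_only, b_only}.
    """
    ka, kb = list(key), list(key)
    for name, df in (("a", sites_a), ("b", sites_b)):
        missing = [c for c in key if c not in df.columns]
        if missing:
            raise ValueError(f"table {name} missing key columns {missing}")
        if df.duplicated(subset=list(key)).any():
            raise ValueError(f"duplicate keys in table {name}")
    merged = sites_a.merge(
        sites_b, on=list(key), how="outer", suffixes=("_a", "_b"),
        indicator=True,
    )
    status = merged["_merge"].map(
        {"both": "conserved", "left_only": "a_only", "right_only": "b_only"}
    )
    merged = merged.drop(columns="_merge").assign(status=status)
    n_cons = int((status == "conserved").sum())
    return (n_cons, int((status == "a_only").sum()),
            int((status == "b_only").sum()), merged)


def plot_editing_bars(
    long_table: pd.DataFrame,
    path: str,
    alpha: float = 0.05,
    results: pd.DataFrame | None = None,
) -> None:
    """Grouped bar plot of mean editing efficiency per site and condition,
    error bars one standard deviation; sites significant in ``results`` are
    starred."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stats_df = (
        long_table.groupby(["site_id", "condition"])["efficiency"]
        .agg(["mean", "std"])
        .reset_index()
    )
    sites = sorted(stats_df["site_id"].unique())
    conditions = sorted(stats_df["condition"].unique())
    x = np.arange(len(sites))
    width = 0.8 / max(len(conditions), 1)
    sig_sites = set()
    if results is not None:
        sig_sites = set(results.loc[results["significant"], "site_id"])

    fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(sites)), 4))
    for j, cond in enumerate(conditions):
        sub = stats_df[stats_df["condition"] == cond].set_index("site_id")
        means = [sub["mean"].get(s, np.nan) for s in sites]
        sds = [sub["std"].get(s, 0.0) for s in sites]
        ax.bar(x + j * width, means, width, yerr=sds, capsize=2, label=cond)
    for i, s in enumerate(sites):
        if s in sig_sites:
            ax.text(x[i] + 0.4, 1.02, "*", ha="center")
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(sites, rotation=90, fontsize=7)
    ax.set_ylabel("editing efficiency T/(C+T)")
    ax.set_ylim(0, 1.1)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
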
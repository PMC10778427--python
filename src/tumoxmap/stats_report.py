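"""Nonparametric statistics on the joined MRI-target / histology table.

Mirrors the comparison design of region-level tumor studies: a
Kruskal-Wallis H test across the nonenhancing / enhancing / necrosis
compartments per metric, Mann-Whitney U post hoc pairs (raw p-values,
no multiple-testing correction — comparisons are annotated directly),
and Spearman rank correlations between each MRI metric and its
histological counterpart (OEF vs HIF-1alpha score, CBV vs vessel
density, vessel size vs vessel diameter).  Rows with missing values are
dropped listwise per tested pair and counted.
"""

from __future__ import annotations

import itertools
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VOI_GROUPS",
    "MRI_HISTOLOGY_PAIRS",
    "kruskal_wallis",
    "mann_whitney",
    "spearman",
    "report",
]

VOI_GROUPS = ("nonenhancing", "enhancing", "necrosis")

#: (MRI metric column, histology column) pairs tested for correlation.
MRI_HISTOLOGY_PAIRS = (
    ("OEF", "hif_score"),
    ("CBV", "vessel_density"),
    ("vessel_size", "vessel_diameter_um"),
)

ALPHA = 0.05


def kruskal_wallis(groups: dict[str, np.ndarray]) -> dict:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k-1 df).

    Requires at least two groups of at least two observations each.
    The all-tied degenerate case returns H = 0, p = 1.
    """
    for name, vals in groups.items():
        if len(vals) == 0:
            raise ValueError(f"group {name!r} is empty")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return {"H": 0.0, "p": 1.0, "n": int(pooled.size)}
    h, p = stats.kruskal(*arrays)
    return {"H": float(h), "p": float(p), "n": int(pooled.size)}


def mann_whitney(x: np.ndarray, y: np.ndarray) -> dict:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when both groups have n <= 8 and no ties span the
    groups; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {"U": float(res.statistic), "p": float(res.pvalue), "n1": int(x.size), "n2": int(y.size)}


def spearman(x: np.ndarray, y: np.ndarray) -> dict:
    """Spearman rank correlation with average ranks for ties.

    p-value from the t approximation; zero variance in either vector is
    reported as undefined (r = NaN) rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return {"r": float("nan"), "p": float("nan"), "n": int(x.size), "significant": False}
    r, p = stats.spearmanr(x, y)
    return {"r": float(r), "p": float(p), "n": int(x.size), "significant": bool(p < ALPHA)}


def _plots(paired: pd.DataFrame, results: dict, out_dir: Path) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    metrics = [m for m, _ in MRI_HISTOLOGY_PAIRS] + [h for _, h in MRI_HISTOLOGY_PAIRS]
    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    for ax, metric in zip(axes.ravel(), metrics):
        groups = [
            paired.loc[paired.voi_label == g, metric].dropna().to_numpy() for g in VOI_GROUPS
        ]
        means = [g.mean() if g.size else np.nan for g in groups]
        sds = [g.std(ddof=1) if g.size > 1 else 0.0 for g in groups]
        ax.bar(range(len(VOI_GROUPS)), means, yerr=sds, capsize=4, color="#7da7c9")
        ax.set_xticks(range(len(VOI_GROUPS)), VOI_GROUPS, rotation=20)
        ax.set_title(metric)
        for pairres in results["mann_whitney"].get(metric, []):
            if pairres["p"] < ALPHA:
                i = VOI_GROUPS.index(pairres["group_a"])
                j = VOI_GROUPS.index(pairres["group_b"])
                ymax = np.nanmax([m + s for m, s in zip(means, sds)])
                ax.plot([i, j], [ymax * 1.05] * 2, "k-", lw=0.8)
                ax.text((i + j) / 2, ymax * 1.07, f"* p={pairres['p']:.3g}",
                        ha="center", fontsize=7)
    fig.tight_layout()
    p = out_dir / "group_comparisons.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(str(p))

    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, (mri, histo) in zip(axes, MRI_HISTOLOGY_PAIRS):
        sub = paired[[mri, histo]].dropna()
        ax.scatter(sub[mri], sub[histo], s=18, color="#b05050")
        sp = results["spearman"].get(f"{mri}_vs_{histo}")
        if sp is None:
            ax.set_title(f"{mri} vs {histo}\n(too few pairs)")
        else:
            star = "*" if sp.get("significant") else ""
            ax.set_title(f"{mri} vs {histo}\nr={sp['r']:.2f}, p={sp['p']:.3g}{star}")
        ax.set_xlabel(mri)
        ax.set_ylabel(histo)
    fig.tight_layout()
    p = out_dir / "mri_histology_correlations.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(str(p))
    return written


def report(paired: pd.DataFrame, out_dir: str | Path | None = None) -> dict:
    """Run the full statistical comparison on a paired table.

    ``paired`` needs columns voi_label, OEF, CBV, vessel_size,
    hif_score, vessel_density, vessel_diameter_um.  Returns a results
    dict (also written as stats.json with plots when ``out_dir`` is
    given).  Groups absent from the table are skipped with a logged
    reason; pairwise tests run on whichever pairs are available.
    """
    results: dict = {"kruskal_wallis": {}, "mann_whitney": {}, "spearman": {},
                     "skipped": [], "n_rows": int(len(paired))}
    metrics = [m for m, _ in MRI_HISTOLOGY_PAIRS] + [h for _, h in MRI_HISTOLOGY_PAIRS]

    for metric in metrics:
        if metric not in paired.columns:
            results["skipped"].append(f"{metric}: column missing")
            continue
        groups = {
            g: paired.loc[paired.voi_label == g, metric].dropna().to_numpy()
            for g in VOI_GROUPS
        }
        usable = {g: v for g, v in groups.items() if v.size >= 2}
        if len(usable) >= 2:
            results["kruskal_wallis"][metric] = kruskal_wallis(usable)
        else:
            results["skipped"].append(
                f"Kruskal-Wallis on {metric}: fewer than two groups with n >= 2"
            )
        pair_results = []
        for a, b in itertools.combinations(VOI_GROUPS, 2):
            if groups[a].size and groups[b].size:
                res = mann_whitney(groups[a], groups[b])
                res.update(group_a=a, group_b=b)
                pair_results.append(res)
            else:
                results["skipped"].append(f"Mann-Whitney {metric} {a} vs {b}: empty group")
        results["mann_whitney"][metric] = pair_results

    for mri, histo in MRI_HISTOLOGY_PAIRS:
        sub = paired[[mri, histo]].dropna()
        key = f"{mri}_vs_{histo}"
        if len(sub) >= 3:
            res = spearman(sub[mri].to_numpy(), sub[histo].to_numpy())
            res["n_dropped"] = int(len(paired) - len(sub))
            results["spearman"][key] = res
        else:
            results["skipped"].append(f"Spearman {key}: fewer than 3 complete pairs")

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        # record basenames so the report content is run-directory independent
        results["plots"] = [Path(p).name for p in _plots(paired, results, out)]
        with open(out / "stats.json", "w") as fh:
            json.dump(results, fh, indent=2, default=float)
    return results
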
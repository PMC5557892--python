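"""Functional validation analyses: grouped CDF/KS comparisons of fold
changes, targetome overlap testing, chimera-peak support with a
saturation fit, and intersection with external prediction intervals.

Fold changes are ordering-faithful pseudocount CPM ratios rather than a
count-model fit; the grouped cumulative-distribution comparisons only
require a monotone per-gene statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

PSEUDOCOUNT = 0.5


# ---------------------------------------------------------------------------
# fold changes and grouped KS comparisons

def compute_log2fc(
    counts_treated: pd.DataFrame, counts_control: pd.DataFrame
) -> pd.Series:
    """Per-gene log2((CPM_t + 0.5) / (CPM_c + 0.5)), CPM averaged over
    replicate columns; the gene universe is the index intersection."""
    genes = counts_treated.index.intersection(counts_control.index)
    if genes.empty:
        raise ValueError("no overlapping genes between conditions")
    cpm_t = (counts_treated / counts_treated.sum(axis=0) * 1e6).loc[genes].mean(axis=1)
    cpm_c = (counts_control / counts_control.sum(axis=0) * 1e6).loc[genes].mean(axis=1)
    return pd.Series(
        np.log2((cpm_t + PSEUDOCOUNT) / (cpm_c + PSEUDOCOUNT)), index=genes, name="log2fc"
    )


def cdf_ks_compare(
    log2fc: pd.Series, grouping: pd.Series, reference: str
) -> pd.DataFrame:
    """Per-group n, median log2FC and two-sided (asymptotic) KS p-value
    against the reference group.

    ``grouping`` assigns each gene to exactly one group label; genes
    absent from ``grouping`` are ignored.  Groups with n < 2 get NaN p."""
    df = pd.DataFrame({"log2fc": log2fc}).join(grouping.rename("group"), how="inner")
    if reference not in set(df["group"]):
        raise ValueError(f"reference group {reference!r} absent")
    ref_vals = df.loc[df["group"] == reference, "log2fc"].to_numpy()
    rows = []
    for group, sub in df.groupby("group", sort=True):
        vals = sub["log2fc"].to_numpy()
        if group == reference:
            d, p = 0.0, 1.0
        elif len(vals) < 2 or len(ref_vals) < 2:
            d, p = np.nan, np.nan
        else:
            res = stats.ks_2samp(vals, ref_vals, alternative="two-sided", method="asymp")
            d, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "group": group,
                "n": len(vals),
                "median_log2fc": float(np.median(vals)) if len(vals) else np.nan,
                "ks_D": d,
                "ks_p": p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# targetome overlap

def targetome_overlap(
    chimeras_a: pd.DataFrame,
    chimeras_b: pd.DataFrame,
    min_fraction: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric gene-overlap test per shared abundant miRNA.

    Inputs need ``mirna`` and ``gene_id`` columns.  The gene universe is
    genes with at least one chimera (any region) in both datasets;
    tested miRNAs carry >= ``min_fraction`` of the chimeras in both.
    p is the upper tail of the shared-target count."""
    genes_a = set(chimeras_a["gene_id"].dropna())
    genes_b = set(chimeras_b["gene_id"].dropna())
    universe = genes_a & genes_b
    if not universe:
        raise ValueError("empty gene universe")
    frac_a = chimeras_a["mirna"].value_counts(normalize=True)
    frac_b = chimeras_b["mirna"].value_counts(normalize=True)
    tested = sorted(
        set(frac_a[frac_a >= min_fraction].index)
        & set(frac_b[frac_b >= min_fraction].index)
    )
    N = len(universe)
    rows = []
    for mirna in tested:
        ta = set(chimeras_a.loc[chimeras_a["mirna"] == mirna, "gene_id"]) & universe
        tb = set(chimeras_b.loc[chimeras_b["mirna"] == mirna, "gene_id"]) & universe
        shared = len(ta & tb)
        p = float(stats.hypergeom.sf(shared - 1, N, len(ta), len(tb))) if shared else 1.0
        rows.append(
            {
                "mirna": mirna,
                "universe": N,
                "targets_a": len(ta),
                "targets_b": len(tb),
                "shared": shared,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# chimera-peak support and saturation fit

@dataclass
class SupportCurve:
    bin_centers: np.ndarray
    support_fraction: np.ndarray
    n_per_bin: np.ndarray
    asymptote: Optional[float] = None  # A in y = A / (1 + exp(-(x - x0)/w))
    midpoint: Optional[float] = None
    width: Optional[float] = None
    asymptote_ci: Optional[tuple] = None
    converged: bool = False


def sigmoid(x: np.ndarray, A: float, x0: float, w: float) -> np.ndarray:
    return A / (1.0 + np.exp(-(x - x0) / w))


def fit_sigmoid(x: np.ndarray, y: np.ndarray) -> Optional[tuple]:
    """Least-squares 3-parameter logistic fit; returns (A, x0, w, A_se)."""
    try:
        p0 = (min(1.0, max(y.max(), 0.1)), float(np.median(x)), max(np.ptp(x) / 5, 1e-3))
        popt, pcov = optimize.curve_fit(
            sigmoid, x, y, p0=p0, bounds=([0, -np.inf, 1e-9], [1.0, np.inf, np.inf]),
            maxfev=10000,
        )
        return float(popt[0]), float(popt[1]), float(popt[2]), float(np.sqrt(pcov[0, 0]))
    except (RuntimeError, ValueError):
        return None


def chimera_peak_support(
    peak_heights: Sequence[float],
    peak_supported: Sequence[bool],
    n_bins: int = 10,
) -> SupportCurve:
    """Fraction of CLIP peaks overlapping >=1 chimera per normalized-
    height bin (deciles), with a sigmoidal saturation fit whose
    asymptote estimates the maximum attainable chimera support."""
    h = np.asarray(peak_heights, dtype=float)
    s = np.asarray(peak_supported, dtype=bool)
    if h.size == 0:
        raise ValueError("no peaks")
    edges = np.unique(np.quantile(h, np.linspace(0, 1, n_bins + 1)))
    idx = np.clip(np.searchsorted(edges, h, side="right") - 1, 0, len(edges) - 2)
    centers, fracs, ns = [], [], []
    for b in range(len(edges) - 1):
        mask = idx == b
        if not mask.any():
            continue
        centers.append(float(h[mask].mean()))
        fracs.append(float(s[mask].mean()))
        ns.append(int(mask.sum()))
    curve = SupportCurve(np.array(centers), np.array(fracs), np.array(ns))
    fit = fit_sigmoid(curve.bin_centers, curve.support_fraction)
    if fit is not None:
        A, x0, w, se = fit
        curve.asymptote, curve.midpoint, curve.width = A, x0, w
        curve.asymptote_ci = (A - 1.96 * se, A + 1.96 * se)
        curve.converged = True
    return curve


def support_by_bc(clusters: Sequence, peaks: Sequence) -> pd.DataFrame:
    """Fraction of interaction clusters overlapping >=1 peak, by BC."""
    rows: dict[int, list[int]] = {}
    for c in clusters:
        supported = any(c.span.overlaps(p.interval) for p in peaks)
        rows.setdefault(c.bc, []).append(int(supported))
    return pd.DataFrame(
        [
            {"bc": bc, "n": len(v), "support_fraction": float(np.mean(v))}
            for bc, v in sorted(rows.items())
        ]
    )


# ---------------------------------------------------------------------------
# intersection with external prediction intervals

def intersect_predictions(
    clusters: Sequence,
    predictions: pd.DataFrame,
    seed_class_of: dict,
    expressed_genes: Optional[set] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overlap of chimera clusters with family-matched prediction
    intervals, per seed class and per family.

    ``predictions`` needs chrom/start/end/strand and a ``family`` column;
    ``seed_class_of`` maps a cluster identity to its seed class label.
    Clusters on genes failing the 100-tag expression rule are excluded
    when ``expressed_genes`` is given.  Returns (by_seed_class,
    by_family) overlap-fraction tables; the per-family table also
    reports the converse fraction of predictions with chimera support."""
    from .intervals import GenomicInterval

    pred_by_family: dict[str, list[GenomicInterval]] = {}
    for row in predictions.itertuples(index=False):
        pred_by_family.setdefault(row.family, []).append(
            GenomicInterval(row.chrom, row.start, row.end, getattr(row, "strand", "+"))
        )
    if expressed_genes is None:
        usable = list(clusters)
    else:
        usable = [c for c in clusters if c.gene_id in expressed_genes]

    by_class: dict[str, list[int]] = {}
    by_family: dict[str, dict] = {}
    matched_predictions: dict[str, set] = {}
    for c in usable:
        fam = str(c.key)
        preds = pred_by_family.get(fam, [])
        hit_idx = [i for i, p in enumerate(preds) if c.span.overlaps(p)]
        hit = bool(hit_idx)
        seed_class = seed_class_of.get(id(c), seed_class_of.get(fam, "none"))
        by_class.setdefault(seed_class, []).append(int(hit))
        fam_entry = by_family.setdefault(fam, {"n": 0, "hits": 0})
        fam_entry["n"] += 1
        fam_entry["hits"] += int(hit)
        matched_predictions.setdefault(fam, set()).update(hit_idx)

    class_df = pd.DataFrame(
        [
            {"seed_class": k, "n": len(v), "overlap_fraction": float(np.mean(v))}
            for k, v in sorted(by_class.items())
        ]
    )
    fam_rows = []
    for fam, entry in sorted(by_family.items()):
        n_pred = len(pred_by_family.get(fam, []))
        fam_rows.append(
            {
                "family": fam,
                "n_clusters": entry["n"],
                "overlap_fraction": entry["hits"] / entry["n"],
                "n_predictions": n_pred,
                "prediction_support_fraction": (
                    len(matched_predictions.get(fam, set())) / n_pred if n_pred else np.nan
                ),
            }
        )
    return class_df, pd.DataFrame(fam_rows)
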
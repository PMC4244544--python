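"""ROI extraction and inter-institution statistics.

A deterministic vascular-territory template partitions the phantom's
cortical band into anterior / middle / posterior cerebral artery
territories per hemisphere, adds the deep nuclei, cerebellum, vermis,
pons and a centrum-semiovale white-matter region, and the group tools
reproduce the clinical comparison: paired t between conditions,
t / Mann-Whitney U between institution pairs, and the Steel-Dwass
all-pairs nonparametric multiple comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .core import ImageVolume, PhantomSpec

__all__ = [
    "ROISet",
    "make_roi_template",
    "roi_means",
    "group_compare",
    "mann_whitney_exact",
    "steel_dwass",
    "summary_table",
    "BILATERAL_REGIONS",
    "MIDLINE_REGIONS",
]

BILATERAL_REGIONS = ("hemisphere", "ACA", "MCA", "PCA", "basal_ganglia",
                     "thalamus", "cerebellum", "white_matter")
MIDLINE_REGIONS = ("pons", "vermis")


@dataclass
class ROISet:
    """Named region masks on the phantom grid (regions may overlap only
    through the composite 'hemisphere' region)."""

    masks: dict[str, np.ndarray]
    spacing_mm: tuple[float, float, float]

    def names(self):
        return list(self.masks)


def _erode2d(mask: np.ndarray, iterations: int) -> np.ndarray:
    if iterations <= 0:
        return mask
    out = np.zeros_like(mask)
    for s in range(mask.shape[0]):
        out[s] = ndimage.binary_erosion(mask[s], iterations=iterations)
    return out if out.any() else mask


def make_roi_template(phantom: PhantomSpec, erosion_mm: float = 0.0) -> ROISet:
    """Deterministic territory partition of the phantom.

    Cortex is split by the angle from the anterior axis into ACA (< 35
    degrees), MCA (35-110) and PCA (> 110) per hemisphere; hemisphere =
    ACA + MCA + PCA + basal ganglia + thalamus.  With ``erosion_mm`` 0
    (default) the gray-matter regions exactly partition the GM mask; a
    positive erosion shrinks each region in-plane (atlas ROIs sit inside
    territories, away from tissue boundaries) and is skipped for any
    region it would empty.
    """
    labels = phantom.labels
    n = labels.shape[-1]
    sp = phantom.spacing_mm[-1]
    c = (n - 1) / 2.0
    jj, ii = np.meshgrid(np.arange(n), np.arange(n))
    x = (jj - c) * sp
    y = (c - ii) * sp
    ang = np.degrees(np.abs(np.arctan2(x, y)))  # angle from anterior axis
    left = x > 0
    it = max(0, int(round(erosion_mm / sp)))

    cortex = phantom.mask("cortex")
    sectors = {"ACA": ang < 35.0, "MCA": (ang >= 35.0) & (ang < 110.0),
               "PCA": ang >= 110.0}

    masks: dict[str, np.ndarray] = {}
    for side, side2d in (("right", ~left), ("left", left)):
        for terr, sec in sectors.items():
            masks[f"{terr}_{side}"] = _erode2d(cortex, it) & (sec & side2d)[None]
        for deep in ("basal_ganglia", "thalamus"):
            key = f"{deep}_{'l' if side == 'left' else 'r'}"
            masks[f"{deep}_{side}"] = _erode2d(phantom.mask(key), max(it - 1, 0))
        if "cerebellum" in phantom.structures:
            masks[f"cerebellum_{side}"] = _erode2d(phantom.mask("cerebellum"), it) & side2d[None]
        wm = phantom.mask("white_matter")
        # carve out the deep nuclei before eroding the centrum semiovale
        for deep in ("basal_ganglia_l", "basal_ganglia_r", "thalamus_l", "thalamus_r"):
            wm = wm & ~phantom.mask(deep)
        masks[f"white_matter_{side}"] = _erode2d(wm, it) & side2d[None]
        masks[f"hemisphere_{side}"] = (masks[f"ACA_{side}"] | masks[f"MCA_{side}"]
                                       | masks[f"PCA_{side}"]
                                       | masks[f"basal_ganglia_{side}"]
                                       | masks[f"thalamus_{side}"])
    for region in MIDLINE_REGIONS:
        if region in phantom.structures:
            masks[region] = _erode2d(phantom.mask(region), max(it - 1, 0))
    for name, m in masks.items():
        if not m.any():
            raise ValueError(f"ROI template region '{name}' is empty")
    return ROISet(masks=masks, spacing_mm=phantom.spacing_mm)


def roi_means(image: ImageVolume, rois: ROISet) -> pd.DataFrame:
    """Mean image value per region: left/right rows plus bilateral
    averages (mean of the two side means)."""
    if image.data.shape != next(iter(rois.masks.values())).shape:
        raise ValueError("image and ROI template grids differ")
    rows = []
    for name, mask in rois.masks.items():
        rows.append({"region": name, "mean": float(image.data[mask].mean()),
                     "n_voxels": int(mask.sum())})
    df = pd.DataFrame(rows)
    for region in BILATERAL_REGIONS:
        l, r = f"{region}_left", f"{region}_right"
        if l in rois.masks and r in rois.masks:
            lv = df.loc[df.region == l, "mean"].iloc[0]
            rv = df.loc[df.region == r, "mean"].iloc[0]
            df.loc[len(df)] = {"region": f"{region}_avg", "mean": (lv + rv) / 2.0,
                               "n_voxels": int(rois.masks[l].sum() + rois.masks[r].sum())}
    return df


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U by exhaustive enumeration (small samples,
    ties handled by mid-ranks): returns (U of x, exact two-sided p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    from itertools import combinations
    pooled = np.concatenate([x, y])
    nx = len(x)
    ranks = sps.rankdata(pooled)
    r_obs = ranks[:nx].sum()
    u_obs = r_obs - nx * (nx + 1) / 2.0
    mu = nx * len(y) / 2.0
    count = 0
    total = 0
    for comb in combinations(range(len(pooled)), nx):
        r = ranks[list(comb)].sum()
        u = r - nx * (nx + 1) / 2.0
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return float(u_obs), count / total


def group_compare(x, y, mode: str = "mann_whitney"):
    """Two-group comparison used by the cohort reports.

    Returns ``(statistic, p, flag)``; ``flag`` marks degenerate input
    (zero variance in t modes).  Mann-Whitney is exact (enumeration) for
    groups of up to 8, otherwise the normal approximation with tie
    correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two observations per group")
    if mode == "paired_t":
        if len(x) != len(y):
            raise ValueError("paired test needs equal lengths")
        d = x - y
        if np.allclose(d.std(ddof=1), 0.0):
            return 0.0, 1.0, True
        res = sps.ttest_rel(x, y)
        return float(res.statistic), float(res.pvalue), False
    if mode == "unpaired_t":
        if np.allclose(x.std(ddof=1), 0.0) and np.allclose(y.std(ddof=1), 0.0):
            return 0.0, 1.0, True
        res = sps.ttest_ind(x, y)
        return float(res.statistic), float(res.pvalue), False
    if mode == "mann_whitney":
        if max(len(x), len(y)) <= 8:
            u, p = mann_whitney_exact(x, y)
            return u, p, False
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return float(res.statistic), float(res.pvalue), False
    raise ValueError(f"unknown mode {mode!r}")


def _pair_rank_stat(xi, xj):
    """Tie-corrected standardized rank-sum statistic for one pair."""
    ni, nj = len(xi), len(xj)
    n = ni + nj
    ranks = sps.rankdata(np.concatenate([xi, xj]))
    r = ranks[:ni].sum()
    e = ni * (n + 1) / 2.0
    v = ni * nj / (n * (n - 1)) * (np.sum(ranks ** 2) - n * (n + 1) ** 2 / 4.0)
    if v <= 0:
        return 0.0
    return (r - e) / np.sqrt(v)


def _steel_dwass_exact_null(groups) -> np.ndarray:
    """Null distribution of max |pairwise standardized rank statistic|
    over all relabelings of the pooled sample into the group sizes."""
    from itertools import combinations
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]

    def rec(avail, remaining):
        if len(remaining) == 1:
            yield [avail]
            return
        for comb in combinations(range(len(avail)), remaining[0]):
            taken = [avail[c] for c in comb]
            left = [a for q, a in enumerate(avail) if q not in comb]
            for rest in rec(left, remaining[1:]):
                yield [taken] + rest

    tie_free = len(np.unique(pooled)) == len(pooled)
    if tie_free:
        # U statistic as a submatrix sum of the comparison matrix; for
        # continuous data the variance has the closed form ni nj (n+1)/12
        greater = (pooled[:, None] > pooled[None, :]).astype(float)
        maxima = []
        for parts in rec(list(range(len(pooled))), sizes):
            m = 0.0
            for i in range(len(parts)):
                for j in range(i + 1, len(parts)):
                    gi, gj = parts[i], parts[j]
                    ni, nj = len(gi), len(gj)
                    u = greater[np.ix_(gi, gj)].sum()
                    e = ni * nj / 2.0
                    v = ni * nj * (ni + nj + 1) / 12.0
                    m = max(m, abs(u - e) / np.sqrt(v))
            maxima.append(m)
        return np.asarray(maxima)
    maxima = []
    for parts in rec(list(range(len(pooled))), sizes):
        gs = [pooled[p] for p in parts]
        m = 0.0
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                m = max(m, abs(_pair_rank_stat(gs[i], gs[j])))
        maxima.append(m)
    return np.asarray(maxima)


def steel_dwass(groups, method: str = "auto") -> pd.DataFrame:
    """Steel-Dwass all-pairs multiple comparison.

    For every pair the tie-corrected standardized rank-sum statistic t is
    referred either to the exact permutation distribution of the maximum
    over pairs (small samples) or to the studentized-range asymptote
    p = P(Q_k >= sqrt(2) |t|).  ``method``: ``exact``, ``asymptotic`` or
    ``auto`` (exact when the relabeling count is below ~1e5).  Requires
    >= 3 groups of >= 3 each.
    """
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    if k < 3:
        raise ValueError("Steel-Dwass needs at least three groups")
    if any(len(g) < 3 for g in groups):
        raise ValueError("each group needs at least three observations")
    if method == "auto":
        from math import comb
        total = 1
        left = sum(len(g) for g in groups)
        for g in groups:
            total *= comb(left, len(g))
            left -= len(g)
        method = "exact" if total <= 100_000 else "asymptotic"
    null_max = _steel_dwass_exact_null(groups) if method == "exact" else None
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            t = _pair_rank_stat(groups[i], groups[j])
            if null_max is not None:
                p = float((null_max >= abs(t) - 1e-12).mean())
            elif abs(t) > 0:
                p = float(sps.studentized_range.sf(np.sqrt(2.0) * abs(t), k, np.inf))
            else:
                p = 1.0
            rows.append({"group_i": i, "group_j": j, "statistic": float(t),
                         "p_adjusted": min(p, 1.0)})
    return pd.DataFrame(rows)


def summary_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD report per institution x region x condition, with a
    per-subject CVR summary (CVR is computed subject-wise, then
    averaged; it is not derived from the group mean CBF values).

    ``cohort`` columns: institution, subject, region, condition
    (rest/acz), cbf.
    """
    required = {"institution", "subject", "region", "condition", "cbf"}
    if not required.issubset(cohort.columns):
        raise ValueError(f"cohort table needs columns {sorted(required)}")
    if (cohort.cbf < 0).any():
        raise ValueError("negative CBF in cohort table")
    rows = []
    for (inst, region), g in cohort.groupby(["institution", "region"], sort=False):
        wide = g.pivot_table(index="subject", columns="condition", values="cbf")
        entry = {"institution": inst, "region": region}
        for cond in ("rest", "acz"):
            if cond in wide:
                vals = wide[cond].dropna()
                entry[f"{cond}_mean"] = float(vals.mean())
                entry[f"{cond}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
                entry[f"{cond}_n"] = int(len(vals))
                if len(vals) == 1:
                    entry["single_subject"] = True
        if {"rest", "acz"}.issubset(wide.columns):
            both = wide.dropna()
            cvr = 100.0 * (both["acz"] - both["rest"]) / both["rest"]
            entry["cvr_mean"] = float(cvr.mean())
            entry["cvr_sd"] = float(cvr.std(ddof=1)) if len(cvr) > 1 else 0.0
        rows.append(entry)
    return pd.DataFrame(rows)
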
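"""Per-cell quantification, α/β classification, colocalization, statistics.

A segmented field yields one row per cell: area, centroid, and the median
intensity of each channel over the cell's pixels.  Cells are classified by
a hormone-ratio rule: a cell is a β-cell when its
insulin median is at least 50% more intense than its glucagon median
(inclusive, insulin >= 1.5 x glucagon), an α-cell in the mirrored case,
and unclassified otherwise — including when both medians are zero.

IGFBP7 co-staining with the cell's defining hormone is summarized per cell
by the Manders overlap coefficient, and group differences in per-cell
median IGFBP7 intensity are compared with the Mann-Whitney test within
each cell class (cells, not donors, are the statistical unit by default;
per-donor aggregation is available as an option).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

ALPHA = "alpha"
BETA = "beta"
UNCLASSIFIED = "unclassified"

INTENSITY_CHANNELS = ("nuclear", "insulin", "glucagon", "igfbp7")


def cell_features(
    cells: np.ndarray, image: dict, donor_id: str = "donor0", group: str = "ND"
) -> pd.DataFrame:
    """One record per labeled cell: area, centroid, per-channel median.

    Medians use the usual even-count convention (mean of the two middle
    values). An empty label image gives an empty table.
    """
    cells = np.asarray(cells)
    if cells.min() < 0:
        raise ValueError("labels must be non-negative")
    labels = np.unique(cells)
    labels = labels[labels > 0]
    cols = {
        "donor_id": donor_id,
        "group": group,
        "cell_id": labels,
    }
    if len(labels) == 0:
        frame = pd.DataFrame(columns=["donor_id", "group", "cell_id", "area_px",
                                      "centroid_row", "centroid_col"]
                             + [f"median_{ch}" for ch in image])
        return frame
    areas = ndimage.sum_labels(np.ones_like(cells, dtype=np.int64), cells, labels)
    centroids = np.array(ndimage.center_of_mass(np.ones_like(cells), cells, labels))
    cols["area_px"] = areas.astype(np.int64)
    cols["centroid_row"] = centroids[:, 0]
    cols["centroid_col"] = centroids[:, 1]
    for ch, plane in image.items():
        plane = np.asarray(plane, dtype=np.float64)
        if plane.shape != cells.shape:
            raise ValueError(f"channel {ch!r} shape differs from label image")
        cols[f"median_{ch}"] = ndimage.median(plane, cells, labels)
    return pd.DataFrame(cols)


def classify_cells(table: pd.DataFrame, ratio: float = 1.5) -> pd.DataFrame:
    """Assign alpha/beta/unclassified by the inclusive hormone-ratio rule.

    insulin >= ratio x glucagon -> beta; glucagon >= ratio x insulin ->
    alpha; otherwise (including both medians zero) unclassified.  The rule
    is scale-invariant: multiplying both medians by any c > 0 leaves the
    class unchanged.
    """
    if ratio <= 1:
        raise ValueError("ratio must exceed 1")
    ins = table["median_insulin"].to_numpy(dtype=float)
    glu = table["median_glucagon"].to_numpy(dtype=float)
    if (ins < 0).any() or (glu < 0).any():
        raise ValueError("negative medians")
    both_zero = (ins == 0) & (glu == 0)
    beta = (ins >= ratio * glu) & ~both_zero
    alpha = (glu >= ratio * ins) & ~both_zero
    out = table.copy()
    out["cell_class"] = np.select([beta, alpha], [BETA, ALPHA], default=UNCLASSIFIED)
    return out


def manders_overlap(a: np.ndarray, b: np.ndarray, region: np.ndarray | None = None) -> float:
    """Manders overlap coefficient sum(ab)/sqrt(sum(a^2) sum(b^2)) over a region.

    Bounded in [0, 1] by Cauchy–Schwarz for non-negative intensities and
    invariant to separate positive rescaling of either channel.  Undefined
    (error) when both channels are all zero on the region.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if region is None:
        region = np.ones(a.shape, dtype=bool)
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("empty region")
    av, bv = a[region], b[region]
    if (av < 0).any() or (bv < 0).any():
        raise ValueError("intensities must be non-negative")
    den = np.sqrt(np.sum(av**2) * np.sum(bv**2))
    if den == 0:
        raise ValueError("overlap undefined: a channel is all zero on the region")
    # Cauchy-Schwarz bounds the true value by 1; clip the float rounding excess
    return float(min(np.sum(av * bv) / den, 1.0))


def per_cell_moc(cells: np.ndarray, image: dict, table: pd.DataFrame) -> pd.DataFrame:
    """IGFBP7 overlap with the defining hormone, per classified cell.

    α-cells: MOC(igfbp7, glucagon); β-cells: MOC(igfbp7, insulin), each over
    the cell's own pixels. Unclassified cells get NaN.
    """
    out = table.copy()
    moc = np.full(len(table), np.nan)
    igf = np.asarray(image["igfbp7"], dtype=np.float64)
    partner = {ALPHA: np.asarray(image["glucagon"], dtype=np.float64),
               BETA: np.asarray(image["insulin"], dtype=np.float64)}
    for i, row in enumerate(table.itertuples(index=False)):
        if row.cell_class not in partner:
            continue
        region = cells == row.cell_id
        try:
            moc[i] = manders_overlap(igf, partner[row.cell_class], region)
        except ValueError:
            moc[i] = np.nan
    out["moc"] = moc
    return out


def mann_whitney(x, y, method: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U (statistic of x) with a two-sided p value.

    ``auto``: exact null distribution when the pooled sample is small
    (n_x+n_y <= 12) and tie-free; otherwise the normal approximation with
    midranks, tie correction and continuity correction.  ``exact`` and
    ``asymptotic`` force one path.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    if method == "auto":
        pooled = np.concatenate([x, y])
        no_ties = np.unique(pooled).size == pooled.size
        method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_exact_enumeration(x, y) -> tuple[float, float]:
    """Exact Mann-Whitney by enumerating all rank assignments (tie-free).

    Brute force over all C(n_x+n_y, n_x) group assignments of the pooled
    values; intended for small samples and as an audit path.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size != pooled.size:
        raise ValueError("exact enumeration requires tie-free data")
    nx = x.size
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    idx = range(pooled.size)
    us = []
    for comb in itertools.combinations(idx, nx):
        xs = pooled[list(comb)]
        ys = np.delete(pooled, list(comb))
        us.append(sum(1 for xi in xs for yj in ys if xi > yj))
    us = np.asarray(us)
    n = len(us)
    # two-sided: distribution of U is symmetric about nx*ny/2
    mid = nx * y.size / 2.0
    p = np.sum(np.abs(us - mid) >= abs(u_obs - mid) - 1e-12) / n
    return float(u_obs), float(min(1.0, p))


def t_test_two_sample(x, y) -> tuple[float, float]:
    """Classical pooled-variance two-sample t-test (n_x + n_y − 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per sample")
    sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / (x.size + y.size - 2)
    if sp2 == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class GroupSummary:
    """Per (group, class) cell counts and IGFBP7 medians, plus group tests."""

    n_cells: dict = field(default_factory=dict)  # {(group, class) -> int}
    median_igfbp7: dict = field(default_factory=dict)  # {(group, class) -> float}
    tests: dict = field(default_factory=dict)  # {class -> {"U":…, "p":…, "groups": (g0, g1)}}
    n_unclassified: int = 0

    def ratio(self, cls: str, numerator: str = "T2D", denominator: str = "ND") -> float:
        """Ratio of group medians within a class (e.g. T2D/ND for α-cells)."""
        return self.median_igfbp7[(numerator, cls)] / self.median_igfbp7[(denominator, cls)]

    def to_dict(self) -> dict:
        return {
            "n_cells": {f"{g}/{c}": int(n) for (g, c), n in self.n_cells.items()},
            "median_igfbp7": {f"{g}/{c}": float(v) for (g, c), v in self.median_igfbp7.items()},
            "tests": {c: {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
                      for c, d in self.tests.items()},
            "n_unclassified": int(self.n_unclassified),
        }


def summarize_groups(table: pd.DataFrame, value_col: str = "median_igfbp7") -> GroupSummary:
    """Group-level summary of per-cell median IGFBP7 with Mann-Whitney tests.

    For each (donor group, cell class in {alpha, beta}) the cell count and
    the median of per-cell medians; within each class a two-sided
    Mann-Whitney test between the two donor groups (skipped when a group is
    absent).  Unclassified cells are excluded from summaries but counted.
    """
    if len(table) == 0:
        return GroupSummary()
    if "cell_class" not in table:
        raise ValueError("table must be classified first")
    n_unclass = int((table["cell_class"] == UNCLASSIFIED).sum())
    classified = table[table["cell_class"].isin([ALPHA, BETA])]

    n_cells, medians = {}, {}
    for (g, c), sub in classified.groupby(["group", "cell_class"], sort=True):
        n_cells[(g, c)] = len(sub)
        medians[(g, c)] = float(sub[value_col].median())

    tests = {}
    groups = sorted(classified["group"].unique())
    if len(groups) == 2:
        g0, g1 = groups
        for c in (ALPHA, BETA):
            x = classified.loc[(classified["group"] == g0) & (classified["cell_class"] == c), value_col]
            y = classified.loc[(classified["group"] == g1) & (classified["cell_class"] == c), value_col]
            if len(x) and len(y):
                u, p = mann_whitney(x, y)
                tests[c] = {"U": u, "p": p, "groups": (g0, g1)}
    return GroupSummary(n_cells=n_cells, median_igfbp7=medians, tests=tests,
                        n_unclassified=n_unclass)


def summarize_by_donor(table: pd.DataFrame, value_col: str = "median_igfbp7") -> pd.DataFrame:
    """Optional per-donor aggregation: median of cell medians per donor/class."""
    classified = table[table["cell_class"].isin([ALPHA, BETA])]
    return (classified.groupby(["group", "donor_id", "cell_class"])[value_col]
            .median().rename("donor_median").reset_index())
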
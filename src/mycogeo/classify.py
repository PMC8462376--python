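"""Habitat specialist/generalist classification and occupancy analysis.

Within a transect, an OTU is a *generalist* when it occurs more than
once in each habitat (occupancy >= 2 in soil and in phylloplane), a
*specialist* when it occurs more than once in exactly one habitat and
never in the other, and *unclassified* otherwise (e.g. twice in soil and
once on leaves, which satisfies neither rule).  Occupancy is the number
of samples in which the OTU occurs within the transect, capped by the
number of sampling locations.  The input table must already have
singletons removed; "occurs" means abundance strictly > 0.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import PHYLLOPLANE, SOIL
from .stats import benjamini_hochberg, wilcoxon_rank_sum
from .table import SpatialOtuTable

logger = logging.getLogger(__name__)

__all__ = [
    "OtuClassification",
    "occupancy",
    "classify_otus",
    "compare_occupancy",
    "occupancy_abundance_points",
    "loess_curve",
]

SOIL_SPECIALIST = "soil_specialist"
PHYLLO_SPECIALIST = "phylloplane_specialist"
GENERALIST = "generalist"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class OtuClassification:
    otu_id: str
    transect_id: str
    label: str
    occupancy_soil: int
    occupancy_phyllo: int


def occupancy(table: SpatialOtuTable) -> pd.DataFrame:
    """Occurrence counts per (otu, transect, habitat).

    Returns a long DataFrame with columns otu_id, transect, habitat,
    occupancy.  Zero-occupancy combinations are included for transects
    where the OTU appears in at least one habitat's sample set, so the
    classification rules can read both habitats at once.
    """
    pres = table.presence()
    md = table.metadata
    rows = []
    for (transect, habitat), grp in md.groupby(["transect", "habitat"], sort=False):
        counts = pres.loc[grp.index].sum(axis=0)
        for otu, c in counts.items():
            rows.append((otu, transect, habitat, int(c)))
    return pd.DataFrame(rows, columns=["otu_id", "transect", "habitat", "occupancy"])


def _apply_rules(occ_soil: int, occ_phyllo: int) -> str:
    if occ_soil >= 2 and occ_phyllo >= 2:
        return GENERALIST
    if occ_soil >= 2 and occ_phyllo == 0:
        return SOIL_SPECIALIST
    if occ_phyllo >= 2 and occ_soil == 0:
        return PHYLLO_SPECIALIST
    return UNCLASSIFIED


def classify_otus(table: SpatialOtuTable, scope: str = "per_transect") -> list[OtuClassification]:
    """Assign specialist/generalist labels from occupancy tallies.

    ``scope='per_transect'`` (default) applies the rules within each
    transect independently; ``scope='study'`` pools occupancies over all
    transects, so "exclusively" is judged study-wide.  OTUs absent from
    a transect entirely are not listed for that transect.
    """
    occ = occupancy(table)
    wide = occ.pivot_table(
        index=["otu_id", "transect"], columns="habitat", values="occupancy", fill_value=0
    )
    for hab in (SOIL, PHYLLOPLANE):
        if hab not in wide.columns:
            wide[hab] = 0
    if scope == "study":
        pooled = wide.groupby(level="otu_id").sum()
        return [
            OtuClassification(str(otu), "study", _apply_rules(int(r[SOIL]), int(r[PHYLLOPLANE])),
                              int(r[SOIL]), int(r[PHYLLOPLANE]))
            for otu, r in pooled.iterrows()
            if r[SOIL] + r[PHYLLOPLANE] > 0
        ]
    if scope != "per_transect":
        raise ValueError("scope must be 'per_transect' or 'study'")
    out = []
    for (otu, transect), r in wide.iterrows():
        s, p = int(r[SOIL]), int(r[PHYLLOPLANE])
        if s + p == 0:
            continue
        out.append(OtuClassification(str(otu), str(transect), _apply_rules(s, p), s, p))
    return out


def classifications_to_frame(classifications: list[OtuClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "otu_id": c.otu_id,
                "transect": c.transect_id,
                "label": c.label,
                "occupancy_soil": c.occupancy_soil,
                "occupancy_phyllo": c.occupancy_phyllo,
            }
            for c in classifications
        ]
    )


def _occupancy_groups(classifications: list[OtuClassification]) -> dict[str, np.ndarray]:
    """The four class-habitat occupancy pools compared in the histogram figure."""
    pools: dict[str, list[int]] = {
        "soil_specialist": [],
        "phylloplane_specialist": [],
        "generalist_soil": [],
        "generalist_phylloplane": [],
    }
    for c in classifications:
        if c.label == SOIL_SPECIALIST:
            pools["soil_specialist"].append(c.occupancy_soil)
        elif c.label == PHYLLO_SPECIALIST:
            pools["phylloplane_specialist"].append(c.occupancy_phyllo)
        elif c.label == GENERALIST:
            pools["generalist_soil"].append(c.occupancy_soil)
            pools["generalist_phylloplane"].append(c.occupancy_phyllo)
    return {k: np.asarray(v) for k, v in pools.items() if len(v)}


def compare_occupancy(classifications: list[OtuClassification]) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum tests between class-habitat occupancy pools.

    All unordered pairs of the populated groups are tested; p-values are
    Benjamini-Hochberg corrected across the pair set.  Groups with fewer
    than 2 observations are skipped with a warning.  Columns include the
    per-group median and interquartile range.
    """
    pools = _occupancy_groups(classifications)
    usable = {k: v for k, v in pools.items() if len(v) >= 2}
    for k in set(pools) - set(usable):
        logger.warning("compare_occupancy: group %s has < 2 observations; skipped", k)
    rows = []
    for g1, g2 in itertools.combinations(sorted(usable), 2):
        res = wilcoxon_rank_sum(usable[g1], usable[g2])
        rows.append(
            {
                "group_a": g1,
                "group_b": g2,
                "statistic": res.statistic,
                "p": res.p_value,
                "median_a": float(np.median(usable[g1])),
                "iqr_a": float(np.subtract(*np.percentile(usable[g1], [75, 25]))),
                "median_b": float(np.median(usable[g2])),
                "iqr_b": float(np.subtract(*np.percentile(usable[g2], [75, 25]))),
                "n_a": len(usable[g1]),
                "n_b": len(usable[g2]),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = benjamini_hochberg(df["p"].to_numpy())
    return df


def occupancy_abundance_points(
    table: SpatialOtuTable, classifications: list[OtuClassification]
) -> pd.DataFrame:
    """Interspecific occupancy-abundance points, one per (otu, transect, habitat).

    Local abundance is the OTU's summed (normalized) abundance across
    its occupied samples divided by the occupancy, so it measures how
    dense the OTU is where it does occur.  Points require occupancy >= 1.
    """
    label_of = {(c.otu_id, c.transect_id): c.label for c in classifications}
    ab = table.abundance
    pres = ab > 0
    md = table.metadata
    rows = []
    for (transect, habitat), grp in md.groupby(["transect", "habitat"], sort=False):
        sub = ab.loc[grp.index]
        occ = pres.loc[grp.index].sum(axis=0)
        sums = sub.sum(axis=0)
        for otu in ab.columns:
            k = int(occ[otu])
            if k < 1:
                continue
            rows.append(
                {
                    "otu_id": otu,
                    "transect": transect,
                    "habitat": habitat,
                    "label": label_of.get((otu, transect), UNCLASSIFIED),
                    "occupancy": k,
                    "local_abundance": float(sums[otu]) / k,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# loess


def loess_curve(
    x,
    y,
    span: float = 0.75,
    degree: int = 2,
    n_grid: int = 50,
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Tricube-weighted local polynomial regression on an even grid.

    At each grid point the ``ceil(span * n)`` nearest observations get
    tricube weights (1 - (d/dmax)^3)^3 and a degree-``degree``
    polynomial is fitted by weighted least squares; the pointwise
    interval comes from the local weighted residual variance propagated
    through the linear smoother weights.  Returns a DataFrame with
    columns x, fitted, se, lower, upper.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < max(5, degree + 2):
        raise ValueError(f"need at least {max(5, degree + 2)} points")
    k = int(np.ceil(span * n))
    grid = np.linspace(x.min(), x.max(), n_grid)
    from scipy.stats import norm as _norm

    zcrit = _norm.ppf(0.5 + conf_level / 2)
    fitted = np.empty(n_grid)
    se = np.empty(n_grid)
    for gi, x0 in enumerate(grid):
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="mergesort")[:k]
        dmax = d[idx].max()
        if dmax == 0:
            w = np.ones(len(idx))
        else:
            w = (1 - np.minimum(d[idx] / dmax, 1.0) ** 3) ** 3
        pos = w > 0
        if pos.sum() < degree + 1:
            raise ValueError(
                f"span {span} too small to cover {degree + 1} points at x = {x0:g}"
            )
        xi, yi, wi = x[idx][pos], y[idx][pos], w[pos]
        X = np.vander(xi - x0, degree + 1, increasing=True)
        WX = X * wi[:, None]
        XtWX = X.T @ WX
        beta, *_ = np.linalg.lstsq(XtWX, WX.T @ yi, rcond=None)
        fitted[gi] = beta[0]
        # linear smoother row for the intercept at x0
        try:
            inv = np.linalg.pinv(XtWX)
        except np.linalg.LinAlgError:
            inv = np.linalg.pinv(XtWX)
        lrow = (inv @ WX.T)[0]
        resid = yi - X @ beta
        dof = max(pos.sum() - (degree + 1), 1)
        sigma2 = float((wi * resid**2).sum() / (wi.sum() * dof / pos.sum()))
        se[gi] = np.sqrt(max(sigma2, 0.0) * float((lrow**2).sum()))
    return pd.DataFrame(
        {
            "x": grid,
            "fitted": fitted,
            "se": se,
            "lower": fitted - zcrit * se,
            "upper": fitted + zcrit * se,
        }
    )
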
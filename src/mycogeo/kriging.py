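"""Ordinary kriging of OTU abundance over a transect grid.

Given a fitted variogram model, ordinary kriging predicts abundance at
unsampled locations as the best linear unbiased combination of the
observations: at each prediction point the weights solve

    [ Gamma  1 ] [ w  ]   [ gamma_0 ]
    [ 1^T    0 ] [ mu ] = [ 1       ]

where Gamma holds model semivariances between data points, gamma_0 the
semivariances between data points and the prediction point, and mu the
Lagrange multiplier enforcing sum(w) = 1.  The kriging variance is
w . gamma_0 + mu.  With the nugget fixed at zero the predictor is an
exact interpolator: at a data location it returns the observed value
with zero variance.

A global neighborhood is used (every datum enters every system): the
per-transect sample counts here are tiny, and a search neighborhood
would only add artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve
from scipy.spatial.distance import cdist

from .classify import GENERALIST, OtuClassification
from .design import HABITATS
from .table import SpatialOtuTable
from .variogram import RangeEstimate, VariogramModel, surviving

logger = logging.getLogger(__name__)

__all__ = [
    "KrigedSurface",
    "ordinary_kriging",
    "krige_at_points",
    "kriging_weights",
    "paired_surface_maps",
    "render_surface_pair",
]


@dataclass(frozen=True)
class KrigedSurface:
    """Gridded prediction and kriging standard error for one OTU/habitat."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    predictions: np.ndarray  # shape (len(grid_y), len(grid_x))
    standard_errors: np.ndarray
    model: VariogramModel
    otu_id: str = ""
    habitat: str = ""
    transect_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.grid_x, self.grid_y)
        return pd.DataFrame(
            {
                "x": xx.ravel(),
                "y": yy.ravel(),
                "prediction": self.predictions.ravel(),
                "se": self.standard_errors.ravel(),
            }
        )


def _dedupe(coords: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average values at duplicate coordinates (keeps the system nonsingular)."""
    uniq, inverse = np.unique(coords, axis=0, return_inverse=True)
    if len(uniq) == len(coords):
        return coords, values
    avg = np.zeros(len(uniq))
    counts = np.bincount(inverse)
    np.add.at(avg, inverse, values)
    avg /= counts
    logger.info("kriging: averaged %d duplicate coordinates", len(coords) - len(uniq))
    return uniq, avg


def ordinary_kriging(
    values,
    coords,
    model: VariogramModel,
    grid_resolution: float = 0.5,
    bounds: tuple[float, float, float, float] | None = None,
    otu_id: str = "",
    habitat: str = "",
    transect_id: str = "",
) -> KrigedSurface:
    """Krige ``values`` observed at ``coords`` onto a regular grid.

    The grid covers ``bounds = (xmin, xmax, ymin, ymax)`` (default: the
    data bounding box) at ``grid_resolution`` meters.  Requires a
    converged variogram model.  Duplicate coordinates are averaged
    before solving.
    """
    z = np.asarray(values, float)
    pts = np.asarray(coords, float)
    if len(z) != len(pts) or len(z) < 2:
        raise ValueError("need >= 2 data points with matching coordinates")
    if not model.converged:
        raise ValueError("variogram model did not converge; refusing to krige")
    pts, z = _dedupe(pts, z)
    n = len(pts)

    D = cdist(pts, pts)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = model.gamma(D)
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    try:
        lu = lu_factor(A)
    except Exception as exc:  # singular system
        raise ValueError(f"singular kriging system (n={n}): {exc}") from exc

    if bounds is None:
        bounds = (pts[:, 0].min(), pts[:, 0].max(), pts[:, 1].min(), pts[:, 1].max())
    xmin, xmax, ymin, ymax = bounds
    gx = np.arange(xmin, xmax + grid_resolution / 2, grid_resolution)
    gy = np.arange(ymin, ymax + grid_resolution / 2, grid_resolution)
    nodes = np.array([(x, y) for y in gy for x in gx])

    G0 = model.gamma(cdist(pts, nodes))  # n x m
    B = np.vstack([G0, np.ones(len(nodes))])
    sol = lu_solve(lu, B)  # (n+1) x m
    W, mu = sol[:n], sol[n]
    preds = W.T @ z
    var = np.einsum("im,im->m", W, G0) + mu
    se = np.sqrt(np.clip(var, 0.0, None))

    shape = (len(gy), len(gx))
    return KrigedSurface(
        grid_x=gx,
        grid_y=gy,
        predictions=preds.reshape(shape),
        standard_errors=se.reshape(shape),
        model=model,
        otu_id=otu_id,
        habitat=habitat,
        transect_id=transect_id,
    )


def krige_at_points(
    values, coords, model: VariogramModel, points
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary-kriging predictions and standard errors at arbitrary points."""
    z = np.asarray(values, float)
    pts = np.asarray(coords, float)
    pts, z = _dedupe(pts, z)
    n = len(pts)
    nodes = np.asarray(points, float)
    D = cdist(pts, pts)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = model.gamma(D)
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    lu = lu_factor(A)
    G0 = model.gamma(cdist(pts, nodes))
    B = np.vstack([G0, np.ones(len(nodes))])
    sol = lu_solve(lu, B)
    W, mu = sol[:n], sol[n]
    preds = W.T @ z
    var = np.einsum("im,im->m", W, G0) + mu
    return preds, np.sqrt(np.clip(var, 0.0, None))


def kriging_weights(pts: np.ndarray, model: VariogramModel, node: np.ndarray):
    """Solve one ordinary-kriging system; returns (weights, mu). Exposed for checks."""
    pts = np.asarray(pts, float)
    n = len(pts)
    D = cdist(pts, pts)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = model.gamma(D)
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    b = np.empty(n + 1)
    b[:n] = model.gamma(cdist(pts, node[None, :]))[:, 0]
    b[n] = 1.0
    sol = np.linalg.solve(A, b)
    return sol[:n], sol[n]


def paired_surface_maps(
    table: SpatialOtuTable,
    classifications: list[OtuClassification],
    estimates: list[RangeEstimate],
    grid_resolution: float = 0.5,
    bounds: tuple[float, float, float, float] | None = None,
) -> pd.DataFrame:
    """Coupled soil/phylloplane kriged maps for qualifying generalists.

    An (otu, transect) qualifies when the OTU is a generalist there and
    holds a surviving (screened, non-culled, non-outlier, converged)
    range estimate in *both* habitats.  For each qualifying pair both
    habitats are kriged on a shared grid and the Pearson correlation of
    the two prediction rasters summarizes cross-habitat synchrony.

    Returns a DataFrame with columns otu_id, transect, raster_correlation,
    soil_surface, phylloplane_surface (surface objects embedded).
    """
    gen = {(c.otu_id, c.transect_id) for c in classifications if c.label == GENERALIST}
    by_key: dict[tuple[str, str, str], RangeEstimate] = {
        (e.otu_id, e.transect_id, e.habitat): e for e in surviving(estimates)
        if e.model.converged
    }
    qualifying = sorted(
        (otu, transect)
        for (otu, transect) in gen
        if all((otu, transect, hab) in by_key for hab in HABITATS)
    )
    if not qualifying:
        logger.info("paired_surface_maps: no qualifying OTUs")
    md = table.metadata
    rows = []
    for otu, transect in qualifying:
        surfaces = {}
        for hab in HABITATS:
            sids = md.index[(md["transect"] == transect) & (md["habitat"] == hab)]
            coords = md.loc[sids, ["x", "y"]].to_numpy(float)
            values = table.abundance.loc[sids, otu].to_numpy(float)
            est = by_key[(otu, transect, hab)]
            surfaces[hab] = ordinary_kriging(
                values, coords, est.model,
                grid_resolution=grid_resolution, bounds=bounds,
                otu_id=otu, habitat=hab, transect_id=transect,
            )
        a = surfaces[HABITATS[0]].predictions.ravel()
        b = surfaces[HABITATS[1]].predictions.ravel()
        if a.std() == 0 or b.std() == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(a, b)[0, 1])
        rows.append(
            {
                "otu_id": otu,
                "transect": transect,
                "raster_correlation": r,
                "soil_surface": surfaces[HABITATS[0]],
                "phylloplane_surface": surfaces[HABITATS[1]],
            }
        )
    return pd.DataFrame(
        rows, columns=["otu_id", "transect", "raster_correlation", "soil_surface", "phylloplane_surface"]
    )


def render_surface_pair(soil: KrigedSurface, phyllo: KrigedSurface, path) -> None:
    """Render a coupled map pair (dark = low, light = high abundance)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(6, 8), sharey=True)
    for ax, surf, title in ((axes[0], soil, "soil"), (axes[1], phyllo, "phylloplane")):
        im = ax.pcolormesh(surf.grid_x, surf.grid_y, surf.predictions, cmap="viridis", shading="auto")
        ax.set_title(f"{surf.otu_id}\n{title} ({surf.transect_id})", fontsize=8)
        ax.set_aspect("equal")
        fig.colorbar(im, ax=ax, shrink=0.6)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
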
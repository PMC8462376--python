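"""Inter-habitat spatial autocorrelation via randomized pairing.

At every grid location the design collects a soil and a phylloplane
community.  If the two habitats exchange migrants locally, a phylloplane
community should resemble the soil community *at its own location* more
than soil communities elsewhere.  The test compares the mean Bray-Curtis
dissimilarity of same-location cross-habitat pairs against a null built
from derangements of the location pairing (no pair stays matched), and
reports a two-sample t-test between the observed and randomized pools.
Spatial autocorrelation is called when the observed mean is *smaller*
than the randomized mean with a significant p-value.

Singletons are retained here: this is a community-dissimilarity
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import PHYLLOPLANE, SOIL
from .stats import TestResult, bray_curtis_pairs, t_test_two_sample
from .table import SpatialOtuTable

logger = logging.getLogger(__name__)

__all__ = [
    "PairedHabitatResult",
    "observed_pair_dissimilarities",
    "randomized_pair_dissimilarities",
    "inter_habitat_test",
]


@dataclass(frozen=True)
class PairedHabitatResult:
    """One row of the inter-habitat dissimilarity table."""

    scale_label: str
    observed_mean_bc: float
    randomized_mean_bc: float
    t_statistic: float
    p_value: float
    n_pairs: int
    n_randomizations: int
    seed: int

    @property
    def autocorrelated(self) -> bool:
        """Observed pairs more similar than the null, significantly."""
        return self.observed_mean_bc < self.randomized_mean_bc and self.p_value < 0.05


def _paired_matrices(
    table: SpatialOtuTable, sample_ids: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
    """Soil and phylloplane abundance rows aligned by (transect, location)."""
    md = table.metadata if sample_ids is None else table.metadata.loc[sample_ids]
    keys: dict[tuple[str, int], dict[str, str]] = {}
    for sid, row in md.iterrows():
        keys.setdefault((row["transect"], int(row["location_index"])), {})[row["habitat"]] = sid
    complete = sorted(k for k, v in keys.items() if SOIL in v and PHYLLOPLANE in v)
    incomplete = [k for k, v in keys.items() if len(v) < 2]
    if incomplete:
        logger.warning("skipping %d unpaired locations: %s", len(incomplete), incomplete[:5])
    if not complete:
        raise ValueError("no complete soil/phylloplane pairs in scope")
    soil_ids = [keys[k][SOIL] for k in complete]
    phyllo_ids = [keys[k][PHYLLOPLANE] for k in complete]
    A = table.abundance.loc[soil_ids].to_numpy(float)
    B = table.abundance.loc[phyllo_ids].to_numpy(float)
    return A, B, complete


def observed_pair_dissimilarities(
    table: SpatialOtuTable, sample_ids: list[str] | None = None
) -> np.ndarray:
    """BC between the soil and phylloplane community of each location.

    One value per complete pair, ordered by (transect, location_index).
    """
    A, B, _ = _paired_matrices(table, sample_ids)
    return bray_curtis_pairs(A, B)


def random_derangement(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform random permutation of range(n) with no fixed point."""
    if n < 2:
        raise ValueError("a derangement needs n >= 2")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def randomized_pair_dissimilarities(
    table: SpatialOtuTable,
    sample_ids: list[str] | None = None,
    n_randomizations: int = 99,
    seed: int = 0,
) -> np.ndarray:
    """Null BC values from derangements of the location pairing.

    Each iteration draws a derangement pi of the complete locations and
    emits BC(soil_i, phylloplane_pi(i)) for every i; no same-location
    pair is ever emitted.  The concatenated vector over all iterations
    is returned (length n_pairs * n_randomizations).
    """
    A, B, _ = _paired_matrices(table, sample_ids)
    n = len(A)
    if n < 2:
        raise ValueError("randomized pairing needs at least 2 complete pairs")
    rng = np.random.default_rng(seed)
    out = [bray_curtis_pairs(A, B[random_derangement(rng, n)]) for _ in range(n_randomizations)]
    return np.concatenate(out)


def inter_habitat_test(
    table: SpatialOtuTable,
    scale: str = "both",
    n_randomizations: int = 99,
    seed: int = 0,
) -> list[PairedHabitatResult]:
    """Observed vs randomized cross-habitat dissimilarity at one or two scales.

    ``scale`` is "entire_study", "per_transect" or "both".  At the study
    scale the derangement runs over all locations of all transects; at
    the transect scale it is confined within each transect.  The
    t-statistic and two-sided p come from a Welch t-test between the
    observed and the pooled randomized vectors.
    """
    results = []
    jobs: list[tuple[str, list[str] | None]] = []
    if scale in ("entire_study", "both"):
        jobs.append(("entire_study", None))
    if scale in ("per_transect", "both"):
        for t in table.transects():
            jobs.append((f"transect:{t}", table.samples_where(transect=t)))
    if not jobs:
        raise ValueError("scale must be 'entire_study', 'per_transect' or 'both'")

    for i, (label, scope) in enumerate(jobs):
        obs = observed_pair_dissimilarities(table, scope)
        rand = randomized_pair_dissimilarities(
            table, scope, n_randomizations=n_randomizations, seed=seed + i
        )
        tt: TestResult = t_test_two_sample(obs, rand, variant="welch")
        results.append(
            PairedHabitatResult(
                scale_label=label,
                observed_mean_bc=float(obs.mean()),
                randomized_mean_bc=float(rand.mean()),
                t_statistic=tt.statistic,
                p_value=tt.p_value,
                n_pairs=len(obs),
                n_randomizations=n_randomizations,
                seed=seed + i,
            )
        )
    return results


def results_to_frame(results: list[PairedHabitatResult]) -> pd.DataFrame:
    """Tabular form of the inter-habitat test, one row per scale."""
    return pd.DataFrame(
        [
            {
                "scale": r.scale_label,
                "observed_mean_bc": r.observed_mean_bc,
                "randomized_mean_bc": r.randomized_mean_bc,
                "t": r.t_statistic,
                "p": r.p_value,
                "n_pairs": r.n_pairs,
                "n_randomizations": r.n_randomizations,
                "autocorrelated": r.autocorrelated,
            }
            for r in results
        ]
    )
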
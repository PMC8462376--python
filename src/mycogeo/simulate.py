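"""Synthetic paired-habitat OTU tables with known spatial ground truth.

The generator emulates the grid-transect, two-habitat sampling design:
each OTU's log-abundance over a transect is a zero-mean Gaussian random
field with an exponential covariance, generalists share a latent field
between soil and phylloplane through a mixing coefficient rho, and
specialists carry a field in their home habitat only (identically zero
elsewhere).  Observed counts are Poisson (or negative-binomial) draws
around exp(base + Z - offset), so sparsity, depth and autocorrelation
are all controllable and every downstream inference can be checked
against the ground truth the generator wrote down.

Covariance convention: the latent field uses C(h) = sill * exp(-h / a)
with range parameter ``a``; the corresponding semivariogram reaches 95%
of its sill at the *effective range* 3a, which is the quantity the
variography module reports.  ``SyntheticParams.true_range`` is therefore
an effective range and is divided by 3 internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import HABITATS, PHYLLOPLANE, SOIL, StudyDesign
from .table import SpatialOtuTable

__all__ = [
    "SyntheticParams",
    "simulate_gaussian_random_field",
    "simulate_latent_fields",
    "simulate_coupled_transect",
    "simulate_study",
]

_JITTER = 1e-10  # relative diagonal jitter before factorization


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs of the synthetic study.

    ``true_range`` is the effective range (meters at 95% of sill) of the
    latent exponential field; ``coupling_rho`` is the cross-habitat
    correlation of generalists' latent fields; ``detection_offset``
    shifts log-intensity downward, controlling sparsity/occupancy;
    ``base_log_abundance`` sets overall depth and ``abundance_sd`` the
    standard deviation of per-OTU log-abundance offsets (0 = all taxa
    equally abundant on average; > 0 adds the interspecific abundance
    heterogeneity real OTU tables show).
    """

    design: StudyDesign = field(default_factory=StudyDesign)
    n_soil_specialists: int = 20
    n_phyllo_specialists: int = 20
    n_generalists: int = 20
    sill: float = 1.0
    true_range: float = 6.0
    coupling_rho: float = 0.8
    base_log_abundance: float = 2.0
    abundance_sd: float = 0.0
    detection_offset: float = 1.0
    noise_model: str = "poisson"
    nb_dispersion: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sill <= 0:
            raise ValueError("sill must be > 0")
        if self.true_range <= 0:
            raise ValueError("true_range must be > 0")
        if min(self.n_soil_specialists, self.n_phyllo_specialists, self.n_generalists) < 0:
            raise ValueError("OTU counts must be >= 0")
        if abs(self.coupling_rho) > 1:
            raise ValueError("|coupling_rho| must be <= 1")
        if self.noise_model not in ("poisson", "negative_binomial"):
            raise ValueError("noise_model must be 'poisson' or 'negative_binomial'")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.abundance_sd < 0:
            raise ValueError("abundance_sd must be >= 0")

    @property
    def range_param(self) -> float:
        """Exponential range parameter a = effective_range / 3."""
        return self.true_range / 3.0


def exponential_covariance(coords, sill: float, range_param: float) -> np.ndarray:
    """C(h) = sill * exp(-h / a) over all pairwise distances, with jitter."""
    pts = np.asarray(coords, dtype=float)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    C = sill * np.exp(-d / range_param)
    C[np.diag_indices_from(C)] += _JITTER * sill
    return C


def _field_factor(coords, sill: float, range_param: float) -> np.ndarray:
    C = exponential_covariance(coords, sill, range_param)
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance not positive definite after jitter "
            f"(n={len(C)}, sill={sill}, range_param={range_param}); "
            "co-located points may need averaging"
        ) from exc


def simulate_gaussian_random_field(coords, sill, range_param, seed) -> np.ndarray:
    """One draw from the zero-mean GRF with exponential covariance.

    Deterministic given the seed; a single point reduces to one draw
    from Normal(0, sill).
    """
    pts = np.asarray(coords, dtype=float)
    if pts.size == 0:
        raise ValueError("need at least one coordinate")
    rng = np.random.default_rng(seed)
    L = _field_factor(pts, sill, range_param)
    return L @ rng.standard_normal(len(pts))


def _otu_roster(params: SyntheticParams) -> pd.DataFrame:
    rows = []
    for i in range(params.n_soil_specialists):
        rows.append((f"OTU_S{i + 1:03d}", "soil_specialist", SOIL))
    for i in range(params.n_phyllo_specialists):
        rows.append((f"OTU_P{i + 1:03d}", "phylloplane_specialist", PHYLLOPLANE))
    for i in range(params.n_generalists):
        rows.append((f"OTU_G{i + 1:03d}", "generalist", "both"))
    return pd.DataFrame(rows, columns=["otu_id", "class", "habitat"])


def _draw_counts(rng: np.random.Generator, lam: np.ndarray, params: SyntheticParams) -> np.ndarray:
    if params.noise_model == "poisson":
        return rng.poisson(lam)
    k = params.nb_dispersion
    return rng.negative_binomial(k, k / (k + lam))


def simulate_latent_fields(
    params: SyntheticParams, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Latent log-abundance fields for one transect.

    For each generalist the soil field Z_s and an independent field
    Z_ind share the covariance; the phylloplane field is
    Z_p = rho * Z_s + sqrt(1 - rho^2) * Z_ind, so rho = 1 duplicates the
    soil field exactly and rho = 0 decouples the habitats.  Specialists
    get a field in their home habitat only.  Returns
    (latents, active): habitat -> n_locations x n_otus matrix, and
    habitat -> boolean activity mask per OTU.
    """
    design = params.design
    coords = design.grid_coordinates()
    n_loc = len(coords)
    L = _field_factor(coords, params.sill, params.range_param)
    roster = _otu_roster(params)
    rho = params.coupling_rho
    latents = {SOIL: np.zeros((n_loc, len(roster))), PHYLLOPLANE: np.zeros((n_loc, len(roster)))}
    active = {SOIL: np.zeros(len(roster), bool), PHYLLOPLANE: np.zeros(len(roster), bool)}
    for j, row in roster.iterrows():
        if row["class"] == "generalist":
            z_s = L @ rng.standard_normal(n_loc)
            z_ind = L @ rng.standard_normal(n_loc)
            latents[SOIL][:, j] = z_s
            latents[PHYLLOPLANE][:, j] = rho * z_s + np.sqrt(1 - rho**2) * z_ind
            active[SOIL][j] = active[PHYLLOPLANE][j] = True
        else:
            home = row["habitat"]
            latents[home][:, j] = L @ rng.standard_normal(n_loc)
            active[home][j] = True
    return latents, active


def simulate_coupled_transect(
    params: SyntheticParams,
    transect_id: str,
    rng: np.random.Generator | None = None,
    otu_base_offsets: np.ndarray | None = None,
) -> SpatialOtuTable:
    """Simulate one transect: paired coordinates, coupled latent fields.

    Counts are drawn per noise model around
    lambda = exp(base + b_j + Z - offset), where b_j is the OTU's fixed
    log-abundance offset (N(0, abundance_sd^2); a species-level trait
    shared across transects when drawn by :func:`simulate_study`).  An
    OTU's abundance outside its home habitat is exactly 0.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    design = params.design
    coords = design.grid_coordinates()
    n_loc = len(coords)
    roster = _otu_roster(params)
    if otu_base_offsets is None:
        otu_base_offsets = (
            rng.normal(0.0, params.abundance_sd, len(roster))
            if params.abundance_sd > 0
            else np.zeros(len(roster))
        )
    fields, active = simulate_latent_fields(params, rng)

    sample_rows, meta_rows, count_rows = [], [], []
    for habitat in HABITATS:
        lam = np.exp(
            params.base_log_abundance
            + otu_base_offsets[None, :]
            + fields[habitat]
            - params.detection_offset
        )
        lam = lam * active[habitat][None, :]  # inactive habitat: exactly 0
        counts = np.where(active[habitat][None, :], _draw_counts(rng, lam, params), 0)
        for loc in range(n_loc):
            sid = f"{transect_id}_L{loc:02d}_{habitat}"
            sample_rows.append(sid)
            x, y = coords[loc]
            meta_rows.append((transect_id, habitat, loc, x, y))
            count_rows.append(counts[loc])

    abundance = pd.DataFrame(
        np.asarray(count_rows, dtype=np.int64),
        index=pd.Index(sample_rows, name="sample_id"),
        columns=roster["otu_id"].tolist(),
    )
    metadata = pd.DataFrame(
        meta_rows,
        index=pd.Index(sample_rows, name="sample_id"),
        columns=["transect", "habitat", "location_index", "x", "y"],
    )
    return SpatialOtuTable(abundance, metadata)


def simulate_study(params: SyntheticParams) -> tuple[SpatialOtuTable, pd.DataFrame]:
    """Simulate the full multi-transect study plus its ground-truth table.

    Returns the concatenated count table (locations x 2 habitats x
    n_transects samples) and a DataFrame with columns otu_id, class,
    habitat, true_range_m, coupling_rho.
    """
    rng = np.random.default_rng(params.seed)
    n_otus = (
        params.n_soil_specialists + params.n_phyllo_specialists + params.n_generalists
    )
    # species-level abundance offsets: one draw per OTU, shared across transects
    offsets = (
        rng.normal(0.0, params.abundance_sd, n_otus)
        if params.abundance_sd > 0
        else np.zeros(n_otus)
    )
    tables = [
        simulate_coupled_transect(params, tid, rng=rng, otu_base_offsets=offsets)
        for tid in params.design.transect_ids()
    ]
    abundance = pd.concat([t.abundance for t in tables], axis=0)
    metadata = pd.concat([t.metadata for t in tables], axis=0)
    table = SpatialOtuTable(abundance, metadata)

    truth = _otu_roster(params).copy()
    truth["true_range_m"] = params.true_range
    truth["coupling_rho"] = np.where(truth["class"] == "generalist", params.coupling_rho, np.nan)
    return table, truth


def with_seed(params: SyntheticParams, seed: int) -> SyntheticParams:
    """Convenience: same study conditions under a different seed."""
    return replace(params, seed=int(seed))
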
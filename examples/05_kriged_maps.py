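"""Coupled kriged distribution maps for generalist OTUs.

For a generalist screened as spatially autocorrelated in both habitats
of the same transect, ordinary kriging interpolates its abundance over
the transect grid separately per habitat; the correlation of the two
prediction rasters measures cross-habitat synchrony of the OTU's
spatial distribution.
"""

from mycogeo import (
    StudyDesign,
    SyntheticParams,
    classify_otus,
    paired_surface_maps,
    remove_singletons,
    simulate_study,
)
from mycogeo.variogram import RangeEstimate, VariogramModel

params = SyntheticParams(
    design=StudyDesign(n_transects=1),
    n_soil_specialists=0, n_phyllo_specialists=0, n_generalists=3,
    coupling_rho=0.95, base_log_abundance=3.0, detection_offset=0.0, seed=5,
)
table, _ = simulate_study(params)
normalized = remove_singletons(table).log1p_normalized()
classifications = classify_otus(normalized)

# a fixed fitted model keeps the example focused on the kriging step
model = VariogramModel(sill=1.0, range_param=2.0, sse=0.0, converged=True)
estimates = [
    RangeEstimate(o, "T1", h, "generalist", model.effective_range, model)
    for o in normalized.otu_ids
    for h in ("soil", "phylloplane")
]
maps = paired_surface_maps(normalized, classifications, estimates, grid_resolution=1.0)

for _, row in maps.iterrows():
    surf = row["soil_surface"]
    print(f"{row['otu_id']}  grid {surf.predictions.shape}  "
          f"raster correlation soil~phylloplane: {row['raster_correlation']:.2f}")
print(
    "\nHigh raster correlations mean the OTU occupies the same parts of the\n"
    "transect above and below ground -- coupled distributions."
)
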
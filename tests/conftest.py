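"""Shared fixtures: tiny hand-built tables and scaled synthetic studies."""

import numpy as np
import pandas as pd
import pytest

from mycogeo import SpatialOtuTable, StudyDesign, SyntheticParams


def make_table(abundance_rows, meta_rows, otu_ids=None, normalized=False):
    """Build a SpatialOtuTable from plain lists.

    ``meta_rows`` are (sample_id, transect, habitat, location_index, x, y).
    """
    sample_ids = [m[0] for m in meta_rows]
    n_otus = len(abundance_rows[0])
    if otu_ids is None:
        otu_ids = [f"OTU{j + 1}" for j in range(n_otus)]
    abundance = pd.DataFrame(abundance_rows, index=pd.Index(sample_ids, name="sample_id"),
                             columns=otu_ids, dtype=float)
    metadata = pd.DataFrame(
        [m[1:] for m in meta_rows],
        index=pd.Index(sample_ids, name="sample_id"),
        columns=["transect", "habitat", "location_index", "x", "y"],
    )
    return SpatialOtuTable(abundance, metadata, normalized=normalized)


@pytest.fixture
def toy_paired_table():
    """Two locations in one transect, both habitats, 3 OTUs."""
    meta = [
        ("s0", "T1", "soil", 0, 0.0, 0.0),
        ("s1", "T1", "soil", 1, 5.0, 0.0),
        ("p0", "T1", "phylloplane", 0, 0.0, 0.0),
        ("p1", "T1", "phylloplane", 1, 5.0, 0.0),
    ]
    counts = [
        [1, 2, 3],
        [4, 0, 1],
        [3, 2, 1],
        [0, 5, 0],
    ]
    return make_table(counts, meta)


@pytest.fixture
def small_params():
    """Small but fully featured synthetic study (2 transects, 15 OTUs)."""
    return SyntheticParams(
        design=StudyDesign(n_transects=2),
        n_soil_specialists=5,
        n_phyllo_specialists=5,
        n_generalists=5,
        seed=11,
    )


@pytest.fixture
def field_design_params():
    """The full 6-transect, 36-location, 2-habitat design."""
    return SyntheticParams(seed=5)


@pytest.fixture
def dense_grid_coords():
    """20 x 20 grid at 1 m spacing for field-level checks."""
    return [(float(i), float(j)) for j in range(20) for i in range(20)]
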
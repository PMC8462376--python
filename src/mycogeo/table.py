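"""The spatial OTU table: abundances joined to sample geography.

``SpatialOtuTable`` is the universal input of the pipeline: a samples x
OTUs abundance matrix (raw counts or normalized reals) together with
per-sample metadata placing each sample on a transect grid and in one of
the two habitats.  Samples from the two habitats are paired through a
shared ``location_index`` and must then share coordinates exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import HABITATS

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ["sample_id", "transect", "habitat", "location_index", "x", "y"]


class ValidationError(ValueError):
    """Raised when an input table violates the spatial-table contract."""


@dataclass(frozen=True)
class SpatialOtuTable:
    """Samples x OTUs abundance matrix with per-sample spatial metadata.

    Attributes
    ----------
    abundance:
        DataFrame indexed by sample id with OTU ids as columns; entries
        are non-negative counts or normalized values.
    metadata:
        DataFrame indexed by sample id with columns transect, habitat,
        location_index, x, y.
    normalized:
        True when abundances are normalized reals rather than raw counts.
    """

    abundance: pd.DataFrame
    metadata: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        _validate(self.abundance, self.metadata)

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_otus(self) -> int:
        return self.abundance.shape[1]

    def values(self) -> np.ndarray:
        return self.abundance.to_numpy(dtype=float)

    def transect_of(self, sample_id: str) -> str:
        return self.metadata.at[sample_id, "transect"]

    def habitat_of(self, sample_id: str) -> str:
        return self.metadata.at[sample_id, "habitat"]

    def coord_of(self, sample_id: str) -> tuple[float, float]:
        row = self.metadata.loc[sample_id]
        return float(row["x"]), float(row["y"])

    def location_index_of(self, sample_id: str) -> int:
        return int(self.metadata.at[sample_id, "location_index"])

    def transects(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.metadata["transect"]:
            seen.setdefault(t, None)
        return list(seen)

    # -- views -----------------------------------------------------------
    def subset_samples(self, sample_ids: list[str]) -> "SpatialOtuTable":
        return SpatialOtuTable(
            self.abundance.loc[sample_ids],
            self.metadata.loc[sample_ids],
            normalized=self.normalized,
        )

    def samples_where(self, transect: str | None = None, habitat: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.metadata.index)
        if transect is not None:
            mask &= self.metadata["transect"] == transect
        if habitat is not None:
            mask &= self.metadata["habitat"] == habitat
        return list(self.metadata.index[mask])

    def presence(self) -> pd.DataFrame:
        """Boolean presence matrix; present means abundance strictly > 0."""
        return self.abundance > 0

    def log1p_normalized(self) -> "SpatialOtuTable":
        """Variance-stabilized view: log(1 + abundance), flagged normalized."""
        return SpatialOtuTable(np.log1p(self.abundance), self.metadata, normalized=True)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions; rows with zero total stay all-zero."""
        totals = self.abundance.sum(axis=1)
        safe = totals.replace(0, np.nan)
        rel = self.abundance.div(safe, axis=0).fillna(0.0)
        return rel


def _validate(abundance: pd.DataFrame, metadata: pd.DataFrame) -> None:
    if abundance.index.has_duplicates:
        dups = abundance.index[abundance.index.duplicated()].tolist()
        raise ValidationError(f"duplicate sample ids in abundance table: {dups}")
    if abundance.columns.has_duplicates:
        dups = abundance.columns[abundance.columns.duplicated()].tolist()
        raise ValidationError(f"duplicate OTU ids: {dups}")
    if metadata.index.has_duplicates:
        dups = metadata.index[metadata.index.duplicated()].tolist()
        raise ValidationError(f"duplicate sample ids in metadata: {dups}")
    missing = [c for c in METADATA_COLUMNS[1:] if c not in metadata.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    only_ab = set(abundance.index) - set(metadata.index)
    only_md = set(metadata.index) - set(abundance.index)
    if only_ab or only_md:
        raise ValidationError(
            "samples present in only one file: "
            f"abundance-only={sorted(only_ab)}, metadata-only={sorted(only_md)}"
        )
    if abundance.size:
        vals = abundance.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("abundance table contains non-numeric entries")
        if np.isnan(vals).any():
            bad = abundance.index[np.isnan(vals).any(axis=1)].tolist()
            raise ValidationError(f"abundance contains missing values in samples {bad}")
        if (vals < 0).any():
            bad = abundance.index[(vals < 0).any(axis=1)].tolist()
            raise ValidationError(f"negative abundance in samples {bad}")
    bad_hab = metadata.index[~metadata["habitat"].isin(HABITATS)].tolist()
    if bad_hab:
        labels = metadata.loc[bad_hab, "habitat"].tolist()
        raise ValidationError(
            f"habitat label outside {set(HABITATS)} in samples {bad_hab}: {labels}"
        )
    # paired design: one sample per (transect, location, habitat); shared coords
    key = metadata[["transect", "location_index", "habitat"]]
    if key.duplicated().any():
        bad = metadata.index[key.duplicated()].tolist()
        raise ValidationError(
            f"(transect, location_index, habitat) occurs more than once: samples {bad}"
        )
    for (_, _), grp in metadata.groupby(["transect", "location_index"], sort=False):
        if len(grp) > 1:
            xs, ys = grp["x"].to_numpy(float), grp["y"].to_numpy(float)
            if np.ptp(xs) > 1e-9 or np.ptp(ys) > 1e-9:
                raise ValidationError(
                    f"paired samples {grp.index.tolist()} share a location index "
                    "but have different coordinates"
                )


def read_spatial_otu_table(
    abundance_path, metadata_path, normalized: bool = False
) -> SpatialOtuTable:
    """Read the TSV pair (abundance matrix, sample metadata) and validate.

    The abundance file is a tab-separated samples x OTUs matrix whose
    header row holds OTU ids and whose first column holds sample ids.
    The metadata file has columns sample_id, transect, habitat,
    location_index, x, y.
    """
    abundance = pd.read_csv(abundance_path, sep="\t", index_col=0)
    abundance.index = abundance.index.astype(str)
    abundance.columns = abundance.columns.astype(str)
    metadata = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str, "transect": str})
    if "sample_id" not in metadata.columns:
        raise ValidationError("metadata missing columns: ['sample_id']")
    metadata = metadata.set_index("sample_id")
    table = SpatialOtuTable(abundance, metadata[METADATA_COLUMNS[1:]], normalized=normalized)
    return table


def write_spatial_otu_table(table: SpatialOtuTable, abundance_path, metadata_path) -> None:
    """Write the TSV pair read back identically by :func:`read_spatial_otu_table`."""
    ab = table.abundance
    if not table.normalized:
        # integer counts round-trip bit-exactly
        ab = ab.astype(np.int64) if _is_integral(ab) else ab
    ab.to_csv(abundance_path, sep="\t", index_label="sample_id", float_format="%.12g")
    md = table.metadata.copy()
    md.to_csv(metadata_path, sep="\t", index_label="sample_id", float_format="%.12g")


def _is_integral(df: pd.DataFrame) -> bool:
    vals = df.to_numpy()
    if not vals.size:
        return True
    return bool(np.all(np.equal(np.mod(vals, 1), 0)))


def remove_singletons(table: SpatialOtuTable) -> SpatialOtuTable:
    """Drop OTUs present (abundance > 0) in exactly one sample study-wide.

    Community-dissimilarity analyses keep singletons; occupancy,
    classification and variography work on the filtered table.  The
    sample set is never changed.
    """
    presence_counts = (table.abundance > 0).sum(axis=0)
    keep = presence_counts != 1
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("remove_singletons: dropped %d singleton OTUs", n_dropped)
        return replace(table, abundance=table.abundance.loc[:, keep])
    return table
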
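"""Packaged reference tables."""

from importlib.resources import files

import pandas as pd

__all__ = ["load_reference_cluster_table"]


def load_reference_cluster_table() -> pd.DataFrame:
    """Published habitat-configuration table for the ten movement
    clusters of the tracked Great Indian Bustard.

    Columns: cluster centroid (lat/lon), footprint area (km²),
    land-cover percentages (builtup/crop/open/others/water), distance
    to the nearest high-tension powerline (m), road density (km/km²)
    and mean NDVI at the cluster start date. Used to validate the
    summary arithmetic of :mod:`gibmove.habitat_summary`.
    """
    path = files(__package__).joinpath("reference_cluster_table.csv")
    with path.open() as fh:
        return pd.read_csv(fh)
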
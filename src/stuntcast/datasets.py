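"""Bundled reference tables.

The only shipped dataset is the published regional summary of the 2007-2010
FSNAU/UNICEF nutrition surveys in Somalia (cluster, children-examined and
children-stunted counts by region and zone).  The cluster-level microdata are
not public; the summary counts are inputs for the observed-prevalence
arithmetic and for format checks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .data_model import ClusterRecord

__all__ = ["load_somalia_summary", "somalia_summary_clusters"]


def load_somalia_summary() -> pd.DataFrame:
    """Regional survey summary counts: zone, region, clusters, examined, stunted."""
    with resources.files("stuntcast.data").joinpath(
        "somalia_fsnau_2007_2010_summary.csv"
    ).open("r") as fh:
        return pd.read_csv(fh)


def somalia_summary_clusters() -> list[ClusterRecord]:
    """The regional summary as one aggregate pseudo-cluster per region.

    Coordinates are placeholders (the microdata are not public); the records
    exist so the observed-prevalence operation can reproduce the published
    percent-stunted column from the counts.
    """
    df = load_somalia_summary()
    return [
        ClusterRecord(
            cluster_id=row.region,
            x=0.5,
            y=0.5,
            year=2007,
            season="Gu",
            n_examined=int(row.n_examined),
            n_stunted=int(row.n_stunted),
            region=row.region,
        )
        for row in df.itertuples()
    ]
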
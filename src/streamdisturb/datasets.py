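"""Bundled reference dataset: the 25-stream survey table.

Site-level characteristics of 25 headwater streams sampled across the
Iguassu and Upper Parana ecoregions: forest land cover (FLC), agricultural
land use (ALU) and urban land use (ULU) as percentages of the catchment,
the Rapid Habitat Diversity Assessment total (RHDA), the Integrated
Disturbance Index (IDI), and chlorophyll-a biomass (ug/L) as a primary
productivity proxy.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["load_streams"]

_STREAMS_CSV = """\
site_id,flc,alu,ulu,rhda,idi,chla
S1,62.4,37.6,0.0,84.0,0.049,0.00
S2,76.0,24.0,0.0,94.0,0.011,0.11
S3,50.0,50.0,0.0,85.6,0.054,0.02
S4,25.2,71.3,3.5,68.6,0.175,0.30
S5,27.0,73.0,0.0,52.0,0.097,0.58
S6,15.9,84.1,0.0,56.3,0.170,0.03
S7,14.9,51.0,34.0,64.3,0.352,0.48
S8,16.5,0.8,82.7,43.3,0.542,1.29
S9,3.0,0.0,97.0,44.6,0.814,0.40
S10,80.3,19.7,0.0,87.3,0.005,0.02
S11,42.4,57.4,0.2,90.0,0.031,0.14
S12,46.1,52.9,0.0,72.6,0.064,0.04
S13,44.9,55.1,0.0,90.0,0.065,0.56
S14,44.8,55.2,0.0,86.6,0.067,0.09
S15,16.9,83.1,0.0,82.3,0.167,0.39
S16,20.7,79.3,0.0,76.3,0.151,0.00
S17,15.8,59.8,24.4,42.0,0.214,0.29
S18,4.5,10.1,85.5,38.3,0.643,0.20
S19,5.9,18.3,75.8,34.6,0.497,1.79
S20,53.4,46.6,0.0,98.0,0.075,0.10
S21,46.9,53.1,0.0,94.3,0.079,0.09
S22,20.1,79.9,0.0,65.0,0.140,0.20
S23,17.2,82.8,0.0,75.0,0.172,0.01
S24,9.0,60.7,30.4,34.0,0.181,2.43
S25,13.3,48.3,38.4,54.0,0.276,0.01
"""


def load_streams() -> pd.DataFrame:
    """Return the 25-stream survey table, indexed by site id.

    Columns: ``flc``, ``alu``, ``ulu`` (percent of catchment), ``rhda``
    (habitat-diversity total), ``idi`` (integrated disturbance index),
    ``chla`` (chlorophyll-a, ug/L).
    """
    return pd.read_csv(io.StringIO(_STREAMS_CSV), index_col="site_id")
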
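"""Packaged screen-result fixtures.

Two small published tables ship with the package: the gene x reporter hit
table of fold decreases in stress-reporter expression (with 'ns' cells for
non-significant results and the '>>>' sentinel for signal indistinguishable
from background), and the strain x RNAi mean-lifespan table from which every
lifespan-extension statistic derives.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _data_path(name: str):
    return resources.files("wormscreen.data").joinpath(name)


def load_hit_table() -> pd.DataFrame:
    """Gene x reporter fold-decrease table (hsp-4, hsp-6, sod-3, gst-4).

    Cells hold printed fold-decrease values as strings, 'ns', or '>>>'; the
    'function' column carries gene annotations.
    """
    with resources.as_file(_data_path("hit_table.tsv")) as p:
        return pd.read_csv(p, sep="\t", index_col="gene", dtype=str)


def load_mean_lifespans() -> pd.DataFrame:
    """Printed mean lifespans (days) per RNAi clone x strain.

    Index is the RNAi clone ('vector' = empty-vector control); columns are
    N2 wild type and the long-lived isp-1;ctb-1, eat-2 and daf-2 mutants.
    """
    with resources.as_file(_data_path("mean_lifespans.csv")) as p:
        return pd.read_csv(p, index_col="rnai")
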
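"""Published LH2 benchmark metric tables for the study conditions this
pipeline models.

The fixture holds the eight-metric rows reported for every
(DR method, feature-selection method, classifier) cell on the Lung Harvard 2
dataset (181 samples: 150 adenocarcinoma, 31 mesothelioma).  The cells are
inputs — used for cross-table aggregation and for reconstructing the
integer confusion matrices behind the printed (accuracy, F1) pairs — never
outputs of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: LH2 cohort composition the reported tables were computed on.
LH2_N, LH2_N_ADENO, LH2_N_MESO = 181, 150, 31


def load_reported_metrics() -> pd.DataFrame:
    """The full reported grid: 3 DR x {none, EHO, CS} x 7 classifiers = 63 rows."""
    with resources.files("mgx.data").joinpath("lh2_reported_metrics.csv").open() as fh:
        return pd.read_csv(fh)


def reported_row(dr: str, fsel: str, classifier: str) -> pd.Series:
    df = load_reported_metrics()
    hit = df[(df.dr == dr) & (df.fsel == fsel) & (df.classifier == classifier)]
    if len(hit) != 1:
        raise KeyError(f"no unique reported row for ({dr}, {fsel}, {classifier})")
    return hit.iloc[0]


def reported_cells(fsel: str, metric: str) -> pd.Series:
    """The 21 cells (3 DR x 7 classifiers) of one metric for one selection condition."""
    df = load_reported_metrics()
    return df[df.fsel == fsel][metric]
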
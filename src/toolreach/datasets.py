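"""Packaged reference data.

``load_pd_clinical`` returns the demographic and clinical table of the
14 patients (age, education in years, disease duration in years, UPDRS
motor score in the on-medication state, Hoehn & Yahr stage, and the
body side most affected).  The printed footer of the published table
reports mean (SD) per column; note that its means are only consistent
with truncation, not rounding (e.g. mean age 66.86 printed as 66) —
see :func:`toolreach.stats.describe` modes.
"""

from importlib import resources

import pandas as pd

__all__ = ["load_pd_clinical"]


def load_pd_clinical() -> pd.DataFrame:
    with resources.files("toolreach").joinpath("data/pd_clinical.csv").open() as fh:
        return pd.read_csv(fh)
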
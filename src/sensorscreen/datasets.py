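"""Packaged reference tables."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_tcs_survey"]


def load_tcs_survey() -> pd.DataFrame:
    """Per-strain grouped-TCS survey across 17 gut bacterial species.

    Columns: strain, total_tcs, grouped, sapi_compatible,
    bsai_compatible_not_sapi, amplified, library1, library2.
    """
    ref = resources.files("sensorscreen") / "data" / "tcs_survey.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
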
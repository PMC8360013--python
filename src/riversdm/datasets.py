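"""Packaged reference tables.

Small published summary tables shipped with the package: national-scale
mean occurrence probabilities of 41 Swiss EPT species for the baseline
(2015-2025), mid-century (2055-2065) and end-century (2080-2090) decades
under the RCP2.6 and RCP8.5 pathways, with the printed relative-change
columns.  They serve as worked-example inputs for the change-table
arithmetic and its order statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_changes"]

_FILES = {
    "RCP2.6": "ept_mean_occurrence_rcp26.csv",
    "RCP8.5": "ept_mean_occurrence_rcp85.csv",
}


def load_reference_changes(scenario: str = "RCP8.5") -> pd.DataFrame:
    """Load the reference occurrence-change table for one pathway.

    Columns: species, p_t1, p_t2, delta_t2_pct, p_t3, delta_t3_pct, where
    the delta columns are the printed relative changes (%) versus the
    baseline decade.
    """
    if scenario not in _FILES:
        raise KeyError(f"unknown scenario {scenario!r}; choose from {sorted(_FILES)}")
    ref = resources.files("riversdm.data") / _FILES[scenario]
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
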
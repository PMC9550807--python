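"""Bundled example datasets.

``ms_family_scores``: the published per-individual weighted sum score,
genome-wide PRS, affection status and age for 37 members of six
consanguineous multiplex MS families (the seventh family of the study had
no genotyped unaffected members and so no within-family listing).  Used as
the worked example for the within-family trend analysis.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_family_scores() -> pd.DataFrame:
    """Per-individual risk-score listing for six multiplex MS families."""
    with resources.files("famburden.data").joinpath(
        "ms_family_scores.tsv"
    ).open("r") as fh:
        return pd.read_csv(fh, sep="\t")
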
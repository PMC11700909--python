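"""Prevalence of inadequate zinc intake against EAR/RDA cutoffs.

Implements the EAR cut-point style screen used in survey work: the
percentage of individuals whose daily zinc intake falls strictly below
a sex-specific cutoff, per age band and pooled per sex.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .dri import DEFAULT_STANDARDS, ReferenceStandards
from .intake import AgeBand, Sex

BAND_ORDER = (AgeBand.Y19_30.value, AgeBand.Y31_50.value, AgeBand.Y51_70.value)


def percent_below(values: Sequence[float], cutoff: float) -> float:
    """Percentage of values strictly below the cutoff.

    A value exactly at the cutoff counts as meeting it (strict "<");
    ties are measure-zero for continuous intake data. Full precision is
    returned; rounding happens at the reporting layer.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("percent_below needs a non-empty sample")
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    return 100.0 * float(np.count_nonzero(arr < cutoff)) / arr.size


def adequacy_table(
    cohort: pd.DataFrame, standards: ReferenceStandards = DEFAULT_STANDARDS
) -> pd.DataFrame:
    """Percent of individuals below each EAR/RDA standard per stratum.

    ``cohort`` needs ``sex``, ``age_band`` and ``zinc_mg`` columns.
    Rows: the three bands per sex plus an ``all``-band total per sex.
    Empty strata yield n = 0 with NaN percentages. The containment
    invariant (below-EAR <= below-RDA within a source) holds by
    construction because each RDA exceeds its EAR.
    """
    rows = []
    for sex in (Sex.MALE, Sex.FEMALE):
        sex_mask = cohort["sex"] == sex.value
        for band in BAND_ORDER + (AgeBand.ALL.value,):
            mask = sex_mask if band == AgeBand.ALL.value else (
                sex_mask & (cohort["age_band"] == band)
            )
            zinc = cohort.loc[mask, "zinc_mg"]
            row = {"sex": sex.value, "age_band": band, "n": int(mask.sum())}
            for source in ("iom", "col"):
                for kind in ("ear", "rda"):
                    cutoff = getattr(standards, f"{source}_{kind}_{sex.value}")
                    key = f"pct_below_{source}_{kind}"
                    row[key] = percent_below(zinc, cutoff) if row["n"] else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
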
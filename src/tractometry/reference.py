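"""Published cohort summary statistics used as re-computation inputs.

The packaged table holds the group means, standard deviations and sample
sizes (490 men, 575 women) of total brain volume, white-matter volume and
the TBV-normalized volumes of the white matter tracts reported
significantly different between the sexes in the 1065-subject HCP
young-adult cohort study.  The effect sizes and relative differences are
recomputed from these summaries by :mod:`tractometry.stats`; the
``printed_*`` columns carry the originally published (rounded) values for
cross-checking only.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_cohort_summary", "recompute_published_effects"]


def load_cohort_summary() -> pd.DataFrame:
    with resources.files("tractometry.data").joinpath("hcp_cohort_summary.tsv").open() as f:
        return pd.read_csv(f, sep="\t")


def recompute_published_effects() -> pd.DataFrame:
    """Cohen's d and relative difference recomputed from the summaries."""
    from .stats import cohens_d, effect_bin, relative_difference

    df = load_cohort_summary().copy()
    df["cohens_d"] = [
        cohens_d(r.mean_m, r.sd_m, r.n_m, r.mean_f, r.sd_f, r.n_f) for r in df.itertuples()
    ]
    df["effect_bin"] = [effect_bin(d) for d in df["cohens_d"]]
    df["relative_difference_pct"] = [
        relative_difference(r.mean_m, r.mean_f) for r in df.itertuples()
    ]
    return df
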
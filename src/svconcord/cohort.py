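"""Reference cohort concordance table and its summary arithmetic.

The package ships the per-comparison rearrangement and copy-number
concordance counts of an 11-patient breast cancer primary/metastasis WGS
cohort (two directional rows per comparison: each tumor's total, the
pair's shared count, and the tumor's specific count, plus one CN
similarity percentage per comparison).  These counts are inputs; all
percentages and summary statistics are recomputed from them with the
package's reporting arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .compare import round_half_away, summarize_rows


def load_reference_cohort() -> pd.DataFrame:
    """The shipped cohort table, with roles derived from sample labels
    (P* = primary, M* = metastasis) and directional percentages
    recomputed from the counts."""
    with resources.files("svconcord.data").joinpath(
        "breast_cohort_rearrangements.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["role"] = df["sample"].map(lambda s: "primary" if s.startswith("P") else "metastasis")
    df["paired_role"] = df["paired_sample"].map(
        lambda s: "primary" if s.startswith("P") else "metastasis"
    )
    df["matched"] = True
    df["pct_shared"] = 100.0 * df["shared"] / df["total"]
    df["pct_shared_rounded"] = df["pct_shared"].map(round_half_away)
    return df


def reference_summary() -> dict:
    """Cohort summary recomputed from the shipped counts."""
    return summarize_rows(load_reference_cohort())


def directional_pct(shared: int, total: int) -> int:
    """Reported directional shared percentage for one table row."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_away(100.0 * shared / total)
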
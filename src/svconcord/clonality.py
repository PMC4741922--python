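"""Coverage-normalized read-support ("clonality") tables for the shared
rearrangements of a tumor pair.

Read support is a proxy for the clonal fraction of an event; dividing by
the sample's overall sequence coverage makes supports comparable between
samples sequenced to different depths.  Plotting metastasis against
primary puts fully clonal shared events on the identity diagonal, while
a subclone amplified (or expanded) k-fold in the metastasis lines its
events up along a slope-k diagonal.
"""

from __future__ import annotations

import pandas as pd

from .compare import PairComparison
from .model import SampleMeta


def clonality_table(
    pc: PairComparison,
    meta_a: SampleMeta,
    meta_b: SampleMeta,
    use_physical: bool = False,
) -> pd.DataFrame:
    """One row per shared rearrangement with per-sample normalized
    support.

    Supports for rescued / looked-up sides come from the partner's raw
    call or evidence count (>= 1 by construction; a zero is floored to 1
    since a shared call implies at least one observed read pair).
    Interchromosomal events contribute one row, flagged ``two_sided`` for
    plotting both breakpoint sides.
    """
    cov_a = meta_a.physical_coverage if use_physical else meta_a.sequence_coverage
    cov_b = meta_b.physical_coverage if use_physical else meta_b.sequence_coverage
    if cov_a <= 0 or cov_b <= 0:
        raise ValueError("coverage must be positive for clonality normalization")
    rows = []
    for k, p in enumerate(pc.shared_pairs):
        rep = p.representative()
        sup_a = max(1, p.support_a)
        sup_b = max(1, p.support_b)
        rows.append(
            {
                "event": f"e{k}",
                "chrom_left": rep.left.chrom,
                "pos_left": rep.left.pos,
                "chrom_right": rep.right.chrom,
                "pos_right": rep.right.pos,
                "sv_type": rep.sv_type,
                "provenance": p.provenance,
                "support_a": sup_a,
                "support_b": sup_b,
                "norm_support_a": sup_a / cov_a,
                "norm_support_b": sup_b / cov_b,
                "two_sided": rep.sv_type == "CTX",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event", "chrom_left", "pos_left", "chrom_right", "pos_right",
            "sv_type", "provenance", "support_a", "support_b",
            "norm_support_a", "norm_support_b", "two_sided",
        ],
    )


def plot_clonality(table: pd.DataFrame, path: str, label_a: str = "primary",
                   label_b: str = "metastasis") -> None:
    """Scatter of normalized support, partner sample against the first."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    intra = table[~table["two_sided"]]
    ctx = table[table["two_sided"]]
    ax.scatter(intra["norm_support_a"], intra["norm_support_b"], marker="o", s=18,
               label="intrachromosomal")
    if len(ctx):
        ax.scatter(ctx["norm_support_a"], ctx["norm_support_b"], marker="x", s=22,
                   label="interchromosomal")
    lim = max(table["norm_support_a"].max(), table["norm_support_b"].max(), 1.0) * 1.05
    ax.plot([0, lim], [0, lim], lw=0.8, color="grey")
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel(f"normalized support, {label_a}")
    ax.set_ylabel(f"normalized support, {label_b}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
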
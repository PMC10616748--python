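"""The published 16-miRNA worked-example signature table.

A small packaged table of circulating miRNAs differentially expressed in
early pregnancy under both preeclampsia and vitamin-D insufficiency
(direction of regulation, linear fold change, FDR), used as the worked
example for signature-level summaries. One entry is printed without its
arm suffix in the source table ("hsa-miR-31-5"); it is kept verbatim and
handled by name normalization.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_signature_table", "signature_summary"]


def load_signature_table() -> pd.DataFrame:
    """Load the packaged signature table.

    Columns: ``mirna``, ``regulation`` (Upregulated/Downregulated),
    ``fold_change`` (linear, case vs control), ``fdr``.
    """
    with resources.files("premodmir.data").joinpath("pe_vitd_signature.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def signature_summary(table: pd.DataFrame | None = None) -> dict:
    """Headline statistics of a signature table.

    Returns row count, percentage upregulated, min/max fold change, and a
    per-miRNA fold-change lookup.
    """
    if table is None:
        table = load_signature_table()
    up = table["regulation"].str.lower().str.startswith("up")
    return {
        "n_rows": int(len(table)),
        "pct_upregulated": 100.0 * float(up.mean()),
        "max_fold_change": float(table["fold_change"].max()),
        "min_fold_change": float(table["fold_change"].min()),
        "fold_change_by_mirna": dict(zip(table["mirna"], table["fold_change"].astype(float))),
    }
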
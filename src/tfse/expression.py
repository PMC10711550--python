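"""Relative expression from qPCR Ct tables by the comparative 2^−ΔΔCt method.

Per condition, replicate Cts are averaged on the Ct scale, then
ΔCt = Ct(target) − Ct(reference), ΔΔCt = ΔCt(condition) − ΔCt(control),
fold change = 2^−ΔΔCt and log2FC = −ΔΔCt.  The control condition's fold is
1 by construction, and a constant plate offset added to every Ct of a
sample cancels in ΔCt.  Per-replicate folds (samples paired within a
condition) are also computed so error bars (SEM) can be drawn.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ddct_fold_change"]

REQUIRED_COLUMNS = ["sample", "condition", "gene", "ct"]


def ddct_fold_change(
    table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    control_condition: str,
) -> pd.DataFrame:
    """2^−ΔΔCt fold changes of ``target_gene`` per condition vs the control.

    ``table`` needs columns sample, condition, gene, ct (case-insensitive
    names accepted).  Every sample must carry a reference-gene Ct.
    Returns one row per condition with columns condition, gene, dct,
    ddct, fold, log2fc, sem, n_replicates.
    """
    df = table.copy()
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if np.any(df["ct"] <= 0):
        raise ValueError("Ct values must be positive cycle numbers")
    conditions = df["condition"].unique().tolist()
    if control_condition not in conditions:
        raise ValueError(
            f"control condition {control_condition!r} not in table "
            f"(has: {conditions})"
        )

    def gene_ct(sub: pd.DataFrame, gene: str, what: str) -> pd.Series:
        g = sub[sub["gene"] == gene]
        if g.empty:
            raise ValueError(f"{what}: no Ct rows for gene {gene!r}")
        return g.groupby("sample")["ct"].mean()

    # per-sample ΔCt so plate offsets cancel within a sample
    per_sample: dict[str, pd.Series] = {}
    for cond in conditions:
        sub = df[df["condition"] == cond]
        tgt = gene_ct(sub, target_gene, f"condition {cond!r}")
        ref = gene_ct(sub, reference_gene, f"condition {cond!r} (reference)")
        if not set(tgt.index).issubset(set(ref.index)):
            raise ValueError(
                f"condition {cond!r}: samples missing a reference-gene Ct: "
                f"{sorted(set(tgt.index) - set(ref.index))}"
            )
        per_sample[cond] = tgt - ref.loc[tgt.index]

    dct_control = float(per_sample[control_condition].mean())
    rows = []
    for cond in conditions:
        dct = float(per_sample[cond].mean())
        ddct = dct - dct_control
        rep_folds = np.power(2.0, -(per_sample[cond] - dct_control))
        n = len(rep_folds)
        sem = float(rep_folds.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append(
            {
                "condition": cond,
                "gene": target_gene,
                "dct": dct,
                "ddct": ddct,
                "fold": 2.0 ** (-ddct),
                "log2fc": -ddct,
                "sem": sem,
                "n_replicates": n,
            }
        )
    return pd.DataFrame(rows)
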
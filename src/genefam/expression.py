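"""Expression post-processing: atlas transform, breadth classes, ΔΔCt.

The RNA-seq side works on a gene × tissue FPKM matrix: entries are
log2(FPKM+1)-transformed for heatmapping, and each gene is classed by
expression breadth (silent / restricted / constitutive) against an
"expressed" threshold.  The qPCR side implements the Livak comparative
ΔΔCt method: per-replicate ΔCt against a reference gene, normalization
to a calibrator sample, relative expression 2^(−ΔΔCt) with mean ± SE
over replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Entrywise log2(FPKM + 1)."""
    if (matrix.values < 0).any():
        raise ValueError("FPKM matrix has negative entries")
    return np.log2(matrix + 1.0)


def classify_breadth(
    matrix: pd.DataFrame,
    on_threshold: float = 1.0,
    constitutive_frac: float = 0.9,
) -> pd.Series:
    """Per-gene expression-breadth class on the raw FPKM matrix.

    silent: below threshold everywhere; constitutive: at or above the
    threshold in >= constitutive_frac of tissues; otherwise restricted.
    """
    on = matrix >= on_threshold
    frac_on = on.mean(axis=1)
    out = pd.Series("restricted", index=matrix.index, name="breadth_class")
    out[frac_on == 0.0] = "silent"
    out[frac_on >= constitutive_frac] = "constitutive"
    return out


def delta_delta_ct(
    table: pd.DataFrame,
    ref_gene: str,
    calibrator: str,
) -> pd.DataFrame:
    """Relative expression by the comparative ΔΔCt (Livak) method.

    ``table`` is long-format with columns gene, sample, replicate, ct.
    Per replicate, ΔCt = Ct_target − Ct_reference (replicates paired
    within each sample); ΔΔCt subtracts the mean calibrator ΔCt, and
    relative expression is 2^(−ΔΔCt), summarized as mean ± standard
    error over replicates.  The result is invariant to adding a
    constant to all Ct values of a sample.
    """
    required = {"gene", "sample", "replicate", "ct"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    ref = table[table["gene"] == ref_gene].set_index(["sample", "replicate"])["ct"]
    samples = set(table["sample"])
    if not samples <= set(ref.index.get_level_values(0)):
        missing = sorted(samples - set(ref.index.get_level_values(0)))
        raise ValueError(f"reference gene {ref_gene} missing in samples {missing}")
    targets = table[table["gene"] != ref_gene].copy()
    keys = list(zip(targets["sample"], targets["replicate"]))
    try:
        targets["delta_ct"] = targets["ct"].values - ref.loc[keys].values
    except KeyError as exc:
        raise ValueError(f"reference Ct missing for {exc.args[0]}") from None

    rows = []
    for gene, sub in targets.groupby("gene", sort=True):
        cal = sub[sub["sample"] == calibrator]
        if cal.empty:
            raise ValueError(f"calibrator sample {calibrator!r} missing for {gene}")
        baseline = cal["delta_ct"].mean()
        for sample, ss in sub.groupby("sample", sort=True):
            rel = 2.0 ** (-(ss["delta_ct"] - baseline))
            n = len(rel)
            se = float(rel.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            rows.append({
                "gene": gene, "sample": sample,
                "relative_expression": float(rel.mean()),
                "se": se, "n_replicates": n,
            })
    return pd.DataFrame(rows, columns=[
        "gene", "sample", "relative_expression", "se", "n_replicates"])
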
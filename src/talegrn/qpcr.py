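"""qPCR quantification: relative expression, ChIP enrichment, fold changes.

Quantities derive from threshold cycles (Ct) under the assumption of
perfect doubling per cycle: the amount of template is proportional to
0.5^Ct, so a gene's expression relative to a reference (gapdh for RT-qPCR,
input DNA for ChIP-qPCR) is 0.5^Ct_gene / 0.5^Ct_ref = 2^(Ct_ref - Ct_gene).
Replicate ratios are compared between conditions with a two-sided
equal-variance (Student) unpaired t-test; p <= 0.05 is called significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CtMeasurement:
    target: str
    ct: float
    reference_ct: float
    replicate: int = 1
    condition: str = ""

    def __post_init__(self) -> None:
        if self.ct <= 0 or self.reference_ct <= 0:
            raise ValueError(f"{self.target}: Ct values must be positive")


def relative_expression(ct_gene: float, ct_ref: float) -> float:
    """0.5^ct_gene / 0.5^ct_ref, i.e. expression normalized to the reference."""
    return float(0.5**ct_gene / 0.5**ct_ref)


def chip_enrichment(ct_ip: float, ct_input: float) -> float:
    """0.5^ct_ip / 0.5^ct_input: ChIP DNA recovery as a fraction of input."""
    return float(0.5**ct_ip / 0.5**ct_input)


def fold_change_with_test(
    values_experimental,
    values_control,
    alpha: float = 0.05,
) -> dict:
    """Mean fold change with SEM and an unpaired t-test between conditions.

    Fold change is the ratio of group means (experimental over control);
    the SEM is that of the experimental replicates scaled by the control
    mean, so error bars live on the fold-change scale.  The test is a
    two-sided Student t-test on the raw replicate ratios.
    """
    exp = np.asarray(values_experimental, dtype=float)
    ctl = np.asarray(values_control, dtype=float)
    if len(exp) < 2 or len(ctl) < 2:
        raise ValueError("need >= 2 replicates per group")
    fc = float(exp.mean() / ctl.mean())
    sem = float(exp.std(ddof=1) / np.sqrt(len(exp)) / ctl.mean())
    t, p = stats.ttest_ind(exp, ctl, equal_var=True)
    return {
        "fold_change": fc,
        "sem": sem,
        "t": float(t),
        "pvalue": float(p),
        "significant": bool(p <= alpha),
        "test": "unpaired two-sided Student t (equal variance)",
    }


def analyze_ct_table(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-target fold change of experimental vs control replicate ratios.

    Expects columns target, condition, replicate, ct, reference_ct with
    exactly two conditions per target; the lexicographically first condition
    is treated as control.  Each replicate is normalized to its matched
    reference before conditions are compared.
    """
    rows = []
    for target, g in table.groupby("target", sort=True):
        conds = sorted(g["condition"].unique())
        if len(conds) != 2:
            raise ValueError(f"target {target}: expected 2 conditions, got {conds}")
        control, experimental = conds[0], conds[1]
        ratios = {
            c: [
                chip_enrichment(r.ct, r.reference_ct)
                for r in g[g["condition"] == c].itertuples()
            ]
            for c in conds
        }
        res = fold_change_with_test(ratios[experimental], ratios[control], alpha=alpha)
        rows.append(
            {
                "target": target,
                "control": control,
                "experimental": experimental,
                "fold_change": res["fold_change"],
                "sem": res["sem"],
                "pvalue": res["pvalue"],
                "significant": res["significant"],
            }
        )
    return pd.DataFrame(rows)
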
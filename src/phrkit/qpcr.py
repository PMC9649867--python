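"""Relative expression from qPCR threshold cycles.

Implements the 2^(-dCt) method normalized to the geometric mean of two
stable reference genes (Vandesompele-style multi-reference normalization):

    dCt  = Ct_target - geomean(Ct_ref1, Ct_ref2, ...)
    rel  = 2 ** (-dCt)
    fold = mean(rel | treated) / mean(rel | control)

The geometric mean is taken on the Ct scale by default; pass
``linear_scale=True`` to average the linearized quantities 2^(-Ct) instead
(equivalent to the arithmetic mean of Cts being replaced by the geometric
mean of quantities).
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .records import CtRecord

__all__ = [
    "geometric_mean",
    "relative_expression",
    "fold_change",
    "expression_table",
    "read_ct_table",
]


def geometric_mean(values: Sequence[float]) -> float:
    """Geometric mean of strictly positive reals; equals the value for a singleton."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of an empty list is undefined")
    if not np.all(arr > 0):
        raise ValueError("geometric mean requires all values > 0")
    return float(gmean(arr))


def relative_expression(ct_target: float, ct_refs: Sequence[float], *, linear_scale: bool = False) -> float:
    """2^(-dCt) with dCt = Ct_target - geometric mean of the reference Cts.

    With ``linear_scale=True`` the reference level is the geometric mean of
    the linearized reference quantities 2^(-Ct_ref); on the Ct scale that is
    the arithmetic mean of reference Cts, so the two conventions coincide for
    equal reference Cts and differ only slightly otherwise.
    """
    if len(ct_refs) == 0:
        raise ValueError("at least one reference Ct is required")
    if linear_scale:
        ref_level = geometric_mean([2.0 ** (-c) for c in ct_refs])
        return float(2.0 ** (-ct_target) / ref_level)
    ref_ct = geometric_mean(ct_refs)
    return float(2.0 ** (-(ct_target - ref_ct)))


def fold_change(expr_treated: Sequence[float] | float, expr_control: Sequence[float] | float,
                *, reducer: str = "ratio_of_means") -> float:
    """Fold change of treated over control relative expression.

    reducer="ratio_of_means" (default) divides the mean treated expression by
    the mean control expression; "mean_of_ratios" averages per-replicate
    ratios treated_i / mean(control) — identical at zero noise, slightly
    different under replicate noise.
    """
    t = np.atleast_1d(np.asarray(expr_treated, dtype=float))
    c = np.atleast_1d(np.asarray(expr_control, dtype=float))
    if c.size == 0 or not np.all(c > 0):
        raise ValueError("control expression must be positive and non-empty")
    if reducer == "ratio_of_means":
        return float(t.mean() / c.mean())
    if reducer == "mean_of_ratios":
        return float((t / c.mean()).mean())
    raise ValueError(f"unknown reducer {reducer!r}")


def read_ct_table(path) -> list[CtRecord]:
    """Read a Ct table TSV with columns gene, condition, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    need = {"gene", "condition", "replicate", "ct"}
    if not need.issubset(df.columns):
        raise ValueError(f"Ct table must have columns {sorted(need)}, got {list(df.columns)}")
    return [CtRecord(r.gene, r.condition, int(r.replicate), float(r.ct)) for r in df.itertuples()]


def expression_table(records: Iterable[CtRecord], reference_genes: Sequence[str],
                     control_condition: str, *, reducer: str = "ratio_of_means",
                     linear_scale: bool = False) -> pd.DataFrame:
    """Per-gene, per-condition relative expression and fold change vs control.

    Reference Cts are paired with target Cts by (condition, replicate); the
    reference level for a replicate is the geometric mean of that replicate's
    reference-gene Cts. Returns a DataFrame with columns gene, condition,
    n, relative_expression (mean over replicates), sd, fold_change_vs_control.
    """
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        return pd.DataFrame(columns=["gene", "condition", "n", "relative_expression", "sd",
                                     "fold_change_vs_control"])
    missing = set(reference_genes) - set(df.gene.unique())
    if missing:
        raise ValueError(f"reference genes absent from Ct table: {sorted(missing)}")

    refs = (df[df.gene.isin(reference_genes)]
            .groupby(["condition", "replicate"])["ct"]
            .apply(lambda c: geometric_mean(list(c)))
            .rename("ref_ct"))
    tgt = df[~df.gene.isin(reference_genes)].merge(refs, on=["condition", "replicate"])
    tgt["rel"] = [relative_expression(ct, [ref], linear_scale=linear_scale)
                  for ct, ref in zip(tgt.ct, tgt.ref_ct)]

    rows = []
    for (gene, cond), grp in tgt.groupby(["gene", "condition"], sort=False):
        ctrl = tgt[(tgt.gene == gene) & (tgt.condition == control_condition)]["rel"]
        if ctrl.empty:
            raise ValueError(f"no control-condition ({control_condition!r}) replicates for {gene}")
        rows.append({
            "gene": gene,
            "condition": cond,
            "n": len(grp),
            "relative_expression": float(grp.rel.mean()),
            "sd": float(grp.rel.std(ddof=1)) if len(grp) > 1 else 0.0,
            "fold_change_vs_control": fold_change(grp.rel.to_numpy(), ctrl.to_numpy(),
                                                  reducer=reducer),
        })
    return pd.DataFrame(rows)
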
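"""Standard-curve relative quantification of qPCR transcript levels.

A dilution series of reference cDNA gives, per gene, a least-squares line
Ct = m·log10(amount) + b. Unknown samples are inverted through the curve
(amount = 10^((Ct − b)/m)), normalised to a reference gene (Gapdh by
default) within each sample, and finally expressed as fold change over a
control condition. The amplification efficiency implied by the slope,
E = 10^(−1/m) − 1, is reported; a perfect doubling per cycle has
m = −1/log10(2) ≈ −3.3219 and E = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ..transport import InvalidParameterError


class StandardCurveError(ValueError):
    """The dilution series does not support a usable standard curve."""


@dataclass(frozen=True)
class QpcrRecord:
    sample: str
    gene: str
    ct: float


@dataclass(frozen=True)
class StandardCurve:
    gene: str
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def amount(self, ct: float) -> float:
        """Invert the curve: relative template amount from a Ct value."""
        return 10.0 ** ((ct - self.intercept) / self.slope)


@dataclass(frozen=True)
class RelativeExpression:
    gene: str
    sample: str
    amount: float
    amount_over_reference: float
    fold_vs_control: float


def fit_standard_curve(dilution_series, gene: str = "",
                       min_r_squared: float = 0.98) -> StandardCurve:
    """Fit Ct = m·log10(amount) + b to a dilution series.

    ``dilution_series`` is an iterable of ``(log10_amount, ct)`` pairs with
    at least 3 distinct dilutions. The slope must be negative (Ct falls as
    template rises); a fit with r² below ``min_r_squared`` is rejected.
    """
    pairs = np.asarray(list(dilution_series), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise InvalidParameterError("dilution series must be (log10_amount, ct) pairs")
    if len(np.unique(pairs[:, 0])) < 3:
        raise StandardCurveError("need >= 3 distinct dilutions for a standard curve")
    res = stats.linregress(pairs[:, 0], pairs[:, 1])
    r2 = float(res.rvalue ** 2)
    if res.slope >= 0:
        raise StandardCurveError(
            f"non-negative slope {res.slope:.3f}: Ct must decrease with amount")
    if r2 < min_r_squared:
        raise StandardCurveError(
            f"standard curve r²={r2:.4f} below minimum {min_r_squared} "
            f"(slope {res.slope:.3f}, intercept {res.intercept:.3f})")
    return StandardCurve(gene=gene, slope=float(res.slope),
                         intercept=float(res.intercept), r_squared=r2)


def relative_expression(records, curves: dict[str, StandardCurve],
                        control_sample: str,
                        reference_gene: str = "Gapdh") -> pd.DataFrame:
    """Standard-curve amounts, reference-gene and control normalisation.

    For each record, amount = curve.amount(Ct); within a sample each gene's
    amount is divided by the reference gene's amount; fold_vs_control then
    divides by the same ratio in ``control_sample``. Samples lacking the
    reference gene are skipped with a warning column in the result;
    a missing per-gene curve raises.
    """
    recs = [r if isinstance(r, QpcrRecord) else QpcrRecord(**r) for r in records]
    df = pd.DataFrame([{"sample": r.sample, "gene": r.gene, "ct": r.ct} for r in recs])
    if df.empty:
        raise InvalidParameterError("no qPCR records")
    missing_curves = set(df["gene"]) - set(curves)
    if missing_curves:
        raise InvalidParameterError(f"no standard curve for genes: {sorted(missing_curves)}")
    if control_sample not in set(df["sample"]):
        raise InvalidParameterError(f"control sample {control_sample!r} absent")
    df["amount"] = [curves[g].amount(ct) for g, ct in zip(df["gene"], df["ct"])]
    ref = df[df["gene"] == reference_gene].set_index("sample")["amount"]
    rows = []
    for (sample, gene), sub in df.groupby(["sample", "gene"], sort=False):
        if sample not in ref.index:
            import warnings
            warnings.warn(f"sample {sample!r} lacks reference gene "
                          f"{reference_gene!r}; skipped", stacklevel=2)
            continue
        amount = float(sub["amount"].mean())
        rows.append({"sample": sample, "gene": gene, "amount": amount,
                     "amount_over_reference": amount / float(ref[sample])})
    out = pd.DataFrame(rows)
    ctrl = out[out["sample"] == control_sample].set_index("gene")["amount_over_reference"]
    folds = []
    for _, row in out.iterrows():
        if row["gene"] in ctrl.index and ctrl[row["gene"]] > 0:
            folds.append(row["amount_over_reference"] / ctrl[row["gene"]])
        else:
            folds.append(float("nan"))
    out["fold_vs_control"] = folds
    return out
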
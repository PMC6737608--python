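"""Bundled published summary inputs.

The INTERSTROKE study (a large international case-control study of acute
stroke) published, for its ten major risk factors, the confounder-adjusted
average log-odds ratio and the exposure prevalence among controls.  Those
two numbers per factor are exactly the inputs the approximate-PAF formula
and both graphical devices need, so they ship here as a ready-made summary
table for worked examples and for plotting without subject-level data
(which is not publicly deposited).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["stroke_risk_factors"]

# factor, exposure kind, prevalence of a non-reference level in controls,
# average log-odds ratio (adjusted for age, sex, country and the other
# nine risk factors)
_STROKE_ROWS = [
    ("High blood pressure", "binary", 0.474, 1.093),
    ("Lack of physical activity", "binary", 0.837, 0.501),
    ("ApoB/ApoA ratio (tertiles)", "multicategory", 0.669, 0.428),
    ("Diet score (tertiles)", "multicategory", 0.670, 0.378),
    ("Waist-hip ratio (tertiles)", "multicategory", 0.670, 0.294),
    ("Smoking", "binary", 0.224, 0.513),
    ("Cardiac causes", "binary", 0.049, 1.156),
    ("Alcohol consumption (3 levels)", "multicategory", 0.277, 0.186),
    ("Global stress", "binary", 0.144, 0.301),
    ("Diabetes", "binary", 0.129, 0.148),
]


def stroke_risk_factors() -> pd.DataFrame:
    """Published stroke risk-factor summaries (10 factors).

    Returns a summary-schema frame with columns ``factor``, ``kind``,
    ``prevalence`` (exposure prevalence in controls) and ``beta_ave``
    (average log-odds ratio, natural log), ordered by approximate PAF
    descending as in the source publication.
    """
    return pd.DataFrame(
        _STROKE_ROWS, columns=["factor", "kind", "prevalence", "beta_ave"]
    )
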
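"""Estimated glomerular filtration rate (eGFR) calculators.

Two creatinine-based comparators used in dialysis-initiation assessment:

* :func:`egfr_cmdrd` — the Chinese-modified MDRD study equation 7,
  ``170 * Scr^-0.999 * age^-0.176 * BUN^-0.170 * Alb^0.318`` with a 0.762
  female factor and a 1.202 Chinese-descent factor.
* :func:`egfr_ckdepi` — the 2009 CKD-EPI creatinine equation (sex-specific
  kappa/alpha knot, age decay 0.993^age; race coefficient off by default).

Both return the raw floating-point estimate in mL/min/1.73 m^2; display
rounding is left to the caller so computation and presentation stay separate.
"""

from __future__ import annotations

import numpy as np

__all__ = ["egfr_cmdrd", "egfr_ckdepi"]


def _check_positive(**values: float) -> None:
    for name, v in values.items():
        arr = np.asarray(v, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError(f"{name} must be positive and finite, got {v!r}")


def egfr_cmdrd(
    scr: float,
    age: float,
    bun: float,
    alb: float,
    female: bool = False,
    chinese: bool = True,
):
    """Chinese-modified MDRD study equation 7 (mL/min/1.73 m^2).

    Parameters are serum creatinine (mg/dL), age (years), blood urea
    nitrogen (mg/dL) and serum albumin (g/dL). ``chinese`` applies the 1.202
    ethnicity factor (on by default: the target population), ``female`` the
    0.762 sex factor. Accepts scalars or numpy arrays.
    """
    _check_positive(scr=scr, age=age, bun=bun, alb=alb)
    scr, age, bun, alb = (np.asarray(x, dtype=float) for x in (scr, age, bun, alb))
    out = 170.0 * scr**-0.999 * age**-0.176 * bun**-0.170 * alb**0.318
    out = out * np.where(np.asarray(female, dtype=bool), 0.762, 1.0)
    out = out * np.where(np.asarray(chinese, dtype=bool), 1.202, 1.0)
    return out if out.ndim else float(out)


def egfr_ckdepi(scr: float, age: float, female: bool, black: bool = False):
    """CKD-EPI 2009 creatinine equation (mL/min/1.73 m^2).

    ``eGFR = 141 * min(Scr/k, 1)^alpha * max(Scr/k, 1)^-1.209 * 0.993^age``
    with k = 0.7 / alpha = -0.329 for women and k = 0.9 / alpha = -0.411 for
    men, a 1.018 female factor and an optional 1.159 race factor (default
    off). Accepts scalars or numpy arrays.
    """
    _check_positive(scr=scr, age=age)
    scr = np.asarray(scr, dtype=float)
    age = np.asarray(age, dtype=float)
    fem = np.asarray(female, dtype=bool)
    kappa = np.where(fem, 0.7, 0.9)
    alpha = np.where(fem, -0.329, -0.411)
    ratio = scr / kappa
    out = (
        141.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993**age
    )
    out = out * np.where(fem, 1.018, 1.0)
    if black:
        out = out * np.where(np.asarray(black, dtype=bool), 1.159, 1.0)
    return out if out.ndim else float(out)
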
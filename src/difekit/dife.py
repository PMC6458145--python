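"""The DIFE score: a fuzzy-mathematics equation for haemodialysis-initiation timing.

The score of patient *x* is

    Y = p15 + p1 * W * ( p2 * Scr^p3 * ln(age)^p4 * Alb^p5 * Hb^p6
                         * ln(BUN)^p7 * P^p8
                         + p9 * e^HF + p10 * e^DM + p11 * e^female + p16 )

with a sigmoid weighting multiplier over the six numerical indicators

    W = 1 / (1 + exp(t1 + t2*Scr + t3*Alb + t4*Hb + t5*ln(BUN) + t6*P)).

Scr and BUN are in mg/dL, Alb and Hb in g/dL, phosphate (P) in mmol/L; HF
(heart failure), DM (diabetes) and female are 0/1 indicators, so each
exponential term contributes 1 or e. Lower Y means more urgent initiation:
scores below the decision threshold (30 by convention) flag patients who
should start haemodialysis at once and are predicted poor three-year
survivors.

The 13 consequent parameters are indexed p1-p11, p15, p16 (p12-p14 do not
appear in the closed form) and the six gate parameters t1-t6.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "PARAM_NAMES",
    "DifeParameters",
    "weighting_w",
    "dife_score",
    "dife_scores",
    "classify_initiation",
    "example_parameters",
]

#: Canonical parameter order used for (de)serialisation and optimisation.
PARAM_NAMES = [
    "p1", "p2", "p3", "p4", "p5", "p6", "p7", "p8",
    "p9", "p10", "p11", "p15", "p16",
    "t1", "t2", "t3", "t4", "t5", "t6",
]

_CONSEQUENT = PARAM_NAMES[:13]
_GATES = PARAM_NAMES[13:]


@dataclass(frozen=True)
class DifeParameters:
    """The 13 consequent and 6 gate parameters of the score."""

    p1: float; p2: float; p3: float; p4: float; p5: float; p6: float
    p7: float; p8: float; p9: float; p10: float; p11: float
    p15: float; p16: float
    t1: float; t2: float; t3: float; t4: float; t5: float; t6: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {name} must be finite, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Iterable[float]) -> "DifeParameters":
        values = list(values)
        if len(values) != len(PARAM_NAMES):
            raise ValueError(f"expected {len(PARAM_NAMES)} parameters, got {len(values)}")
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))

    @classmethod
    def from_json(cls, path: str | Path) -> "DifeParameters":
        """Load a parameter file; fails loudly on missing or extra keys."""
        payload = json.loads(Path(path).read_text())
        missing = sorted(set(PARAM_NAMES) - set(payload))
        extra = sorted(set(payload) - set(PARAM_NAMES))
        if missing or extra:
            raise ValueError(
                f"parameter file {path}: missing keys {missing}, unexpected keys {extra}"
            )
        return cls(**{k: float(payload[k]) for k in PARAM_NAMES})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    """Overflow-safe 1/(1+exp(eta)), i.e. the logistic function of -eta."""
    return expit(-np.asarray(eta, dtype=float))


def _validate_inputs(scr, age, alb, hb, bun, phosphate) -> None:
    for name, v in (("scr", scr), ("alb", alb), ("hb", hb), ("bun", bun), ("phosphate", phosphate)):
        arr = np.asarray(v, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError(f"{name} must be positive and finite")
    age_arr = np.asarray(age, dtype=float)
    if not np.all(np.isfinite(age_arr)) or np.any(age_arr <= 1):
        raise ValueError("age must exceed 1 year (ln(age) > 0)")


def weighting_w(
    params: DifeParameters,
    scr,
    alb,
    hb,
    bun,
    phosphate,
):
    """Sigmoid weighting multiplier W in (0, 1) over the numerical indicators."""
    _validate_inputs(scr, 2.0, alb, hb, bun, phosphate)
    scr, alb, hb, bun, phosphate = (
        np.asarray(x, dtype=float) for x in (scr, alb, hb, bun, phosphate)
    )
    eta = (
        params.t1
        + params.t2 * scr
        + params.t3 * alb
        + params.t4 * hb
        + params.t5 * np.log(bun)
        + params.t6 * phosphate
    )
    out = _sigmoid(eta)
    return out if out.ndim else float(out)


def dife_score(
    params: DifeParameters,
    scr,
    age,
    alb,
    hb,
    bun,
    phosphate,
    heart_failure,
    diabetes,
    female,
):
    """Evaluate the score Y. Accepts scalars or aligned numpy arrays.

    Units: Scr/BUN mg/dL, Alb/Hb g/dL, phosphate mmol/L; apply
    :func:`difekit.cohort.convert_units` beforehand if needed.
    """
    _validate_inputs(scr, age, alb, hb, bun, phosphate)
    scr, age, alb, hb, bun, phosphate = (
        np.asarray(x, dtype=float) for x in (scr, age, alb, hb, bun, phosphate)
    )
    hf = np.asarray(heart_failure, dtype=float)
    dm = np.asarray(diabetes, dtype=float)
    fem = np.asarray(female, dtype=float)
    for name, b in (("heart_failure", hf), ("diabetes", dm), ("female", fem)):
        if not np.all(np.isin(b, (0.0, 1.0))):
            raise ValueError(f"{name} must be binary 0/1")

    w = weighting_w(params, scr, alb, hb, bun, phosphate)
    product = (
        params.p2
        * scr**params.p3
        * np.log(age) ** params.p4
        * alb**params.p5
        * hb**params.p6
        * np.log(bun) ** params.p7
        * phosphate**params.p8
    )
    inner = (
        product
        + params.p9 * np.exp(hf)
        + params.p10 * np.exp(dm)
        + params.p11 * np.exp(fem)
        + params.p16
    )
    y = params.p15 + params.p1 * w * inner
    return y if np.ndim(y) else float(y)


def dife_scores(df: pd.DataFrame, params: DifeParameters) -> np.ndarray:
    """Score every patient in a cohort table (canonical column names)."""
    return np.asarray(
        dife_score(
            params,
            scr=df["scr_mgdl"].to_numpy(),
            age=df["age"].to_numpy(),
            alb=df["alb_gdl"].to_numpy(),
            hb=df["hb_gdl"].to_numpy(),
            bun=df["bun_mgdl"].to_numpy(),
            phosphate=df["phosphate_mmoll"].to_numpy(),
            heart_failure=df["heart_failure"].to_numpy(),
            diabetes=df["diabetes"].to_numpy(),
            female=df["female"].to_numpy(),
        ),
        dtype=float,
    )


def classify_initiation(score: float, threshold: float = 30.0) -> tuple[str, str]:
    """Map a score to an initiation decision and predicted-survival label.

    ``score < threshold`` -> ("start_now", "poor"): start haemodialysis at
    once, predicted poor three-year survival. ``score >= threshold`` ->
    ("prepare_and_wait", "good"). The boundary belongs to the good side.
    """
    if not (math.isfinite(score) and math.isfinite(threshold)):
        raise ValueError("score and threshold must be finite")
    if score < threshold:
        return "start_now", "poor"
    return "prepare_and_wait", "good"


def example_parameters() -> DifeParameters:
    """A synthetic, illustrative parameter set (NOT fitted to any real cohort).

    Chosen so that typical incident-dialysis covariates yield scores around
    the conventional threshold of 30 with a clinically sensible orientation:
    higher albumin/haemoglobin raise Y (can wait), heart failure and
    diabetes lower it (start sooner). Used for demos and ground-truth
    simulation studies.
    """
    return DifeParameters(
        p1=1.0, p2=0.8, p3=-0.4, p4=-1.2, p5=1.1, p6=0.9, p7=1.3, p8=-0.5,
        p9=-4.0, p10=-2.5, p11=1.0, p15=12.0, p16=30.0,
        t1=2.0, t2=0.05, t3=-0.6, t4=-0.12, t5=0.1, t6=0.15,
    )
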
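"""Covariate term handling shared by the simulator and the model fitters.

A *term* is a covariate name, optionally squared on the standardized scale
(written ``"name^2"``). The special term ``"auto"`` denotes the neighbor
auto-covariate and is resolved by the sampler, not here.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

AUTO_TERM = "auto"
INTERCEPT = "intercept"


def parse_term(term: str) -> tuple[str, int]:
    """Split ``"elevation^2"`` into ``("elevation", 2)``."""
    if "^" in term:
        name, power = term.split("^", 1)
        return name, int(power)
    return term, 1


def term_base(term: str) -> str:
    return parse_term(term)[0]


def term_values(df: pd.DataFrame, term: str) -> np.ndarray:
    name, power = parse_term(term)
    return df[name].to_numpy(float) ** power


def design_matrix(df: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    """Intercept column followed by one column per term (auto excluded)."""
    cols = [np.ones(len(df))]
    for term in terms:
        if term == AUTO_TERM:
            continue
        cols.append(term_values(df, term))
    return np.column_stack(cols)


def linear_predictor(df: pd.DataFrame, coefs: Mapping[str, float]) -> np.ndarray:
    """Evaluate intercept + sum(coef * term) over the station table."""
    eta = np.full(len(df), float(coefs.get(INTERCEPT, 0.0)))
    for term, coef in coefs.items():
        if term in (INTERCEPT, AUTO_TERM):
            continue
        eta = eta + float(coef) * term_values(df, term)
    return eta
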
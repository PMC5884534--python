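"""DIC computation and staged forward model selection.

Model structure is chosen in stages, in the order the probability
parameters enter the hierarchy: detection first, then initial occupancy,
then the colonization/extinction dynamics. Within a stage every single-term
candidate is compared by DIC against the stage null (the structure carried
over from earlier stages); if any candidate beats the null, terms are added
forward-stepwise while DIC keeps decreasing. The full audit table — every
fitted candidate, its DIC, pD and convergence flag — is part of the output,
because DIC differences between hierarchical models are suggestive rather
than definitive and a final choice may legitimately prefer a close
competitor on subject-matter grounds (the ``override`` hook).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._sampler import MCMCConfig
from .data_model import DetectionHistory, StationTable
from .occupancy import DynamicOccupancyModel, ModelSpec, NeighborGraph

logger = logging.getLogger(__name__)

STAGE_ORDER = ("detection", "initial_occupancy", "dynamics")
_STAGE_PARAMS = {
    "detection": ("p",),
    "initial_occupancy": ("psi1",),
    "dynamics": ("gamma", "eps"),
}


def dic(fit) -> tuple[float, float, float]:
    """Deviance Information Criterion of a fitted model.

    Uses the Spiegelhalter mean-deviance penalty:
    pD = mean(deviance) - deviance(posterior means), DIC = mean(deviance) + pD.
    Returns (DIC, pD, mean deviance).
    """
    if getattr(fit, "deviance_draws_", None) is None or getattr(
        fit, "deviance_at_mean_", None
    ) is None:
        raise ValueError("fit carries no deviance draws / point deviance")
    return float(fit.dic_), float(fit.pd_), float(fit.mean_deviance_)


def dic_from_deviance(
    deviance_draws: np.ndarray, deviance_at_posterior_mean: float
) -> tuple[float, float, float]:
    """DIC from raw deviance draws plus the plug-in deviance."""
    deviance_draws = np.asarray(deviance_draws, float)
    if deviance_draws.size == 0:
        raise ValueError("empty deviance draws")
    mean_dev = float(deviance_draws.mean())
    p_d = mean_dev - float(deviance_at_posterior_mean)
    return mean_dev + p_d, p_d, mean_dev


@dataclass
class SelectionStage:
    """One stage of the forward search.

    ``candidates`` are (parameter, term) pairs; parameters must belong to
    the stage (p for detection, psi1 for initial occupancy, gamma/eps for
    dynamics). The term ``"auto"`` is the neighbor auto-covariate.
    """

    name: str
    candidates: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if self.name not in STAGE_ORDER:
            raise ValueError(f"unknown stage {self.name!r}; use one of {STAGE_ORDER}")
        allowed = _STAGE_PARAMS[self.name]
        for param, term in self.candidates:
            if param not in allowed:
                raise ValueError(
                    f"stage {self.name!r} cannot modify {param!r} (allowed: {allowed})"
                )


def default_stages() -> list[SelectionStage]:
    """The study's candidate sets: detection from ground cover and distance
    to water; initial occupancy from topography and water; dynamics from
    the auto-covariate and distance to water (linear and quadratic)."""
    return [
        SelectionStage("detection", [("p", "ground_cover"), ("p", "dist_any_water")]),
        SelectionStage(
            "initial_occupancy",
            [("psi1", "elevation"), ("psi1", "slope"), ("psi1", "dist_any_water")],
        ),
        SelectionStage(
            "dynamics",
            [
                ("gamma", "auto"),
                ("eps", "auto"),
                ("gamma", "dist_any_water"),
                ("gamma", "dist_any_water^2"),
                ("eps", "dist_any_water"),
                ("eps", "dist_any_water^2"),
            ],
        ),
    ]


def forward_select(
    stages: Sequence[SelectionStage],
    history: DetectionHistory,
    stations: StationTable,
    graph: NeighborGraph | None = None,
    mcmc: MCMCConfig | None = None,
    flagged_pairs: Sequence[tuple[str, str, float]] = (),
    base_spec: ModelSpec | None = None,
    keep_fits: bool = False,
) -> tuple[ModelSpec, dict[str, pd.DataFrame]]:
    """Staged forward DIC search over model structures.

    At each stage the stage null (earlier stages' winner) and every
    single-term candidate are fitted; a candidate is informative iff its DIC
    is below the null's. If any is, terms are added forward-stepwise while
    DIC decreases. Ties break toward the simpler model. Candidates that fail
    the collinearity screen or the convergence check are excluded from the
    competition but logged in the audit table. Returns the winning spec and
    one audit table per stage (sorted by DIC, ``delta_dic`` vs the stage
    null).
    """
    config = mcmc or MCMCConfig()
    current = base_spec or ModelSpec()
    tables: dict[str, pd.DataFrame] = {}
    fits: dict[str, DynamicOccupancyModel] = {}
    fit_counter = 0

    def do_fit(spec: ModelSpec):
        nonlocal fit_counter
        fit_counter += 1
        model = DynamicOccupancyModel(
            spec=spec, mcmc=config.with_seed(config.seed + fit_counter),
            flagged_pairs=flagged_pairs,
        )
        model.fit(stations, history, graph)
        if keep_fits:
            fits[spec.describe()] = model
        return model

    for stage in stages:
        rows = []
        null_fit = do_fit(current)
        null_dic = null_fit.dic_
        rows.append(
            {
                "model": current.describe(), "added": "(null)",
                "dic": null_dic, "pd": null_fit.pd_,
                "mean_deviance": null_fit.mean_deviance_,
                "converged": null_fit.converged_, "status": "stage_null",
            }
        )
        informative = []
        for param, term in stage.candidates:
            spec = current.with_term(param, term)
            try:
                spec.check_collinearity(flagged_pairs)
            except Exception as exc:
                logger.info("stage %s: %s excluded (%s)", stage.name, term, exc)
                rows.append(
                    {"model": spec.describe(), "added": f"{param}:{term}",
                     "dic": np.nan, "pd": np.nan, "mean_deviance": np.nan,
                     "converged": False, "status": f"excluded: {exc}"}
                )
                continue
            fit = do_fit(spec)
            status = "candidate"
            if not fit.converged_:
                status = "excluded: non-convergence"
                logger.info(
                    "stage %s: candidate %s excluded, max R-hat %.3f",
                    stage.name, term, float(np.max(fit.rhat_)),
                )
            rows.append(
                {"model": spec.describe(), "added": f"{param}:{term}",
                 "dic": fit.dic_, "pd": fit.pd_,
                 "mean_deviance": fit.mean_deviance_,
                 "converged": fit.converged_, "status": status}
            )
            if fit.converged_ and fit.dic_ < null_dic:
                informative.append(((param, term), spec, fit.dic_))

        if informative:
            informative.sort(key=lambda r: r[2])
            (best_pt, best_spec, best_dic) = informative[0]
            remaining = [pt for pt, _, _ in informative[1:]]
            improved = True
            while improved and remaining:
                improved = False
                trials = []
                for param, term in remaining:
                    spec = best_spec.with_term(param, term)
                    try:
                        spec.check_collinearity(flagged_pairs)
                    except Exception as exc:
                        rows.append(
                            {"model": spec.describe(), "added": f"{param}:{term}",
                             "dic": np.nan, "pd": np.nan, "mean_deviance": np.nan,
                             "converged": False, "status": f"excluded: {exc}"}
                        )
                        continue
                    fit = do_fit(spec)
                    status = "step" if fit.converged_ else "excluded: non-convergence"
                    rows.append(
                        {"model": spec.describe(), "added": f"{param}:{term}",
                         "dic": fit.dic_, "pd": fit.pd_,
                         "mean_deviance": fit.mean_deviance_,
                         "converged": fit.converged_, "status": status}
                    )
                    if fit.converged_:
                        trials.append(((param, term), spec, fit.dic_))
                if trials:
                    trials.sort(key=lambda r: r[2])
                    pt, spec, d = trials[0]
                    if d < best_dic:  # strict decrease; ties keep the simpler model
                        best_pt, best_spec, best_dic = pt, spec, d
                        remaining = [r for r in remaining if r != pt]
                        improved = True
            current = best_spec
        table = pd.DataFrame(rows)
        table["delta_dic"] = table["dic"] - null_dic
        tables[stage.name] = table.sort_values(
            "dic", na_position="last", kind="stable"
        ).reset_index(drop=True)

    if keep_fits:
        tables["_fits"] = fits  # type: ignore[assignment]
    return current, tables
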
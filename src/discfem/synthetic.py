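"""Synthetic specimens and verification fixtures.

The in vitro arm of the study is emulated by a stochastic failure model:
each specimen independently develops each failure type (large/small annulus
failure, large/small endplate-junction failure) with a probability given by
a logistic link on a chosen regional-stress predictor,

    P(failure) = 1 / (1 + exp(-(stress - location) / scale)).

Locations and scales default to the empirically identified risk thresholds:
large failures become likely around the high-risk stress (10 MPa axial),
small failures around the low-risk bound (6 MPa), and endplate failures
around the 3.5 MPa interface threshold. Simulated counts feed the same
scoring and regression pipeline as the experimental table.

``make_fixture`` returns the small deterministic meshes used throughout the
verification suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .failure import FailureCounts, damage_score
from .geometry import DiscGeometryConfig, DiscMesh, MeshResolution, \
    box_mesh, build_disc_mesh

__all__ = ["FailureModel", "simulate_specimens", "make_fixture",
           "MINI_DISC_RESOLUTION"]

#: coarse resolution used by the mini-disc verification fixture; three
#: axial layers keep the cranial/middle/caudal banding non-degenerate
MINI_DISC_RESOLUTION = MeshResolution(n_theta=8, n_rad_np=1, n_rad_af=2,
                                      n_axial=3, n_cep=1, n_bep=1)


@dataclass(frozen=True)
class LogisticLink:
    """Location (MPa) and scale (MPa) of a logistic failure probability."""

    location: float
    scale: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def probability(self, stress) -> np.ndarray:
        z = (np.asarray(stress, dtype=float) - self.location) / self.scale
        return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class FailureModel:
    """Per-failure-type logistic links from stress predictors to occurrence.

    ``aff_predictor`` / ``epjf_predictor`` name the stress column driving
    annulus and endplate failures respectively.
    """

    large_aff: LogisticLink = field(default_factory=lambda: LogisticLink(10.0, 1.5))
    small_aff: LogisticLink = field(default_factory=lambda: LogisticLink(6.0, 1.5))
    large_epjf: LogisticLink = field(default_factory=lambda: LogisticLink(3.5, 0.8))
    small_epjf: LogisticLink = field(default_factory=lambda: LogisticLink(2.5, 0.8))
    aff_predictor: str = "axial"
    epjf_predictor: str = "interface"


def simulate_specimens(stress_by_scenario: pd.DataFrame, model: FailureModel,
                       n_per_scenario: int = 6,
                       seed: Optional[int] = None) -> pd.DataFrame:
    """Draw per-specimen failure indicators for each scenario.

    ``stress_by_scenario``: one row per scenario with at least the columns
    named by the model's predictors plus a ``scenario`` column. Each of the
    ``n_per_scenario`` specimens draws its four failure indicators as
    independent Bernoulli variables; the damage score is attached per row.
    """
    if n_per_scenario < 1:
        raise ValueError("n_per_scenario must be >= 1")
    for col in (model.aff_predictor, model.epjf_predictor, "scenario"):
        if col not in stress_by_scenario.columns:
            raise ValueError(f"missing stress column {col!r}")
    if not np.all(np.isfinite(
            stress_by_scenario[[model.aff_predictor,
                                model.epjf_predictor]].to_numpy(float))):
        raise ValueError("stresses must be finite")
    rng = np.random.default_rng(seed)
    rows = []
    for _, sc in stress_by_scenario.iterrows():
        s_af = float(sc[model.aff_predictor])
        s_ep = float(sc[model.epjf_predictor])
        probs = {
            "large_aff": model.large_aff.probability(s_af),
            "small_aff": model.small_aff.probability(s_af),
            "large_epjf": model.large_epjf.probability(s_ep),
            "small_epjf": model.small_epjf.probability(s_ep),
        }
        for j in range(n_per_scenario):
            rec = {"scenario": int(sc["scenario"]), "specimen": j}
            for k, p in probs.items():
                rec[k] = int(rng.random() < p)
            # a large failure supersedes a small one of the same type
            if rec["large_aff"]:
                rec["small_aff"] = 0
            if rec["large_epjf"]:
                rec["small_epjf"] = 0
            rec["score"] = damage_score(FailureCounts(
                scenario=rec["scenario"], large_aff=rec["large_aff"],
                small_aff=rec["small_aff"], large_epjf=rec["large_epjf"],
                small_epjf=rec["small_epjf"], specimen=j))
            rows.append(rec)
    return pd.DataFrame(rows)


def make_fixture(name: str) -> DiscMesh:
    """Deterministic verification meshes.

    ``single-element``: one unit hex; ``patch-block``: 3x3x3 block;
    ``tension-bar``: 1x1x10 bar; ``mini-disc``: a ~200-element disc with the
    default dimensions.
    """
    builders = {
        "single-element": lambda: box_mesh(1, 1, 1, 1.0, 1.0, 1.0, "NP"),
        "patch-block": lambda: box_mesh(3, 3, 3, 3.0, 3.0, 3.0, "CEP-cranial"),
        "tension-bar": lambda: box_mesh(1, 1, 10, 1.0, 1.0, 10.0, "NP"),
        "mini-disc": lambda: build_disc_mesh(
            DiscGeometryConfig(resolution=MINI_DISC_RESOLUTION)),
    }
    if name not in builders:
        raise KeyError(f"unknown fixture {name!r}; valid: "
                       f"{sorted(builders)}")
    return builders[name]()
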
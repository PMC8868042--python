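"""Latent-class cohort simulator for two paired binary tests.

Each unit (a breast) carries a latent disease status drawn Bernoulli(pi).
Conditional on status, the index test and the reference test fire with
their respective operating characteristics — (s, e) for the index test,
(alpha, beta) for the reference — and a single dependence parameter
``delta`` in [0, 1] tilts the conditional joint distribution toward
agreement:

    P(both fire) = p q + delta (min(p, q) - p q)

where p, q are the two tests' conditional positivity probabilities.
delta = 0 is exact conditional independence (the identifying assumption
of the imperfect-reference correction); delta = 1 is maximal positive
dependence given the margins.  The marginals are preserved for every
delta, and all four conditional cell probabilities stay in [0, 1] for
delta in [0, 1], which is validated at construction.

The simulator exists so every estimator in the package can be tested
end-to-end against known truth: it emits SubjectRecords that carry
``true_status``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .tables import SubjectRecord

# Conditional cell order everywhere in this module:
# (index+, ref+), (index+, ref-), (index-, ref+), (index-, ref-)


def _joint(p: float, q: float, delta: float) -> tuple[float, float, float, float]:
    """Joint (both, first-only, second-only, neither) with margins p, q."""
    both = p * q + delta * (min(p, q) - p * q)
    return (both, p - both, q - both, 1.0 - p - q + both)


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters for one simulated cohort.

    Defaults for the reference test are the mammographic operating
    characteristics used throughout the package (alpha = 0.869,
    beta = 0.889).
    """

    n_units: int
    prevalence: float
    index_sensitivity: float
    index_specificity: float
    ref_sensitivity: float = 0.869
    ref_specificity: float = 0.889
    dependence: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units <= 0:
            raise ValueError(f"n_units must be positive, got {self.n_units}")
        for name in (
            "prevalence",
            "index_sensitivity",
            "index_specificity",
            "ref_sensitivity",
            "ref_specificity",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if not 0.0 <= self.dependence <= 1.0:
            raise ValueError(f"dependence must lie in [0, 1], got {self.dependence}")
        for cells in conditional_cells(self).values():
            if any(not -1e-12 <= p <= 1.0 + 1e-12 for p in cells):
                raise ValueError("dependence infeasible for the given marginals")


def conditional_cells(params: CohortParams) -> dict[str, tuple[float, float, float, float]]:
    """Analytic conditional cell probabilities given each latent status."""
    diseased = _joint(
        params.index_sensitivity, params.ref_sensitivity, params.dependence
    )
    healthy = _joint(
        1.0 - params.index_specificity,
        1.0 - params.ref_specificity,
        params.dependence,
    )
    return {"diseased": diseased, "healthy": healthy}


def marginal_cells(params: CohortParams) -> tuple[float, float, float, float]:
    """Unconditional cell probabilities (a, b, c, d)/N in expectation."""
    cond = conditional_cells(params)
    pi = params.prevalence
    return tuple(
        pi * cond["diseased"][k] + (1.0 - pi) * cond["healthy"][k] for k in range(4)
    )


def simulate_cohort(params: CohortParams) -> list[SubjectRecord]:
    """Draw one cohort of breast-level records, reproducibly from the seed.

    Units are assigned to synthetic participants two at a time (right
    breast then left), so (unit_id, side) pairs are unique.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_units
    cond = conditional_cells(params)
    cum_diseased = np.cumsum(cond["diseased"])
    cum_healthy = np.cumsum(cond["healthy"])

    diseased = rng.random(n) < params.prevalence
    u = rng.random(n)
    cell = np.where(
        diseased,
        np.searchsorted(cum_diseased, u, side="right"),
        np.searchsorted(cum_healthy, u, side="right"),
    ).clip(0, 3)
    index_pos = cell <= 1
    ref_pos = (cell == 0) | (cell == 2)

    records = []
    for i in range(n):
        records.append(
            SubjectRecord(
                unit_id=f"S{i // 2 + 1:06d}",
                side="right" if i % 2 == 0 else "left",
                index_result=bool(index_pos[i]),
                reference_result=bool(ref_pos[i]),
                true_status=bool(diseased[i]),
            )
        )
    return records


def write_manifest(params: CohortParams, path: str | Path) -> None:
    """Record the generative parameters and seed beside a written cohort."""
    payload = {"generator": "diagval.simulate.simulate_cohort", "params": asdict(params)}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
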
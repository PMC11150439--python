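"""Desk-scale benchmark study: cohorts and pipeline grid.

Reproduces the structure of a multi-dataset pipeline evaluation with the
synthetic generator: several independent test-retest cohorts plus
independent condition (anaesthesia-like) cohorts, and a reduced pipeline
grid covering the edge-processing stages (connectivity measure x filtering
scheme x binarisation) that dominate pipeline performance.

Cohort sizes mirror typical public test-retest and anaesthesia studies:
retest groups of 25 and 18 subjects, condition groups of 15 and 16.
"""

from __future__ import annotations

import dataclasses

from .cohort import CohortSpec, generate_cohort
from .evaluation import PipelineSpec, enumerate_pipelines
from .io import CohortDataset

__all__ = [
    "RETEST_SIZES",
    "CONDITION_SIZES",
    "make_retest_cohort",
    "make_condition_cohort",
    "benchmark_cohorts",
    "edge_stage_grid",
]

RETEST_SIZES = {"trt_a": 25, "trt_b": 18}
CONDITION_SIZES = {"cond_a": 15, "cond_b": 16}


def _spec(seed: int, n_subjects: int, **overrides) -> CohortSpec:
    return dataclasses.replace(
        CohortSpec(), seed=seed, n_subjects=n_subjects, **overrides
    )


def make_retest_cohort(
    name: str, n_subjects: int, seed: int, **overrides
) -> CohortDataset:
    """Test-retest cohort: two rest sessions per subject (the perturbed
    session is generated but dropped, as a retest dataset has none)."""
    sessions = [
        s
        for s in generate_cohort(_spec(seed, n_subjects, **overrides))
        if s.session_id != "perturbed"
    ]
    return CohortDataset(name, sessions)


def make_condition_cohort(
    name: str, n_subjects: int, seed: int, **overrides
) -> CohortDataset:
    """Condition cohort: rest plus perturbed sessions for every subject."""
    return CohortDataset(
        name, generate_cohort(_spec(seed, n_subjects, **overrides))
    )


def benchmark_cohorts(
    seed: int, **overrides
) -> tuple[dict[str, CohortDataset], dict[str, CohortDataset]]:
    """The default benchmark: two independent retest cohorts and two
    independent condition cohorts, all derived from one root seed."""
    retest = {
        name: make_retest_cohort(name, n, seed * 1000 + i + 1, **overrides)
        for i, (name, n) in enumerate(RETEST_SIZES.items())
    }
    condition = {
        name: make_condition_cohort(name, n, seed * 1000 + 100 + i, **overrides)
        for i, (name, n) in enumerate(CONDITION_SIZES.items())
    }
    return retest, condition


def edge_stage_grid(n_nodes: int = 40) -> list[PipelineSpec]:
    """The 32-member edge-stage sub-grid (2 measures x 8 filters x 2
    binarisation options) at a fixed node set, without GSR."""
    return enumerate_pipelines(
        {"gsr": (False,), "node_set": ("synthetic",), "n_nodes": (n_nodes,)}
    )
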
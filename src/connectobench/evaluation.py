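"""Pipeline grid enumeration, per-pipeline evaluation, and the five
suitability criteria.

A pipeline is one path through the construction grid

    GSR (on/off) x node set (4 types x 3 sizes) x connectivity measure
    (Pearson / mutual information) x filtering scheme (8) x binarisation
    (on/off)  =  2 x 4 x 3 x 2 x 8 x 2 = 768 pipelines.

Each pipeline is scored on:

  I   low test-retest Portrait Divergence (global rank in the top fraction,
      averaged over per-dataset rankings),
  II  a significantly *larger* PDiv for an awake-vs-perturbed contrast than
      for test-retest (permutation two-sample Welch t, negative sign
      convention), in every condition dataset,
  III within-subject PDiv smaller than between-subject PDiv for at least
      half the subjects in every test-retest dataset,
  IV  no significant Spearman correlation between test-retest PDiv and the
      subjects' change in mean framewise displacement,
  V   no empty networks in any test-retest dataset.

A pipeline is "optimal" when all five criteria pass; "opposite" status
marks pipelines whose condition contrast is significantly positive (the
misleading direction) in every condition dataset.
"""

from __future__ import annotations

import dataclasses
import itertools
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import mutual_information_matrix, pearson_matrix
from .graphs import (
    FILTER_LABELS,
    FilteredNetwork,
    absolute_threshold,
    binarise,
    eco_filter,
    omst_filter,
    proportional_threshold,
)
from .io import CohortDataset, global_signal_regress
from .portraits import portrait_divergence

__all__ = [
    "PipelineSpec",
    "DEFAULT_AXES",
    "enumerate_pipelines",
    "criterion_dataset_cells",
    "run_pipeline",
    "test_retest_pdiv",
    "condition_pdiv",
    "criterion_pdiv_rank",
    "condition_contrast",
    "criterion_within_between",
    "criterion_motion",
    "criterion_empty",
    "evaluate_pipelines",
    "select_optimal",
    "enrichment_permutation",
    "edge_stage_group",
    "write_selection_table",
    "read_selection_table",
]


@dataclasses.dataclass(frozen=True)
class PipelineSpec:
    """One member of the construction grid.  ``node_set`` and ``n_nodes``
    are metadata for synthetic cohorts (all synthetic node sets are
    statistically exchangeable); they label the parcellation axis."""

    gsr: bool
    node_set: str
    n_nodes: int
    measure: str
    filter: str
    binarise: bool

    def __post_init__(self) -> None:
        if self.measure not in ("pearson", "mutual_information"):
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.filter not in FILTER_LABELS + ("mst_baseline",):
            raise ValueError(f"unknown filter {self.filter!r}")

    @property
    def pipeline_id(self) -> str:
        return "|".join(
            [
                "gsr" if self.gsr else "nogsr",
                f"{self.node_set}{self.n_nodes}",
                self.measure,
                self.filter,
                "binary" if self.binarise else "weighted",
            ]
        )


DEFAULT_AXES: dict[str, tuple] = {
    "gsr": (True, False),
    "node_set": ("anatomical", "functional", "multimodal", "ica"),
    "n_nodes": (100, 200, 400),
    "measure": ("pearson", "mutual_information"),
    "filter": FILTER_LABELS,
    "binarise": (False, True),
}


def enumerate_pipelines(axes: dict[str, tuple] | None = None) -> list[PipelineSpec]:
    """Cartesian product of the grid axes in the fixed documented order
    (gsr, node_set, n_nodes, measure, filter, binarise); ids are stable."""
    ax = dict(DEFAULT_AXES)
    if axes:
        ax.update(axes)
    for key, values in ax.items():
        if not values:
            raise ValueError(f"axis {key!r} is empty")
    return [
        PipelineSpec(g, ns, nn, me, fi, bi)
        for g, ns, nn, me, fi, bi in itertools.product(
            ax["gsr"], ax["node_set"], ax["n_nodes"], ax["measure"], ax["filter"], ax["binarise"]
        )
    ]


def criterion_dataset_cells(
    retest_names: tuple[str, ...], condition_names: tuple[str, ...]
) -> list[tuple[str, str]]:
    """The (criterion, dataset) evaluation cells of the report schema:
    criteria I, III, IV, V per test-retest dataset and criterion II per
    condition dataset (4 retest + 2 condition datasets -> 18 cells)."""
    cells = [(c, d) for d in retest_names for c in ("I", "III", "IV", "V")]
    cells += [("II", d) for d in condition_names]
    return cells


def _filter_dispatch(measure_matrix, spec: PipelineSpec, sdm_density: float) -> FilteredNetwork:
    f = spec.filter
    if f == "abs_0.3":
        return absolute_threshold(measure_matrix, 0.3)
    if f == "abs_0.5":
        return absolute_threshold(measure_matrix, 0.5)
    if f == "fd_5":
        return proportional_threshold(measure_matrix, 0.05, "fd_5")
    if f == "fd_10":
        return proportional_threshold(measure_matrix, 0.10, "fd_10")
    if f == "fd_20":
        return proportional_threshold(measure_matrix, 0.20, "fd_20")
    if f == "sdm":
        return proportional_threshold(measure_matrix, sdm_density, "sdm")
    if f == "eco":
        return eco_filter(measure_matrix)
    if f == "omst":
        return omst_filter(measure_matrix)
    raise ValueError(f"unknown filter {f!r}")


def run_pipeline(
    spec: PipelineSpec,
    cohort: CohortDataset,
    sdm_density: float = 0.25,
    mi_bins: int | None = None,
) -> dict[tuple[str, str], FilteredNetwork]:
    """Apply GSR (if on) -> connectivity measure -> filter -> binarisation
    to every session of the cohort; empty networks are flagged, not fatal."""
    networks: dict[tuple[str, str], FilteredNetwork] = {}
    for session in cohort.sessions:
        s = global_signal_regress(session) if spec.gsr else session
        if spec.measure == "pearson":
            conn = pearson_matrix(s)
        else:
            conn = mutual_information_matrix(s, n_bins=mi_bins)
        net = _filter_dispatch(conn, spec, sdm_density)
        if spec.binarise:
            net = binarise(net)
        networks[(session.subject_id, session.session_id)] = net
    return networks


def _pair_pdiv(
    networks: dict[tuple[str, str], FilteredNetwork],
    pairs,
    n_bins: int,
) -> tuple[dict[str, float], list[str]]:
    """Per-subject PDiv over (sessionA, sessionB) pairs; subjects with an
    empty network are excluded and reported."""
    values: dict[str, float] = {}
    excluded: list[str] = []
    for a, b in pairs:
        na = networks[(a.subject_id, a.session_id)]
        nb = networks[(b.subject_id, b.session_id)]
        if na.is_empty or nb.is_empty:
            excluded.append(a.subject_id)
            continue
        values[a.subject_id] = portrait_divergence(na, nb, n_bins=n_bins)
    return values, excluded


def test_retest_pdiv(
    networks: dict[tuple[str, str], FilteredNetwork],
    cohort: CohortDataset,
    n_bins: int = 50,
) -> tuple[dict[str, float], float]:
    """PDiv between the two rest sessions of each subject, plus the group
    mean (NaN when every subject is excluded)."""
    values, _ = _pair_pdiv(networks, cohort.retest_pairs(), n_bins)
    mean = float(np.mean(list(values.values()))) if values else float("nan")
    return values, mean


def condition_pdiv(
    networks: dict[tuple[str, str], FilteredNetwork],
    cohort: CohortDataset,
    n_bins: int = 50,
) -> tuple[dict[str, float], float]:
    """PDiv between each subject's awake session and perturbed session."""
    values, _ = _pair_pdiv(networks, cohort.condition_pairs(), n_bins)
    mean = float(np.mean(list(values.values()))) if values else float("nan")
    return values, mean


def criterion_pdiv_rank(
    per_dataset_means: pd.DataFrame, top_fraction: float = 0.2
) -> pd.DataFrame:
    """Rank pipelines by mean test-retest PDiv within each dataset (rank 1 =
    lowest; ties get the average rank); the global rank is the mean across
    datasets; a pipeline passes if its global rank is within the top
    fraction (boundary inclusive)."""
    if len(per_dataset_means) < 2:
        raise ValueError("ranking needs at least 2 pipelines")
    ranks = per_dataset_means.rank(axis=0, method="average", na_option="bottom")
    global_rank = ranks.mean(axis=1)
    cutoff = top_fraction * len(per_dataset_means)
    return pd.DataFrame(
        {
            **{f"rank_{c}": ranks[c] for c in per_dataset_means.columns},
            "global_rank": global_rank,
            "crit_I": global_rank <= cutoff,
        }
    )


def _welch_t(x: np.ndarray, y: np.ndarray) -> float:
    vx = x.var(ddof=1) / len(x)
    vy = y.var(ddof=1) / len(y)
    return float((x.mean() - y.mean()) / np.sqrt(vx + vy))


def condition_contrast(
    pdiv_retest,
    pdiv_condition,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutation-based two-sample Welch t-test.

    t = mean(retest) - mean(condition) over the pooled standard error, so a
    *negative* t means the condition contrast exceeds the test-retest
    contrast (the expected direction).  The p-value is the fraction of
    group-label permutations with |t_perm| >= |t_obs| (add-one corrected).
    """
    x = np.asarray(list(pdiv_retest), dtype=float)
    y = np.asarray(list(pdiv_condition), dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 values per group")
    if x.var(ddof=0) == 0 and y.var(ddof=0) == 0:
        raise ValueError("degenerate zero-variance groups")
    pooled = np.concatenate([x, y])
    rng = rng or np.random.default_rng()
    t_obs = _welch_t(x, y)
    n1 = len(x)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        px, py = perm[:n1], perm[n1:]
        if px.var(ddof=0) == 0 and py.var(ddof=0) == 0:
            count += 1
            continue
        if abs(_welch_t(px, py)) >= abs(t_obs) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return t_obs, p


def criterion_within_between(
    networks: dict[tuple[str, str], FilteredNetwork],
    cohort: CohortDataset,
    n_bins: int = 50,
) -> float:
    """Proportion of subjects whose within-subject PDiv (rest1 vs rest2) is
    smaller than their between-subject PDiv (mean over rest1_s vs rest2_s'
    for all other subjects s')."""
    subjects = cohort.subjects
    if len(subjects) < 2:
        raise ValueError("within-between criterion needs at least 2 subjects")
    a, b = cohort.design.retest_pair
    usable = [
        s
        for s in subjects
        if not networks[(s, a)].is_empty and not networks[(s, b)].is_empty
    ]
    if len(usable) < 2:
        return float("nan")
    wins = 0
    for s in usable:
        ws = portrait_divergence(networks[(s, a)], networks[(s, b)], n_bins=n_bins)
        bs_vals = [
            portrait_divergence(networks[(s, a)], networks[(s2, b)], n_bins=n_bins)
            for s2 in usable
            if s2 != s
        ]
        if ws < float(np.mean(bs_vals)):
            wins += 1
    return wins / len(usable)


def criterion_motion(
    pdiv_by_subject: dict[str, float], cohort: CohortDataset
) -> tuple[float, float]:
    """Spearman correlation between per-subject test-retest PDiv and the
    absolute difference in session mean framewise displacement.  Undefined
    (constant) inputs return (nan, 1.0): treated as a pass."""
    a, b = cohort.design.retest_pair
    subjects = [s for s in cohort.subjects if s in pdiv_by_subject]
    if len(subjects) < 5:
        raise ValueError("motion criterion needs at least 5 subjects")
    pdivs = np.array([pdiv_by_subject[s] for s in subjects])
    dfd = np.array(
        [abs(cohort.session(s, a).mean_fd - cohort.session(s, b).mean_fd) for s in subjects]
    )
    if np.ptp(pdivs) == 0 or np.ptp(dfd) == 0:
        return float("nan"), 1.0
    rho, p = stats.spearmanr(pdivs, dfd)
    return float(rho), float(p)


def criterion_empty(networks: dict[tuple[str, str], FilteredNetwork]) -> bool:
    """True (pass) iff no session's network is empty."""
    return not any(net.is_empty for net in networks.values())


def evaluate_pipelines(
    pipelines: list[PipelineSpec],
    retest_cohorts: dict[str, CohortDataset],
    condition_cohorts: dict[str, CohortDataset],
    *,
    reference_retest: str | None = None,
    top_fraction: float = 0.2,
    n_perm: int = 1000,
    sdm_density: float = 0.25,
    mi_bins: int | None = None,
    n_bins: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Run every pipeline over every cohort and assemble the evaluation
    table with per-dataset metrics, criterion flags, and status labels.

    Criterion II compares each condition cohort's awake-vs-perturbed PDiv
    against the test-retest PDiv of the ``reference_retest`` cohort
    (default: the first test-retest cohort), mirroring a design where the
    condition cohort and the reference test-retest cohort are independent
    groups of subjects.
    """
    if not retest_cohorts:
        raise ValueError("need at least one test-retest cohort")
    reference_retest = reference_retest or next(iter(retest_cohorts))
    rows = []
    for spec in pipelines:
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, zlib.crc32(spec.pipeline_id.encode())])
        )
        row: dict = {
            "pipeline_id": spec.pipeline_id,
            "gsr": spec.gsr,
            "node_set": spec.node_set,
            "n_nodes": spec.n_nodes,
            "measure": spec.measure,
            "filter": spec.filter,
            "binarise": spec.binarise,
        }
        retest_values: dict[str, dict[str, float]] = {}
        for name, cohort in retest_cohorts.items():
            networks = run_pipeline(spec, cohort, sdm_density=sdm_density, mi_bins=mi_bins)
            values, mean = test_retest_pdiv(networks, cohort, n_bins=n_bins)
            retest_values[name] = values
            row[f"pdiv_{name}"] = mean
            row[f"wb_prop_{name}"] = criterion_within_between(networks, cohort, n_bins=n_bins)
            if values:
                try:
                    rho, p = criterion_motion(values, cohort)
                except ValueError:  # too few subjects: not evaluable, pass
                    rho, p = float("nan"), 1.0
            else:
                rho, p = float("nan"), 1.0
            row[f"motion_rho_{name}"] = rho
            row[f"motion_p_{name}"] = p
            row[f"empty_{name}"] = not criterion_empty(networks)
        for name, cohort in condition_cohorts.items():
            networks = run_pipeline(spec, cohort, sdm_density=sdm_density, mi_bins=mi_bins)
            cvalues, _ = condition_pdiv(networks, cohort, n_bins=n_bins)
            rvalues = retest_values[reference_retest]
            if len(cvalues) >= 3 and len(rvalues) >= 3:
                try:
                    t, p = condition_contrast(
                        rvalues.values(), cvalues.values(), n_perm=n_perm, rng=rng
                    )
                except ValueError:
                    t, p = float("nan"), 1.0
            else:
                t, p = float("nan"), 1.0
            row[f"t_{name}"] = t
            row[f"p_{name}"] = p
        rows.append(row)
    table = pd.DataFrame(rows).set_index("pipeline_id", drop=False)
    return _attach_flags(
        table,
        retest_names=tuple(retest_cohorts),
        condition_names=tuple(condition_cohorts),
        top_fraction=top_fraction,
        alpha=alpha,
    )


def _attach_flags(
    table: pd.DataFrame,
    retest_names: tuple[str, ...],
    condition_names: tuple[str, ...],
    top_fraction: float,
    alpha: float,
) -> pd.DataFrame:
    """Criterion flags are pure functions of the stored metrics, so they can
    be recomputed from a written table."""
    table = table.copy()
    means = table[[f"pdiv_{n}" for n in retest_names]]
    rank_info = criterion_pdiv_rank(means, top_fraction=top_fraction)
    for name in retest_names:
        table[f"rank_{name}"] = rank_info[f"rank_pdiv_{name}"]
    table["global_rank"] = rank_info["global_rank"]
    table["crit_I"] = rank_info["crit_I"]
    relaxed = criterion_pdiv_rank(means, top_fraction=0.5)
    table["crit_I_relaxed"] = relaxed["crit_I"]

    if condition_names:
        sig_neg = np.ones(len(table), dtype=bool)
        sig_pos = np.ones(len(table), dtype=bool)
        for name in condition_names:
            t = table[f"t_{name}"].to_numpy()
            p = table[f"p_{name}"].to_numpy()
            sig_neg &= (p < alpha) & (t < 0)
            sig_pos &= (p < alpha) & (t > 0)
        table["crit_II"] = sig_neg
        table["opposite"] = sig_pos
    else:
        table["crit_II"] = True
        table["opposite"] = False

    wb = table[[f"wb_prop_{n}" for n in retest_names]].to_numpy()
    table["crit_III"] = np.all(np.nan_to_num(wb, nan=-1.0) >= 0.5, axis=1)
    mp = table[[f"motion_p_{n}" for n in retest_names]].to_numpy()
    table["crit_IV"] = np.all(np.nan_to_num(mp, nan=1.0) >= alpha, axis=1)
    empty = table[[f"empty_{n}" for n in retest_names]].to_numpy()
    table["crit_V"] = ~np.any(empty, axis=1)

    strict = ["crit_I", "crit_II", "crit_III", "crit_IV", "crit_V"]
    table["optimal"] = table[strict].all(axis=1)
    table["optimal_relaxed"] = table[
        ["crit_I_relaxed", "crit_II", "crit_III", "crit_IV", "crit_V"]
    ].all(axis=1)
    return table


def select_optimal(table: pd.DataFrame) -> tuple[list[str], list[str]]:
    """(strict, relaxed) optimal pipeline ids: strict passes all five
    criteria; relaxed substitutes the top-50% PDiv rank cut."""
    strict = table.index[table["optimal"]].tolist()
    relaxed = table.index[table["optimal_relaxed"]].tolist()
    return strict, relaxed


def edge_stage_group(pipeline_id: str) -> str:
    """Group label for the edge-processing stage: measure x filter x
    binarisation (32 groups in the default grid)."""
    _, _, measure, filt, weight = pipeline_id.split("|")
    return f"{measure}|{filt}|{weight}"


def enrichment_permutation(
    optimal_ids: list[str],
    grouping: dict[str, str],
    n_draws: int = 100_000,
    rng: np.random.Generator | None = None,
    chunk: int = 500_000,
) -> dict:
    """Monte-Carlo probability that a random subset of size
    ``len(optimal_ids)`` drawn from all pipelines has at least m members in
    one group, where m is the largest group count observed among the
    optimal pipelines.

    Uses multivariate-hypergeometric sampling over the group sizes, which
    is equivalent to drawing the subset without replacement and counting
    group multiplicities.  Returns the add-one-corrected estimate, its
    Monte-Carlo standard error, and m.
    """
    rng = rng or np.random.default_rng()
    groups = pd.Series(grouping)
    sizes = groups.value_counts()
    observed = pd.Series([grouping[i] for i in optimal_ids]).value_counts()
    m = int(observed.max())
    k = len(optimal_ids)
    if m <= 1:
        return {"p": 1.0, "se": 0.0, "m": m, "n_draws": n_draws}
    hits = 0
    remaining = n_draws
    colors = sizes.to_numpy()
    while remaining > 0:
        batch = min(chunk, remaining)
        counts = rng.multivariate_hypergeometric(colors, k, size=batch, method="count")
        hits += int((counts.max(axis=1) >= m).sum())
        remaining -= batch
    p = (hits + 1) / (n_draws + 1)
    se = float(np.sqrt(max(hits, 1)) / n_draws)
    return {"p": p, "se": se, "m": m, "n_draws": n_draws, "hits": hits}


def write_selection_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Flat CSV report: one row per pipeline, columns for every per-dataset
    metric, criterion flag, and status label ('Optimal', 'Opposite', ...)."""
    path = Path(path)
    out = table.copy()
    status = np.where(
        out["optimal"], "Optimal", np.where(out["opposite"], "Opposite", "Non-optimal")
    )
    out["status"] = status
    out.to_csv(path, index=False)
    return path


def read_selection_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    return table.set_index("pipeline_id", drop=False)
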
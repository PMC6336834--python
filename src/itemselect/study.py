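"""Monte Carlo evaluation of item-assessment methods as selection criteria.

The study design crosses two sample sizes (N = 200, 1000) with three levels
of discrimination-parameter spread.  Each level is a bank of 20 items with
locations beta_i = 0 and discriminations equidistant on the log scale over
[-0.5, 0.5] (small), [-1, 1] (average) or [-2, 2] (large), so every bank has
a geometric-median discrimination of 1.  Dichotomous data are generated
from the two-parameter logistic model with a standard normal latent trait.

Within each of the six cells, every replication draws one data set and runs
both selection procedures under all four assessment methods (bottom-up runs
are seeded with the population-optimal initial pair, items {19, 20}, so that
the 18-step orderings of all runs range over the same items as the ideal
ordering).  Each produced ordering is compared with the ideal ordering by
Kendall's tau; agreement of orderings across replications is summarised by
Kendall's W; and per-step population reliabilities of the produced subtests
yield percentile trajectory bands.

Seeding: replication r of the cell (variance level v, sample size N) under
master seed s uses ``SeedSequence((s, index(v), N, r))``, so cells are
reproducible independently of execution order.
"""

from __future__ import annotations

import logging
import time
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from . import concordance
from .estimators import METHODS, ScoreMatrix
from .irt import ItemParams, LatentDist, TheoreticalMoments, theoretical_moments
from .selection import PROCEDURES, SelectionTrace, bottom_up, ideal_ordering, top_down

__all__ = [
    "VARIANCE_LEVELS",
    "discrimination_set",
    "item_bank",
    "generate_scores",
    "Design",
    "MethodCellResult",
    "CellResult",
    "run_cell",
    "run_study",
    "StudyResult",
    "make_fixtures",
]

logger = logging.getLogger(__name__)

VARIANCE_LEVELS = ("small", "average", "large")
SAMPLE_SIZES = (200, 1000)
_LOG_HALF_RANGE = {"small": 0.5, "average": 1.0, "large": 2.0}
_N_ITEMS = 20
TRAJECTORY_PROBS = (2.5, 50.0, 97.5)


def discrimination_set(level: str) -> np.ndarray:
    """The 20 discrimination parameters of one spread level.

    Values are ``exp`` of a 20-point equidistant grid on the log scale,
    stored at full precision (the familiar two-decimal table values are
    roundings of these).
    """
    try:
        h = _LOG_HALF_RANGE[level]
    except KeyError:
        raise ValueError(
            f"unknown variance level {level!r}; expected one of {VARIANCE_LEVELS}"
        ) from None
    return np.exp(np.linspace(-h, h, _N_ITEMS))


def item_bank(level: str) -> ItemParams:
    """Item parameters of one design cell: graded discriminations, beta = 0."""
    return ItemParams(discrimination_set(level), np.zeros(_N_ITEMS))


def generate_scores(params: ItemParams, N: int, seed) -> ScoreMatrix:
    """Simulate an N x J dichotomous score matrix from the 2PLM.

    Latent values are drawn i.i.d. standard normal; item scores are
    conditionally independent Bernoulli draws (local independence).  ``seed``
    is anything accepted by :func:`numpy.random.default_rng`.
    """
    if N < 1:
        raise ValueError("N must be at least 1")
    rng = np.random.default_rng(seed)
    theta = rng.standard_normal(N)
    P = expit(np.outer(theta, params.alpha) - params.alpha * params.beta)
    values = (rng.random((N, params.J)) < P).astype(np.int8)
    return ScoreMatrix(values)


@dataclass(frozen=True)
class Design:
    """Configuration of a (possibly partial) simulation study."""

    variance_levels: tuple[str, ...] = VARIANCE_LEVELS
    sample_sizes: tuple[int, ...] = SAMPLE_SIZES
    replications: int = 1000
    base_seed: int = 20182298
    procedures: tuple[str, ...] = PROCEDURES
    methods: tuple[str, ...] = METHODS

    def __post_init__(self) -> None:
        if self.replications < 2:
            raise ValueError("need at least 2 replications")
        for lv in self.variance_levels:
            if lv not in VARIANCE_LEVELS:
                raise ValueError(f"unknown variance level {lv!r}")
        for n in self.sample_sizes:
            if n < 1:
                raise ValueError("sample sizes must be positive")
        for pr in self.procedures:
            if pr not in PROCEDURES:
                raise ValueError(f"unknown procedure {pr!r}")
        for me in self.methods:
            if me not in METHODS:
                raise ValueError(f"unknown method {me!r}")
        if not (self.variance_levels and self.sample_sizes
                and self.procedures and self.methods):
            raise ValueError("all design factors must be non-empty")

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "Design":
        kwargs = {}
        for key in ("variance_levels", "sample_sizes", "procedures", "methods"):
            if key in cfg:
                val = cfg[key]
                if isinstance(val, str):
                    val = [v.strip() for v in val.split(",")]
                kwargs[key] = tuple(
                    int(v) if key == "sample_sizes" else str(v) for v in val
                )
        for key in ("replications", "base_seed"):
            if key in cfg:
                kwargs[key] = int(cfg[key])
        return cls(**kwargs)


@dataclass(frozen=True)
class MethodCellResult:
    """Summaries of one method x procedure combination within a cell."""

    procedure: str
    method: str
    taus: np.ndarray
    w: float
    trajectory: pd.DataFrame  # step, p2.5, p50, p97.5 of population rho_XX'
    diagnostics: Counter

    @property
    def mean_tau(self) -> float:
        return float(self.taus.mean())

    @property
    def sd_tau(self) -> float:
        return float(self.taus.std(ddof=1))


@dataclass(frozen=True)
class CellResult:
    """All summaries of one design cell (variance level x sample size)."""

    level: str
    N: int
    replications: int
    results: dict[tuple[str, str], MethodCellResult]
    ideal: dict[str, SelectionTrace]


def _subset_reliability_path(
    moments: TheoreticalMoments, trace_ordering, procedure: str, initial
) -> np.ndarray:
    """Population rho_XX' of the subtest after each selection step."""
    var_T = moments.var_T("exact")
    var_X = moments.var_X
    cov = moments.cov_X
    members = [int(l) - 1 for l in initial]
    sT = var_T[members].sum()
    sX = var_X[members].sum()
    C = cov[np.ix_(members, members)]
    off = C.sum() - np.trace(C)
    out = np.empty(len(trace_ordering))
    mask = np.zeros(moments.J, dtype=bool)
    mask[members] = True
    for s, label in enumerate(trace_ordering):
        k = int(label) - 1
        if procedure == "bottom_up":
            off += 2.0 * cov[k, mask].sum()
            sT += var_T[k]
            sX += var_X[k]
            mask[k] = True
        else:
            mask[k] = False
            off -= 2.0 * cov[k, mask].sum()
            sT -= var_T[k]
            sX -= var_X[k]
        out[s] = (sT + off) / (sX + off)
    return out


def run_cell(
    level: str,
    N: int,
    design: Design,
    seed_for_rep: Callable[[int], object] | None = None,
) -> CellResult:
    """Run every replication of one design cell.

    The same generated data set feeds all method x procedure combinations
    of a replication.  ``seed_for_rep`` overrides the default per-replication
    seed derivation (used in tests to force degenerate designs).
    """
    params = item_bank(level)
    moments = theoretical_moments(params, LatentDist())
    ideal = {pr: ideal_ordering(moments, pr) for pr in PROCEDURES}
    ideal_pair = ideal["bottom_up"].initial_set
    references = {pr: ideal[pr].ordering for pr in PROCEDURES}
    # Concordance across replications is taken over the complete addition
    # order for bottom-up runs: the seeded pair occupies steps 1-2 (more
    # reliable item first), the 18 selection steps follow.  Top-down
    # concordance uses the 18 removal steps.  Kendall's tau against the
    # ideal ordering always uses the 18 selection steps only.
    pair_first = tuple(
        sorted(ideal_pair, key=lambda l: -moments.var_T("exact")[l - 1]
               / moments.var_X[l - 1])
    )
    w_reference = {
        "bottom_up": pair_first + references["bottom_up"],
        "top_down": references["top_down"],
    }
    cell_code = VARIANCE_LEVELS.index(level)
    if seed_for_rep is None:
        seed_for_rep = lambda rep: np.random.SeedSequence(
            (design.base_seed, cell_code, N, rep)
        )

    combos = [(pr, me) for pr in design.procedures for me in design.methods]
    taus = {c: np.empty(design.replications) for c in combos}
    orderings: dict[tuple[str, str], list] = {c: [] for c in combos}
    paths = {c: np.empty((design.replications, _N_ITEMS - 2)) for c in combos}
    diagnostics = {c: Counter() for c in combos}

    t0 = time.perf_counter()
    for rep in range(design.replications):
        scores = generate_scores(params, N, seed_for_rep(rep))
        for pr, me in combos:
            if pr == "bottom_up":
                trace = bottom_up(scores, me, ideal_pair)
            else:
                trace = top_down(scores, me)
            ordering = trace.ordering_over(references[pr])
            taus[(pr, me)][rep] = concordance.kendall_tau(ordering, references[pr])
            orderings[(pr, me)].append(ordering)
            paths[(pr, me)][rep] = _subset_reliability_path(
                moments, trace.ordering, pr, trace.initial_set
            )
            diagnostics[(pr, me)].update(trace.diagnostics)
        if rep + 1 in (design.replications, 100) or (rep + 1) % 250 == 0:
            logger.info(
                "cell (%s, N=%d): replication %d/%d [%.1fs]",
                level, N, rep + 1, design.replications, time.perf_counter() - t0,
            )

    results = {}
    for combo in combos:
        pr, me = combo
        prefix = pair_first if pr == "bottom_up" else ()
        ranks = np.vstack(
            [concordance._ranks_of(np.asarray(prefix + o),
                                   np.asarray(w_reference[pr]))
             for o in orderings[combo]]
        )
        w = concordance.kendall_w(ranks)
        bands = np.percentile(paths[combo], TRAJECTORY_PROBS, axis=0)
        trajectory = pd.DataFrame(
            {
                "step": np.arange(1, _N_ITEMS - 1),
                "p2.5": bands[0],
                "p50": bands[1],
                "p97.5": bands[2],
            }
        )
        results[combo] = MethodCellResult(
            procedure=pr,
            method=me,
            taus=taus[combo],
            w=w,
            trajectory=trajectory,
            diagnostics=diagnostics[combo],
        )
    return CellResult(
        level=level, N=N, replications=design.replications,
        results=results, ideal=ideal,
    )


@dataclass(frozen=True)
class StudyResult:
    """Assembled study output: mean-tau table, W table, trajectory bands."""

    table_tau: pd.DataFrame
    table_w: pd.DataFrame
    trajectories: pd.DataFrame
    cells: dict[tuple[str, int], CellResult]

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table_tau.to_csv(outdir / "table4.csv", index=False)
        self.table_w.to_csv(outdir / "table5.csv", index=False)
        for (level, n), group in self.trajectories.groupby(
            ["variance_level", "N"], sort=False
        ):
            group.drop(columns=["variance_level", "N"]).to_csv(
                outdir / f"trajectory_{level}_N{n}.csv", index=False
            )


def run_study(design: Design) -> StudyResult:
    """Run all requested cells and assemble the summary tables."""
    cells: dict[tuple[str, int], CellResult] = {}
    tau_rows, w_rows, traj_rows = [], [], []
    for level in design.variance_levels:
        for N in design.sample_sizes:
            logger.info("running cell (%s, N=%d), m=%d", level, N, design.replications)
            cell = run_cell(level, N, design)
            cells[(level, N)] = cell
            for (pr, me), res in cell.results.items():
                tau_rows.append(
                    {
                        "procedure": pr, "method": me, "N": N,
                        "variance_level": level,
                        "mean_tau": res.mean_tau, "sd_tau": res.sd_tau,
                    }
                )
                w_rows.append(
                    {
                        "procedure": pr, "method": me, "N": N,
                        "variance_level": level, "W": res.w,
                    }
                )
                traj = res.trajectory.copy()
                traj.insert(0, "method", me)
                traj.insert(0, "procedure", pr)
                traj.insert(0, "N", N)
                traj.insert(0, "variance_level", level)
                traj_rows.append(traj)
    return StudyResult(
        table_tau=pd.DataFrame(tau_rows),
        table_w=pd.DataFrame(w_rows),
        trajectories=pd.concat(traj_rows, ignore_index=True),
        cells=cells,
    )


def make_fixtures() -> dict[str, ScoreMatrix]:
    """Small deterministic score matrices for tests and worked examples.

    ``F1`` is an 8 x 3 Guttman-patterned matrix with strictly decreasing
    popularities (7/8, 5/8, 3/8); ``F2`` appends one non-Guttman row.  The
    degenerate fixtures exercise error paths: a constant column and an
    exactly duplicated column.
    """
    f1 = np.array(
        [
            [0, 0, 0],
            [1, 0, 0],
            [1, 0, 0],
            [1, 1, 0],
            [1, 1, 0],
            [1, 1, 1],
            [1, 1, 1],
            [1, 1, 1],
        ]
    )
    f2 = np.vstack([f1, [0, 1, 0]])
    constant = np.array([[1, 0, 1], [1, 1, 0], [1, 0, 0], [1, 1, 1]])
    dup = np.array([[0, 0, 1], [1, 1, 0], [1, 1, 1], [0, 0, 0], [1, 1, 0]])
    return {
        "F1": ScoreMatrix(f1),
        "F2": ScoreMatrix(f2),
        "constant_column": ScoreMatrix(constant),
        "duplicated_columns": ScoreMatrix(dup),
    }
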
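"""Stepwise item-selection procedures for test construction.

Two irreversible procedures are implemented:

bottom-up
    Start from a fixed two-item test and repeatedly add the pool item whose
    assessment value, computed *within the provisional test plus that item*,
    is largest, until the pool is empty.

top-down
    Start from the full pool and repeatedly remove the item whose assessment
    value within the current test is smallest, until two items remain (the
    last decision is made on a three-item test, the smallest test on which
    the assessment methods are defined).

The assessment criterion is any of the sample methods in
:mod:`itemselect.estimators` (MS, L6, CA, CITC).  The *ideal* counterparts
replace the sample criterion by the population sum-score reliability
rho_XX' from :mod:`itemselect.irt`: the bottom-up ideal seeds itself with
the pair of highest rho_XX' and always adds the item whose inclusion
maximises rho_XX'; the top-down ideal removes the item whose omission
maximises rho_XX' of the remainder.

Every step records the full candidate set and criterion values, so a trace
can be audited and re-scored after the fact.  Ties in a criterion are broken
by the smallest original item label, making all procedures deterministic.
"""

from __future__ import annotations

import json
from bisect import insort
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import estimators as est
from .estimators import SingularCovarianceError, UndefinedValueError
from .irt import TheoreticalMoments, test_score_reliability

__all__ = [
    "SelectionStep",
    "SelectionTrace",
    "ideal_ordering",
    "bottom_up",
    "top_down",
    "PROCEDURES",
]

PROCEDURES = ("bottom_up", "top_down")


@dataclass(frozen=True)
class SelectionStep:
    """One selection step: all candidates, their criterion values, the choice."""

    candidates: tuple[int, ...]
    criteria: tuple[float, ...]
    chosen: int
    chosen_value: float


@dataclass
class SelectionTrace:
    """Full record of a stepwise selection run.

    ``ordering`` is the sequence of chosen labels: items *added* for the
    bottom-up procedure (the fixed initial pair is not part of it), items
    *removed* for the top-down procedure (the two survivors are not part of
    it).  ``method`` is the assessment method tag, or ``None`` for the ideal
    procedures driven by population reliability.
    """

    procedure: str
    initial_set: tuple[int, ...]
    steps: list[SelectionStep] = field(default_factory=list)
    method: str | None = None
    diagnostics: Counter = field(default_factory=Counter)

    @property
    def ordering(self) -> tuple[int, ...]:
        return tuple(s.chosen for s in self.steps)

    @property
    def final_set(self) -> tuple[int, ...]:
        """Items in the test after the last step."""
        if self.procedure == "bottom_up":
            return tuple(sorted(set(self.initial_set) | set(self.ordering)))
        return tuple(sorted(set(self.initial_set) - set(self.ordering)))

    def ordering_over(self, reference: Iterable[int]) -> tuple[int, ...]:
        """This trace's ordering restricted to a reference item set.

        For a top-down trace whose survivors differ from the reference's,
        surviving reference items are appended after all removed ones — they
        outlasted every removed item — ordered by their final-step criterion
        (the nearer to removal, the earlier), ties by smallest label.  This
        keeps rank comparisons well defined when a sample run retains items
        the ideal run removes.
        """
        ref = {int(r) for r in reference}
        ordered = [l for l in self.ordering if l in ref]
        missing = ref - set(self.ordering)
        if missing:
            if self.procedure != "top_down" or not missing <= set(self.final_set):
                raise ValueError(
                    f"reference items {sorted(missing)} absent from the trace ordering"
                )
            last = self.steps[-1]
            crit = dict(zip(last.candidates, last.criteria))
            ordered += sorted(missing, key=lambda l: (crit.get(l, np.inf), l))
        if len(ordered) != len(ref):
            raise ValueError("trace ordering does not cover the reference item set")
        return tuple(ordered)

    def to_dict(self) -> dict:
        return {
            "procedure": self.procedure,
            "method": self.method,
            "initial_set": list(self.initial_set),
            "ordering": list(self.ordering),
            "final_set": list(self.final_set),
            "diagnostics": dict(self.diagnostics),
            "steps": [
                {
                    "candidates": list(s.candidates),
                    "criteria": list(s.criteria),
                    "chosen": s.chosen,
                    "chosen_value": s.chosen_value,
                }
                for s in self.steps
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(1, len(self.steps) + 1),
                "chosen_item": [s.chosen for s in self.steps],
                "criterion": [s.chosen_value for s in self.steps],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ideal (population) orderings
# ---------------------------------------------------------------------------


def ideal_ordering(
    moments: TheoreticalMoments,
    procedure: str,
    variance_mode: str = "exact",
) -> SelectionTrace:
    """Selection trace driven by the population sum-score reliability rho_XX'."""
    if procedure not in PROCEDURES:
        raise ValueError(f"procedure must be one of {PROCEDURES}")
    labels = [int(l) for l in moments.labels]

    def rho(subset: Sequence[int]) -> float:
        return test_score_reliability(moments, subset, variance_mode)

    if procedure == "bottom_up":
        best_pair, best_rho = None, -np.inf
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                r = rho((a, b))
                if r > best_rho:
                    best_pair, best_rho = (a, b), r
        trace = SelectionTrace(procedure="bottom_up", initial_set=best_pair)
        test = sorted(best_pair)
        pool = sorted(set(labels) - set(best_pair))
        while pool:
            crit = [rho(sorted(test + [c])) for c in pool]
            k = int(np.argmax(crit))
            chosen = pool.pop(k)
            trace.steps.append(
                SelectionStep(tuple(pool[:k]) + (chosen,) + tuple(pool[k:]),
                              tuple(crit), chosen, crit[k])
            )
            insort(test, chosen)
        return trace

    trace = SelectionTrace(procedure="top_down", initial_set=tuple(sorted(labels)))
    test = sorted(labels)
    while len(test) > 2:
        crit = [rho([l for l in test if l != c]) for c in test]
        k = int(np.argmax(crit))  # omission maximising the remainder's rho
        chosen = test.pop(k)
        trace.steps.append(SelectionStep(tuple(test[:k]) + (chosen,) + tuple(test[k:]),
                                         tuple(crit), chosen, crit[k]))
    return trace


# ---------------------------------------------------------------------------
# vectorised per-step criterion evaluation on sufficient statistics
# ---------------------------------------------------------------------------


def _bottom_up_values(scores, t_idx, c_idx, method, diag: Counter):
    """Criterion value for each candidate: its assessment within test + candidate.

    Closed forms exploit that the candidate's rest score within the enlarged
    test is exactly the current test's sum score, so one pass over the cached
    covariance matrix scores every candidate at once; the regression residual
    variance behind L6 comes from a Schur complement against the test block.
    Results agree with per-item calls of the estimators module (tested).
    """
    labels = scores.item_labels
    if method == "MS":
        p, PJ = scores.popularity(), scores.joint()
        out = np.empty(c_idx.size)
        for k, c in enumerate(c_idx):
            sub = np.append(t_idx, c)
            out[k], flags = est._ms_stats(
                p[sub], PJ[np.ix_(sub, sub)], t_idx.size, labels[sub]
            )
            diag.update(flags)
        return out

    S = scores.cov()
    S_tt = S[np.ix_(t_idx, t_idx)]
    var_R = S_tt.sum()
    if var_R <= 0:
        raise UndefinedValueError("provisional test score has zero variance")
    S_ct = S[np.ix_(c_idx, t_idx)]
    var_c = S[c_idx, c_idx]
    if np.any(var_c <= 0):
        bad = int(labels[c_idx[np.argmin(var_c)]])
        raise UndefinedValueError(f"item {bad} has zero variance")
    r = S_ct.sum(axis=1) / np.sqrt(var_c * var_R)
    if method == "CITC":
        return r
    if method == "CA":
        a_rest = est._alpha_stats(S_tt)
        if a_rest <= 0:
            raise UndefinedValueError(
                "coefficient alpha of the provisional test is not positive"
            )
        vals = r * r / a_rest
        diag.update({"ca_above_one": int(np.count_nonzero(vals > 1.0))})
        return vals
    # L6: residual variance of candidate regressed on the test items
    try:
        B = np.linalg.solve(S_tt, S_ct.T)
    except np.linalg.LinAlgError:
        raise SingularCovarianceError(
            est._collinearity_message(S_tt, labels[t_idx])
        ) from None
    eps2 = var_c - np.einsum("kc,kc->c", S_ct.T, B)
    if np.any(eps2 <= 0):
        bad = int(labels[c_idx[np.argmin(eps2)]])
        raise SingularCovarianceError(
            f"item {bad} is perfectly predicted by the provisional test"
        )
    return 1.0 - eps2 / var_c


def _test_values(scores, idx, method, diag: Counter):
    """Assessment of every item within the test given by positions ``idx``."""
    labels = scores.item_labels
    if method == "MS":
        p, PJ = scores.popularity(), scores.joint()
        p_s, PJ_s, lab_s = p[idx], PJ[np.ix_(idx, idx)], labels[idx]
        out = np.empty(idx.size)
        for j in range(idx.size):
            out[j], flags = est._ms_stats(p_s, PJ_s, j, lab_s)
            diag.update(flags)
        return out

    S = scores.cov()[np.ix_(idx, idx)]
    k = idx.size
    var = np.diag(S).copy()
    if np.any(var <= 0):
        bad = int(labels[idx[np.argmin(var)]])
        raise UndefinedValueError(f"item {bad} has zero variance")
    row = S.sum(axis=1)
    total = S.sum()
    var_R = total - 2.0 * row + var
    if np.any(var_R <= 0):
        bad = int(labels[idx[np.argmin(var_R)]])
        raise UndefinedValueError(f"rest score of item {bad} has zero variance")
    r = (row - var) / np.sqrt(var * var_R)
    if method == "CITC":
        return r
    if method == "CA":
        if k < 3:
            raise UndefinedValueError("method CA requires at least 3 items")
        trace = var.sum()
        a_rest = (k - 1) / (k - 2) * (1.0 - (trace - var) / var_R)
        if np.any(a_rest <= 0):
            bad = int(labels[idx[np.argmin(a_rest)]])
            raise UndefinedValueError(
                f"coefficient alpha of the rest of item {bad} is not positive"
            )
        vals = r * r / a_rest
        diag.update({"ca_above_one": int(np.count_nonzero(vals > 1.0))})
        return vals
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        raise SingularCovarianceError(
            est._collinearity_message(S, labels[idx])
        ) from None
    prec = np.diag(Sinv)
    if np.any(~np.isfinite(prec)) or np.any(prec <= 0):
        raise SingularCovarianceError(est._collinearity_message(S, labels[idx]))
    return 1.0 - (1.0 / prec) / var


# ---------------------------------------------------------------------------
# sample-driven procedures
# ---------------------------------------------------------------------------


def _check_method(method: str) -> None:
    if method not in est.METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {est.METHODS}")


def bottom_up(scores, method: str, initial_pair: Sequence[int]) -> SelectionTrace:
    """Grow a test from ``initial_pair`` by repeatedly adding the best item.

    At each step the criterion for pool candidate ``c`` is the assessment of
    ``c`` itself computed within the provisional test plus ``c``; the argmax
    joins the test, ties going to the smallest original item label.
    """
    _check_method(method)
    initial_pair = tuple(int(l) for l in initial_pair)
    if len(set(initial_pair)) != 2:
        raise ValueError("initial_pair must contain exactly 2 distinct items")
    all_labels = {int(l) for l in scores.item_labels}
    if not set(initial_pair) <= all_labels:
        raise ValueError("initial_pair items not present in the score matrix")
    if scores.J < 3:
        raise ValueError("bottom-up selection needs at least 3 items")
    pos = {int(l): i for i, l in enumerate(scores.item_labels)}
    test = sorted(initial_pair)
    pool = sorted(all_labels - set(initial_pair))
    trace = SelectionTrace(
        procedure="bottom_up", initial_set=initial_pair, method=method
    )
    step_no = 0
    while pool:
        step_no += 1
        t_idx = np.fromiter((pos[l] for l in test), int, len(test))
        c_idx = np.fromiter((pos[l] for l in pool), int, len(pool))
        try:
            vals = _bottom_up_values(scores, t_idx, c_idx, method, trace.diagnostics)
        except (UndefinedValueError, SingularCovarianceError) as exc:
            raise type(exc)(f"bottom-up step {step_no}: {exc}") from exc
        k = int(np.argmax(vals))
        chosen = pool.pop(k)
        trace.steps.append(
            SelectionStep(tuple(pool[:k]) + (chosen,) + tuple(pool[k:]),
                          tuple(vals), chosen, float(vals[k]))
        )
        insort(test, chosen)
    return trace


def top_down(scores, method: str) -> SelectionTrace:
    """Shrink the full test by repeatedly removing the worst item.

    At each step every current item is assessed within the current test and
    the argmin is removed (ties to the smallest label); selection stops when
    two items remain.
    """
    _check_method(method)
    if scores.J < 3:
        raise ValueError("top-down selection needs at least 3 items")
    pos = {int(l): i for i, l in enumerate(scores.item_labels)}
    test = sorted(pos)
    trace = SelectionTrace(
        procedure="top_down", initial_set=tuple(test), method=method
    )
    step_no = 0
    while len(test) > 2:
        step_no += 1
        idx = np.fromiter((pos[l] for l in test), int, len(test))
        try:
            vals = _test_values(scores, idx, method, trace.diagnostics)
        except (UndefinedValueError, SingularCovarianceError) as exc:
            raise type(exc)(f"top-down step {step_no}: {exc}") from exc
        k = int(np.argmin(vals))
        chosen = test.pop(k)
        trace.steps.append(
            SelectionStep(tuple(test[:k]) + (chosen,) + tuple(test[k:]),
                          tuple(vals), chosen, float(vals[k]))
        )
    return trace
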
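"""Sample-based item-assessment methods for dichotomous score matrices.

Four per-item statistics are provided, each a function of the item's
relationship to the rest of the (sub)test it sits in:

CITC
    Corrected item-total correlation: Pearson correlation between the item
    score ``X_i`` and the rest score ``R(i) = X - X_i``.
L6 (Guttman's lambda-6, item version)
    ``1 - eps2_i / var(X_i)`` where ``eps2_i`` is the residual variance of
    the least-squares regression of ``X_i`` on the other items, obtained as
    ``1 / [S^-1]_ii`` from the inverse covariance matrix.
CA (correction for attenuation)
    ``CITC^2 / alpha_rest`` where ``alpha_rest`` is coefficient alpha of the
    remaining items.  Values above 1 are reported as-is and flagged, never
    truncated, so that argmax/argmin selection steps see no spurious ties.
MS (Molenaar–Sijtsma item method)
    Approximates the pass-twice probability ``pi_ii`` of an independent
    replication of the item from its joint proportions with the items
    nearest to it in the sample difficulty (popularity) ordering, under the
    double monotonicity model: linear interpolation between the adjacent
    distinct-popularity groups (tied items are pooled; exact ties with the
    target are used directly), a conditional-rate rule at the two extremes;
    returns ``(pi_hat_ii - p_i^2) / (p_i (1 - p_i))``.

All estimators consume only sufficient statistics (column means, covariance
matrix with N-1 denominator, joint proportion matrix), which
:class:`ScoreMatrix` caches on first use.  :class:`PopulationScores` exposes
the same interface built from model-implied moments, so every estimator and
selection procedure can also be evaluated at the population level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScoreMatrix",
    "PopulationScores",
    "ItemAssessment",
    "UndefinedValueError",
    "SingularCovarianceError",
    "citc",
    "coefficient_alpha",
    "method_ca",
    "method_lambda6",
    "method_ms",
    "assess_all",
    "METHODS",
]

METHODS = ("MS", "L6", "CA", "CITC")

class UndefinedValueError(ValueError):
    """An estimator is undefined for these data (zero variance, alpha <= 0...)."""


class SingularCovarianceError(ValueError):
    """The inter-item covariance matrix is (numerically) singular."""


class ScoreMatrix:
    """An N x J matrix of dichotomous (0/1) item scores.

    Parameters
    ----------
    values : array-like of shape (N, J)
        Entries must be exactly 0 or 1.
    item_labels : sequence of int, optional
        Original item identities, stable across subsetting; defaults to 1..J.

    Sufficient statistics (popularities, covariance matrix, joint proportion
    matrix) are computed lazily and shared with subsets, so repeated
    subtest evaluations never rescan the raw data.
    """

    def __init__(self, values, item_labels: Sequence[int] | None = None):
        values = np.asarray(values)
        if values.ndim != 2:
            raise ValueError("score matrix must be two-dimensional")
        if not np.isin(values, (0, 1)).all():
            raise ValueError("score matrix entries must be exactly 0 or 1")
        self.values = values.astype(np.int8, copy=False)
        if item_labels is None:
            item_labels = np.arange(1, self.values.shape[1] + 1)
        item_labels = np.asarray(item_labels, dtype=int)
        if item_labels.size != self.values.shape[1]:
            raise ValueError("one label per item required")
        if np.unique(item_labels).size != item_labels.size:
            raise ValueError("item labels must be unique")
        self.item_labels = item_labels
        self._pop: np.ndarray | None = None
        self._cov: np.ndarray | None = None
        self._joint: np.ndarray | None = None

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def J(self) -> int:
        return self.values.shape[1]

    def popularity(self) -> np.ndarray:
        """Per-item proportion of 1-scores (sample difficulty)."""
        if self._pop is None:
            self._pop = self.values.mean(axis=0)
        return self._pop

    def cov(self) -> np.ndarray:
        """Sample covariance matrix with N-1 denominator."""
        if self._cov is None:
            if self.N < 2:
                raise ValueError("need at least 2 persons for a covariance matrix")
            self._cov = np.atleast_2d(np.cov(self.values.T.astype(float), ddof=1))
        return self._cov

    def joint(self) -> np.ndarray:
        """Joint proportion matrix P[i, j] = mean(X_i * X_j); diagonal = popularity."""
        if self._joint is None:
            x = self.values.astype(float)
            self._joint = (x.T @ x) / self.N
        return self._joint

    def position(self, label: int) -> int:
        pos = np.flatnonzero(self.item_labels == label)
        if pos.size == 0:
            raise KeyError(f"no item with label {label}")
        return int(pos[0])

    def subset(self, labels: Iterable[int]) -> "ScoreMatrix":
        """Column subset by label, inheriting any cached statistics."""
        idx = np.array([self.position(l) for l in labels], dtype=int)
        sub = ScoreMatrix(self.values[:, idx], self.item_labels[idx])
        ix = np.ix_(idx, idx)
        if self._pop is not None:
            sub._pop = self._pop[idx]
        if self._cov is not None:
            sub._cov = self._cov[ix]
        if self._joint is not None:
            sub._joint = self._joint[ix]
        return sub

    @classmethod
    def from_csv(cls, path) -> "ScoreMatrix":
        """Read a CSV of 0/1 integers, one person per row.

        A first row containing any token other than 0/1 is treated as a
        header of item labels and round-tripped by :meth:`to_csv`.
        """
        first = pd.read_csv(path, header=None, nrows=1)
        has_header = not first.iloc[0].astype(str).isin(["0", "1"]).all()
        if has_header:
            df = pd.read_csv(path)
            labels = [int(c) for c in df.columns]
            return cls(df.to_numpy(), labels)
        return cls(pd.read_csv(path, header=None).to_numpy())

    def to_csv(self, path, header: bool = False) -> None:
        df = pd.DataFrame(self.values, columns=self.item_labels)
        df.to_csv(path, index=False, header=header)


class PopulationScores:
    """Population analogue of :class:`ScoreMatrix` built from 2PLM moments.

    Exposes the same sufficient-statistic interface (popularity, covariance,
    joint proportions) with model-implied values, so estimators and
    selection procedures can be evaluated free of sampling error.  The joint
    matrix diagonal holds the marginal ``pi_i`` (as in a sample, where
    ``X_i^2 = X_i``); the pass-twice probability ``pi_ii`` plays no role in
    the estimators' formulas.
    """

    def __init__(self, moments):
        self.item_labels = np.asarray(moments.labels, dtype=int)
        self._pop = np.asarray(moments.pi, dtype=float)
        self._cov = np.asarray(moments.cov_X, dtype=float)
        joint = np.asarray(moments.pi_joint, dtype=float).copy()
        np.fill_diagonal(joint, self._pop)
        self._joint = joint
        self.N = None

    @property
    def J(self) -> int:
        return self.item_labels.size

    def popularity(self) -> np.ndarray:
        return self._pop

    def cov(self) -> np.ndarray:
        return self._cov

    def joint(self) -> np.ndarray:
        return self._joint

    def position(self, label: int) -> int:
        pos = np.flatnonzero(self.item_labels == label)
        if pos.size == 0:
            raise KeyError(f"no item with label {label}")
        return int(pos[0])

    def subset(self, labels: Iterable[int]) -> "PopulationScores":
        idx = np.array([self.position(l) for l in labels], dtype=int)
        out = object.__new__(PopulationScores)
        out.item_labels = self.item_labels[idx]
        out._pop = self._pop[idx]
        out._cov = self._cov[np.ix_(idx, idx)]
        out._joint = self._joint[np.ix_(idx, idx)]
        out.N = None
        return out


class _StatsView:
    """Subtest view onto precomputed sufficient statistics.

    Used by the selection procedures, which evaluate thousands of candidate
    subtests per data set: slicing the cached 20 x 20 statistic matrices is
    far cheaper than materialising column subsets of the raw scores.
    """

    __slots__ = ("item_labels", "N", "_pop", "_cov", "_joint")

    def __init__(self, parent, idx: np.ndarray):
        ix = np.ix_(idx, idx)
        self.item_labels = parent.item_labels[idx]
        self.N = getattr(parent, "N", None)
        self._pop = parent.popularity()[idx]
        self._cov = parent.cov()[ix]
        self._joint = parent.joint()[ix]

    @property
    def J(self) -> int:
        return self.item_labels.size

    def popularity(self) -> np.ndarray:
        return self._pop

    def cov(self) -> np.ndarray:
        return self._cov

    def joint(self) -> np.ndarray:
        return self._joint

    def position(self, label: int) -> int:
        pos = np.flatnonzero(self.item_labels == label)
        if pos.size == 0:
            raise KeyError(f"no item with label {label}")
        return int(pos[0])


@dataclass(frozen=True)
class ItemAssessment:
    """Per-item values of one assessment method, with diagnostic flags."""

    method: str
    item_labels: np.ndarray
    values: np.ndarray
    diagnostics: dict[int, tuple[str, ...]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        flags = [";".join(self.diagnostics.get(int(l), ())) for l in self.item_labels]
        return pd.DataFrame(
            {
                "item": self.item_labels,
                "method": self.method,
                "value": self.values,
                "flags": flags,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# sufficient-statistic kernels (positions, not labels)
# ---------------------------------------------------------------------------


def _citc_stats(S: np.ndarray, i: int, labels: np.ndarray) -> float:
    row = S[i].sum()
    var_i = S[i, i]
    cov_ir = row - var_i
    var_r = S.sum() - 2.0 * row + var_i
    if var_i <= 0:
        raise UndefinedValueError(f"item {labels[i]} has zero variance")
    if var_r <= 0:
        raise UndefinedValueError(
            f"rest score of item {labels[i]} has zero variance"
        )
    return float(cov_ir / np.sqrt(var_i * var_r))


def _alpha_stats(S: np.ndarray) -> float:
    J = S.shape[0]
    if J < 2:
        raise UndefinedValueError("coefficient alpha requires at least 2 items")
    total = S.sum()
    if total <= 0:
        raise UndefinedValueError("total score has zero variance")
    return float(J / (J - 1) * (1.0 - np.trace(S) / total))


def _ca_stats(S: np.ndarray, i: int, labels: np.ndarray) -> tuple[float, list[str]]:
    if S.shape[0] < 3:
        raise UndefinedValueError("method CA requires at least 3 items")
    r = _citc_stats(S, i, labels)
    keep = np.arange(S.shape[0]) != i
    a_rest = _alpha_stats(S[np.ix_(keep, keep)])
    if a_rest <= 0:
        raise UndefinedValueError(
            f"coefficient alpha of the rest of item {labels[i]} is not positive"
        )
    value = r * r / a_rest
    flags = ["ca_above_one"] if value > 1.0 else []
    return value, flags


def _lambda6_stats(S: np.ndarray, i: int, labels: np.ndarray) -> float:
    if S.shape[0] < 3:
        raise UndefinedValueError("method L6 requires at least 3 items")
    if S[i, i] <= 0:
        raise UndefinedValueError(f"item {labels[i]} has zero variance")
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        raise SingularCovarianceError(_collinearity_message(S, labels)) from None
    prec = Sinv[i, i]
    if not np.isfinite(prec) or prec <= 0 or prec > 1e12 / max(S[i, i], 1e-30):
        raise SingularCovarianceError(_collinearity_message(S, labels))
    eps2 = 1.0 / prec
    return float(1.0 - eps2 / S[i, i])


def _collinearity_message(S: np.ndarray, labels: np.ndarray) -> str:
    d = np.sqrt(np.clip(np.diag(S), 0, None))
    zero = [int(labels[k]) for k in np.flatnonzero(d == 0)]
    if zero:
        return f"covariance matrix singular: zero-variance items {zero}"
    R = S / np.outer(d, d)
    pairs = [
        (int(labels[a]), int(labels[b]))
        for a in range(len(labels))
        for b in range(a + 1, len(labels))
        if abs(R[a, b]) > 1 - 1e-10
    ]
    if pairs:
        return f"covariance matrix singular: collinear item pairs {pairs}"
    return "covariance matrix singular"


def _ms_stats(
    p: np.ndarray, PJ: np.ndarray, i: int, labels: np.ndarray
) -> tuple[float, list[str]]:
    """MS kernel on popularities ``p`` and joint proportions ``PJ``.

    The pass-twice probability of the target item is approximated from its
    joint proportions with the items closest to it in sample difficulty.
    Items are grouped by *distinct* popularity value (tied items sit at the
    same estimated location, so their information is pooled):

    * other items tied with the target are direct stand-ins for an
      independent replication: ``p_hat = mean of their joint proportions``;
    * a target at an interior distinct popularity is interpolated linearly
      between the group-mean joint proportions of the adjacent higher and
      lower popularity groups;
    * a target at the highest or lowest distinct popularity has no bracket,
      so its repeat-pass rate is borrowed from the nearest group:
      ``p_hat = p_i * (group-mean joint) / (group popularity)``, i.e. the
      conditional pass rate among passers of the nearest neighbours.

    The estimate is clamped to its Frechet-feasible interval
    ``[max(0, 2 p_i - 1), p_i]`` and the resulting reliability to at most 1;
    clamps and the tie pooling are recorded as diagnostic flags.
    """
    J = p.size
    if J < 3:
        raise UndefinedValueError("method MS requires at least 3 items")
    p_i = p[i]
    if p_i <= 0 or p_i >= 1:
        raise UndefinedValueError(f"item {labels[i]} has a constant score column")
    flags: list[str] = []
    tied = np.flatnonzero((p == p_i) & (np.arange(J) != i))
    if tied.size:
        flags.append("ms_tied_target")
        p_hat = float(np.mean(PJ[i, tied]))
    else:
        values = np.unique(p)[::-1]  # distinct popularities, descending
        t = int(np.flatnonzero(values == p_i)[0])

        def group_joint(v: float) -> float:
            return float(np.mean(PJ[i, np.flatnonzero(p == v)]))

        if t == 0 or t == values.size - 1:
            v_a = values[1] if t == 0 else values[t - 1]
            p_hat = group_joint(v_a) * p_i / v_a
        else:
            v_prev, v_next = values[t - 1], values[t + 1]
            P_prev, P_next = group_joint(v_prev), group_joint(v_next)
            p_hat = P_next + (p_i - v_next) * (P_prev - P_next) / (v_prev - v_next)
    lo, hi = max(0.0, 2.0 * p_i - 1.0), p_i
    if p_hat < lo:
        flags.append("ms_phat_clamped_low")
        p_hat = lo
    elif p_hat > hi:
        flags.append("ms_phat_clamped_high")
        p_hat = hi
    value = (p_hat - p_i * p_i) / (p_i * (1.0 - p_i))
    if value > 1.0:
        flags.append("ms_reliability_clamped")
        value = 1.0
    return float(value), flags


_KERNELS = {
    "CITC": lambda sc, i: (_citc_stats(sc.cov(), i, sc.item_labels), []),
    "CA": lambda sc, i: _ca_stats(sc.cov(), i, sc.item_labels),
    "L6": lambda sc, i: (_lambda6_stats(sc.cov(), i, sc.item_labels), []),
    "MS": lambda sc, i: _ms_stats(sc.popularity(), sc.joint(), i, sc.item_labels),
}


def _require_n(scores, n_min: int, what: str) -> None:
    n = getattr(scores, "N", None)
    if n is not None and n < n_min:
        raise UndefinedValueError(f"{what} requires at least {n_min} persons")


def citc(scores, item: int) -> float:
    """Corrected item-total correlation of ``item`` (by label) with its rest score."""
    _require_n(scores, 3, "the corrected item-total correlation")
    if scores.J < 2:
        raise UndefinedValueError("a rest score requires at least 2 items")
    return _citc_stats(scores.cov(), scores.position(item), scores.item_labels)


def coefficient_alpha(scores) -> float:
    """Cronbach's coefficient alpha of the full (sub)test."""
    return _alpha_stats(scores.cov())


def method_ca(scores, item: int) -> float:
    """Item-score reliability by correction for attenuation: CITC^2 / alpha_rest."""
    _require_n(scores, 3, "method CA")
    value, _ = _ca_stats(scores.cov(), scores.position(item), scores.item_labels)
    return value


def method_lambda6(scores, item: int) -> float:
    """Item-score reliability by Guttman's lambda-6 (regression residual variance)."""
    _require_n(scores, 3, "method L6")
    return _lambda6_stats(scores.cov(), scores.position(item), scores.item_labels)


def method_ms(scores, item: int) -> float:
    """Item-score reliability by the Molenaar–Sijtsma neighbour method."""
    _require_n(scores, 3, "method MS")
    value, _ = _ms_stats(
        scores.popularity(), scores.joint(), scores.position(item), scores.item_labels
    )
    return value


def assess_all(scores, method: str) -> ItemAssessment:
    """Apply one assessment method to every item of the (sub)test."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    kernel = _KERNELS[method]
    values = np.empty(scores.J)
    diagnostics: dict[int, tuple[str, ...]] = {}
    for i, label in enumerate(scores.item_labels):
        try:
            values[i], flags = kernel(scores, i)
        except (UndefinedValueError, SingularCovarianceError) as exc:
            raise type(exc)(f"item {int(label)}: {exc}") from exc
        if flags:
            diagnostics[int(label)] = tuple(flags)
    return ItemAssessment(
        method=method,
        item_labels=scores.item_labels.copy(),
        values=values,
        diagnostics=diagnostics,
    )
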
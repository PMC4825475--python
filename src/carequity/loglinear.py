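"""Hierarchical log-linear models for multiway contingency tables.

A hierarchical model is identified by its *generating class*: the set of
maximal interaction terms, each a set of axis names.  Including a term
implies every non-empty subset of it (all lower-order interactions and
main effects).  Expected frequencies are the maximum-likelihood fit
under multinomial sampling, computed by iterative proportional fitting
(IPF): the fitted table is repeatedly rescaled so that its margin over
each generating term matches the observed margin.

Model search follows backward elimination from the saturated model: at
each step every maximal term is tentatively deleted (replacing it by its
maximal proper subsets so the model stays hierarchical), the loss of fit
is measured by the likelihood-ratio statistic G² referred to a chi-square
distribution, and the candidate with the largest p-value is removed while
that p-value exceeds the significance threshold (0.05 by default).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import chain, combinations
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import CategoricalAxis, FrequencyTable

__all__ = [
    "Term",
    "GeneratingClass",
    "LoglinearFit",
    "SelectionStep",
    "SelectionTrace",
    "implied_terms",
    "degrees_of_freedom",
    "ipf_fit",
    "lr_change_test",
    "backward_select",
]

#: An interaction term: a non-empty set of axis names.
Term = frozenset


def _fmt_term(term: Term) -> str:
    return "*".join(sorted(term))


class GeneratingClass:
    """The set of maximal terms of a hierarchical log-linear model.

    Terms must form an antichain: no term may contain another (a
    contained term is implied, not maximal).  Axes missing from every
    term are simply not modelled — their margins come out uniform.
    """

    def __init__(self, terms: Iterable[Iterable[str]]):
        terms = {Term(t) for t in terms}
        if any(not t for t in terms):
            raise ValueError("generating-class terms must be non-empty")
        for t in terms:
            for u in terms:
                if t != u and t < u:
                    raise ValueError(
                        f"term {_fmt_term(t)} is contained in {_fmt_term(u)}; "
                        "generating-class terms must be maximal"
                    )
        self.terms: tuple[Term, ...] = tuple(
            sorted(terms, key=lambda t: (-len(t), tuple(sorted(t))))
        )

    # -- structure -----------------------------------------------------------

    def implied_terms(self) -> frozenset[Term]:
        """Downward closure: every non-empty subset of every maximal term."""
        out: set[Term] = set()
        for t in self.terms:
            items = sorted(t)
            out.update(
                Term(c)
                for c in chain.from_iterable(
                    combinations(items, r) for r in range(1, len(items) + 1)
                )
            )
        return frozenset(out)

    def covers(self) -> frozenset[str]:
        """Axis names appearing in at least one term."""
        return frozenset(chain.from_iterable(self.terms))

    def implies(self, other: "GeneratingClass") -> bool:
        """True when *other* is a submodel: each of its terms sits inside one of ours."""
        return all(any(t <= s for s in self.terms) for t in other.terms)

    def drop_term(self, term: Iterable[str]) -> "GeneratingClass":
        """Hierarchical deletion of one maximal term.

        The term is replaced by those of its one-smaller subsets not
        already implied by the remaining terms, keeping the model
        hierarchical and the class an antichain.  Deleting a main
        effect removes its axis from the model.
        """
        term = Term(term)
        if term not in self.terms:
            raise KeyError(f"{_fmt_term(term)} is not a maximal term of {self}")
        rest = [t for t in self.terms if t != term]
        new = list(rest)
        if len(term) > 1:
            for sub in combinations(sorted(term), len(term) - 1):
                s = Term(sub)
                if not any(s <= t for t in rest):
                    new.append(s)
        return GeneratingClass(new)

    # -- serialization / dunder ----------------------------------------------

    def to_json(self) -> str:
        return json.dumps([sorted(t) for t in self.terms])

    @classmethod
    def from_json(cls, text: str) -> "GeneratingClass":
        return cls(json.loads(text))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneratingClass):
            return NotImplemented
        return set(self.terms) == set(other.terms)

    def __hash__(self) -> int:
        return hash(frozenset(self.terms))

    def __iter__(self):
        return iter(self.terms)

    def __len__(self) -> int:
        return len(self.terms)

    def __repr__(self) -> str:
        return "{" + ", ".join(_fmt_term(t) for t in self.terms) + "}"


def implied_terms(gc: GeneratingClass) -> frozenset[Term]:
    """All terms (main effects and interactions) implied by a generating class."""
    return gc.implied_terms()


def saturated_class(table: FrequencyTable) -> GeneratingClass:
    return GeneratingClass([table.axis_names])


def degrees_of_freedom(gc: GeneratingClass, axes: Sequence[CategoricalAxis]) -> int:
    """Residual df: cells minus free parameters (grand mean + one block per term).

    A term over axes with sizes ``s1..sk`` contributes ``prod(si - 1)``
    free parameters under any full-rank coding.
    """
    sizes = {a.name: a.size for a in axes}
    unknown = gc.covers() - set(sizes)
    if unknown:
        raise KeyError(f"generating class uses unknown axes {sorted(unknown)}")
    n_cells = int(np.prod([a.size for a in axes]))
    n_params = 1
    for term in gc.implied_terms():
        n_params += int(np.prod([sizes[name] - 1 for name in term]))
    return n_cells - n_params


@dataclass
class LoglinearFit:
    """IPF fit of a hierarchical model: expected frequencies plus fit statistics.

    ``gsq`` is the likelihood-ratio statistic 2·Σ o·ln(o/f) (zero cells
    contribute nothing); ``pearson`` is Σ (o−f)²/f over cells with f>0.
    """

    observed: FrequencyTable
    fitted: FrequencyTable
    generating_class: GeneratingClass
    gsq: float
    pearson: float
    df: int
    iterations: int
    converged: bool
    max_margin_error: float = field(default=0.0)

    @property
    def p_value(self) -> float:
        """Goodness-of-fit p-value of G² on the residual df (1.0 for saturated)."""
        if self.df == 0:
            return 1.0
        return float(stats.chi2.sf(self.gsq, self.df))


def _margin_indices(table: FrequencyTable, term: Term) -> tuple[int, ...]:
    return tuple(i for i, a in enumerate(table.axes) if a.name not in term)


def _gof(observed: np.ndarray, fitted: np.ndarray) -> tuple[float, float]:
    obs_pos = observed > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(obs_pos, observed / np.where(fitted > 0, fitted, 1.0), 1.0)
        bad = obs_pos & (fitted <= 0)
        gsq = np.inf if bad.any() else float(2.0 * np.sum(observed[obs_pos] * np.log(ratio[obs_pos])))
        fit_pos = fitted > 0
        pearson = float(np.sum((observed[fit_pos] - fitted[fit_pos]) ** 2 / fitted[fit_pos]))
        if bad.any():
            pearson = np.inf
    return gsq, pearson


def ipf_fit(
    table: FrequencyTable,
    gc: GeneratingClass,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> LoglinearFit:
    """Fit a hierarchical log-linear model by iterative proportional fitting.

    Starting from a flat table, each cycle rescales the fitted table to
    match the observed margin of every generating term; the grand total
    is preserved throughout.  Convergence: the maximum absolute margin
    discrepancy over all generating terms falls below *tol*.

    A zero observed margin forces the corresponding fitted cells to
    zero, the ML solution on the boundary (a warning notes it).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    unknown = gc.covers() - set(table.axis_names)
    if unknown:
        raise KeyError(f"generating class uses axes {sorted(unknown)} absent from table")
    observed = table.counts
    n_cells = observed.size
    total = observed.sum()
    fitted = np.full_like(observed, total / n_cells)

    margins = []
    for term in gc.terms:
        over = _margin_indices(table, term)
        obs_m = observed.sum(axis=over)
        if np.any(obs_m == 0):
            warnings.warn(
                f"zero observed margin for term {_fmt_term(term)}: "
                "the matching fitted cells are fixed at 0",
                stacklevel=2,
            )
        margins.append((term, over, obs_m))

    iterations = 0
    err = np.inf
    if not margins:  # grand-mean-only model: flat table, already exact
        err = 0.0
    while margins and iterations < max_iter:
        iterations += 1
        for _, over, obs_m in margins:
            fit_m = fitted.sum(axis=over)
            ratio = np.divide(
                obs_m, fit_m, out=np.zeros_like(obs_m, dtype=float), where=fit_m > 0
            )
            fitted *= np.expand_dims(ratio, over)
        err = 0.0
        for _, over, obs_m in margins:
            err = max(err, float(np.max(np.abs(fitted.sum(axis=over) - obs_m))))
        if err < tol:
            break
    converged = err < tol
    if not converged:
        warnings.warn(
            f"IPF did not reach tol={tol:g} within {max_iter} iterations "
            f"(max margin error {err:.3g})",
            stacklevel=2,
        )
    gsq, pearson = _gof(observed, fitted)
    return LoglinearFit(
        observed=table,
        fitted=FrequencyTable(table.axes, fitted),
        generating_class=gc,
        gsq=gsq,
        pearson=pearson,
        df=degrees_of_freedom(gc, table.axes),
        iterations=iterations,
        converged=converged,
        max_margin_error=err,
    )


class LrChange(NamedTuple):
    delta_gsq: float
    delta_df: int
    p: float


def lr_change_test(fit_without: LoglinearFit, fit_with: LoglinearFit) -> LrChange:
    """Likelihood-ratio test of a nested model pair on the same table.

    ``fit_without`` must be a submodel of ``fit_with``; the difference in
    G² is referred to chi-square on the difference in df.
    """
    if not fit_with.generating_class.implies(fit_without.generating_class):
        raise ValueError(
            f"models are not nested: {fit_without.generating_class} is not a "
            f"submodel of {fit_with.generating_class}"
        )
    if not fit_without.observed.allclose(fit_with.observed):
        raise ValueError("fits are on different observed tables")
    delta_df = fit_without.df - fit_with.df
    if delta_df == 0:
        raise ValueError("models have identical df; the change test is undefined")
    delta_gsq = max(fit_without.gsq - fit_with.gsq, 0.0)
    return LrChange(delta_gsq, delta_df, float(stats.chi2.sf(delta_gsq, delta_df)))


@dataclass(frozen=True)
class SelectionStep:
    step: int
    candidate: Term
    delta_gsq: float
    delta_df: int
    p: float
    removed: bool


@dataclass
class SelectionTrace:
    """Full record of a backward-elimination run."""

    steps: list[SelectionStep]
    final_class: GeneratingClass
    final_fit: LoglinearFit
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": [s.step for s in self.steps],
                "candidate": [_fmt_term(s.candidate) for s in self.steps],
                "delta_gsq": [s.delta_gsq for s in self.steps],
                "delta_df": [s.delta_df for s in self.steps],
                "p": [s.p for s in self.steps],
                "action": ["removed" if s.removed else "kept" for s in self.steps],
            }
        )

    def describe(self) -> str:
        lines = [f"backward elimination, alpha={self.alpha:g}"]
        for s in self.steps:
            action = "removed" if s.removed else "kept"
            lines.append(
                f"  step {s.step}: {_fmt_term(s.candidate):30s} "
                f"dG2={s.delta_gsq:9.3f} ddf={s.delta_df:3d} p={s.p:.4g} -> {action}"
            )
        lines.append(f"final generating class: {self.final_class}")
        return "\n".join(lines)


def backward_select(
    table: FrequencyTable,
    alpha: float = 0.05,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> SelectionTrace:
    """Backward elimination from the saturated model.

    At each step every maximal term of the current generating class is a
    deletion candidate.  The candidate whose removal loses the least fit
    (largest likelihood-ratio p-value) is deleted while that p-value
    exceeds *alpha*; ties prefer higher-order terms, then alphabetical
    order, for determinism.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if len(table.axes) < 2:
        raise ValueError("model selection needs a table with >=2 axes")
    current = saturated_class(table)
    fit_cur = ipf_fit(table, current, tol=tol, max_iter=max_iter)
    steps: list[SelectionStep] = []
    step_no = 0
    while len(current) > 0:
        step_no += 1
        evals = []
        for term in current.terms:
            reduced = current.drop_term(term)
            fit_red = ipf_fit(table, reduced, tol=tol, max_iter=max_iter)
            change = lr_change_test(fit_red, fit_cur)
            evals.append((term, reduced, fit_red, change))
        # largest p wins; ties: higher order first, then lexicographic
        evals.sort(key=lambda e: (-e[3].p, -len(e[0]), tuple(sorted(e[0]))))
        best_term, best_class, best_fit, best_change = evals[0]
        remove = best_change.p > alpha
        for term, _, _, change in evals:
            steps.append(
                SelectionStep(
                    step=step_no,
                    candidate=term,
                    delta_gsq=change.delta_gsq,
                    delta_df=change.delta_df,
                    p=change.p,
                    removed=remove and term == best_term,
                )
            )
        if not remove:
            break
        current, fit_cur = best_class, best_fit
    return SelectionTrace(steps=steps, final_class=current, final_fit=fit_cur, alpha=alpha)
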
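"""Comparative statistics linking branch-wise change counts to a trait.

Per-branch nonsynonymous proportions P = dN/(dN + dS) are contrasted
between branches that retain the reconstructed ancestral state and those
representing shifts to alternative states: clade-averaged shift-vs-sister
comparisons with a paired t-test, and ordinary least-squares regressions
of P on branch age with a joint F-test for group differences in slope and
intercept.

Note that P measures the *composition* of changes, not selection directly:
with roughly three times as many nonsynonymous as synonymous sites per
codon, neutral evolution already gives P near N/(N+S) -- well above 0.5 --
so only contrasts between groups, not the absolute level, are meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ancestral_states import ParsimonyReconstruction, ShiftEvent
from .codon_selection import BranchChangeTable, branch_id
from .phylo_io import DatedTree

__all__ = [
    "branch_proportions", "shift_vs_sister", "ShiftComparison",
    "paired_t_test", "regression_vs_age", "RegressionResult",
    "GroupFit", "classify_selection",
]


def branch_proportions(changes: BranchChangeTable, tree: DatedTree,
                       rec: ParsimonyReconstruction,
                       ancestral_state: str,
                       terminal_only: bool = False) -> pd.DataFrame:
    """Per-branch nonsynonymous proportions with group labels.

    For each branch, P = dN/(dN+dS) is computed per gene first (genes with
    no counted changes on that branch are excluded from the average) and
    then averaged across genes.  The group label comes from the resolved
    parsimony state of the branch's child node: ``"ancestral"`` when it
    equals ``ancestral_state``, otherwise ``"alternative"``.  The age
    covariate is the parent-node age in Ma (equal to the branch length for
    terminal branches on an ultrametric tree).  Branches with all-zero
    counts across genes are excluded with a warning.
    """
    tbl = changes.table.copy()
    tbl["total"] = tbl["dN"] + tbl["dS"]
    nodes = {branch_id(nd): nd for nd in tree.branches()}
    rows = []
    dropped = []
    for br, sub in tbl.groupby("branch"):
        node = nodes[br]
        if terminal_only and not node.is_leaf:
            continue
        used = sub[sub["total"] > 0]
        if used.empty:
            dropped.append(br)
            continue
        p = float((used["dN"] / used["total"]).mean())
        state = rec.resolved[node]
        rows.append({
            "branch": br,
            "P": p,
            "age": node.parent.age,
            "branch_length": node.length,
            "state": state,
            "group": "ancestral" if state == ancestral_state
                     else "alternative",
            "n_genes_used": len(used),
            "is_terminal": node.is_leaf,
        })
    if dropped:
        warnings.warn(f"branches with no counted changes excluded: {dropped}")
    return pd.DataFrame(rows)


@dataclass
class ShiftComparison:
    """Clade-averaged proportions on the two sides of one life-form shift."""

    event: ShiftEvent
    shift_mean_P: float
    sister_mean_P: float
    shift_branches: list[str]
    sister_branches: list[str]

    @property
    def shift_share(self) -> float:
        """Shift-side share of the two means, as a percentage (the two
        shares always sum to 100)."""
        tot = self.shift_mean_P + self.sister_mean_P
        return 100.0 * self.shift_mean_P / tot if tot > 0 else 50.0

    @property
    def sister_share(self) -> float:
        return 100.0 - self.shift_share


def shift_vs_sister(events: list[ShiftEvent], proportions: pd.DataFrame,
                    tree: DatedTree,
                    rec: ParsimonyReconstruction | None = None,
                    ancestral_state: str | None = None,
                    strict: bool = True
                    ) -> tuple[list[ShiftComparison], tuple[float, int, float]]:
    """Shift-side vs sister-side comparison for each shift event.

    The shift side collects every terminal and internal branch of the
    derived clade, including the stem branch of its origin node -- i.e. the
    path from each member terminal back to (but excluding) the divergence
    node.  The sister side collects branches of the divergence node's other
    child lineages that are reconstructed in the ancestral state (nested
    second shifts are excluded).  Each side's P values are averaged with
    equal weight per branch, and a paired t-test is run across events.
    An event with no counted branches on one side is an error under
    ``strict``, otherwise skipped with a warning.
    """
    pmap = dict(zip(proportions["branch"], proportions["P"]))
    comps = []
    for ev in events:
        shift_nodes = tree.clade_nodes(ev.origin)
        shift_ids = [branch_id(nd) for nd in shift_nodes]
        sister_ids = []
        for sis in ev.sister_branches:
            for nd in tree.clade_nodes(sis):
                if rec is not None and ancestral_state is not None \
                        and rec.resolved[nd] != ancestral_state:
                    continue
                sister_ids.append(branch_id(nd))
        shift_ps = [pmap[b] for b in shift_ids if b in pmap]
        sister_ps = [pmap[b] for b in sister_ids if b in pmap]
        if not sister_ps or not shift_ps:
            side = "sister" if not sister_ps else "shift"
            msg = (f"shift event at {branch_id(ev.origin)}: {side} side has "
                   f"no branches with counted changes")
            if strict:
                raise ValueError(msg)
            warnings.warn(msg + "; event skipped")
            continue
        comps.append(ShiftComparison(
            ev, float(np.mean(shift_ps)), float(np.mean(sister_ps)),
            shift_ids, sister_ids))
    if len(comps) >= 2:
        test = paired_t_test(np.array([c.shift_mean_P for c in comps]),
                             np.array([c.sister_mean_P for c in comps]))
    else:
        test = (np.nan, max(len(comps) - 1, 0), np.nan)
    return comps, test


def paired_t_test(x, y) -> tuple[float, int, float]:
    """Classical paired t-test on the differences x - y.

    Returns ``(t, df, p)`` with df = n - 1 and a two-sided p.  Degenerate
    inputs follow explicit conventions: identical vectors give t = 0,
    p = 1; zero-variance differences with nonzero mean give a signed
    infinite t with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired t-test needs two equal-length vectors")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    mean = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        if mean == 0:
            return 0.0, df, 1.0
        return float(np.sign(mean) * np.inf), df, 0.0
    t = mean / (sd / np.sqrt(n))
    return float(t), df, float(2.0 * stats.t.sf(abs(t), df))


@dataclass
class GroupFit:
    group: str
    slope: float
    intercept: float
    r_squared: float
    n: int
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]


@dataclass
class RegressionResult:
    """Per-group OLS of P on age plus a group-equality F-test."""

    groups: dict[str, GroupFit]
    equality_F: float
    equality_df: tuple[int, int]
    equality_p: float

    def predict(self, group: str, ages: np.ndarray) -> np.ndarray:
        g = self.groups[group]
        return g.intercept + g.slope * np.asarray(ages, dtype=float)


def regression_vs_age(proportions: pd.DataFrame,
                      y: str = "P", x: str = "age",
                      group_col: str = "group") -> RegressionResult:
    """OLS of the nonsynonymous proportion on branch age, per group.

    Group equality is tested in a single linear model with a group main
    effect and group x age interaction, by a joint F-test on the two group
    terms; each group needs at least 3 points.
    """
    fits = {}
    for g, sub in proportions.groupby(group_col):
        if len(sub) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 points")
        X = sm.add_constant(sub[x].to_numpy())
        res = sm.OLS(sub[y].to_numpy(), X).fit()
        ci = res.conf_int(alpha=0.05)
        fits[g] = GroupFit(g, float(res.params[1]), float(res.params[0]),
                           float(res.rsquared), len(sub),
                           (float(ci[1][0]), float(ci[1][1])),
                           (float(ci[0][0]), float(ci[0][1])))
    groups = sorted(proportions[group_col].unique())
    if len(groups) != 2:
        raise ValueError("group-equality test needs exactly 2 groups")
    ind = (proportions[group_col] == groups[1]).to_numpy(dtype=float)
    age = proportions[x].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(age), age, ind, ind * age])
    res = sm.OLS(proportions[y].to_numpy(), X).fit()
    ftest = res.f_test(np.array([[0, 0, 1, 0], [0, 0, 0, 1.0]]))
    return RegressionResult(fits, float(ftest.fvalue),
                            (int(ftest.df_num), int(ftest.df_denom)),
                            float(ftest.pvalue))


def classify_selection(omega: float | None, tol: float = 0.05) -> str:
    """Direction of selection from a branch or gene omega.

    ``purifying`` when omega < 1 - tol, ``diversifying`` when
    omega > 1 + tol, ``neutral`` in between; an undefined omega (no
    synonymous changes counted) returns ``undetermined``.
    """
    if omega is None or not np.isfinite(omega):
        return "undetermined"
    if omega < 1.0 - tol:
        return "purifying"
    if omega > 1.0 + tol:
        return "diversifying"
    return "neutral"
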
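"""Piecewise structural equation modeling over linear mixed models.

A path diagram (:class:`DagSpec`) is estimated as a set of component mixed
models, one per endogenous variable, each with a site random intercept.
Goodness of fit uses Shipley's test of d-separation: the basis set of
conditional-independence claims implied by the missing edges is tested
claim-by-claim, and the claim p-values are combined into Fisher's C,

    C = -2 Σ ln p_i,   C ~ χ² with 2k degrees of freedom,

under the hypothesized graph.  Standardized coefficients, Nakagawa
marginal/conditional R², BIC-guided simplification, correlated errors, and
a multigroup (pre/post) comparison complete the layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "DagError",
    "DagSpec",
    "Claim",
    "DsepTest",
    "SemResult",
    "MultigroupResult",
    "basis_set",
    "dsep_pvalues",
    "fishers_c",
    "PiecewiseSEM",
    "fit_sem",
    "multigroup_sem",
]

_Z95 = 1.959963984540054
_P_FLOOR = 1e-300  # guards ln(p) against underflow in extreme claims


class DagError(ValueError):
    """The path diagram is malformed (cycle, undeclared node, ...)."""


@dataclass(frozen=True)
class DagSpec:
    """Directed acyclic path diagram with correlated-error pairs.

    ``edges`` are (cause, effect) pairs; ``correlated`` are unordered pairs
    modeled as bidirectional (non-causal) associations; ``grouping`` names
    the random-effect factor column.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    correlated: tuple[frozenset, ...] = ()
    grouping: str = "site_id"

    def __post_init__(self) -> None:
        declared = set(self.nodes)
        for a, b in self.edges:
            if a not in declared or b not in declared:
                raise DagError(f"edge {a!r} -> {b!r} references an undeclared node")
        for pair in self.correlated:
            if len(pair) != 2:
                raise DagError(f"correlated-error pair {set(pair)} must have two nodes")
            if not pair <= declared:
                raise DagError(f"correlated pair {set(pair)} references an undeclared node")
            a, b = tuple(pair)
            if (a, b) in self.edges or (b, a) in self.edges:
                raise DagError(
                    f"{a!r} ~~ {b!r} cannot also be a directed edge"
                )
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise DagError(f"directed part contains a cycle: {cycle}")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(a for a, b in self.edges if b == node))

    @property
    def endogenous(self) -> tuple[str, ...]:
        targets = {b for _, b in self.edges}
        return tuple(n for n in self.nodes if n in targets)

    @property
    def exogenous(self) -> tuple[str, ...]:
        targets = {b for _, b in self.edges}
        return tuple(n for n in self.nodes if n not in targets)

    def drop_edge(self, edge: tuple[str, str]) -> "DagSpec":
        if edge not in self.edges:
            raise DagError(f"edge {edge} not in DAG")
        return DagSpec(
            nodes=self.nodes,
            edges=tuple(e for e in self.edges if e != edge),
            correlated=self.correlated,
            grouping=self.grouping,
        )

    # -- plain-text config ------------------------------------------------
    @classmethod
    def from_text(cls, text: str, grouping: Optional[str] = None) -> "DagSpec":
        """Parse a plain-text DAG config.

        Lines: ``a -> b`` (directed edge), ``a ~~ b`` (correlated errors),
        ``group: name`` (random-effect factor), optional ``nodes: a b c``;
        ``#`` starts a comment.
        """
        nodes: list[str] = []
        edges: list[tuple[str, str]] = []
        corr: list[frozenset] = []
        group = grouping or "site_id"
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.lower().startswith("group:"):
                group = line.split(":", 1)[1].strip()
            elif line.lower().startswith("nodes:"):
                nodes.extend(line.split(":", 1)[1].split())
            elif "->" in line:
                a, b = (s.strip() for s in line.split("->", 1))
                edges.append((a, b))
            elif "~~" in line:
                a, b = (s.strip() for s in line.split("~~", 1))
                corr.append(frozenset((a, b)))
            else:
                raise DagError(f"cannot parse DAG config line: {raw!r}")
        for a, b in edges:
            for n in (a, b):
                if n not in nodes:
                    nodes.append(n)
        for pair in corr:
            for n in pair:
                if n not in nodes:
                    nodes.append(n)
        if grouping is not None:
            group = grouping
        return cls(nodes=tuple(nodes), edges=tuple(edges), correlated=tuple(corr), grouping=group)

    @classmethod
    def from_file(cls, path, grouping: Optional[str] = None) -> "DagSpec":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_text(fh.read(), grouping=grouping)


class Claim(NamedTuple):
    """One conditional-independence claim: x ⟂ y | given (y is dependent)."""

    x: str
    y: str
    given: tuple[str, ...]


class DsepTest(NamedTuple):
    claim: Claim
    p: float
    flagged: bool


def basis_set(dag: DagSpec) -> list[Claim]:
    """Shipley's basis set of independence claims for a DAG.

    One claim per non-adjacent pair (no directed edge either way and not a
    correlated-error pair), conditioning on the union of both variables'
    parents, with the later variable in topological order as the dependent.
    """
    g = dag.graph()
    order = list(nx.lexicographical_topological_sort(g))
    rank = {n: i for i, n in enumerate(order)}
    adjacent = {frozenset(e) for e in dag.edges} | set(dag.correlated)
    claims: list[Claim] = []
    seen = set()
    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            if frozenset((a, b)) in adjacent:
                continue
            x, y = (a, b) if rank[a] < rank[b] else (b, a)
            given = tuple(sorted((set(dag.parents(x)) | set(dag.parents(y))) - {x, y}))
            key = (x, y, given)
            if key in seen:
                continue
            seen.add(key)
            claims.append(Claim(x=x, y=y, given=given))
    return claims


def _component_formula(y: str, predictors: Sequence[str]) -> str:
    rhs = " + ".join(f"Q('{p}')" for p in predictors) if predictors else "1"
    return f"Q('{y}') ~ {rhs}"


def _fit_component(data: pd.DataFrame, y: str, predictors: Sequence[str], grouping: str):
    from .inference import _fit_lmm

    return _fit_lmm(_component_formula(y, predictors), data, grouping, reml=False)


def dsep_pvalues(
    claims: Sequence[Claim], data: pd.DataFrame, grouping: str = "site_id"
) -> list[DsepTest]:
    """Test each independence claim with a random-intercept mixed model.

    The dependent variable is regressed on its conditioning set plus the
    claimed-independent variable; the two-sided p-value of that added
    coefficient (normal approximation) tests the claim.  Singular or
    degenerate fits are flagged and carried with p = NaN.
    """
    if data[grouping].nunique() < 2:
        raise DagError("d-separation tests require >= 2 grouping levels")
    out: list[DsepTest] = []
    for claim in claims:
        cols = [claim.x, claim.y, *claim.given]
        sub = data[[grouping, *cols]].dropna()
        try:
            if sub[claim.x].std() == 0 or sub[claim.y].std() == 0:
                raise ValueError("constant variable in claim")
            res = _fit_component(sub, claim.y, [*claim.given, claim.x], grouping)
            pvals = res.pvalues
            key = f"Q('{claim.x}')"
            p = float(pvals[key])
            if not np.isfinite(p):
                raise ValueError("non-finite p-value")
            out.append(DsepTest(claim, max(p, _P_FLOOR), False))
        except Exception:
            out.append(DsepTest(claim, float("nan"), True))
    return out


def fishers_c(pvalues: Sequence[float]) -> tuple[float, int, float]:
    """Combine claim p-values into Fisher's C with 2k df.

    Returns (C, df, p) where C = -2 Σ ln p and p is the upper-tail χ²
    probability; an empty claim set is a vacuous perfect fit (0, 0, 1).
    """
    ps = np.asarray(list(pvalues), dtype=float)
    if ps.size == 0:
        return 0.0, 0, 1.0
    if np.any(ps <= 0) or np.any(ps > 1):
        raise ValueError("claim p-values must lie in (0, 1]")
    c = float(-2.0 * np.log(ps).sum())
    df = 2 * ps.size
    return c, df, float(stats.chi2.sf(c, df))


@dataclass
class SemResult:
    """Fitted piecewise SEM: paths, d-separation fit, and R²."""

    path_table: pd.DataFrame  # response, predictor, estimate, std_estimate, se, p
    fisher_c: float
    dsep_df: int
    dsep_p: float
    r2: dict  # endogenous node -> (marginal, conditional)
    correlated_errors: pd.DataFrame  # a, b, r, kind
    dropped_paths: list = field(default_factory=list)
    dsep_tests: list = field(default_factory=list)
    dag: Optional[DagSpec] = None
    n_obs: int = 0


def _nakagawa_r2(res, data: pd.DataFrame, y: str, predictors: Sequence[str], grouping: str):
    """Marginal and conditional R² by variance partitioning."""
    if predictors:
        fixed = res.predict(data)
        var_f = float(np.var(np.asarray(fixed, dtype=float)))
    else:
        var_f = 0.0
    cov_re = np.asarray(res.cov_re, dtype=float)
    var_re = float(cov_re[0, 0]) if cov_re.size else 0.0
    var_e = float(res.scale)
    total = var_f + var_re + var_e
    if total <= 0:
        return 0.0, 0.0
    return var_f / total, (var_f + var_re) / total


class PiecewiseSEM(BaseEstimator):
    """Piecewise SEM estimator over site-random-intercept mixed models.

    Parameters
    ----------
    dag : DagSpec
        The hypothesized path diagram.
    simplify : bool
        Iteratively drop the least-significant non-significant path when
        doing so lowers the summed component-model BIC.
    alpha : float
        Significance threshold used during simplification.

    Attributes (after ``fit``)
    --------------------------
    path_table_, fisher_c_, dsep_df_, dsep_p_, r2_, dropped_paths_,
    correlated_errors_, dag_, result_ (a :class:`SemResult`).
    """

    def __init__(self, dag: DagSpec, simplify: bool = False, alpha: float = 0.05):
        self.dag = dag
        self.simplify = simplify
        self.alpha = alpha

    # -- internals --------------------------------------------------------
    def _fit_components(self, dag: DagSpec, data: pd.DataFrame):
        rows = []
        r2 = {}
        resid = {}
        total_bic = 0.0
        sds = data[list(dag.nodes)].std(ddof=1)
        for node in dag.endogenous:
            parents = dag.parents(node)
            res = _fit_component(data, node, parents, dag.grouping)
            k = len(res.params)
            total_bic += float(-2.0 * res.llf + k * np.log(res.nobs))
            r2[node] = _nakagawa_r2(res, data, node, parents, dag.grouping)
            resid[node] = np.asarray(data[node], dtype=float) - np.asarray(
                res.predict(data), dtype=float
            )
            for parent in parents:
                key = f"Q('{parent}')"
                est = float(res.fe_params[key])
                se = float(res.bse_fe[key])
                p = float(res.pvalues[key])
                rows.append(
                    {
                        "response": node,
                        "predictor": parent,
                        "estimate": est,
                        "std_estimate": est * float(sds[parent]) / float(sds[node]),
                        "se": se,
                        "p": p,
                    }
                )
        table = pd.DataFrame(
            rows, columns=["response", "predictor", "estimate", "std_estimate", "se", "p"]
        )
        return table, r2, resid, total_bic

    def _correlated_errors(self, dag: DagSpec, data: pd.DataFrame, resid: dict) -> pd.DataFrame:
        rows = []
        exo = set(dag.exogenous)
        for pair in dag.correlated:
            a, b = sorted(pair)
            xa = np.asarray(data[a], float) if a in exo else resid[a]
            xb = np.asarray(data[b], float) if b in exo else resid[b]
            kind = "raw" if (a in exo and b in exo) else "residual"
            r = float(np.corrcoef(xa, xb)[0, 1])
            n = len(xa)
            if n > 3 and abs(r) < 1:
                z = np.arctanh(r) * np.sqrt(n - 3)
                p = float(2 * stats.norm.sf(abs(z)))
            else:
                p = float("nan")
            rows.append({"a": a, "b": b, "r": r, "p": p, "kind": kind})
        return pd.DataFrame(rows, columns=["a", "b", "r", "p", "kind"])

    # -- API --------------------------------------------------------------
    def fit(self, data: pd.DataFrame, groups=None):
        dag = self.dag
        cols = [dag.grouping, *dag.nodes]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise DagError(f"data is missing SEM columns: {missing}")
        work = data[cols].dropna().reset_index(drop=True)
        n_dropped = len(data) - len(work)
        if len(work) < 10:
            raise DagError(
                f"only {len(work)} complete-case rows remain after dropping {n_dropped}; need >= 10"
            )
        if work[dag.grouping].nunique() < 2:
            raise DagError("piecewise SEM requires >= 2 grouping levels")

        dropped: list[dict] = []
        table, r2, resid, bic = self._fit_components(dag, work)
        if self.simplify:
            while True:
                cand = table[table["p"] > self.alpha].sort_values("p", ascending=False)
                if cand.empty:
                    break
                accepted = False
                for _, row in cand.iterrows():
                    edge = (row["predictor"], row["response"])
                    new_dag = dag.drop_edge(edge)
                    new_table, new_r2, new_resid, new_bic = self._fit_components(new_dag, work)
                    if new_bic < bic:
                        dropped.append(
                            {"edge": edge, "p_at_drop": float(row["p"]),
                             "bic_before": bic, "bic_after": new_bic}
                        )
                        dag, table, r2, resid, bic = new_dag, new_table, new_r2, new_resid, new_bic
                        accepted = True
                        break
                if not accepted:
                    break

        tests = dsep_pvalues(basis_set(dag), work, dag.grouping)
        usable = [t.p for t in tests if not t.flagged]
        c, dof, p = fishers_c(usable)
        corr = self._correlated_errors(dag, work, resid)

        self.dag_ = dag
        self.path_table_ = table
        self.fisher_c_ = c
        self.dsep_df_ = dof
        self.dsep_p_ = p
        self.r2_ = r2
        self.dropped_paths_ = dropped
        self.correlated_errors_ = corr
        self.result_ = SemResult(
            path_table=table,
            fisher_c=c,
            dsep_df=dof,
            dsep_p=p,
            r2=r2,
            correlated_errors=corr,
            dropped_paths=dropped,
            dsep_tests=tests,
            dag=dag,
            n_obs=len(work),
        )
        return self


def fit_sem(dag: DagSpec, data: pd.DataFrame, simplify: bool = False, alpha: float = 0.05) -> SemResult:
    """Fit a piecewise SEM; see :class:`PiecewiseSEM`."""
    return PiecewiseSEM(dag=dag, simplify=simplify, alpha=alpha).fit(data).result_


@dataclass
class MultigroupResult:
    """Per-path free/constrained classification across two phases."""

    paths: pd.DataFrame  # response, predictor, interaction_p, status, est_*, std_*
    fisher_c: dict  # phase -> (C, df, p)
    n_obs: dict


def multigroup_sem(
    dag: DagSpec, data_pre: pd.DataFrame, data_post: pd.DataFrame, alpha: float = 0.05
) -> MultigroupResult:
    """Multigroup comparison of a piecewise SEM between two phases.

    Every component model is refit on the stacked data with a model-wide
    phase interaction.  Paths whose interaction is significant (p <= alpha)
    are "free" and take phase-specific estimates; the rest are
    "constrained" to the global estimate, with standardized coefficients
    recomputed from each phase's standard deviations.
    """
    cols = [dag.grouping, *dag.nodes]
    pre = data_pre[cols].dropna().reset_index(drop=True)
    post = data_post[cols].dropna().reset_index(drop=True)
    for name, d in (("pre", pre), ("post", post)):
        if d[dag.grouping].nunique() < 2:
            raise DagError(f"{name} phase has < 2 grouping levels")
    stacked = pd.concat(
        [pre.assign(phase=0.0), post.assign(phase=1.0)], ignore_index=True
    )

    # model-wide interaction: every term interacts with phase
    inter_p: dict[tuple[str, str], float] = {}
    for node in dag.endogenous:
        parents = dag.parents(node)
        rhs = " + ".join([f"Q('{p}')" for p in parents] + ["phase"])
        rhs += " + " + " + ".join(f"Q('{p}'):phase" for p in parents)
        from .inference import _fit_lmm

        res = _fit_lmm(f"Q('{node}') ~ {rhs}", stacked, dag.grouping, reml=False)
        for p_ in parents:
            key = f"Q('{p_}'):phase"
            val = float(res.pvalues[key])
            inter_p[(p_, node)] = val if np.isfinite(val) else float("nan")

    global_fit = fit_sem(dag, stacked, simplify=False)
    pre_fit = fit_sem(dag, pre, simplify=False)
    post_fit = fit_sem(dag, post, simplify=False)

    def _lookup(table: pd.DataFrame, pred: str, resp: str, col: str) -> float:
        row = table[(table["predictor"] == pred) & (table["response"] == resp)]
        return float(row[col].iloc[0]) if len(row) else float("nan")

    sds = {"pre": pre.std(ddof=1, numeric_only=True), "post": post.std(ddof=1, numeric_only=True)}
    rows = []
    for (pred, resp), p in inter_p.items():
        free = np.isfinite(p) and p <= alpha
        if free:
            est_pre = _lookup(pre_fit.path_table, pred, resp, "estimate")
            est_post = _lookup(post_fit.path_table, pred, resp, "estimate")
            std_pre = _lookup(pre_fit.path_table, pred, resp, "std_estimate")
            std_post = _lookup(post_fit.path_table, pred, resp, "std_estimate")
        else:
            est = _lookup(global_fit.path_table, pred, resp, "estimate")
            est_pre = est_post = est
            std_pre = est * float(sds["pre"][pred]) / float(sds["pre"][resp])
            std_post = est * float(sds["post"][pred]) / float(sds["post"][resp])
        rows.append(
            {
                "response": resp,
                "predictor": pred,
                "interaction_p": p,
                "status": "free" if free else "constrained",
                "est_pre": est_pre,
                "est_post": est_post,
                "std_pre": std_pre,
                "std_post": std_post,
            }
        )
    paths = pd.DataFrame(
        rows,
        columns=[
            "response", "predictor", "interaction_p", "status",
            "est_pre", "est_post", "std_pre", "std_post",
        ],
    )
    return MultigroupResult(
        paths=paths,
        fisher_c={
            "pre": (pre_fit.fisher_c, pre_fit.dsep_df, pre_fit.dsep_p),
            "post": (post_fit.fisher_c, post_fit.dsep_df, post_fit.dsep_p),
        },
        n_obs={"pre": len(pre), "post": len(post)},
    )
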
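"""Ancestral reconstruction of discrete characters and homoplasy scoring.

Three reconstruction routes are provided for a discrete trait (e.g. the
five springtail life forms) on a dated tree:

* **Parsimony** -- Hartigan's generalisation of Fitch counting, exact on
  polytomies, with one resolved most-parsimonious labelling.
* **Maximum likelihood** -- continuous-time Markov (Mk) models: the
  one-parameter Mk1 model and an all-rates-different asymmetric model,
  fitted by bounded optimisation and compared by a likelihood-ratio test;
  per-node marginal state probabilities come from the up-down algorithm.
* **Bayesian MCMC** -- Metropolis-Hastings over the asymmetric rates with a
  hierarchical exponential prior whose mean is uniform on (0, 30), sampling
  the marginal state probabilities at a focal clade's MRCA across one or
  many input trees.

Homoplasy per state is scored by the retention index RI = (g - s)/(g - r)
on the binary presence/absence recoding of that state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .phylo_io import DatedTree, Node, TraitTable

__all__ = [
    "ParsimonyReconstruction", "ShiftEvent", "RetentionIndexResult",
    "MkFit", "BayesAsrResult", "fitch_parsimony", "count_state_shifts",
    "retention_index", "mk_log_likelihood", "fit_mk", "mk_lrt", "bayes_asr",
    "effective_sample_size",
]


# ---------------------------------------------------------------------------
# parsimony
# ---------------------------------------------------------------------------

@dataclass
class ParsimonyReconstruction:
    """Result of Hartigan/Fitch parsimony on one discrete character."""

    tree: DatedTree
    states: tuple[str, ...]
    state_sets: dict[Node, frozenset[str]]
    resolved: dict[Node, str]
    total_steps: int
    ties: list[Node] = field(default_factory=list)

    def realized_steps(self) -> int:
        """Number of changes implied by the resolved labelling."""
        return sum(1 for nd in self.tree.branches()
                   if self.resolved[nd] != self.resolved[nd.parent])


def fitch_parsimony(tree: DatedTree, traits: TraitTable,
                    prefer_state: str | None = None) -> ParsimonyReconstruction:
    """Minimum-change reconstruction of a discrete character.

    Uses Hartigan's two-pass algorithm, which is exact on multifurcating
    trees: on the up-pass each internal node keeps the states with the
    maximal vote count among its children and adds ``(#children - max
    votes)`` steps.  The down-pass resolves one most-parsimonious labelling;
    at a node whose optimal set has several members not containing the
    parent's state, ``prefer_state`` wins if present, otherwise the lowest
    state index, and the node is recorded as a tie.
    """
    states = traits.states
    state_sets: dict[Node, frozenset[str]] = {}
    steps = 0
    for nd in tree.postorder_nodes:
        if nd.is_leaf:
            try:
                state_sets[nd] = frozenset({traits.assignments[nd.label]})
            except KeyError:
                raise ValueError(f"untraited terminal: {nd.label!r}") from None
        else:
            votes = {s: 0 for s in states}
            for ch in nd.children:
                for s in state_sets[ch]:
                    votes[s] += 1
            top = max(votes.values())
            state_sets[nd] = frozenset(s for s in states if votes[s] == top)
            steps += len(nd.children) - top

    resolved: dict[Node, str] = {}
    ties: list[Node] = []

    def pick(options: frozenset[str]) -> str:
        if prefer_state is not None and prefer_state in options:
            return prefer_state
        return min(options, key=states.index)

    for nd in tree.preorder():
        opts = state_sets[nd]
        if nd is tree.root:
            if len(opts) > 1:
                ties.append(nd)
            resolved[nd] = pick(opts)
        else:
            ps = resolved[nd.parent]
            if ps in opts:
                resolved[nd] = ps
            else:
                if len(opts) > 1:
                    ties.append(nd)
                resolved[nd] = pick(opts)
    return ParsimonyReconstruction(tree, states, state_sets, resolved,
                                   steps, ties)


@dataclass
class ShiftEvent:
    """A maximal subtree reconstructed in a state other than the ancestral one."""

    derived_state: str
    origin: Node                 # first node on the path in the derived state
    divergence_node: Node        # origin's parent (the MRCA of the divergence)
    members: list[str]           # terminal taxa of the subtree in derived_state
    sister_branches: list[Node]  # divergence node's other children, ancestral


def count_state_shifts(rec: ParsimonyReconstruction,
                       ancestral_state: str) -> list[ShiftEvent]:
    """Enumerate shifts away from ``ancestral_state`` in a resolved labelling.

    One event is emitted per maximal subtree whose root is reconstructed in
    a different state while its parent keeps the ancestral state; member
    taxa are the subtree's terminals that carry the derived state.
    """
    if ancestral_state not in rec.states:
        raise ValueError(f"unknown state: {ancestral_state!r}")
    tree = rec.tree
    events = []
    for nd in tree.preorder():
        if nd is tree.root:
            continue
        st = rec.resolved[nd]
        if st != ancestral_state and rec.resolved[nd.parent] == ancestral_state:
            members = [lf.label for lf in tree.clade_leaves(nd)
                       if rec.resolved[lf] == st]
            sisters = [ch for ch in nd.parent.children
                       if ch is not nd
                       and rec.resolved[ch] == ancestral_state]
            events.append(ShiftEvent(st, nd, nd.parent, members, sisters))
    return events


@dataclass
class RetentionIndexResult:
    state: str
    g: int       # maximum possible steps of the binary recoding
    s: int       # observed parsimony steps
    r: int       # minimum possible steps
    ri: float
    defined: bool


def retention_index(tree: DatedTree, traits: TraitTable,
                    state: str) -> RetentionIndexResult:
    """Retention index of the binary presence/absence recoding of ``state``.

    RI = (g - s)/(g - r) with g = min(#tips in state, #tips out of state),
    s = Fitch steps, r = 1 when both states occur (else 0).  For an
    autapomorphic or constant character g = r makes the ratio 0/0; by
    convention the result is reported as 0 with ``defined=False``.
    """
    present = set(traits.taxa_in_state(state))
    n_in = sum(1 for t in tree.taxon_labels if t in present)
    n_out = tree.n_leaves - n_in
    binary = TraitTable(("present", "absent"),
                        {t: ("present" if t in present else "absent")
                         for t in tree.taxon_labels})
    s = fitch_parsimony(tree, binary).total_steps
    g = min(n_in, n_out)
    r = 1 if (n_in and n_out) else 0
    if g == r:
        return RetentionIndexResult(state, g, s, r, 0.0, False)
    return RetentionIndexResult(state, g, s, r, (g - s) / (g - r), True)


# ---------------------------------------------------------------------------
# Mk likelihood machinery
# ---------------------------------------------------------------------------

def _mk1_Q(q: float, k: int) -> np.ndarray:
    Q = np.full((k, k), q, dtype=float)
    np.fill_diagonal(Q, -(k - 1) * q)
    return Q


def _rates_to_Q(rates: np.ndarray) -> np.ndarray:
    Q = np.asarray(rates, dtype=float).copy()
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("rate matrix must be square")
    if (Q[~np.eye(Q.shape[0], dtype=bool)] < 0).any():
        raise ValueError("negative off-diagonal rates")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _transition_probs(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """P(t) for every branch length, via eigendecomposition with an expm
    fallback for defective rate matrices."""
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        P = np.einsum("ij,bj,jk->bik", V, np.exp(np.outer(lengths, w)), Vinv)
        P = np.real(P)
        if not np.isfinite(P).all():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        P = np.stack([linalg.expm(Q * t) for t in lengths])
    return np.clip(P, 0.0, None)


def _tip_partials(tree: DatedTree, traits: TraitTable) -> np.ndarray:
    k = traits.k
    L = np.zeros((len(tree.postorder_nodes), k))
    for lf in tree.leaves:
        st = traits.assignments.get(lf.label)
        if st is None:
            raise ValueError(f"untraited terminal: {lf.label!r}")
        L[lf.index, traits.states.index(st)] = 1.0
    return L


def _pruning(tree: DatedTree, traits: TraitTable, P: dict[Node, np.ndarray],
             root_prior: np.ndarray):
    """Felsenstein pruning; returns (log-likelihood, partials, log-scalers)."""
    n = len(tree.postorder_nodes)
    L = _tip_partials(tree, traits)
    logscale = np.zeros(n)
    for nd in tree.postorder_nodes:
        if nd.is_leaf:
            continue
        part = np.ones(traits.k)
        sc = 0.0
        for ch in nd.children:
            part = part * (P[ch] @ L[ch.index])
            sc += logscale[ch.index]
        m = part.max()
        if m <= 0:
            return -np.inf, L, logscale
        L[nd.index] = part / m
        logscale[nd.index] = sc + np.log(m)
    root = tree.root
    lik = float(root_prior @ L[root.index])
    if lik <= 0:
        return -np.inf, L, logscale
    return np.log(lik) + logscale[root.index], L, logscale


def _branch_P(tree: DatedTree, Q: np.ndarray) -> dict[Node, np.ndarray]:
    branches = tree.branches()
    lengths = np.array([nd.length for nd in branches])
    mats = _transition_probs(Q, lengths)
    return dict(zip(branches, mats))


def mk_log_likelihood(tree: DatedTree, traits: TraitTable, rates,
                      root_prior: np.ndarray | None = None) -> float:
    """Log-likelihood of a discrete character under an Mk model.

    ``rates`` is a scalar (Mk1, all transitions at rate q) or a full k x k
    matrix of instantaneous rates (off-diagonals; the diagonal is set so
    rows sum to zero).  The root prior defaults to uniform over states.
    """
    k = traits.k
    if np.isscalar(rates):
        if rates < 0:
            raise ValueError("negative rate")
        Q = _mk1_Q(float(rates), k)
    else:
        Q = _rates_to_Q(rates)
        if Q.shape[0] != k:
            raise ValueError("rate matrix size does not match state count")
    prior = (np.full(k, 1.0 / k) if root_prior is None
             else np.asarray(root_prior, dtype=float))
    P = _branch_P(tree, Q)
    ll, _, _ = _pruning(tree, traits, P, prior)
    return ll


def _marginals(tree: DatedTree, traits: TraitTable, P: dict[Node, np.ndarray],
               root_prior: np.ndarray) -> dict[Node, np.ndarray]:
    """Marginal state probabilities at every node (up-down algorithm)."""
    ll, L, logscale = _pruning(tree, traits, P, root_prior)
    if not np.isfinite(ll):
        raise ValueError("zero likelihood; cannot compute marginals")
    k = traits.k
    down: dict[Node, np.ndarray] = {tree.root: root_prior.astype(float)}
    # precompute child messages M_ch[i] = sum_j P_ch[i,j] L_ch[j] (unscaled ok)
    msg = {}
    for nd in tree.postorder_nodes:
        if nd is not tree.root:
            msg[nd] = P[nd] @ L[nd.index]
    for nd in tree.preorder():
        if nd.is_leaf:
            continue
        for ch in nd.children:
            out = down[nd].copy()
            for sib in nd.children:
                if sib is not ch:
                    out = out * msg[sib]
            m = out.max()
            if m > 0:
                out = out / m
            down[ch] = out @ P[ch]
    marg = {}
    for nd in tree.postorder_nodes:
        v = down[nd] * L[nd.index]
        tot = v.sum()
        marg[nd] = v / tot if tot > 0 else np.full(k, 1.0 / k)
    return marg


@dataclass
class MkFit:
    """A fitted Mk model with marginal ancestral state probabilities."""

    model: str                       # "mk1" | "asymm"
    states: tuple[str, ...]
    rates: np.ndarray                # k x k instantaneous rate matrix
    log_likelihood: float
    marginals: dict[Node, np.ndarray]
    root_prior: np.ndarray
    n_parameters: int
    converged: bool = True
    at_bound: bool = False

    def marginal_at(self, node: Node) -> dict[str, float]:
        return dict(zip(self.states, self.marginals[node]))


_LOG_Q_BOUNDS = (-9.0, 3.0)   # log10 of per-Ma rates explored by the fits


def fit_mk(tree: DatedTree, traits: TraitTable, model: str = "mk1",
           root_prior: np.ndarray | None = None, n_starts: int = 3,
           seed: int = 0) -> MkFit:
    """Maximum-likelihood fit of the Mk1 or asymmetric (all-rates) model.

    Mk1 has a single rate; the asymmetric generalisation gives every
    ordered state pair its own rate (k(k-1) parameters), matching the
    two-parameter model at k = 2.  Optimisation is on log10 rates, with
    multistart for the asymmetric model.  A fit driven to the rate bounds
    (e.g. a constant character pushing q to 0) is flagged ``at_bound``.
    """
    k = traits.k
    prior = (np.full(k, 1.0 / k) if root_prior is None
             else np.asarray(root_prior, dtype=float))
    lo, hi = _LOG_Q_BOUNDS

    if model == "mk1":
        def nll(logq):
            return -mk_log_likelihood(tree, traits, 10.0 ** logq, prior)

        res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-7})
        q = 10.0 ** res.x
        Q = _mk1_Q(q, k)
        ll = -res.fun
        at_bound = res.x < lo + 0.05 or res.x > hi - 0.05
        fit = MkFit("mk1", traits.states, Q, ll,
                    _marginals(tree, traits, _branch_P(tree, Q), prior),
                    prior, 1, bool(res.success), at_bound)
        return fit

    if model != "asymm":
        raise ValueError(f"unknown model: {model!r}")

    off = ~np.eye(k, dtype=bool)
    n_par = k * (k - 1)

    def vec_to_Q(v):
        Q = np.zeros((k, k))
        Q[off] = 10.0 ** np.asarray(v)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def nll(v):
        ll, _, _ = _pruning(tree, traits, _branch_P(tree, vec_to_Q(v)), prior)
        return -ll if np.isfinite(ll) else 1e12

    # seed starts from the Mk1 fit
    base = fit_mk(tree, traits, "mk1", prior)
    q0 = np.log10(max(base.rates[0, 1], 10.0 ** lo))
    rng = np.random.default_rng(seed)
    starts = [np.full(n_par, q0)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.clip(q0 + rng.normal(0, 0.7, n_par), lo, hi))
    best = None
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                bounds=[(lo, hi)] * n_par,
                                options={"ftol": 1e-10, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    Q = vec_to_Q(best.x)
    ll = -best.fun
    at_bound = bool((best.x < lo + 0.05).any() or (best.x > hi - 0.05).any())
    # nesting guard: the asymmetric model contains Mk1
    if ll < base.log_likelihood - 1e-6:
        Q = base.rates
        ll = base.log_likelihood
    return MkFit("asymm", traits.states, Q, ll,
                 _marginals(tree, traits, _branch_P(tree, Q), prior),
                 prior, n_par, bool(best.success), at_bound)


def mk_lrt(fit_mk1: MkFit, fit_asymm: MkFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of the asymmetric model against Mk1.

    Returns ``(statistic, df, p)`` with df = (#asymmetric parameters) - 1
    and p from the chi-square distribution.  Tiny negative statistics from
    optimiser tolerance are clipped to zero.
    """
    stat = 2.0 * (fit_asymm.log_likelihood - fit_mk1.log_likelihood)
    if stat < -1e-6:
        raise ValueError("asymmetric fit has lower likelihood than Mk1; "
                         "optimisation failed")
    stat = max(stat, 0.0)
    df = fit_asymm.n_parameters - fit_mk1.n_parameters
    return stat, df, float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# Bayesian MCMC ancestral state reconstruction
# ---------------------------------------------------------------------------

def effective_sample_size(x: np.ndarray) -> float:
    """ESS by Geyer's initial positive sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        return float(n)
    x = x - x.mean()
    var = x.var()
    if var == 0:
        return float(n)
    acf = np.correlate(x, x, mode="full")[n - 1:] / (var * n)
    # sums of adjacent autocorrelation pairs, truncated when negative
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = acf[t] + acf[t + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(n / max(tau, 1.0))


@dataclass
class BayesAsrResult:
    """Posterior state probabilities at a focal node, averaged over chains."""

    states: tuple[str, ...]
    posterior: np.ndarray            # averaged per-state probabilities
    chain_means: np.ndarray          # n_chains x k
    ess: np.ndarray                  # per chain, on the focal-state trace
    n_chains: int
    n_kept: int                      # samples retained after equivocal filter
    support_call: str                # a state, "unsupported" or "equivocal"
    low_ess: bool = False

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.states, self.posterior))


def bayes_asr(trees, traits: TraitTable, focal_clade,
              n_chains: int = 3, n_iter: int = 30000,
              burn_in: int | None = None, seed: int = 0,
              hyper_upper: float = 30.0, proposal_scale: float = 0.35,
              support_threshold: float = 0.7,
              equivocal_margin: float = 0.05) -> BayesAsrResult:
    """MCMC reconstruction of the state at the MRCA of ``focal_clade``.

    The model is the asymmetric Mk model with a hierarchical prior: rates
    are iid exponential with mean m, and m is uniform on (0, ``hyper_upper``).
    When several trees are supplied one is drawn uniformly at each
    iteration, so the posterior integrates over topological uncertainty.
    Samples whose state vector is essentially flat (maximum probability
    within ``equivocal_margin`` of 1/k) are discarded as equivocal; the
    remaining per-iteration marginals are averaged within and then across
    chains.  The call is a state only when its averaged probability exceeds
    ``support_threshold``; chains with ESS < 200 are flagged.
    """
    if isinstance(trees, DatedTree):
        trees = [trees]
    trees = list(trees)
    if not trees:
        raise ValueError("no trees supplied")
    focal_clade = list(focal_clade)
    if not focal_clade:
        raise ValueError("empty focal clade")
    if burn_in is None:
        burn_in = n_iter // 4
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    k = traits.k
    off = ~np.eye(k, dtype=bool)
    n_par = k * (k - 1)
    prior_vec = np.full(k, 1.0 / k)
    focal_nodes = [t.mrca(focal_clade) for t in trees]

    def log_posterior(rates_vec, m, tree):
        if m <= 0 or m >= hyper_upper:
            return -np.inf, None
        Q = np.zeros((k, k))
        Q[off] = rates_vec
        np.fill_diagonal(Q, -Q.sum(axis=1))
        P = _branch_P(tree, Q)
        ll, L, logscale = _pruning(tree, traits, P, prior_vec)
        if not np.isfinite(ll):
            return -np.inf, None
        log_prior = -n_par * np.log(m) - rates_vec.sum() / m
        return ll + log_prior, P

    # start chains near the Mk1 ML rate (jittered per chain) so that short
    # runs already explore the posterior mode
    q_ml = fit_mk(trees[0], traits, "mk1", prior_vec).rates[0, 1]
    q_ml = float(np.clip(q_ml, 1e-8, hyper_upper / 2))

    chain_means = []
    ess = []
    n_kept_total = 0
    for c in range(n_chains):
        rng = np.random.default_rng(seed + c)
        m = float(np.clip(q_ml * np.exp(rng.normal(0, 0.5)),
                          1e-8, hyper_upper * 0.9))
        rates = q_ml * np.exp(rng.normal(0, 0.5, n_par))
        ti = rng.integers(len(trees))
        lp, _ = log_posterior(rates, m, trees[ti])
        while not np.isfinite(lp):
            m = rng.uniform(0, hyper_upper)
            rates = rng.exponential(1e-3, n_par)
            lp, _ = log_posterior(rates, m, trees[ti])
        samples = []
        trace = []
        for it in range(n_iter):
            ti = rng.integers(len(trees))
            tree = trees[ti]
            if rng.random() < 0.3:
                # lognormal random walk on the hyper-mean
                m_new = m * np.exp(rng.normal(0, 1.0))
                rates_new = rates
                log_hastings = np.log(m_new) - np.log(m)
            else:
                m_new = m
                rates_new = rates * np.exp(
                    rng.normal(0, proposal_scale, n_par))
                # Jacobian of the multiplicative proposal
                log_hastings = (np.log(rates_new).sum()
                                - np.log(rates).sum())
            lp_new, _ = log_posterior(rates_new, m_new, tree)
            if len(trees) > 1:
                # re-evaluate the current state on the freshly drawn tree
                lp, _ = log_posterior(rates, m, tree)
            if np.log(rng.random()) < lp_new - lp + log_hastings:
                rates, m, lp = rates_new, m_new, lp_new
            if it >= burn_in:
                Q = np.zeros((k, k))
                Q[off] = rates
                np.fill_diagonal(Q, -Q.sum(axis=1))
                marg = _marginals(tree, traits, _branch_P(tree, Q),
                                  prior_vec)
                p = marg[focal_nodes[ti]]
                trace.append(p.max())
                if p.max() > 1.0 / k + equivocal_margin:
                    samples.append(p)
        n_kept_total += len(samples)
        chain_means.append(np.mean(samples, axis=0) if samples
                           else np.full(k, np.nan))
        ess.append(effective_sample_size(np.array(trace)))
    chain_means = np.array(chain_means)
    ess = np.array(ess)
    if n_kept_total == 0:
        posterior = np.full(k, 1.0 / k)
        call = "equivocal"
    else:
        posterior = np.nanmean(chain_means, axis=0)
        posterior = posterior / posterior.sum()
        best = int(np.argmax(posterior))
        call = (traits.states[best]
                if posterior[best] > support_threshold else "unsupported")
    return BayesAsrResult(traits.states, posterior, chain_means, ess,
                          n_chains, n_kept_total, call,
                          bool((ess < 200).any()))
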
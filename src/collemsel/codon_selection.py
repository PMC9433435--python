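"""Codon-level selection analysis on a fixed tree.

The selection statistics consumed downstream are *counts*: synonymous and
nonsynonymous changes assigned to individual branches.  The route here is

1. fit (or accept) a GY94 codon model -- transition/transversion ratio
   kappa, selection parameter omega, equilibrium codon frequencies pi
   (F3x4 by default) -- by maximum likelihood on the alignment;
2. reconstruct marginal maximum-likelihood ancestral codons at every
   internal node by the up-down algorithm;
3. count changes per branch Nei--Gojobori style: per-codon synonymous and
   nonsynonymous site fractions, and pathway-averaged change counts between
   the reconstructed parent and child codons.

Site-heterogeneous models M1a (nearly neutral) and M2a (positive selection)
are fitted as omega mixtures and compared by a likelihood-ratio test with
2 degrees of freedom; per-site posteriors for the positive-selection class
are Naive Empirical Bayes values at the MLEs.

No multiple-hit correction is applied to the branch counts: after
reconstruction the per-branch divergences are small, which is the regime
where uncorrected counts are adequate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .codes import GeneticCode, get_code, is_transition
from .phylo_io import CodonAlignment, DatedTree, Node

__all__ = [
    "CodonModelParams", "SiteModelFit", "BranchChangeTable",
    "f3x4_frequencies", "empirical_codon_frequencies", "gy94_rate_matrix",
    "codon_log_likelihood", "fit_site_model", "site_lrt",
    "reconstruct_ancestral_codons", "branch_change_table", "gene_site_counts",
    "branch_omega", "standardized_gene_pct", "complex_summary",
    "branch_id", "DEFAULT_COMPLEX_MAP",
]

#: OXPHOS complex membership of the 13 mitochondrial protein-coding genes
DEFAULT_COMPLEX_MAP = {
    "nad1": "I", "nad2": "I", "nad3": "I", "nad4": "I", "nad4l": "I",
    "nad5": "I", "nad6": "I",
    "cytb": "III",
    "cox1": "IV", "cox2": "IV", "cox3": "IV",
    "atp6": "V", "atp8": "V",
}


# ---------------------------------------------------------------------------
# code structure caches
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _code_struct(code_id: int):
    """Sense-codon index arrays for one genetic code."""
    code = get_code(code_id)
    sense = code.sense_codons
    n = len(sense)
    idx = code.codon_index
    aa = [code.forward[c] for c in sense]
    pairs_i, pairs_j, ts, nonsyn = [], [], [], []
    for i, ci in enumerate(sense):
        for pos in range(3):
            for nt in "ACGT":
                if nt == ci[pos]:
                    continue
                cj = ci[:pos] + nt + ci[pos + 1:]
                j = idx.get(cj)
                if j is None:       # stop codon
                    continue
                pairs_i.append(i)
                pairs_j.append(j)
                ts.append(is_transition(ci[pos], nt))
                nonsyn.append(aa[i] != aa[j])
    return (code, n, np.array(pairs_i), np.array(pairs_j),
            np.array(ts, dtype=bool), np.array(nonsyn, dtype=bool))


# ---------------------------------------------------------------------------
# codon frequencies
# ---------------------------------------------------------------------------

def _sense_freqs_from_nt(pos_freqs: np.ndarray, code: GeneticCode) -> np.ndarray:
    nt_idx = {n: i for i, n in enumerate("ACGT")}
    pi = np.array([
        pos_freqs[0, nt_idx[c[0]]] * pos_freqs[1, nt_idx[c[1]]]
        * pos_freqs[2, nt_idx[c[2]]]
        for c in code.sense_codons
    ])
    tot = pi.sum()
    if tot <= 0:
        raise ValueError("degenerate nucleotide frequencies")
    return pi / tot


def f3x4_frequencies(aln: CodonAlignment) -> np.ndarray:
    """F3x4 codon frequencies: per-position nucleotide frequencies
    multiplied and renormalised over sense codons."""
    counts = np.zeros((3, 4))
    nt_idx = {n: i for i, n in enumerate("ACGT")}
    for taxon, seq in aln.sequences.items():
        for i in range(aln.n_codons):
            if aln.mask[taxon][i]:
                continue
            codon = seq[3 * i:3 * i + 3].upper()
            for pos, c in enumerate(codon):
                counts[pos, nt_idx[c]] += 1
    counts += 0.25  # tiny pseudocount keeps all sense codons reachable
    return _sense_freqs_from_nt(counts / counts.sum(axis=1, keepdims=True),
                                aln.code)


def empirical_codon_frequencies(aln: CodonAlignment) -> np.ndarray:
    """Observed sense-codon frequencies with a small pseudocount."""
    counts = np.full(len(aln.code.sense_codons), 0.1)
    idx = aln.code.codon_index
    for taxon, seq in aln.sequences.items():
        for i in range(aln.n_codons):
            if aln.mask[taxon][i]:
                continue
            counts[idx[seq[3 * i:3 * i + 3].upper()]] += 1
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# GY94 rate matrix and transition probabilities
# ---------------------------------------------------------------------------

def gy94_rate_matrix(kappa: float, omega: float, pi: np.ndarray,
                     code_id: int = 5, normalize: bool = True) -> np.ndarray:
    """GY94 instantaneous rate matrix over sense codons.

    Single-nucleotide moves only; rate to codon j is pi_j, times kappa for
    transitions, times omega for nonsynonymous changes.  With
    ``normalize`` the matrix is scaled to one expected substitution per
    codon per unit time at equilibrium, so branch lengths are in expected
    substitutions per codon.
    """
    _, n, pi_i, pi_j, ts, nonsyn = _code_struct(code_id)
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (n,):
        raise ValueError(f"pi must have length {n}")
    Q = np.zeros((n, n))
    rates = pi[pi_j].copy()
    rates[ts] *= kappa
    rates[nonsyn] *= omega
    Q[pi_i, pi_j] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalize:
        scale = -(pi * np.diag(Q)).sum()
        if scale > 0:
            Q /= scale
    return Q


class _CodonEig:
    """Eigendecomposition of a reversible GY94 matrix, giving cheap P(t)."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        B = 0.5 * (B + B.T)          # symmetrise away rounding noise
        w, U = np.linalg.eigh(B)
        self.w = w
        self.left = U / sq[:, None] * 1.0      # D^{-1/2} U
        self.right = (U * sq[:, None]).T       # U^T D^{1/2}
        #: expected substitutions per codon per unit time at equilibrium
        self.mean_rate = float(-(pi * np.diag(Q)).sum())

    def P(self, t: float) -> np.ndarray:
        M = (self.left * np.exp(self.w * t)) @ self.right
        return np.clip(M, 0.0, None)

    def branch_P(self, tree: "DatedTree", scale: float = 1.0
                 ) -> dict["Node", np.ndarray]:
        """P(t) for every branch at once (one batched contraction)."""
        branches = tree.branches()
        ts = np.array([nd.length for nd in branches]) * scale
        E = np.exp(np.outer(ts, self.w))
        mats = np.einsum("ik,bk,kj->bij", self.left, E, self.right,
                         optimize=True)
        np.maximum(mats, 0.0, out=mats)
        return dict(zip(branches, mats))


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

@dataclass
class CodonModelParams:
    """Parameters of a GY94 (mixture) codon model.

    ``class_omegas``/``class_props`` describe the omega mixture; M0 is the
    single-class case.
    """

    kappa: float
    class_omegas: tuple[float, ...]
    class_props: tuple[float, ...]
    pi: np.ndarray
    code_id: int = 5
    #: expected substitutions per codon per unit branch length (per Ma for
    #: dated trees); estimated jointly with the other parameters
    tree_scale: float = 1.0

    def __post_init__(self):
        if len(self.class_omegas) != len(self.class_props):
            raise ValueError("omega/proportion length mismatch")
        if abs(sum(self.class_props) - 1.0) > 1e-8:
            raise ValueError("mixture proportions must sum to 1")

    @property
    def omega(self) -> float:
        """Mean omega over classes (equals omega itself for M0)."""
        return float(np.dot(self.class_omegas, self.class_props))


def _patterns(tree: DatedTree, aln: CodonAlignment):
    """Site-pattern compression: codon index per (taxon, pattern), -1 = missing."""
    idx = aln.code.codon_index
    taxa = tree.taxon_labels
    cols = []
    site_to_pattern = []
    pat_index: dict[tuple, int] = {}
    for i in range(aln.n_codons):
        col = tuple(
            -1 if aln.mask[t][i] else idx[aln.codon(t, i)]
            for t in taxa)
        j = pat_index.setdefault(col, len(cols))
        if j == len(cols):
            cols.append(col)
        site_to_pattern.append(j)
    mat = np.array(cols, dtype=int).T            # n_taxa x n_patterns
    counts = np.bincount(site_to_pattern, minlength=len(cols)).astype(float)
    return mat, counts, np.array(site_to_pattern)


def _class_site_logliks(tree: DatedTree, pat: np.ndarray, pi: np.ndarray,
                        P: dict[Node, np.ndarray],
                        return_partials: bool = False):
    """Per-pattern log-likelihood under one omega class.

    ``P`` maps each branch (child node) to its transition matrix.  Returns
    the log site likelihoods, and optionally the scaled partials + P mats
    needed by the marginal reconstruction.
    """
    n_state = pi.size
    n_pat = pat.shape[1]
    taxa = tree.taxon_labels
    trow = {t: r for r, t in enumerate(taxa)}
    partial: dict[Node, np.ndarray] = {}
    logscale: dict[Node, np.ndarray] = {}
    for nd in tree.postorder_nodes:
        if nd.is_leaf:
            continue
        acc = np.ones((n_state, n_pat))
        sc = np.zeros(n_pat)
        for ch in nd.children:
            if ch.is_leaf:
                codons = pat[trow[ch.label]]
                msg = np.where(codons[None, :] >= 0,
                               P[ch][:, np.clip(codons, 0, None)], 1.0)
            else:
                msg = P[ch] @ partial[ch]
                sc += logscale[ch]
            acc *= msg
        m = acc.max(axis=0)
        m[m == 0] = 1.0
        partial[nd] = acc / m
        logscale[nd] = sc + np.log(m)
    root = tree.root
    site_lik = pi @ partial[root]
    with np.errstate(divide="ignore"):
        out = np.log(site_lik) + logscale[root]
    if return_partials:
        return out, partial, logscale, P
    return out


def codon_log_likelihood(tree: DatedTree, aln: CodonAlignment,
                         params: CodonModelParams) -> float:
    """Mixture (or single-class) GY94 log-likelihood by pruning.

    Branch lengths of ``tree`` are interpreted in expected substitutions
    per codon (the GY94 matrix is normalised to mean rate 1).
    """
    pat, counts, _ = _patterns(tree, aln)
    eigs = [_CodonEig(gy94_rate_matrix(params.kappa, om, params.pi,
                                       params.code_id, normalize=False),
                      params.pi)
            for om in params.class_omegas]
    # joint normalisation: one expected substitution per codon per unit of
    # (scaled) branch length averaged over classes, so faster classes
    # genuinely accumulate more changes
    common = float(np.dot([e.mean_rate for e in eigs], params.class_props))
    per_class = [
        _class_site_logliks(tree, pat, params.pi,
                            eig.branch_P(tree, params.tree_scale / common))
        for eig in eigs]
    L = np.stack(per_class)                       # n_class x n_patterns
    logp = np.log(np.asarray(params.class_props))[:, None]
    site = _logsumexp0(L + logp)
    return float((site * counts).sum())


def _logsumexp0(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=0)
    return m + np.log(np.exp(a - m[None, :]).sum(axis=0))


# ---------------------------------------------------------------------------
# site-model fits
# ---------------------------------------------------------------------------

@dataclass
class SiteModelFit:
    """A fitted site model (M0, M1a or M2a)."""

    model: str
    params: CodonModelParams
    log_likelihood: float
    n_parameters: int
    converged: bool = True
    site_posterior: np.ndarray | None = None   # P(positive class | site), M2a

    def positively_selected_sites(self, threshold: float = 0.95) -> list[int]:
        """0-based sites whose posterior for the positive class reaches
        ``threshold`` (the conventional 0.95 cut-off)."""
        if self.site_posterior is None:
            return []
        return [int(i) for i in np.nonzero(
            np.nan_to_num(self.site_posterior) >= threshold)[0]]


_KAPPA_BOUNDS = (0.1, 50.0)
_OMEGA_BOUNDS = (1e-4, 20.0)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def fit_site_model(tree: DatedTree, aln: CodonAlignment, model: str = "M0",
                   pi: np.ndarray | None = None, freq_model: str = "F3x4",
                   n_starts: int = 5, seed: int = 0,
                   init: "SiteModelFit | None" = None,
                   tol: float = 1e-8) -> SiteModelFit:
    """ML fit of an omega site model on a fixed tree.

    ``model`` is ``"M0"`` (one omega), ``"M1a"`` (omega0 < 1 and omega1 = 1)
    or ``"M2a"`` (M1a plus a positive class omega2 >= 1).  Codon
    frequencies are F3x4 from the alignment unless supplied (``pi``) or
    ``freq_model="empirical"``.  Bounded multistart L-BFGS-B over
    kappa in [0.1, 50] and omega in [1e-4, 20].  ``init`` warm-starts the
    search from a previously fitted (typically nested) model.
    """
    if pi is None:
        pi = (empirical_codon_frequencies(aln) if freq_model == "empirical"
              else f3x4_frequencies(aln))
    code_id = aln.code.code_id
    pat, counts, site_to_pattern = _patterns(tree, aln)

    eig_cache: dict[tuple[float, float], _CodonEig] = {}

    def get_eig(kappa, om):
        # finite-difference gradient steps perturb one parameter at a
        # time, so most evaluations reuse cached decompositions; the
        # matrices are left unnormalised and the mixture-level
        # normalisation is folded into the time scaling below
        key = (kappa, om)
        if key not in eig_cache:
            if len(eig_cache) > 256:
                eig_cache.clear()
            Q = gy94_rate_matrix(kappa, om, pi, code_id, normalize=False)
            eig_cache[key] = _CodonEig(Q, pi)
        return eig_cache[key]

    def class_liks(kappa, omegas, scale, props):
        eigs = [get_eig(kappa, om) for om in omegas]
        common = float(np.dot([e.mean_rate for e in eigs], props))
        return np.stack([
            _class_site_logliks(tree, pat, pi,
                                eig.branch_P(tree, scale / common))
            for eig in eigs])

    def mixture_nll(kappa, omegas, props, scale):
        L = class_liks(kappa, omegas, scale, props)
        site = _logsumexp0(L + np.log(np.asarray(props))[:, None])
        val = float((site * counts).sum())
        return -val if np.isfinite(val) else 1e12

    lk_lo, lk_hi = np.log(_KAPPA_BOUNDS)
    lw_lo, lw_hi = np.log(_OMEGA_BOUNDS)
    # the tree scale converts the tree's branch-length unit (Ma for dated
    # trees) into expected substitutions per codon
    h = max(tree.height, 1e-12)
    ls_lo, ls_hi = np.log(1e-4 / h), np.log(50.0 / h)
    scale0 = [np.log(0.3 / h), np.log(1.5 / h)]

    if model == "M0":
        def unpack(x):
            return np.exp(x[0]), (np.exp(x[1]),), (1.0,), np.exp(x[2])
        bounds = [(lk_lo, lk_hi), (lw_lo, lw_hi), (ls_lo, ls_hi)]
        x0s = [np.array([np.log(2.0), np.log(w), s])
               for w in (0.2, 1.0, 3.0) for s in scale0]
        n_par = 3
    elif model == "M1a":
        def unpack(x):
            w0 = np.exp(x[1])
            p0 = _sigmoid(x[2])
            return np.exp(x[0]), (w0, 1.0), (p0, 1.0 - p0), np.exp(x[3])
        bounds = [(lk_lo, lk_hi), (lw_lo, np.log(0.999)), (-8.0, 8.0),
                  (ls_lo, ls_hi)]
        x0s = [np.array([np.log(2.0), np.log(w), p, s])
               for w in (0.1, 0.5) for p in (0.0, 1.5) for s in scale0]
        n_par = 4
    elif model == "M2a":
        def unpack(x):
            w0 = np.exp(x[1])
            p0 = _sigmoid(x[2])
            p1 = (1.0 - p0) * _sigmoid(x[3])
            w2 = np.exp(x[4])
            return (np.exp(x[0]), (w0, 1.0, w2), (p0, p1, 1.0 - p0 - p1),
                    np.exp(x[5]))
        bounds = [(lk_lo, lk_hi), (lw_lo, np.log(0.999)), (-8.0, 8.0),
                  (-8.0, 8.0), (0.0, lw_hi), (ls_lo, ls_hi)]
        x0s = [np.array([np.log(2.0), np.log(w), 0.5, 0.0, np.log(w2), s])
               for w2 in (4.0, 1.5) for w in (0.1, 0.5) for s in scale0]
        n_par = 6
    else:
        raise ValueError(f"unknown site model: {model!r}")

    rng = np.random.default_rng(seed)
    starts = []
    if init is not None:
        starts.append(_warm_start(model, init, bounds))
    starts += x0s[:max(0, n_starts - len(starts))]
    while len(starts) < n_starts:
        base = x0s[rng.integers(len(x0s))]
        jit = base + rng.normal(0, 0.4, base.size)
        starts.append(np.clip(jit, [b[0] for b in bounds],
                              [b[1] for b in bounds]))

    def nll(x):
        kappa, omegas, props, scale = unpack(x)
        return mixture_nll(kappa, omegas, props, scale)

    # scipy's ftol is relative; convert the absolute log-likelihood
    # tolerance using the magnitude at the first start
    f0 = abs(nll(starts[0]))
    ftol = tol / max(1.0, f0)
    best = None
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                options={"ftol": ftol, "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
    kappa, omegas, props, scale = unpack(best.x)
    params = CodonModelParams(kappa, tuple(omegas), tuple(props),
                              np.asarray(pi), code_id, scale)
    fit = SiteModelFit(model, params, -best.fun, n_par, bool(best.success))
    if model == "M2a":
        L = class_liks(kappa, omegas, scale, props)
        logp = np.log(np.asarray(props))[:, None]
        joint = L + logp
        post = np.exp(joint[2] - _logsumexp0(joint))
        per_site = post[site_to_pattern].astype(float)
        site_mask = np.array(aln.site_mask)
        per_site[site_mask] = np.nan
        fit.site_posterior = per_site
    return fit


def _warm_start(model: str, init: SiteModelFit,
                bounds: list[tuple[float, float]]) -> np.ndarray:
    """Transform a fitted model's MLEs into a starting vector for ``model``."""
    p = init.params
    k = np.log(p.kappa)
    s = np.log(p.tree_scale)
    w0 = p.class_omegas[0]
    if model == "M0":
        x = [k, np.log(max(p.omega, 1e-4)), s]
    elif model == "M1a":
        if init.model == "M0":
            w0 = min(max(p.omega, 1e-4), 0.9)
            p0 = 0.7
        else:
            p0 = p.class_props[0]
        x = [k, np.log(min(max(w0, 1e-4), 0.99)),
             _logit(p0), s]
    elif model == "M2a":
        if init.model == "M1a":
            p0, p1 = p.class_props[0], p.class_props[1]
            # shave a sliver off the neutral class for the positive class
            p1 = max(p1 - 0.05, 0.01)
        else:
            p0, p1 = 0.6, 0.3
        rest = max(1.0 - p0, 1e-3)
        x = [k, np.log(min(max(w0, 1e-4), 0.99)), _logit(p0),
             _logit(min(max(p1 / rest, 1e-3), 1 - 1e-3)), np.log(2.0), s]
    else:
        raise ValueError(model)
    return np.clip(np.array(x), [b[0] for b in bounds],
                   [b[1] for b in bounds])


def _logit(p: float) -> float:
    p = min(max(p, 1e-3), 1 - 1e-3)
    return float(np.log(p / (1 - p)))


def site_lrt(fit_m1a: SiteModelFit, fit_m2a: SiteModelFit
             ) -> tuple[float, int, float]:
    """Likelihood-ratio test of M2a against M1a (df = 2)."""
    stat = 2.0 * (fit_m2a.log_likelihood - fit_m1a.log_likelihood)
    stat = max(stat, 0.0)
    return stat, 2, float(stats.chi2.sf(stat, 2))


# ---------------------------------------------------------------------------
# ancestral codon reconstruction and branch counting
# ---------------------------------------------------------------------------

@dataclass
class AncestralCodons:
    """Marginal ML codon sequences at every node of one gene's tree."""

    gene_name: str
    sequences: dict[Node, list[str | None]]   # None at masked sites
    posterior: dict[Node, np.ndarray]         # per-site reconstruction prob
    params: CodonModelParams


def reconstruct_ancestral_codons(tree: DatedTree, aln: CodonAlignment,
                                 params: CodonModelParams | None = None,
                                 **fit_kwargs) -> AncestralCodons:
    """Marginal ancestral codons at internal nodes under an M0 GY94 model.

    If ``params`` is omitted an M0 model is first fitted to the alignment.
    Columns masked in any taxon are left unreconstructed (``None``) --
    they are also excluded from downstream counting.
    """
    if params is None:
        params = fit_site_model(tree, aln, "M0", **fit_kwargs).params
    pi = np.asarray(params.pi)
    Q = gy94_rate_matrix(params.kappa, params.omega, pi, params.code_id)
    eig = _CodonEig(Q, pi)
    pat, counts, site_to_pattern = _patterns(tree, aln)
    _, partial, logscale, P = _class_site_logliks(
        tree, pat, pi, eig.branch_P(tree, params.tree_scale),
        return_partials=True)
    n_pat = pat.shape[1]
    n_state = pi.size
    taxa = tree.taxon_labels
    trow = {t: r for r, t in enumerate(taxa)}

    # outside (down) pass over patterns
    down: dict[Node, np.ndarray] = {
        tree.root: np.broadcast_to(pi[:, None], (n_state, n_pat)).copy()}
    msg: dict[Node, np.ndarray] = {}
    for nd in tree.postorder_nodes:
        if nd is tree.root:
            continue
        if nd.is_leaf:
            codons = pat[trow[nd.label]]
            msg[nd] = np.where(codons[None, :] >= 0,
                               P[nd][:, np.clip(codons, 0, None)], 1.0)
        else:
            msg[nd] = P[nd] @ partial[nd]
    for nd in tree.preorder():
        if nd.is_leaf:
            continue
        for ch in nd.children:
            out = down[nd].copy()
            for sib in nd.children:
                if sib is not ch:
                    out *= msg[sib]
            m = out.max(axis=0)
            m[m == 0] = 1.0
            down[ch] = (out / m).T @ P[ch]
            down[ch] = down[ch].T

    site_mask = np.array(aln.site_mask)
    sense = aln.code.sense_codons
    sequences: dict[Node, list[str | None]] = {}
    posterior: dict[Node, np.ndarray] = {}
    for nd in tree.postorder_nodes:
        if nd.is_leaf:
            seq = [None if aln.mask[nd.label][i] else aln.codon(nd.label, i)
                   for i in range(aln.n_codons)]
            sequences[nd] = seq
            posterior[nd] = np.where(site_mask, np.nan, 1.0)
            continue
        marg = down[nd] * partial[nd]
        tot = marg.sum(axis=0)
        tot[tot == 0] = 1.0
        marg = marg / tot
        best = marg.argmax(axis=0)
        prob = marg.max(axis=0)
        seq = []
        pp = np.empty(aln.n_codons)
        for i in range(aln.n_codons):
            if site_mask[i]:
                seq.append(None)
                pp[i] = np.nan
            else:
                j = site_to_pattern[i]
                seq.append(sense[best[j]])
                pp[i] = prob[j]
        sequences[nd] = seq
        posterior[nd] = pp
    return AncestralCodons(aln.gene_name, sequences, posterior, params)


def branch_id(node: Node) -> str:
    """Stable identifier of the branch above ``node``."""
    return node.label if node.is_leaf else f"node{node.index}"


@dataclass
class BranchChangeTable:
    """Per-branch, per-gene synonymous/nonsynonymous change counts."""

    table: pd.DataFrame      # columns: branch, gene, dN, dS, n_sites_used
    terminal_branches: list[str] = field(default_factory=list)

    def per_branch_totals(self) -> pd.DataFrame:
        return (self.table.groupby("branch")[["dN", "dS"]]
                .sum().reset_index())

    def gene_totals(self) -> pd.DataFrame:
        return self.table.groupby("gene")[["dN", "dS"]].sum().reset_index()


def branch_change_table(tree: DatedTree,
                        ancestors: AncestralCodons | list[AncestralCodons],
                        code: GeneticCode | None = None) -> BranchChangeTable:
    """Pathway-averaged dN/dS change counts for every branch and gene.

    Counts compare each node's reconstructed (or observed, at tips) codons
    with its parent's; masked columns contribute nothing.
    """
    if isinstance(ancestors, AncestralCodons):
        ancestors = [ancestors]
    rows = []
    for anc in ancestors:
        gcode = code or get_code(anc.params.code_id)
        for nd in tree.branches():
            parent_seq = anc.sequences[nd.parent]
            child_seq = anc.sequences[nd]
            dn = ds = 0.0
            used = 0
            for ca, cb in zip(parent_seq, child_seq):
                if ca is None or cb is None:
                    continue
                used += 1
                if ca != cb:
                    nd_, sd_ = gcode.pathway_count(ca, cb)
                    dn += nd_
                    ds += sd_
            rows.append({"branch": branch_id(nd), "gene": anc.gene_name,
                         "dN": dn, "dS": ds, "n_sites_used": used})
    table = pd.DataFrame(rows)
    terminals = [lf.label for lf in tree.leaves]
    return BranchChangeTable(table, terminals)


def gene_site_counts(aln: CodonAlignment) -> tuple[float, float]:
    """Gene-level synonymous (S) and nonsynonymous (N) site totals.

    Nei--Gojobori site fractions summed over unmasked columns and averaged
    across the gene's sequences.
    """
    S = N = 0.0
    n_seq = 0
    for taxon, seq in aln.sequences.items():
        s_tot = n_tot = 0.0
        for i in range(aln.n_codons):
            if aln.mask[taxon][i]:
                continue
            s, n = aln.code.ng_sites(seq[3 * i:3 * i + 3].upper())
            s_tot += s
            n_tot += n
        S += s_tot
        N += n_tot
        n_seq += 1
    if n_seq == 0:
        raise ValueError("empty alignment")
    return S / n_seq, N / n_seq


def branch_omega(dn_count: float, ds_count: float, N: float, S: float
                 ) -> float | None:
    """omega = (dN/N)/(dS/S) from branch counts and gene site totals.

    Returns None (undefined) when no synonymous changes were counted on the
    branch -- reported rather than treated as infinite.
    """
    if N <= 0 or S <= 0:
        raise ValueError("site totals must be positive")
    if ds_count == 0:
        return None
    return (dn_count / N) / (ds_count / S)


def standardized_gene_pct(total_nonsyn_changes: float, gene_size: int,
                          n_branches: int) -> float:
    """Nonsynonymous changes standardised by gene size and branch count:
    ``changes / (gene_size * n_branches) * 100``.

    ``gene_size`` is the alignment length in codons.
    """
    if gene_size <= 0 or n_branches <= 0:
        raise ValueError("gene size and branch count must be positive")
    return total_nonsyn_changes / (gene_size * n_branches) * 100.0


def complex_summary(changes: BranchChangeTable,
                    gene_sizes: dict[str, int],
                    complex_map: dict[str, str] | None = None,
                    n_branches: int | None = None) -> pd.DataFrame:
    """Standardised nonsynonymous percentages per gene and OXPHOS complex.

    Counts and codon sizes are summed within a complex before the
    standardisation formula is applied.  Genes absent from the map are
    excluded with a warning column in the per-gene frame.
    """
    import warnings

    cmap = DEFAULT_COMPLEX_MAP if complex_map is None else complex_map
    gene_totals = changes.table.groupby("gene")[["dN", "dS"]].sum()
    if n_branches is None:
        n_branches = changes.table["branch"].nunique()
    gene_rows = []
    cx: dict[str, dict[str, float]] = {}
    for gene, row in gene_totals.iterrows():
        size = gene_sizes[gene]
        pct = standardized_gene_pct(row["dN"], size, n_branches)
        complex_name = cmap.get(gene)
        if complex_name is None:
            warnings.warn(f"gene {gene!r} missing from complex map; excluded")
        gene_rows.append({"gene": gene, "complex": complex_name,
                          "dN": row["dN"], "dS": row["dS"],
                          "size_codons": size, "pct_nonsyn": pct})
        if complex_name is not None:
            acc = cx.setdefault(complex_name, {"dN": 0.0, "size": 0})
            acc["dN"] += row["dN"]
            acc["size"] += size
    complex_rows = []
    for name, acc in cx.items():
        complex_rows.append({
            "complex": name,
            "pct_nonsyn": standardized_gene_pct(acc["dN"], acc["size"],
                                                n_branches)})
    out = pd.DataFrame(complex_rows, columns=["complex", "pct_nonsyn"])
    out = out.sort_values("pct_nonsyn", ascending=False).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out.attrs["per_gene"] = pd.DataFrame(gene_rows)
    return out
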
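"""Simulators for trees, discrete traits and codon alignments.

Every stage of the analysis can be exercised without external data:

* ultrametric birth-death trees conditioned on a tip count, with node ages
  rescaled to a chosen root age in Ma;
* discrete traits evolved by Gillespie simulation of a continuous-time
  Markov (Mk) process, recording the true node states;
* codon alignments evolved under a GY94 model -- single-nucleotide moves,
  transition bias kappa, selection parameter omega (per-branch overrides
  and site-class mixtures supported), target codon frequencies pi, stop
  codons forbidden -- again by event simulation, so the *true* per-branch
  synonymous and nonsynonymous event counts exist for oracle comparisons
  (endpoint sampling from matrix exponentials would not provide them);
* bundled "shift scenarios" that designate derived-state clades and
  multiply omega on their branches, the harness for power and
  false-positive studies of the shift-vs-sister comparison.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codon_selection import _code_struct, branch_id, gy94_rate_matrix
from .phylo_io import (CodonAlignment, DatedTree, Node, TraitTable,
                       LIFE_FORMS)

__all__ = [
    "simulate_bd_tree", "simulate_mk_trait", "simulate_codon_alignment",
    "make_shift_scenario", "SimulatedTrait", "SimulatedAlignment",
    "ShiftScenario",
]


# ---------------------------------------------------------------------------
# birth-death trees
# ---------------------------------------------------------------------------

def simulate_bd_tree(n_tips: int, birth: float = 1.0, death: float = 0.0,
                     root_age: float = 400.0, seed: int | np.random.Generator = 0,
                     max_attempts: int = 1000) -> DatedTree:
    """Ultrametric birth-death tree conditioned on ``n_tips`` extant taxa.

    Forward simulation from the root split; a replicate is accepted at the
    moment the extant lineage count first reaches ``n_tips`` (with both
    root children surviving), extinct lineages are pruned, and all ages are
    rescaled so the root sits at ``root_age`` Ma.  Repeated sampling up to
    ``max_attempts``.
    """
    if birth <= death or death < 0:
        raise ValueError("need birth > death >= 0")
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    for _ in range(max_attempts):
        root = Node()
        left, right = Node(), Node()
        root.children = [left, right]
        split_time = {root: 0.0}         # time at which a node bifurcates
        alive = [left, right]
        t = 0.0
        ok = False
        while alive:
            n = len(alive)
            if n == n_tips:
                ok = True
                break
            t += rng.exponential(1.0 / ((birth + death) * n))
            idx = rng.integers(n)
            nd = alive.pop(idx)
            if rng.random() < birth / (birth + death):
                c1, c2 = Node(), Node()
                nd.children = [c1, c2]
                split_time[nd] = t
                alive.extend([c1, c2])
            # else: death -- the lineage simply ends before the present
        if not ok:
            continue
        for i, nd in enumerate(alive):
            nd.label = f"t{i + 1}"
        height = t if t > 0 else 1.0

        def prune(nd):
            """Drop extinct subtrees; suppress degree-2 pass-throughs."""
            if not nd.children:
                return nd if nd.label is not None else None
            kept = [c for c in (prune(ch) for ch in nd.children)
                    if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                return kept[0]
            nd.children = kept
            return nd

        top = prune(root)
        if top is not root:
            continue  # root split must survive on both sides

        scale = root_age / height

        def set_lengths(nd):
            # nd's branch to each child spans from nd's split to the
            # child's own split (internal) or the present (extant tip)
            for ch in nd.children:
                end = split_time[ch] if ch.children else height
                ch.length = (end - split_time[nd]) * scale
                set_lengths(ch)

        set_lengths(root)
        root.length = None
        tree = DatedTree(root)
        if tree.n_leaves == n_tips:
            return tree
    raise ValueError(f"failed to reach {n_tips} extant tips in "
                     f"{max_attempts} attempts")


# ---------------------------------------------------------------------------
# discrete traits
# ---------------------------------------------------------------------------

@dataclass
class SimulatedTrait:
    """Simulated trait with full truth: node states and per-branch changes."""

    table: TraitTable
    node_states: dict[Node, str]
    branch_events: dict[str, list[tuple[str, str]]]   # branch id -> jumps

    @property
    def n_changes(self) -> int:
        return sum(len(v) for v in self.branch_events.values())


def simulate_mk_trait(tree: DatedTree, Q: np.ndarray,
                      states: tuple[str, ...], root_state: str,
                      seed: int | np.random.Generator = 0) -> SimulatedTrait:
    """Gillespie simulation of an Mk trait along the tree.

    ``Q`` is the k x k instantaneous rate matrix (diagonal recomputed);
    waiting times are exponential in the current state's total rate and
    jumps follow the state's rate row.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    Q = np.asarray(Q, dtype=float).copy()
    np.fill_diagonal(Q, 0.0)
    k = len(states)
    totals = Q.sum(axis=1)
    jump = np.divide(Q, totals[:, None], out=np.full_like(Q, 1.0 / (k - 1)),
                     where=totals[:, None] > 0)
    node_states: dict[Node, str] = {tree.root: root_state}
    events: dict[str, list[tuple[str, str]]] = {}
    sidx = {s: i for i, s in enumerate(states)}
    for nd in tree.preorder():
        if nd is tree.root:
            continue
        s = sidx[node_states[nd.parent]]
        t = 0.0
        log = []
        while True:
            rate = totals[s]
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= nd.length:
                break
            s_new = rng.choice(k, p=jump[s])
            log.append((states[s], states[s_new]))
            s = s_new
        node_states[nd] = states[s]
        events[branch_id(nd)] = log
    table = TraitTable(tuple(states),
                       {lf.label: node_states[lf] for lf in tree.leaves})
    return SimulatedTrait(table, node_states, events)


# ---------------------------------------------------------------------------
# codon alignments
# ---------------------------------------------------------------------------

@dataclass
class SimulatedAlignment:
    """Simulated codon alignment plus the generating truth."""

    alignment: CodonAlignment
    node_sequences: dict[Node, list[str]]
    branch_events: dict[str, list[tuple[int, str, str, bool]]]
    #: branch id -> (synonymous, nonsynonymous) realized event counts
    branch_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.branch_counts:
            for br, log in self.branch_events.items():
                syn = sum(1 for ev in log if ev[3])
                self.branch_counts[br] = (syn, len(log) - syn)


def _mean_rate(kappa, omega, pi, code_id):
    Q = gy94_rate_matrix(kappa, omega, pi, code_id, normalize=False)
    return float(-(np.asarray(pi) * np.diag(Q)).sum())


def _jump_struct(kappa, omega, pi, code_id, rate_div):
    """Total rate per codon and jump-chain cumulative probs for one omega.

    ``rate_div`` is the common normalisation constant shared by all omega
    classes of the gene, so classes with higher omega genuinely accumulate
    more substitutions per unit branch length.
    """
    Q = gy94_rate_matrix(kappa, omega, pi, code_id, normalize=False)
    totals = -np.diag(Q).copy() / rate_div
    R = Q.copy()
    np.fill_diagonal(R, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = R / (-np.diag(Q))[:, None]
    P[-np.diag(Q) <= 0] = 0.0
    return totals, np.cumsum(P, axis=1)


def simulate_codon_alignment(tree: DatedTree, n_codons: int,
                             kappa: float = 2.0, omega: float = 0.2,
                             pi: np.ndarray | None = None,
                             code_id: int = 5,
                             branch_omega: dict[str, float] | None = None,
                             site_classes: tuple[tuple[float, ...],
                                                 tuple[float, ...]] | None = None,
                             rate_scale: float = 1.0,
                             seed: int | np.random.Generator = 0,
                             gene_name: str = "gene1") -> SimulatedAlignment:
    """GY94 Gillespie simulation of one gene along the tree.

    Branch lengths are ``rate_scale * length`` expected substitutions per
    codon (each branch's generator is normalised to mean rate 1 at the
    equilibrium frequencies under its own omega).  ``branch_omega`` maps
    branch ids (tip label or ``node<i>``) to omega overrides;
    ``site_classes = (omegas, props)`` draws a fixed omega class per site
    (M1a/M2a-style data).  The root sequence is drawn from ``pi``
    (uniform over sense codons by default).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    code, n_state, *_ = _code_struct(code_id)
    sense = code.sense_codons
    aa = [code.forward[c] for c in sense]
    if pi is None:
        pi = np.full(n_state, 1.0 / n_state)
    pi = np.asarray(pi, dtype=float)
    branch_omega = branch_omega or {}
    bad = set(branch_omega) - {branch_id(nd) for nd in tree.branches()}
    if bad:
        raise ValueError(f"unknown branch ids in omega map: {sorted(bad)}")

    if site_classes is None:
        site_omega = np.full(n_codons, float(omega))
        # branch lengths in expected substitutions/codon at the base omega
        common = _mean_rate(kappa, float(omega), pi, code_id)
    else:
        omegas, props = site_classes
        cls = rng.choice(len(omegas), size=n_codons, p=np.asarray(props))
        site_omega = np.asarray(omegas, dtype=float)[cls]
        # joint normalisation over the omega mixture, matching the fitted
        # site models
        common = float(np.dot([_mean_rate(kappa, w, pi, code_id)
                               for w in omegas], props))

    structs: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def struct_for(w: float):
        if w not in structs:
            structs[w] = _jump_struct(kappa, w, pi, code_id, common)
        return structs[w]

    root_seq = rng.choice(n_state, size=n_codons, p=pi)
    node_seq_idx: dict[Node, np.ndarray] = {tree.root: root_seq}
    events: dict[str, list[tuple[int, str, str, bool]]] = {}
    for nd in tree.preorder():
        if nd is tree.root:
            continue
        mult = branch_omega.get(branch_id(nd))
        seq = node_seq_idx[nd.parent].copy()
        length = nd.length * rate_scale
        log = []
        for site in range(n_codons):
            w = mult if mult is not None else site_omega[site]
            totals, cum = struct_for(float(w))
            s = seq[site]
            t = 0.0
            while True:
                rate = totals[s]
                if rate <= 0:
                    break
                t += rng.exponential(1.0 / rate)
                if t >= length:
                    break
                s_new = int(np.searchsorted(cum[s], rng.random()))
                log.append((site, sense[s], sense[s_new],
                            aa[s] == aa[s_new]))
                s = s_new
            seq[site] = s
        node_seq_idx[nd] = seq
        events[branch_id(nd)] = log

    sequences = {}
    node_sequences = {}
    for nd in tree.postorder_nodes:
        codons = [sense[i] for i in node_seq_idx[nd]]
        node_sequences[nd] = codons
        if nd.is_leaf:
            sequences[nd.label] = "".join(codons)
    aln = CodonAlignment(gene_name, sequences, code)
    params = {"kappa": kappa, "omega": omega, "n_codons": n_codons,
              "code_id": code_id, "rate_scale": rate_scale,
              "branch_omega": dict(branch_omega),
              "site_classes": (list(map(float, site_classes[0])),
                               list(map(float, site_classes[1])))
              if site_classes else None}
    return SimulatedAlignment(aln, node_sequences, events, params=params)


# ---------------------------------------------------------------------------
# shift scenarios
# ---------------------------------------------------------------------------

@dataclass
class ShiftScenario:
    """A full input bundle with designated life-form shifts.

    ``shift_tip_sets`` lists the member tips of each designated derived
    clade; omega is multiplied by ``omega_multiplier`` on every branch
    inside those clades (including the stem).  A multiplier of 1 is the
    null bundle.
    """

    tree: DatedTree
    traits: TraitTable
    alignments: list[SimulatedAlignment]
    shift_tip_sets: list[list[str]]
    shift_states: list[str]
    ancestral_state: str
    omega_multiplier: float
    params: dict = field(default_factory=dict)

    def save(self, out_dir) -> None:
        """Write tree, alignments, traits and a provenance JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.tree.write(out / "tree.nwk")
        with open(out / "traits.tsv", "w") as fh:
            for taxon, state in self.traits.assignments.items():
                fh.write(f"{taxon}\t{state}\n")
        for sim in self.alignments:
            sim.alignment.write_fasta(out / f"{sim.alignment.gene_name}.fasta")
        with open(out / "provenance.json", "w") as fh:
            json.dump(self.params, fh, indent=2, default=str)


def _pick_shift_clades(tree: DatedTree, n_shifts: int, clade_sizes,
                       rng) -> list[Node]:
    """Disjoint shift origins whose divergence nodes keep a free sister."""
    chosen: list[Node] = []
    taken: set[Node] = set()

    def subtree_free(nd):
        return not any(x in taken for x in tree.clade_nodes(nd))

    candidates = []
    for nd in tree.branches():
        leaves = tree.clade_leaves(nd)
        if len(leaves) in clade_sizes:
            candidates.append(nd)
    order = rng.permutation(len(candidates))
    for i in order:
        nd = candidates[i]
        if len(chosen) == n_shifts:
            break
        parent = nd.parent
        if parent is None or not subtree_free(nd):
            continue
        # the sister side must retain at least one untouched lineage
        sisters = [ch for ch in parent.children if ch is not nd]
        if not any(subtree_free(s) for s in sisters):
            continue
        # keep divergence nodes distinct to avoid nested bookkeeping
        if any(parent in tree.clade_nodes(c) or c.parent is parent
               for c in chosen):
            continue
        chosen.append(nd)
        taken.update(tree.clade_nodes(nd))
        taken.add(parent)
    return chosen


def make_shift_scenario(seed: int = 0, n_tips: int = 16,
                        n_shifts: int = 4, clade_sizes=(1, 2),
                        n_genes: int = 5, n_codons: int = 300,
                        kappa: float = 2.0, base_omega: float = 0.2,
                        omega_multiplier: float = 1.0,
                        root_age: float = 400.0,
                        tree_depth_subs: float = 0.4,
                        birth: float = 1.0, death: float = 0.0
                        ) -> ShiftScenario:
    """Simulate a complete study bundle with designated life-form shifts.

    A birth-death tree is drawn, ``n_shifts`` disjoint clades (of
    ``clade_sizes`` tips) are assigned derived life-form states with all
    other tips in the ancestral state, and ``n_genes`` codon alignments are
    evolved with omega multiplied by ``omega_multiplier`` on every branch
    of the derived clades.  ``tree_depth_subs`` sets the expected
    root-to-tip divergence in substitutions per codon at the base omega.
    """
    rng = np.random.default_rng(seed)
    tree = simulate_bd_tree(n_tips, birth, death, root_age, rng)
    origins = _pick_shift_clades(tree, n_shifts, clade_sizes, rng)
    if len(origins) < n_shifts:
        raise ValueError(f"could only place {len(origins)} of {n_shifts} "
                         f"shift clades on the tree")
    ancestral = "hemiedaphic"
    derived_pool = [s for s in LIFE_FORMS if s != ancestral]
    assignments = {t: ancestral for t in tree.taxon_labels}
    shift_tip_sets = []
    shift_states = []
    shift_branches = []
    for i, origin in enumerate(origins):
        state = derived_pool[i % len(derived_pool)]
        tips = [lf.label for lf in tree.clade_leaves(origin)]
        for t in tips:
            assignments[t] = state
        shift_tip_sets.append(tips)
        shift_states.append(state)
        shift_branches.extend(branch_id(nd)
                              for nd in tree.clade_nodes(origin))
    traits = TraitTable(LIFE_FORMS, assignments)
    rate_scale = tree_depth_subs / tree.height
    omega_map = {br: base_omega * omega_multiplier for br in shift_branches}
    alignments = []
    for g in range(n_genes):
        sim = simulate_codon_alignment(
            tree, n_codons, kappa=kappa, omega=base_omega,
            branch_omega=omega_map, rate_scale=rate_scale,
            seed=rng, gene_name=f"gene{g + 1}")
        alignments.append(sim)
    params = {"seed": seed, "n_tips": n_tips, "n_shifts": n_shifts,
              "clade_sizes": list(clade_sizes), "n_genes": n_genes,
              "n_codons": n_codons, "kappa": kappa,
              "base_omega": base_omega,
              "omega_multiplier": omega_multiplier,
              "root_age": root_age, "tree_depth_subs": tree_depth_subs,
              "birth": birth, "death": death,
              "shift_tip_sets": shift_tip_sets,
              "shift_states": shift_states}
    return ShiftScenario(tree, traits, alignments, shift_tip_sets,
                         shift_states, ancestral, omega_multiplier, params)
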
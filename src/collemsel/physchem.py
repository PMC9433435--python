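"""Radical amino-acid property changes along a phylogeny.

For each physicochemical property, every possible single-nucleotide
nonsynonymous codon change under the genetic code is assigned to one of
eight equal-width magnitude categories of |delta property| -- 1 the most
conservative, 8 the most radical.  Observed replacements, inferred from the
reconstructed ancestral codon sequences on every branch, are tallied per
category and compared with the neutral expectation (the category
distribution over all enumerable changes) by a per-category binomial
z-score.  |z| > 3.09 corresponds to a one-sided p < 0.001; a significant
positive z in the radical categories 7-8 is the signature of selection
favouring property-changing replacements.

A sliding window (15 codons by default, advancing one codon at a time)
localises the signal along the gene; the whole-gene profile drives the
radical-selection flag.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from .codes import GeneticCode, get_code
from .codon_selection import AncestralCodons, _code_struct
from .phylo_io import DatedTree

__all__ = [
    "Z_CRITICAL", "N_CATEGORIES", "load_property_table", "build_categories",
    "expected_category_probs", "category_z", "CategoryProfile",
    "radical_change_scan", "PropertyScan",
]

#: one-sided standard-normal critical value for p < 0.001
Z_CRITICAL = 3.09

N_CATEGORIES = 8

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"


def load_property_table(path=None) -> tuple[dict[str, dict[str, float]],
                                            dict[str, str]]:
    """The packaged 20-property amino-acid table.

    Returns ``(values, sources)`` where ``values[property][aa]`` is the
    numeric value and ``sources[property]`` names the published scale it
    was taken from.
    """
    if path is None:
        text = (importlib.resources.files("collemsel") / "data"
                / "aa_properties.tsv").read_text()
    else:
        text = open(path).read()
    lines = [ln for ln in text.splitlines()
             if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    aas = header[2:]
    values: dict[str, dict[str, float]] = {}
    sources: dict[str, str] = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        name = parts[0]
        sources[name] = parts[1]
        values[name] = {aa: float(v) for aa, v in zip(aas, parts[2:])}
        if set(values[name]) != set(AA_ORDER):
            raise ValueError(f"property {name!r} missing amino acids")
    return values, sources


def _enumerate_changes(code: GeneticCode):
    """Ordered single-nucleotide nonsynonymous sense-codon changes, as
    (source codon index, aa_from, aa_to) triples."""
    _, n, pi_i, pi_j, ts, nonsyn = _code_struct(code.code_id)
    sense = code.sense_codons
    out = []
    for i, j in zip(pi_i[nonsyn], pi_j[nonsyn]):
        out.append((int(i), code.forward[sense[i]], code.forward[sense[j]]))
    return out


def build_categories(prop_values: dict[str, float],
                     code: GeneticCode | None = None) -> np.ndarray:
    """Equal-width category bin edges for one property.

    The range [0, max |delta|] over all enumerable one-step nonsynonymous
    changes is divided into eight bins; returns the 9 bin edges.  A
    property that is constant across amino acids has zero range and is
    rejected.
    """
    code = code or get_code(5)
    deltas = [abs(prop_values[a1] - prop_values[a2])
              for _, a1, a2 in _enumerate_changes(code)]
    top = max(deltas)
    if top <= 0:
        raise ValueError("property has zero range over enumerable changes")
    return np.linspace(0.0, top, N_CATEGORIES + 1)


def categorize(delta: float, edges: np.ndarray) -> int:
    """Category (1..8) of one |delta property| under the given bin edges."""
    d = abs(delta)
    if d >= edges[-1]:
        return N_CATEGORIES
    return int(np.searchsorted(edges, d, side="right"))


def expected_category_probs(prop_values: dict[str, float],
                            code: GeneticCode | None = None,
                            codon_freqs: np.ndarray | None = None
                            ) -> np.ndarray:
    """Neutral category distribution for one property.

    By default every enumerable one-step nonsynonymous change counts
    equally.  With ``codon_freqs`` (length = number of sense codons) each
    change is weighted by its source-codon frequency divided by the source
    codon's number of non-stop single-nucleotide neighbours.
    """
    code = code or get_code(5)
    edges = build_categories(prop_values, code)
    changes = _enumerate_changes(code)
    if codon_freqs is not None:
        codon_freqs = np.asarray(codon_freqs, dtype=float)
        n_neigh = np.array([len(code.neighbors(c))
                            for c in code.sense_codons], dtype=float)
    p = np.zeros(N_CATEGORIES)
    for i, a1, a2 in changes:
        w = 1.0 if codon_freqs is None else codon_freqs[i] / n_neigh[i]
        c = categorize(prop_values[a1] - prop_values[a2], edges)
        p[c - 1] += w
    return p / p.sum()


def category_z(observed: np.ndarray, expected_probs: np.ndarray
               ) -> tuple[np.ndarray, bool]:
    """Per-category binomial z-scores.

    ``z_c = (O_c - N p_c) / sqrt(N p_c (1 - p_c))`` with N the total count.
    Returns ``(z, defined)``; when N = 0 all z are reported as 0 with
    ``defined=False``.  Categories with p_c of 0 or 1 get z = 0 (no
    sampling variance under the expectation).
    """
    O = np.asarray(observed, dtype=float)
    p = np.asarray(expected_probs, dtype=float)
    N = O.sum()
    if N <= 0:
        return np.zeros_like(p), False
    var = N * p * (1.0 - p)
    z = np.zeros_like(p)
    ok = var > 0
    z[ok] = (O[ok] - N * p[ok]) / np.sqrt(var[ok])
    return z, True


@dataclass
class CategoryProfile:
    """Observed/expected category counts and z-scores for one scope."""

    property: str
    expected_probs: np.ndarray
    observed: np.ndarray
    z: np.ndarray
    N: float
    window: tuple[int, int] | None = None     # 0-based [start, end) codons
    defined: bool = True

    def significant(self, category: int, threshold: float = Z_CRITICAL
                    ) -> bool:
        return self.defined and self.z[category - 1] > threshold


@dataclass
class PropertyScan:
    """Whole-gene and per-window category profiles for one property."""

    property: str
    gene: CategoryProfile
    windows: list[CategoryProfile] = field(default_factory=list)
    radical_positive: bool = False
    radical_category: int | None = None    # 8 preferred when both 7 and 8 hit
    radical_z: float | None = None


def _branch_replacements(tree: DatedTree, ancestors: AncestralCodons,
                         code: GeneticCode) -> list[tuple[int, str, str, float]]:
    """(site, aa_from, aa_to, weight) over all branches of the tree."""
    out = []
    for nd in tree.branches():
        parent_seq = ancestors.sequences[nd.parent]
        child_seq = ancestors.sequences[nd]
        for i, (ca, cb) in enumerate(zip(parent_seq, child_seq)):
            if ca is None or cb is None or ca == cb:
                continue
            for aa1, aa2, w in code.pathway_replacements(ca, cb):
                out.append((i, aa1, aa2, w))
    return out


def radical_change_scan(tree: DatedTree, ancestors: AncestralCodons,
                        properties: dict[str, dict[str, float]] | None = None,
                        window: int = 15,
                        codon_freqs: np.ndarray | None = None,
                        code: GeneticCode | None = None
                        ) -> dict[str, PropertyScan]:
    """TreeSAAP-style scan of one gene for radical property changes.

    Observed amino-acid replacements are collected from all branches of the
    reconstructed gene history (multi-step codon differences contribute
    pathway-averaged fractional counts).  For each property the whole-gene
    and per-window category tallies are converted to z-scores; a gene is
    flagged as under radical positive selection for a property when
    category 7 or 8 of the whole-gene profile exceeds z = 3.09, reporting
    category 8's z when both are significant.

    A window longer than the gene degenerates to a single whole-gene
    window.
    """
    code = code or get_code(ancestors.params.code_id)
    if properties is None:
        properties, _ = load_property_table()
    n_codons = len(next(iter(ancestors.sequences.values())))
    repl = _branch_replacements(tree, ancestors, code)
    window = min(window, n_codons)
    out: dict[str, PropertyScan] = {}
    for name, vals in properties.items():
        edges = build_categories(vals, code)
        p = expected_category_probs(vals, code, codon_freqs)
        site_cat: list[tuple[int, int, float]] = []
        gene_obs = np.zeros(N_CATEGORIES)
        for site, aa1, aa2, w in repl:
            c = categorize(vals[aa1] - vals[aa2], edges)
            gene_obs[c - 1] += w
            site_cat.append((site, c, w))
        z, defined = category_z(gene_obs, p)
        gene_profile = CategoryProfile(name, p, gene_obs, z,
                                       float(gene_obs.sum()), None, defined)
        profiles = []
        for start in range(0, n_codons - window + 1):
            obs = np.zeros(N_CATEGORIES)
            for site, c, w in site_cat:
                if start <= site < start + window:
                    obs[c - 1] += w
            zw, dw = category_z(obs, p)
            profiles.append(CategoryProfile(name, p, obs, zw,
                                            float(obs.sum()),
                                            (start, start + window), dw))
        scan = PropertyScan(name, gene_profile, profiles)
        hit7 = gene_profile.significant(7)
        hit8 = gene_profile.significant(8)
        if hit7 or hit8:
            scan.radical_positive = True
            scan.radical_category = 8 if hit8 else 7
            scan.radical_z = float(gene_profile.z[scan.radical_category - 1])
        out[name] = scan
    return out
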
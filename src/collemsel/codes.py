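"""Genetic-code helpers.

Thin wrapper over Biopython's NCBI codon tables specialised for codon-level
evolutionary analyses: fast codon <-> index lookups, sense-codon enumeration,
single-nucleotide neighbourhoods, Nei--Gojobori site fractions and pathway
change counting.

The default code throughout the package is NCBI translation table 5
(invertebrate mitochondrial): TGA = Trp, AGA/AGG = Ser, ATA = Met, and only
TAA/TAG are stops, leaving 62 sense codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
STOP = "*"

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def is_transition(a: str, b: str) -> bool:
    """True when the single-nucleotide change a->b is a transition."""
    return (a, b) in _TRANSITIONS


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code bound to an NCBI translation-table id."""

    code_id: int
    forward: dict[str, str]          # codon -> one-letter amino acid
    stop_codons: frozenset[str]
    sense_codons: tuple[str, ...]    # sorted
    codon_index: dict[str, int] = field(repr=False, default_factory=dict)

    @classmethod
    def from_ncbi_id(cls, code_id: int = 5) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[code_id]
        forward = {c.upper(): aa for c, aa in table.forward_table.items()}
        stops = frozenset(s.upper() for s in table.stop_codons)
        sense = tuple(sorted(forward))
        obj = cls(code_id=code_id, forward=forward, stop_codons=stops,
                  sense_codons=sense)
        obj.codon_index.update({c: i for i, c in enumerate(sense)})
        return obj

    # -- basic queries ---------------------------------------------------
    def translate(self, codon: str) -> str:
        """Translate one codon; stops return ``"*"``.

        Raises ValueError on ambiguity codes or gaps -- callers are expected
        to mask those first.
        """
        codon = codon.upper()
        if codon in self.stop_codons:
            return STOP
        try:
            return self.forward[codon]
        except KeyError:
            raise ValueError(f"not an unambiguous codon: {codon!r}") from None

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stop_codons

    def is_sense(self, codon: str) -> bool:
        return codon.upper() in self.forward

    def neighbors(self, codon: str, include_stops: bool = False) -> list[str]:
        """All nine single-nucleotide mutants of ``codon``."""
        out = []
        for pos in range(3):
            for nt in NUCLEOTIDES:
                if nt == codon[pos]:
                    continue
                mutant = codon[:pos] + nt + codon[pos + 1:]
                if include_stops or mutant not in self.stop_codons:
                    out.append(mutant)
        return out

    # -- Nei--Gojobori primitives ---------------------------------------
    def ng_sites(self, codon: str) -> tuple[float, float]:
        """Synonymous and nonsynonymous site fractions of one sense codon.

        Each codon position contributes one site, split between synonymous
        and nonsynonymous in proportion to the fate of its single-nucleotide
        mutants; mutants that create a stop codon are excluded from the
        denominator, so s + n = 3 only when no neighbour is a stop.
        """
        codon = codon.upper()
        aa = self.translate(codon)
        if aa == STOP:
            raise ValueError(f"ng_sites of a stop codon: {codon}")
        s = 0.0
        n = 0.0
        for pos in range(3):
            syn = 0
            nonstop = 0
            for nt in NUCLEOTIDES:
                if nt == codon[pos]:
                    continue
                mutant = codon[:pos] + nt + codon[pos + 1:]
                if mutant in self.stop_codons:
                    continue
                nonstop += 1
                if self.forward[mutant] == aa:
                    syn += 1
            if nonstop:
                s += syn / nonstop
                n += (nonstop - syn) / nonstop
        return s, n

    def pathway_count(self, codon_a: str, codon_b: str) -> tuple[float, float]:
        """Nonsynonymous/synonymous step counts between two sense codons.

        Averages over all minimal mutational pathways (orderings of the
        differing positions) that avoid stop codons.  If every ordering
        passes through a stop the per-position fallback classifies each
        differing position independently against ``codon_a``.
        Returns ``(nd, sd)`` with nd + sd equal to the number of differing
        positions.
        """
        a = codon_a.upper()
        b = codon_b.upper()
        if not (self.is_sense(a) and self.is_sense(b)):
            raise ValueError(f"pathway_count requires sense codons: {a}, {b}")
        diff = [i for i in range(3) if a[i] != b[i]]
        if not diff:
            return 0.0, 0.0
        paths = []
        for order in permutations(diff):
            cur = a
            steps = []
            ok = True
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1:]
                if nxt in self.stop_codons:
                    ok = False
                    break
                steps.append(self.forward[cur] == self.forward[nxt])
                cur = nxt
            if ok:
                paths.append(steps)
        if not paths:
            # all pathways blocked; classify positions independently
            nd = sd = 0.0
            for pos in diff:
                mutant = a[:pos] + b[pos] + a[pos + 1:]
                if mutant in self.stop_codons or \
                        self.forward[mutant] != self.forward[a]:
                    nd += 1.0
                else:
                    sd += 1.0
            return nd, sd
        nd = sum(sum(0 if syn else 1 for syn in p) for p in paths) / len(paths)
        sd = sum(sum(1 if syn else 0 for syn in p) for p in paths) / len(paths)
        return nd, sd

    def pathway_replacements(self, codon_a: str,
                             codon_b: str) -> list[tuple[str, str, float]]:
        """Amino-acid replacements implied by a codon difference.

        Enumerates the same stop-free minimal pathways as
        :meth:`pathway_count`; every nonsynonymous step contributes one
        ``(aa_from, aa_to, weight)`` entry with weight 1/#pathways, so the
        weights sum to the nonsynonymous step count.  Falls back to
        independent per-position classification when all pathways are
        blocked by stops.
        """
        a = codon_a.upper()
        b = codon_b.upper()
        if not (self.is_sense(a) and self.is_sense(b)):
            raise ValueError("pathway_replacements requires sense codons")
        diff = [i for i in range(3) if a[i] != b[i]]
        if not diff:
            return []
        paths = []
        for order in permutations(diff):
            cur = a
            repl = []
            ok = True
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1:]
                if nxt in self.stop_codons:
                    ok = False
                    break
                aa1, aa2 = self.forward[cur], self.forward[nxt]
                if aa1 != aa2:
                    repl.append((aa1, aa2))
                cur = nxt
            if ok:
                paths.append(repl)
        if not paths:
            out = []
            for pos in diff:
                mutant = a[:pos] + b[pos] + a[pos + 1:]
                if mutant in self.stop_codons:
                    continue
                aa1, aa2 = self.forward[a], self.forward[mutant]
                if aa1 != aa2:
                    out.append((aa1, aa2, 1.0))
            return out
        w = 1.0 / len(paths)
        out = []
        for repl in paths:
            for aa1, aa2 in repl:
                out.append((aa1, aa2, w))
        return out


@lru_cache(maxsize=8)
def get_code(code_id: int = 5) -> GeneticCode:
    """Cached accessor for a :class:`GeneticCode`."""
    return GeneticCode.from_ncbi_id(code_id)
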
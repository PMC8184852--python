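"""Codon-level utilities shared by the sequence simulator and Ka/Ks.

Built on the standard genetic code.  For every codon we pre-compute, per
position, which single-nucleotide changes are synonymous, nonsynonymous or
create a stop; degeneracy classes follow the 0-/2-/4-fold convention used by
counting Ka/Ks methods (3-fold degenerate positions are binned as 2-fold).
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations, product

from Bio.Data.CodonTable import standard_dna_table

NUCS = "ACGT"
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)
SENSE_CODONS = sorted(CODON_TO_AA)


def is_transition(a: str, b: str) -> bool:
    return (a, b) in TRANSITIONS


@lru_cache(maxsize=None)
def neighbors(codon: str, pos: int):
    """Single-nucleotide variants of ``codon`` at ``pos``.

    Returns list of (new_codon, kind) with kind in {"syn", "nonsyn", "stop"}.
    """
    out = []
    for nt in NUCS:
        if nt == codon[pos]:
            continue
        new = codon[:pos] + nt + codon[pos + 1 :]
        if new in STOP_CODONS:
            kind = "stop"
        elif CODON_TO_AA[new] == CODON_TO_AA[codon]:
            kind = "syn"
        else:
            kind = "nonsyn"
        out.append((new, kind))
    return out


@lru_cache(maxsize=None)
def syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the three possible changes at ``pos`` that are synonymous."""
    kinds = [k for _, k in neighbors(codon, pos)]
    return sum(k == "syn" for k in kinds) / 3.0


@lru_cache(maxsize=None)
def degeneracy(codon: str, pos: int) -> int:
    """Degeneracy class of a codon position: 0-, 2- or 4-fold.

    Positions where one or two of the three changes are synonymous count as
    2-fold (the usual treatment of 3-fold sites); all-synonymous is 4-fold.
    """
    n_syn = sum(k == "syn" for _, k in neighbors(codon, pos))
    if n_syn == 0:
        return 0
    if n_syn == 3:
        return 4
    return 2


def pathway_events(c1: str, c2: str):
    """Average single-step substitution events over all pathways c1 -> c2.

    Each event is (degeneracy_class, is_transition, is_synonymous) weighted by
    the inverse number of admissible pathways.  Pathways passing through a
    stop codon are excluded when at least one stop-free pathway exists.
    The degeneracy class of each step is that of the source codon at the
    changed position.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return []
    paths = []
    for order in permutations(diff):
        cur = c1
        steps = []
        has_stop = False
        for pos in order:
            new = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if new in STOP_CODONS:
                has_stop = True
            if cur in STOP_CODONS:
                # source is a stop: classify change as nonsynonymous, 0-fold
                steps.append((0, is_transition(cur[pos], c2[pos]), False))
            else:
                syn = (
                    new not in STOP_CODONS
                    and CODON_TO_AA.get(new) == CODON_TO_AA.get(cur)
                )
                steps.append((degeneracy(cur, pos), is_transition(cur[pos], c2[pos]), syn))
            cur = new
        paths.append((has_stop, steps))
    clean = [s for stop, s in paths if not stop]
    use = clean if clean else [s for _, s in paths]
    w = 1.0 / len(use)
    events = []
    for steps in use:
        for deg, ts, syn in steps:
            events.append((deg, ts, syn, w))
    return events


def codon_site_counts(codon: str):
    """(L0, L2, L4) site counts for one codon."""
    counts = [0.0, 0.0, 0.0]
    for pos in range(3):
        deg = degeneracy(codon, pos)
        counts[{0: 0, 2: 1, 4: 2}[deg]] += 1.0
    return counts


def fractional_site_counts(codon: str):
    """(n_syn_sites, n_nonsyn_sites) fractional site counts (NG86 style)."""
    s = sum(syn_fraction(codon, pos) for pos in range(3))
    return s, 3.0 - s


ALL_CODONS = ["".join(p) for p in product(NUCS, repeat=3)]
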
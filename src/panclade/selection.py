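"""Pairwise dN/dS by the Nei-Gojobori (1986) counting method.

Synonymous site counts average, over each codon position, the fraction of
the three possible single-base changes that preserve the amino acid
(changes creating a stop codon count as nonsynonymous, so S + N equals the
nucleotide length).  Codons differing at several positions average their
synonymous/nonsynonymous difference counts over all minimal mutational
pathways, excluding pathways that pass through a stop codon.  Proportions
are Jukes-Cantor corrected, d = -(3/4) ln(1 - 4p/3), and omega = dN/dS;
omega < 1 indicates purifying (negative) selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import log

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[11]
_AA = dict(_TABLE.forward_table)
_STOPS = set(_TABLE.stop_codons)


@dataclass
class DnDsResult:
    s_sites: float  # S
    n_sites: float  # N
    s_diffs: float  # Sd
    n_diffs: float  # Nd
    ps: float
    pn: float
    ds: float | None  # None when the JC correction is undefined (p >= 3/4)
    dn: float | None
    omega: float | None  # None when dS == 0 or either distance is undefined
    classification: str  # purifying | neutral | positive | undefined

    @property
    def codon_count(self) -> int:
        return round((self.s_sites + self.n_sites) / 3)


def _check_cds(name: str, cds: str) -> None:
    if not cds or len(cds) % 3:
        raise ValueError(f"{name}: length must be a positive multiple of 3")
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if any(b not in "ACGT" for b in codon):
            raise ValueError(f"{name}: non-ACGT codon {codon!r} at position {i}")
        if codon in _STOPS and i < len(cds) - 3:
            raise ValueError(f"{name}: internal stop codon {codon} at position {i}")


def synonymous_fraction(codon: str) -> float:
    """S sites of one codon: per position, synonymous single-base changes / 3."""
    aa = _AA[codon]
    syn = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in _STOPS and _AA[mutant] == aa:
                syn += 1
    return syn / 3.0


def pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, averaged over minimal mutational pathways.

    Pathways passing through a stop codon are excluded; if every pathway
    does, all pathways are used (degenerate case).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in permutations(diff_pos):
        current = c1
        steps = []
        through_stop = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in _STOPS and nxt != c2:
                through_stop = True
            aa_cur = _AA.get(current)
            aa_nxt = _AA.get(nxt)
            steps.append(aa_cur is not None and aa_nxt is not None and aa_cur == aa_nxt)
            current = nxt
        pathways.append((through_stop, steps))
    admissible = [steps for stop, steps in pathways if not stop]
    if not admissible:
        admissible = [steps for _, steps in pathways]
    sd = sum(sum(1 for s in steps if s) for steps in admissible) / len(admissible)
    nd = sum(sum(1 for s in steps if not s) for steps in admissible) / len(admissible)
    return sd, nd


def _jc(p: float) -> float | None:
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def ng86_pairwise(cds1: str, cds2: str) -> DnDsResult:
    """NG86 dN/dS for one pair of equal-length, in-frame, gap-free CDS."""
    _check_cds("cds1", cds1)
    _check_cds("cds2", cds2)
    if len(cds1) != len(cds2):
        raise ValueError("sequences must have equal length")
    if cds1[-3:] in _STOPS or cds2[-3:] in _STOPS:
        if not (cds1[-3:] in _STOPS and cds2[-3:] in _STOPS):
            raise ValueError("terminal stop codon present in only one sequence")
        cds1, cds2 = cds1[:-3], cds2[:-3]  # stop codons carry no NG86 sites
        if not cds1:
            raise ValueError("sequences contain only a stop codon")
    s1 = s2 = sd = nd = 0.0
    n_codons = len(cds1) // 3
    for i in range(n_codons):
        c1 = cds1[3 * i : 3 * i + 3]
        c2 = cds2[3 * i : 3 * i + 3]
        s1 += synonymous_fraction(c1)
        s2 += synonymous_fraction(c2)
        dsd, dnd = pathway_differences(c1, c2)
        sd += dsd
        nd += dnd
    s_sites = (s1 + s2) / 2.0
    n_sites = 3.0 * n_codons - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds = _jc(ps)
    dn = _jc(pn)
    if ds is None or dn is None or ds == 0.0:
        omega = None
        classification = "undefined"
    else:
        omega = dn / ds
        if omega < 1.0:
            classification = "purifying"
        elif omega > 1.0:
            classification = "positive"
        else:
            classification = "neutral"
    return DnDsResult(
        s_sites=s_sites, n_sites=n_sites, s_diffs=sd, n_diffs=nd,
        ps=ps, pn=pn, ds=ds, dn=dn, omega=omega, classification=classification,
    )
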
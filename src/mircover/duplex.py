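"""Seed-site detection, duplex alignment and hybridization free energy.

A miRNA recognises a 3'UTR through Watson–Crick pairing of its seed
(nucleotides 2–8 from the 5' end) to a site on the UTR, optionally helped by
supplementary pairing of the miRNA 3' region.  Four canonical site classes
are detected, from strongest to weakest:

* ``8mer``     — seed match at positions 2–8 plus an A opposite position 1;
* ``7mer-m8``  — seed match at positions 2–8;
* ``7mer-A1``  — seed match at positions 2–7 plus an A opposite position 1;
* ``6mer``     — seed match at positions 2–7 only.

On the UTR (5'→3') the site runs antiparallel to the seed, so the base
pairing position 8 sits at the 5' edge of the site and the position-1 A at
its 3' edge.  One site is reported per seed-core occurrence, labelled with
the most specific class it supports.  G:U wobble is not accepted inside the
seed; it is accepted (scored +1) in the 3'-supplementary alignment.

The supplementary region is aligned by an affine-gap global alignment of
the miRNA (displayed 3'→5') against the UTR window (5'→3') under
complementarity scores +5 (Watson–Crick), +1 (G:U), −3 (mismatch), with gap
penalties −8 to open and −2 to extend, and deterministic traceback.  The
hybridization free energy of the resulting duplex is an additive
nearest-neighbor sum over stacked pairs plus initiation and linear loop
penalties, using the parameter table shipped with the package
(``data/rna_stack_params.tsv``).  The scale is a reproducible surrogate:
relative ordering of sites is meaningful, exact agreement with any
particular folding program is not a goal.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Dict, List, Tuple

from .model import SequenceSet, normalize_rna, reverse_complement

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_SITE_LENGTH = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

MATCH_WC = 5.0
MATCH_WOBBLE = 1.0
MISMATCH = -3.0
GAP_OPEN = -8.0
GAP_EXTEND = -2.0

GAP = "-"


@dataclass(frozen=True)
class SeedSite:
    """One seed-anchored site on a UTR; 0-based half-open coordinates."""

    utr_id: str
    start: int
    end: int
    site_type: str

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.end - self.start != _SITE_LENGTH[self.site_type]:
            raise ValueError(
                f"{self.site_type} site must span {_SITE_LENGTH[self.site_type]} nt, "
                f"got [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class DuplexAlignment:
    """Three-row duplex alignment: miRNA 3'→5', pairing bars, UTR 5'→3'."""

    mirna_line: str
    bars: str
    utr_line: str
    score: float

    def __post_init__(self) -> None:
        if not (len(self.mirna_line) == len(self.bars) == len(self.utr_line)):
            raise ValueError("alignment rows must have equal length")
        for m, b, u in zip(self.mirna_line, self.bars, self.utr_line):
            if b == "|" and (m, u) not in _WC | _WOBBLE:
                raise ValueError(f"pairing bar over non-pairing column {m}/{u}")

    @property
    def n_paired(self) -> int:
        return self.bars.count("|")


@dataclass(frozen=True)
class DuplexHit:
    """A scored miRNA–UTR interaction at one seed site."""

    mirna_id: str
    utr_id: str
    site: SeedSite
    alignment: DuplexAlignment
    delta_g: float
    non_binding: bool = False


def find_seed_sites(mirna: str, utr: str, utr_id: str = "") -> List[SeedSite]:
    """Scan a UTR for canonical seed-match sites of a miRNA.

    Returns one site per occurrence of the seed core (reverse complement of
    miRNA positions 2–7), classified as the most specific of 8mer,
    7mer-m8, 7mer-A1 or 6mer, in left-to-right order.  Overlapping core
    occurrences are all reported.  Seed pairing is strict Watson–Crick.
    """
    mir = normalize_rna(mirna)
    seq = normalize_rna(utr)
    if len(mir) < 8:
        raise ValueError(f"miRNA must be at least 8 nt, got {len(mir)}")

    core = reverse_complement(mir[1:7])  # pairs miRNA positions 2-7
    m8 = reverse_complement(mir[7])  # pairs miRNA position 8, 5' of the core
    sites: List[SeedSite] = []
    j = seq.find(core)
    while j != -1:
        has_m8 = j > 0 and seq[j - 1] == m8
        has_a1 = j + 6 < len(seq) and seq[j + 6] == "A"
        if has_m8 and has_a1:
            sites.append(SeedSite(utr_id, j - 1, j + 7, "8mer"))
        elif has_m8:
            sites.append(SeedSite(utr_id, j - 1, j + 6, "7mer-m8"))
        elif has_a1:
            sites.append(SeedSite(utr_id, j, j + 7, "7mer-A1"))
        else:
            sites.append(SeedSite(utr_id, j, j + 6, "6mer"))
        j = seq.find(core, j + 1)
    return sites


def _pair_score(a: str, b: str) -> float:
    if (a, b) in _WC:
        return MATCH_WC
    if (a, b) in _WOBBLE:
        return MATCH_WOBBLE
    return MISMATCH


def align_duplex(mirna: str, utr_window: str) -> DuplexAlignment:
    """Global complementarity alignment of a miRNA against a UTR window.

    The miRNA is reversed (3'→5') so that both rows read left to right in
    duplex orientation; gaps are affine; ties in the dynamic program are
    broken deterministically (pair column, then gap in the miRNA row, then
    gap in the UTR row).
    """
    mir = normalize_rna(mirna)
    win = normalize_rna(utr_window)  # raises on empty
    a = mir[::-1]  # miRNA 3'->5'
    b = win  # UTR 5'->3'
    m, n = len(a), len(b)
    NEG = float("-inf")

    # Gotoh: M ends in a pair/mismatch column, GB in a miRNA-row gap
    # (consumes UTR), GA in a UTR-row gap (consumes miRNA).
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    GB = [[NEG] * (n + 1) for _ in range(m + 1)]
    GA = [[NEG] * (n + 1) for _ in range(m + 1)]
    M[0][0] = 0.0

    # traceback pointers: state entered from, per cell
    ptr_M = [[None] * (n + 1) for _ in range(m + 1)]
    ptr_GB = [[None] * (n + 1) for _ in range(m + 1)]
    ptr_GA = [[None] * (n + 1) for _ in range(m + 1)]

    def best(options):
        # options: list of (score, tag); first maximal wins (tie preference)
        top = max(s for s, _ in options)
        for s, tag in options:
            if s == top:
                return s, tag
        raise AssertionError

    # Tie preference everywhere: pair column (M), then miRNA-row gap (GB),
    # then UTR-row gap (GA).  Unreachable states stay -inf, so boundary
    # cells need no special cases.
    for i in range(m + 1):
        for j in range(n + 1):
            if i > 0 and j > 0:
                s, tag = best(
                    [(M[i - 1][j - 1], "M"), (GB[i - 1][j - 1], "GB"), (GA[i - 1][j - 1], "GA")]
                )
                M[i][j] = s + _pair_score(a[i - 1], b[j - 1])
                ptr_M[i][j] = tag
            if j > 0:
                s, tag = best(
                    [
                        (M[i][j - 1] + GAP_OPEN, "M"),
                        (GB[i][j - 1] + GAP_EXTEND, "GB"),
                        (GA[i][j - 1] + GAP_OPEN, "GA"),
                    ]
                )
                GB[i][j] = s
                ptr_GB[i][j] = tag
            if i > 0:
                s, tag = best(
                    [
                        (M[i - 1][j] + GAP_OPEN, "M"),
                        (GB[i - 1][j] + GAP_OPEN, "GB"),
                        (GA[i - 1][j] + GAP_EXTEND, "GA"),
                    ]
                )
                GA[i][j] = s
                ptr_GA[i][j] = tag

    score, state = best([(M[m][n], "M"), (GB[m][n], "GB"), (GA[m][n], "GA")])

    mir_row: List[str] = []
    bar_row: List[str] = []
    utr_row: List[str] = []
    i, j = m, n
    while i > 0 or j > 0:
        if state == "M":
            prev = ptr_M[i][j]
            x, y = a[i - 1], b[j - 1]
            mir_row.append(x)
            utr_row.append(y)
            bar_row.append("|" if (x, y) in _WC | _WOBBLE else " ")
            i, j = i - 1, j - 1
        elif state == "GB":
            prev = ptr_GB[i][j]
            mir_row.append(GAP)
            utr_row.append(b[j - 1])
            bar_row.append(" ")
            j -= 1
        else:  # GA
            prev = ptr_GA[i][j]
            mir_row.append(a[i - 1])
            utr_row.append(GAP)
            bar_row.append(" ")
            i -= 1
        state = prev

    return DuplexAlignment(
        mirna_line="".join(reversed(mir_row)),
        bars="".join(reversed(bar_row)),
        utr_line="".join(reversed(utr_row)),
        score=score,
    )


@lru_cache(maxsize=1)
def load_energy_params() -> Dict[str, float]:
    """Load the packaged nearest-neighbor parameter table (kcal/mol, 37 C)."""
    path = Path(__file__).parent / "data" / "rna_stack_params.tsv"
    params: Dict[str, float] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("key\t"):
            continue
        key, value = line.split("\t")
        params[key] = float(value)
    return params


def duplex_free_energy(alignment: DuplexAlignment) -> float:
    """Additive nearest-neighbor ΔG (kcal/mol) of an aligned duplex.

    Stacked pairs (consecutive paired columns) contribute the packaged
    stacking term keyed by the UTR-strand dinucleotide; stacks involving a
    G:U wobble get a flat term.  Each internal run of unpaired columns
    costs ``loop_open + loop_per_nt × (unpaired nucleotides)``; dangling
    ends are free.  An alignment with no paired column returns the bare
    initiation penalty (a non-binding flag for callers).
    """
    p = load_energy_params()
    paired = [k for k, bar in enumerate(alignment.bars) if bar == "|"]
    dg = p["initiation"]
    if not paired:
        return dg
    for c, d in zip(paired, paired[1:]):
        if d == c + 1:  # stacked
            pair1 = (alignment.mirna_line[c], alignment.utr_line[c])
            pair2 = (alignment.mirna_line[d], alignment.utr_line[d])
            if pair1 in _WC and pair2 in _WC:
                dg += p[alignment.utr_line[c] + alignment.utr_line[d]]
            else:
                dg += p["wobble_stack"]
        else:  # internal loop / bulge between two helices
            n_unpaired = sum(
                (alignment.mirna_line[k] != GAP) + (alignment.utr_line[k] != GAP)
                for k in range(c + 1, d)
            )
            dg += p["loop_open"] + p["loop_per_nt"] * n_unpaired
    return dg


def _window_for_site(utr_seq: str, site: SeedSite, mirna_len: int) -> Tuple[int, str]:
    """UTR window covering the site plus room 5'-ward for the miRNA 3' region."""
    ext = max(0, mirna_len - (site.end - site.start))
    wstart = max(0, site.start - ext)
    return wstart, utr_seq[wstart : site.end]


def report_sites(mirnas: SequenceSet, utrs: SequenceSet, top_n: int = 3) -> List[DuplexHit]:
    """Align and score every seed site of every (miRNA, UTR) pair.

    For each pair the ``top_n`` most favorable (lowest ΔG) hits are kept;
    the combined table is sorted by ΔG ascending with (utr_id, start,
    mirna_id) tie-breaks.
    """
    if top_n < 0:
        raise ValueError("top_n must be >= 0")
    hits: List[DuplexHit] = []
    for mir_id in sorted(mirnas):
        mir_seq = mirnas[mir_id]
        for utr_id in sorted(utrs):
            utr_seq = utrs[utr_id]
            pair_hits: List[DuplexHit] = []
            for site in find_seed_sites(mir_seq, utr_seq, utr_id=utr_id):
                _, window = _window_for_site(utr_seq, site, len(mir_seq))
                aln = align_duplex(mir_seq, window)
                dg = duplex_free_energy(aln)
                pair_hits.append(
                    DuplexHit(
                        mirna_id=mir_id,
                        utr_id=utr_id,
                        site=site,
                        alignment=aln,
                        delta_g=dg,
                        non_binding=aln.n_paired == 0,
                    )
                )
            pair_hits.sort(key=lambda h: (h.delta_g, h.utr_id, h.site.start))
            hits.extend(pair_hits[:top_n])
    hits.sort(key=lambda h: (h.delta_g, h.utr_id, h.site.start, h.mirna_id))
    return hits
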
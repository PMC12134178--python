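"""BH3-like motif discovery in protein sequences.

BH3 motifs of the Bcl-2 family are short amphipathic helices carrying four
conserved hydrophobic residues (h1-h4, canonically spaced 0/4/7/11 along
the helix) and a conserved aspartate two positions after h3 (the "h3+2"
slot).  This module finds candidate motifs two ways:

* global pairwise alignment (Needleman-Wunsch, affine gaps, BLOSUM62, free
  end gaps — the EMBOSS-Needle-style configuration) of a known BH3 query
  against a target protein, reporting the target coordinates of the
  aligned core and its percent identity;
* consensus scanning: sliding a window over the target and requiring each
  h-slot to hold a nonpolar residue (h2 additionally tolerates Thr, whose
  branched side chain still packs nonpolar contacts) and the h3+2 slot to
  hold Asp or a tolerable substitute (Glu/Asn/Gln).  h1 may be relaxed,
  since genuine BH3-like motifs exist that conserve only h2-h4.

Candidate windows are scored for amphipathic character by the hydrophobic
moment muH at the ideal helical angle of 100 degrees per residue
(Eisenberg consensus hydropathy scale by default).

Coordinates are 1-based inclusive throughout, matching UniProt numbering.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "BH3Query",
    "ConsensusPattern",
    "MotifHit",
    "AlignmentResult",
    "BAX_BH3",
    "EISENBERG_SCALE",
    "NONPOLAR_RESIDUES",
    "needle_align",
    "percent_identity",
    "consensus_scan",
    "hydrophobic_moment",
    "scan_report",
    "read_fasta",
]

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")

#: Eisenberg consensus hydropathy scale (dimensionless)
EISENBERG_SCALE: dict[str, float] = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

NONPOLAR_RESIDUES = frozenset("AVLIMFWC")


@dataclass(frozen=True)
class BH3Query:
    """A reference BH3 sequence with the 0-based offsets of its h1-h4 and
    h3+2 residues."""

    name: str
    sequence: str
    h_offsets: tuple[int, int, int, int]
    d_offset: int

    def __post_init__(self) -> None:
        if list(self.h_offsets) != sorted(set(self.h_offsets)):
            raise ValueError("h offsets must be strictly increasing")
        if max(*self.h_offsets, self.d_offset) >= len(self.sequence):
            raise ValueError("offsets extend beyond the query sequence")
        if self.d_offset != self.h_offsets[2] + 2:
            raise ValueError("the conserved-acidic slot must sit at h3 + 2")


#: Human Bax BH3 segment (UniProt Q07813 residues 57-72) with
#: h1 = L59, h2 = L63, h3 = I66, h4 = L70 and the conserved D68 at h3+2.
BAX_BH3 = BH3Query(
    name="Bax-BH3",
    sequence="KKLSECLKRIGDELDS",
    h_offsets=(2, 6, 9, 13),
    d_offset=11,
)


@dataclass(frozen=True)
class ConsensusPattern:
    """Sliding-window BH3 consensus.

    Offsets are 0-based within the window; defaults place h1/h2/h3/h4 at
    0/4/7/11 and the conserved acidic slot at 9 (= h3 + 2).
    """

    h_offsets: tuple[int, int, int, int] = (0, 4, 7, 11)
    d_offset: int = 9
    nonpolar: frozenset = NONPOLAR_RESIDUES
    h2_extra: frozenset = frozenset("T")
    d_allowed: frozenset = frozenset("DENQ")
    require_h1: bool = True

    def __post_init__(self) -> None:
        if self.d_offset != self.h_offsets[2] + 2:
            raise ValueError("d_offset must equal h3 offset + 2")

    @property
    def window_length(self) -> int:
        return max(*self.h_offsets, self.d_offset) + 1

    def allowed(self, slot: str) -> frozenset:
        if slot == "h2":
            return self.nonpolar | self.h2_extra
        if slot == "d":
            return self.d_allowed
        return self.nonpolar

    def matches(self, window: str) -> bool:
        window = window.upper()
        slots = [("h2", self.h_offsets[1]), ("h3", self.h_offsets[2]),
                 ("h4", self.h_offsets[3]), ("d", self.d_offset)]
        if self.require_h1:
            slots.insert(0, ("h1", self.h_offsets[0]))
        return all(window[off] in self.allowed(name) for name, off in slots)


@dataclass
class MotifHit:
    """One candidate BH3-like window on a target protein (1-based
    inclusive coordinates)."""

    start: int
    end: int
    h_residues: dict
    source: str  # "alignment" | "consensus"
    percent_identity: float = float("nan")
    hydrophobic_moment: float = float("nan")
    query_name: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("invalid hit coordinates")


@dataclass
class AlignmentResult:
    """Pairwise global alignment of a BH3 query against a target."""

    aligned_query: str
    aligned_target: str
    score: float
    target_start: int  # 1-based first target residue aligned to the query core
    target_end: int  # 1-based last target residue aligned to the query core
    query_name: str = ""


def _validate_sequence(seq: str, name: str) -> str:
    seq = seq.upper()
    bad = [i + 1 for i, aa in enumerate(seq) if aa not in VALID_RESIDUES]
    if bad:
        raise ValueError(f"{name} contains invalid residues at positions {bad[:10]}")
    if not seq:
        raise ValueError(f"{name} is empty")
    return seq


def _build_matrix(name: str = "BLOSUM62"):
    mat = substitution_matrices.load(name)
    # unknown residue X is tolerated but uninformative
    if "X" in mat.alphabet:
        for aa in mat.alphabet:
            mat["X", aa] = 0.0
            mat[aa, "X"] = 0.0
    return mat


def _make_aligner(gap_open, gap_extend, matrix, free_end_gaps):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _build_matrix(matrix) if isinstance(matrix, str) else matrix
    # gap of length L costs gap_open + (L-1)*gap_extend
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    if free_end_gaps:
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # Biopython < 1.86 naming
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


def needle_align(
    query: str,
    target: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    matrix: str = "BLOSUM62",
    free_end_gaps: bool = True,
) -> AlignmentResult:
    """Global Needleman-Wunsch alignment with affine gaps.

    End gaps are free by default, so a short query finds its best-matching
    segment of a long target while the alignment remains global.  A gap of
    length L costs ``gap_open + (L - 1) * gap_extend``.  Case-insensitive;
    X is accepted and scored 0 against everything.
    """
    query = _validate_sequence(query, "query")
    target = _validate_sequence(target, "target")
    aligner = _make_aligner(gap_open, gap_extend, matrix, free_end_gaps)
    aln = aligner.align(target, query)[0]  # first = deterministic preferred traceback
    aligned_target, aligned_query = str(aln[0]), str(aln[1])
    blocks = aln.aligned[0]  # target-coordinate blocks aligned to query residues
    if len(blocks) == 0:
        # optimum leaves the query entirely in (free) end gaps: no core
        t_start = t_end = 0
    else:
        t_start = int(blocks[0][0]) + 1
        t_end = int(blocks[-1][1])
    return AlignmentResult(
        aligned_query=aligned_query,
        aligned_target=aligned_target,
        score=float(aln.score),
        target_start=t_start,
        target_end=t_end,
    )


def percent_identity(result: AlignmentResult, denominator: str = "core") -> float:
    """Percent identical columns of a pairwise alignment.

    denominator='core' counts columns between the query's first and last
    aligned residues (the sensible choice when a short motif is aligned to
    a full-length protein); 'full' counts every column including end gaps.
    """
    q, t = result.aligned_query, result.aligned_target
    if not q or len(q) != len(t):
        raise ValueError("empty or inconsistent alignment")
    residue_cols = [i for i, aa in enumerate(q) if aa != "-"]
    if not residue_cols:
        raise ValueError("query contributes no residues to the alignment")
    if denominator == "core":
        lo, hi = residue_cols[0], residue_cols[-1] + 1
    elif denominator == "full":
        lo, hi = 0, len(q)
    else:
        raise ValueError("denominator must be 'core' or 'full'")
    n_cols = hi - lo
    n_ident = sum(1 for i in range(lo, hi) if q[i] == t[i] and q[i] != "-")
    return 100.0 * n_ident / n_cols


def consensus_scan(target: str, pattern: ConsensusPattern | None = None) -> list[MotifHit]:
    """All windows of ``target`` whose required slots match the BH3
    consensus, in ascending position order."""
    pattern = pattern or ConsensusPattern()
    target = _validate_sequence(target, "target")
    w = pattern.window_length
    hits = []
    for start in range(len(target) - w + 1):
        window = target[start : start + w]
        if pattern.matches(window):
            h = {
                "h1": window[pattern.h_offsets[0]],
                "h2": window[pattern.h_offsets[1]],
                "h3": window[pattern.h_offsets[2]],
                "h4": window[pattern.h_offsets[3]],
                "h3+2": window[pattern.d_offset],
            }
            hits.append(
                MotifHit(start=start + 1, end=start + w, h_residues=h, source="consensus")
            )
    return hits


def hydrophobic_moment(
    window: str,
    scale: dict[str, float] | None = None,
    delta_deg: float = 100.0,
) -> tuple[float, float]:
    """Hydrophobic moment of a residue window on an ideal helical wheel.

        muH = | sum_n H(aa_n) * exp(i * n * delta) |

    with delta = ``delta_deg`` in radians (100 degrees per residue for an
    ideal alpha helix).  Returns (muH, muH / len(window)).  High values
    mean hydrophobicity is segregated to one helix face (amphipathicity).
    """
    scale = scale or EISENBERG_SCALE
    window = window.upper()
    if len(window) < 2:
        raise ValueError("window must contain at least 2 residues")
    missing = sorted({aa for aa in window if aa not in scale})
    if missing:
        raise ValueError(f"residues missing from the hydropathy scale: {missing}")
    delta = math.radians(delta_deg)
    total = sum(scale[aa] * cmath.exp(1j * n * delta) for n, aa in enumerate(window))
    mu = abs(total)
    return mu, mu / len(window)


def _overlaps(a: MotifHit, b: MotifHit) -> bool:
    return a.start <= b.end and b.start <= a.end


def scan_report(
    target: str,
    queries: list[BH3Query] | None = None,
    pattern: ConsensusPattern | None = None,
    moment_threshold: float | None = None,
    scale: dict[str, float] | None = None,
) -> list[MotifHit]:
    """Combined alignment + consensus motif report for one target.

    Alignment hits (one per query: the aligned core of the query on the
    target, with core percent identity) are merged with consensus-scan
    hits; overlapping hits are deduplicated keeping the alignment-derived
    one.  Every hit is annotated with its hydrophobic moment, and the list
    is ranked by (percent identity, muH) descending; ``moment_threshold``
    drops weakly amphipathic windows.
    """
    queries = BAX_BH3 if queries is None else queries
    if isinstance(queries, BH3Query):
        queries = [queries]
    target = _validate_sequence(target, "target")
    hits: list[MotifHit] = []
    for q in queries:
        res = needle_align(q.sequence, target)
        pid = percent_identity(res, denominator="core")
        start, end = res.target_start, res.target_end
        h = {
            name: target[start - 1 + off] if start - 1 + off < end else ""
            for name, off in zip(
                ("h1", "h2", "h3", "h4", "h3+2"), (*q.h_offsets, q.d_offset)
            )
        }
        hits.append(
            MotifHit(
                start=start,
                end=end,
                h_residues=h,
                source="alignment",
                percent_identity=pid,
                query_name=q.name,
            )
        )
    for hit in consensus_scan(target, pattern):
        if not any(_overlaps(hit, kept) for kept in hits):
            hits.append(hit)
    for hit in hits:
        window = target[hit.start - 1 : hit.end]
        if len(window) >= 2 and all(aa in (scale or EISENBERG_SCALE) for aa in window):
            hit.hydrophobic_moment = hydrophobic_moment(window, scale)[0]
    if moment_threshold is not None:
        hits = [
            h for h in hits
            if not (h.hydrophobic_moment < moment_threshold)  # keep NaN
        ]
    def rank(h: MotifHit):
        pid = h.percent_identity if not math.isnan(h.percent_identity) else -1.0
        mu = h.hydrophobic_moment if not math.isnan(h.hydrophobic_moment) else -1.0
        return (-pid, -mu, h.start)
    return sorted(hits, key=rank)


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> {record id: sequence} (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
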
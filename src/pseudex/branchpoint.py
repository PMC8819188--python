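"""AG-exclusion zone and branch-point analysis.

Branch-point definition needs two things: a workable branch adenosine motif,
and a continuous AG-dinucleotide-free stretch (the AG-exclusion zone, AGEZ)
connecting it to the acceptor. Mutations can "close the circuit" between a
branch point and an acceptor in three ways -- improving an in-range branch
motif, enlarging the AGEZ, or moving a branch point closer to the acceptor --
and a fourth, weaker signal is the gain of a new pyrimidine in the tract.

The AGEZ is counted strictly between the bounding upstream AG and the acceptor
AG (neither dinucleotide included). Branch scores come from a pluggable model
over a 7-mer window with the branch A fixed at position 6 of 7; published SVM
branch scores are consumed as data, never recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import InstigatingMutation
from .sequences import check_dna
from .motifs import MotifModel

DEFAULT_SCAN_LIMIT = 500
DEFAULT_MAX_BRANCH_DISTANCE = 100


@dataclass(frozen=True)
class AgezReport:
    """AGEZ immediately 5' of one acceptor.

    ``length`` counts nucleotides strictly between the bounding upstream AG and
    the acceptor AG. ``upstream_ag_offset`` is the 1-based distance from the
    acceptor to the A of the bounding AG (``length + 2``), or None when no AG
    occurs within ``scan_limit`` (then ``length`` is the scanned span).
    """

    length: int
    upstream_ag_offset: int | None
    scan_limit: int

    @property
    def ag_found(self) -> bool:
        return self.upstream_ag_offset is not None


@dataclass(frozen=True)
class BranchPointCandidate:
    """One candidate branch adenosine. ``offset`` is 0-based into the scanned
    sequence; ``distance_to_acceptor`` is 1-based (the base immediately 5' of
    the acceptor has distance 1)."""

    offset: int
    distance_to_acceptor: int
    window_seq: str
    score: float


@dataclass(frozen=True)
class BranchPointDelta:
    """Before/after branch-point characteristics for one mutation."""

    agez_before: int
    agez_after: int
    bps_before: float | None
    bps_after: float | None
    moved_closer: bool
    pyrimidine_gain: bool

    @property
    def agez_increased(self) -> bool:
        return self.agez_after > self.agez_before

    @property
    def bps_increased(self) -> bool:
        if self.bps_before is None or self.bps_after is None:
            return False
        return self.bps_after > self.bps_before


def compute_agez(upstream_seq: str, scan_limit: int = DEFAULT_SCAN_LIMIT) -> AgezReport:
    """Measure the AGEZ from the sequence immediately 5' of an acceptor AG.

    ``upstream_seq`` runs 5'->3' with its last base abutting the acceptor AG
    (the acceptor dinucleotide itself excluded). Only the 3'-most
    ``scan_limit`` nucleotides are examined.
    """
    upstream_seq = check_dna(upstream_seq, what="AGEZ upstream sequence")
    scan = upstream_seq[-scan_limit:] if scan_limit else upstream_seq
    idx = scan.rfind("AG")
    if idx == -1:
        return AgezReport(len(scan), None, scan_limit)
    length = len(scan) - idx - 2
    return AgezReport(length, length + 2, scan_limit)


def scan_branchpoints(
    agez_seq: str,
    model: MotifModel,
    max_distance: int = DEFAULT_MAX_BRANCH_DISTANCE,
) -> list[BranchPointCandidate]:
    """Score every candidate branch A within ``max_distance`` of the acceptor.

    ``agez_seq`` ends immediately 5' of the acceptor AG (optionally padded
    further 5' so windows near the zone's 5' edge are complete). Windows are
    7-mers with the branch A at position 6; adenosines too close to the 5' end
    for a full window are skipped. Sorted by score (desc), then distance.
    """
    agez_seq = check_dna(agez_seq, what="AGEZ sequence")
    out = []
    n = len(agez_seq)
    for i, b in enumerate(agez_seq):
        if b != "A":
            continue
        distance = n - i
        if distance > max_distance:
            continue
        window = agez_seq[i - 5 : i + 2]
        if len(window) != 7:
            continue
        out.append(BranchPointCandidate(i, distance, window, model.score(window)))
    out.sort(key=lambda c: (-c.score, c.distance_to_acceptor))
    return out


def best_branchpoint(
    agez_seq: str, model: MotifModel, max_distance: int = DEFAULT_MAX_BRANCH_DISTANCE
) -> BranchPointCandidate | None:
    candidates = scan_branchpoints(agez_seq, model, max_distance)
    return candidates[0] if candidates else None


def branchpoint_delta(
    wt: tuple[AgezReport | int, float | None, int | None],
    mut: tuple[AgezReport | int, float | None, int | None],
    mutation: InstigatingMutation | None = None,
    *,
    mutations: list[InstigatingMutation] | None = None,
    strand: str = "+",
) -> BranchPointDelta:
    """Assemble the before/after branch-point comparison.

    ``wt`` and ``mut`` are (AGEZ report or plain length, best branch score,
    branch distance); the sides must come from the same model and scan
    parameters -- or directly from a published table. ``moved_closer`` fires
    when the best branch point ends up nearer the acceptor with its score
    unchanged or improved. ``pyrimidine_gain`` fires for any SNV whose
    alternate allele is a pyrimidine (C/T), a crude proxy for strengthening
    the polypyrimidine tract.
    """
    agez_b = wt[0].length if isinstance(wt[0], AgezReport) else int(wt[0])
    agez_a = mut[0].length if isinstance(mut[0], AgezReport) else int(mut[0])
    bps_b, dist_b = wt[1], wt[2]
    bps_a, dist_a = mut[1], mut[2]
    moved_closer = (
        dist_b is not None
        and dist_a is not None
        and dist_a < dist_b
        and (bps_b is None or bps_a is None or bps_a >= bps_b)
    )
    muts = list(mutations) if mutations is not None else []
    if mutation is not None:
        muts.append(mutation)
    # alleles are stored on the reference strand; the tract-side pyrimidine is
    # judged on the transcript strand
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    def tx_alt(m: InstigatingMutation) -> str:
        return m.alt_allele if strand == "+" else comp.get(m.alt_allele, "")
    pyr_gain = any(m.is_snv and tx_alt(m) in ("C", "T") for m in muts)
    return BranchPointDelta(agez_b, agez_a, bps_b, bps_a, moved_closer, pyr_gain)
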
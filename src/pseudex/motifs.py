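"""Splice-site motif scoring under a pluggable log-odds contract.

Scores are log2(model / background) in bits. The donor window is the 9-mer
spanning exonic -3..-1 plus intronic +1..+6; the acceptor window is the 23-mer
spanning intronic -20..-1 plus exonic +1..+3. Models are pluggable: a simple
additive position-weight model is packaged for self-contained analyses and
tests, and loaders for externally published maximum-entropy tables live in
:mod:`pseudex.maxent`. Published web-tool scores are never silently
approximated -- reproducing them requires supplying the published tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .model import InstigatingMutation
from .sequences import apply_mutation, check_dna

DONOR_POSITIONS: tuple[int, ...] = (-3, -2, -1, 1, 2, 3, 4, 5, 6)
ACCEPTOR_POSITIONS: tuple[int, ...] = tuple(range(-20, 0)) + (1, 2, 3)
BRANCH_POSITIONS: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)  # branch A at 6

DONOR_CONSENSUS = "CAGGTAAGT"
# Modal bases across canonical acceptor compilations: a pyrimidine tract, the
# yAG core, then the exonic G.
ACCEPTOR_CONSENSUS = "T" * 17 + "CAG" + "GTT"
BRANCH_CONSENSUS = "TACTAAC"


@dataclass
class MotifModel:
    """A total scoring function over fixed-width DNA windows."""

    name: str
    kind: str  # 'donor' | 'acceptor' | 'branch'
    positions: tuple[int, ...]
    scorer: Callable[[str], float]
    provenance: str = ""

    @property
    def width(self) -> int:
        return len(self.positions)

    def score(self, window: str) -> float:
        window = check_dna(window, what=f"{self.kind} window")
        if len(window) != self.width:
            raise ValueError(
                f"{self.kind} window must be {self.width} nt, got {len(window)}"
            )
        return self.scorer(window)


class AdditiveMotifModel(MotifModel):
    """Sum of independent per-position weights (a first-order PWM in bits)."""

    def __init__(self, name, kind, positions, weights, provenance=""):
        self.name = name
        self.kind = kind
        self.positions = tuple(positions)
        self.weights = dict(weights)
        self.provenance = provenance
        self.scorer = self._score

    def _score(self, window: str) -> float:
        return sum(
            self.weights.get((p, b), 0.0) for p, b in zip(self.positions, window)
        )


@dataclass(frozen=True)
class SiteScore:
    """A scored candidate splice site; ``position`` is the cleavage boundary
    (first intronic base for donors, first exonic base for acceptors) as a
    0-based offset into the scanned sequence."""

    position: int
    kind: str
    score: float
    window_seq: str


def zero_model(kind: str) -> MotifModel:
    """The calibration null: every window scores 0 bits."""
    positions = {
        "donor": DONOR_POSITIONS,
        "acceptor": ACCEPTOR_POSITIONS,
        "branch": BRANCH_POSITIONS,
    }[kind]
    return MotifModel(f"zero-{kind}", kind, positions, lambda w: 0.0, "null model")


def _consensus_model(kind: str, positions, consensus: str, name: str) -> AdditiveMotifModel:
    weights = {}
    for p, cons in zip(positions, consensus):
        for b in "ACGT":
            weights[(p, b)] = 1.0 if b == cons else -1.0
    return AdditiveMotifModel(name, kind, positions, weights, "packaged toy model")


def toy_donor_model() -> AdditiveMotifModel:
    """+1 bit per consensus base of CAG|GTAAGT, -1 otherwise."""
    return _consensus_model("donor", DONOR_POSITIONS, DONOR_CONSENSUS, "toy-donor")


def toy_acceptor_model() -> AdditiveMotifModel:
    return _consensus_model(
        "acceptor", ACCEPTOR_POSITIONS, ACCEPTOR_CONSENSUS, "toy-acceptor"
    )


def toy_branch_model() -> AdditiveMotifModel:
    return _consensus_model("branch", BRANCH_POSITIONS, BRANCH_CONSENSUS, "toy-branch")


def score_donor(seq9: str, model: MotifModel) -> float:
    """Score a 9-mer donor window (exonic -3..-1 | intronic +1..+6)."""
    return model.score(seq9)


def score_acceptor(seq23: str, model: MotifModel) -> float:
    """Score a 23-mer acceptor window (intronic -20..-1 | exonic +1..+3)."""
    return model.score(seq23)


@dataclass(frozen=True)
class DeltaScore:
    before: float
    after: float
    window_destroyed: bool = False

    @property
    def delta(self) -> float:
        return self.after - self.before


def delta_site_score(
    wt_window: str,
    mutation: InstigatingMutation,
    model: MotifModel,
    *,
    window_start: int,
    context_seq: str | None = None,
    context_start: int = 0,
) -> DeltaScore:
    """Score change a mutation causes on one motif window.

    ``window_start`` places the wild-type window on the genomic axis (reference
    strand; the window must be given in reference orientation). SNVs outside
    the window give delta 0. Indels are rescored on the reconstructed mutant
    window, which needs flanking sequence: pass ``context_seq`` (a reference
    slice containing the window plus slack, located at ``context_start``).
    Without enough context to rebuild a full-width mutant window the result is
    flagged ``window_destroyed``.
    """
    width = model.width
    window_end = window_start + width
    before = model.score(wt_window)
    if not mutation.overlaps(window_start, window_end):
        return DeltaScore(before, before)
    if mutation.kind == "SNV":
        i = mutation.genomic_start - window_start
        mut_window = wt_window[:i] + mutation.alt_allele + wt_window[i + 1 :]
        return DeltaScore(before, model.score(mut_window))
    if context_seq is None:
        context_seq, context_start = wt_window, window_start
    try:
        mutant = apply_mutation(context_seq, mutation, context_start)
    except ValueError:
        return DeltaScore(before, before, window_destroyed=True)
    from .sequences import shift_after

    new_start = shift_after(mutation, window_start) - context_start
    mut_window = mutant[new_start : new_start + width]
    if len(mut_window) != width:
        return DeltaScore(before, before, window_destroyed=True)
    return DeltaScore(before, model.score(mut_window))


def find_candidate_sites(
    seq: str,
    model: MotifModel,
    kind: str,
    threshold: float,
    *,
    require_dinuc: bool = True,
    allow_gc: bool = False,
) -> list[SiteScore]:
    """All windows scoring >= threshold, sorted by position.

    Donor windows must carry GT (or GC with ``allow_gc``) at +1..+2 and
    acceptor windows AG at -2..-1 unless ``require_dinuc`` is off.
    """
    seq = check_dna(seq)
    out: list[SiteScore] = []
    if kind == "donor":
        # boundary b: exon ends at b; window = seq[b-3 : b+6]
        for b in range(3, len(seq) - 5):
            dinuc = seq[b : b + 2]
            if require_dinuc and dinuc != "GT" and not (allow_gc and dinuc == "GC"):
                continue
            window = seq[b - 3 : b + 6]
            s = model.score(window)
            if s >= threshold:
                out.append(SiteScore(b, "donor", s, window))
    elif kind == "acceptor":
        # boundary b: exon starts at b; window = seq[b-20 : b+3]
        for b in range(20, len(seq) - 2):
            if require_dinuc and seq[b - 2 : b] != "AG":
                continue
            window = seq[b - 20 : b + 3]
            s = model.score(window)
            if s >= threshold:
                out.append(SiteScore(b, "acceptor", s, window))
    else:
        raise ValueError(f"kind must be 'donor' or 'acceptor', got {kind!r}")
    return out


U12_DONOR_IUPAC = "RTATCCT"  # +1..+7; the motif's initial base tolerates A or G
U12_BRANCH_IUPAC = "CCTTWAY"  # DNA reading of the minor-spliceosome branch motif


def spliceosome_type(
    donor_intronic: str,
    branch_region: str,
    *,
    donor_pattern: str = U12_DONOR_IUPAC,
    branch_pattern: str = U12_BRANCH_IUPAC,
) -> str:
    """Call U2 vs putative U12 processing for one intron.

    ``donor_intronic`` must start at intron position +1 (>= 7 nt); the branch
    region is the ~40 nt immediately 5' of the partner acceptor. A U12 call
    needs both the conserved U12 donor heptamer and a U12 branch motif --
    either alone is not sufficient.
    """
    from .hexamer import scan_motifs

    donor_intronic = check_dna(donor_intronic, what="donor region")
    if len(donor_intronic) < 7:
        raise ValueError("donor region must cover intron positions +1..+7")
    head = donor_intronic[:7]
    donor_hit = bool(scan_motifs(head, [donor_pattern]))
    branch_hit = bool(scan_motifs(branch_region, [branch_pattern]))
    return "putative_U12" if donor_hit and branch_hit else "U2"


def acceptor_dinuc_distance(dinuc: str) -> int:
    """Hamming distance of an acceptor terminal dinucleotide from AG.

    Non-canonical acceptors observed in PE catalogues almost always sit at
    distance <= 1 (the one-nucleotide rule).
    """
    dinuc = check_dna(dinuc, what="dinucleotide")
    if len(dinuc) != 2:
        raise ValueError("dinucleotide must be 2 nt")
    return sum(a != b for a, b in zip(dinuc, "AG"))


def load_additive_model(path: str, kind: str, name: str | None = None) -> AdditiveMotifModel:
    """Read an additive model table: lines of ``position_label<TAB>base<TAB>weight``."""
    positions = {
        "donor": DONOR_POSITIONS,
        "acceptor": ACCEPTOR_POSITIONS,
        "branch": BRANCH_POSITIONS,
    }[kind]
    weights: dict[tuple[int, str], float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            label, base, w = line.split("\t")
            weights[(int(label), base.upper())] = float(w)
    return AdditiveMotifModel(
        name or path, kind, positions, weights, provenance=f"file:{path}"
    )


def write_additive_model(model: AdditiveMotifModel, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# additive {model.kind} model: {model.name}\n")
        for (p, b), w in sorted(model.weights.items()):
            fh.write(f"{p}\t{b}\t{w}\n")
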
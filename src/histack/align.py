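"""Pairwise alignment of query histones into reference (HMfB) numbering.

Each query is aligned globally to the reference sequence once, and every
downstream score is a lookup through the resulting position map.  Pairwise
alignment to a fixed reference makes the numbering of a query independent of
panel composition, which is what reference-projected multiple alignments are
used for in practice.

Terminal query residues that precede the first matched reference column are
the N-extension (candidate N-tail); residues after the last matched column are
the C-extension.  Reference positions missing before the first / after the
last matched column are N-/C-truncations of the fold.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .reference import ReferenceHistone

__all__ = [
    "HistoneSequence",
    "AlignmentMap",
    "TerminiAnnotation",
    "AlignParams",
    "TerminiThresholds",
    "align_to_reference",
    "residue_at",
    "annotate_termini",
    "read_fasta",
    "GAP",
]

GAP = "-"

_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]+$")


class NotAHistoneError(ValueError):
    """Query rejected before alignment (too short / bad alphabet)."""


@dataclass(frozen=True)
class HistoneSequence:
    """A single protein query: id, optional accession, free-text taxon, residues."""

    id: str
    residues: str
    accession: str | None = None
    taxon_label: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise NotAHistoneError(f"{self.id}: empty sequence")
        if not _AA_RE.match(self.residues.upper()):
            bad = sorted(set(self.residues.upper()) - set("ACDEFGHIKLMNPQRSTVWYX"))
            raise NotAHistoneError(f"{self.id}: non-amino-acid characters {bad}")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignParams:
    """Global-alignment settings (substitution matrix and affine gap costs)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    min_query_length: int = 20


@dataclass(frozen=True)
class AlignmentMap:
    """Matched-column map between a query and the reference numbering.

    ``pairs`` holds (reference_position, query_position) for every matched
    column, strictly increasing in both coordinates; both are 1-based.
    """

    query_id: str
    ref_length: int
    query_length: int
    pairs: tuple[tuple[int, int], ...]
    n_extension: str
    c_extension: str
    alignment_score: float
    _by_ref: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        prev_r, prev_q = 0, 0
        for r, q in self.pairs:
            if r <= prev_r or q <= prev_q:
                raise ValueError(f"{self.query_id}: crossing or duplicate pair ({r},{q})")
            if not (1 <= r <= self.ref_length and 1 <= q <= self.query_length):
                raise ValueError(f"{self.query_id}: pair ({r},{q}) out of range")
            prev_r, prev_q = r, q
        object.__setattr__(self, "_by_ref", {r: q for r, q in self.pairs})

    def query_position(self, ref_position: int) -> int | None:
        return self._by_ref.get(ref_position)


@dataclass(frozen=True)
class TerminiThresholds:
    """Tail / truncation calling thresholds (residue counts).

    An extension of at least ``tail_min`` residues is called a tail; N-tails
    of ``h4_like_min`` or more residues are classed as H4-like (eukaryote-tail
    length), shorter tails as "short".  A terminus missing at least
    ``truncation_min`` reference positions is called truncated, which
    separates genuine loss of part of helix alpha1 or alpha3 from ragged ends.
    """

    tail_min: int = 4
    h4_like_min: int = 13
    truncation_min: int = 5


@dataclass(frozen=True)
class TerminiAnnotation:
    n_tail_length: int
    c_tail_length: int
    n_truncation_length: int
    c_truncation_length: int
    n_tail_class: str  # none | short | h4_like
    flags: frozenset[str]

    def __post_init__(self) -> None:
        for name, flag in (
            ("n_tail_length", "n_tail"),
            ("c_tail_length", "c_tail"),
            ("n_truncation_length", "n_truncated"),
            ("c_truncation_length", "c_truncated"),
        ):
            if (flag in self.flags) != (getattr(self, name) > 0):
                raise ValueError(f"flag {flag} inconsistent with {name}")


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    # terminal gaps are free: tails and truncations are unaligned overhangs,
    # not penalized indels (semiglobal alignment)
    aligner.end_gap_score = 0.0
    return aligner


def align_to_reference(
    query: HistoneSequence,
    reference: ReferenceHistone,
    align_params: AlignParams | None = None,
) -> AlignmentMap:
    """Globally align ``query`` to the reference and return the position map.

    Deterministic for identical inputs: the highest-scoring alignment under
    the configured matrix/gap costs is taken, with the aligner's canonical
    traceback order breaking ties.
    """
    params = align_params or AlignParams()
    if reference.sequence is None:
        raise ValueError("reference carries no sequence; cannot align")
    if len(query) < params.min_query_length:
        raise NotAHistoneError(
            f"{query.id}: length {len(query)} < {params.min_query_length}; "
            "not a plausible histone"
        )
    aligner = _aligner(params)
    alignment = aligner.align(reference.sequence, query.residues)[0]
    pairs: list[tuple[int, int]] = []
    for (r0, r1), (q0, q1) in zip(*alignment.aligned):
        pairs.extend((r0 + k + 1, q0 + k + 1) for k in range(r1 - r0))
    first_q = pairs[0][1] if pairs else 1
    last_q = pairs[-1][1] if pairs else 0
    return AlignmentMap(
        query_id=query.id,
        ref_length=reference.length,
        query_length=len(query),
        pairs=tuple(pairs),
        n_extension=query.residues[: first_q - 1],
        c_extension=query.residues[last_q:],
        alignment_score=float(alignment.score),
    )


def residue_at(amap: AlignmentMap, query: HistoneSequence, position: int) -> str:
    """Query residue matched to a reference position, or the gap marker.

    Positions are 1-based reference numbering; out-of-range positions raise.
    """
    if not 1 <= position <= amap.ref_length:
        raise ValueError(f"reference position {position} outside [1, {amap.ref_length}]")
    q = amap.query_position(position)
    return GAP if q is None else query.residues[q - 1]


def residue_view(amap: AlignmentMap, query: HistoneSequence) -> dict[int, str]:
    """Position -> residue mapping over all matched reference positions."""
    return {r: query.residues[q - 1] for r, q in amap.pairs}


def annotate_termini(
    amap: AlignmentMap, thresholds: TerminiThresholds | None = None
) -> TerminiAnnotation:
    """Call tails (query extensions) and truncations (missing fold ends).

    Extensions or missing stretches below the calling thresholds are treated
    as ragged ends: the corresponding length is reported as 0 and no flag is
    set, so flags and lengths stay biconditional.
    """
    th = thresholds or TerminiThresholds()
    n_ext = len(amap.n_extension)
    c_ext = len(amap.c_extension)
    if amap.pairs:
        n_miss = amap.pairs[0][0] - 1
        c_miss = amap.ref_length - amap.pairs[-1][0]
    else:
        n_miss, c_miss = amap.ref_length, 0
    n_tail = n_ext if n_ext >= th.tail_min else 0
    c_tail = c_ext if c_ext >= th.tail_min else 0
    n_trunc = n_miss if n_miss >= th.truncation_min else 0
    c_trunc = c_miss if c_miss >= th.truncation_min else 0
    flags = set()
    if n_tail:
        flags.add("n_tail")
    if c_tail:
        flags.add("c_tail")
    if n_trunc:
        flags.add("n_truncated")
    if c_trunc:
        flags.add("c_truncated")
    if not n_tail:
        n_class = "none"
    elif n_tail >= th.h4_like_min:
        n_class = "h4_like"
    else:
        n_class = "short"
    return TerminiAnnotation(
        n_tail_length=n_tail,
        c_tail_length=c_tail,
        n_truncation_length=n_trunc,
        c_truncation_length=c_trunc,
        n_tail_class=n_class,
        flags=frozenset(flags),
    )


def read_fasta(path) -> list[HistoneSequence]:
    """Read a multi-FASTA of queries.

    The description line is parsed best-effort as "id accession taxon...";
    a second token containing a digit and a dot (e.g. ``ADP77985.1``) is taken
    as a database accession, the remainder as the taxon label.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = rec.description.split()
        accession = None
        taxon = ""
        rest = tokens[1:] if tokens and tokens[0] == rec.id else tokens
        if rest and re.search(r"\d", rest[0]) and "." in rest[0]:
            accession = rest[0]
            taxon = " ".join(rest[1:])
        else:
            taxon = " ".join(rest)
        out.append(
            HistoneSequence(
                id=rec.id, residues=str(rec.seq), accession=accession, taxon_label=taxon
            )
        )
    return out
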
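"""Synthetic histone panels with exact ground truth.

Each synthetic sequence is the reference (HMfB) scaffold with its scored
positions rewritten to force a sampled assessment outcome:

* the dimer-dimer interface (46/49/59/62) is set to a template realizing the
  sampled criterion verdict (canonical L/H/D/L; a weakened 49-59 bond; or a
  charge-repulsive, defect-rich surface),
* stacking-loop residue 16 is set to a small / medium / large side chain,
* a chosen number of catalog position pairs is made interaction-competent via
  a fixed "safe chain" of pair assignments whose prefixes never create
  unintended interactions at other catalog pairs; every remaining catalog
  position is set to alanine, so the constructed pair count is exact.

Nuisance mutations (off-target sequence noise) never touch scored positions,
and sampled tails / terminal truncations are applied last.  Ground-truth
labels are recomputed from the exactly known position -> residue map after
truncation, so truth is by construction, independent of any alignment.

Sequences are written to FASTA and truth labels to a sidecar TSV; labels are
never encoded in FASTA headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import HistoneSequence
from .assessment import (
    Verdict,
    classify_overall,
    enumerate_stacking_pairs_view,
    score_dimer_interface_view,
    score_stacking_interface_view,
)
from .reference import ReferenceHistone, StackingPairCatalog

__all__ = ["SyntheticSpec", "TailSpec", "TruthRecord", "generate_panel", "write_panel"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Pair assignments whose prefixes yield exact constructed pair counts: with all
# other catalog positions set to alanine, no prefix activates any unintended
# catalog pair (checked by the generator after assembly).
_SAFE_CHAIN: tuple[tuple[int, int, str, str], ...] = (
    (30, 61, "K", "E"),
    (34, 65, "E", "R"),
    (14, 48, "D", "R"),
    (13, 18, "K", "E"),
    (26, 57, "K", "E"),
    (37, 45, "R", "E"),
    (2, 48, "E", "R"),
    (14, 53, "D", "K"),
)

_DIMER_TEMPLATES: dict[Verdict, dict[int, str]] = {
    Verdict.LIKELY: {46: "L", 49: "H", 59: "D", 62: "L"},
    Verdict.UNCERTAIN: {46: "L", 49: "N", 59: "D", 62: "L"},
    Verdict.UNLIKELY: {46: "L", 49: "D", 59: "D", 62: "E"},
}

_POS16_CHOICES: dict[Verdict, str] = {
    Verdict.LIKELY: "GAS",
    Verdict.UNCERTAIN: "TNPV",
    Verdict.UNLIKELY: "WFYKRELQ",
}

_KRICH_TAIL = "KKGGKAKRSTGAKQLT"  # sampling alphabet for H4-like tails
_PLAIN_TAIL = "ASTGNQEDKLVP"


@dataclass(frozen=True)
class TailSpec:
    """Probabilities of terminal features; lengths sampled uniformly in range."""

    p_n_short: float = 0.15  # 5-10 residue N-tail
    p_n_h4like: float = 0.15  # 14-20 residue lysine-rich N-tail
    p_c_short: float = 0.15  # 5-11 residue C-tail
    p_c_long: float = 0.10  # fixed 28-residue C-tail
    p_n_trunc: float = 0.0  # lose 8-12 N-terminal reference positions
    p_c_trunc: float = 0.0  # lose 6-10 C-terminal reference positions


@dataclass(frozen=True)
class SyntheticSpec:
    n_sequences: int = 60
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {"likely": 0.5, "uncertain": 0.3, "unlikely": 0.2}
    )
    tail_spec: TailSpec = field(default_factory=TailSpec)
    nuisance_mutation_rate: float = 0.0
    adversarial_rate: float = 0.0  # substitution rate at scored positions
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1, got {total}")
        for name in ("nuisance_mutation_rate", "adversarial_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {rate}")


@dataclass(frozen=True)
class TruthRecord:
    """Construction-side ground truth for one synthetic sequence."""

    id: str
    intended_class: str
    dimer: Verdict
    stacking: Verdict
    pair_count: int
    overall: Verdict
    n_tail_length: int
    c_tail_length: int
    n_truncation_length: int
    c_truncation_length: int


class ImpossibleClassError(ValueError):
    """Requested assessment outcome cannot be constructed from the catalog."""


def _sample_triple(rng: np.random.Generator, target: Verdict) -> tuple[Verdict, Verdict, int]:
    """Sample a (dimer, stacking, pair count) triple realizing ``target``."""
    if target is Verdict.LIKELY:
        return Verdict.LIKELY, Verdict.LIKELY, int(rng.integers(2, 7))
    if target is Verdict.UNCERTAIN:
        combos = (
            (Verdict.UNCERTAIN, Verdict.LIKELY, int(rng.integers(2, 7))),
            (Verdict.LIKELY, Verdict.UNCERTAIN, int(rng.integers(2, 7))),
            (Verdict.LIKELY, Verdict.UNLIKELY, int(rng.integers(3, 7))),
        )
        return combos[int(rng.integers(len(combos)))]
    combos = (
        (Verdict.UNLIKELY, Verdict.LIKELY, int(rng.integers(0, 3))),
        (Verdict.UNCERTAIN, Verdict.UNLIKELY, int(rng.integers(0, 3))),
        (Verdict.UNLIKELY, Verdict.UNLIKELY, int(rng.integers(0, 3))),
    )
    return combos[int(rng.integers(len(combos)))]


def _chain_assignments(
    count: int, catalog: StackingPairCatalog
) -> dict[int, str]:
    pairs_available = catalog.position_pairs()
    usable = [c for c in _SAFE_CHAIN if (c[0], c[1]) in pairs_available]
    if count > len(usable):
        raise ImpossibleClassError(
            f"cannot construct {count} stacking pairs: catalog supports at most "
            f"{len(usable)} safe-chain pairs"
        )
    assignment: dict[int, str] = {p: "A" for p in catalog.positions()}
    for pos_a, pos_b, res_a, res_b in usable[:count]:
        for pos, res in ((pos_a, res_a), (pos_b, res_b)):
            if assignment.get(pos, res) not in ("A", res):
                raise ImpossibleClassError(f"conflicting assignment at position {pos}")
            assignment[pos] = res
    return assignment


def _sample_tails(rng: np.random.Generator, ts: TailSpec) -> tuple[str, str, int, int]:
    n_tail = c_tail = ""
    u = rng.random()
    if u < ts.p_n_h4like:
        length = int(rng.integers(14, 21))
        n_tail = "".join(rng.choice(list(_KRICH_TAIL), size=length))
    elif u < ts.p_n_h4like + ts.p_n_short:
        length = int(rng.integers(5, 11))
        n_tail = "".join(rng.choice(list(_PLAIN_TAIL), size=length))
    v = rng.random()
    if v < ts.p_c_long:
        c_tail = "".join(rng.choice(list(_PLAIN_TAIL), size=28))
    elif v < ts.p_c_long + ts.p_c_short:
        length = int(rng.integers(5, 12))
        c_tail = "".join(rng.choice(list(_PLAIN_TAIL), size=length))
    n_trunc = int(rng.integers(8, 13)) if rng.random() < ts.p_n_trunc else 0
    c_trunc = int(rng.integers(6, 11)) if rng.random() < ts.p_c_trunc else 0
    if n_trunc and n_tail:
        n_tail = ""  # a truncated fold start and an N-tail are contradictory
    if c_trunc and c_tail:
        c_tail = ""
    return n_tail, c_tail, n_trunc, c_trunc


def generate_panel(
    spec: SyntheticSpec,
    reference: ReferenceHistone,
    catalog: StackingPairCatalog,
) -> list[tuple[HistoneSequence, TruthRecord]]:
    """Generate ``spec.n_sequences`` labelled histone-like sequences.

    Fully reproducible from ``spec.seed``.  Raises ImpossibleClassError when a
    sampled outcome cannot be built from the supplied catalog.
    """
    if reference.sequence is None:
        raise ValueError("reference carries no sequence")
    rng = np.random.default_rng(spec.seed)
    classes = list(spec.class_mix)
    probs = np.array([spec.class_mix[c] for c in classes], dtype=float)
    scored = (
        catalog.positions()
        | set(reference.stacking_interface_positions)
        | set(reference.dimer_interface_positions)
    )
    out: list[tuple[HistoneSequence, TruthRecord]] = []
    for i in range(spec.n_sequences):
        target = Verdict.from_token(str(rng.choice(classes, p=probs)))
        dimer_v, stacking_v, count = _sample_triple(rng, target)
        assignment = _chain_assignments(count, catalog)
        assignment.update(_DIMER_TEMPLATES[dimer_v])
        assignment[16] = str(rng.choice(list(_POS16_CHOICES[stacking_v])))

        residues = list(reference.sequence)
        for pos, res in assignment.items():
            residues[pos - 1] = res
        for pos in range(1, reference.length + 1):
            rate = spec.adversarial_rate if pos in scored else spec.nuisance_mutation_rate
            if rate and rng.random() < rate:
                current = residues[pos - 1]
                choices = [a for a in AMINO_ACIDS if a != current]
                residues[pos - 1] = str(rng.choice(choices))

        n_tail, c_tail, n_trunc, c_trunc = _sample_tails(rng, spec.tail_spec)
        kept = range(1 + n_trunc, reference.length + 1 - c_trunc)
        known_map = {pos: residues[pos - 1] for pos in kept}

        truth_dimer = score_dimer_interface_view(known_map).value
        truth_stacking = score_stacking_interface_view(known_map).value
        truth_count = len(enumerate_stacking_pairs_view(known_map, catalog))
        truth = TruthRecord(
            id=f"syn{i:04d}",
            intended_class=target.ascii,
            dimer=truth_dimer,
            stacking=truth_stacking,
            pair_count=truth_count,
            overall=classify_overall(truth_dimer, truth_stacking, truth_count),
            n_tail_length=len(n_tail),
            c_tail_length=len(c_tail),
            n_truncation_length=n_trunc,
            c_truncation_length=c_trunc,
        )
        seq = n_tail + "".join(residues[pos - 1] for pos in kept) + c_tail
        out.append((HistoneSequence(id=truth.id, residues=seq), truth))
    return out


def write_panel(
    panel: Sequence[tuple[HistoneSequence, TruthRecord]], fasta_path, truth_path
) -> None:
    """Write sequences to FASTA and truth labels to a sidecar TSV."""
    with open(fasta_path, "w") as fh:
        for seq, _ in panel:
            fh.write(f">{seq.id}\n{seq.residues}\n")
    rows = [
        {
            "id": t.id,
            "intended_class": t.intended_class,
            "dimer": t.dimer.ascii,
            "stacking": t.stacking.ascii,
            "pair_count": t.pair_count,
            "overall": t.overall.ascii,
            "n_tail_length": t.n_tail_length,
            "c_tail_length": t.c_tail_length,
            "n_truncation_length": t.n_truncation_length,
            "c_truncation_length": t.c_truncation_length,
        }
        for _, t in panel
    ]
    pd.DataFrame(rows).to_csv(truth_path, sep="\t", index=False)
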
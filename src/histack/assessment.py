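"""Three-criteria assessment of hypernucleosome formation.

A histone dimer can extend into a stacked superhelical rod (hypernucleosome)
when three things hold, all evaluated in HMfB reference numbering:

1. **Dimer-dimer (tetramerization) interface** (positions 46, 49, 59, 62):
   hydrophobic residues at 46 and 62, and a salt-bridge-grade hydrogen bond
   between 49 and 59 (His49-Asp59 in HMfB).  Substitutions that weaken the
   49-59 bond, replace the hydrophobic pair, or give the interface a like
   charge (e.g. acidic at both 49 and 62) each count as one defect.
2. **Stacking interface** (loop 15-17): the pivotal residue 16 must be small
   (glycine in HMfB); bulkier side chains sterically block close stacking of
   successive dimer layers.
3. **Potential stacking interactions**: candidate hydrogen bonds / salt
   bridges between residues of dimer *i* and dimers *i*+2 / *i*+3, enumerated
   over a catalog of structurally facing position pairs.  More such pairs
   mean a more stable, compact rod; few pairs mean a "floppy" one.

The overall verdict (likely / uncertain / unlikely, printed +, ±, −) is a
pure function of the two interface verdicts and the pair count.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import (
    GAP,
    AlignParams,
    AlignmentMap,
    HistoneSequence,
    TerminiAnnotation,
    TerminiThresholds,
    align_to_reference,
    annotate_termini,
    residue_view,
)
from .reference import ReferenceHistone, StackingPairCatalog

__all__ = [
    "Verdict",
    "CriterionScore",
    "StackingPair",
    "AssessmentRecord",
    "AssessSettings",
    "complementarity",
    "score_dimer_interface",
    "score_stacking_interface",
    "enumerate_stacking_pairs",
    "classify_overall",
    "assess",
    "write_report",
]

# Residue chemistry used throughout.  Histidine is treated as basic and as
# both H-bond donor and acceptor; tryptophan as donor only.  No pKa modelling.
BASIC = frozenset("KRH")
ACIDIC = frozenset("DE")
DONORS = frozenset("RKWNQSTYH")
ACCEPTORS = frozenset("DENQSTYH")
HYDROPHOBIC = frozenset("AVLIMF")


class Verdict(enum.Enum):
    """Three-level call, ordered unlikely < uncertain < likely."""

    UNLIKELY = 0
    UNCERTAIN = 1
    LIKELY = 2

    @property
    def symbol(self) -> str:
        return {0: "−", 1: "±", 2: "+"}[self.value]

    @property
    def ascii(self) -> str:
        return {0: "minus", 1: "pm", 2: "plus"}[self.value]

    @classmethod
    def from_token(cls, token: str) -> "Verdict":
        t = token.strip()
        table = {
            "+": cls.LIKELY, "plus": cls.LIKELY, "likely": cls.LIKELY,
            "±": cls.UNCERTAIN, "pm": cls.UNCERTAIN, "uncertain": cls.UNCERTAIN,
            "−": cls.UNLIKELY, "-": cls.UNLIKELY, "minus": cls.UNLIKELY,
            "unlikely": cls.UNLIKELY,
        }
        if t not in table:
            raise ValueError(f"unknown verdict token {token!r}")
        return table[t]

    def __lt__(self, other: "Verdict") -> bool:
        return self.value < other.value


@dataclass(frozen=True)
class CriterionScore:
    value: Verdict
    defects: tuple[str, ...] = ()
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class StackingPair:
    """One realized inter-dimer interaction at a catalog position pair."""

    pos_a: int
    pos_b: int
    res_a: str
    res_b: str
    kind: str  # salt_bridge | sidechain_hbond | backbone_mediated

    def token(self) -> str:
        """Tabular notation, e.g. ``K30-E61`` or ``K14(bb)-R48``."""
        bb_a = bb_b = ""
        if self.kind == "backbone_mediated":
            # (bb) marks the side whose backbone carbonyl is the acceptor,
            # i.e. the residue that is not the side-chain donor.
            if self.res_a not in DONORS:
                bb_a = "(bb)"
            else:
                bb_b = "(bb)"
        return f"{self.res_a}{self.pos_a}{bb_a}-{self.res_b}{self.pos_b}{bb_b}"


@dataclass(frozen=True)
class VolumeClasses:
    """Side-chain volume classes for the stacking-loop residue 16.

    Small residues permit close layer stacking; medium ones strain it; large
    ones block it.  Boundaries follow standard residue volumes and are
    config-exposed because the underlying structural statement is only that
    bulkier residues interfere.
    """

    small: frozenset[str] = frozenset("GASC")
    medium: frozenset[str] = frozenset("TDNPV")


@dataclass(frozen=True)
class AssessSettings:
    align_params: AlignParams = field(default_factory=AlignParams)
    termini_thresholds: TerminiThresholds = field(default_factory=TerminiThresholds)
    volume_classes: VolumeClasses = field(default_factory=VolumeClasses)


@dataclass(frozen=True)
class AssessmentRecord:
    """One report row: both criteria, enumerated pairs, termini, overall call."""

    query_id: str
    accession: str | None
    dimer_interface: CriterionScore
    stacking_interface: CriterionScore
    stacking_pairs: tuple[StackingPair, ...]
    termini: TerminiAnnotation
    overall: Verdict
    notes: str = ""

    @property
    def stacking_count(self) -> int:
        return len(self.stacking_pairs)


def complementarity(res_a: str, res_b: str, backbone_allowed: bool = False) -> str | None:
    """Interaction class available to two residues facing across dimer layers.

    Returns ``salt_bridge`` for basic x acidic pairs, ``sidechain_hbond`` when
    one side chain can donate and the other accept a hydrogen bond,
    ``backbone_mediated`` when only a backbone carbonyl can accept (permitted
    for marked catalog entries with at least one side-chain donor), and None
    otherwise.  The gap marker (or X) on either side yields None.
    """
    a, b = res_a.upper(), res_b.upper()
    if a in (GAP, "X") or b in (GAP, "X"):
        return None
    if (a in BASIC and b in ACIDIC) or (b in BASIC and a in ACIDIC):
        return "salt_bridge"
    if (a in DONORS and b in ACCEPTORS) or (b in DONORS and a in ACCEPTORS):
        return "sidechain_hbond"
    if backbone_allowed and (a in DONORS or b in DONORS):
        return "backbone_mediated"
    return None


def _verdict_from_defects(n: int) -> Verdict:
    if n == 0:
        return Verdict.LIKELY
    if n == 1:
        return Verdict.UNCERTAIN
    return Verdict.UNLIKELY


def score_dimer_interface_view(view: Mapping[int, str]) -> CriterionScore:
    """Dimer-dimer interface criterion on a position -> residue mapping.

    Defects: non-hydrophobic (or missing) residue at 46 or 62; a 49-59 pair
    weaker than a salt-bridge-grade hydrogen bond (His/Lys/Arg against
    Asp/Glu — the His49-Asp59 bond is the crucial one, and substitutions like
    H49N or D59S weaken it); and like-charge repulsion across the interface
    surface (49 and 62 both acidic or both basic).
    """
    r46 = view.get(46, GAP)
    r49 = view.get(49, GAP)
    r59 = view.get(59, GAP)
    r62 = view.get(62, GAP)
    defects = []
    for pos, res in ((46, r46), (62, r62)):
        if res not in HYDROPHOBIC:
            what = "missing" if res == GAP else res
            defects.append(f"position {pos}: {what} not hydrophobic")
    if complementarity(r49, r59) != "salt_bridge":
        defects.append(f"49-59 pair {r49}-{r59} lacks salt-bridge-grade H-bond")
    if (r49 in ACIDIC and r62 in ACIDIC) or (r49 in BASIC and r62 in BASIC):
        charge = "acidic" if r49 in ACIDIC else "basic"
        defects.append(f"like-charge ({charge}) interface surface at 49/62")
    return CriterionScore(_verdict_from_defects(len(defects)), tuple(defects))


def score_stacking_interface_view(
    view: Mapping[int, str], volume_classes: VolumeClasses | None = None
) -> CriterionScore:
    """Stacking-interface criterion: side-chain volume class at position 16.

    Small -> likely, medium -> uncertain, large or missing (e.g. the 15-17
    loop lost to truncation) -> unlikely.  Residues at 15 and 17 are reported
    as notes but never change the class.
    """
    vc = volume_classes or VolumeClasses()
    r16 = view.get(16, GAP)
    notes = tuple(
        f"position {p}: {view.get(p, GAP)}" for p in (15, 17)
    )
    if r16 == GAP:
        return CriterionScore(
            Verdict.UNLIKELY, (f"stacking loop residue 16 missing",), notes
        )
    if r16 in vc.small:
        return CriterionScore(Verdict.LIKELY, (), notes)
    if r16 in vc.medium:
        return CriterionScore(
            Verdict.UNCERTAIN, (f"position 16: {r16} medium volume",), notes
        )
    return CriterionScore(
        Verdict.UNLIKELY, (f"position 16: {r16} large volume",), notes
    )


def enumerate_stacking_pairs_view(
    view: Mapping[int, str], catalog: StackingPairCatalog
) -> tuple[StackingPair, ...]:
    """All catalog position pairs whose residues are interaction-competent.

    Output follows catalog order, deduplicated on the position pair; a residue
    may participate in several pairs; missing residues yield no pair.
    """
    out: list[StackingPair] = []
    seen: set[tuple[int, int]] = set()
    for entry in catalog:
        if entry.positions in seen:
            continue
        res_a = view.get(entry.pos_a, GAP)
        res_b = view.get(entry.pos_b, GAP)
        kind = complementarity(res_a, res_b, backbone_allowed=entry.backbone_allowed)
        if kind is not None:
            out.append(StackingPair(entry.pos_a, entry.pos_b, res_a, res_b, kind))
            seen.add(entry.positions)
    return tuple(out)


def score_dimer_interface(
    amap: AlignmentMap, query: HistoneSequence, reference: ReferenceHistone
) -> CriterionScore:
    return score_dimer_interface_view(residue_view(amap, query))


def score_stacking_interface(
    amap: AlignmentMap,
    query: HistoneSequence,
    reference: ReferenceHistone,
    volume_classes: VolumeClasses | None = None,
) -> CriterionScore:
    return score_stacking_interface_view(residue_view(amap, query), volume_classes)


def enumerate_stacking_pairs(
    amap: AlignmentMap, query: HistoneSequence, catalog: StackingPairCatalog
) -> tuple[StackingPair, ...]:
    return enumerate_stacking_pairs_view(residue_view(amap, query), catalog)


def classify_overall(dimer: Verdict, stacking: Verdict, pair_count: int) -> Verdict:
    """Overall hypernucleosome-formation call.

    If either interface criterion is unlikely, the histone is unlikely to
    multimerize unless enough (>2) potential stacking interactions remain to
    rescue an open / floppy rod, in which case it is uncertain.  Otherwise a
    single uncertain criterion makes the overall call uncertain; with both
    criteria likely the call is likely, regardless of how many stacking
    interactions merely tune compactness and stability.
    """
    if pair_count < 0:
        raise ValueError(f"pair_count must be >= 0, got {pair_count}")
    worst = min(dimer, stacking)
    if worst is Verdict.UNLIKELY:
        return Verdict.UNLIKELY if pair_count <= 2 else Verdict.UNCERTAIN
    if worst is Verdict.UNCERTAIN:
        return Verdict.UNCERTAIN
    return Verdict.LIKELY


def assess(
    query: HistoneSequence,
    reference: ReferenceHistone,
    catalog: StackingPairCatalog,
    settings: AssessSettings | None = None,
) -> AssessmentRecord:
    """Full per-histone pipeline: align, annotate termini, score, classify."""
    st = settings or AssessSettings()
    amap = align_to_reference(query, reference, st.align_params)
    view = residue_view(amap, query)
    termini = annotate_termini(amap, st.termini_thresholds)
    dimer = score_dimer_interface_view(view)
    stacking = score_stacking_interface_view(view, st.volume_classes)
    pairs = enumerate_stacking_pairs_view(view, catalog)
    overall = classify_overall(dimer.value, stacking.value, len(pairs))
    notes = []
    if termini.n_tail_class != "none":
        notes.append(f"N-tail ({termini.n_tail_class}, {termini.n_tail_length} aa)")
    if "c_tail" in termini.flags:
        notes.append(f"C-tail ({termini.c_tail_length} aa)")
    if "n_truncated" in termini.flags:
        notes.append(f"N-truncated ({termini.n_truncation_length} ref positions)")
    if "c_truncated" in termini.flags:
        notes.append(f"C-truncated ({termini.c_truncation_length} ref positions)")
    return AssessmentRecord(
        query_id=query.id,
        accession=query.accession,
        dimer_interface=dimer,
        stacking_interface=stacking,
        stacking_pairs=pairs,
        termini=termini,
        overall=overall,
        notes="; ".join(notes),
    )


def records_to_frame(records: Sequence[AssessmentRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        t = r.termini
        trunc = []
        if t.n_truncation_length:
            trunc.append(f"n:{t.n_truncation_length}")
        if t.c_truncation_length:
            trunc.append(f"c:{t.c_truncation_length}")
        rows.append(
            {
                "id": r.query_id,
                "accession": r.accession or ".",
                "dimer_interface": r.dimer_interface.value.symbol,
                "dimer_interface_ascii": r.dimer_interface.value.ascii,
                "stacking_interface": r.stacking_interface.value.symbol,
                "stacking_interface_ascii": r.stacking_interface.value.ascii,
                "stacking_count": r.stacking_count,
                "stacking_pairs": ";".join(p.token() for p in r.stacking_pairs) or ".",
                "n_tail": t.n_tail_length,
                "c_tail": t.c_tail_length,
                "truncations": ";".join(trunc) or ".",
                "overall": r.overall.symbol,
                "overall_ascii": r.overall.ascii,
                "notes": r.notes or ".",
            }
        )
    return pd.DataFrame(rows)


def write_report(records: Sequence[AssessmentRecord], path) -> None:
    """Write the tabular assessment report (TSV, one row per input histone)."""
    records_to_frame(records).to_csv(path, sep="\t", index=False)
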
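"""Curated 33-histone assessment panel used for rule calibration.

The bundled TSV transcribes the published per-histone verdicts for a panel of
archaeal histones spanning every histone-encoding (candidate) phylum: interface
criteria, enumerated potential stacking interactions (with residue identities
in HMfB numbering), the overall call, and terminal features.  It serves two
purposes: the overall-classification rule is validated against every row, and
the printed residue pairs act as chemistry fixtures for the complementarity
rules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .assessment import Verdict, classify_overall

__all__ = ["PanelPair", "PanelRow", "load_panel", "failing_multiple_criteria"]

_PAIR_RE = re.compile(
    r"^(?P<res_a>[A-Z])(?P<pos_a>\d+)(?P<bb_a>\(bb\))?-"
    r"(?P<res_b>[A-Z])(?P<pos_b>\d+)(?P<bb_b>\(bb\))?$"
)


@dataclass(frozen=True)
class PanelPair:
    res_a: str
    pos_a: int
    res_b: str
    pos_b: int
    backbone: bool

    @property
    def positions(self) -> tuple[int, int]:
        a, b = sorted((self.pos_a, self.pos_b))
        return (a, b)


@dataclass(frozen=True)
class PanelRow:
    lineage: str
    histone: str
    dimer: Verdict
    stacking: Verdict
    n_pairs: int
    pairs: tuple[PanelPair, ...]
    overall: Verdict
    features: str

    def reclassify(self) -> Verdict:
        """Overall verdict recomputed from this row's criterion triple."""
        return classify_overall(self.dimer, self.stacking, self.n_pairs)


def _parse_pair(token: str) -> PanelPair:
    m = _PAIR_RE.match(token.strip())
    if m is None:
        raise ValueError(f"unparsable stacking-pair token {token!r}")
    return PanelPair(
        res_a=m["res_a"],
        pos_a=int(m["pos_a"]),
        res_b=m["res_b"],
        pos_b=int(m["pos_b"]),
        backbone=bool(m["bb_a"] or m["bb_b"]),
    )


def load_panel(source: str | Path | None = None) -> tuple[PanelRow, ...]:
    """Load the bundled curated panel (or a TSV with the same schema)."""
    if source is None:
        text = (resources.files("histack") / "data" / "panel_assessments.tsv").read_text()
    else:
        text = Path(source).read_text()
    rows: list[PanelRow] = []
    header: list[str] | None = None
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if header is None:
            header = fields
            continue
        rec = dict(zip(header, fields))
        pairs = tuple(
            _parse_pair(tok) for tok in rec["pairs"].split(";") if tok and tok != "."
        )
        row = PanelRow(
            lineage=rec["lineage"],
            histone=rec["histone"],
            dimer=Verdict.from_token(rec["dimer"]),
            stacking=Verdict.from_token(rec["stacking"]),
            n_pairs=int(rec["n_pairs"]),
            pairs=pairs,
            overall=Verdict.from_token(rec["overall"]),
            features="" if rec["features"] == "." else rec["features"],
        )
        if row.n_pairs != len(row.pairs):
            raise ValueError(f"{row.histone}: n_pairs {row.n_pairs} != {len(row.pairs)} pairs")
        rows.append(row)
    return tuple(rows)


def failing_multiple_criteria(
    rows: tuple[PanelRow, ...], few_pairs_max: int = 2
) -> tuple[PanelRow, ...]:
    """Histones that combine defects in all three criteria.

    A histone "fails multiple criteria" when its dimer-dimer interface is
    compromised (not likely), position 16 carries a bulky substitution (not
    likely), and few potential stacking interactions remain (count at most
    ``few_pairs_max``).  Such histones cannot form hypernucleosomes.
    """
    return tuple(
        r
        for r in rows
        if r.dimer is not Verdict.LIKELY
        and r.stacking is not Verdict.LIKELY
        and r.n_pairs <= few_pairs_max
    )
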
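# Methods

## Scope and model

`histack` scores single archaeal histone sequences for their ability to join
a hypernucleosome — the stacked, left-handed superhelical rod formed by
histone dimers multimerizing along DNA. The model is purely residue-based:
every rule reads amino-acid identities at fixed positions of the HMfB
reference fold (69 residues, 1-based numbering). No structure prediction,
energetics, or pKa modelling is attempted.

## Reference projection by pairwise alignment

Each query is aligned once to the HMfB sequence with a global affine-gap
alignment (BLOSUM62, gap open 10, gap extend 1) in which terminal gaps are
free (semiglobal). Free end gaps are the correct model here: residues beyond
the reference fold are tails, and missing fold ends are truncations — neither
is an indel to be penalized. Every downstream lookup is "the query residue
matched to reference position *p*", with a gap marker when the column is
unmatched. Query residues inside internal insertions have no reference
coordinate and are invisible to scoring.

This replaces a one-shot multiple alignment of a whole panel: projecting an
MSA onto the reference row and dropping gap columns is equivalent in effect,
but per-query pairwise alignment is deterministic and independent of panel
composition. Ties in the traceback are resolved by the aligner's canonical
order; identical inputs always give identical maps.

Queries shorter than 20 residues are rejected as implausible histones.

## Termini annotation

* extension ≥ 4 residues → tail; shorter overhangs are ragged ends and
  report length 0 (flags and lengths are biconditional).
* N-tails of 4–12 residues are "short"; ≥ 13 are "h4_like" (the length range
  of eukaryotic H4 N-tails). The boundary at 13 splits the two observed
  regimes — 5–10-residue short tails vs ~16–20-residue lysine-rich tails.
* a terminus missing ≥ 5 reference positions → truncation (distinguishes
  genuine loss of part of helix α1 or α3 from ragged ends).

## Residue chemistry

One fixed table drives all interaction calls:

* basic {K, R, H}; acidic {D, E};
* side-chain H-bond donors {R, K, W, N, Q, S, T, Y, H};
* side-chain H-bond acceptors {D, E, N, Q, S, T, Y, H};
* hydrophobic {A, V, L, I, M, F}.

Histidine is both donor and acceptor and basic; tryptophan donates only.
`complementarity(a, b, backbone_allowed)` returns, in order of precedence,
`salt_bridge` (basic × acidic), `sidechain_hbond` (donor × acceptor),
`backbone_mediated` (only for catalog entries flagged as permitting a
backbone-carbonyl acceptor, and only when at least one side chain can
donate), else none. A gap or unknown residue (X) on either side yields none.

## The three criteria

**Dimer–dimer interface (46, 49, 59, 62).** Defects: (a) residue at 46 or 62
outside the hydrophobic set (a gap from truncation counts); (b) the 49–59
pair weaker than salt-bridge-grade — the His49–Asp59 contact is an ionic
hydrogen bond, and observed substitutions (H49N, D59S, H49D) each weaken it,
so plain donor/acceptor complementarity (e.g. N–D) is deliberately *not*
sufficient; (c) a like-charged interface surface (49 and 62 both acidic or
both basic). 0 defects → likely, 1 → uncertain, ≥ 2 → unlikely.

**Stacking interface (15–17).** Volume class of the residue at 16:
small {G, A, S, C} → likely; medium {T, D, N, P, V} → uncertain; anything
larger, or a missing 16 (truncated loop) → unlikely. Residues at 15 and 17
are reported as notes but never change the class. The class sets are
config-exposed (`VolumeClasses`) since the underlying structural statement
is only that bulkier residues interfere.

**Stacking-pair enumeration.** For each catalog position pair, the two
residues are looked up and the pair is counted when `complementarity` is
non-none, deduplicated on the position pair (so one residue may join several
pairs, e.g. K14 bonding both E18 and E48). Output preserves catalog order.

**Overall classification.** A pure function of (dimer verdict, stacking
verdict, pair count): if either interface is unlikely → unlikely when count
≤ 2, else uncertain; else if either is uncertain → uncertain; else likely.
The rule is monotone in all three inputs (verified over the full input grid)
and reproduces the recorded overall verdict of all 33 rows of the bundled
assessment panel. The pair-count rescue threshold (> 2) is what separates
"few interactions, broken interface" histones (−) from broken-interface
histones with enough residual contacts for a floppy rod (±).

## The stacking-pair catalog

Shipped as editable TSV (`data/stacking_catalog.tsv`), 24 unordered position
pairs. The pairs derive from inspection of which residues face a neighbouring
dimer layer in the stacked-rod crystal arrangement; users with structures can
regenerate or extend the file. `layer_offset` (whether a pair belongs to the
*i*+2 or *i*+3 interface) is carried for forward compatibility but unknown
for all bundled entries. `backbone_allowed` is true for (14,41), (14,44),
(14,48), (15,41) — the pairs observed with apolar partners or annotated as
backbone-mediated. The pair (14,53) rests on a single observation and is
flagged `uncertain`. Pairs are unordered: nothing records which dimer of a
stacked pair contributes which residue.

**Known limitation — sequence-level counts are an upper bound.** The catalog
is the union of pairs observed across a whole panel, and the chemistry rules
are permissive, so enumerating a full sequence typically yields more pairs
than are geometrically realized in any one structure (full-length HMfB: 16
candidate pairs vs 3 contacts in the crystal). Per-histone structural
filtering cannot be reproduced from sequence alone. The enumerator is
therefore a comparative screen — more candidate pairs, more potential rod
stability — not a contact predictor, and the canonical three-pair HMfB
result is recovered exactly when scoring the curated functional identities
(the positions with documented roles) rather than all 69 residues.

## Idealized rod geometry

One pseudo-atom per dimer on a left-handed helix. Defaults
(`data/geometry_defaults.yaml`): 30 bp wrapped per dimer, 0.34 nm/bp, axial
rise 1.02 nm per dimer (nucleosome-like superhelical pitch, ~3 dimers per
turn), radius 3.25 nm. Linear compaction is the closed form
`bp_per_dimer × bp_rise / rise_per_dimer` = 10.0 with the defaults —
independent of rod length, which is the precise sense in which wrapping
"scales linearly" with subunit number. Compaction is interpreted as DNA
contour length over rod axial length; the radius and angular density affect
only coordinate output. The contact graph contains exactly the (i, i+2) and
(i, i+3) edges, (n−2)₊ + (n−3)₊ in total. The PDB writer emits the
pseudo-atom trace (Å) for visualization only.

## Synthetic panels

The generator emulates the structure of a real histone panel — a conserved
fold core with variable interface residues, tails and truncations — with
exact ground truth:

* a target overall class is sampled from `class_mix` (defaults 0.5 / 0.3 /
  0.2 likely / uncertain / unlikely, roughly the mix seen in surveyed
  panels), then realized by a (dimer, stacking, count) triple;
* interface positions get fixed templates (L/H/D/L; L/N/D/L; L/D/D/E), and
  position 16 a residue from the target volume class;
* the pair count is forced through a fixed "safe chain" of pair assignments
  whose prefixes never activate unintended catalog pairs, with every
  remaining catalog position set to alanine — so constructed counts are
  exact, up to 8;
* nuisance mutations (default rate 0) hit only non-scored positions; an
  adversarial rate can additionally mutate scored positions to probe rule
  sensitivity;
* tails are sampled per `TailSpec` (short 5–10, H4-like lysine-rich 14–20,
  C-tails 5–11 or a fixed 28), truncations remove 8–12 N- or 6–10 C-terminal
  reference positions.

Truth labels are recomputed from the exactly known position→residue map
*after* truncation, so they remain exact even when truncation itself changes
a verdict (e.g. a lost position 62 is a dimer-interface defect). Sequences go
to FASTA and labels to a sidecar TSV — never into FASTA headers.

What passing recovery tests shows: alignment-based projection plus the rules
recover construction-time truth (≥ 95% required; in practice 100% at zero
noise, with occasional ±1 truncation-length edge effects when a terminal
residue re-pairs). What it does not show: performance on real divergent
histones, where positions co-vary phylogenetically and alignment ambiguity
is larger — the generator deliberately models no phylogenetic covariance.

## Numerical and degenerate-input choices

* Alignment ties: aligner's canonical traceback; documented as a convention,
  any fixed one suffices.
* Gap at any scored position: silently no pair (enumeration), a defect
  (dimer interface), unlikely (position 16); truncated histones remain
  scoreable end to end.
* Empty alignment (no matched columns) annotates a full-length N-truncation.
* Reports contain no timestamps; reruns are byte-identical. Run metadata
  (config hash, version) goes to a sidecar file.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`.

## Problem sizes

Bundled panel: 33 histones, 118 printed stacking pairs. Synthetic validation
panels: 60 sequences (label recovery), 40 (truncation mode), 8 (fixed C-tail
recovery). Geometry checks: rods of 1–50 dimers. These sizes keep the whole
validation suite in the low seconds while exercising every rule branch.
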
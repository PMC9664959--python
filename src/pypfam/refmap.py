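"""Reference-anchored residue mapping and chromophore-site classification.

Homologs are globally aligned to the reference PYP sequence (H. halophila
numbering: 1-based positions on the supplied reference FASTA). Each reference
position then maps to the aligned target residue or a gap, which lets the
package read the chromophore-binding positions (Tyr42, Glu46, Cys69, plus the
clade-signature sites 50/92/96/100/119), label substitutions in the usual
``Y42F`` notation (gaps written ``-``, e.g. ``C69-``), and call a homolog
*functional* exactly when the residue mapped to position 69 is cysteine - no
cysteine, no thioester, no chromophore.

A star multiple alignment is assembled by merging the pairwise alignments on
reference positions (insertions relative to the reference become left-aligned
insert columns), and per-group conservation profiles are computed over the
reference-anchored columns only, matching residue-numbering semantics.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AA, ScoringParams, global_align
from .synthdata import SequenceRecord

#: Default probed positions (reference numbering).
DEFAULT_POSITIONS = (42, 46, 50, 69, 92, 96, 100, 119)

#: Maps whose global-alignment bit score falls below this floor are flagged
#: unreliable and excluded from residue calling / MSA building.
MIN_MAP_BITSCORE = 20.0


@dataclass
class ReferenceMap:
    """Mapping of every reference position to the aligned target residue
    (or ``"-"``), plus the insertions absorbed between reference positions."""

    sequence_id: str
    mapping: dict[int, str]
    #: insertions[k] = residues inserted between reference positions k and
    #: k+1 (k = 0 for an N-terminal extension).
    insertions: dict[int, str]
    alignment_score: int
    bit_score: float
    reliable: bool


@dataclass
class ResidueCall:
    sequence_id: str
    residues_at: dict[int, str]
    substitution_labels: list[str]
    functional: bool


@dataclass
class FamilySummary:
    """Output of :func:`classify_family`."""

    n_total: int
    n_functional: int
    member_ids: list[str]
    label_counts: dict[str, int]
    label_fractions: dict[str, float]
    triad_conserved_fraction: float
    #: True if any functional call carries both a position-42 and a
    #: position-46 substitution label (never observed in the real family).
    functional_42_46_cooccurrence: bool

    @property
    def member_fraction(self) -> float:
        return self.n_functional / self.n_total if self.n_total else 0.0


@dataclass
class StarMSA:
    """Reference-anchored star alignment: the reference row comes first and is
    gap-free in reference-anchored columns; all rows have equal length."""

    ids: list[str]
    rows: list[str]
    #: column index (0-based) of each reference position (1-based)
    ref_columns: dict[int, int]

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]


# --------------------------------------------------------------------------
# Mapping and calling
# --------------------------------------------------------------------------


def map_to_reference(
    seq: SequenceRecord,
    reference: SequenceRecord,
    params: ScoringParams | None = None,
    min_bitscore: float = MIN_MAP_BITSCORE,
) -> ReferenceMap:
    """Globally align ``seq`` to the reference and read off the per-position
    mapping. Maps scoring below ``min_bitscore`` bits are flagged unreliable."""
    params = params or ScoringParams()
    res = global_align(
        seq.residues, reference.residues, params, seq.id, reference.id
    )
    mapping = {pos: "-" for pos in range(1, len(reference.residues) + 1)}
    insertions: dict[int, str] = {}
    last_ref = 0
    for q, s in res.aligned_pairs:
        if s is not None:
            if q is not None:
                mapping[s] = seq.residues[q - 1]
            last_ref = s
        else:  # insertion in the target relative to the reference
            insertions[last_ref] = insertions.get(last_ref, "") + seq.residues[q - 1]
    return ReferenceMap(
        sequence_id=seq.id,
        mapping=mapping,
        insertions=insertions,
        alignment_score=res.raw_score,
        bit_score=res.bit_score,
        reliable=res.bit_score >= min_bitscore,
    )


def call_residues(
    refmap: ReferenceMap,
    reference: SequenceRecord,
    positions=DEFAULT_POSITIONS,
) -> ResidueCall:
    """Read the probed positions off a reference map.

    A substitution label ``{ref}{pos}{obs}`` is emitted iff the observed
    residue differs from the reference residue (gap written ``-``); the
    functional flag is true iff position 69 carries a cysteine.
    """
    L = len(reference.residues)
    for pos in positions:
        if not 1 <= pos <= L:
            raise ValueError(f"position {pos} outside reference length {L}")
    residues_at = {pos: refmap.mapping[pos] for pos in positions}
    labels = []
    for pos in positions:
        ref_res = reference.residues[pos - 1]
        obs = residues_at[pos]
        if obs != ref_res:
            labels.append(f"{ref_res}{pos}{obs}")
    functional = refmap.mapping.get(69) == "C"
    return ResidueCall(
        sequence_id=refmap.sequence_id,
        residues_at=residues_at,
        substitution_labels=labels,
        functional=functional,
    )


def classify_family(calls) -> FamilySummary:
    """Family membership and substitution census over a set of residue calls.

    Members are the functional calls (Cys69 conserved). Label fractions are
    over all calls; the triad fraction counts calls with the reference residue
    at all of 42, 46, and 69.
    """
    calls = list(calls)
    n_total = len(calls)
    label_counts: Counter = Counter()
    members = []
    triad = 0
    cooccur = False
    for c in calls:
        label_counts.update(c.substitution_labels)
        if c.functional:
            members.append(c.sequence_id)
            has42 = any(lab[1:-1] == "42" for lab in c.substitution_labels)
            has46 = any(lab[1:-1] == "46" for lab in c.substitution_labels)
            if has42 and has46:
                cooccur = True
        if not any(lab[1:-1] in ("42", "46", "69") for lab in c.substitution_labels):
            triad += 1
    fractions = {
        lab: cnt / n_total for lab, cnt in sorted(label_counts.items())
    } if n_total else {}
    return FamilySummary(
        n_total=n_total,
        n_functional=len(members),
        member_ids=members,
        label_counts=dict(sorted(label_counts.items())),
        label_fractions=fractions,
        triad_conserved_fraction=triad / n_total if n_total else 0.0,
        functional_42_46_cooccurrence=cooccur,
    )


# --------------------------------------------------------------------------
# Star MSA and conservation profiles
# --------------------------------------------------------------------------


def star_msa(
    seqs,
    reference: SequenceRecord,
    params: ScoringParams | None = None,
    refmaps: dict[str, ReferenceMap] | None = None,
) -> StarMSA:
    """Merge pairwise reference alignments into a star MSA.

    Insertions relative to the reference share left-aligned insert-column
    blocks (one block per inter-reference slot, as wide as the longest
    insertion there); sequences with unreliable maps are dropped with a
    warning. The reference is always the first row.
    """
    params = params or ScoringParams()
    seqs = list(seqs)
    maps: list[ReferenceMap] = []
    for rec in seqs:
        rm = (refmaps or {}).get(rec.id) or map_to_reference(rec, reference, params)
        if not rm.reliable:
            warnings.warn(
                f"excluding {rec.id!r} from star MSA (bit score "
                f"{rm.bit_score:.1f} below reliability floor)",
                stacklevel=2,
            )
            continue
        maps.append(rm)
    L = len(reference.residues)
    ins_width = {k: 0 for k in range(0, L + 1)}
    for rm in maps:
        for k, ins in rm.insertions.items():
            ins_width[k] = max(ins_width[k], len(ins))
    ids = [reference.id] + [rm.sequence_id for rm in maps]
    ref_columns: dict[int, int] = {}
    col = ins_width[0]
    for pos in range(1, L + 1):
        ref_columns[pos] = col
        col += 1 + ins_width[pos]

    def build_row(mapping: dict[int, str], insertions: dict[int, str]) -> str:
        parts = [insertions.get(0, "").ljust(ins_width[0], "-")]
        for pos in range(1, L + 1):
            parts.append(mapping[pos])
            parts.append(insertions.get(pos, "").ljust(ins_width[pos], "-"))
        return "".join(parts)

    ref_mapping = {p: reference.residues[p - 1] for p in range(1, L + 1)}
    rows = [build_row(ref_mapping, {})]
    for rm in maps:
        rows.append(build_row(rm.mapping, rm.insertions))
    return StarMSA(ids=ids, rows=rows, ref_columns=ref_columns)


def conservation_profile(
    msa: StarMSA,
    group_labels: dict[str, str],
) -> dict[str, pd.DataFrame]:
    """Per-group residue frequency profiles over reference-anchored columns.

    Returns, per group, a DataFrame indexed by reference position with one
    column per residue plus ``-``; each row sums to 1. Insert columns are
    excluded (profiles are reference-anchored). Groups must be non-empty.
    """
    groups: dict[str, list[int]] = {}
    for i, seq_id in enumerate(msa.ids):
        g = group_labels.get(seq_id)
        if g is not None:
            groups.setdefault(g, []).append(i)
    if not groups:
        raise ValueError("no rows matched any group label")
    for g, rows in groups.items():
        if not rows:
            raise ValueError(f"group {g!r} is empty")
    alphabet = list(AA) + ["-"]
    aidx = {a: i for i, a in enumerate(alphabet)}
    positions = sorted(msa.ref_columns)
    out = {}
    for g, row_idx in groups.items():
        mat = np.zeros((len(positions), len(alphabet)))
        for r in row_idx:
            row = msa.rows[r]
            for pi, pos in enumerate(positions):
                mat[pi, aidx[row[msa.ref_columns[pos]]]] += 1
        mat /= mat.sum(axis=1, keepdims=True)
        out[g] = pd.DataFrame(mat, index=positions, columns=alphabet)
    return out


# --------------------------------------------------------------------------
# TSV / aligned-FASTA output
# --------------------------------------------------------------------------


def write_calls(calls, path, positions=DEFAULT_POSITIONS) -> None:
    with open(path, "w") as fh:
        header = ["id"] + [f"residue@{p}" for p in positions] + ["labels", "functional"]
        fh.write("\t".join(header) + "\n")
        for c in calls:
            row = [c.sequence_id]
            row += [c.residues_at.get(p, "-") for p in positions]
            row.append(",".join(c.substitution_labels))
            row.append(str(c.functional))
            fh.write("\t".join(row) + "\n")


def write_msa_fasta(msa: StarMSA, path) -> None:
    with open(path, "w") as fh:
        for seq_id, row in zip(msa.ids, msa.rows):
            fh.write(f">{seq_id}\n")
            for i in range(0, len(row), 60):
                fh.write(row[i : i + 60] + "\n")
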
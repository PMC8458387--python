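"""Consensus design and circular permutation of tandem-repeat proteins.

Repeat proteins such as WD40 beta-propellers consist of near-identical
sequence repeats.  This module builds per-column residue profiles from an
ungapped repeat alignment, derives consensus sequences (recording exact
frequency ties, which must be resolved by an external override or a
background table), computes sequence-logo information content, and
constructs circularly permuted "Velcro" variants of a tandem-repeat
sequence, in which the chain termini are relocated into a loop so that the
ring-closing blade mixes p N-terminal with q C-terminal strands.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "RepeatAlignment",
    "PositionProfile",
    "ConsensusResult",
    "PermutantSpec",
    "VELCRO_KINDS",
    "AlignmentError",
    "AlphabetError",
    "UnresolvedTieError",
    "DeletionPolicyError",
    "build_profile",
    "consensus_sequence",
    "column_information_content",
    "percent_identity",
    "make_circular_permutant",
    "strand_ownership",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

#: Velcro kind -> index (1-based) of the strand the new N-terminus precedes.
#: "nv" keeps the termini outside the closing sheet (cut before strand 1);
#: "v31"/"v22"/"v13" cut before strands 2/3/4, splitting the closing blade
#: 3+1, 2+2 and 1+3 between the N- and C-terminal chain ends.
VELCRO_KINDS = {"nv": 1, "v31": 2, "v22": 3, "v13": 4}


class AlignmentError(ValueError):
    """Sequences of mixed length, empty alignment, or all-gap column."""


class AlphabetError(ValueError):
    """A symbol outside the 20 standard residues plus the gap character."""


class UnresolvedTieError(ValueError):
    """Strict tie policy hit an exact frequency tie without an override."""

    def __init__(self, positions: Sequence[int]):
        self.positions = list(positions)
        super().__init__(
            "unresolved consensus tie at position(s) "
            + ", ".join(str(p) for p in self.positions)
        )


class DeletionPolicyError(ValueError):
    """prefer-glycine deletion requested but the cut residue is not Gly."""


@dataclass(frozen=True)
class RepeatAlignment:
    """Ungapped-or-gapped alignment of the repeats of one tandem protein."""

    sequences: tuple[str, ...]
    repeat_length: int

    @classmethod
    def from_sequences(cls, sequences: Sequence[str]) -> "RepeatAlignment":
        if not sequences:
            raise AlignmentError("alignment must contain at least one sequence")
        seqs = tuple(s.upper() for s in sequences)
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise AlignmentError(f"sequences have mixed lengths: {sorted(lengths)}")
        allowed = set(AMINO_ACIDS) | {GAP}
        for i, s in enumerate(seqs):
            bad = set(s) - allowed
            if bad:
                raise AlphabetError(
                    f"sequence {i} contains non-standard symbol(s): {sorted(bad)}"
                )
        return cls(sequences=seqs, repeat_length=lengths.pop())


@dataclass(frozen=True)
class PositionProfile:
    """Per-column residue counts and frequencies (gaps excluded)."""

    counts: tuple[Mapping[str, int], ...]
    columns: tuple[Mapping[str, float], ...]
    n_sequences: int

    @property
    def length(self) -> int:
        return len(self.columns)

    def modal_residues(self, position: int) -> frozenset[str]:
        """Residues sharing the maximal frequency at a 1-based position."""
        col = self.columns[position - 1]
        top = max(col.values())
        return frozenset(r for r, f in col.items() if f == top)


@dataclass(frozen=True)
class ConsensusResult:
    sequence: str
    ties: tuple[tuple[int, frozenset[str]], ...]
    overrides_applied: tuple[tuple[int, str], ...]


@dataclass(frozen=True)
class PermutantSpec:
    """Where to cut a tandem-repeat ring to place a given Velcro closure.

    strand_ranges are 1-based inclusive (start, end) positions of the four
    beta-strands within one repeat, ordered from the innermost strand
    outwards.  deletion_policy is either "prefer-glycine" (the deleted cut
    residue must be Gly) or an explicit 1-based position within the repeat
    naming the residue to delete (must coincide with the cut residue).
    """

    velcro: str
    strand_ranges: tuple[tuple[int, int], ...]
    n_repeats: int
    deletion_policy: str | int = "prefer-glycine"
    repeat_length: int | None = None

    def __post_init__(self):
        if self.velcro not in VELCRO_KINDS:
            raise ValueError(f"unknown velcro kind {self.velcro!r}; expected one of {sorted(VELCRO_KINDS)}")
        if len(self.strand_ranges) != 4:
            raise ValueError("exactly four strand ranges are required")
        if self.n_repeats < 2:
            raise ValueError("n_repeats must be >= 2")
        prev_end = 0
        for start, end in self.strand_ranges:
            if start <= prev_end or end < start:
                raise ValueError("strand ranges must be ordered, non-overlapping and 1-based")
            prev_end = end


def build_profile(alignment: RepeatAlignment | Sequence[str]) -> PositionProfile:
    """Tally residues per column; frequencies exclude gaps from the denominator.

    Raises AlignmentError on mixed lengths or an all-gap column and
    AlphabetError on non-standard symbols.
    """
    if not isinstance(alignment, RepeatAlignment):
        alignment = RepeatAlignment.from_sequences(alignment)
    counts: list[dict[str, int]] = []
    freqs: list[dict[str, float]] = []
    for j in range(alignment.repeat_length):
        col = Counter(s[j] for s in alignment.sequences)
        col.pop(GAP, None)
        total = sum(col.values())
        if total == 0:
            raise AlignmentError(f"column {j + 1} contains only gaps")
        counts.append(dict(col))
        freqs.append({r: c / total for r, c in col.items()})
    return PositionProfile(
        counts=tuple(counts), columns=tuple(freqs),
        n_sequences=len(alignment.sequences),
    )


def consensus_sequence(
    profile: PositionProfile,
    overrides: Mapping[int, str] | None = None,
    tie_policy: str = "background",
    background: Mapping[str, float] | None = None,
) -> ConsensusResult:
    """Emit the per-column modal residue, recording exact frequency ties.

    Ties are resolved, in order of precedence, by `overrides`
    (1-based position -> residue; overrides always win, tied or not), then by
    the tie policy: "background" picks the tied residue with the highest
    background frequency (uniform background falls back to alphabetical
    order, which keeps the result deterministic), while "strict" raises
    UnresolvedTieError listing every unresolved position.
    """
    overrides = dict(overrides or {})
    for pos, res in overrides.items():
        if not 1 <= pos <= profile.length:
            raise ValueError(f"override position {pos} outside repeat length {profile.length}")
        if res.upper() not in AMINO_ACIDS:
            raise AlphabetError(f"override residue {res!r} is not a standard amino acid")
    if tie_policy not in ("background", "strict"):
        raise ValueError(f"unknown tie policy {tie_policy!r}")

    out: list[str] = []
    ties: list[tuple[int, frozenset[str]]] = []
    applied: list[tuple[int, str]] = []
    unresolved: list[int] = []
    for pos in range(1, profile.length + 1):
        modal = profile.modal_residues(pos)
        if len(modal) > 1:
            ties.append((pos, modal))
        if pos in overrides:
            res = overrides[pos].upper()
            applied.append((pos, res))
        elif len(modal) == 1:
            (res,) = modal
        elif tie_policy == "strict":
            unresolved.append(pos)
            res = "?"
        else:
            bg = background or {}
            # highest background frequency wins; alphabetical as final tiebreak
            res = max(sorted(modal), key=lambda r: bg.get(r, 0.0))
        out.append(res)
    if unresolved:
        raise UnresolvedTieError(unresolved)
    return ConsensusResult(
        sequence="".join(out), ties=tuple(ties), overrides_applied=tuple(applied)
    )


def column_information_content(
    profile: PositionProfile,
    background: str | Mapping[str, float] = "uniform",
) -> list[float]:
    """Per-column information content in bits.

    Under the uniform background this is log2(20) minus the Shannon entropy
    of the column; under an explicit background it is the Kullback-Leibler
    divergence from the background, the usual relative-entropy logo height.
    """
    if background == "uniform":
        bg = {r: 1.0 / len(AMINO_ACIDS) for r in AMINO_ACIDS}
    else:
        bg = dict(background)
        if abs(sum(bg.values()) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
    bits = []
    for col in profile.columns:
        ic = 0.0
        for r, f in col.items():
            if f > 0:
                ic += f * math.log2(f / bg[r])
        bits.append(ic)
    return bits


def percent_identity(seq_a: str, seq_b: str, digits: int | None = 0) -> float:
    """100 x matches / length for two ungapped, equal-length sequences.

    Rounded to `digits` decimals (default nearest integer); pass None for
    the unrounded value.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise ValueError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty sequences")
    pid = 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)
    return pid if digits is None else round(pid, digits) if digits else round(pid)


def _cut_index(spec: PermutantSpec) -> int:
    """0-based index within the repeat of the new N-terminal (cut) residue.

    The cut point is the last loop residue before the target strand, so the
    residue removed afterwards is always a loop residue, never part of a
    strand.
    """
    k = VELCRO_KINDS[spec.velcro]
    strand_start = spec.strand_ranges[k - 1][0]  # 1-based
    if k == 1:
        prev_end = 0
    else:
        prev_end = spec.strand_ranges[k - 2][1]
    if strand_start - 1 <= prev_end:
        raise ValueError(
            f"no loop residue before strand {k} (strand starts at {strand_start}, previous strand ends at {prev_end})"
        )
    return strand_start - 2  # last loop residue, 0-based


def make_circular_permutant(
    tandem_sequence: str,
    spec: PermutantSpec,
    delete: bool = True,
) -> str:
    """Circularly permute a tandem-repeat sequence to the requested Velcro.

    Rotates the full sequence left so the new N-terminus is the loop residue
    immediately preceding the target strand, then deletes that residue (the
    paper-style close-termini relief; disable with delete=False).  Under the
    "prefer-glycine" policy the deleted residue must be glycine; an explicit
    integer policy names the repeat position to delete instead and must
    match the cut residue.
    """
    seq = tandem_sequence.upper()
    repeat_length = spec.repeat_length or (len(seq) // spec.n_repeats)
    if len(seq) != spec.n_repeats * repeat_length:
        raise ValueError(
            f"tandem length {len(seq)} != n_repeats {spec.n_repeats} x repeat_length {repeat_length}"
        )
    for _, end in spec.strand_ranges:
        if end > repeat_length:
            raise ValueError("strand range exceeds repeat length")
    cut = _cut_index(spec)
    rotated = seq[cut:] + seq[:cut]
    if not delete:
        return rotated
    removed = rotated[0]
    if spec.deletion_policy == "prefer-glycine":
        if removed != "G":
            raise DeletionPolicyError(
                f"cut residue at repeat position {cut + 1} is {removed}, not Gly; "
                "supply an explicit deletion position for this variant"
            )
    elif isinstance(spec.deletion_policy, int):
        if spec.deletion_policy != cut + 1:
            raise DeletionPolicyError(
                f"explicit deletion position {spec.deletion_policy} does not match "
                f"the cut residue at repeat position {cut + 1}"
            )
    else:
        raise ValueError(f"unknown deletion policy {spec.deletion_policy!r}")
    return rotated[1:]


def strand_ownership(spec: PermutantSpec) -> tuple[int, int]:
    """(N-terminal, C-terminal) strand counts of the ring-closing blade.

    Cutting before strand k leaves strands k..4 of the closing blade on the
    N-terminal end of the chain and strands 1..k-1 on the C-terminal end.
    """
    k = VELCRO_KINDS[spec.velcro]
    return (4 - k + 1, k - 1)
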
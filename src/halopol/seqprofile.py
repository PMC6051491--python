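"""Sequence-level halophilicity statistics.

Halophilic proteins characteristically carry an excess of acidic surface
residues. This module quantifies that signature for a single protein:
charge composition and negative/positive ratios (whole-chain and per
domain), bulky vs. small hydrophobic side-chain classes, the acidic
positions unique to the query relative to a non-halophilic homolog in a
pairwise alignment, and the overlap of those positions with a per-residue
intrinsic-disorder probability track.

Conventions: acidic = {D, E} and basic = {R, K} only (no His, no pKa
model); X is tolerated in sequences but excluded from every numerator and
denominator; residue and domain coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "SequenceRecord",
    "DomainAnnotation",
    "ChargeProfile",
    "HydrophobicClasses",
    "DisorderTrack",
    "AlignedPair",
    "OverlapResult",
    "charge_composition",
    "domain_charge_profiles",
    "hydrophobic_classes",
    "unique_acidic_positions",
    "disorder_overlap",
]

ACIDIC = frozenset("DE")
BASIC = frozenset("RK")
BULKY = frozenset("FIL")
SMALL = frozenset("GAST")
_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class SequenceRecord:
    """A protein sequence over the 20-letter alphabet (X tolerated)."""

    id: str
    residues: str

    def __post_init__(self):
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValidationError("residues", "sequence is empty")
        bad = set(self.residues) - _ALPHABET
        if bad:
            raise ValidationError("residues", f"invalid residue letters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class DomainAnnotation:
    """Named residue range, 1-based inclusive."""

    name: str
    start: int
    end: int

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValidationError("start", f"domain {self.name!r}: need 1 <= start <= end")


@dataclass
class ChargeProfile:
    n_acidic: int
    n_basic: int
    n_total: int
    pct_acidic: float
    pct_basic: float
    ratio_neg_pos: float | None  # None when n_basic == 0 (undefined)


@dataclass
class HydrophobicClasses:
    n_bulky: int
    n_small: int
    n_total: int
    pct_bulky: float
    pct_small: float


@dataclass
class DisorderTrack:
    """Per-residue disorder probabilities (e.g. a RONN output track)."""

    probabilities: np.ndarray
    threshold: float = 0.5

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.ndim != 1 or self.probabilities.size == 0:
            raise ValidationError("probabilities", "need a non-empty 1-D array")
        if np.any((self.probabilities < 0) | (self.probabilities > 1)):
            raise ValidationError("probabilities", "must be in [0, 1]")

    def __len__(self) -> int:
        return self.probabilities.size


@dataclass
class AlignedPair:
    """A pairwise alignment as a column list of 1-based positions or gaps.

    ``columns`` holds (query_pos | None, subject_pos | None) per alignment
    column. :meth:`from_gapped` builds it from two equal-length gapped
    strings (e.g. an aligned FASTA pair from any global aligner).
    """

    query_id: str
    subject_id: str
    columns: list[tuple[int | None, int | None]] = field(default_factory=list)

    def __post_init__(self):
        qprev = sprev = 0
        for q, s in self.columns:
            if q is None and s is None:
                raise ValidationError("columns", "all-gap alignment column")
            if q is not None:
                if q != qprev + 1:
                    raise ValidationError("columns", "query positions must be consecutive")
                qprev = q
            if s is not None:
                if s != sprev + 1:
                    raise ValidationError("columns", "subject positions must be consecutive")
                sprev = s

    @classmethod
    def from_gapped(
        cls, query_aln: str, subject_aln: str, query_id: str = "query", subject_id: str = "subject"
    ) -> "AlignedPair":
        if len(query_aln) != len(subject_aln):
            raise ValidationError("alignment", "gapped sequences differ in length")
        cols: list[tuple[int | None, int | None]] = []
        q = s = 0
        for a, b in zip(query_aln.upper(), subject_aln.upper()):
            qpos = spos = None
            if a != "-":
                q += 1
                qpos = q
            if b != "-":
                s += 1
                spos = s
            cols.append((qpos, spos))
        return cls(query_id=query_id, subject_id=subject_id, columns=cols)


@dataclass
class OverlapResult:
    """Fraction of tagged positions inside disordered regions.

    Percentages are None when the corresponding position set is empty
    (undefined, not zero).
    """

    pct_overall: float | None
    pct_by_tag: dict[str, float | None]
    n_positions: int


def _counted(residues: Iterable[str]) -> list[str]:
    return [r for r in residues if r != "X"]


def charge_composition(seq: SequenceRecord | str) -> ChargeProfile:
    """Acidic (D+E) and basic (R+K) counts, percentages and their ratio.

    The ratio is None (undefined) when the sequence has no basic residues;
    counts and percentages are still returned.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else SequenceRecord("q", seq).residues
    counted = _counted(residues)
    n = len(counted)
    if n == 0:
        raise ValidationError("residues", "no countable residues (all X)")
    n_acidic = sum(r in ACIDIC for r in counted)
    n_basic = sum(r in BASIC for r in counted)
    return ChargeProfile(
        n_acidic=n_acidic,
        n_basic=n_basic,
        n_total=n,
        pct_acidic=n_acidic / n * 100.0,
        pct_basic=n_basic / n * 100.0,
        ratio_neg_pos=n_acidic / n_basic if n_basic > 0 else None,
    )


def domain_charge_profiles(
    seq: SequenceRecord, domains: Sequence[DomainAnnotation]
) -> dict[str, ChargeProfile]:
    """Charge composition restricted to each annotated domain."""
    out: dict[str, ChargeProfile] = {}
    for dom in domains:
        if dom.end > len(seq):
            raise ValidationError("domains", f"domain {dom.name!r} extends past the sequence end")
        out[dom.name] = charge_composition(seq.residues[dom.start - 1 : dom.end])
    return out


def hydrophobic_classes(seq: SequenceRecord | str) -> HydrophobicClasses:
    """Bulky (F, I, L) vs. small (G, A, S, T) hydrophobic side-chain counts."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else SequenceRecord("q", seq).residues
    counted = _counted(residues)
    n = len(counted)
    if n == 0:
        raise ValidationError("residues", "no countable residues (all X)")
    n_bulky = sum(r in BULKY for r in counted)
    n_small = sum(r in SMALL for r in counted)
    return HydrophobicClasses(
        n_bulky=n_bulky,
        n_small=n_small,
        n_total=n,
        pct_bulky=n_bulky / n * 100.0,
        pct_small=n_small / n * 100.0,
    )


def unique_acidic_positions(
    pair: AlignedPair,
    query: SequenceRecord,
    subject: SequenceRecord,
    count_gap_columns: bool = True,
) -> list[tuple[int, str]]:
    """Query positions whose acidic residue has no acidic counterpart.

    Returns (position, 'D'|'E') for every query position whose residue is
    Asp/Glu while the aligned subject residue is not. Query residues aligned
    to a subject gap (e.g. a halophilic acidic insert) count as unique by
    default; set ``count_gap_columns=False`` to require an aligned,
    non-acidic subject residue.
    """
    n_q = max((q for q, _ in pair.columns if q is not None), default=0)
    n_s = max((s for _, s in pair.columns if s is not None), default=0)
    if n_q > len(query) or n_s > len(subject):
        raise ValidationError("pair", "alignment refers to positions beyond a sequence end")
    out: list[tuple[int, str]] = []
    for qpos, spos in pair.columns:
        if qpos is None:
            continue
        q_res = query.residues[qpos - 1]
        if q_res not in ACIDIC:
            continue
        if spos is None:
            if count_gap_columns:
                out.append((qpos, q_res))
        elif subject.residues[spos - 1] not in ACIDIC:
            out.append((qpos, q_res))
    return out


def disorder_overlap(
    positions: Sequence[tuple[int, str]], track: DisorderTrack
) -> OverlapResult:
    """Percentage of tagged positions falling in disordered regions.

    A position is "in disorder" when its track probability is >= the track
    threshold. Empty position sets yield None (not applicable) rather
    than 0.
    """
    for pos, _ in positions:
        if not 1 <= pos <= len(track):
            raise ValidationError("positions", f"position {pos} beyond the disorder track")
    tags = sorted({tag for _, tag in positions})

    def pct(subset: list[int]) -> float | None:
        if not subset:
            return None
        hits = sum(track.probabilities[p - 1] >= track.threshold for p in subset)
        return hits / len(subset) * 100.0

    return OverlapResult(
        pct_overall=pct([p for p, _ in positions]),
        pct_by_tag={tag: pct([p for p, t in positions if t == tag]) for tag in tags},
        n_positions=len(positions),
    )
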
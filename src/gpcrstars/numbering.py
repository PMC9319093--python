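"""Ballesteros–Weinstein generic numbering for GPCR residues.

Class A GPCR positions are addressed as ``segment.position`` where segment is
a transmembrane helix (1–7) or an inter-helix loop (12, 23, 34, 45, 56, 67)
and position 50 marks the most conserved residue of the segment (the anchor).
Within a segment, numbering is a pure offset from the anchor: residue
``anchor_seqnum + k`` carries position ``50 + k``.  Loop segments (e.g. the
EL2 cysteine at 45.50) follow the same anchor convention.

The module builds a bijective :class:`NumberingMap` from a per-segment
:class:`AnchorSet` so geometry code can address residues as ``"3.50"``
instead of raw author numbers.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

__all__ = [
    "ResidueID",
    "GenericNumber",
    "SegmentSpan",
    "AnchorSet",
    "NumberingMap",
    "build_numbering",
    "load_anchors",
    "gpr18_anchors",
]

#: Valid segment labels: TM1–TM7 plus the six inter-helix loops.
VALID_SEGMENTS = frozenset({1, 2, 3, 4, 5, 6, 7, 12, 23, 34, 45, 56, 67})


@dataclass(frozen=True, order=True)
class ResidueID:
    """Author residue identity: chain, 1-based sequence number, insertion code."""

    chain: str = "A"
    seqnum: int = 1
    icode: str = ""

    def __post_init__(self) -> None:
        if len(self.chain) != 1:
            raise ValueError(f"chain must be a single character, got {self.chain!r}")
        if self.seqnum < 1:
            raise ValueError(f"seqnum must be >= 1, got {self.seqnum}")

    def __str__(self) -> str:
        return f"{self.chain}:{self.seqnum}{self.icode}"


@dataclass(frozen=True, order=True)
class GenericNumber:
    """A generic position rendered as ``segment.position`` (e.g. 3.50)."""

    segment: int
    position: int

    def __post_init__(self) -> None:
        if self.segment not in VALID_SEGMENTS:
            raise ValueError(f"unknown segment label {self.segment}")
        if not 1 <= self.position <= 99:
            raise ValueError(f"position must lie in [1, 99], got {self.position}")

    def __str__(self) -> str:
        return f"{self.segment}.{self.position}"

    @classmethod
    def parse(cls, text: str) -> "GenericNumber":
        seg, _, pos = text.partition(".")
        return cls(int(seg), int(pos))


@dataclass(frozen=True)
class SegmentSpan:
    """Residue span of one segment with its X.50 anchor residue."""

    segment: int
    start: int
    end: int
    anchor: int

    def __post_init__(self) -> None:
        if self.segment not in VALID_SEGMENTS:
            raise ValueError(f"unknown segment label {self.segment}")
        if not self.start <= self.end:
            raise ValueError(f"segment {self.segment}: start {self.start} > end {self.end}")
        if not self.start <= self.anchor <= self.end:
            raise ValueError(
                f"segment {self.segment}: anchor {self.anchor} outside span "
                f"[{self.start}, {self.end}]"
            )
        # Offset arithmetic must stay inside the 1–99 position window.
        for seq in (self.start, self.end):
            pos = 50 + seq - self.anchor
            if not 1 <= pos <= 99:
                raise ValueError(
                    f"segment {self.segment}: residue {seq} maps to position {pos}, "
                    "outside [1, 99]"
                )


@dataclass(frozen=True)
class AnchorSet:
    """Ordered collection of disjoint segment spans."""

    spans: tuple[SegmentSpan, ...]

    def __post_init__(self) -> None:
        spans = sorted(self.spans, key=lambda s: s.start)
        prev = None
        for span in spans:
            if prev is not None and span.start <= prev.end:
                raise ValueError(
                    f"segments {prev.segment} and {span.segment} overlap "
                    f"({prev.start}-{prev.end} vs {span.start}-{span.end})"
                )
            prev = span
        seen = set()
        for span in self.spans:
            if span.segment in seen:
                raise ValueError(f"segment {span.segment} declared twice")
            seen.add(span.segment)
        object.__setattr__(self, "spans", tuple(spans))


class NumberingMap:
    """Bijection between :class:`ResidueID` and :class:`GenericNumber`.

    Within each segment ``seqnum − anchor_seqnum == position − 50``.
    """

    def __init__(self, anchors: AnchorSet, chain: str = "A") -> None:
        self.anchors = anchors
        self.chain = chain
        self._to_gn: dict[ResidueID, GenericNumber] = {}
        self._to_res: dict[GenericNumber, ResidueID] = {}
        for span in anchors.spans:
            for seq in range(span.start, span.end + 1):
                rid = ResidueID(chain, seq)
                gn = GenericNumber(span.segment, 50 + seq - span.anchor)
                self._to_gn[rid] = gn
                self._to_res[gn] = rid

    def __len__(self) -> int:
        return len(self._to_gn)

    def __contains__(self, key: Union[ResidueID, GenericNumber, str]) -> bool:
        if isinstance(key, str):
            key = GenericNumber.parse(key)
        if isinstance(key, GenericNumber):
            return key in self._to_res
        return key in self._to_gn

    def generic_number(self, residue: Union[ResidueID, int]) -> GenericNumber:
        """Generic number of a residue; raises ``KeyError`` if uncovered."""
        if isinstance(residue, int):
            residue = ResidueID(self.chain, residue)
        try:
            return self._to_gn[residue]
        except KeyError:
            raise KeyError(f"residue {residue} is not covered by any segment span") from None

    def lookup(self, gn: Union[GenericNumber, str]) -> ResidueID:
        """Residue carrying generic number *gn*; raises ``KeyError`` if absent."""
        if isinstance(gn, str):
            try:
                gn = GenericNumber.parse(gn)
            except ValueError:
                raise KeyError(f"generic number {gn} is not present in the numbering map") from None
        try:
            return self._to_res[gn]
        except KeyError:
            raise KeyError(f"generic number {gn} is not present in the numbering map") from None

    def residues(self) -> Iterable[ResidueID]:
        return self._to_gn.keys()


def build_numbering(anchors: AnchorSet, chain: str = "A") -> NumberingMap:
    """Expand an anchor set into the full residue ↔ generic-number bijection."""
    return NumberingMap(anchors, chain=chain)


def load_anchors(path: Union[str, Path]) -> AnchorSet:
    """Read an anchor annotation file (JSON or CSV).

    JSON layout: ``{"segments": [{"segment": 3, "start": 94, "end": 126,
    "anchor": 119}, ...]}``.  CSV uses the same four column names.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        rows = payload["segments"]
    else:
        with path.open(newline="") as fh:
            rows = list(csv.DictReader(fh))
    spans = tuple(
        SegmentSpan(
            segment=int(r["segment"]),
            start=int(r["start"]),
            end=int(r["end"]),
            anchor=int(r["anchor"]),
        )
        for r in rows
    )
    return AnchorSet(spans)


def gpr18_anchors() -> AnchorSet:
    """The packaged GPR18 anchor annotation (all segments, literature anchors)."""
    from importlib.resources import files

    return load_anchors(Path(str(files("gpcrstars.data") / "gpr18_anchors.json")))
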
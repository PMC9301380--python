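"""Human TRD germline segments used for junction decomposition.

The CDR3delta junction runs from the conserved V-segment cysteine (C104,
IMGT numbering) through the conserved J-segment phenylalanine/tryptophan
(F/W118), both inclusive.  Decomposing a junction into germline-attributable
and inserted nucleotides therefore only needs the junction-proximal ends of
the segments: the 3' tail of TRDV2 starting at the C104 codon, the complete
(short) TRDD segments, and the 5' head of each TRDJ up to and including the
F118 codon.

The reference ships as in-repo constants (reference alleles *01 only;
allele-level polymorphism is irrelevant at the region-level resolution of
the analyses here).  Coordinates are 0-based, half-open; anchor offsets
point at the first nucleotide of the anchor codon.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio.Seq import Seq

__all__ = [
    "GermlineSegment",
    "GermlineReference",
    "GermlineError",
    "UnknownSegmentError",
    "load_reference",
    "j_region_of",
]

_DNA = frozenset("ACGT")


class GermlineError(ValueError):
    """Corrupt or inconsistent germline fixture."""


class UnknownSegmentError(KeyError):
    """A segment identifier that does not name a packaged TRD segment."""


@dataclass(frozen=True)
class GermlineSegment:
    """One germline TRD segment (junction-proximal region).

    ``junction_anchor_offset`` is the 0-based offset of the first nucleotide
    of the conserved anchor codon (C104 for V, F/W118 for J); D segments
    have no anchor and carry ``None``.
    """

    segment_id: str
    segment_class: str  # "V", "D" or "J"
    nt_sequence: str
    aa_tail_or_head: str
    junction_anchor_offset: int | None


# Junction-proximal regions, reference alleles *01.
# TRDV2 tail: ...A Y Y C A C D T with the C104 codon at offset 9; the
# germline-encoded junction prefix is therefore CACDT.  The TRDD segments
# are complete.  TRDJ heads are given through the F118 codon plus the start
# of FR4; translation frames start after the leading partial codon.
_RAW_SEGMENTS: tuple[tuple[str, str, str, int, int], ...] = (
    # (segment_id, class, nt, frame_offset, anchor_offset)
    ("TRDV2*01", "V", "GCCTATTACTGTGCCTGTGACACC", 0, 9),
    ("TRDD1*01", "D", "GAAATAGT", 0, -1),
    ("TRDD2*01", "D", "CCTTCCTAC", 0, -1),
    ("TRDD3*01", "D", "ACTGGGGGATACG", 1, -1),
    ("TRDJ1*01", "J", "ACACCGATAAACTCATCTTTGGAAAAGGAACCCGTGTGACTGTGGAACCAA", 2, 17),
    ("TRDJ2*01", "J", "GGTTGACCGCACAGCTCTTCTTTGGAAAAGGAACCCAACTGATCGTGGAACCA", 2, 20),
    ("TRDJ3*01", "J", "CTCCTGGGACACCCGACAGATGTTTTTCGGGACAGGGATTGAGTTGTTTGTTGAGCCA", 1, 25),
    ("TRDJ4*01", "J", "CCCGGCCTTCCTCGGACAAGCTCATCTTTGGAAAAGGCACCCGTCTGATCGTCCATCCG", 2, 26),
)


def _translate(nt: str) -> str:
    return str(Seq(nt).translate())


def _build_segment(segment_id: str, cls: str, nt: str, frame: int, anchor: int) -> GermlineSegment:
    if not nt or set(nt) - _DNA:
        raise GermlineError(f"{segment_id}: nt_sequence must be non-empty A/C/G/T")
    n_codons = (len(nt) - frame) // 3
    aa = _translate(nt[frame : frame + 3 * n_codons])
    if "*" in aa:
        raise GermlineError(f"{segment_id}: stop codon in junction-proximal region")
    anchor_offset = anchor if anchor >= 0 else None
    if cls == "V":
        if anchor_offset is None or _translate(nt[anchor_offset : anchor_offset + 3]) != "C":
            raise GermlineError(f"{segment_id}: V anchor codon does not translate to C")
    elif cls == "J":
        if anchor_offset is None or _translate(nt[anchor_offset : anchor_offset + 3]) not in ("F", "W"):
            raise GermlineError(f"{segment_id}: J anchor codon does not translate to F/W")
    elif cls != "D":
        raise GermlineError(f"{segment_id}: unknown segment class {cls!r}")
    return GermlineSegment(segment_id, cls, nt, aa, anchor_offset)


_J_CALL_RE = re.compile(r"^TRDJ([1-4])(\*\d+)?$")


class GermlineReference(Mapping[str, GermlineSegment]):
    """Immutable collection of the packaged TRD segments."""

    __hash__ = object.__hash__  # identity hash (reference content is immutable)

    def __init__(self, segments: Iterable[GermlineSegment]):
        self._segments = {s.segment_id: s for s in segments}

    def __getitem__(self, segment_id: str) -> GermlineSegment:
        try:
            return self._segments[segment_id]
        except KeyError:
            raise UnknownSegmentError(segment_id) from None

    def __iter__(self):
        return iter(self._segments)

    def __len__(self) -> int:
        return len(self._segments)

    # -- junction-facing views -------------------------------------------------

    def v_junction_region(self) -> str:
        """Germline V nucleotides from the C104 codon to the segment 3' end."""
        v = self["TRDV2*01"]
        assert v.junction_anchor_offset is not None
        return v.nt_sequence[v.junction_anchor_offset :]

    def j_junction_region(self, j_region: str) -> str:
        """Germline J nucleotides from the segment 5' end through F/W118."""
        j = self[f"TRDJ{j_region[-1]}*01"] if j_region.startswith("J") else self[j_region]
        assert j.junction_anchor_offset is not None
        return j.nt_sequence[: j.junction_anchor_offset + 3]

    def j_head_aa(self, j_region: str) -> str:
        """Translated J head through the anchor (in the segment's frame)."""
        region = self.j_junction_region(j_region)
        frame = len(region) % 3
        return _translate(region[frame:])

    def d_segments(self) -> list[GermlineSegment]:
        return sorted(
            (s for s in self._segments.values() if s.segment_class == "D"),
            key=lambda s: s.segment_id,
        )

    def j_regions(self) -> list[str]:
        return sorted(
            f"J{s.segment_id[4]}" for s in self._segments.values() if s.segment_class == "J"
        )

    # -- audit I/O -------------------------------------------------------------

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for sid in sorted(self._segments):
                fh.write(f">{sid}\n{self._segments[sid].nt_sequence}\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GermlineReference":
        layout = {row[0]: row for row in _RAW_SEGMENTS}
        segments = []
        header = None
        chunks: list[str] = []
        with open(path, encoding="utf-8") as fh:
            for line in list(fh) + [">"]:
                line = line.strip()
                if line.startswith(">"):
                    if header is not None:
                        if header not in layout:
                            raise UnknownSegmentError(header)
                        _, seg_cls, _, frame, anchor = layout[header]
                        nt = "".join(chunks).upper()
                        segments.append(_build_segment(header, seg_cls, nt, frame, anchor))
                    header, chunks = line[1:].split()[0] if line[1:] else None, []
                else:
                    chunks.append(line)
        return cls(segments)


_CANONICAL = tuple(_build_segment(*row) for row in _RAW_SEGMENTS)


def load_reference() -> GermlineReference:
    """Load the packaged TRD reference (validated; immutable; no network)."""
    return GermlineReference(_CANONICAL)


def j_region_of(j_call: str) -> str:
    """Map a TRDJ segment call (allele suffix optional) to its region label.

    >>> j_region_of("TRDJ1*01")
    'J1'
    """
    m = _J_CALL_RE.match(j_call.strip())
    if not m:
        raise UnknownSegmentError(f"not a TRDJ segment call: {j_call!r}")
    return f"J{m.group(1)}"
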
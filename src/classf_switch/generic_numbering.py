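"""Generic (Ballesteros–Weinstein-style) residue numbering for 7TM receptors.

Class F receptors (FZD1-10, SMO) are compared across paralogs using generic
labels of the form ``helix.offset`` (e.g. ``6.32`` = transmembrane helix 6,
relative position 32).  A :class:`SegmentMap` anchors each helix to a span of
1-based sequence positions; labels within a helix are consecutive sequence
offsets from the anchor, with no structure-based bulge correction.

Labels can be propagated from a reference receptor across a multiple sequence
alignment so that a family-wide analysis (e.g. mutation counting) can pool
positions that share a generic label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "GenericLabel",
    "HelixSegment",
    "SegmentMap",
    "UnmappedPositionError",
    "UnmappedLabelError",
    "propagate_labels",
]


class UnmappedPositionError(KeyError):
    """A sequence position falls outside every mapped helix segment."""


class UnmappedLabelError(KeyError):
    """A generic label falls outside every mapped helix segment."""


@dataclass(frozen=True, order=True)
class GenericLabel:
    """A generic residue label ``helix.offset``, e.g. 6.32.

    ``helix`` runs 1-7 for the transmembrane helices and 8 for helix 8;
    ``offset`` is the (two-digit) position within the helix.
    """

    helix: int
    offset: int

    def __post_init__(self) -> None:
        if not 1 <= self.helix <= 8:
            raise ValueError(f"helix must be in 1..8, got {self.helix}")
        if self.offset < 1:
            raise ValueError(f"offset must be >= 1, got {self.offset}")

    def __str__(self) -> str:
        return f"{self.helix}.{self.offset:02d}"

    @classmethod
    def parse(cls, text: str) -> "GenericLabel":
        """Parse ``"6.32"`` into ``GenericLabel(6, 32)``."""
        try:
            helix_s, offset_s = str(text).strip().split(".")
            return cls(int(helix_s), int(offset_s))
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"not a generic label: {text!r}") from exc

    def shifted(self, delta: int) -> "GenericLabel":
        return GenericLabel(self.helix, self.offset + delta)


@dataclass(frozen=True)
class HelixSegment:
    """A contiguous run of labelled residues in one helix.

    ``seq_start``/``seq_end`` are 1-based sequence positions (author
    numbering, matching PDB resSeq); ``label_start`` is the generic label of
    ``seq_start`` and labels increase by one per residue to ``seq_end``.
    """

    helix: int
    seq_start: int
    seq_end: int
    label_start: GenericLabel

    def __post_init__(self) -> None:
        if self.seq_end < self.seq_start:
            raise ValueError(
                f"seq_end {self.seq_end} < seq_start {self.seq_start}"
            )
        if self.label_start.helix != self.helix:
            raise ValueError(
                f"label_start helix {self.label_start.helix} != segment helix {self.helix}"
            )

    @property
    def label_end(self) -> GenericLabel:
        return self.label_start.shifted(self.seq_end - self.seq_start)

    def __len__(self) -> int:
        return self.seq_end - self.seq_start + 1

    def contains_position(self, position: int) -> bool:
        return self.seq_start <= position <= self.seq_end

    def contains_label(self, label: GenericLabel) -> bool:
        return (
            label.helix == self.helix
            and self.label_start.offset <= label.offset <= self.label_end.offset
        )


@dataclass(frozen=True)
class SegmentMap:
    """All residue <-> generic-label correspondences for one receptor.

    Segments must not overlap in sequence coordinates, and within a helix
    their label (offset) ranges must be disjoint and ordered consistently
    with the sequence.  A helix may be split into several segments: label
    propagation across an alignment with a mid-helix insertion produces
    exactly that shape.
    """

    receptor_id: str
    segments: tuple[HelixSegment, ...]
    sequence: str | None = None

    def __post_init__(self) -> None:
        segs = tuple(sorted(self.segments, key=lambda s: s.seq_start))
        object.__setattr__(self, "segments", segs)
        for a, b in zip(segs, segs[1:]):
            if b.seq_start <= a.seq_end:
                raise ValueError(
                    f"segments overlap in sequence: {a} / {b}"
                )
        by_helix: dict[int, list[HelixSegment]] = {}
        for s in segs:
            by_helix.setdefault(s.helix, []).append(s)
        for helix, group in by_helix.items():
            for a, b in zip(group, group[1:]):
                if b.label_start.offset <= a.label_end.offset:
                    raise ValueError(
                        f"helix {helix} label ranges overlap or run backwards: {a} / {b}"
                    )
        if self.sequence is not None:
            for s in segs:
                if s.seq_end > len(self.sequence):
                    raise ValueError(
                        f"segment {s} extends past sequence length {len(self.sequence)}"
                    )

    def assign_label(self, position: int) -> GenericLabel:
        """Generic label of a 1-based sequence position.

        Raises :class:`UnmappedPositionError` for positions outside every
        segment (loops, termini).
        """
        for s in self.segments:
            if s.contains_position(position):
                return s.label_start.shifted(position - s.seq_start)
        raise UnmappedPositionError(
            f"unmapped position {position} in receptor {self.receptor_id}"
        )

    def label_to_position(self, label: GenericLabel | str) -> int:
        """Inverse of :meth:`assign_label`."""
        if isinstance(label, str):
            label = GenericLabel.parse(label)
        for s in self.segments:
            if s.contains_label(label):
                return s.seq_start + (label.offset - s.label_start.offset)
        raise UnmappedLabelError(
            f"unmapped label {label} in receptor {self.receptor_id}"
        )

    def is_mapped(self, position: int) -> bool:
        return any(s.contains_position(position) for s in self.segments)

    def labels(self) -> list[GenericLabel]:
        """All labels of the map, in sequence order."""
        out: list[GenericLabel] = []
        for s in self.segments:
            out.extend(s.label_start.shifted(i) for i in range(len(s)))
        return out

    def positions(self) -> list[int]:
        out: list[int] = []
        for s in self.segments:
            out.extend(range(s.seq_start, s.seq_end + 1))
        return out

    def with_receptor_id(self, receptor_id: str) -> "SegmentMap":
        return replace(self, receptor_id=receptor_id)


def _segments_from_pairs(
    pairs: list[tuple[int, GenericLabel]]
) -> tuple[HelixSegment, ...]:
    """Compress (position, label) pairs into maximal consecutive segments."""
    pairs = sorted(pairs)
    segments: list[HelixSegment] = []
    run: list[tuple[int, GenericLabel]] = []
    for pos, label in pairs:
        if run:
            prev_pos, prev_label = run[-1]
            consecutive = (
                pos == prev_pos + 1
                and label.helix == prev_label.helix
                and label.offset == prev_label.offset + 1
            )
            if not consecutive:
                segments.append(
                    HelixSegment(run[0][1].helix, run[0][0], run[-1][0], run[0][1])
                )
                run = []
        run.append((pos, label))
    if run:
        segments.append(
            HelixSegment(run[0][1].helix, run[0][0], run[-1][0], run[0][1])
        )
    return tuple(segments)


def _as_sequence_mapping(msa) -> dict[str, str]:
    """Accept a Bio.Align.MultipleSeqAlignment or a {id: gapped_seq} mapping."""
    if hasattr(msa, "items"):
        return {str(k): str(v) for k, v in msa.items()}
    return {rec.id: str(rec.seq) for rec in msa}


def propagate_labels(
    msa,
    reference_id: str,
    reference_map: SegmentMap,
) -> dict[str, SegmentMap]:
    """Propagate the reference receptor's labels across an alignment.

    Every alignment column whose reference residue carries a generic label
    transfers that label to each target sequence's ungapped position in that
    column; columns where the target has a gap contribute nothing (no
    interpolation across gaps).

    Parameters
    ----------
    msa
        Aligned sequences: a ``Bio.Align.MultipleSeqAlignment`` or a mapping
        of sequence id to gapped sequence string.
    reference_id
        Id of the reference sequence within the alignment.
    reference_map
        SegmentMap of the reference (positions refer to its ungapped
        sequence).

    Returns
    -------
    dict mapping each sequence id (including the reference) to its
    propagated :class:`SegmentMap`.
    """
    seqs = _as_sequence_mapping(msa)
    if reference_id not in seqs:
        raise KeyError(f"reference_id {reference_id!r} not present in alignment")
    ref = seqs[reference_id]
    ref_len = sum(1 for c in ref if c != "-")
    max_mapped = max((s.seq_end for s in reference_map.segments), default=0)
    if max_mapped > ref_len:
        raise ValueError(
            f"reference map extends to position {max_mapped} but ungapped "
            f"reference has only {ref_len} residues"
        )

    # label of each alignment column, where the reference is mapped
    column_labels: dict[int, GenericLabel] = {}
    ref_pos = 0
    for col, char in enumerate(ref):
        if char == "-":
            continue
        ref_pos += 1
        if reference_map.is_mapped(ref_pos):
            column_labels[col] = reference_map.assign_label(ref_pos)

    out: dict[str, SegmentMap] = {}
    for seq_id, gapped in seqs.items():
        pairs: list[tuple[int, GenericLabel]] = []
        pos = 0
        for col, char in enumerate(gapped):
            if char == "-":
                continue
            pos += 1
            label = column_labels.get(col)
            if label is not None:
                pairs.append((pos, label))
        out[seq_id] = SegmentMap(
            receptor_id=seq_id,
            segments=_segments_from_pairs(pairs),
            sequence=gapped.replace("-", "") or None,
        )
    return out
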
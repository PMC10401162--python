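"""BIOES encoding of protein motif/domain/region annotations.

UniProt-style sequence features (motifs, domains, regions of interest)
are span annotations over an amino-acid sequence.  For token-level
learning objectives each residue is tagged in the BIOES scheme:

* a span of length 1 → ``S-<Category>`` (single)
* a span of length ≥ 2 → ``B-<Category>``, ``I-<Category>``*, ``E-<Category>``
* residues outside any span → ``O``

Coordinates are 1-based inclusive, matching the UniProt feature
convention; internal arrays convert at the boundary.  Each annotation
kind (motif / domain / region) is encoded on its own tag track since
categories are kind-qualified (``Motif1``, ``Domain2``): spans of
different kinds may overlap, spans of the same kind may not.  A combined
single-track encoding is available but errors on cross-kind overlap.

Category inventories in real corpora are heavily long-tailed; rare
categories below a count threshold are merged into a sentinel ``Other``
category by :func:`merge_long_tail`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .exceptions import DecodingError, EncodingError, ParseError

__all__ = [
    "KINDS",
    "OTHER_CATEGORY",
    "Span",
    "AnnotatedSequence",
    "BIOESTagSequence",
    "CategoryVocabulary",
    "encode_bioes",
    "encode_bioes_combined",
    "decode_bioes",
    "merge_long_tail",
    "read_annotations",
    "write_tags",
    "read_tags",
]

KINDS = ("motif", "domain", "region")
OTHER_CATEGORY = "Other"


@dataclass(frozen=True)
class Span:
    """A 1-based inclusive entity span."""

    start: int
    end: int
    category: str
    kind: str = "motif"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind {self.kind!r} not in {KINDS}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"need 1 ≤ start ≤ end, got [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotatedSequence:
    """An amino-acid sequence with its entity span annotations."""

    sequence: str
    entities: list[Span] = field(default_factory=list)
    sequence_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        n = len(self.sequence)
        for sp in self.entities:
            if sp.end > n:
                raise EncodingError(
                    f"span [{sp.start}, {sp.end}] exceeds sequence length {n}"
                )
        for kind in KINDS:
            spans = sorted(
                (s for s in self.entities if s.kind == kind), key=lambda s: s.start
            )
            for prev, cur in zip(spans, spans[1:]):
                if cur.start <= prev.end:
                    raise EncodingError(
                        f"overlapping {kind} spans [{prev.start},{prev.end}] and "
                        f"[{cur.start},{cur.end}]"
                    )


@dataclass
class BIOESTagSequence:
    """One tag per residue, each ``O`` or ``<P>-<Category>``, P ∈ BIES."""

    tags: list[str]

    def __post_init__(self) -> None:
        for i, t in enumerate(self.tags):
            if t == "O":
                continue
            if len(t) < 3 or t[0] not in "BIES" or t[1] != "-":
                raise ValueError(f"malformed tag {t!r} at position {i + 1}")

    def __len__(self) -> int:
        return len(self.tags)

    def __iter__(self):
        return iter(self.tags)


@dataclass
class CategoryVocabulary:
    """Retained categories after long-tail merging, plus the mapping.

    ``resolve`` sends retained categories to themselves and everything
    else (merged or unseen) to ``Other``.
    """

    categories: list[str]
    counts: dict[str, int]
    min_count: int = 0
    merged: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if OTHER_CATEGORY not in self.categories:
            self.categories = list(self.categories) + [OTHER_CATEGORY]

    def resolve(self, category: str) -> str:
        if category in self.merged:
            return self.merged[category]
        if category in self.categories:
            return category
        return OTHER_CATEGORY


def merge_long_tail(counts: dict[str, int], min_count: int) -> CategoryVocabulary:
    """Merge categories with fewer than ``min_count`` occurrences into
    the sentinel ``Other`` category."""
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be nonnegative")
    retained = [c for c, n in counts.items() if n >= min_count]
    merged = {c: OTHER_CATEGORY for c, n in counts.items() if n < min_count}
    return CategoryVocabulary(
        categories=retained, counts=dict(counts), min_count=min_count, merged=merged
    )


def _encode_track(
    seq: AnnotatedSequence, kind: str, vocab: CategoryVocabulary | None
) -> BIOESTagSequence:
    tags = ["O"] * len(seq.sequence)
    for sp in seq.entities:
        if sp.kind != kind:
            continue
        cat = vocab.resolve(sp.category) if vocab is not None else sp.category
        i, j = sp.start - 1, sp.end - 1  # to 0-based
        if sp.length == 1:
            tags[i] = f"S-{cat}"
        else:
            tags[i] = f"B-{cat}"
            for k in range(i + 1, j):
                tags[k] = f"I-{cat}"
            tags[j] = f"E-{cat}"
    return BIOESTagSequence(tags)


def encode_bioes(
    seq: AnnotatedSequence, vocab: CategoryVocabulary | None = None
) -> dict[str, BIOESTagSequence]:
    """Encode an annotated sequence as one BIOES tag track per kind.

    Categories are resolved through ``vocab`` when given (unknown or
    merged categories become ``Other``); with no vocabulary, categories
    pass through unchanged.
    """
    return {kind: _encode_track(seq, kind, vocab) for kind in KINDS}


def encode_bioes_combined(
    seq: AnnotatedSequence, vocab: CategoryVocabulary | None = None
) -> BIOESTagSequence:
    """Single-track encoding across all kinds; errors if spans of
    different kinds overlap (they cannot share one track)."""
    tags = ["O"] * len(seq.sequence)
    for kind in KINDS:
        track = _encode_track(seq, kind, vocab)
        for i, t in enumerate(track):
            if t == "O":
                continue
            if tags[i] != "O":
                raise EncodingError(
                    f"cross-kind overlap at position {i + 1}: {tags[i]} vs {t}"
                )
            tags[i] = t
    return BIOESTagSequence(tags)


def decode_bioes(
    tags: BIOESTagSequence | list[str], kind: str = "motif"
) -> list[Span]:
    """Recover entity spans from one BIOES tag track.

    Inverse of :func:`encode_bioes` on valid input; a grammar violation
    (I without B, dangling B, prefix/category mismatch) raises
    :class:`DecodingError` naming the 1-based position.
    """
    if isinstance(tags, BIOESTagSequence):
        tags = tags.tags
    spans: list[Span] = []
    open_start: int | None = None
    open_cat: str | None = None
    for idx, tag in enumerate(tags):
        pos = idx + 1
        if tag == "O":
            if open_start is not None:
                raise DecodingError(
                    f"position {pos}: O inside an open entity (missing E)", pos
                )
            continue
        if len(tag) < 3 or tag[1] != "-" or tag[0] not in "BIES":
            raise DecodingError(f"position {pos}: malformed tag {tag!r}", pos)
        prefix, cat = tag[0], tag[2:]
        if prefix == "S":
            if open_start is not None:
                raise DecodingError(f"position {pos}: S inside an open entity", pos)
            spans.append(Span(pos, pos, cat, kind))
        elif prefix == "B":
            if open_start is not None:
                raise DecodingError(f"position {pos}: B inside an open entity", pos)
            open_start, open_cat = pos, cat
        elif prefix == "I":
            if open_start is None:
                raise DecodingError(f"position {pos}: I without a preceding B", pos)
            if cat != open_cat:
                raise DecodingError(
                    f"position {pos}: category switch {open_cat!r} → {cat!r}", pos
                )
        else:  # E
            if open_start is None:
                raise DecodingError(f"position {pos}: E without a preceding B", pos)
            if cat != open_cat:
                raise DecodingError(
                    f"position {pos}: category switch {open_cat!r} → {cat!r}", pos
                )
            spans.append(Span(open_start, pos, cat, kind))
            open_start = open_cat = None
    if open_start is not None:
        raise DecodingError(
            f"position {len(tags)}: entity opened at {open_start} never closed",
            len(tags),
        )
    return spans


# ---------------------------------------------------------------------------
# TSV interfaces


def read_annotations(path: str | Path) -> list[AnnotatedSequence]:
    """Read annotations from a TSV with columns
    ``sequence_id  sequence  kind  category  start  end``.

    Rows with an empty kind/category declare an unannotated sequence.
    """
    path = Path(path)
    seqs: dict[str, str] = {}
    spans: dict[str, list[Span]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[:2] != ["sequence_id", "sequence"]:
            raise ParseError(f"{path}: line 1: bad header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 2:
                raise ParseError(f"{path}: line {lineno}: too few columns")
            sid, seq = row[0], row[1]
            if sid not in seqs:
                seqs[sid] = seq
                spans[sid] = []
                order.append(sid)
            elif seqs[sid] != seq:
                raise ParseError(
                    f"{path}: line {lineno}: sequence mismatch for {sid!r}"
                )
            if len(row) >= 6 and row[2]:
                try:
                    spans[sid].append(
                        Span(int(row[4]), int(row[5]), row[3], row[2])
                    )
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return [
        AnnotatedSequence(sequence=seqs[sid], entities=spans[sid], sequence_id=sid)
        for sid in order
    ]


def write_tags(
    path: str | Path,
    seq: AnnotatedSequence,
    tracks: dict[str, BIOESTagSequence],
    append: bool = False,
) -> None:
    """Write per-residue tags as TSV rows
    ``sequence_id  position  residue  <kind tags...>``."""
    path = Path(path)
    mode = "a" if append and path.exists() else "w"
    with open(path, mode, newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if mode == "w":
            writer.writerow(["sequence_id", "position", "residue", *tracks.keys()])
        for i, residue in enumerate(seq.sequence):
            writer.writerow(
                [seq.sequence_id, i + 1, residue]
                + [tracks[k].tags[i] for k in tracks]
            )


def read_tags(path: str | Path) -> dict[str, dict[str, BIOESTagSequence]]:
    """Read a tag TSV back into per-sequence, per-kind tag tracks."""
    path = Path(path)
    out: dict[str, dict[str, list[str]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[:3] != ["sequence_id", "position", "residue"]:
            raise ParseError(f"{path}: line 1: bad header {header}")
        kinds = header[3:]
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(f"{path}: line {lineno}: column count mismatch")
            sid = row[0]
            tracks = out.setdefault(sid, {k: [] for k in kinds})
            for k, tag in zip(kinds, row[3:]):
                tracks[k].append(tag)
    return {
        sid: {k: BIOESTagSequence(tags) for k, tags in tracks.items()}
        for sid, tracks in out.items()
    }
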
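"""AP-1/TRE motif scanning and promoter reporter-construct algebra.

The AP-1 complex binds the TPA-responsive element (TRE) consensus
TGA(C/G)TCA.  The two admissible words, TGACTCA and TGAGTCA, are reverse
complements of each other, so a single forward scan covers both strands:
a TGACTCA occurrence is reported on "+" and a TGAGTCA occurrence as the "-"
reading of the same site.  Half sites are the invariant 4-mer TGAC (and its
reverse-complement reading GTCA); half sites lying inside a full TRE are
flagged as embedded.  N never matches.

Reporter constructs are promoter fragments in TSS-relative coordinates
(negative = upstream, half-open intervals) with an activity label.  The
essential promoter region is the interval-set difference between what every
active construct retains and what any inactive construct retains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

TRE_WORDS = {"TGACTCA": "+", "TGAGTCA": "-"}
HALF_WORDS = {"TGAC": "+", "GTCA": "-"}

Interval = tuple[int, int]


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence: 0-based offset, strand, kind, literal text."""

    position: int
    strand: str
    kind: str
    matched_text: str
    embedded: bool = False

    def __post_init__(self) -> None:
        expected = 7 if self.kind == "full_TRE" else 4
        if self.kind not in ("full_TRE", "half_site"):
            raise ValueError(f"unknown motif kind {self.kind!r}")
        if len(self.matched_text) != expected:
            raise ValueError(
                f"{self.kind} hit must match {expected} bp, got "
                f"{self.matched_text!r}"
            )
        if self.position < 0:
            raise ValueError("position must be >= 0")

    @property
    def footprint(self) -> Interval:
        return (self.position, self.position + len(self.matched_text))


@dataclass(frozen=True)
class ReporterConstruct:
    """A promoter fragment (retained intervals) with an activity label."""

    name: str
    retained_intervals: tuple[Interval, ...]
    activity: str = "unknown"
    hits: tuple[MotifHit, ...] = ()

    def __post_init__(self) -> None:
        if self.activity not in ("active", "inactive", "unknown"):
            raise ValueError(f"invalid activity {self.activity!r}")
        object.__setattr__(
            self, "retained_intervals", normalize_intervals(self.retained_intervals)
        )
        object.__setattr__(self, "hits", tuple(self.hits))


@dataclass(frozen=True)
class PromoterModel:
    """A promoter span in TSS-relative coordinates, optionally with sequence.

    The default span ``(-1100, 0)`` is the 1.1 kb of 5' flanking sequence
    upstream of the TSS.  When a sequence is attached, its index i maps to
    relative coordinate ``span[0] + i``.
    """

    span: Interval = (-1100, 0)
    sequence: str | None = None
    hits: tuple[MotifHit, ...] = ()

    def __post_init__(self) -> None:
        a, b = self.span
        if b <= a:
            raise ValueError("span must have positive length")
        if self.sequence is not None and len(self.sequence) != b - a:
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match span "
                f"length {b - a}"
            )
        for h in self.hits:
            if not (0 <= h.position and h.footprint[1] <= b - a):
                raise ValueError(f"hit at {h.position} outside span")
        object.__setattr__(self, "hits", tuple(self.hits))


# ---------------------------------------------------------------------------
# interval-set algebra (sorted disjoint half-open intervals)
# ---------------------------------------------------------------------------


def normalize_intervals(intervals: Iterable[Interval]) -> tuple[Interval, ...]:
    """Sort, validate and merge touching/overlapping half-open intervals."""
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    for a, b in ivs:
        if b <= a:
            raise ValueError(f"interval ({a}, {b}) has non-positive length")
    merged: list[Interval] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return tuple(merged)


def intersect_interval_sets(
    x: Iterable[Interval], y: Iterable[Interval]
) -> tuple[Interval, ...]:
    xs, ys = normalize_intervals(x), normalize_intervals(y)
    out: list[Interval] = []
    i = j = 0
    while i < len(xs) and j < len(ys):
        a = max(xs[i][0], ys[j][0])
        b = min(xs[i][1], ys[j][1])
        if a < b:
            out.append((a, b))
        if xs[i][1] < ys[j][1]:
            i += 1
        else:
            j += 1
    return tuple(out)


def union_interval_sets(
    x: Iterable[Interval], y: Iterable[Interval]
) -> tuple[Interval, ...]:
    return normalize_intervals(list(x) + list(y))


def difference_interval_sets(
    x: Iterable[Interval], y: Iterable[Interval]
) -> tuple[Interval, ...]:
    xs, ys = normalize_intervals(x), normalize_intervals(y)
    out: list[Interval] = []
    for a, b in xs:
        cur = a
        for c, d in ys:
            if d <= cur or c >= b:
                continue
            if c > cur:
                out.append((cur, c))
            cur = max(cur, d)
            if cur >= b:
                break
        if cur < b:
            out.append((cur, b))
    return tuple(out)


def interval_set_length(intervals: Iterable[Interval]) -> int:
    return sum(b - a for a, b in normalize_intervals(intervals))


def covers(outer: Iterable[Interval], inner: Iterable[Interval]) -> bool:
    """True if the interval set ``outer`` fully contains ``inner``."""
    return not difference_interval_sets(inner, outer)


# ---------------------------------------------------------------------------
# motif scanning
# ---------------------------------------------------------------------------


def scan_tre(sequence: str) -> list[MotifHit]:
    """All full TRE consensus occurrences TGA(C/G)TCA in a sequence.

    Each genomic site is reported once: strand "+" for the TGACTCA reading,
    "-" when the site reads TGAGTCA on the forward strand (i.e. TGACTCA on
    the reverse).  N never matches.
    """
    seq = sequence.upper()
    hits: list[MotifHit] = []
    for i in range(len(seq) - 6):
        word = seq[i : i + 7]
        strand = TRE_WORDS.get(word)
        if strand is not None:
            hits.append(MotifHit(i, strand, "full_TRE", word))
    return hits


def scan_half_sites(sequence: str) -> list[MotifHit]:
    """All AP-1 half-site occurrences (TGAC forward, GTCA reverse reading).

    Half sites whose footprint lies inside a full TRE occurrence are
    reported with ``embedded=True`` so callers can count free-standing half
    sites separately.
    """
    seq = sequence.upper()
    full_footprints = [h.footprint for h in scan_tre(seq)]
    hits: list[MotifHit] = []
    for i in range(len(seq) - 3):
        word = seq[i : i + 4]
        strand = HALF_WORDS.get(word)
        if strand is None:
            continue
        embedded = any(a <= i and i + 4 <= b for a, b in full_footprints)
        hits.append(MotifHit(i, strand, "half_site", word, embedded=embedded))
    return hits


def mutate_site(sequence: str, hit: MotifHit, replacement_word: str) -> str:
    """Replace the hit's footprint with a new word; rest of sequence intact.

    The hit must still match the sequence at its recorded position.  The
    replacement may change length (the spec case TGAC -> TTAC preserves it).
    """
    start, end = hit.footprint
    if sequence[start:end].upper() != hit.matched_text.upper():
        raise ValueError(
            f"hit text {hit.matched_text!r} does not match sequence at "
            f"position {hit.position}"
        )
    return sequence[:start] + replacement_word + sequence[end:]


# ---------------------------------------------------------------------------
# reporter constructs
# ---------------------------------------------------------------------------


def apply_deletion(
    promoter: PromoterModel,
    deletion: Interval | None,
    name: str = "",
    activity: str = "unknown",
) -> ReporterConstruct:
    """Delete a sub-interval of the promoter span, keeping the rest.

    Motif hits whose footprint falls inside the deletion are removed from the
    construct's hit list; hits are kept in promoter-relative coordinates.
    An empty deletion (None) returns the intact promoter as a construct.
    """
    span = promoter.span
    if deletion is None:
        retained: tuple[Interval, ...] = (span,)
        kept_hits = promoter.hits
    else:
        a, b = deletion
        if b <= a:
            raise ValueError("deletion must have positive length")
        if a < span[0] or b > span[1]:
            raise ValueError(f"deletion {deletion} outside promoter span {span}")
        retained = difference_interval_sets([span], [deletion])
        kept_hits = tuple(
            h
            for h in promoter.hits
            if covers(retained, [_hit_relative_footprint(h, span)])
        )
    return ReporterConstruct(
        name=name, retained_intervals=retained, activity=activity, hits=kept_hits
    )


def _hit_relative_footprint(hit: MotifHit, span: Interval) -> Interval:
    start, end = hit.footprint
    return (span[0] + start, span[0] + end)


def infer_essential_region(
    constructs: Sequence[ReporterConstruct],
) -> tuple[Interval, ...]:
    """Minimal promoter region consistent with the activity pattern.

    Returns (intersection of retained intervals over active constructs)
    minus (union of retained intervals over inactive constructs), as a
    sorted disjoint interval set.  Requires at least one active construct
    with known activity; with no inactive construct the intersection of the
    actives is returned with a warning (the region is then only an upper
    bound).
    """
    unknown = [c.name for c in constructs if c.activity == "unknown"]
    if unknown:
        raise ValueError(f"constructs with unknown activity: {unknown}")
    actives = [c for c in constructs if c.activity == "active"]
    inactives = [c for c in constructs if c.activity == "inactive"]
    if not actives:
        raise ValueError("essential-region inference needs >= 1 active construct")
    essential = actives[0].retained_intervals
    for c in actives[1:]:
        essential = intersect_interval_sets(essential, c.retained_intervals)
    if not inactives:
        warnings.warn(
            "no inactive construct: returning the intersection of active "
            "constructs (an upper bound on the essential region)",
            stacklevel=2,
        )
        return essential
    lost: tuple[Interval, ...] = ()
    for c in inactives:
        lost = union_interval_sets(lost, c.retained_intervals)
    return difference_interval_sets(essential, lost)


def predict_activity(
    construct: ReporterConstruct, essential: Sequence[Interval]
) -> str:
    """"active" iff the construct retains the entire essential region."""
    essential = normalize_intervals(essential)
    if not essential:
        raise ValueError("essential region is empty")
    return "active" if covers(construct.retained_intervals, essential) else "inactive"
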
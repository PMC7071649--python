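"""Intron positions and phases in protein/domain coordinates, and
classification of the domain's intron-insertion pattern.

An intron's coordinate is its ``cds_offset``: the number of coding
nucleotides preceding it in transcription order.  Phase is then
``cds_offset mod 3`` (0 between codons, 1 after the first nucleotide of a
codon, 2 after the second).  A phase-0 intron sitting after residue ``r``
is treated as protein position ``r`` for anchor matching.

Eight signature patterns (labels a, c, e, f, h, i, j, k) describe where
0-2 introns fall relative to conserved anchor residues of the bHLH domain
(Arg-11, Phe-21, Lys-33, Leu-50); the packaged registry encodes them and
their relations (f lacks the first intron of a, e lacks the second, c adds
a Leu-50 intron to e, k has none).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .domain_profile import DomainHit
from .sequence_io import GeneModel

__all__ = [
    "IntronEvent",
    "PatternSignature",
    "PatternRegistry",
    "cds_introns",
    "map_to_domain",
    "classify_pattern",
    "load_registry",
    "ANCHOR_COLUMNS",
]

logger = logging.getLogger(__name__)

ANCHOR_COLUMNS = (11, 21, 33, 50)


@dataclass
class IntronEvent:
    cds_offset: int
    phase: int
    protein_position: int
    domain_column: int | None = None

    @classmethod
    def from_offset(cls, cds_offset: int) -> "IntronEvent":
        phase = cds_offset % 3
        if phase > 0:
            pos = cds_offset // 3 + 1  # intron interrupts this codon
        else:
            pos = cds_offset // 3  # intron sits after this residue
        return cls(cds_offset=cds_offset, phase=phase, protein_position=pos)


@dataclass(frozen=True)
class PatternSignature:
    label: str
    sites: tuple[tuple[int, int], ...]  # (anchor_column, phase)
    notes: str = ""

    def __post_init__(self) -> None:
        if not 0 <= len(self.sites) <= 2:
            raise ValueError(f"pattern {self.label!r}: 0-2 sites allowed")


@dataclass
class PatternRegistry:
    signatures: list[PatternSignature]
    tolerance: int = 2

    def __post_init__(self) -> None:
        labels = [s.label for s in self.signatures]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate pattern labels in registry")
        if len(self.signatures) != 8:
            raise ValueError(f"registry must hold 8 signatures, got {len(labels)}")
        zero = [s for s in self.signatures if not s.sites]
        if len(zero) != 1:
            raise ValueError("exactly one signature must have zero sites")
        by = {s.label: s for s in self.signatures}
        # Pattern relations among a/c/e/f, validated at load time.
        if {"a", "c", "e", "f"} <= set(by):
            a, c, e, f = by["a"], by["c"], by["e"], by["f"]
            if f.sites != a.sites[1:]:
                raise ValueError("relation violated: f must equal a minus its first site")
            if e.sites != a.sites[:1]:
                raise ValueError("relation violated: e must equal a minus its second site")
            if not (len(c.sites) == 2 and c.sites[0] == e.sites[0]
                    and c.sites[1][0] == 50):
                raise ValueError("relation violated: c must equal e plus a site at L-50")

    @property
    def zero_site_label(self) -> str:
        return next(s.label for s in self.signatures if not s.sites)

    def __getitem__(self, label: str) -> PatternSignature:
        return next(s for s in self.signatures if s.label == label)


def load_registry(path: str | Path | None = None, tolerance: int = 2) -> PatternRegistry:
    """Load the pattern registry TSV (label, anchor_column, phase)."""
    if path is None:
        text = resources.files("bhlhsurvey.data").joinpath("intron_registry.tsv").read_text()
    else:
        text = Path(path).read_text()
    sites: dict[str, list[tuple[int, int]]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("label\t"):
            continue
        label, col, phase = line.split("\t")
        sites.setdefault(label, [])
        if col != "-":
            sites[label].append((int(col), int(phase)))
    signatures = [
        PatternSignature(label=lab, sites=tuple(s)) for lab, s in sites.items()
    ]
    return PatternRegistry(signatures=signatures, tolerance=tolerance)


def cds_introns(model: GeneModel) -> list[IntronEvent]:
    """Introns of a gene model as coding-offset events, transcription order.

    For a minus-strand gene the CDS segment list is walked 3'->5' in genomic
    coordinates, so offsets equal those of the plus-strand mirror gene.
    """
    segs = list(model.cds_segments)
    if not segs:
        return []
    if model.strand == "-":
        segs = segs[::-1]
    events: list[IntronEvent] = []
    offset = 0
    for seg in segs[:-1]:
        offset += seg[1] - seg[0] + 1
        events.append(IntronEvent.from_offset(offset))
    return events


def map_to_domain(events: list[IntronEvent], hit: DomainHit) -> list[IntronEvent]:
    """Attach the nearest mapped consensus column to events inside the
    domain; events outside [hit.start, hit.end] keep ``domain_column=None``.
    Ties between equally near columns go to the smaller column.
    """
    mapped = [(col, pos) for col, pos in hit.column_map.items() if pos is not None]
    for ev in events:
        if hit.start <= ev.protein_position <= hit.end:
            ev.domain_column = min(
                mapped, key=lambda cp: (abs(cp[1] - ev.protein_position), cp[0])
            )[0]
        else:
            ev.domain_column = None
    return events


def classify_pattern(
    events: list[IntronEvent], registry: PatternRegistry
) -> str:
    """Match the multiset of in-domain (column, phase) events against the
    registry; return the unique matching label, the zero-site label for
    intron-less domains, or "unclassified" (no match, or ambiguous — the
    ambiguity is logged).
    """
    observed = sorted(
        (ev.domain_column, ev.phase) for ev in events if ev.domain_column is not None
    )
    matches: list[str] = []
    for sig in registry.signatures:
        if len(sig.sites) != len(observed):
            continue
        if _multiset_match(observed, sorted(sig.sites), registry.tolerance):
            matches.append(sig.label)
    if len(matches) == 1:
        return matches[0]
    if len(matches) > 1:
        logger.warning(
            "ambiguous intron pattern %s matches %s", observed, sorted(matches)
        )
    return "unclassified"


def _multiset_match(
    observed: list[tuple[int, int]],
    sites: list[tuple[int, int]],
    tolerance: int,
) -> bool:
    """Exact bipartite matching between observed events and signature sites
    (at most 2 of each): phases equal, columns within +-tolerance."""
    if len(observed) != len(sites):
        return False
    if not observed:
        return True

    def ok(obs: tuple[int, int], site: tuple[int, int]) -> bool:
        return obs[1] == site[1] and abs(obs[0] - site[0]) <= tolerance

    if len(observed) == 1:
        return ok(observed[0], sites[0])
    return (ok(observed[0], sites[0]) and ok(observed[1], sites[1])) or (
        ok(observed[0], sites[1]) and ok(observed[1], sites[0])
    )
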
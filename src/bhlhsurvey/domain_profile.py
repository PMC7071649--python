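"""Position-specific scoring profile for the bHLH domain: build, glocal
scan, region annotation, conservation statistics, and DNA-binding
classification.

The bHLH domain is modelled as 55 consensus columns spanning the basic
region, helix 1, the loop and helix 2.  DNA-binding capacity follows the
classical residue grammar: at least five basic residues in the basic region
are required for DNA binding at all; E-box (CANNTG) recognition requires a
fixed set of basic-region/helix-1 residues, and G-box (CACGTG) recognition
a superset of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .sequence_io import ProteinRecord, read_fasta

__all__ = [
    "ScoringProfile",
    "DomainHit",
    "ConservationProfile",
    "BindingCall",
    "SiteConfig",
    "AMINO_ACIDS",
    "build_profile",
    "scan_domain",
    "annotate_regions",
    "conservation_profile",
    "classify_binding",
    "load_site_config",
    "load_seed_alignment",
    "default_profile",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

CATEGORIES = ("G-box", "E-box", "non-E-box", "atypical")


@dataclass
class ScoringProfile:
    """Log-odds profile over ``length`` consensus columns.

    ``columns[j][res]`` is the score in bits of residue ``res`` at column
    ``j+1``; ``probs`` keeps the pre-log source probabilities (they sum to 1
    per column).  Gap penalties are affine, in bits.
    """

    columns: list[dict[str, float]]
    probs: list[dict[str, float]]
    background: dict[str, float]
    pseudocount: float
    gap_open: float = 10.0
    gap_extend: float = 2.0

    @property
    def length(self) -> int:
        return len(self.columns)

    def score(self, column: int, residue: str) -> float:
        """Score (bits) of ``residue`` at 1-based ``column``; unknown
        residues (e.g. X) score the column minimum."""
        col = self.columns[column - 1]
        return col.get(residue, min(col.values()))

    def consensus(self) -> str:
        return "".join(max(c, key=c.get) for c in self.columns)

    def max_score(self) -> float:
        return sum(max(c.values()) for c in self.columns)


@dataclass
class DomainHit:
    """A located domain with its per-column alignment.

    ``column_map[j]`` (key 1..profile length) is the 1-based protein
    position aligned to consensus column ``j``, or ``None`` where the
    column is deleted.  Mapped positions are strictly increasing.
    """

    protein_id: str
    start: int
    end: int
    score: float
    column_map: dict[int, int | None]
    region_of_column: dict[int, str] = field(default_factory=dict)

    @property
    def n_gaps(self) -> int:
        return sum(1 for v in self.column_map.values() if v is None)


@dataclass
class ConservationProfile:
    modal_residue: dict[int, str]
    percent: dict[int, float]
    flags70: set[int]
    flags90: set[int]


@dataclass
class BindingCall:
    category: str
    basic_count: int
    ebox_sites_present: bool
    gbox_sites_present: bool
    evidence: dict[int, str]


@dataclass
class SiteConfig:
    """Residue-rule configuration in consensus-column coordinates."""

    regions: dict[str, tuple[int, int]]
    basic_residue_set: frozenset[str]
    ebox_sites: list[tuple[int, frozenset[str]]]
    gbox_sites: list[tuple[int, frozenset[str]]]
    min_score: float = 52.9
    gap_open: float = 10.0
    gap_extend: float = 2.0
    n_columns: int = 55

    def __post_init__(self) -> None:
        covered: list[int] = []
        for name, (lo, hi) in self.regions.items():
            if lo > hi:
                raise ValueError(f"region {name!r} has inverted bounds ({lo},{hi})")
            covered.extend(range(lo, hi + 1))
        if sorted(covered) != list(range(1, self.n_columns + 1)):
            raise ValueError(
                f"region boundaries do not partition 1..{self.n_columns}"
            )
        for sites in (self.ebox_sites, self.gbox_sites):
            if not sites:
                raise ValueError("site list is empty")
            for col, _ in sites:
                if not 1 <= col <= self.n_columns:
                    raise ValueError(f"site column {col} outside 1..{self.n_columns}")

    @property
    def basic_region_columns(self) -> range:
        lo, hi = self.regions["basic"]
        return range(lo, hi + 1)

    def region_of(self, column: int) -> str:
        for name, (lo, hi) in self.regions.items():
            if lo <= column <= hi:
                return name
        raise ValueError(f"column {column} outside 1..{self.n_columns}")


def load_site_config(path: str | Path | None = None) -> SiteConfig:
    """Load a flat key=value site configuration (packaged default)."""
    if path is None:
        text = resources.files("bhlhsurvey.data").joinpath("site_config.cfg").read_text()
    else:
        text = Path(path).read_text()
    kv: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()

    def _range(s: str) -> tuple[int, int]:
        lo, _, hi = s.partition("-")
        return int(lo), int(hi)

    def _sites(s: str) -> list[tuple[int, frozenset[str]]]:
        out = []
        for item in s.split(","):
            col, _, allowed = item.partition(":")
            out.append((int(col), frozenset(allowed)))
        return out

    regions = {
        "basic": _range(kv["basic_region"]),
        "helix1": _range(kv["helix1"]),
        "loop": _range(kv["loop"]),
        "helix2": _range(kv["helix2"]),
    }
    return SiteConfig(
        regions=regions,
        basic_residue_set=frozenset(kv["basic_residues"]),
        ebox_sites=_sites(kv["ebox_sites"]),
        gbox_sites=_sites(kv["gbox_sites"]),
        min_score=float(kv.get("min_score", 52.9)),
        gap_open=float(kv.get("gap_open", 10.0)),
        gap_extend=float(kv.get("gap_extend", 2.0)),
    )


def uniform_background() -> dict[str, float]:
    return {a: 1.0 / len(AMINO_ACIDS) for a in AMINO_ACIDS}


def build_profile(
    seed_alignment: list[str],
    background: dict[str, float] | None = None,
    pseudocount: float = 1.0,
    gap_open: float = 10.0,
    gap_extend: float = 2.0,
) -> ScoringProfile:
    """Build a log-odds scoring profile from an ungapped seed alignment.

    score(column, residue) = log2(((count + pseudocount*bg) / (n + pseudocount)) / bg)
    """
    if len(seed_alignment) < 2:
        raise ValueError("need at least 2 aligned seed sequences")
    length = len(seed_alignment[0])
    if any(len(s) != length for s in seed_alignment):
        raise ValueError("seed alignment sequences have unequal lengths")
    if background is None:
        background = uniform_background()
    if any(background.get(a, 0.0) <= 0.0 for a in AMINO_ACIDS):
        raise ValueError("background frequencies must be positive for all residues")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    n = len(seed_alignment)
    columns: list[dict[str, float]] = []
    probs: list[dict[str, float]] = []
    for j in range(length):
        counts = {a: 0 for a in AMINO_ACIDS}
        for s in seed_alignment:
            if s[j] in counts:
                counts[s[j]] += 1
        p = {
            a: (counts[a] + pseudocount * background[a]) / (n + pseudocount)
            for a in AMINO_ACIDS
        }
        probs.append(p)
        columns.append({a: math.log2(p[a] / background[a]) for a in AMINO_ACIDS})
    return ScoringProfile(
        columns=columns, probs=probs, background=dict(background),
        pseudocount=pseudocount, gap_open=gap_open, gap_extend=gap_extend,
    )


def load_seed_alignment() -> list[str]:
    """The packaged 55-column seed alignment (aligned FASTA)."""
    with resources.as_file(
        resources.files("bhlhsurvey.data").joinpath("seed_alignment.fasta")
    ) as p:
        return [r.sequence for r in read_fasta(p)]


def default_profile(config: SiteConfig | None = None) -> ScoringProfile:
    """Profile built from the packaged seed alignment with default settings."""
    if config is None:
        config = load_site_config()
    return build_profile(
        load_seed_alignment(), gap_open=config.gap_open, gap_extend=config.gap_extend
    )


# DP state preference used for deterministic tie-breaking: maximise score,
# then minimise alignment start, then minimise gap count.
_NEG = (-math.inf, 0, 0)


def _better(a: tuple[float, int, int], b: tuple[float, int, int]) -> bool:
    """True if state a=(score, start, gaps) is preferred over b."""
    if a[0] != b[0]:
        return a[0] > b[0]
    if a[1] != b[1]:
        return a[1] < b[1]
    return a[2] < b[2]


def scan_domain(
    record: ProteinRecord,
    profile: ScoringProfile,
    min_score: float = 52.9,
) -> DomainHit | None:
    """Glocal profile scan: all profile columns must be consumed, protein
    ends are free; affine gap penalties.  Returns the best hit if its score
    reaches ``min_score``, else ``None`` (the protein is excluded from the
    family).

    Ties are broken toward the smallest start, then the fewest gaps.
    """
    seq = record.sequence
    N, L = len(seq), profile.length
    if N < 10:
        raise ValueError(f"protein {record.id!r} shorter than 10 residues")
    go, ge = profile.gap_open, profile.gap_extend

    # States per (residue i, column j): M match, D column deleted, I residue
    # inserted after column j. Each cell holds (score, start, gaps) plus a
    # backpointer.
    M = [[_NEG] * (L + 1) for _ in range(N + 1)]
    D = [[_NEG] * (L + 1) for _ in range(N + 1)]
    I = [[_NEG] * (L + 1) for _ in range(N + 1)]
    bM: list[list[str | None]] = [[None] * (L + 1) for _ in range(N + 1)]
    bD: list[list[str | None]] = [[None] * (L + 1) for _ in range(N + 1)]
    bI: list[list[str | None]] = [[None] * (L + 1) for _ in range(N + 1)]

    # Column 0 start states: free protein prefix of any length.
    for i in range(N + 1):
        M[i][0] = (0.0, i + 1, 0)  # start recorded as first matched residue

    for j in range(1, L + 1):
        for i in range(N + 1):
            if i >= 1:
                s = profile.score(j, seq[i - 1])
                best, ptr = _NEG, None
                for tag, st in (("M", M[i - 1][j - 1]), ("D", D[i - 1][j - 1]),
                                ("I", I[i - 1][j - 1])):
                    if st[0] == -math.inf:
                        continue
                    # entering the profile at column 1 fixes the start
                    cand = (st[0] + s, i if j == 1 else st[1], st[2])
                    if _better(cand, best):
                        best, ptr = cand, tag
                M[i][j], bM[i][j] = best, ptr
            # Deletion: column j aligned to gap (no residue consumed).
            best, ptr = _NEG, None
            for tag, st, pen in (("M", M[i][j - 1], go), ("D", D[i][j - 1], ge),
                                 ("I", I[i][j - 1], go)):
                if st[0] == -math.inf:
                    continue
                start = st[1] if not (j == 1) else i + 1
                cand = (st[0] - pen, start, st[2] + 1)
                if _better(cand, best):
                    best, ptr = cand, tag
            D[i][j], bD[i][j] = best, ptr
            # Insertion: residue i inserted after column j (j >= 1 only).
            if i >= 1:
                best, ptr = _NEG, None
                for tag, st, pen in (("M", M[i - 1][j], go), ("I", I[i - 1][j], ge),
                                     ("D", D[i - 1][j], go)):
                    if st[0] == -math.inf:
                        continue
                    cand = (st[0] - pen, st[1], st[2] + 1)
                    if _better(cand, best):
                        best, ptr = cand, tag
                I[i][j], bI[i][j] = best, ptr

    # Alignment ends at the last column (M or D); protein suffix is free.
    best, end_i, end_tag = _NEG, None, None
    for i in range(N + 1):
        for tag, st in (("M", M[i][L]), ("D", D[i][L])):
            if st[0] == -math.inf:
                continue
            if _better(st, best):
                best, end_i, end_tag = st, i, tag
    if best[0] < min_score:
        return None

    # Traceback to recover the column map.
    column_map: dict[int, int | None] = {}
    i, j, tag = end_i, L, end_tag
    while j > 0:
        if tag == "M":
            column_map[j] = i
            tag = bM[i][j]
            i, j = i - 1, j - 1
        elif tag == "D":
            column_map[j] = None
            tag = bD[i][j]
            j = j - 1
        else:  # insertion
            tag = bI[i][j]
            i = i - 1
    mapped = [v for v in column_map.values() if v is not None]
    if not mapped:
        return None
    start, end = min(mapped), max(mapped)
    return DomainHit(
        protein_id=record.id, start=start, end=end, score=best[0],
        column_map=dict(sorted(column_map.items())),
    )


def annotate_regions(hit: DomainHit, config: SiteConfig) -> DomainHit:
    """Label each consensus column with its secondary-structure region."""
    if not hit.column_map:
        raise ValueError("hit has no column_map")
    hit.region_of_column = {
        col: config.region_of(col) for col in hit.column_map
    }
    return hit


def conservation_profile(
    hits: list[DomainHit], records: dict[str, ProteinRecord]
) -> ConservationProfile:
    """Per-column identity conservation over the aligned domains.

    percent = 100 * modal count / non-gap count; flags70/flags90 hold the
    columns with conservation strictly above 70% / 90%.  Columns with no
    non-gap residues are excluded from both flag sets.
    """
    if not hits:
        raise ValueError("need at least one domain hit")
    n_cols = max(max(h.column_map) for h in hits)
    modal: dict[int, str] = {}
    percent: dict[int, float] = {}
    flags70: set[int] = set()
    flags90: set[int] = set()
    for col in range(1, n_cols + 1):
        counts: dict[str, int] = {}
        for h in hits:
            pos = h.column_map.get(col)
            if pos is None:
                continue
            res = records[h.protein_id].sequence[pos - 1]
            counts[res] = counts.get(res, 0) + 1
        if not counts:
            continue
        res, cnt = max(sorted(counts.items()), key=lambda kv: kv[1])
        total = sum(counts.values())
        pct = 100.0 * cnt / total
        modal[col], percent[col] = res, pct
        if pct > 70.0:
            flags70.add(col)
        if pct > 90.0:
            flags90.add(col)
    return ConservationProfile(
        modal_residue=modal, percent=percent, flags70=flags70, flags90=flags90
    )


def classify_binding(
    hit: DomainHit, record: ProteinRecord, config: SiteConfig
) -> BindingCall:
    """DNA-binding classification from the residue grammar.

    (1) fewer than five basic residues in the basic region -> atypical
        (non-DNA-binding);
    (2) else if every E-box site carries an allowed residue: all G-box sites
        present -> G-box, otherwise -> E-box;
    (3) else -> non-E-box.
    A column aligned to a gap never counts as an allowed residue.
    """
    seq = record.sequence

    def residue_at(col: int) -> str | None:
        pos = hit.column_map.get(col)
        return None if pos is None else seq[pos - 1]

    basic_count = 0
    for col in config.basic_region_columns:
        res = residue_at(col)
        if res is not None and res in config.basic_residue_set:
            basic_count += 1

    evidence: dict[int, str] = {}
    def sites_ok(sites: list[tuple[int, frozenset[str]]]) -> bool:
        ok = True
        for col, allowed in sites:
            res = residue_at(col)
            evidence[col] = res if res is not None else "-"
            if res is None or res not in allowed:
                ok = False
        return ok

    ebox_ok = sites_ok(config.ebox_sites)
    gbox_ok = sites_ok(config.gbox_sites)

    if basic_count < 5:
        category = "atypical"
    elif ebox_ok:
        category = "G-box" if gbox_ok else "E-box"
    else:
        category = "non-E-box"
    return BindingCall(
        category=category, basic_count=basic_count,
        ebox_sites_present=ebox_ok, gbox_sites_present=gbox_ok,
        evidence=evidence,
    )
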
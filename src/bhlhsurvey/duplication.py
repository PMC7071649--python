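"""Homolog pairing, collinear (synteny) block chaining, and duplication-
origin classification for an allopolyploid hybrid genome and its two
progenitor genomes.

A collinear block is a run of homologous gene pairs whose chromosome ranks
are strictly monotone on both sides (parallel or antiparallel) with bounded
rank gaps.  Family members are classified by precedence: membership of an
inter-genome block means the gene was inherited through the hybridisation
(whole-genome duplication); an intra-genome block means segmental
duplication; adjacent same-chromosome homologs (at most ``max_intervening``
genes apart, default 0 = strictly adjacent) are tandem duplicates; anything
else is dispersed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneOrderTable",
    "HomologPair",
    "SyntenyBlock",
    "DuplicationCall",
    "ORIGINS",
    "homolog_pairs",
    "find_collinear_blocks",
    "classify_duplication",
]

ORIGINS = ("inherited", "segmental", "tandem", "dispersed")


@dataclass
class GeneOrderTable:
    """Gene order across one or more genomes.

    ``table`` columns: genome, chromosome, rank, gene_id.  Ranks are
    consecutive from 1 within each chromosome; gene ids unique per genome.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"genome", "chromosome", "rank", "gene_id"}
        if not required <= set(self.table.columns):
            raise ValueError(f"gene-order table needs columns {sorted(required)}")
        for (genome, chrom), grp in self.table.groupby(["genome", "chromosome"]):
            ranks = sorted(grp["rank"])
            if ranks != list(range(1, len(ranks) + 1)):
                raise ValueError(
                    f"ranks on {genome}/{chrom} are not consecutive from 1"
                )
        for genome, grp in self.table.groupby("genome"):
            if grp["gene_id"].duplicated().any():
                raise ValueError(f"duplicate gene ids in genome {genome!r}")
        self._index = {
            row.gene_id: (row.genome, row.chromosome, row.rank)
            for row in self.table.itertuples()
        }

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def locate(self, gene_id: str) -> tuple[str, str, int]:
        try:
            return self._index[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GeneOrderTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class HomologPair:
    gene_a: str
    gene_b: str
    similarity: float
    same_genome: bool

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair {self.gene_a!r}")


@dataclass
class SyntenyBlock:
    chrom_a: tuple[str, str]  # (genome, chromosome)
    chrom_b: tuple[str, str]
    anchors: list[tuple[str, str]]  # ordered (gene_a, gene_b) pairs
    orientation: str  # parallel | antiparallel
    scope: str  # intra | inter

    @property
    def genes(self) -> set[str]:
        return {g for pair in self.anchors for g in pair}


@dataclass(frozen=True)
class DuplicationCall:
    gene_id: str
    origin: str
    evidence: str


def homolog_pairs(
    similarity: pd.DataFrame,
    cutoff: float,
    genome_of: dict[str, str],
    higher_is_closer: bool = True,
) -> list[HomologPair]:
    """All unordered gene pairs whose similarity passes the cutoff.

    ``similarity`` is a symmetric genes x genes table (similarity scores, or
    distances with ``higher_is_closer=False``).
    """
    if list(similarity.index) != list(similarity.columns):
        raise ValueError("similarity table must have identical row/column labels")
    vals = similarity.to_numpy(dtype=float)
    if not np.allclose(vals, vals.T, atol=1e-12):
        raise ValueError("similarity table must be symmetric")
    genes = list(similarity.index)
    pairs: list[HomologPair] = []
    for i, j in combinations(range(len(genes)), 2):
        v = vals[i, j]
        hit = v >= cutoff if higher_is_closer else v <= cutoff
        if hit:
            a, b = genes[i], genes[j]
            pairs.append(
                HomologPair(
                    gene_a=a, gene_b=b, similarity=float(v),
                    same_genome=genome_of[a] == genome_of[b],
                )
            )
    return pairs


def _chain_anchors(
    anchors: list[tuple[int, int, str, str]],
    sign: int,
    min_pairs: int,
    max_gap: int,
) -> list[list[int]]:
    """Longest-chain DP over anchors (rank_a, rank_b, gene_a, gene_b).

    A chain is strictly increasing in rank_a and strictly increasing
    (sign=+1) or decreasing (sign=-1) in rank_b, with successive rank gaps
    at most ``max_gap`` on both sides.  Returns candidate chains (anchor
    index lists) of length >= min_pairs, longest first, ties by smaller
    start rank.
    """
    order = sorted(range(len(anchors)), key=lambda k: (anchors[k][0], anchors[k][1]))
    n = len(order)
    best_len = [1] * n
    prev = [-1] * n
    for x in range(n):
        ax, bx = anchors[order[x]][0], anchors[order[x]][1]
        for y in range(x):
            ay, by = anchors[order[y]][0], anchors[order[y]][1]
            if ay >= ax or (ax - ay) - 1 > max_gap:
                continue
            db = (bx - by) * sign
            if db <= 0 or db - 1 > max_gap:
                continue
            if best_len[y] + 1 > best_len[x]:
                best_len[x] = best_len[y] + 1
                prev[x] = y
    chains: list[list[int]] = []
    for x in range(n):
        if best_len[x] < min_pairs:
            continue
        chain = []
        k = x
        while k != -1:
            chain.append(order[k])
            k = prev[k]
        chains.append(chain[::-1])
    chains.sort(key=lambda c: (-len(c), anchors[c[0]][0], anchors[c[0]][1]))
    return chains


def find_collinear_blocks(
    pairs: list[HomologPair],
    orders: GeneOrderTable,
    min_pairs: int = 3,
    max_gap: int = 5,
) -> list[SyntenyBlock]:
    """Chain homolog pairs into collinear blocks per chromosome pair.

    Both orientations are searched; overlapping chains are resolved
    greedily by chain length (ties by smaller start rank), and an anchor
    pair is used by at most one block.
    """
    # bucket anchors by unordered chromosome pair, orienting each anchor
    by_chrom: dict[tuple, list[tuple[int, int, str, str]]] = {}
    for p in pairs:
        ga, ca, ra = orders.locate(p.gene_a)
        gb, cb, rb = orders.locate(p.gene_b)
        ka, kb = (ga, ca), (gb, cb)
        if kb < ka:
            ka, kb = kb, ka
            a, b, ra, rb = p.gene_b, p.gene_a, rb, ra
        else:
            a, b = p.gene_a, p.gene_b
        by_chrom.setdefault((ka, kb), []).append((ra, rb, a, b))

    blocks: list[SyntenyBlock] = []
    for (ka, kb), anchors in sorted(by_chrom.items()):
        candidates: list[tuple[list[int], str]] = []
        for sign, orient in ((1, "parallel"), (-1, "antiparallel")):
            for chain in _chain_anchors(anchors, sign, min_pairs, max_gap):
                candidates.append((chain, orient))
        candidates.sort(
            key=lambda co: (-len(co[0]), anchors[co[0][0]][0], anchors[co[0][0]][1])
        )
        used: set[int] = set()
        for chain, orient in candidates:
            if any(k in used for k in chain):
                continue
            used.update(chain)
            blocks.append(
                SyntenyBlock(
                    chrom_a=ka,
                    chrom_b=kb,
                    anchors=[(anchors[k][2], anchors[k][3]) for k in chain],
                    orientation=orient,
                    scope="intra" if ka[0] == kb[0] else "inter",
                )
            )
    return blocks


def classify_duplication(
    gene_id: str,
    blocks: list[SyntenyBlock],
    pairs: list[HomologPair],
    orders: GeneOrderTable,
    max_intervening: int = 0,
) -> DuplicationCall:
    """Classify one gene's duplication origin with the stated precedence:
    inter-genome block (inherited) > intra-genome block (segmental) >
    adjacent same-chromosome homolog (tandem) > dispersed.
    """
    genome, chrom, rank = orders.locate(gene_id)
    for scope, origin in (("inter", "inherited"), ("intra", "segmental")):
        for bi, block in enumerate(blocks):
            if block.scope == scope and gene_id in block.genes:
                return DuplicationCall(
                    gene_id=gene_id, origin=origin, evidence=f"block:{bi}"
                )
    for p in pairs:
        if gene_id not in (p.gene_a, p.gene_b):
            continue
        partner = p.gene_b if gene_id == p.gene_a else p.gene_a
        pg, pc, pr = orders.locate(partner)
        if pg == genome and pc == chrom and abs(pr - rank) - 1 <= max_intervening:
            return DuplicationCall(
                gene_id=gene_id, origin="tandem", evidence=f"partner:{partner}"
            )
    return DuplicationCall(gene_id=gene_id, origin="dispersed", evidence="")
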
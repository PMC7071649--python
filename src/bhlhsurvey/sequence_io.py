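"""Readers/writers for the formats the pipeline touches and basic protein
physicochemical properties (length, average molecular weight, isoelectric
point).

Coordinates follow the GFF3 convention everywhere on disk: 1-based,
inclusive on both ends.  Internal protein coordinates are 1-based.  CDS
offsets are counted in transcription order as "coding nucleotides preceding
the intron" (a 0-based count), which makes intron phase = offset mod 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinRecord",
    "GeneModel",
    "ProteinProperties",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "protein_properties",
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "load_pka_table",
]

# Average (isotope-averaged) residue masses in Daltons.  The free amino-acid
# mass minus one water; summing residues and adding one water back gives the
# peptide mass.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
    # Ambiguous residue: contributes no mass and no charge (conservative).
    "X": 0.0,
}
WATER_MASS = 18.0153

_CANONICAL = set(AVERAGE_RESIDUE_MASS)


@dataclass
class ProteinRecord:
    """One protein sequence with its identifier."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record has an empty id")
        if not self.sequence:
            raise ValueError(f"protein record {self.id!r} has an empty sequence")
        if any(c.isspace() for c in self.sequence):
            raise ValueError(f"protein record {self.id!r} contains whitespace")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A gene model: exon and CDS intervals on a chromosome.

    Intervals are 1-based inclusive and stored sorted by start regardless of
    strand.  ``flags`` collects soft validation problems (e.g. a CDS whose
    total length is not a multiple of 3); such models are kept but must not
    be used silently.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds_segments: list[tuple[int, int]]
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(
                f"gene {self.gene_id!r}: unknown strand symbol {self.strand!r}"
            )
        self.exons = sorted(self.exons)
        self.cds_segments = sorted(self.cds_segments)
        for name, ivals in (("exon", self.exons), ("CDS", self.cds_segments)):
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"gene {self.gene_id!r}: overlapping {name} intervals "
                        f"({s1},{e1}) and ({s2},{e2})"
                    )
        for cs, ce in self.cds_segments:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValueError(
                    f"gene {self.gene_id!r}: CDS ({cs},{ce}) not contained in any exon"
                )
        if self.cds_length % 3 != 0:
            self.flags.append("cds_not_modulo_3")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)


@dataclass(frozen=True)
class ProteinProperties:
    length: int
    molecular_weight: float
    isoelectric_point: float


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of records.

    Multi-line sequences are concatenated and input order preserved.
    Raises ``ValueError`` on duplicate ids, empty sequences or an empty file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} in {path} has no sequence")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA (byte-stable for fixed input)."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (one per mRNA) from a GFF3 file.

    Uses an in-memory gffutils database; expects gene/mRNA/exon/CDS features
    with ID/Parent attributes per the GFF3 standard.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GFF3 file not found: {path}")
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        models.append(
            GeneModel(
                gene_id=mrna.id,
                chromosome=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds_segments=cds,
            )
        )
    return models


def load_pka_table(path: str | Path | None = None) -> dict[str, tuple[float, int]]:
    """Load the ionizable-group pKa table: group -> (pKa, charge sign).

    The packaged default is an EMBOSS-style set.  Groups are the protein
    termini (``nterm``/``cterm``) and the one-letter codes of ionizable side
    chains.
    """
    if path is None:
        src = resources.files("bhlhsurvey.data").joinpath("pka.tsv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, tuple[float, int]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("group\t"):
            continue
        group, pka, sign = line.split("\t")
        table[group] = (float(pka), +1 if sign == "+" else -1)
    return table


def net_charge(sequence: str, ph: float, pka: dict[str, tuple[float, int]]) -> float:
    """Henderson-Hasselbalch net charge of a peptide at a given pH."""
    charge = 0.0
    groups = ["nterm", "cterm"] + [c for c in sequence if c in pka]
    for g in groups:
        k, sign = pka[g]
        if sign > 0:
            charge += 1.0 / (1.0 + 10.0 ** (ph - k))
        else:
            charge -= 1.0 / (1.0 + 10.0 ** (k - ph))
    return charge


def isoelectric_point(
    sequence: str,
    pka: dict[str, tuple[float, int]] | None = None,
    tol: float = 0.01,
) -> float:
    """pH at which the net charge crosses zero, found by bisection.

    The charge function is strictly decreasing in pH, so the root is unique.
    """
    if pka is None:
        pka = load_pka_table()
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def protein_properties(
    record: ProteinRecord,
    pka: dict[str, tuple[float, int]] | None = None,
) -> ProteinProperties:
    """Length, average molecular weight (Da) and isoelectric point.

    MW is the sum of average residue masses plus one water.  ``X`` residues
    contribute zero mass and no charge.
    """
    seq = record.sequence.upper()
    bad = set(seq) - _CANONICAL
    if bad:
        raise ValueError(
            f"protein {record.id!r}: non-canonical residues {sorted(bad)}"
        )
    mw = sum(AVERAGE_RESIDUE_MASS[c] for c in seq) + WATER_MASS
    pi = isoelectric_point(seq, pka)
    return ProteinProperties(length=len(seq), molecular_weight=mw, isoelectric_point=pi)
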
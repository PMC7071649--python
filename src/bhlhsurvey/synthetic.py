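"""Synthetic-data generators with machine-readable ground truth.

Every input the pipeline consumes can be generated here: proteomes with
planted bHLH domains of each DNA-binding category, gene models with planted
intron patterns, hybrid/progenitor genomes with planted duplication
origins, FPKM matrices with planted tissue programs / spikes / hormone
responders, and qPCR Ct tables with planted fold changes.  Each generator
is a pure function of its parameters and seed.

Defaults emulate the study conditions of a desk-scale family survey:
uniform 1/20 background residue frequencies, 55-column domains embedded in
random flanks, 3 qPCR replicates per condition, five hormone treatments
with five timepoints, and lognormal FPKM noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domain_profile import (
    AMINO_ACIDS,
    ScoringProfile,
    SiteConfig,
    default_profile,
    load_site_config,
)
from .gene_structure import PatternRegistry, load_registry
from .sequence_io import GeneModel, ProteinRecord

__all__ = [
    "gen_proteome",
    "gen_gene_models",
    "gen_duplicated_genomes",
    "gen_expression",
    "gen_qpcr",
    "gen_subfamily_alignment",
    "gene_models_to_gff3",
]

HORMONES = ("IAA", "GA3", "6-BA", "ABA", "ACC")
TIMEPOINTS = ("1h", "3h", "6h", "12h", "24h")

_NONBASIC = [a for a in AMINO_ACIDS if a not in "RKH"]


def _sample_domain(rng: np.random.Generator, profile: ScoringProfile) -> list[str]:
    """Sample one domain sequence column-wise from the profile's source
    probabilities."""
    residues = list(AMINO_ACIDS)
    return [
        str(rng.choice(residues, p=[p[a] for a in residues]))
        for p in profile.probs
    ]


def _force_category(
    domain: list[str],
    category: str,
    config: SiteConfig,
    rng: np.random.Generator,
) -> list[str]:
    """Edit a sampled domain so it satisfies exactly one binding category."""
    basic_cols = list(config.basic_region_columns)
    site_cols = {c for c, _ in config.ebox_sites} | {c for c, _ in config.gbox_sites}

    def set_col(col: int, res: str) -> None:
        domain[col - 1] = res

    def basic_count() -> int:
        return sum(1 for c in basic_cols if domain[c - 1] in config.basic_residue_set)

    if category == "atypical":
        # 3-4 basic residues in the basic region: first strip, then re-add.
        for c in basic_cols:
            if domain[c - 1] in config.basic_residue_set:
                set_col(c, str(rng.choice(_NONBASIC)))
        n_basic = int(rng.integers(3, 5))
        for c in rng.choice(basic_cols, size=n_basic, replace=False):
            set_col(int(c), str(rng.choice(["R", "K", "H"])))
        return domain

    # typical categories share the E-box site residues
    for col, allowed in config.ebox_sites:
        set_col(col, sorted(allowed)[0])
    if category == "G-box":
        for col, allowed in config.gbox_sites:
            set_col(col, sorted(allowed)[0])
    elif category == "E-box":
        # break a G-box-only site with a residue outside its allowed set
        gb_only = [
            (c, al) for c, al in config.gbox_sites
            if c not in {c2 for c2, _ in config.ebox_sites}
        ]
        col, allowed = gb_only[0]
        forbidden = [a for a in _NONBASIC if a not in allowed]
        set_col(col, str(rng.choice(forbidden)))
    elif category == "non-E-box":
        # break an E-box site outside the basic region when possible
        col, allowed = max(config.ebox_sites, key=lambda ca: ca[0])
        forbidden = [a for a in _NONBASIC if a not in allowed]
        set_col(col, str(rng.choice(forbidden)))
    else:
        raise ValueError(f"unknown category {category!r}")

    # guarantee DNA-binding competence: >= 5 basic residues
    free = [c for c in basic_cols if c not in site_cols]
    rng.shuffle(free)
    while basic_count() < 5:
        c = free.pop()
        set_col(c, str(rng.choice(["R", "K"])))
    return domain


def _random_flank(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def gen_proteome(
    n_per_category: dict[str, int],
    flank_length: int = 100,
    seed: int = 0,
    profile: ScoringProfile | None = None,
    config: SiteConfig | None = None,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Proteins with planted bHLH domains of the requested categories.

    Returns (records, truth) where truth has columns protein_id, category,
    domain_start, domain_end, seed.
    """
    if any(n < 0 for n in n_per_category.values()):
        raise ValueError("category counts must be non-negative")
    rng = np.random.default_rng(seed)
    if profile is None:
        profile = default_profile()
    if config is None:
        config = load_site_config()
    records: list[ProteinRecord] = []
    rows = []
    i = 0
    for category in ("G-box", "E-box", "non-E-box", "atypical"):
        for _ in range(n_per_category.get(category, 0)):
            i += 1
            domain = _force_category(
                _sample_domain(rng, profile), category, config, rng
            )
            left = _random_flank(rng, flank_length)
            right = _random_flank(rng, flank_length)
            seq = left + "".join(domain) + right
            pid = f"syn{i:04d}"
            records.append(ProteinRecord(id=pid, sequence=seq))
            rows.append(
                {
                    "protein_id": pid,
                    "category": category,
                    "domain_start": flank_length + 1,
                    "domain_end": flank_length + profile.length,
                    "seed": seed,
                }
            )
    return records, pd.DataFrame(rows)


def gen_gene_models(
    pattern_counts: dict[str, int],
    jitter: int = 0,
    seed: int = 0,
    registry: PatternRegistry | None = None,
    profile: ScoringProfile | None = None,
    flank_residues: int = 30,
    intron_length: int = 120,
) -> tuple[list[GeneModel], list[ProteinRecord], pd.DataFrame]:
    """Gene models whose intron offsets realise the registry signatures.

    For each requested pattern label, genes are built with a planted domain
    (columns map 1:1 onto protein positions) and CDS segments split so that
    the intron (anchor, phase) sites of the signature are realised within
    +-jitter residues.  Genes alternate between plus and minus strand.
    Pattern groups share a prototype domain (members differ by two extra
    substitutions) so that domain distances reflect group membership.
    """
    if registry is None:
        registry = load_registry()
    if jitter > registry.tolerance:
        raise ValueError(
            f"jitter {jitter} exceeds registry tolerance {registry.tolerance}"
        )
    rng = np.random.default_rng(seed)
    if profile is None:
        profile = default_profile()
    L_dom = profile.length
    prototypes = {
        sig.label: _sample_domain(rng, profile) for sig in registry.signatures
    }
    models: list[GeneModel] = []
    records: list[ProteinRecord] = []
    rows = []
    i = 0
    genome_cursor = 1
    for sig in registry.signatures:
        for _ in range(pattern_counts.get(sig.label, 0)):
            i += 1
            gene_id = f"gene{i:04d}"
            domain = list(prototypes[sig.label])
            for col in rng.choice(range(1, L_dom + 1), size=2, replace=False):
                domain[int(col) - 1] = str(rng.choice(list(AMINO_ACIDS)))
            protein = (
                _random_flank(rng, flank_residues)
                + "".join(domain)
                + _random_flank(rng, flank_residues)
            )
            n_res = len(protein)
            offsets = []
            deltas = []
            for col, phase in sig.sites:
                delta = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
                pos = flank_residues + col + delta
                off = 3 * (pos - 1) + phase if phase > 0 else 3 * pos
                offsets.append(off)
                deltas.append(delta)
            offsets_sorted = sorted(offsets)
            if any(b - a < 3 for a, b in zip(offsets_sorted, offsets_sorted[1:])):
                raise ValueError("intron offsets collide; reduce jitter")
            cds_total = 3 * n_res
            piece_lengths = []
            prev = 0
            for off in offsets_sorted:
                piece_lengths.append(off - prev)
                prev = off
            piece_lengths.append(cds_total - prev)
            strand = "+" if i % 2 else "-"
            layout = piece_lengths if strand == "+" else piece_lengths[::-1]
            start = genome_cursor
            segs = []
            pos = start
            for k, plen in enumerate(layout):
                segs.append((pos, pos + plen - 1))
                pos += plen
                if k < len(layout) - 1:
                    pos += intron_length
            genome_cursor = pos + 500
            models.append(
                GeneModel(
                    gene_id=gene_id, chromosome="chr1", strand=strand,
                    exons=list(segs), cds_segments=list(segs),
                )
            )
            records.append(ProteinRecord(id=gene_id, sequence=protein))
            rows.append(
                {
                    "gene_id": gene_id,
                    "pattern": sig.label,
                    "strand": strand,
                    "n_introns": len(offsets_sorted),
                    "offsets": ",".join(map(str, offsets_sorted)),
                    "jitter": ",".join(map(str, deltas)),
                    "seed": seed,
                }
            )
    return models, records, pd.DataFrame(rows)


def gene_models_to_gff3(models: list[GeneModel]) -> str:
    """Serialise gene models as GFF3 (gene/mRNA/exon/CDS, UTR-less)."""
    lines = ["##gff-version 3"]
    for m in models:
        lo = min(s for s, _ in m.exons)
        hi = max(e for _, e in m.exons)
        g = f"{m.gene_id}.g"
        lines.append(
            f"{m.chromosome}\tsynthetic\tgene\t{lo}\t{hi}\t.\t{m.strand}\t.\tID={g}"
        )
        lines.append(
            f"{m.chromosome}\tsynthetic\tmRNA\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
            f"ID={m.gene_id};Parent={g}"
        )
        for s, e in m.exons:
            lines.append(
                f"{m.chromosome}\tsynthetic\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                f"Parent={m.gene_id}"
            )
        segs = m.cds_segments if m.strand == "+" else m.cds_segments[::-1]
        cum = 0
        for s, e in segs:
            lines.append(
                f"{m.chromosome}\tsynthetic\tCDS\t{s}\t{e}\t.\t{m.strand}\t"
                f"{(3 - cum % 3) % 3}\tParent={m.gene_id}"
            )
            cum += e - s + 1
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# duplicated genomes


@dataclass
class DuplicatedGenomes:
    orders: "pd.DataFrame"  # genome, chromosome, rank, gene_id
    pairs: list[tuple[str, str]]
    truth: pd.DataFrame  # gene_id, origin


def gen_duplicated_genomes(
    n_inherited: int = 20,
    n_segmental: int = 6,
    n_tandem: int = 4,
    n_dispersed: int = 5,
    seed: int = 0,
    family_ids: list[str] | None = None,
    run_length: int = 5,
    filler_spacing: int = 7,
) -> DuplicatedGenomes:
    """Two progenitor genomes (A, B) and one hybrid genome (H) with planted
    duplication origins for the hybrid family genes.

    Inherited genes sit in inter-genome collinear runs of ``run_length``
    anchor pairs against a progenitor; segmental genes in intra-genome runs
    between two hybrid chromosomes; tandem genes as adjacent homolog pairs;
    dispersed genes have a far-away background partner (spaced beyond any
    chaining gap).  ``family_ids``, when given, are assigned in the order
    inherited, segmental, tandem, dispersed.
    """
    if n_inherited % run_length:
        raise ValueError("n_inherited must be a multiple of run_length")
    if run_length < 3:
        raise ValueError("run_length must be >= 3 (minimum chainable block)")
    if n_segmental % 2 or n_tandem % 2:
        raise ValueError("segmental and tandem counts must be even")
    if n_segmental and n_segmental < 6:
        raise ValueError("n_segmental must be 0 or >= 6 to form a chainable block")
    n_family = n_inherited + n_segmental + n_tandem + n_dispersed
    if family_ids is None:
        family_ids = [f"fam{i:03d}" for i in range(1, n_family + 1)]
    if len(family_ids) != n_family:
        raise ValueError("family_ids length must equal total planted count")
    rng = np.random.default_rng(seed)
    ids = iter(family_ids)
    chroms: dict[tuple[str, str], list[str]] = {}
    pairs: list[tuple[str, str]] = []
    truth_rows = []
    bg_counter = [0]

    def filler(k: int = 1) -> list[str]:
        out = []
        for _ in range(k):
            bg_counter[0] += 1
            out.append(f"bg{bg_counter[0]:04d}")
        return out

    def chrom(genome: str, name: str) -> list[str]:
        return chroms.setdefault((genome, name), [])

    # inherited: runs of consecutive anchor pairs H chromosome <-> progenitor
    n_runs = n_inherited // run_length
    progenitors = ["A", "B"]
    for r in range(n_runs):
        h = chrom("H", f"H{r + 1}")
        pg = progenitors[r % 2]
        p = chrom(pg, f"{pg}{r // 2 + 1}")
        h.extend(filler(2))
        p.extend(filler(2))
        for _ in range(run_length):
            g = next(ids)
            partner = filler(1)[0]
            h.append(g)
            p.append(partner)
            pairs.append((g, partner))
            truth_rows.append({"gene_id": g, "origin": "inherited"})
        h.extend(filler(2))
        p.extend(filler(2))

    # segmental: an intra-genome run between two dedicated hybrid chromosomes
    seg_genes = [next(ids) for _ in range(n_segmental)]
    half = n_segmental // 2
    left, right = seg_genes[:half], seg_genes[half:]
    ca = chrom("H", "H90")
    cb = chrom("H", "H91")
    ca.extend(filler(2))
    cb.extend(filler(2))
    for ga, gb in zip(left, right):
        ca.append(ga)
        cb.append(gb)
        pairs.append((ga, gb))
        truth_rows.append({"gene_id": ga, "origin": "segmental"})
        truth_rows.append({"gene_id": gb, "origin": "segmental"})
    ca.extend(filler(2))
    cb.extend(filler(2))

    # tandem: adjacent homolog pairs separated by wide filler stretches
    ct = chrom("H", "H95")
    for _ in range(n_tandem // 2):
        ct.extend(filler(filler_spacing))
        g1, g2 = next(ids), next(ids)
        ct.extend([g1, g2])
        pairs.append((g1, g2))
        truth_rows.append({"gene_id": g1, "origin": "tandem"})
        truth_rows.append({"gene_id": g2, "origin": "tandem"})
    ct.extend(filler(filler_spacing))

    # dispersed: partner on another chromosome, spaced beyond chaining range
    cd = chrom("H", "H96")
    ce = chrom("H", "H97")
    for _ in range(n_dispersed):
        g = next(ids)
        partner = filler(1)[0]
        cd.extend(filler(filler_spacing - 1) + [g])
        ce.extend(filler(filler_spacing - 1) + [partner])
        pairs.append((g, partner))
        truth_rows.append({"gene_id": g, "origin": "dispersed"})

    _ = rng  # layout is deterministic; rng reserved for future variation
    rows = []
    for (genome, cname), genes in sorted(chroms.items()):
        for rank, gid in enumerate(genes, start=1):
            rows.append(
                {"genome": genome, "chromosome": cname, "rank": rank, "gene_id": gid}
            )
    orders = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return DuplicatedGenomes(orders=orders, pairs=pairs, truth=truth)


# ---------------------------------------------------------------------------
# expression and qPCR


@dataclass
class ExpressionDataset:
    tissue: pd.DataFrame  # genes x samples FPKM
    control: pd.Series  # per-gene control FPKM (untreated roots)
    treated: dict[str, pd.DataFrame]  # hormone -> genes x timepoints FPKM
    truth: pd.DataFrame  # gene_id, role, block, spike_sample, hormones


def gen_expression(
    n_per_block: tuple[int, ...] = (20, 20),
    n_spike: int = 5,
    n_subthreshold: int = 5,
    responder_spec: tuple[tuple[int, tuple[str, ...]], ...] = ((10, ("IAA", "ABA")),),
    n_samples: int = 50,
    noise_sd: float = 0.15,
    seed: int = 0,
    high_fpkm: float = 60.0,
    low_fpkm: float = 2.0,
    effect_fold: float = 8.0,
) -> ExpressionDataset:
    """FPKM matrices with planted tissue programs, spikes, sub-threshold
    genes and hormone responders.

    Tissue samples are split evenly into one high-expression group per
    block; block genes are high (``high_fpkm``) in their group and low
    elsewhere.  Spike genes have a single extreme sample.  Sub-threshold
    genes never reach FPKM 1.  Responders change ``effect_fold``-fold under
    their planted hormones at one timepoint.  All values carry lognormal
    noise with ``noise_sd`` on the log2 scale.
    """
    k = len(n_per_block)
    if k < 1 or n_samples < 2 * k:
        raise ValueError("need at least two samples per block")
    rng = np.random.default_rng(seed)
    samples = [f"S{j:02d}" for j in range(1, n_samples + 1)]
    groups = np.array_split(np.arange(n_samples), k)

    def noisy(base: np.ndarray) -> np.ndarray:
        return base * 2.0 ** rng.normal(0.0, noise_sd, size=base.shape)

    rows, truth_rows, gene_ids = [], [], []
    i = 0

    def add_gene(base: np.ndarray, role: str, **extra) -> str:
        nonlocal i
        i += 1
        gid = f"expr{i:04d}"
        gene_ids.append(gid)
        rows.append(noisy(base))
        truth_rows.append({"gene_id": gid, "role": role, **extra})
        return gid

    for b, n_genes in enumerate(n_per_block):
        base = np.full(n_samples, low_fpkm)
        base[groups[b]] = high_fpkm
        for _ in range(n_genes):
            add_gene(base.copy(), "block", block=b + 1)
    for _ in range(n_spike):
        base = np.full(n_samples, low_fpkm)
        spike_at = int(rng.integers(0, n_samples))
        base[spike_at] = 100.0 * high_fpkm
        add_gene(base, "spike", spike_sample=samples[spike_at])
    for _ in range(n_subthreshold):
        base = np.full(n_samples, float(rng.uniform(0.2, 0.5)))
        add_gene(base, "subthreshold")

    # hormone responders live in the same gene universe
    responder_ids: dict[str, tuple[str, ...]] = {}
    for n_resp, hormones in responder_spec:
        for _ in range(n_resp):
            gid = add_gene(np.full(n_samples, low_fpkm), "responder",
                           hormones=",".join(hormones))
            responder_ids[gid] = hormones

    all_genes = gene_ids
    tissue = pd.DataFrame(np.vstack(rows), index=all_genes, columns=samples)
    control = pd.Series(
        noisy(np.full(len(all_genes), low_fpkm * 4)), index=all_genes, name="CK"
    )
    treated: dict[str, pd.DataFrame] = {}
    for hormone in HORMONES:
        base = np.tile(control.to_numpy()[:, None], (1, len(TIMEPOINTS)))
        for gi, gid in enumerate(all_genes):
            if hormone in responder_ids.get(gid, ()):
                tp = int(rng.integers(0, len(TIMEPOINTS)))
                base[gi, tp] = base[gi, tp] * effect_fold
        treated[hormone] = pd.DataFrame(
            noisy(base), index=all_genes, columns=list(TIMEPOINTS)
        )
    truth = pd.DataFrame(truth_rows)
    return ExpressionDataset(
        tissue=tissue, control=control, treated=treated, truth=truth
    )


def gen_qpcr(
    genes: list[str],
    conditions: list[str],
    true_log2_effects: dict[tuple[str, str], float],
    replicate_sd: float = 0.2,
    n_replicates: int = 3,
    seed: int = 0,
    control_condition: str = "CK",
    target_baseline_ct: float = 24.0,
    reference_ct: float = 15.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate Ct tables with planted log2 fold changes.

    Ct of the target gene is its baseline minus the planted effect (a
    doubling lowers Ct by one cycle); the reference gene is constant.  Both
    carry Gaussian Ct noise with sd ``replicate_sd``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    all_conditions = [control_condition] + [
        c for c in conditions if c != control_condition
    ]
    rows, truth_rows = [], []
    for gene in genes:
        for cond in all_conditions:
            effect = 0.0 if cond == control_condition else true_log2_effects.get(
                (gene, cond), 0.0
            )
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "gene": gene,
                        "condition": cond,
                        "replicate": rep,
                        "ct_target": target_baseline_ct - effect
                        + float(rng.normal(0, replicate_sd)),
                        "ct_reference": reference_ct
                        + float(rng.normal(0, replicate_sd)),
                    }
                )
            truth_rows.append(
                {"gene": gene, "condition": cond, "true_log2_effect": effect}
            )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def write_survey_dataset(
    outdir,
    seed: int = 0,
    pattern_counts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Write a complete toy survey dataset (30 genes by default) into a
    directory, with one truth table joining all planted labels.

    Files written: proteins.fasta, genes.gff3, references.tsv, orders.tsv,
    pairs.tsv, tissue_fpkm.tsv, hormone_fpkm.tsv, qpcr_ct.tsv, truth.tsv.
    """
    from pathlib import Path

    from .sequence_io import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if pattern_counts is None:
        pattern_counts = {"a": 5, "c": 3, "e": 3, "f": 5, "h": 3, "i": 3,
                          "j": 3, "k": 5}
    models, records, truth_patterns = gen_gene_models(
        pattern_counts, jitter=0, seed=seed
    )
    gene_ids = [r.id for r in records]
    n = len(gene_ids)
    write_fasta(records, outdir / "proteins.fasta")
    (outdir / "genes.gff3").write_text(gene_models_to_gff3(models))

    # subfamily references: the first gene of each pattern group
    refs = []
    for s, (label, grp) in enumerate(truth_patterns.groupby("pattern", sort=True),
                                     start=1):
        refs.append({"tip": grp["gene_id"].iloc[0], "subfamily": f"S{s}"})
    pd.DataFrame(refs).to_csv(outdir / "references.tsv", sep="\t", index=False)

    # duplication plant re-using the same gene ids
    if n < 26:
        raise ValueError("survey dataset needs at least 26 genes")
    n_inh = 15
    dup = gen_duplicated_genomes(
        n_inherited=n_inh, n_segmental=6, n_tandem=4, n_dispersed=n - n_inh - 10,
        seed=seed + 1, family_ids=gene_ids,
    )
    dup.orders.to_csv(outdir / "orders.tsv", sep="\t", index=False)
    pd.DataFrame(dup.pairs, columns=["gene_a", "gene_b"]).to_csv(
        outdir / "pairs.tsv", sep="\t", index=False
    )

    # expression over the same genes: 2 programs, spikes, sub-threshold,
    # 2-hormone responders
    expr = gen_expression(
        n_per_block=(10, 10), n_spike=3, n_subthreshold=2,
        responder_spec=((5, ("IAA", "ABA")),), seed=seed + 2,
    )
    rename = dict(zip(expr.tissue.index, gene_ids))
    tissue = expr.tissue.rename(index=rename)
    tissue.to_csv(outdir / "tissue_fpkm.tsv", sep="\t")
    hdf = pd.DataFrame(index=tissue.index)
    hdf["CK"] = expr.control.rename(index=rename)
    for hormone, tdf in expr.treated.items():
        tdf = tdf.rename(index=rename)
        for tp in tdf.columns:
            hdf[f"{hormone}_{tp}"] = tdf[tp]
    hdf.to_csv(outdir / "hormone_fpkm.tsv", sep="\t")

    qpcr_genes = gene_ids[:5]
    conditions = ["IAA_6h", "ABA_6h"]
    effects = {(g, c): 1.5 for g in qpcr_genes for c in conditions}
    ct, qpcr_truth = gen_qpcr(qpcr_genes, conditions, effects, seed=seed + 3)
    ct.to_csv(outdir / "qpcr_ct.tsv", sep="\t", index=False)

    truth = truth_patterns.merge(dup.truth, on="gene_id", how="left")
    expr_truth = expr.truth.copy()
    expr_truth["gene_id"] = expr_truth["gene_id"].map(rename)
    truth = truth.merge(expr_truth, on="gene_id", how="left")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return truth


def gen_subfamily_alignment(
    n_subfamilies: int = 3,
    n_references: int = 3,
    n_queries: int = 10,
    length: int = 55,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Aligned domain sequences falling into well-separated subfamily
    clades, with labeled references and unlabeled queries.

    Returns (aligned, reference_labels, truth) where truth maps every tip
    to its planted subfamily.
    """
    rng = np.random.default_rng(seed)
    residues = list(AMINO_ACIDS)
    aligned: dict[str, str] = {}
    reference_labels: dict[str, str] = {}
    truth_rows = []
    prototypes = [
        "".join(rng.choice(residues, size=length)) for _ in range(n_subfamilies)
    ]
    q = 0
    for s, proto in enumerate(prototypes, start=1):
        label = f"S{s}"

        def member(name: str) -> None:
            seq = list(proto)
            for col in rng.choice(length, size=2, replace=False):
                seq[int(col)] = str(rng.choice(residues))
            aligned[name] = "".join(seq)
            truth_rows.append({"tip": name, "subfamily": label})

        for r in range(1, n_references + 1):
            name = f"{label}_ref{r}"
            member(name)
            reference_labels[name] = label
    for _ in range(n_queries):
        q += 1
        s = int(rng.integers(0, n_subfamilies))
        name = f"query{q:02d}"
        label = f"S{s + 1}"
        seq = list(prototypes[s])
        for col in rng.choice(length, size=2, replace=False):
            seq[int(col)] = str(rng.choice(residues))
        aligned[name] = "".join(seq)
        truth_rows.append({"tip": name, "subfamily": label})
    return aligned, reference_labels, pd.DataFrame(truth_rows)
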
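"""End-to-end survey orchestration: run every stage on one dataset and
join the results into a per-gene report with summary counts.

A dataset directory holds the pipeline inputs in plain-text formats:

- ``proteins.fasta``      protein sequences
- ``genes.gff3``          gene models (exon/CDS)
- ``orders.tsv``          gene-order table (genome, chromosome, rank, gene_id)
- ``pairs.tsv``           homolog pairs (gene_a, gene_b)
- ``references.tsv``      optional subfamily reference labels (tip, subfamily)
- ``tissue_fpkm.tsv``     FPKM matrix, genes x tissue samples
- ``hormone_fpkm.tsv``    FPKM with a CK column and hormone_timepoint columns
- ``qpcr_ct.tsv``         replicate Ct table

Percentages in summaries are reported to one decimal, rounded half-up,
with "typical" defined as the union of the three DNA-binding categories.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, fields, asdict
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from . import __version__
from .domain_profile import (
    annotate_regions,
    classify_binding,
    default_profile,
    load_site_config,
    scan_domain,
)
from .duplication import (
    GeneOrderTable,
    HomologPair,
    classify_duplication,
    find_collinear_blocks,
)
from .expression import (
    cluster_blocks,
    ddct,
    filter_expressed,
    hormone_response,
    tissue_specific,
)
from .gene_structure import cds_introns, classify_pattern, load_registry, map_to_domain
from .phylogeny import assign_subfamilies, bootstrap_support
from .sequence_io import read_fasta, read_gff3

__all__ = ["SurveyConfig", "SurveyReport", "run_survey", "summarize_categories",
           "round_percent"]


@dataclass
class SurveyConfig:
    """All thresholds and paths of a survey run, validated on creation."""

    dataset_dir: str
    min_score: float | None = None  # None: packaged calibrated default
    min_support: float = 0.5
    bootstrap_replicates: int = 100
    pattern_tolerance: int = 2
    min_pairs: int = 3
    max_gap: int = 5
    max_intervening: int = 0
    min_fpkm: float = 1.0
    z_threshold: float = 3.0
    fc_threshold: float = 1.0
    k_blocks: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("min_support", 0.0 <= self.min_support <= 1.0),
            ("bootstrap_replicates", self.bootstrap_replicates >= 1),
            ("pattern_tolerance", self.pattern_tolerance >= 0),
            ("min_pairs", self.min_pairs >= 2),
            ("max_gap", self.max_gap >= 0),
            ("max_intervening", self.max_intervening >= 0),
            ("min_fpkm", self.min_fpkm >= 0),
            ("z_threshold", self.z_threshold >= 0),
            ("fc_threshold", self.fc_threshold >= 0),
            ("k_blocks", self.k_blocks >= 1),
        ]
        bad = [name for name, ok in checks if not ok]
        if bad:
            raise ValueError(f"config values out of bounds: {bad}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "SurveyConfig":
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
        known = {f.name: f.type for f in fields(cls)}
        unknown = set(kv) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        casts = {
            "dataset_dir": str, "min_score": float, "min_support": float,
            "bootstrap_replicates": int, "pattern_tolerance": int,
            "min_pairs": int, "max_gap": int, "max_intervening": int,
            "min_fpkm": float, "z_threshold": float, "fc_threshold": float,
            "k_blocks": int, "seed": int,
        }
        args = {k: casts[k](v) for k, v in kv.items()}
        args.update(overrides)
        return cls(**args)


@dataclass
class SurveyReport:
    per_gene: pd.DataFrame
    summaries: dict[str, pd.DataFrame]
    config: SurveyConfig
    newick: str = ""

    def to_tsv(self) -> str:
        """Full report as TSV with a config-echo header (deterministic)."""
        buf = io.StringIO()
        buf.write(f"# bhlhsurvey v{__version__} survey report\n")
        for key, value in asdict(self.config).items():
            buf.write(f"# {key} = {value}\n")
        self.per_gene.to_csv(buf, sep="\t", index=False)
        for axis, table in self.summaries.items():
            buf.write(f"\n# summary: {axis}\n")
            table.to_csv(buf, sep="\t", index=False)
        return buf.getvalue()


def round_percent(count: int, total: int) -> float:
    """Percentage to one decimal, half-up (presentation convention)."""
    if total == 0:
        raise ValueError("empty total")
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_categories(per_gene: pd.DataFrame, axes: list[str] | None = None
                         ) -> dict[str, pd.DataFrame]:
    """Counts and one-decimal percentages for each classification axis.

    For the binding axis an extra "typical" row aggregates the three
    DNA-binding categories (G-box + E-box + non-E-box).
    """
    if per_gene.empty:
        raise ValueError("empty report")
    if axes is None:
        axes = [c for c in ("category", "pattern", "subfamily", "origin", "block")
                if c in per_gene.columns]
    total = len(per_gene)
    out: dict[str, pd.DataFrame] = {}
    for axis in axes:
        counts = per_gene[axis].value_counts()
        rows = [
            {"value": str(val), "count": int(n), "percent": round_percent(int(n), total)}
            for val, n in sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
        ]
        if axis == "category":
            typical = int(counts.reindex(["G-box", "E-box", "non-E-box"]).fillna(0).sum())
            rows.append({"value": "typical", "count": typical,
                         "percent": round_percent(typical, total)})
        out[axis] = pd.DataFrame(rows)
    return out


def run_survey(config: SurveyConfig) -> SurveyReport:
    """Run all stages (scan -> classify -> patterns -> tree -> duplication
    -> expression) and join the per-gene results.

    Every stage failure is re-raised with the stage name attached.
    """
    d = Path(config.dataset_dir)
    if not d.is_dir():
        raise FileNotFoundError(f"dataset directory not found: {d}")

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"survey stage {name!r} failed: {exc}") from exc

    site = load_site_config()
    min_score = config.min_score if config.min_score is not None else site.min_score
    profile = default_profile(site)
    registry = load_registry(tolerance=config.pattern_tolerance)

    records = stage("scan", lambda: read_fasta(d / "proteins.fasta"))
    rec_by_id = {r.id: r for r in records}
    hits, categories, basic_counts = {}, {}, {}
    for r in records:
        hit = scan_domain(r, profile, min_score=min_score)
        if hit is None:
            categories[r.id] = "excluded"
            continue
        annotate_regions(hit, site)
        hits[r.id] = hit
        call = classify_binding(hit, r, site)
        categories[r.id] = call.category
        basic_counts[r.id] = call.basic_count

    patterns = {}
    gff = d / "genes.gff3"
    if gff.exists():
        models = stage("patterns", lambda: read_gff3(gff))
        for m in models:
            if m.gene_id not in hits:
                continue
            events = map_to_domain(cds_introns(m), hits[m.gene_id])
            patterns[m.gene_id] = classify_pattern(events, registry)

    subfamilies: dict[str, str] = {}
    newick = ""
    if len(hits) >= 3:
        def tree_stage():
            aligned = {}
            for pid, hit in hits.items():
                seq = rec_by_id[pid].sequence
                aligned[pid] = "".join(
                    "-" if pos is None else seq[pos - 1]
                    for col, pos in sorted(hit.column_map.items())
                )
            tree = bootstrap_support(
                aligned, n_replicates=config.bootstrap_replicates, seed=config.seed
            )
            refs_path = d / "references.tsv"
            assignment = None
            if refs_path.exists():
                refs_df = pd.read_csv(refs_path, sep="\t")
                refs = dict(zip(refs_df["tip"], refs_df["subfamily"]))
                refs = {t: l for t, l in refs.items() if t in aligned}
                if refs:
                    assignment = assign_subfamilies(
                        tree, refs, min_support=config.min_support
                    )
            return tree, assignment

        tree, assignment = stage("tree", tree_stage)
        newick = tree.newick()
        if assignment:
            subfamilies = assignment.labels

    origins: dict[str, str] = {}
    orders_path = d / "orders.tsv"
    if orders_path.exists():
        def dup_stage():
            orders = GeneOrderTable.read_tsv(orders_path)
            pairs_df = pd.read_csv(d / "pairs.tsv", sep="\t")
            genome_of = {
                row.gene_id: row.genome for row in orders.table.itertuples()
            }
            pairs = [
                HomologPair(
                    gene_a=row.gene_a, gene_b=row.gene_b, similarity=1.0,
                    same_genome=genome_of[row.gene_a] == genome_of[row.gene_b],
                )
                for row in pairs_df.itertuples()
            ]
            blocks = find_collinear_blocks(
                pairs, orders, min_pairs=config.min_pairs, max_gap=config.max_gap
            )
            out = {}
            for r in records:
                if r.id in orders:
                    out[r.id] = classify_duplication(
                        r.id, blocks, pairs, orders,
                        max_intervening=config.max_intervening,
                    ).origin
            return out

        origins = stage("duplication", dup_stage)

    blocks_of: dict[str, int] = {}
    spec_flags: dict[str, int] = {}
    hormone_counts: dict[str, int] = {}
    tissue_path = d / "tissue_fpkm.tsv"
    if tissue_path.exists():
        def expr_stage():
            tissue = pd.read_csv(tissue_path, sep="\t", index_col=0)
            retained, _excluded = filter_expressed(tissue, min_fpkm=config.min_fpkm)
            k = min(config.k_blocks, len(retained))
            assignment = cluster_blocks(retained, k=k)
            spec = tissue_specific(retained, z_threshold=config.z_threshold)
            hpath = d / "hormone_fpkm.tsv"
            hcounts: dict[str, int] = {}
            if hpath.exists():
                hdf = pd.read_csv(hpath, sep="\t", index_col=0)
                control = hdf["CK"]
                treated = {}
                hormones = sorted({c.split("_")[0] for c in hdf.columns if "_" in c})
                for h in hormones:
                    cols = [c for c in hdf.columns if c.startswith(h + "_")]
                    treated[h] = hdf[cols].rename(
                        columns={c: c.split("_", 1)[1] for c in cols}
                    )
                resp = hormone_response(
                    control, treated, fc_threshold=config.fc_threshold,
                    min_fpkm=config.min_fpkm,
                )
                hcounts = dict((resp.calls != "none").sum(axis=1))
            return assignment.blocks, {
                g: len(s) for g, s in spec.flagged.items()
            }, hcounts

        blocks_of, spec_flags, hormone_counts = stage("expression", expr_stage)

    qpcr_rows: list[dict] = []
    qpath = d / "qpcr_ct.tsv"
    if qpath.exists():
        def qpcr_stage():
            ct = pd.read_csv(qpath, sep="\t")
            control = "CK" if "CK" in set(ct["condition"]) else ct["condition"].iloc[0]
            return ddct(ct, control_condition=control)

        for res in stage("qpcr", qpcr_stage):
            qpcr_rows.append(
                {"gene": res.gene, "condition": res.condition, "rq": res.rq,
                 "p": res.p_two_sided, "stars": res.stars}
            )

    per_gene = pd.DataFrame(
        [
            {
                "gene_id": r.id,
                "domain_start": hits[r.id].start if r.id in hits else None,
                "domain_end": hits[r.id].end if r.id in hits else None,
                "domain_score": round(hits[r.id].score, 3) if r.id in hits else None,
                "category": categories[r.id],
                "basic_count": basic_counts.get(r.id),
                "pattern": patterns.get(r.id, "NA"),
                "subfamily": subfamilies.get(r.id, "NA"),
                "origin": origins.get(r.id, "NA"),
                "block": blocks_of.get(r.id, "NA"),
                "n_specific_samples": spec_flags.get(r.id, 0),
                "n_hormones_responsive": hormone_counts.get(r.id, 0),
            }
            for r in records
        ]
    )
    summaries = summarize_categories(per_gene)
    if qpcr_rows:
        summaries["qpcr"] = pd.DataFrame(qpcr_rows)
    return SurveyReport(
        per_gene=per_gene, summaries=summaries, config=config, newick=newick
    )
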
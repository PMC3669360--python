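"""End-to-end orchestration: files in, tables + networks + report out.

Stage order mirrors the analysis narrative: quantile normalization ->
moderated differential expression per RNA class -> pathway
over-representation of the up- and down-regulated mRNA lists -> miRNA
target prediction -> intersection with the DE lists -> anticorrelation
filtering -> one co-expression network per condition -> core-factor
ranking by degree difference -> optional IC50 / resistance index.

Identical config + seed produces a byte-identical ``report.json``
(timestamps live only in the log file). Every intermediate table is
written under the configured output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diffexpr, doseresp, enrich, network, targets
from .matrix import ExpressionMatrix
from .synth import read_fasta

logger = logging.getLogger(__name__)

# below this probe count the quantile target is too unstable to be useful
MIN_PROBES_FOR_QN = 100


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    Thresholds default to the conventional screen: DE at p < 0.05 (set
    ``de_use_fdr`` to threshold the BH q-value instead), per-condition
    correlation screen at |r| >= 0.99, target anticorrelation at r < 0
    with opposite DE directions required.
    """

    mrna_matrix: str
    lncrna_matrix: str
    mirna_matrix: str
    design: str
    mirna_fasta: str
    utr_fasta: str
    gene_sets_gmt: str
    outdir: str
    dose_response_csv: str | None = None

    condition_a: str = "resistant"
    condition_b: str = "parental"
    quantile_normalize: bool = True
    de_p_threshold: float = 0.05
    de_use_fdr: bool = False
    de_fc_threshold: float | None = None
    enrich_p_threshold: float = 0.05
    r_min: float = 0.99
    corr_p_max: float = 0.05
    r_max: float = 0.0
    require_opposite_direction: bool = True
    k_core_k: int = 2
    top_n_core_factors: int = 10
    parental_line: str = "parental"
    resistant_line: str = "resistant"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.de_p_threshold <= 1 or not 0 < self.enrich_p_threshold <= 1:
            raise ValueError("p thresholds must lie in (0, 1]")
        if not 0 <= self.r_min <= 1:
            raise ValueError("r_min must lie in [0, 1]")
        if self.k_core_k < 1 or self.top_n_core_factors < 1:
            raise ValueError("k and top_n must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def content_hash(self) -> str:
        doc = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


@dataclass
class Diagnostic:
    level: str  # "warning" | "fatal"
    message: str


def validate_inputs(config: PipelineConfig) -> list[Diagnostic]:
    """Consistency checks across the configured inputs; never raises."""
    diags: list[Diagnostic] = []
    paths = {
        "mrna_matrix": config.mrna_matrix,
        "lncrna_matrix": config.lncrna_matrix,
        "mirna_matrix": config.mirna_matrix,
        "design": config.design,
        "mirna_fasta": config.mirna_fasta,
        "utr_fasta": config.utr_fasta,
        "gene_sets_gmt": config.gene_sets_gmt,
    }
    if config.dose_response_csv:
        paths["dose_response_csv"] = config.dose_response_csv
    missing = {k: p for k, p in paths.items() if not Path(p).is_file()}
    for k, p in missing.items():
        diags.append(Diagnostic("fatal", f"{k} file not found: {p}"))
    if missing:
        return diags

    try:
        matrices = {
            "mRNA": ExpressionMatrix.read_tsv(config.mrna_matrix, config.design),
            "lncRNA": ExpressionMatrix.read_tsv(config.lncrna_matrix, config.design),
            "miRNA": ExpressionMatrix.read_tsv(config.mirna_matrix, config.design),
        }
    except ValueError as exc:
        diags.append(Diagnostic("fatal", f"matrix/design inconsistency: {exc}"))
        return diags

    sample_sets = {c: tuple(m.sample_ids) for c, m in matrices.items()}
    if len(set(sample_sets.values())) != 1:
        diags.append(Diagnostic("fatal", "expression matrices disagree on samples"))
    for cond in (config.condition_a, config.condition_b):
        if cond not in matrices["mRNA"].conditions:
            diags.append(Diagnostic("fatal", f"condition {cond!r} absent from design"))

    try:
        mirna_seqs = read_fasta(config.mirna_fasta)
        utr_seqs = read_fasta(config.utr_fasta)
    except ValueError as exc:
        diags.append(Diagnostic("fatal", f"FASTA problem: {exc}"))
        return diags
    missing_mirna = [p for p in matrices["miRNA"].probe_ids if p not in mirna_seqs]
    if missing_mirna:
        diags.append(
            Diagnostic(
                "warning",
                f"{len(missing_mirna)} miRNA probes lack a mature sequence",
            )
        )
    missing_utr = [p for p in matrices["mRNA"].probe_ids if p not in utr_seqs]
    if missing_utr:
        diags.append(
            Diagnostic("warning", f"{len(missing_utr)} mRNA probes lack a 3'UTR sequence")
        )

    sets = enrich.read_gmt(config.gene_sets_gmt)
    universe = set(matrices["mRNA"].probe_ids)
    if sets and not any(gs.member_ids & universe for gs in sets):
        diags.append(Diagnostic("warning", "no gene set overlaps the mRNA universe"))
    return diags


def _write_de_table(records: pd.DataFrame, path: Path) -> None:
    out = records.rename(
        columns={"mean_a": "mean_A", "mean_b": "mean_B", "log2_fc": "log2FC"}
    )
    out.to_csv(path, sep="\t")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the report dict (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    try:
        return _run(config, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> dict:
    stage = "load"
    try:
        matrices = {
            "mRNA": ExpressionMatrix.read_tsv(config.mrna_matrix, config.design),
            "lncRNA": ExpressionMatrix.read_tsv(config.lncrna_matrix, config.design),
            "miRNA": ExpressionMatrix.read_tsv(config.mirna_matrix, config.design),
        }
        mirna_seqs = read_fasta(config.mirna_fasta)
        utr_seqs = read_fasta(config.utr_fasta)
        gene_sets = enrich.read_gmt(config.gene_sets_gmt)
        logger.info(
            "loaded matrices: %s",
            {c: m.values.shape for c, m in matrices.items()},
        )

        stage = "normalize"
        if config.quantile_normalize:
            # QN estimates a common distribution from the probes; with very
            # few probes rank collisions flatten real effects, so tiny
            # matrices are left on their original scale.
            for c, m in list(matrices.items()):
                if len(m.probe_ids) >= MIN_PROBES_FOR_QN:
                    matrices[c] = diffexpr.quantile_normalize(m)
                    logger.info("quantile normalization applied to %s", c)
                else:
                    logger.info(
                        "quantile normalization skipped for %s (%d probes < %d)",
                        c, len(m.probe_ids), MIN_PROBES_FOR_QN,
                    )

        stage = "differential expression"
        de_tables: dict[str, pd.DataFrame] = {}
        de_up: dict[str, list[str]] = {}
        de_down: dict[str, list[str]] = {}
        # The variance prior is an array-wide nuisance parameter; a class
        # with too few probes to fit its own borrows the mRNA-array prior.
        fallback_prior = None
        for c in ("mRNA", "lncRNA", "miRNA"):
            m = matrices[c]
            try:
                records = diffexpr.rvm_t_test(m, config.condition_a, config.condition_b)
            except ValueError:
                if fallback_prior is None:
                    raise
                logger.info("class %s too small for its own prior; borrowing mRNA prior", c)
                records = diffexpr.rvm_t_test(
                    m, config.condition_a, config.condition_b, prior=fallback_prior
                )
            if c == "mRNA":
                sa = m.samples_for(config.condition_a)
                sb = m.samples_for(config.condition_b)
                d = len(sa) + len(sb) - 2
                fallback_prior = diffexpr.fit_rvm_prior(records["s2"], d)
            up, down = diffexpr.classify_de(
                records,
                p_threshold=config.de_p_threshold,
                fdr=config.de_use_fdr,
                fc_threshold=config.de_fc_threshold,
            )
            de_tables[c] = records
            de_up[c], de_down[c] = up, down
            _write_de_table(records, outdir / f"de_{c.lower()}.tsv")
            logger.info("DE %s: %d up, %d down of %d probes", c, len(up), len(down), len(records))

        stage = "hierarchical clustering"
        de_mrna_ids = de_up["mRNA"] + de_down["mRNA"]
        if len(de_mrna_ids) >= 2 and len(matrices["mRNA"].sample_ids) >= 2:
            sub = matrices["mRNA"].subset_probes(de_mrna_ids)
            z, leaves = diffexpr.hierarchical_cluster(sub, axis="samples")
            (outdir / "sample_clustering.newick").write_text(
                diffexpr.linkage_to_newick(z, sub.sample_ids) + "\n"
            )
            sub.values.loc[:, leaves].to_csv(outdir / "de_mrna_reordered.tsv", sep="\t")

        stage = "pathway enrichment"
        universe = matrices["mRNA"].probe_ids
        enrich_records = {}
        for direction, idlist in (("up", de_up["mRNA"]), ("down", de_down["mRNA"])):
            records = enrich.enrich_gene_sets(
                idlist, universe, gene_sets, p_threshold=config.enrich_p_threshold
            )
            enrich.records_to_frame(records).to_csv(
                outdir / f"enrichment_{direction}.tsv", sep="\t", index=False
            )
            enrich_records[direction] = records
            logger.info(
                "enrichment (%s): %d sets scored, %d significant",
                direction,
                len(records),
                sum(r.significant for r in records),
            )

        stage = "target prediction"
        relations = targets.predict_targets(mirna_seqs, utr_seqs)
        n_predicted = len(relations)

        stage = "DE intersection"
        de_mirna_ids = de_up["miRNA"] + de_down["miRNA"]
        intersected = targets.intersect_with_de(relations, de_mrna_ids, de_mirna_ids)

        stage = "anticorrelation filter"
        directions_mirna = dict(de_tables["miRNA"]["direction"])
        directions_mrna = dict(de_tables["mRNA"]["direction"])
        filtered = targets.anticorrelation_filter(
            intersected,
            matrices["miRNA"],
            matrices["mRNA"],
            r_max=config.r_max,
            require_opposite_direction=config.require_opposite_direction,
            mirna_directions=directions_mirna,
            mrna_directions=directions_mrna,
        )
        pd.DataFrame(targets.relations_to_rows(filtered)).to_csv(
            outdir / "target_relations.tsv", sep="\t", index=False
        )
        logger.info(
            "target funnel: %d predicted -> %d DE-intersected -> %d anticorrelated",
            n_predicted,
            len(intersected),
            len(filtered),
        )

        stage = "network construction"
        directions_all = {
            **directions_mrna,
            **directions_mirna,
            **dict(de_tables["lncRNA"]["direction"]),
        }
        de_probe_sets = {
            "mRNA": de_mrna_ids,
            "lncRNA": de_up["lncRNA"] + de_down["lncRNA"],
            "miRNA": de_mirna_ids,
        }
        networks = []
        for cond in (config.condition_b, config.condition_a):
            sub = {
                c: matrices[c].subset_probes(de_probe_sets[c])
                for c in matrices
                if de_probe_sets[c]
            }
            if sub:
                cond_samples = matrices["mRNA"].samples_for(cond)
                pairs = network.correlation_pairs(
                    sub,
                    sample_subset=cond_samples,
                    r_min=config.r_min,
                    p_max=config.corr_p_max,
                )
            else:
                pairs = []
            net = network.build_network(
                pairs, filtered, gene_sets, cond, directions=directions_all
            )
            networks.append(net)
            network.write_sif(net, outdir / f"network_{cond}.sif")
            network.write_graphml(net, outdir / f"network_{cond}.graphml")
            network.write_node_metrics(net, outdir / f"network_{cond}_nodes.tsv")
            logger.info("network %s: %s", cond, net.summary())
        network.write_summary(networks, outdir / "network_summary.json")

        stage = "core factors"
        cores = network.core_regulatory_factors(
            networks[0], networks[1], top_n=config.top_n_core_factors
        )
        cores.to_csv(outdir / "core_factors.tsv", sep="\t", index=False)

        stage = "dose response"
        dose_block = None
        if config.dose_response_csv:
            curves = doseresp.read_viability_csv(config.dose_response_csv)
            ic50s = {
                name: doseresp.estimate_ic50(curve) for name, curve in curves.items()
            }
            dose_block = {"ic50": ic50s}
            if config.parental_line in ic50s and config.resistant_line in ic50s:
                dose_block["resistance_index"] = doseresp.resistance_index(
                    ic50s[config.resistant_line], ic50s[config.parental_line]
                )
            with open(outdir / "ic50.json", "w") as fh:
                json.dump(dose_block, fh, indent=2, sort_keys=True)
                fh.write("\n")
            logger.info("dose response: %s", dose_block)
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = {
        "provenance": {"config_hash": config.content_hash(), "seed": config.seed},
        "de_counts": {
            c: {"up": len(de_up[c]), "down": len(de_down[c]), "total": len(de_tables[c])}
            for c in de_tables
        },
        "target_funnel": {
            "predicted": n_predicted,
            "de_intersected": len(intersected),
            "anticorrelated": len(filtered),
        },
        "enrichment": {
            direction: [
                {"set_id": r.set_id, "Re": r.Re, "p_fisher": r.p_fisher, "q": r.q_value}
                for r in records[:10]
            ]
            for direction, records in enrich_records.items()
        },
        "networks": [n.summary() for n in networks],
        "core_factors": cores.to_dict(orient="records"),
        "dose_response": dose_block,
    }
    with open(Path(config.outdir) / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_markdown_summary(report, Path(config.outdir) / "report.md")
    return report


def _write_markdown_summary(report: dict, path: Path) -> None:
    lines = ["# Pipeline summary", ""]
    lines.append("## Differential expression")
    for c, d in report["de_counts"].items():
        lines.append(f"- {c}: {d['up']} up, {d['down']} down (of {d['total']})")
    f = report["target_funnel"]
    lines += [
        "",
        "## miRNA target funnel",
        f"- predicted relations: {f['predicted']}",
        f"- after DE intersection: {f['de_intersected']}",
        f"- after anticorrelation filter: {f['anticorrelated']}",
        "",
        "## Networks",
    ]
    for n in report["networks"]:
        lines.append(
            f"- {n['condition']}: {n['n_nodes']} nodes / {n['n_edges']} edges "
            f"({n['nodes_by_class']})"
        )
    if report.get("dose_response"):
        lines += ["", "## Dose response", f"- {report['dose_response']}"]
    path.write_text("\n".join(lines) + "\n")
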
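"""Synthetic two-condition expression datasets with known ground truth.

The generator emulates the design of a parental-vs-resistant cell-line
microarray study run in triplicate: three probe-by-sample matrices (mRNA,
lncRNA, miRNA) on the log2 scale, mature miRNA and 3'UTR sequences, and
pathway gene sets, together with a truth record of everything planted:

* differential expression — a fraction of probes per class receives a
  condition effect of +/- ``log2_effect_size`` in the resistant samples,
  with both directions represented;
* lncRNA–mRNA co-expression blocks — members share a per-sample latent
  factor whose loading is set to hit ``block_corr`` in expectation;
* miRNA -> mRNA repression — planted pairs are differentially expressed
  in opposite directions (hence anticorrelated across the pooled samples)
  and the target's UTR carries a planted 8mer seed site;
* gene sets — one set enriched for planted differential mRNAs plus null
  sets drawn uniformly.

Intensities are additive Gaussian on the log2 scale. Per-probe residual
variances are drawn from an inverse-gamma distribution (shape 3, scaled
so the mean variance is ``noise_sd**2``) — the same family the moderated
t-test assumes, and the heterogeneity real arrays show. A single integer
seed drives all randomness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, write_design_tsv
from .enrich import GeneSet, read_gmt, write_gmt
from .targets import find_seed_sites, normalize_rna, seed_site_text

CONDITIONS = ("parental", "resistant")
_BASELINE_MEAN = 9.0
_BASELINE_SD = 2.0
_VARIANCE_SHAPE = 3.0  # inverse-gamma shape of per-probe residual variances
_BLOCK_SIZE = 8  # probes per planted co-expression block (half lncRNA, half mRNA)
_MIRNA_LENGTH = 22
_ENRICHED_SET_DE = 20  # planted-pathway members drawn from DE mRNAs
_ENRICHED_SET_NULL = 10


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic two-condition triplicate design."""

    n_mrna: int = 600
    n_lncrna: int = 400
    n_mirna: int = 30
    n_reps_per_condition: int = 3
    de_fraction: float = 0.10
    log2_effect_size: float = 2.0
    noise_sd: float = 0.5
    n_corr_blocks: int = 4
    block_corr: float = 0.9
    n_planted_targets: int = 30
    utr_length: int = 200
    n_gene_sets: int = 10
    gene_set_size: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mrna", "n_lncrna", "n_mirna", "n_reps_per_condition", "utr_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if abs(self.block_corr) > 1:
            raise ValueError("|block_corr| must be <= 1")
        if self.n_planted_targets > self.n_mrna:
            raise ValueError("planted targets exceed mRNA probes")
        n_de_mrna = round(self.de_fraction * self.n_mrna)
        if self.n_planted_targets > 0:
            if n_de_mrna < self.n_planted_targets:
                raise ValueError(
                    "de_fraction leaves fewer DE mRNAs than planted targets"
                )
            if round(self.de_fraction * self.n_mirna) < 1:
                raise ValueError("planted targets need >= 1 DE miRNA")
        if self.n_corr_blocks * _BLOCK_SIZE // 2 > min(self.n_mrna, self.n_lncrna):
            raise ValueError("correlation blocks exceed available probes")


@dataclass
class SynthTruth:
    """Ground truth of everything the generator planted."""

    de_labels: dict[str, dict[str, str]]  # class -> probe -> up/down
    planted_pairs: list[tuple[str, str]]  # (miRNA id, mRNA id)
    block_membership: dict[str, int]  # probe -> block id
    planted_site_positions: dict[str, list[int]]  # "mRNA|miRNA" -> 1-based starts

    def label(self, rna_class: str, probe: str) -> str:
        return self.de_labels.get(rna_class, {}).get(probe, "null")

    def de_ids(self, rna_class: str) -> set[str]:
        return set(self.de_labels.get(rna_class, {}))


@dataclass
class SynthDataset:
    config: SynthConfig
    mrna: ExpressionMatrix
    lncrna: ExpressionMatrix
    mirna: ExpressionMatrix
    mirna_seqs: dict[str, str]
    utr_seqs: dict[str, str]
    gene_sets: list[GeneSet]
    truth: SynthTruth


def _ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _sample_frame(n_reps: int) -> pd.DataFrame:
    rows = [
        {"sample_id": f"{cond}_{r + 1}", "condition": cond, "replicate": r + 1}
        for cond in CONDITIONS
        for r in range(n_reps)
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def plant_seed_sites(utr: str, mirna: str, site_type: str, position: int) -> str:
    """Splice a canonical seed site into a UTR at a 1-based position."""
    u = normalize_rna(utr)
    site = seed_site_text(mirna, site_type)
    if position < 1 or position + len(site) - 1 > len(u):
        raise ValueError("site position out of UTR range")
    i = position - 1
    return u[:i] + site + u[i + len(site):]


def generate_dataset(config: SynthConfig) -> SynthDataset:
    """Deterministically generate one synthetic dataset from a config."""
    rng = np.random.default_rng(config.seed)
    design = _sample_frame(config.n_reps_per_condition)
    samples = list(design.index)
    n_samples = len(samples)
    resistant = np.array(
        [design.loc[s, "condition"] == "resistant" for s in samples], dtype=float
    )

    ids = {
        "mRNA": _ids("MRNA", config.n_mrna),
        "lncRNA": _ids("LNC", config.n_lncrna),
        "miRNA": _ids("MIR", config.n_mirna),
    }

    # --- choose DE probes and directions -----------------------------
    de_labels: dict[str, dict[str, str]] = {c: {} for c in ids}
    counts = {
        "mRNA": round(config.de_fraction * config.n_mrna),
        "lncRNA": round(config.de_fraction * config.n_lncrna),
        "miRNA": round(config.de_fraction * config.n_mirna),
    }
    chosen: dict[str, list[str]] = {}
    for c in ids:
        chosen[c] = list(rng.choice(ids[c], size=counts[c], replace=False))

    # planted miRNA -> mRNA pairs: miRNA and target DE in opposite directions
    planted_pairs: list[tuple[str, str]] = []
    if config.n_planted_targets > 0 and counts["miRNA"] > 0:
        mirna_dirs = {
            m: ("up" if rng.random() < 0.5 else "down") for m in chosen["miRNA"]
        }
        de_labels["miRNA"] = dict(mirna_dirs)
        target_mrnas = chosen["mRNA"][: config.n_planted_targets]
        pair_mirnas = rng.choice(chosen["miRNA"], size=config.n_planted_targets)
        for mirna_id, mrna_id in zip(pair_mirnas, target_mrnas):
            planted_pairs.append((str(mirna_id), mrna_id))
            de_labels["mRNA"][mrna_id] = (
                "down" if mirna_dirs[str(mirna_id)] == "up" else "up"
            )
        for mrna_id in chosen["mRNA"][config.n_planted_targets :]:
            de_labels["mRNA"][mrna_id] = "up" if rng.random() < 0.5 else "down"
    else:
        for c in ("miRNA", "mRNA"):
            for probe in chosen[c]:
                de_labels[c][probe] = "up" if rng.random() < 0.5 else "down"
    for probe in chosen["lncRNA"]:
        de_labels["lncRNA"][probe] = "up" if rng.random() < 0.5 else "down"

    # --- co-expression blocks over non-DE lncRNA/mRNA probes ---------
    block_membership: dict[str, int] = {}
    half = _BLOCK_SIZE // 2
    free_mrna = [p for p in ids["mRNA"] if p not in de_labels["mRNA"]]
    free_lnc = [p for p in ids["lncRNA"] if p not in de_labels["lncRNA"]]
    block_mrna = rng.choice(free_mrna, size=config.n_corr_blocks * half, replace=False)
    block_lnc = rng.choice(free_lnc, size=config.n_corr_blocks * half, replace=False)
    for b in range(config.n_corr_blocks):
        for p in list(block_mrna[b * half : (b + 1) * half]) + list(
            block_lnc[b * half : (b + 1) * half]
        ):
            block_membership[str(p)] = b
    block_factors = rng.standard_normal((config.n_corr_blocks, n_samples))

    # --- intensities ---------------------------------------------------
    matrices: dict[str, ExpressionMatrix] = {}
    rho = config.block_corr
    for c in ids:
        n_probes = len(ids[c])
        baseline = rng.normal(_BASELINE_MEAN, _BASELINE_SD, size=n_probes)
        # per-probe residual variance ~ inverse-gamma, mean noise_sd^2
        gam = rng.gamma(
            _VARIANCE_SHAPE,
            1.0 / (config.noise_sd**2 * (_VARIANCE_SHAPE - 1.0)),
            size=n_probes,
        )
        sigma = 1.0 / np.sqrt(gam)
        x = baseline[:, None] + rng.standard_normal((n_probes, n_samples)) * sigma[:, None]
        for i, probe in enumerate(ids[c]):
            label = de_labels[c].get(probe)
            if label is not None:
                effect = config.log2_effect_size if label == "up" else -config.log2_effect_size
                x[i] += effect * resistant
            if probe in block_membership and rho != 0:
                lam = np.sign(rho) * sigma[i] * np.sqrt(abs(rho) / (1.0 - abs(rho)))
                x[i] += lam * block_factors[block_membership[probe]]
        matrices[c] = ExpressionMatrix(
            values=pd.DataFrame(x, index=ids[c], columns=samples), design=design
        )

    # --- sequences -----------------------------------------------------
    mirna_seqs = {m: _random_rna(rng, _MIRNA_LENGTH) for m in ids["miRNA"]}
    utr_seqs = {g: _random_rna(rng, config.utr_length) for g in ids["mRNA"]}
    planted_site_positions: dict[str, list[int]] = {}
    for mirna_id, mrna_id in planted_pairs:
        pos = int(rng.integers(1, config.utr_length - 8 + 2))
        utr_seqs[mrna_id] = plant_seed_sites(
            utr_seqs[mrna_id], mirna_seqs[mirna_id], "8mer", pos
        )
        planted_site_positions.setdefault(f"{mrna_id}|{mirna_id}", []).append(pos)

    # --- gene sets -----------------------------------------------------
    gene_sets: list[GeneSet] = []
    de_mrnas = sorted(de_labels["mRNA"])
    if de_mrnas and config.n_gene_sets > 0:
        n_de_pick = min(_ENRICHED_SET_DE, len(de_mrnas))
        members = set(rng.choice(de_mrnas, size=n_de_pick, replace=False))
        members |= set(
            rng.choice(ids["mRNA"], size=_ENRICHED_SET_NULL, replace=False)
        )
        gene_sets.append(
            GeneSet("PATHWAY_PLANTED", "enriched for planted DE mRNAs", frozenset(members))
        )
    while len(gene_sets) < config.n_gene_sets:
        members = frozenset(
            rng.choice(ids["mRNA"], size=min(config.gene_set_size, config.n_mrna), replace=False)
        )
        gene_sets.append(
            GeneSet(f"PATHWAY_NULL{len(gene_sets):02d}", "random background set", members)
        )

    truth = SynthTruth(
        de_labels={c: dict(sorted(d.items())) for c, d in de_labels.items()},
        planted_pairs=sorted(planted_pairs),
        block_membership=block_membership,
        planted_site_positions=planted_site_positions,
    )
    return SynthDataset(
        config=config,
        mrna=matrices["mRNA"],
        lncrna=matrices["lncRNA"],
        mirna=matrices["miRNA"],
        mirna_seqs=mirna_seqs,
        utr_seqs=utr_seqs,
        gene_sets=gene_sets,
        truth=truth,
    )


# ----------------------------------------------------------------------
# fixture I/O
# ----------------------------------------------------------------------

def _write_fasta(seqs: Mapping[str, str], path: Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_fixtures(dataset: SynthDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset as plain-text fixtures; returns a file manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    for name, matrix in (
        ("mrna", dataset.mrna),
        ("lncrna", dataset.lncrna),
        ("mirna", dataset.mirna),
    ):
        path = out / f"{name}.tsv"
        matrix.write_tsv(path)
        manifest[f"{name}_matrix"] = path
    write_design_tsv(dataset.mrna.design, out / "design.tsv")
    manifest["design"] = out / "design.tsv"

    _write_fasta(dataset.mirna_seqs, out / "mirna.fasta")
    manifest["mirna_fasta"] = out / "mirna.fasta"
    _write_fasta(dataset.utr_seqs, out / "utr.fasta")
    manifest["utr_fasta"] = out / "utr.fasta"

    write_gmt(dataset.gene_sets, out / "gene_sets.gmt")
    manifest["gene_sets"] = out / "gene_sets.gmt"

    truth = {
        "config": asdict(dataset.config),
        "de_labels": dataset.truth.de_labels,
        "planted_pairs": [list(p) for p in dataset.truth.planted_pairs],
        "block_membership": dataset.truth.block_membership,
        "planted_site_positions": dataset.truth.planted_site_positions,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["truth"] = out / "truth.json"
    return manifest


def read_fixtures(dir_path: str | Path) -> SynthDataset:
    """Inverse of :func:`write_fixtures`; reproduces the dataset exactly."""
    d = Path(dir_path)
    with open(d / "truth.json") as fh:
        truth_doc = json.load(fh)
    config = SynthConfig(**truth_doc["config"])
    truth = SynthTruth(
        de_labels=truth_doc["de_labels"],
        planted_pairs=[tuple(p) for p in truth_doc["planted_pairs"]],
        block_membership=truth_doc["block_membership"],
        planted_site_positions=truth_doc["planted_site_positions"],
    )
    return SynthDataset(
        config=config,
        mrna=ExpressionMatrix.read_tsv(d / "mrna.tsv", d / "design.tsv"),
        lncrna=ExpressionMatrix.read_tsv(d / "lncrna.tsv", d / "design.tsv"),
        mirna=ExpressionMatrix.read_tsv(d / "mirna.tsv", d / "design.tsv"),
        mirna_seqs=read_fasta(d / "mirna.fasta"),
        utr_seqs=read_fasta(d / "utr.fasta"),
        gene_sets=read_gmt(d / "gene_sets.gmt"),
        truth=truth,
    )
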
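"""Seed-based miRNA target-site prediction and expression filtering.

Canonical site classes on a 3'UTR, for a mature miRNA read 5'->3':

* ``8mer``     — perfect Watson–Crick complement of miRNA positions 2–8,
  followed (3' on the UTR) by an A opposite miRNA position 1;
* ``7mer-m8``  — perfect complement of positions 2–8, no A1;
* ``7mer-A1``  — perfect complement of positions 2–7 plus the A1.

No G:U wobble is allowed in the seed, and the A1 nucleotide must literally
be an A on the UTR (it is not required to pair with miRNA position 1).
Coordinates are 1-based inclusive on the UTR in its 5'->3' sense.

An optional non-default mode also reports 3'-compensatory sites: a seed
match of positions 2–7 with exactly one mismatch rescued by at least four
consecutive Watson–Crick pairs to miRNA positions 13–17.

Prediction is intersected with differential-expression calls and then
screened by expression anticorrelation: a candidate repression pair should
show negative miRNA–mRNA correlation across samples and opposite
differential-expression directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .matrix import ExpressionMatrix

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")
COMPENSATORY = "3p-compensatory"

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_ALPHABET = set("ACGUT")


def normalize_rna(seq: str) -> str:
    """Uppercase and fold T onto U; reject non-nucleotide characters."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    s = normalize_rna(seq)
    return "".join(_COMPLEMENT[c] for c in reversed(s))


def seed_site_text(mirna: str, site_type: str) -> str:
    """UTR text (5'->3') of a canonical site for ``mirna`` (5'->3')."""
    m = normalize_rna(mirna)
    if len(m) < 8:
        raise ValueError("miRNA shorter than 8 nt")
    if site_type == "8mer":
        return reverse_complement(m[1:8]) + "A"
    if site_type == "7mer-m8":
        return reverse_complement(m[1:8])
    if site_type == "7mer-A1":
        return reverse_complement(m[1:7]) + "A"
    raise ValueError(f"unknown site type {site_type!r}")


@dataclass(frozen=True)
class SeedSite:
    """One seed-match occurrence on a 3'UTR (1-based inclusive coords)."""

    site_type: str
    utr_start: int
    utr_end: int
    site_sequence: str
    mirna_id: str = ""
    mrna_id: str = ""


@dataclass
class TargetRelation:
    """One candidate miRNA -> mRNA regulation with its supporting sites."""

    mirna_id: str
    mrna_id: str
    sites: list[SeedSite]
    correlation_r: float | None = None
    passed_de_intersection: bool = False
    passed_anticorrelation: bool = False

    @property
    def best_site_type(self) -> str:
        order = {"8mer": 0, "7mer-m8": 1, "7mer-A1": 2, COMPENSATORY: 3}
        return min((s.site_type for s in self.sites), key=order.__getitem__)


def _occurrences(text: str, pattern: str) -> list[int]:
    """All (overlapping) 0-based start offsets of ``pattern`` in ``text``."""
    hits, i = [], text.find(pattern)
    while i != -1:
        hits.append(i)
        i = text.find(pattern, i + 1)
    return hits


def find_seed_sites(
    mirna: str, utr: str, include_compensatory: bool = False
) -> list[SeedSite]:
    """Scan a 3'UTR for canonical seed sites of one miRNA.

    Every maximal occurrence is reported once at its own coordinates; an
    8mer suppresses the 7mer classifications contained within its span.
    """
    m = normalize_rna(mirna)
    if len(m) < 8:
        raise ValueError("miRNA shorter than 8 nt")
    u = normalize_rna(utr)

    t8 = seed_site_text(m, "8mer")
    t7m8 = seed_site_text(m, "7mer-m8")
    t7a1 = seed_site_text(m, "7mer-A1")

    sites: list[SeedSite] = []
    spans8 = [(i, i + 8) for i in _occurrences(u, t8)]
    for i, j in spans8:
        sites.append(SeedSite("8mer", i + 1, j, u[i:j]))

    def contained_in_8mer(i: int, j: int) -> bool:
        return any(a <= i and j <= b for a, b in spans8)

    for i in _occurrences(u, t7m8):
        if not contained_in_8mer(i, i + 7):
            sites.append(SeedSite("7mer-m8", i + 1, i + 7, u[i : i + 7]))
    for i in _occurrences(u, t7a1):
        if not contained_in_8mer(i, i + 7):
            # avoid double-reporting a span already classified as 7mer-m8
            if t7a1 != t7m8 or not any(
                s.utr_start == i + 1 and s.site_type == "7mer-m8" for s in sites
            ):
                sites.append(SeedSite("7mer-A1", i + 1, i + 7, u[i : i + 7]))

    if include_compensatory:
        canonical_starts = {s.utr_start for s in sites}
        for s in _compensatory_sites(m, u):
            if s.utr_start not in canonical_starts:
                sites.append(s)

    sites.sort(key=lambda s: (s.utr_start, s.site_type))
    return sites


def _compensatory_sites(m: str, u: str) -> list[SeedSite]:
    """Seed 2–7 with one mismatch rescued by >=4 consecutive WC pairs to
    miRNA positions 13–17. Off by default; thresholds are this package's
    reading of the loosely defined class."""
    if len(m) < 17:
        return []
    seed6 = seed_site_text(m, "7mer-A1")[:6]  # complement of positions 2-7
    comp3p = reverse_complement(m[12:17])  # pairs miRNA 13..17, UTR 5'->3'
    out: list[SeedSite] = []
    for i in range(len(u) - 5):
        window = u[i : i + 6]
        mism = sum(1 for a, b in zip(window, seed6) if a != b)
        if mism != 1:
            continue
        # miRNA position 13 pairs the UTR nucleotide 6 upstream of the
        # seed-window start; positions 13-17 occupy u[i-10 : i-5].
        lo = i - 10
        if lo < 0:
            continue
        region = u[lo : lo + 5]
        run = best = 0
        for a, b in zip(region, comp3p):
            run = run + 1 if a == b else 0
            best = max(best, run)
        if best >= 4:
            out.append(SeedSite(COMPENSATORY, i + 1, i + 6, window))
    return out


def predict_targets(
    mirnas: Mapping[str, str],
    utrs: Mapping[str, str],
    include_compensatory: bool = False,
) -> list[TargetRelation]:
    """One relation per (miRNA, mRNA) pair with at least one seed site."""
    if not mirnas or not utrs:
        raise ValueError("empty sequence collection")
    for name, coll in (("miRNA", mirnas), ("UTR", utrs)):
        if len(set(coll)) != len(coll):
            raise ValueError(f"duplicate {name} ids")
    relations: list[TargetRelation] = []
    norm_utrs = {mid: normalize_rna(s) for mid, s in utrs.items()}
    for mirna_id in sorted(mirnas):
        mseq = mirnas[mirna_id]
        for mrna_id in sorted(norm_utrs):
            sites = find_seed_sites(
                mseq, norm_utrs[mrna_id], include_compensatory=include_compensatory
            )
            if sites:
                sites = [
                    replace(s, mirna_id=mirna_id, mrna_id=mrna_id) for s in sites
                ]
                relations.append(TargetRelation(mirna_id, mrna_id, sites))
    return relations


def intersect_with_de(
    relations: Iterable[TargetRelation],
    de_mrna_ids: Iterable[str],
    de_mirna_ids: Iterable[str],
) -> list[TargetRelation]:
    """Keep relations whose mRNA and miRNA are both differentially expressed."""
    mr, mi = set(de_mrna_ids), set(de_mirna_ids)
    kept = []
    for rel in relations:
        if rel.mrna_id in mr and rel.mirna_id in mi:
            kept.append(
                replace_relation(rel, passed_de_intersection=True)
            )
    return kept


def replace_relation(rel: TargetRelation, **kw) -> TargetRelation:
    return TargetRelation(
        mirna_id=rel.mirna_id,
        mrna_id=rel.mrna_id,
        sites=list(rel.sites),
        correlation_r=kw.get("correlation_r", rel.correlation_r),
        passed_de_intersection=kw.get(
            "passed_de_intersection", rel.passed_de_intersection
        ),
        passed_anticorrelation=kw.get(
            "passed_anticorrelation", rel.passed_anticorrelation
        ),
    )


def anticorrelation_filter(
    relations: Iterable[TargetRelation],
    mirna_matrix: ExpressionMatrix,
    mrna_matrix: ExpressionMatrix,
    r_max: float = 0.0,
    require_opposite_direction: bool = True,
    mirna_directions: Mapping[str, str] | None = None,
    mrna_directions: Mapping[str, str] | None = None,
) -> list[TargetRelation]:
    """Retain relations with Pearson r < ``r_max`` across all shared samples.

    With ``require_opposite_direction`` the miRNA and mRNA must also carry
    opposite differential-expression directions (up vs down), mirroring a
    repression screen; direction maps are then mandatory.
    """
    if list(mirna_matrix.sample_ids) != list(mrna_matrix.sample_ids):
        raise ValueError("miRNA and mRNA matrices must share sample ordering")
    if require_opposite_direction and (
        mirna_directions is None or mrna_directions is None
    ):
        raise ValueError("direction maps required when filtering on direction")

    kept = []
    for rel in relations:
        x = mirna_matrix.values.loc[rel.mirna_id].to_numpy(dtype=float)
        y = mrna_matrix.values.loc[rel.mrna_id].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if not (r < r_max):
            continue
        if require_opposite_direction:
            da = mirna_directions.get(rel.mirna_id, "null")
            db = mrna_directions.get(rel.mrna_id, "null")
            if {da, db} != {"up", "down"}:
                continue
        kept.append(
            replace_relation(rel, correlation_r=r, passed_anticorrelation=True)
        )
    return kept


def relations_to_rows(relations: Iterable[TargetRelation]) -> list[dict]:
    """Flatten relations for TSV export."""
    rows = []
    for rel in relations:
        rows.append(
            {
                "mirna_id": rel.mirna_id,
                "mrna_id": rel.mrna_id,
                "n_sites": len(rel.sites),
                "best_site_type": rel.best_site_type,
                "site_coords": ";".join(
                    f"{s.site_type}:{s.utr_start}-{s.utr_end}" for s in rel.sites
                ),
                "r": "" if rel.correlation_r is None else rel.correlation_r,
                "passed_de_intersection": rel.passed_de_intersection,
                "passed_anticorrelation": rel.passed_anticorrelation,
            }
        )
    return rows
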
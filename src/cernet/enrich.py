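"""Gene-set over-representation analysis with an explicit enrichment ratio.

For a gene set ("category", e.g. a KEGG pathway) tested against a list of
differential genes drawn from an array-wide universe, let

    nf = differential genes inside the set,
    n  = all differential genes on the array,
    Nf = set members present on the array,
    N  = all genes on the array.

The enrichment ratio is Re = (nf/n) / (Nf/N) — the observed proportion of
differential genes in the category over its background proportion.
Significance is assessed by the one-sided Fisher exact test (the
hypergeometric upper tail P(X >= nf)), with a Pearson chi-square p on the
same 2x2 table reported as a cross-check, and Benjamini–Hochberg FDR
across sets within one run. Up- and down-regulated lists are conventionally
tested in separate runs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    member_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError(f"gene set {self.set_id!r} is empty")


@dataclass(frozen=True)
class EnrichmentRecord:
    set_id: str
    nf: int
    n: int
    Nf: int
    N: int
    Re: float
    p_fisher: float
    p_chisq: float
    q_value: float = math.nan
    significant: bool = False


def enrichment_ratio(nf: int, n: int, Nf: int, N: int) -> float:
    """Re = (nf/n) / (Nf/N)."""
    if n <= 0 or Nf <= 0 or N <= 0:
        raise ZeroDivisionError("n, Nf and N must be positive")
    return (nf / n) / (Nf / N)


def _validate_table(nf: int, n: int, Nf: int, N: int) -> None:
    if min(nf, n, Nf, N) < 0:
        raise ValueError("negative count")
    if n > N or Nf > N:
        raise ValueError("margins exceed the universe")
    if nf > min(n, Nf) or nf < max(0, n + Nf - N):
        raise ValueError("inconsistent 2x2 margins")


def overrepresentation_test(nf: int, n: int, Nf: int, N: int) -> tuple[float, float]:
    """One-sided Fisher (hypergeometric tail sum) and Pearson chi-square p.

    Fisher: P(X >= nf) for X ~ Hypergeometric(N, Nf, n), computed as the
    explicit tail sum of the pmf. Chi-square: no continuity correction;
    NaN when a zero margin makes the statistic undefined.
    """
    _validate_table(nf, n, Nf, N)
    ks = np.arange(nf, min(n, Nf) + 1)
    p_fisher = float(np.clip(stats.hypergeom.pmf(ks, N, Nf, n).sum(), 0.0, 1.0))

    table = np.array([[nf, n - nf], [Nf - nf, N - n - Nf + nf]])
    try:
        p_chisq = float(stats.chi2_contingency(table, correction=False).pvalue)
    except ValueError:  # zero row/column margin
        p_chisq = math.nan
    return p_fisher, p_chisq


def enrich_gene_sets(
    de_ids: Iterable[str],
    universe_ids: Iterable[str],
    sets: Sequence[GeneSet],
    p_threshold: float = 0.05,
) -> list[EnrichmentRecord]:
    """Score every gene set against a differential list.

    Set membership is intersected with the universe first; sets disjoint
    from the universe are dropped with a warning. Records come back sorted
    by ascending Fisher p (ties by set id), with BH q-values across sets.
    """
    universe = set(universe_ids)
    de = set(de_ids)
    stray = de - universe
    if stray:
        raise ValueError(f"differential genes absent from universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(de)

    rows: list[EnrichmentRecord] = []
    for gs in sets:
        members = gs.member_ids & universe
        if not members:
            logger.warning("gene set %s is disjoint from the universe; dropped", gs.set_id)
            continue
        Nf = len(members)
        nf = len(members & de)
        if n == 0:
            re_, p_fisher, p_chisq = 0.0, 1.0, math.nan
        else:
            re_ = enrichment_ratio(nf, n, Nf, N)
            p_fisher, p_chisq = overrepresentation_test(nf, n, Nf, N)
        rows.append(
            EnrichmentRecord(gs.set_id, nf, n, Nf, N, re_, p_fisher, p_chisq)
        )

    rows.sort(key=lambda r: (r.p_fisher, r.set_id))
    qs = bh_fdr([r.p_fisher for r in rows]) if rows else []
    return [
        EnrichmentRecord(
            r.set_id, r.nf, r.n, r.Nf, r.N, r.Re, r.p_fisher, r.p_chisq,
            q_value=float(q), significant=bool(r.p_fisher < p_threshold),
        )
        for r, q in zip(rows, qs)
    ]


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "nf": r.nf,
                "n": r.n,
                "Nf": r.Nf,
                "N": r.N,
                "Re": r.Re,
                "p_fisher": r.p_fisher,
                "p_chisq": r.p_chisq,
                "q": r.q_value,
                "significant": r.significant,
            }
            for r in records
        ]
    )


# ----------------------------------------------------------------------
# GMT I/O
# ----------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """GMT: one set per line — name, description, then tab-separated members."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            members = frozenset(m for m in parts[2:] if m)
            sets.append(GeneSet(parts[0], parts[1], members))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.set_id, gs.description, *sorted(gs.member_ids)]))
            fh.write("\n")


def plot_enrichment(records: Sequence[EnrichmentRecord], path: str | Path, title: str = "") -> None:
    """Horizontal bar chart of -log10(Fisher p) per set."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    recs = list(records)[::-1]
    names = [r.set_id for r in recs]
    heights = [-math.log10(max(r.p_fisher, 1e-300)) for r in recs]
    fig, ax = plt.subplots(figsize=(6, max(2, 0.35 * len(recs))))
    ax.barh(names, heights, color="#4477aa")
    ax.set_xlabel("-log10 (p value)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
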
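"""Hypergeometric over-representation analysis of the key target genes.

Each term in a gene-set collection (GO BP/CC/MF categories or pathways) is
tested for overlap with the query list using the upper-tail hypergeometric
probability P(X >= k) for X ~ Hypergeom(N, K, n): N background genes, K term
members, n query genes, k overlapping. An optional EASE variant computes the
tail at k-1, the conservative score some annotation servers report. Rows are
filtered at raw p < p_max and sorted by overlap count descending (ties by p,
then term id) — the ranking convention of the screening procedure. A
Benjamini–Hochberg adjusted p is reported per category alongside but is not
used for filtering by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import NetpharmError

CATEGORIES = ("BP", "CC", "MF", "pathway")


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    category: str
    genes: frozenset[str]


class GeneSetCollection:
    """A validated list of terms with unique ids and nonempty member sets."""

    def __init__(self, terms: Iterable[GeneSet]):
        self.terms = list(terms)
        seen = set()
        for t in self.terms:
            if not t.genes:
                raise NetpharmError(f"term {t.term_id} has no member genes")
            if t.term_id in seen:
                raise NetpharmError(f"duplicate term id {t.term_id}")
            seen.add(t.term_id)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)


def hypergeom_tail(k: int, K: int, n: int, N: int, ease: bool = False) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Parameters are the overlap k, term size K, query size n and background N.
    With ``ease`` the tail is computed at max(k-1, 0), which can only be larger
    (more conservative).
    """
    if not (0 <= k <= min(n, K) and K <= N and n <= N):
        raise NetpharmError(
            f"impossible hypergeometric counts k={k}, K={K}, n={n}, N={N}"
        )
    x = max(k - 1, 0) if ease else k
    # sf(x-1) = P(X >= x); scipy's hypergeom works in log space internally
    return float(hypergeom.sf(x - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, order-preserving."""
    ps = list(p_values)
    if not ps:
        return []
    for p in ps:
        if not (0 < p <= 1):
            raise NetpharmError(f"p-value {p} outside (0, 1]")
    _, adj, _, _ = multipletests(ps, method="fdr_bh")
    return [float(x) for x in adj]


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    background: int,
    p_max: float = 0.05,
    ease: bool = False,
) -> pd.DataFrame:
    """Over-representation of ``query`` against every term of the collection.

    One row per term with overlap k >= 1; BH adjustment is applied within each
    category over the tested terms; rows with raw p < ``p_max`` are retained
    and sorted by count descending, ties by p ascending then term id.
    """
    qset = {g.upper() for g in query}
    if not qset:
        raise NetpharmError("empty query gene set")
    if background < len(qset):
        raise NetpharmError(
            f"background {background} smaller than query ({len(qset)})"
        )
    for t in collection:
        if len(t.genes) > background:
            raise NetpharmError(
                f"background {background} smaller than term {t.term_id} ({len(t.genes)})"
            )

    rows = []
    for t in collection:
        members = {g.upper() for g in t.genes}
        overlap = sorted(qset & members)
        k = len(overlap)
        if k == 0:
            continue
        p = hypergeom_tail(k, len(members), len(qset), background, ease=ease)
        rows.append(
            {
                "term_id": t.term_id,
                "term_name": t.term_name,
                "category": t.category,
                "count": k,
                "list_size": len(qset),
                "term_size": len(members),
                "background": background,
                "p_value": p,
                "overlap_genes": ";".join(overlap),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "category", "count", "list_size",
            "term_size", "background", "p_value", "overlap_genes",
        ],
    )
    if df.empty:
        df["adjusted_p"] = pd.Series(dtype=float)
        return df

    df["adjusted_p"] = 1.0
    for cat, idx in df.groupby("category").groups.items():
        df.loc[idx, "adjusted_p"] = bh_adjust(df.loc[idx, "p_value"].tolist())

    df = df[df["p_value"] < p_max]
    df = df.sort_values(
        ["count", "p_value", "term_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, category: str | None = None) -> GeneSetCollection:
    """Read a GMT file: ``term_id<TAB>description<TAB>gene...`` per line.

    The category is parsed from a ``category=X`` token in the description
    field when present, else taken from the ``category`` argument, else "BP".
    """
    terms = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise NetpharmError(f"GMT line with fewer than 3 fields: {line!r}")
            desc = parts[1]
            cat = category or "BP"
            name = desc
            if desc.startswith("category="):
                cat, _, name = desc[len("category="):].partition("|")
            terms.append(
                GeneSet(
                    term_id=parts[0],
                    term_name=name or parts[0],
                    category=cat,
                    genes=frozenset(g for g in parts[2:] if g),
                )
            )
    return GeneSetCollection(terms)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in collection:
            desc = f"category={t.category}|{t.term_name}"
            fh.write("\t".join([t.term_id, desc, *sorted(t.genes)]) + "\n")


def write_enrichment_tsv(df: pd.DataFrame, outdir: str | Path, stem: str = "enrichment") -> list[Path]:
    """One TSV per category present in the result."""
    outdir = Path(outdir)
    written = []
    for cat, sub in df.groupby("category"):
        path = outdir / f"{stem}_{cat}.tsv"
        sub.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written
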
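"""Synthetic fixtures for every input the screening pipeline consumes.

Real runs of this kind of screen pull from half a dozen external databases
(herbal-compound ADME tables, two target-prediction servers, four disease-gene
catalogs, an interaction database export, a public expression series). This
module emulates each of those inputs with the statistical structure the
screening stages assume, so the whole pipeline is testable offline:

* compound tables whose OB/DL values straddle the 30% / 0.18 ADME cutoffs;
* per-source prediction scores straddling each source's threshold;
* partially overlapping disease gene lists from several sources;
* sparse background interaction graphs with planted dense modules whose edge
  confidences are guaranteed to survive the downstream cutoff (so module
  recovery is well-posed);
* gene-set collections for over-representation analysis;
* a two-group expression matrix with designated differentially expressed genes.

Every generator is a pure function of its ``FixtureConfig``: a single integer
seed feeds one package-owned seed sequence, and each generator draws from its
own numbered sub-stream in a fixed documented order, so any subset of fixtures
is reproducible independently of the others. Gene identifiers are synthetic
symbols ("G0001", ...) with no claim to real nomenclature.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .enrichment import CATEGORIES, GeneSet, GeneSetCollection
from .errors import ConfigurationError
from .expression import ExpressionMatrix
from .screening import COMPOUND_COLUMNS, PREDICTION_COLUMNS
from .ppi import EDGE_COLUMNS

# sub-stream ids, in pipeline order
_STREAM_COMPOUNDS = 1
_STREAM_PREDICTIONS = 2
_STREAM_DISEASE = 3
_STREAM_PPI = 4
_STREAM_EXPRESSION = 5
_STREAM_GENESETS = 6


class SourceScoreParams(BaseModel):
    """Score distribution and screening threshold for one prediction source."""

    model_config = ConfigDict(extra="forbid")

    family: Literal["uniform", "normal"] = "uniform"
    params: tuple[float, float] = (0.0, 0.2)
    threshold: float = 0.1


class FixtureConfig(BaseModel):
    """All knobs of the synthetic-data generators.

    Defaults describe the study conditions the pipeline targets: a 12-herb
    formula with ~25 candidate compounds each and a fifth of compound
    identities shared between herbs; two prediction sources whose score
    distributions straddle their 0.1 and 1.5 cutoffs; four disease-gene
    sources sharing a common core; a 5% background interaction graph with two
    planted modules — a strong dense one (the ground-truth key module) and a
    larger, weaker one that survives the degree screen but should lose the
    six-metric screen — whose edges are guaranteed to survive the 0.7
    confidence cutoff; and a 10+10-sample expression contrast with unit
    Gaussian noise.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int = Field(default=0, ge=0)

    # compound table
    n_herbs: int = Field(default=12, ge=1)
    compounds_per_herb: int = Field(default=25, ge=1)
    shared_compound_fraction: float = Field(default=0.2, ge=0, le=1)
    ob_range: tuple[float, float] = (0.0, 100.0)
    dl_range: tuple[float, float] = (0.0, 1.0)

    # target predictions
    per_source_score_params: dict[str, SourceScoreParams] = {
        "swisstarget": SourceScoreParams(family="uniform", params=(0.0, 0.2), threshold=0.1),
        "stitch": SourceScoreParams(family="uniform", params=(0.0, 3.0), threshold=1.5),
    }
    mean_predictions_per_source: float = Field(default=6.0, gt=0)

    # gene universe and disease sources
    gene_universe_size: int = Field(default=1000, ge=10)
    n_disease_sources: int = Field(default=4, ge=1)
    genes_per_disease_source: int = Field(default=80, ge=1)
    disease_source_overlap: float = Field(default=0.3, ge=0, le=1)

    # PPI fixture
    background_edge_prob: float = Field(default=0.05, ge=0, le=1)
    planted_modules: list[tuple[int, float]] = [(14, 0.9), (20, 0.45)]
    edge_score_range: tuple[float, float] = (400.0, 1000.0)
    edge_score_scale: Literal["int1000", "unit"] = "int1000"
    planted_min_confidence: float = Field(default=0.7, ge=0, le=1)

    # gene sets
    n_terms_per_category: int = Field(default=15, ge=1)
    term_size_range: tuple[int, int] = (10, 60)

    # expression
    n_samples_per_group: int = Field(default=10, ge=2)
    de_genes: list[tuple[str, float]] = []
    noise_sd: float = Field(default=1.0, ge=0)

    @model_validator(mode="after")
    def _check_ranges(self) -> "FixtureConfig":
        for name, (lo, hi) in (
            ("ob_range", self.ob_range),
            ("dl_range", self.dl_range),
            ("edge_score_range", self.edge_score_range),
            ("term_size_range", self.term_size_range),
        ):
            if lo > hi:
                raise ValueError(f"{name} must be an ordered pair, got {(lo, hi)}")
        if not (0 <= self.ob_range[0] and self.ob_range[1] <= 100):
            raise ValueError("ob_range must lie within [0, 100]")
        if not (0 <= self.dl_range[0] and self.dl_range[1] <= 1):
            raise ValueError("dl_range must lie within [0, 1]")
        for size, p in self.planted_modules:
            if size < 3:
                raise ValueError(f"planted module size {size} < 3")
            if size > self.gene_universe_size:
                raise ValueError(
                    f"planted module size {size} exceeds gene universe "
                    f"({self.gene_universe_size})"
                )
            if not (0 <= p <= 1):
                raise ValueError(f"within-module probability {p} outside [0, 1]")
        return self


def _rng(cfg: FixtureConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


def gene_universe(cfg: FixtureConfig) -> list[str]:
    """The synthetic gene symbols G0001..G<N>."""
    width = max(4, len(str(cfg.gene_universe_size)))
    return [f"G{i:0{width}d}" for i in range(1, cfg.gene_universe_size + 1)]


# ---------------------------------------------------------------------------
# compounds
# ---------------------------------------------------------------------------

def shared_pool_size(cfg: FixtureConfig) -> int:
    return int(np.floor(cfg.shared_compound_fraction * cfg.compounds_per_herb))


def expected_distinct_compounds(cfg: FixtureConfig) -> int:
    """Ground-truth distinct compound count implied by the sharing scheme."""
    s = shared_pool_size(cfg)
    return s + cfg.n_herbs * (cfg.compounds_per_herb - s)


def gen_compound_table(cfg: FixtureConfig) -> pd.DataFrame:
    """Herb × compound table with OB/DL spanning the ADME cutoffs.

    A fixed pool of ``floor(shared_compound_fraction · compounds_per_herb)``
    compound identities recurs in every herb; the remaining slots hold
    herb-unique compounds. OB and DL are drawn uniformly once per distinct
    compound, so shared compounds carry consistent values.
    """
    rng = _rng(cfg, _STREAM_COMPOUNDS)
    s = shared_pool_size(cfg)
    n_distinct = expected_distinct_compounds(cfg)
    width = max(4, len(str(n_distinct)))
    ids = [f"C{i:0{width}d}" for i in range(1, n_distinct + 1)]
    shared_ids = ids[:s]

    ob = rng.uniform(cfg.ob_range[0], cfg.ob_range[1], size=n_distinct)
    dl = rng.uniform(cfg.dl_range[0], cfg.dl_range[1], size=n_distinct)
    props = {cid: (float(o), float(d)) for cid, o, d in zip(ids, ob, dl)}

    rows = []
    cursor = s
    for h in range(1, cfg.n_herbs + 1):
        herb = f"herb{h:02d}"
        herb_ids = list(shared_ids) + ids[cursor : cursor + (cfg.compounds_per_herb - s)]
        cursor += cfg.compounds_per_herb - s
        for cid in herb_ids:
            o, d = props[cid]
            rows.append((cid, herb, f"cpd-{cid}", o, d))
    return pd.DataFrame(rows, columns=COMPOUND_COLUMNS)


# ---------------------------------------------------------------------------
# target predictions
# ---------------------------------------------------------------------------

def _draw_scores(rng: np.random.Generator, source: SourceScoreParams, size: int) -> np.ndarray:
    if source.family == "uniform":
        return rng.uniform(source.params[0], source.params[1], size=size)
    return rng.normal(source.params[0], source.params[1], size=size)


def gen_target_predictions(compounds: pd.DataFrame, cfg: FixtureConfig) -> pd.DataFrame:
    """Per-compound, per-source target predictions with threshold-spanning scores.

    Each distinct compound draws a Poisson number of target genes per source
    (without replacement within a compound–source pair); scores come from the
    configured family so some fall below and some above each source threshold.
    """
    if not cfg.per_source_score_params:
        raise ConfigurationError("per_source_score_params must not be empty")
    rng = _rng(cfg, _STREAM_PREDICTIONS)
    genes = np.array(gene_universe(cfg))
    rows: list[tuple[str, str, str, float]] = []
    if compounds.empty:
        return pd.DataFrame(columns=PREDICTION_COLUMNS)
    for cid in compounds["compound_id"].drop_duplicates():
        for source in sorted(cfg.per_source_score_params):
            score_params = cfg.per_source_score_params[source]
            k = int(rng.poisson(cfg.mean_predictions_per_source))
            k = min(k, len(genes))
            if k == 0:
                continue
            picked = rng.choice(genes, size=k, replace=False)
            scores = _draw_scores(rng, score_params, k)
            rows.extend((cid, g, source, float(x)) for g, x in zip(picked, scores))
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)


# ---------------------------------------------------------------------------
# disease sources
# ---------------------------------------------------------------------------

def gen_disease_targets(cfg: FixtureConfig) -> dict[str, set[str]]:
    """Per-source disease gene sets sharing a common core.

    A core of ``round(disease_source_overlap · genes_per_disease_source)``
    genes appears in every source; the non-core members are sampled disjointly
    across sources, so overlap 0 yields fully disjoint sets and overlap 1
    identical ones.
    """
    rng = _rng(cfg, _STREAM_DISEASE)
    universe = gene_universe(cfg)
    m = cfg.genes_per_disease_source
    core_size = int(round(cfg.disease_source_overlap * m))
    need = core_size + cfg.n_disease_sources * (m - core_size)
    if need > len(universe):
        raise ConfigurationError(
            f"disease sources need {need} distinct genes but the universe has {len(universe)}"
        )
    drawn = rng.choice(np.array(universe), size=need, replace=False)
    core = set(map(str, drawn[:core_size]))
    out: dict[str, set[str]] = {}
    cursor = core_size
    for i in range(1, cfg.n_disease_sources + 1):
        unique = set(map(str, drawn[cursor : cursor + (m - core_size)]))
        cursor += m - core_size
        out[f"source_{i}"] = core | unique
    return out


# ---------------------------------------------------------------------------
# PPI edges
# ---------------------------------------------------------------------------

def _confidence_cutoff(cfg: FixtureConfig) -> float:
    return (
        cfg.planted_min_confidence * 1000.0
        if cfg.edge_score_scale == "int1000"
        else cfg.planted_min_confidence
    )


def gen_ppi_edges(
    genes: Sequence[str], cfg: FixtureConfig
) -> tuple[pd.DataFrame, list[list[str]]]:
    """STRING-dialect edge table over ``genes`` with planted dense modules.

    Background edges appear independently with ``background_edge_prob`` and
    carry confidences uniform on ``edge_score_range``; each planted module of
    (size, within_prob) gets its node set sampled disjointly from ``genes``
    and its edges drawn with ``within_prob`` at confidences guaranteed at or
    above the downstream cutoff. Duplicate pairs collapse keeping the higher
    score; no self-loops. Returns the edge table and the ground-truth module
    node sets.
    """
    rng = _rng(cfg, _STREAM_PPI)
    nodes = sorted(map(str, genes))
    n = len(nodes)
    total_module = sum(size for size, _ in cfg.planted_modules)
    for size, _ in cfg.planted_modules:
        if size > n:
            raise ConfigurationError(f"planted module size {size} exceeds |genes| = {n}")
    if total_module > n:
        raise ConfigurationError(
            f"planted modules need {total_module} distinct genes but only {n} supplied"
        )

    lo, hi = cfg.edge_score_range
    cutoff = _confidence_cutoff(cfg)
    scores: dict[tuple[str, str], float] = {}

    # background draws first (fixed order), then modules
    if n >= 2 and cfg.background_edge_prob > 0:
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(len(iu)) < cfg.background_edge_prob
        bg_scores = rng.uniform(lo, hi, size=int(mask.sum()))
        for i, j, sc in zip(iu[mask], ju[mask], bg_scores):
            scores[(nodes[i], nodes[j])] = float(sc)

    available = list(nodes)
    modules: list[list[str]] = []
    for size, within_prob in cfg.planted_modules:
        picked = sorted(map(str, rng.choice(np.array(available), size=size, replace=False)))
        available = [g for g in available if g not in set(picked)]
        modules.append(picked)
        for ai in range(size):
            for bi in range(ai + 1, size):
                if rng.random() < within_prob:
                    pair = (picked[ai], picked[bi])
                    sc = float(rng.uniform(max(cutoff, lo), max(cutoff, hi)))
                    scores[pair] = max(scores.get(pair, -np.inf), sc)

    rows = sorted((a, b, s) for (a, b), s in scores.items())
    df = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    if cfg.edge_score_scale == "int1000" and not df.empty:
        df["combined_score"] = np.floor(df["combined_score"]).astype(int)
    return df, modules


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def gen_gene_sets(
    cfg: FixtureConfig, focus_genes: Sequence[str] | None = None
) -> GeneSetCollection:
    """Random gene-set collection over the universe, one block per category.

    When ``focus_genes`` is given, the first term of every category includes
    all of them, so an over-representation signal exists for that query.
    """
    rng = _rng(cfg, _STREAM_GENESETS)
    universe = np.array(gene_universe(cfg))
    lo, hi = cfg.term_size_range
    terms = []
    for cat in CATEGORIES:
        for i in range(1, cfg.n_terms_per_category + 1):
            size = int(rng.integers(lo, hi + 1))
            size = min(size, len(universe))
            members = set(map(str, rng.choice(universe, size=size, replace=False)))
            if i == 1 and focus_genes:
                members |= {str(g) for g in focus_genes}
            terms.append(
                GeneSet(
                    term_id=f"{cat}:T{i:03d}",
                    term_name=f"synthetic {cat} term {i}",
                    category=cat,
                    genes=frozenset(members),
                )
            )
    return GeneSetCollection(terms)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def gen_expression_matrix(cfg: FixtureConfig) -> ExpressionMatrix:
    """Two-group expression matrix over the gene universe.

    Per-gene baselines are uniform on [4, 12] (log2-intensity-like); every
    entry adds Gaussian noise with ``noise_sd``; case columns of each gene in
    ``de_genes`` are shifted by its log2 fold change.
    """
    rng = _rng(cfg, _STREAM_EXPRESSION)
    genes = gene_universe(cfg)
    gene_index = {g: i for i, g in enumerate(genes)}
    for g, _ in cfg.de_genes:
        if g not in gene_index:
            raise ConfigurationError(f"de gene {g!r} not in the gene universe")
    m = cfg.n_samples_per_group
    baseline = rng.uniform(4.0, 12.0, size=len(genes))
    values = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(len(genes), 2 * m))
    for g, lfc in cfg.de_genes:
        values[gene_index[g], m:] += lfc
    samples = [f"ctrl_{i+1:02d}" for i in range(m)] + [f"case_{i+1:02d}" for i in range(m)]
    labels = pd.Series(
        ["control"] * m + ["case"] * m,
        index=pd.Index(samples, name="sample"),
        name="group",
    )
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionMatrix(values=df, labels=labels)


# ---------------------------------------------------------------------------
# table I/O (UTF-8 TSV; gene lists are headerless one-symbol-per-line files)
# ---------------------------------------------------------------------------

def write_compounds(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_compounds(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"compound_id": str, "herb": str, "name": str})


def write_predictions(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"compound_id": str, "gene": str, "source": str})


def write_gene_list(genes, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gene_list(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_edges(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
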
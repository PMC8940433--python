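"""Compound ADME filtering and target-set assembly.

The screening stage reduces a herb-formula compound table to pharmacologically
plausible compounds (oral bioavailability and drug-likeness cutoffs), filters
per-source target predictions by each source's score threshold, takes the union
over prediction sources, unions multi-source disease gene lists, and intersects
the two to yield the overlapped genes (OGEs) that seed the PPI network.

All thresholds are inclusive (``>=``) by default, matching the cutoff notation
used for these databases (OB >= 30%, DL >= 0.18, per-source score cutoffs);
``ScreenConfig.strict`` switches every comparison to strictly-greater for
sensitivity analysis.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from .errors import ConfigurationError, NetpharmError

COMPOUND_COLUMNS = ["compound_id", "herb", "name", "OB", "DL"]
PREDICTION_COLUMNS = ["compound_id", "gene", "source", "score"]


class ScreenConfig(BaseModel):
    """Thresholds for the compound and target-prediction screens.

    Parameters
    ----------
    ob_min : float
        Minimum oral bioavailability in percent (default 30).
    dl_min : float
        Minimum drug-likeness, unitless in [0, 1] (default 0.18).
    source_min_score : dict
        Per-source minimum prediction score, on each source's own scale.
        Defaults cover a probability-scaled source (0.1) and a
        confidence-scaled source (1.5); the scales are treated as opaque.
    strict : bool
        When True use strictly-greater comparisons everywhere.
    """

    model_config = ConfigDict(extra="forbid")

    ob_min: float = 30.0
    dl_min: float = 0.18
    source_min_score: dict[str, float] = {"swisstarget": 0.1, "stitch": 1.5}
    strict: bool = False

    @field_validator("ob_min", "dl_min")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not pd.notna(v) or v in (float("inf"), float("-inf")):
            raise ValueError("threshold must be finite")
        return v


def _keep(values: pd.Series, cutoff: float, strict: bool) -> pd.Series:
    return values > cutoff if strict else values >= cutoff


def validate_compound_table(records: pd.DataFrame) -> pd.DataFrame:
    """Check the compound table schema; name the first offending row on failure."""
    missing_cols = [c for c in COMPOUND_COLUMNS if c not in records.columns]
    if missing_cols:
        raise NetpharmError(f"compound table missing columns: {missing_cols}")
    for col in ("OB", "DL"):
        bad = records.index[records[col].isna()]
        if len(bad):
            row = records.loc[bad[0]]
            raise NetpharmError(
                f"missing {col} for compound {row['compound_id']!r} (row index {bad[0]})"
            )
    return records


def filter_compounds(records: pd.DataFrame, cfg: ScreenConfig | None = None) -> pd.DataFrame:
    """Retain compounds with OB >= ob_min and DL >= dl_min, preserving input order."""
    cfg = cfg or ScreenConfig()
    validate_compound_table(records)
    mask = _keep(records["OB"], cfg.ob_min, cfg.strict) & _keep(
        records["DL"], cfg.dl_min, cfg.strict
    )
    return records.loc[mask].copy()


def dedupe_compounds(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse rows sharing a compound_id into one row per compound.

    The herb field becomes the sorted, semicolon-joined list of contributing
    herbs; other fields come from the first occurrence. Output keeps
    first-appearance order.
    """
    if records.empty:
        return records.copy()
    herbs = records.groupby("compound_id", sort=False)["herb"].agg(
        lambda h: ";".join(sorted(set(h)))
    )
    out = records.drop_duplicates("compound_id", keep="first").copy()
    out["herb"] = out["compound_id"].map(herbs)
    return out.reset_index(drop=True)


def assemble_compound_targets(
    predictions: pd.DataFrame, cfg: ScreenConfig | None = None
) -> list[str]:
    """Union over sources of genes whose prediction score passes that source's cutoff.

    Gene symbols are upper-cased before the set union so mixed-case inputs
    (e.g. human vs rodent symbol conventions) deduplicate correctly. Returns a
    sorted gene list.
    """
    cfg = cfg or ScreenConfig()
    if predictions.empty:
        return []
    unknown = set(predictions["source"]) - set(cfg.source_min_score)
    if unknown:
        raise ConfigurationError(f"no score threshold configured for source(s): {sorted(unknown)}")
    cutoffs = predictions["source"].map(cfg.source_min_score)
    mask = (
        predictions["score"] > cutoffs if cfg.strict else predictions["score"] >= cutoffs
    )
    genes = predictions.loc[mask, "gene"].str.upper()
    return sorted(set(genes))


def union_disease_targets(sources: Mapping[str, Iterable[str]]) -> list[str]:
    """Sorted union of the per-source disease gene sets (case-normalized)."""
    if not sources:
        raise NetpharmError("no disease sources supplied")
    out: set[str] = set()
    for genes in sources.values():
        out.update(g.upper() for g in genes)
    return sorted(out)


def overlap_genes(
    compound_targets: Iterable[str], disease_targets: Iterable[str]
) -> list[str]:
    """Sorted intersection of compound targets and disease targets (the OGEs)."""
    a = {g.upper() for g in compound_targets}
    b = {g.upper() for g in disease_targets}
    return sorted(a & b)


def filtered_predictions(
    predictions: pd.DataFrame, cfg: ScreenConfig | None = None
) -> pd.DataFrame:
    """Prediction rows that pass their source's score cutoff (for reporting)."""
    cfg = cfg or ScreenConfig()
    if predictions.empty:
        return predictions.copy()
    unknown = set(predictions["source"]) - set(cfg.source_min_score)
    if unknown:
        raise ConfigurationError(f"no score threshold configured for source(s): {sorted(unknown)}")
    cutoffs = predictions["source"].map(cfg.source_min_score)
    mask = predictions["score"] > cutoffs if cfg.strict else predictions["score"] >= cutoffs
    return predictions.loc[mask].copy()


def compounds_without_targets(
    compounds: pd.DataFrame, predictions: pd.DataFrame, cfg: ScreenConfig | None = None
) -> list[str]:
    """Compound ids with zero surviving predictions, for the run report.

    A herb (or compound) can legitimately contribute nothing after filtering;
    the pipeline reports rather than errors on this.
    """
    surviving = filtered_predictions(predictions, cfg)
    with_targets = set(surviving["compound_id"]) if not surviving.empty else set()
    return sorted(set(compounds["compound_id"]) - with_targets)
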
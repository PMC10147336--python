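"""Packaged data fixtures.

Two kinds ship with the package:

* transcriptions of published summary tables — the taxon-by-region
  occupancy table, the six-model comparison table (LnL, d, e, j, AICc,
  weight), the per-node sister-lineage RED table with biogeographical
  correlates, and the per-island co-occurrence/hybridization rates with
  first-colonization ages;
* synthetic stand-ins (file names prefixed ``synthetic_``) for inputs
  whose full underlying data are not published: a per-node support table
  across five phylogenetic analyses constructed to reproduce the
  published node-selection outcome, and a small demonstration pair list.

Everything is validated against the domain-type invariants on load and
fails loudly on schema drift.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .divergence import DivergenceRecord, pool_incongruent


def _data_path(name: str):
    return resources.files("islandrad.data").joinpath(name)


def _read(name: str, **kw) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as path:
        return pd.read_csv(path, sep="\t", **kw)


def load_occupancy() -> pd.DataFrame:
    """Taxon-by-region 0/1 presence table (index: taxon)."""
    df = _read("table1_occupancy.tsv", index_col=0)
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("occupancy fixture must be 0/1")
    if (vals.sum(axis=1) < 1).any():
        raise ValueError("every taxon must occupy at least one region")
    return df


def load_model_table() -> pd.DataFrame:
    """Published six-model comparison (model, LnL, d, e, j, AICc, AICc_wt)."""
    df = _read("table3_models.tsv")
    expected = {"model", "LnL", "d", "e", "j", "AICc", "AICc_wt"}
    if set(df.columns) != expected:
        raise ValueError("model-table fixture schema mismatch")
    if len(df) != 6:
        raise ValueError("model-table fixture must have 6 rows")
    if not np.isclose(df["AICc_wt"].sum(), 1.0, atol=5e-3):
        raise ValueError("Akaike weights must sum to ~1")
    return df


def load_red_table() -> pd.DataFrame:
    """Published sister-lineage RED table.

    17 consensus rows, 4 inconsistently resolved nodes with one row per
    analysis (concatML / ASTRAL / dating), and the printed pooled row.
    """
    df = _read("table6_red.tsv", dtype={"node": str})
    if (df["morphological_RED"] < 0).any() or (df["ecological_RED"] < 0).any():
        raise ValueError("REDs must be non-negative")
    if not set(df["correlate"]) <= {"intra", "inter"}:
        raise ValueError("unknown correlate in RED fixture")
    n_consensus = (df["analysis"] == "consensus").sum()
    incongruent = df[~df["analysis"].isin(["consensus", "pooled"])]
    if n_consensus != 17 or incongruent["node"].nunique() != 4:
        raise ValueError("RED fixture must carry 17 consensus + 4 pooled nodes")
    return df


def load_island_rates() -> pd.DataFrame:
    """Published per-island co-occurrence/hybridization percentages with
    first-colonization age estimates (western Canary Islands)."""
    df = _read("island_rates.tsv")
    if not ((df["hybridization_pct"] <= df["cooccurrence_pct"]).all()):
        raise ValueError("hybridization rate cannot exceed co-occurrence rate")
    return df


def load_support_tables() -> pd.DataFrame:
    """SYNTHETIC per-node support across five phylogenetic analyses,
    constructed to reproduce the published selection outcome (17 nodes
    recovered in all analyses with top support in at least one; the
    four-node subclade missing from the species-tree analyses)."""
    df = _read("synthetic_support.tsv")
    if not set(df["support_type"]) <= {"BS", "PP"}:
        raise ValueError("support types must be BS or PP")
    return df


def load_pair_list() -> pd.DataFrame:
    """SYNTHETIC demonstration pair list (taxon_a, taxon_b, islands,
    is_hybrid) consistent with the occupancy fixture."""
    return _read("synthetic_pairs.tsv")


def red_records(pool: bool = True) -> list[DivergenceRecord]:
    """Divergence records from the RED fixture.

    With ``pool=True`` the four inconsistently resolved nodes are replaced
    by one pooled record (per-analysis REDs averaged), mirroring how the
    group comparison was run; the printed pooled row itself is never used
    for computation.
    """
    df = load_red_table()
    records = []
    for _, row in df[df["analysis"] == "consensus"].iterrows():
        records.append(
            DivergenceRecord(
                node=row["node"],
                morphological=float(row["morphological_RED"]),
                ecological=float(row["ecological_RED"]),
                correlate=row["correlate"],
                islands=row["islands"] if isinstance(row["islands"], str) else None,
                support=float(row["support_pct"]) / 100.0,
                n_characters_differing=float(row["n_diff"]),
            )
        )
    incon = df[~df["analysis"].isin(["consensus", "pooled"])]
    sub = [
        DivergenceRecord(
            node=f'{row["node"]}/{row["analysis"]}',
            morphological=float(row["morphological_RED"]),
            ecological=float(row["ecological_RED"]),
            correlate=row["correlate"],
            islands=row["islands"],
            support=float(row["support_pct"]) / 100.0,
            n_characters_differing=float(row["n_diff"]),
        )
        for _, row in incon.iterrows()
    ]
    if pool:
        records.append(pool_incongruent(sub, node_label="46-49"))
    else:
        records.extend(sub)
    return records


def load_fixtures() -> dict:
    """All fixtures, validated, keyed by short name."""
    return {
        "occupancy": load_occupancy(),
        "model_table": load_model_table(),
        "red_table": load_red_table(),
        "island_rates": load_island_rates(),
        "support_tables": load_support_tables(),
        "pair_list": load_pair_list(),
    }
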
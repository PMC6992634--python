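"""Best-hit annotation, the two-condition contaminant filter, and TF-homolog
identification from BLAST-style hit tables.

A hit table is a :class:`pandas.DataFrame` with at least the columns
``query, subject, bitscore, evalue`` and, for the contaminant filter,
``is_deuterostome`` and ``is_panel`` (subject belongs to the echinoderm
reference panel: A. japonicus, P. parvimensis, C. schmeltzii, P. miniata,
L. variegatus, S. purpuratus).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "best_hit",
    "flag_contaminants",
    "identify_tf_homologs",
    "ContaminantReport",
]

HIT_COLUMNS = ["query", "subject", "bitscore", "evalue"]


def _check_hits(hits: pd.DataFrame, extra: tuple[str, ...] = ()) -> None:
    missing = [c for c in (*HIT_COLUMNS, *extra) if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")


def _rank_best(hits: pd.DataFrame) -> pd.DataFrame:
    """Deterministic best hit per query: bitscore desc, evalue asc, subject lex."""
    orderly = hits.sort_values(
        ["bitscore", "evalue", "subject"], ascending=[False, True, True], kind="mergesort"
    )
    return orderly.drop_duplicates("query", keep="first")


def best_hit(
    hits: pd.DataFrame,
    evalue_max: float = 1e-5,
    protein_lengths: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Best qualifying hit per query.

    Hits with ``evalue > evalue_max`` are discarded first (1e-5, the BLASTP
    default significance ceiling); among the rest the maximal-bitscore hit
    wins, with ties broken by lower e-value then lexicographically smaller
    subject ID.  Queries with no qualifying hit are absent from the output.

    Returns columns ``query, best_subject, best_bitscore, best_evalue`` and,
    when ``protein_lengths`` is given, ``protein_aa_len``.
    """
    _check_hits(hits)
    qualifying = hits[hits["evalue"] <= evalue_max]
    if qualifying.empty:
        out = pd.DataFrame(
            columns=["query", "best_subject", "best_bitscore", "best_evalue"]
        )
    else:
        out = (
            _rank_best(qualifying)[HIT_COLUMNS]
            .rename(
                columns={
                    "subject": "best_subject",
                    "bitscore": "best_bitscore",
                    "evalue": "best_evalue",
                }
            )
            .reset_index(drop=True)
        )
    if protein_lengths is not None:
        lengths = pd.Series(protein_lengths)
        out["protein_aa_len"] = out["query"].map(lengths)
    return out


@dataclass
class ContaminantReport:
    """Per-removal audit trail of the two triggering scores."""

    removed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["query", "nrp_subject", "nrp_bitscore", "panel_bitscore", "had_panel_hit"]
        )
    )

    def __len__(self) -> int:
        return len(self.removed)


def flag_contaminants(
    nrp_hits: pd.DataFrame,
    bitscore_min: float = 200.0,
    panel_frac: float = 0.8,
) -> tuple[set[str], set[str], ContaminantReport]:
    """Split queries into (keep, remove) by the non-deuterostome contaminant rule.

    A query is removed iff both conditions hold for its *best* NRP hit
    (``is_panel == False`` rows; ties broken as in :func:`best_hit`):

    1. the best NRP hit is to a non-deuterostome subject with bitscore
       strictly above ``bitscore_min`` (default 200), and
    2. no panel hit reaches a bitscore strictly greater than
       ``panel_frac`` (default 0.8) of that NRP bitscore — an absent panel
       hit counts as bitscore 0 and therefore cannot rescue.

    Everything else is kept, including queries with no NRP hit at all: the
    filter targets confident foreign matches only.
    """
    _check_hits(nrp_hits, extra=("is_deuterostome", "is_panel"))
    queries = set(nrp_hits["query"].unique())

    nrp = nrp_hits[~nrp_hits["is_panel"].astype(bool)]
    panel_best = (
        nrp_hits[nrp_hits["is_panel"].astype(bool)]
        .groupby("query")["bitscore"]
        .max()
    )

    remove: set[str] = set()
    rows = []
    for _, hit in _rank_best(nrp).iterrows():
        q = hit["query"]
        if hit["is_deuterostome"] or hit["bitscore"] <= bitscore_min:
            continue
        pb = float(panel_best.get(q, 0.0))
        if pb > panel_frac * hit["bitscore"]:
            continue
        remove.add(q)
        rows.append(
            {
                "query": q,
                "nrp_subject": hit["subject"],
                "nrp_bitscore": float(hit["bitscore"]),
                "panel_bitscore": pb,
                "had_panel_hit": q in panel_best.index,
            }
        )
    report = ContaminantReport(
        pd.DataFrame(rows, columns=ContaminantReport().removed.columns)
        if rows
        else ContaminantReport().removed
    )
    return queries - remove, remove, report


def identify_tf_homologs(
    annotations: pd.DataFrame,
    tf_reference: set[str],
    min_aa: int = 200,
) -> set[str]:
    """Queries whose best hit is a known transcription factor and whose
    predicted protein is strictly longer than ``min_aa`` residues (200 by
    default; short fragments cannot be confidently typed as TFs)."""
    if annotations.empty or not tf_reference:
        return set()
    required = {"query", "best_subject", "protein_aa_len"}
    missing = required - set(annotations.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    mask = annotations["best_subject"].isin(tf_reference) & (
        annotations["protein_aa_len"] > min_aa
    )
    return set(annotations.loc[mask, "query"])
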
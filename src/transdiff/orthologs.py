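"""One-to-one ortholog pairing from cross-species hit tables.

Two matchers are provided:

* :func:`greedy_pairing` — repeatedly commit the globally best-scoring
  remaining query–subject hit and delete both members from every other hit
  list.  When a protein family in one species aligns best to a single member
  of the other species' family, this still pairs the remaining members with
  their next-best partners instead of discarding them.
* :func:`reciprocal_best_hit` — the classical baseline: a pair is emitted only
  when each sequence is the other's unique top-scoring match.

Whenever every best hit is unique, the RBH pairs are a subset of the greedy
pairs (a mutual-best pair outscores every hit touching either member, so the
greedy sweep commits it before either member can be consumed).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["PairSet", "greedy_pairing", "reciprocal_best_hit", "compare_pairings"]


@dataclass(frozen=True)
class PairSet:
    """One-to-one query↔subject assignments with the score behind each pair."""

    pairs: pd.DataFrame  # columns: query, subject, bitscore
    method: str

    def __post_init__(self) -> None:
        if self.pairs["query"].duplicated().any() or self.pairs["subject"].duplicated().any():
            raise ValueError("PairSet must be one-to-one in both coordinates")

    def as_set(self) -> set[tuple[str, str]]:
        return set(zip(self.pairs["query"], self.pairs["subject"]))

    def __len__(self) -> int:
        return len(self.pairs)


_EMPTY = pd.DataFrame(columns=["query", "subject", "bitscore"])


def _sorted_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Deterministic global ordering: bitscore desc, evalue asc, (query, subject) lex."""
    cols = ["bitscore", "evalue", "query", "subject"]
    ascending = [False, True, True, True]
    if "evalue" not in hits.columns:
        cols, ascending = ["bitscore", "query", "subject"], [False, True, True]
    return hits.sort_values(cols, ascending=ascending, kind="mergesort")


def greedy_pairing(hits: pd.DataFrame) -> PairSet:
    """Greedy global best-pair matching.

    Iteratively selects the highest-scoring remaining hit, emits it as a
    pair, and removes all remaining hits involving either member, until the
    hit list is exhausted.  Equivalent to a single sweep over the globally
    sorted hit list, skipping rows whose query or subject is already taken.
    """
    missing = [c for c in ("query", "subject", "bitscore") if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    if hits.empty:
        return PairSet(_EMPTY.copy(), "greedy")
    used_q: set = set()
    used_s: set = set()
    rows = []
    for row in _sorted_hits(hits).itertuples(index=False):
        if row.query in used_q or row.subject in used_s:
            continue
        used_q.add(row.query)
        used_s.add(row.subject)
        rows.append((row.query, row.subject, row.bitscore))
    return PairSet(pd.DataFrame(rows, columns=["query", "subject", "bitscore"]), "greedy")


def _best_partner(hits: pd.DataFrame, by: str, partner: str, break_ties: bool) -> dict:
    """Map ``by``-ID → its best ``partner`` under the tie policy, or drop the
    ID entirely when its top score is tied and ties are not broken."""
    out: dict = {}
    for key, grp in hits.groupby(by):
        top = grp["bitscore"].max()
        contenders = grp[grp["bitscore"] == top]
        if len(contenders) > 1 and not break_ties:
            continue
        if "evalue" in contenders.columns:
            contenders = contenders.sort_values(
                ["evalue", "query", "subject"], kind="mergesort"
            )
        else:
            contenders = contenders.sort_values(["query", "subject"], kind="mergesort")
        row = contenders.iloc[0]
        out[key] = (row[partner], float(row["bitscore"]))
    return out


def reciprocal_best_hit(hits: pd.DataFrame, break_ties: bool = False) -> PairSet:
    """Classical reciprocal-best-hit pairing.

    ``(q, s)`` is emitted iff ``s`` is ``q``'s top-scoring subject and ``q``
    is ``s``'s top-scoring query.  By default a tie at the top invalidates the
    member (strict uniqueness); with ``break_ties=True`` the deterministic
    policy (evalue asc, then lexicographic) chooses a winner instead.
    """
    if hits.empty:
        return PairSet(_EMPTY.copy(), "rbh")
    best_s = _best_partner(hits, "query", "subject", break_ties)
    best_q = _best_partner(hits, "subject", "query", break_ties)
    rows = [
        (q, s, score)
        for q, (s, score) in sorted(best_s.items())
        if best_q.get(s, (None,))[0] == q
    ]
    return PairSet(pd.DataFrame(rows, columns=["query", "subject", "bitscore"]), "rbh")


def compare_pairings(
    greedy: PairSet,
    rbh: PairSet,
    truth: set[tuple[str, str]] | None = None,
) -> dict:
    """Pair counts, overlap, and (with ground truth) precision/recall per method."""
    g, r = greedy.as_set(), rbh.as_set()
    report: dict = {
        "n_greedy": len(g),
        "n_rbh": len(r),
        "n_overlap": len(g & r),
    }
    if truth is not None:
        for name, pairs in (("greedy", g), ("rbh", r)):
            tp = len(pairs & truth)
            report[f"precision_{name}"] = tp / len(pairs) if pairs else float("nan")
            report[f"recall_{name}"] = tp / len(truth) if truth else float("nan")
    return report
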
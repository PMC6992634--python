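"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes the quantity by the most literal route available —
whole-frame translation and string splitting for CDS enumeration, repeated
linear scans for greedy matching, an explicit per-position loop for the
enrichment running sum — deliberately sharing no code with the package.
"""

from __future__ import annotations

from Bio.Seq import Seq


def cds_bruteforce(sequence: str, min_aa: int = 30) -> set[tuple[str, int, int, str]]:
    """All maximal stop-free stretches >= min_aa codons, as
    (strand, frame, start, protein) with start on the reported orientation."""
    out = set()
    seq = sequence.upper()
    rc = str(Seq(seq).reverse_complement())
    for strand, oriented in (("+", seq), ("-", rc)):
        for frame in range(3):
            codons = [
                oriented[i : i + 3]
                for i in range(frame, len(oriented) - 2, 3)
            ]
            aa = [
                "*" if c in ("TAA", "TAG", "TGA") else ("X" if "N" in c else str(Seq(c).translate()))
                for c in codons
            ]
            translated = "".join(aa)
            pos = 0
            for chunk in translated.split("*"):
                if len(chunk) >= min_aa and set(chunk) != {"X"}:
                    start = frame + 3 * pos
                    out.add((strand, frame, start, chunk))
                pos += len(chunk) + 1
    return out


def greedy_bruteforce(rows: list[tuple[str, str, float, float]]) -> set[tuple[str, str]]:
    """Literal simulation of the verbal pairing rule on
    (query, subject, bitscore, evalue) rows: scan for the best remaining hit,
    emit it, delete every hit touching either member, repeat."""
    remaining = list(rows)
    pairs = set()
    while remaining:
        best = remaining[0]
        for row in remaining[1:]:
            better = row[2] > best[2] or (
                row[2] == best[2]
                and (
                    row[3] < best[3]
                    or (row[3] == best[3] and (row[0], row[1]) < (best[0], best[1]))
                )
            )
            if better:
                best = row
        pairs.add((best[0], best[1]))
        remaining = [r for r in remaining if r[0] != best[0] and r[1] != best[1]]
    return pairs


def es_bruteforce(
    ranked_genes: list[str], metrics: list[float], members: set[str], p: float = 1.0
) -> float:
    """Enrichment score by an explicit position-by-position running sum."""
    n = len(ranked_genes)
    hit_weight_total = sum(
        abs(m) ** p for g, m in zip(ranked_genes, metrics) if g in members
    )
    n_hit = sum(1 for g in ranked_genes if g in members)
    n_miss = n - n_hit
    running = 0.0
    best = 0.0
    for gene, metric in zip(ranked_genes, metrics):
        if gene in members:
            if hit_weight_total > 0:
                running += abs(metric) ** p / hit_weight_total
            else:
                running += 1.0 / n_hit
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best) or (abs(running) == abs(best) and running > best):
            best = running
    return best
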
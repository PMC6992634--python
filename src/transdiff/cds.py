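"""Stop-codon-anchored CDS extraction from assembled transcripts.

Candidate coding regions are the maximal stop-free stretches in each of the
six reading frames.  Unlike conventional ORF callers, a stretch begins
immediately after the previous stop codon (or at the frame start), *not* at
the first ATG: assembled contigs are frequently 5'-truncated, so requiring a
Met start discards genuine partial CDSs.  Internal ATGs never open a separate
record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio.Seq import Seq

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_IUPAC_NT = frozenset("ACGTN")

__all__ = ["CdsRecord", "extract_cds", "best_cds", "extract_cds_fasta"]


@dataclass(frozen=True)
class CdsRecord:
    """One candidate coding region.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    reported orientation: for ``strand == '-'`` they index into the reverse
    complement of the input sequence, so that for either strand
    ``translate(oriented_seq[start:end]) == protein``.
    """

    transcript_id: str
    strand: str  # '+' or '-'
    frame: int  # 0, 1, 2
    start: int
    end: int
    protein: str

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("CDS interval length must be a multiple of 3")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def aa_len(self) -> int:
        return len(self.protein)


def _translate_codon(codon: str) -> str:
    if "N" in codon:
        return "X"
    return str(Seq(codon).translate())


def _frame_records(
    seq: str, strand: str, frame: int, min_aa: int, transcript_id: str
) -> Iterator[CdsRecord]:
    n_codons = (len(seq) - frame) // 3
    run_start = frame  # nt position where the current stop-free run began
    run_aa: list[str] = []
    for i in range(n_codons):
        pos = frame + 3 * i
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            yield from _emit(transcript_id, strand, frame, run_start, pos, run_aa, min_aa)
            run_start = pos + 3
            run_aa = []
        else:
            run_aa.append(_translate_codon(codon))
    yield from _emit(
        transcript_id, strand, frame, run_start, frame + 3 * n_codons, run_aa, min_aa
    )


def _emit(
    transcript_id: str,
    strand: str,
    frame: int,
    start: int,
    end: int,
    aa: list[str],
    min_aa: int,
) -> Iterator[CdsRecord]:
    if len(aa) < min_aa:
        return
    protein = "".join(aa)
    if set(protein) == {"X"}:
        # ambiguity-only stretches (e.g. poly-N gap fill) carry no coding signal
        return
    yield CdsRecord(transcript_id, strand, frame, start, end, protein)


def extract_cds(
    sequence: str, min_aa: int = 30, transcript_id: str = "seq"
) -> list[CdsRecord]:
    """Report every stop-free stretch of ``>= min_aa`` codons in all 6 frames.

    Each stretch starts right after a stop codon or at the start of its frame
    and ends at the next stop codon or the end of the sequence — never at an
    internal ATG.  Records are sorted by protein length descending (ties:
    '+' strand first, then lower frame, then smaller start).

    Raises ``ValueError`` on characters outside {A, C, G, T, N} or min_aa < 1.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = sequence.upper()
    if not seq:
        return []
    bad = set(seq) - _IUPAC_NT
    if bad:
        raise ValueError(f"non-IUPAC nucleotide characters: {sorted(bad)}")

    records: list[CdsRecord] = []
    rc = str(Seq(seq).reverse_complement())
    for strand, oriented in (("+", seq), ("-", rc)):
        for frame in range(3):
            records.extend(_frame_records(oriented, strand, frame, min_aa, transcript_id))
    records.sort(key=lambda r: (-r.aa_len, r.strand != "+", r.frame, r.start))
    return records


def best_cds(records: Iterable[CdsRecord]) -> CdsRecord | None:
    """Single best candidate per transcript: longest protein, ties broken by
    '+' strand first, then lowest frame, then smallest start."""
    recs = sorted(records, key=lambda r: (-r.aa_len, r.strand != "+", r.frame, r.start))
    return recs[0] if recs else None


def extract_cds_fasta(
    records: Iterable[tuple[str, str]],
    min_aa: int = 30,
    single_best: bool = False,
    rescue_ids: Iterable[str] | None = None,
    rescue_min_aa: int = 1,
) -> list[CdsRecord]:
    """Run :func:`extract_cds` over ``(id, sequence)`` pairs.

    ``rescue_ids`` is the homology-rescue hook: transcripts named there (e.g.
    because a precomputed protein-database hit exists) are re-scanned with the
    relaxed ``rescue_min_aa`` threshold so sub-threshold but homology-supported
    stretches are retained.
    """
    rescue = set(rescue_ids) if rescue_ids is not None else set()
    out: list[CdsRecord] = []
    for tid, seq in records:
        threshold = rescue_min_aa if tid in rescue else min_aa
        recs = extract_cds(seq, min_aa=threshold, transcript_id=tid)
        if single_best:
            top = best_cds(recs)
            recs = [top] if top is not None else []
        out.extend(recs)
    return out
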
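"""The three-condition screen nominating candidate transdifferentiation
regulators among transcription-factor homologs.

A TF passes when its expression peaks at the middle regeneration stage:
stage-2 TPM above unity, the mean of its two stage-2 log fold changes
(vs. stage 1 and vs. stage 3) above one half, and at least one of those two
fold changes above unity.  All three inequalities are strict.  Significance
is reported alongside but is deliberately not a gate: a biologically sharp
peak with a noisy p-value still makes the candidate list.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["select_candidates"]

TPM2_COL = "tpm_stage2"
LFC21_COL = "logfc_stage2_vs_stage1"
LFC23_COL = "logfc_stage2_vs_stage3"


def select_candidates(
    expr: pd.DataFrame,
    tf_set: set[str],
    tpm_min: float = 1.0,
    mean_lfc_min: float = 0.5,
    max_lfc_min: float = 1.0,
    include: set[str] | None = None,
    exclude: set[str] | None = None,
) -> pd.DataFrame:
    """Score every gene in ``expr`` against the candidate-TF screen.

    ``expr`` must carry stage-2 TPM and the two stage-2 contrasts
    (columns ``tpm_stage2``, ``logfc_stage2_vs_stage1``,
    ``logfc_stage2_vs_stage3``, as produced by
    :func:`transdiff.expression.expression_table`).

    A gene passes iff it is in ``tf_set`` AND TPM₂ > tpm_min AND
    (LogFC₂₁ + LogFC₂₃)/2 > mean_lfc_min AND max(LogFC₂₁, LogFC₂₃) >
    max_lfc_min, every inequality strict.  ``reasons`` lists each failed
    gate ('tf', 'tpm', 'mean_lfc', 'max_lfc') so near-misses are auditable.

    ``include``/``exclude`` are post-screen manual-curation lists (e.g. a
    zinc-finger exclusion list after by-hand verification); they override the
    automatic verdict and are flagged in the ``curation`` column.
    """
    missing = [c for c in (TPM2_COL, LFC21_COL, LFC23_COL) if c not in expr.columns]
    if missing:
        raise ValueError(f"expression table missing columns: {missing}")

    out = expr[[TPM2_COL, LFC21_COL, LFC23_COL]].copy()
    out.columns = ["tpm_stage2", "logfc_21", "logfc_23"]
    out["mean_logfc"] = (out["logfc_21"] + out["logfc_23"]) / 2.0

    reasons: list[list[str]] = []
    for gene, row in out.iterrows():
        why = []
        if gene not in tf_set:
            why.append("tf")
        if not row["tpm_stage2"] > tpm_min:
            why.append("tpm")
        if not row["mean_logfc"] > mean_lfc_min:
            why.append("mean_lfc")
        if not max(row["logfc_21"], row["logfc_23"]) > max_lfc_min:
            why.append("max_lfc")
        reasons.append(why)
    out["passed"] = [not r for r in reasons]
    out["reasons"] = reasons

    out["curation"] = ""
    for gene in sorted(include or ()):
        if gene in out.index and not out.at[gene, "passed"]:
            out.at[gene, "passed"] = True
            out.at[gene, "reasons"] = []
            out.at[gene, "curation"] = "include"
    for gene in sorted(exclude or ()):
        if gene in out.index and out.at[gene, "passed"]:
            out.at[gene, "passed"] = False
            out.at[gene, "reasons"] = ["manual_exclude"]
            out.at[gene, "curation"] = "exclude"
    return out
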
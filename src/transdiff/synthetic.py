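"""Synthetic fixtures with planted ground truth for every pipeline stage.

The generator emulates the data shapes an eviscerated-holothurian
regeneration study produces — cross-species hit tables with paralog decoys
and foreign contaminants, negative-binomial count matrices over four
conditions (intact gut plus three regeneration stages, two replicates each),
qPCR Ct tables, transcripts with plantable ORFs, and gene-set collections —
so that recovery of the planted truth can be measured exactly.

A single global seed feeds named substreams (``hits``, ``counts``, ``ct``,
...), so each artefact regenerates independently and byte-identically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .expression import CONDITIONS, CountMatrix

__all__ = [
    "SimConfig",
    "TruthTable",
    "make_truth",
    "simulate_hit_tables",
    "simulate_nrp_hits",
    "simulate_counts",
    "simulate_ct_table",
    "simulate_transcripts",
    "simulate_gene_sets",
]

REFERENCE_GENES = ("Tubulin", "EF1a")
#: non-deuterostome taxa used to label simulated contaminant hits
FOREIGN_TAXA = ("Vibrio sp.", "Symbiodinium sp.", "Aspergillus sp.")
DEUTEROSTOME_TAXON = "Apostichopus japonicus"


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream: independent generator derived from the global seed."""
    return np.random.default_rng([seed, zlib.crc32(stream.encode())])


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the experimental design being emulated: four ordered
    conditions (intact, stage1, stage2, stage3) with two biological
    replicates each (each replicate a pool of individuals), 100-nt reads,
    and a stage-2 expression peak of 1.5 log2 units for planted regulator
    TFs — comfortably above the screen's gates without being trivial.
    """

    n_genes: int = 2000
    n_conditions: int = 4
    n_replicates: int = 2
    nb_dispersion: float = 0.05
    peak_logfc: float = 1.5
    bitscore_noise_sd: float = 10.0
    n_decoys: int = 3
    ct_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        for name in ("n_conditions", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_conditions > len(CONDITIONS):
            raise ValueError(f"at most {len(CONDITIONS)} conditions supported")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.bitscore_noise_sd < 0 or self.ct_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")

    @property
    def conditions(self) -> tuple[str, ...]:
        return CONDITIONS[: self.n_conditions]


@dataclass
class TruthTable:
    """Planted ground truth the pipeline is measured against."""

    gene_ids: tuple[str, ...]
    true_ortholog_pairs: set[tuple[str, str]] = field(default_factory=set)
    contaminant_ids: set[str] = field(default_factory=set)
    #: per planted TF gene, its true per-condition mean count
    planted_tf_means: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_peak_ids: set[str] = field(default_factory=set)

    @property
    def planted_tf_ids(self) -> set[str]:
        return set(self.planted_tf_means)

    def __post_init__(self) -> None:
        queries = [q for q, _ in self.true_ortholog_pairs]
        subjects = [s for _, s in self.true_ortholog_pairs]
        if len(set(queries)) != len(queries) or len(set(subjects)) != len(subjects):
            raise ValueError("true_ortholog_pairs must be one-to-one")
        if not self.planted_peak_ids <= self.planted_tf_ids:
            raise ValueError("planted_peak_ids must be a subset of planted_tf_ids")
        if self.contaminant_ids & self.planted_tf_ids:
            raise ValueError("contaminants cannot carry planted TF signal")
        universe = set(self.gene_ids)
        for ids, what in (
            (set(queries), "ortholog queries"),
            (self.contaminant_ids, "contaminant_ids"),
            (self.planted_tf_ids, "planted_tf_ids"),
        ):
            if not ids <= universe:
                raise ValueError(f"{what} reference IDs outside the gene universe")


def make_truth(
    config: SimConfig,
    n_pairs: int = 50,
    n_tf: int = 40,
    n_peak: int = 20,
    n_contaminants: int = 20,
    baseline_range: tuple[float, float] = (50.0, 500.0),
) -> TruthTable:
    """Plant the ground truth inside a fresh gene universe.

    The first ``n_tf`` genes are TF homologs; ``n_peak`` of them peak at
    stage 2 by ``config.peak_logfc`` log2 units over every other condition,
    the rest stay flat (screen decoys).  ``n_contaminants`` genes at the top
    of the ID range are foreign sequences; ``n_pairs`` genes get a true
    one-to-one ortholog partner in the subject universe.
    """
    if n_peak > n_tf:
        raise ValueError("n_peak must be <= n_tf")
    if n_tf + n_contaminants > config.n_genes or n_pairs > config.n_genes:
        raise ValueError("planted structure does not fit in n_genes")
    rng = _rng(config.seed, "truth")
    genes = tuple(f"G{i:06d}" for i in range(config.n_genes))

    tf_ids = list(genes[:n_tf])
    peak_ids = set(tf_ids[:n_peak])
    contaminants = set(genes[config.n_genes - n_contaminants :])

    lo, hi = baseline_range
    means: dict[str, dict[str, float]] = {}
    for gene in tf_ids:
        base = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        per_cond = {cond: base for cond in config.conditions}
        if gene in peak_ids and "stage2" in per_cond:
            per_cond["stage2"] = base * 2.0**config.peak_logfc
        means[gene] = per_cond

    pairs = {(genes[i], f"H{i:06d}") for i in range(n_pairs)}
    return TruthTable(
        gene_ids=genes,
        true_ortholog_pairs=pairs,
        contaminant_ids=contaminants,
        planted_tf_means=means,
        planted_peak_ids=peak_ids,
    )


def _evalue_from_bitscore(bitscore: np.ndarray) -> np.ndarray:
    # monotone stand-in: higher bitscore, lower e-value
    return np.power(10.0, -np.clip(bitscore, 0, 300) / 3.0)


def simulate_hit_tables(
    config: SimConfig,
    truth: TruthTable,
    family_size: int = 4,
    decoy_gap: float = 25.0,
) -> pd.DataFrame:
    """Cross-species hit table for the ortholog matchers.

    Every true pair gets a hit at a high base bitscore; each query also hits
    ``config.n_decoys`` paralog subjects from the same simulated protein
    family at ``decoy_gap`` bits below its true score.  Gaussian noise of SD
    ``config.bitscore_noise_sd`` perturbs all scores, so with zero noise every
    true pair is the unique mutual best hit, while growing noise increasingly
    lets a strong query outscore a weaker family member's own true hit — the
    regime where greedy pairing beats the reciprocal baseline.
    """
    rng = _rng(config.seed, "hits")
    pairs = sorted(truth.true_ortholog_pairs)
    if not pairs:
        return pd.DataFrame(columns=["query", "subject", "bitscore", "evalue"])
    subjects = [s for _, s in pairs]
    base = rng.uniform(400.0, 800.0, size=len(pairs))

    rows_q, rows_s, rows_b = [], [], []
    for i, (q, s) in enumerate(pairs):
        rows_q.append(q)
        rows_s.append(s)
        rows_b.append(base[i])
        fam_start = (i // family_size) * family_size
        family = [
            j
            for j in range(fam_start, min(fam_start + family_size, len(pairs)))
            if j != i
        ]
        for k in range(min(config.n_decoys, len(family))):
            j = family[k % len(family)]
            rows_q.append(q)
            rows_s.append(subjects[j])
            rows_b.append(base[i] - decoy_gap)
    bits = np.asarray(rows_b) + rng.normal(0.0, config.bitscore_noise_sd, len(rows_b))
    bits = np.maximum(bits, 1.0)
    hits = pd.DataFrame(
        {
            "query": rows_q,
            "subject": rows_s,
            "bitscore": np.round(bits, 1),
            "evalue": _evalue_from_bitscore(np.asarray(bits)),
            "taxon_label": DEUTEROSTOME_TAXON,
            "is_panel": False,
        }
    )
    return hits


def simulate_nrp_hits(config: SimConfig, truth: TruthTable) -> pd.DataFrame:
    """Hit table against a non-redundant protein panel for contaminant
    screening.

    Contaminant genes get a strong (> 200 bit) best hit to a non-deuterostome
    taxon and either no echinoderm-panel hit or one below 80% of it; clean
    genes get a deuterostome best hit plus a panel hit above that fraction.
    """
    rng = _rng(config.seed, "nrp")
    rows = []
    for gene in truth.gene_ids:
        if gene in truth.contaminant_ids:
            nrp_bits = rng.uniform(220.0, 600.0)
            taxon = FOREIGN_TAXA[int(rng.integers(len(FOREIGN_TAXA)))]
            rows.append((gene, f"NRP_{gene}", nrp_bits, taxon, False))
            if rng.random() < 0.5:  # weak echinoderm similarity, below rescue
                rows.append(
                    (gene, f"PANEL_{gene}", rng.uniform(0.2, 0.7) * nrp_bits,
                     DEUTEROSTOME_TAXON, True)
                )
        else:
            nrp_bits = rng.uniform(150.0, 900.0)
            rows.append((gene, f"NRP_{gene}", nrp_bits, DEUTEROSTOME_TAXON, False))
            rows.append(
                (gene, f"PANEL_{gene}", rng.uniform(0.85, 1.0) * nrp_bits,
                 DEUTEROSTOME_TAXON, True)
            )
    df = pd.DataFrame(
        rows, columns=["query", "subject", "bitscore", "taxon_label", "is_panel"]
    )
    df["bitscore"] = df["bitscore"].round(1)
    df["evalue"] = _evalue_from_bitscore(df["bitscore"].to_numpy())
    df["is_deuterostome"] = df["taxon_label"] == DEUTEROSTOME_TAXON
    return df


def simulate_counts(
    config: SimConfig, truth: TruthTable, exact_means: bool = False
) -> CountMatrix:
    """Negative-binomial counts around the planted per-condition means.

    Background (non-TF) genes are flat across conditions with log-uniform
    baselines; planted TFs follow their truth-table means.  Variance is
    μ + αμ² with α = ``config.nb_dispersion``; α ≤ 1e-8 degenerates to
    Poisson.  ``exact_means=True`` writes the rounded expected counts
    directly (the zero-noise limit used for exact-recovery checks).
    Effective lengths are log-uniform on [300, 10000] nt.
    """
    rng = _rng(config.seed, "counts")
    genes = list(truth.gene_ids)
    conditions = config.conditions
    samples = [f"{c}_r{r + 1}" for c in conditions for r in range(config.n_replicates)]
    design = pd.DataFrame(
        {
            "condition": [c for c in conditions for _ in range(config.n_replicates)],
            "replicate": list(range(1, config.n_replicates + 1)) * len(conditions),
        },
        index=pd.Index(samples, name="sample"),
    )
    eff_length = pd.Series(
        np.exp(rng.uniform(np.log(300.0), np.log(10000.0), len(genes))).round(),
        index=genes,
        name="eff_length",
    )
    base = np.exp(rng.uniform(np.log(20.0), np.log(500.0), len(genes)))
    mu = pd.DataFrame(
        {s: base.copy() for s in samples}, index=pd.Index(genes, name="gene")
    )
    for gene, per_cond in truth.planted_tf_means.items():
        for s in samples:
            mu.at[gene, s] = per_cond[design.at[s, "condition"]]

    if exact_means:
        counts = mu.round().astype(int)
    else:
        alpha = config.nb_dispersion
        m = mu.to_numpy()
        if alpha <= 1e-8:
            drawn = rng.poisson(m)
        else:
            n_param = 1.0 / alpha
            p_param = n_param / (n_param + m)
            drawn = rng.negative_binomial(n_param, p_param)
        counts = pd.DataFrame(drawn, index=mu.index, columns=mu.columns)
    return CountMatrix(counts, design, eff_length, read_length=100)


def simulate_ct_table(
    config: SimConfig,
    truth: TruthTable,
    targets: list[str] | None = None,
    n_replicates: int = 3,
    control_condition: str = "stage1",
) -> pd.DataFrame:
    """qPCR Ct table consistent with the planted fold changes.

    Targets default to five planted peak genes.  Ct = baseline −
    log2(relative expression vs ``control_condition``) + N(0, ct_noise_sd);
    the two reference genes (Tubulin, EF1a) are condition-invariant.  The
    qPCR design covers the three regeneration stages with ``n_replicates``
    biological replicates.
    """
    rng = _rng(config.seed, "ct")
    if targets is None:
        targets = sorted(truth.planted_peak_ids)[:5]
    unknown = set(targets) - truth.planted_tf_ids
    if unknown:
        raise ValueError(f"targets without planted means: {sorted(unknown)}")
    conditions = [c for c in config.conditions if c.startswith("stage")]
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} not simulated")

    rows = []
    baselines = {t: rng.uniform(18.0, 26.0) for t in targets}
    ref_ct = {"Tubulin": 15.0, "EF1a": 16.5}
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            for ref, level in ref_ct.items():
                rows.append((ref, cond, rep, level + rng.normal(0, config.ct_noise_sd)))
            for t in targets:
                rel = truth.planted_tf_means[t][cond] / truth.planted_tf_means[t][
                    control_condition
                ]
                ct = baselines[t] - np.log2(rel) + rng.normal(0, config.ct_noise_sd)
                rows.append((t, cond, rep, ct))
    return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])


def simulate_transcripts(
    config: SimConfig,
    n_transcripts: int = 20,
    orf_aa: int = 60,
    flank_nt: int = 40,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Transcripts carrying one planted stop-anchored ORF each.

    Each transcript is random sequence flanking a planted coding stretch of
    ``orf_aa`` sense codons bracketed by stop codons, so the planted protein
    is exactly one maximal stop-free stretch in the forward frame where it
    was inserted.  Returns ``(records, truth)`` where ``truth`` maps
    transcript ID to the planted protein.
    """
    from Bio.Seq import Seq

    rng = _rng(config.seed, "transcripts")
    sense_codons = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA")
    ]
    records, planted = [], {}
    for i in range(n_transcripts):
        orf = "".join(rng.choice(sense_codons, size=orf_aa))
        left = "".join(rng.choice(list("ACGT"), size=flank_nt))
        right = "".join(rng.choice(list("ACGT"), size=flank_nt))
        seq = left + "TAA" + orf + "TAG" + right
        tid = f"T{i:05d}"
        records.append((tid, seq))
        planted[tid] = str(Seq(orf).translate())
    return records, planted


def simulate_gene_sets(
    config: SimConfig,
    truth: TruthTable,
    n_sets: int = 30,
    set_size: int = 25,
    tf_set_fraction: float = 0.5,
) -> dict[str, set[str]]:
    """Gene-set collection in the simulated gene namespace.

    A ``tf_set_fraction`` share of the sets is seeded with 1–3 planted TFs
    (so set filtering retains them); members are otherwise drawn uniformly.
    """
    rng = _rng(config.seed, "genesets")
    genes = np.array(truth.gene_ids)
    tf_ids = sorted(truth.planted_tf_ids)
    sets: dict[str, set[str]] = {}
    for i in range(n_sets):
        members = set(rng.choice(genes, size=min(set_size, len(genes)), replace=False))
        if tf_ids and rng.random() < tf_set_fraction:
            k = int(rng.integers(1, min(3, len(tf_ids)) + 1))
            members |= set(rng.choice(tf_ids, size=k, replace=False))
        sets[f"SET_{i:03d}"] = members
    return sets


def regenerate(config: SimConfig, seed: int) -> SimConfig:
    """Convenience: same configuration under a different global seed."""
    return replace(config, seed=seed)
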
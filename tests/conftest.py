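from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from transdiff.expression import CountMatrix
from transdiff.synthetic import SimConfig, make_truth


@pytest.fixture(scope="session")
def config() -> SimConfig:
    return SimConfig(seed=42)


@pytest.fixture(scope="session")
def truth(config):
    return make_truth(config)


def random_hit_table(
    rng: np.random.Generator,
    max_q: int = 6,
    max_s: int = 6,
    tie_free: bool = False,
) -> pd.DataFrame:
    """Random many-to-many hit table over <= max_q queries and max_s subjects."""
    nq = int(rng.integers(1, max_q + 1))
    ns = int(rng.integers(1, max_s + 1))
    rows = []
    for qi in range(nq):
        for si in range(ns):
            if rng.random() < 0.5:
                rows.append((f"q{qi}", f"s{si}"))
    if not rows:
        rows.append(("q0", "s0"))
    if tie_free:
        scores = rng.permutation(np.arange(1, len(rows) + 1)).astype(float)
    else:
        scores = rng.integers(1, 8, size=len(rows)).astype(float)  # ties likely
    evalues = np.round(10.0 ** -rng.integers(3, 10, size=len(rows)), 12)
    return pd.DataFrame(
        {
            "query": [r[0] for r in rows],
            "subject": [r[1] for r in rows],
            "bitscore": scores,
            "evalue": evalues,
        }
    )


def small_count_matrix(
    counts: dict[str, list[int]],
    conditions: list[str],
    eff_length: dict[str, float] | float = 1000.0,
    read_length: int = 100,
) -> CountMatrix:
    """Convenience constructor: ``counts`` maps gene -> per-sample counts,
    sample i gets condition ``conditions[i]`` with per-condition replicate
    numbering."""
    genes = list(counts)
    samples = []
    seen: dict[str, int] = {}
    for cond in conditions:
        seen[cond] = seen.get(cond, 0) + 1
        samples.append(f"{cond}_r{seen[cond]}")
    frame = pd.DataFrame(
        {s: [counts[g][i] for g in genes] for i, s in enumerate(samples)}, index=genes
    )
    design = pd.DataFrame(
        {
            "condition": conditions,
            "replicate": [int(s.rsplit("_r", 1)[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    if isinstance(eff_length, dict):
        lengths = pd.Series(eff_length)
    else:
        lengths = pd.Series(eff_length, index=genes)
    return CountMatrix(frame, design, lengths, read_length=read_length)
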
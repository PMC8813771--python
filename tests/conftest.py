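"""Shared fixtures: the default simulated line scenario and small helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from saltil import synth

#: Seed used for every fixed-seed scenario in the suite.
SEED = 1


@pytest.fixture(scope="session")
def default_scenario():
    """Default simulated line: 2,000 transcripts, three donor blocks
    (two on chr1, one on chr3) plus 28 dispersed donor genes, default
    divergence model."""
    genome = synth.GenomeSpec.rice_like(2_000)
    mosaic = synth.TruthMosaicConfig()
    annotation, truth = synth.gen_truth_line(genome, mosaic, SEED)
    profiles = synth.gen_variant_profiles(
        annotation, truth.labels, synth.DivergenceModel(), SEED)
    return annotation, truth, profiles


def brute_force_blocks(labels: list[str], min_run: int, max_gap: int):
    """Independent O(n^2) enumeration of maximal qualifying donor runs.

    For one chromosome's position-ordered labels, enumerates every pair of
    donor positions, keeps segments whose internal recurrent gaps are all
    <= max_gap and that cannot be extended either way, then splits them into
    blocks (>= min_run donors, as position lists) and dispersed donors.
    """
    donor_pos = [i for i, lab in enumerate(labels) if lab == "donor"]
    n = len(donor_pos)

    def gap(i: int, j: int) -> int:
        return donor_pos[j] - donor_pos[i] - 1

    maximal = []
    for a in range(n):
        if a > 0 and gap(a - 1, a) <= max_gap:
            continue  # extendable to the left
        for b in range(a, n):
            if b > a and gap(b - 1, b) > max_gap:
                break  # segment broken; longer ones are broken too
            if b < n - 1 and gap(b, b + 1) <= max_gap:
                continue  # extendable to the right
            maximal.append(donor_pos[a:b + 1])
    blocks = [seg for seg in maximal if len(seg) >= min_run]
    dispersed = sorted(p for seg in maximal if len(seg) < min_run for p in seg)
    return blocks, dispersed


def labels_to_calls(labels: list[str], chrom: str = "chr1") -> pd.DataFrame:
    """Build a minimal classified-calls frame from a label sequence."""
    n = len(labels)
    starts = np.arange(n) * 10_000 + 1
    return pd.DataFrame({
        "transcript_id": [f"{chrom}t{i}" for i in range(n)],
        "chrom": chrom,
        "start": starts,
        "end": starts + 5_000,
        "v_test": 0,
        "v_control": 0,
        "delta_v": [20 if lab == "donor" else 0 for lab in labels],
        "label": labels,
    })
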
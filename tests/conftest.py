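"""Shared fixtures: toy gene structures and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from scnsplice.annotation import GeneModel, Transcript
from scnsplice.synthetic import CohortSpec, make_mxe_gene, simulate_cohort


@pytest.fixture
def overlap_gene() -> GeneModel:
    """Two transcripts with partially overlapping exons: T1 [100,200), T2 [150,250)."""
    return GeneModel(
        gene_id="G1",
        gene_name="G1",
        chrom="chr1",
        strand="+",
        transcripts=(
            Transcript("T1", ((100, 200),)),
            Transcript("T2", ((150, 250),)),
        ),
    )


@pytest.fixture
def mxe_gene():
    """Toy MXE gene: two constitutive flanks each side plus A/N exon copies."""
    return make_mxe_gene("GX", "chr1", origin=1_000)


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-sample cohort with default (reported-ratio) switch parameters."""
    return simulate_cohort(CohortSpec(n_samples=30, seed=11))


def random_gene_model(rng: np.random.Generator, max_transcripts=6, max_exons=12) -> GeneModel:
    """Random transcript structures over a shared pool of exon boundaries."""
    n_t = rng.integers(1, max_transcripts + 1)
    pool_edges = np.sort(rng.choice(np.arange(0, 4000), size=2 * max_exons, replace=False))
    exon_pool = [
        (int(pool_edges[2 * i]), int(pool_edges[2 * i + 1]))
        for i in range(max_exons)
        if pool_edges[2 * i + 1] > pool_edges[2 * i]
    ]
    transcripts = []
    for t in range(n_t):
        k = rng.integers(1, len(exon_pool) + 1)
        chosen = sorted(
            exon_pool[i] for i in rng.choice(len(exon_pool), size=k, replace=False)
        )
        # drop overlapping picks to keep transcripts valid
        kept = []
        for s, e in chosen:
            if not kept or s >= kept[-1][1]:
                kept.append((s, e))
        transcripts.append(Transcript(f"T{t}", tuple(kept)))
    return GeneModel(
        gene_id="R", gene_name="R", chrom="chr1", strand="+", transcripts=tuple(transcripts)
    )


def membership_signature_bins(model: GeneModel) -> list[tuple[int, int]]:
    """Brute-force flattening oracle: group contiguous bases by transcript membership."""
    lo = min(s for t in model.transcripts for s, _ in t.exons)
    hi = max(e for t in model.transcripts for _, e in t.exons)
    sigs = []
    for base in range(lo, hi):
        sig = frozenset(
            t.transcript_id
            for t in model.transcripts
            if any(s <= base < e for s, e in t.exons)
        )
        sigs.append(sig)
    bins = []
    start = None
    for i, sig in enumerate(sigs):
        pos = lo + i
        if not sig:
            if start is not None:
                bins.append((start, pos))
                start = None
            continue
        if start is None:
            start, cur = pos, sig
        elif sig != cur:
            bins.append((start, pos))
            start, cur = pos, sig
    if start is not None:
        bins.append((start, hi))
    return bins
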
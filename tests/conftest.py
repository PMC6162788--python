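from __future__ import annotations

import numpy as np
import pytest

from lncfocal.annotation import Exon, Transcript
from lncfocal.pipeline import recovery_experiment
from lncfocal.simdata import SimConfig


def make_transcript(
    tid: str,
    biotype: str,
    chrom: str,
    exon_coords: list[tuple[int, int]],
    strand: str = "+",
    gene_id: str | None = None,
) -> Transcript:
    return Transcript(
        id=tid,
        gene_id=gene_id or tid.rsplit(".", 1)[0],
        biotype=biotype,
        exons=tuple(
            Exon(chrom=chrom, start=s, end=e, strand=strand) for s, e in exon_coords
        ),
    )


@pytest.fixture(scope="session")
def noise_free_run() -> dict:
    """The default noise-free synthetic panel run end-to-end (segment+filter).

    5 chromosomes x 10 Mb, 100 protein-coding + 50 lncRNA genes, 10 planted
    focal deletions (CN 0) and 10 focal amplifications (CN 8), sigma = 0.
    """
    return recovery_experiment(SimConfig(seed=1, probe_sigma=0.0))


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """A reduced genome for unit-level synthetic-data checks."""
    return SimConfig(
        seed=7,
        n_chromosomes=2,
        chrom_length=5_000_000,
        n_pc_genes=20,
        n_lnc_genes=8,
        n_samples=2,
        n_focal_del=2,
        n_focal_amp=2,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
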
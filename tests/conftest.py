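"""Shared fixtures: the standard synthetic cohort and derived tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pupfishpop as pp


@pytest.fixture(scope="session")
def cohort() -> pp.SimulatedCohort:
    """The repo's standard tiny cohort (2 contigs, 6 samples, fixed seed)."""
    return pp.simulate_cohort(pp.fixture_config())


@pytest.fixture(scope="session")
def cohort_files(cohort, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("cohort")
    return cohort.write(outdir)


@pytest.fixture(scope="session")
def effects_table(cohort) -> pd.DataFrame:
    return pp.classify_variants(cohort.gm.sites, cohort.genes, cohort.sequences)


@pytest.fixture(scope="session")
def roh_segments(cohort) -> list[pp.ROHSegment]:
    return pp.detect_roh_cohort(cohort.gm)


def make_matrix(codes: np.ndarray, samples: list[str],
                contig: str = "c1", start: int = 1000, spacing: int = 1000,
                ref: str = "A", alt: str = "T") -> pp.GenotypeMatrix:
    """Small helper: a GenotypeMatrix with evenly spaced sites on one contig."""
    codes = np.asarray(codes, dtype=np.int8)
    n = codes.shape[0]
    sites = pd.DataFrame({
        "contig": [contig] * n,
        "pos": start + spacing * np.arange(n),
        "ref": [ref] * n,
        "alt": [alt] * n,
    })
    return pp.GenotypeMatrix(sites, codes, samples)
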
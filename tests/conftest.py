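"""Shared fixtures: tiny deterministic libraries and screens."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from slscreen import (
    CountMatrix,
    NONTARGETING,
    ScreenDesign,
    ShRNAClone,
    ShRNALibrary,
)


def make_barcodes(n: int, length: int = 21, seed: int = 12345) -> list[str]:
    """Deterministic distinct random barcodes."""
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[str] = []
    bases = "ACGT"
    while len(out) < n:
        s = "".join(bases[i] for i in rng.integers(0, 4, size=length))
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def make_library(
    genes: dict[str, int], n_controls: int = 0, length: int = 21, seed: int = 12345
) -> ShRNALibrary:
    """Library with the given clones-per-gene map plus controls."""
    n = sum(genes.values()) + n_controls
    barcodes = iter(make_barcodes(n, length, seed))
    clones = [
        ShRNAClone(f"{g}_sh{j}", g, next(barcodes))
        for g, k in genes.items()
        for j in range(1, k + 1)
    ]
    clones += [
        ShRNAClone(f"NT_sh{j}", NONTARGETING, next(barcodes))
        for j in range(1, n_controls + 1)
    ]
    return ShRNALibrary(clones=clones, barcode_length=length)


@pytest.fixture
def eight_row_library() -> ShRNALibrary:
    """Two genes with four clones each, no controls."""
    return make_library({"G1": 4, "G2": 4})


@pytest.fixture
def design() -> ScreenDesign:
    return ScreenDesign(ko_samples=("KO1", "KO2"), control_samples=("C1", "C2"))


def counts_from_rows(lib: ShRNALibrary, rows: dict[str, tuple[int, int, int, int]]):
    """CountMatrix over KO1,KO2,C1,C2 from per-clone 4-tuples."""
    df = pd.DataFrame(
        [rows[c] for c in lib.clone_ids],
        index=pd.Index(lib.clone_ids, name="clone_id"),
        columns=["KO1", "KO2", "C1", "C2"],
    )
    return CountMatrix.from_counts(df)


def random_count_matrix(lib: ShRNALibrary, seed: int, low: int = 0, high: int = 1000):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        rng.integers(low, high + 1, size=(len(lib), 4)),
        index=pd.Index(lib.clone_ids, name="clone_id"),
        columns=["KO1", "KO2", "C1", "C2"],
    )
    return CountMatrix.from_counts(df)
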
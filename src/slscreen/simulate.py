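"""Synthetic pooled dropout screens with known ground truth.

Emulates the study design the hit-caller targets: a kinome-scale hairpin
library (~513 genes, 4-10 clones each, plus nontargeting controls) screened
in two genotypes with two replicates each — knockout replicates KO1/KO2 and
corrected/control replicates C1/C2.  Clone abundances follow a log-normal
prior (one integrated hairpin per cell at low MOI, uneven pool representation),
sequencing counts are negative-binomial (Gamma-Poisson) with variance
``m + phi * m**2``, and designated synthetic-lethal genes have their effective
clones depleted ``fold_depletion``-fold in the knockout samples only.

Every stage is deterministic under the master seed; child seeds for the
library, counts, FASTQ, and gene-set stages are derived from it so sub-stages
are individually reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .library import NONTARGETING, ShRNAClone, ShRNALibrary
from .quantify import CountMatrix

__all__ = [
    "SAMPLES",
    "KO_SAMPLES",
    "CONTROL_SAMPLES",
    "SimulationParams",
    "TruthLabels",
    "simulate_library",
    "simulate_counts",
    "simulate_fastq",
    "simulate_gene_sets",
    "expected_counts",
]

KO_SAMPLES = ("KO1", "KO2")
CONTROL_SAMPLES = ("C1", "C2")
SAMPLES = KO_SAMPLES + CONTROL_SAMPLES

_STAGE_LIBRARY, _STAGE_COUNTS, _STAGE_FASTQ, _STAGE_GENESETS = range(4)


class SimulationParams(BaseModel):
    """Generator settings; defaults emulate the kinome screen's shape.

    ``depth`` defaults to 5e6 expected reads per sample (a conventional pooled
    screen depth); test presets use 2e5.  ``dispersion`` is the
    negative-binomial phi in ``var = m + phi*m**2``; 0 degenerates to Poisson.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    n_genes: int = Field(513, ge=0)
    clones_per_gene: tuple[int, int] = (4, 10)
    n_nontargeting: int = Field(100, ge=0)
    abundance_mu: float = 0.0
    abundance_sigma: float = Field(1.0, ge=0)
    depth: float = Field(5e6, gt=0)
    dispersion: float = Field(0.05, ge=0)
    sl_genes: list[str] = Field(default_factory=list)
    n_sl_genes: int = Field(0, ge=0)
    fold_depletion: float = Field(10.0, gt=1)
    penetrance: float = Field(0.8, ge=0, le=1)
    enr_genes: list[str] = Field(default_factory=list)
    fold_enrichment: float = Field(5.0, gt=1)
    error_rate: float = Field(0.01, ge=0, le=1)
    barcode_length: int = Field(21, ge=1)
    read_len: Optional[int] = Field(None, ge=1)
    barcode_offset: int = Field(0, ge=0)
    stuffer_base: str = "A"
    exact_depth: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationParams":
        lo, hi = self.clones_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("clones_per_gene must satisfy 1 <= lo <= hi")
        if self.read_len is not None and self.read_len < self.barcode_offset + self.barcode_length:
            raise ValueError("read_len must cover barcode_offset + barcode_length")
        if self.stuffer_base not in "ACGT":
            raise ValueError("stuffer_base must be one of A/C/G/T")
        return self

    @property
    def effective_read_len(self) -> int:
        if self.read_len is not None:
            return self.read_len
        return self.barcode_offset + self.barcode_length


@dataclass
class TruthLabels:
    """Ground truth for benchmarking: per-gene class and per-clone efficacy."""

    gene_class: dict[str, str]  # neutral | synthetic_lethal | enriched
    clone_effective: dict[str, bool]

    @property
    def sl_genes(self) -> set[str]:
        return {g for g, c in self.gene_class.items() if c == "synthetic_lethal"}

    @property
    def enriched_genes(self) -> set[str]:
        return {g for g, c in self.gene_class.items() if c == "enriched"}

    def effective_clones(self) -> set[str]:
        return {c for c, e in self.clone_effective.items() if e}

    def to_frame(self, lib: ShRNALibrary) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clone_id": lib.clone_ids,
                "gene": [c.gene for c in lib.clones],
                "gene_class": [
                    self.gene_class.get(c.gene, "neutral") for c in lib.clones
                ],
                "effective": [
                    self.clone_effective.get(c.clone_id, False) for c in lib.clones
                ],
            }
        )

    def write(self, path: str | Path, lib: ShRNALibrary) -> None:
        self.to_frame(lib).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def simulate_library(params: SimulationParams) -> ShRNALibrary:
    """Draw a library: gene names G0001..G{n}, random distinct barcodes.

    Raises if the barcode space at the configured length cannot hold the
    requested clone count with headroom.
    """
    rng = _rng(params.seed, _STAGE_LIBRARY)
    lo, hi = params.clones_per_gene
    genes = [f"G{i:04d}" for i in range(1, params.n_genes + 1)]
    n_per_gene = rng.integers(lo, hi + 1, size=params.n_genes)
    n_clones = int(n_per_gene.sum()) + params.n_nontargeting
    space = 4 ** params.barcode_length
    if n_clones > space // 4:
        raise ValueError(
            f"barcode space 4^{params.barcode_length} too small for "
            f"{n_clones} distinct clones"
        )

    seqs: set[str] = set()
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    barcodes: list[str] = []
    while len(barcodes) < n_clones:
        draw = bases[rng.integers(0, 4, size=(n_clones - len(barcodes),
                                              params.barcode_length))]
        for row in draw:
            s = row.tobytes().decode("ascii")
            if s not in seqs:
                seqs.add(s)
                barcodes.append(s)

    clones: list[ShRNAClone] = []
    b = iter(barcodes)
    for gene, k in zip(genes, n_per_gene):
        for j in range(1, int(k) + 1):
            clones.append(ShRNAClone(f"{gene}_sh{j}", gene, next(b)))
    for j in range(1, params.n_nontargeting + 1):
        clones.append(ShRNAClone(f"NT_sh{j:03d}", NONTARGETING, next(b)))
    return ShRNALibrary(clones=clones, barcode_length=params.barcode_length)


def _draw_truth(
    lib: ShRNALibrary, params: SimulationParams, rng: np.random.Generator
) -> TruthLabels:
    universe = lib.genes
    sl = list(params.sl_genes)
    if not sl and params.n_sl_genes:
        sl = sorted(rng.choice(universe, size=params.n_sl_genes, replace=False))
    unknown = (set(sl) | set(params.enr_genes)) - set(universe)
    if unknown:
        raise ValueError(f"designated genes not in simulated universe: {sorted(unknown)}")
    overlap = set(sl) & set(params.enr_genes)
    if overlap:
        raise ValueError(f"genes designated both SL and enriched: {sorted(overlap)}")

    gene_class = {g: "neutral" for g in universe}
    gene_class.update({g: "synthetic_lethal" for g in sl})
    gene_class.update({g: "enriched" for g in params.enr_genes})

    clone_effective: dict[str, bool] = {}
    for gene, clone_ids in lib.gene_index.items():
        if gene_class.get(gene, "neutral") == "neutral":
            for cid in clone_ids:
                clone_effective[cid] = False
            continue
        # Per-clone Bernoulli penetrance, resampled until the gene keeps at
        # least one effective hairpin (a hit gene with zero working clones
        # would be undetectable by construction, not by the caller's fault).
        while True:
            eff = rng.random(len(clone_ids)) < params.penetrance
            if eff.any():
                break
        for cid, e in zip(clone_ids, eff):
            clone_effective[cid] = bool(e)
    return TruthLabels(gene_class=gene_class, clone_effective=clone_effective)


def expected_counts(
    lib: ShRNALibrary, params: SimulationParams, truth: TruthLabels,
    abundance: np.ndarray,
) -> pd.DataFrame:
    """Analytic per-clone expected counts under the generative model."""
    p = abundance / abundance.sum()
    m = np.outer(p * params.depth, np.ones(len(SAMPLES)))
    df = pd.DataFrame(m, index=pd.Index(lib.clone_ids, name="clone_id"),
                      columns=list(SAMPLES))
    for clone in lib.clones:
        if not truth.clone_effective.get(clone.clone_id, False):
            continue
        cls = truth.gene_class.get(clone.gene, "neutral")
        if cls == "synthetic_lethal":
            df.loc[clone.clone_id, list(KO_SAMPLES)] /= params.fold_depletion
        elif cls == "enriched":
            df.loc[clone.clone_id, list(KO_SAMPLES)] *= params.fold_enrichment
    return df


def simulate_counts(
    lib: ShRNALibrary, params: SimulationParams
) -> tuple[CountMatrix, TruthLabels]:
    """Draw the clone x {KO1,KO2,C1,C2} count matrix and its truth labels."""
    if params.depth <= 0:
        raise ValueError("depth must be positive")
    rng = _rng(params.seed, _STAGE_COUNTS)
    truth = _draw_truth(lib, params, rng)
    abundance = rng.lognormal(params.abundance_mu, params.abundance_sigma, len(lib))
    mean = expected_counts(lib, params, truth, abundance)

    if params.exact_depth:
        total = int(round(params.depth))
        cols = {}
        for s in SAMPLES:
            w = mean[s].to_numpy()
            cols[s] = rng.multinomial(total, w / w.sum())
        counts = np.column_stack([cols[s] for s in SAMPLES])
    else:
        m = mean.to_numpy()
        if params.dispersion > 0:
            shape = 1.0 / params.dispersion
            lam = rng.gamma(shape, m * params.dispersion)
            counts = rng.poisson(lam)
        else:
            counts = rng.poisson(m)

    cm = CountMatrix.from_counts(
        pd.DataFrame(counts.astype(np.int64),
                     index=pd.Index(lib.clone_ids, name="clone_id"),
                     columns=list(SAMPLES))
    )
    return cm, truth


def simulate_fastq(
    counts: CountMatrix,
    lib: ShRNALibrary,
    params: SimulationParams,
    outdir: str | Path,
) -> dict[str, Path]:
    """Emit one FASTQ per sample; read totals equal the count-matrix columns.

    Each read embeds its clone's barcode at ``barcode_offset`` (stuffer bases
    elsewhere); every base is substituted independently with probability
    ``error_rate``.  Records are 4-line Sanger FASTQ with constant quality
    'I' so outputs are byte-reproducible under a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(params.seed, _STAGE_FASTQ)
    L = params.barcode_length
    if lib.barcode_length != L:
        raise ValueError("library barcode length differs from params")
    read_len = params.effective_read_len
    off = params.barcode_offset

    template = np.full(read_len, ord(params.stuffer_base), dtype=np.uint8)
    bc = np.frombuffer("".join(lib.sequences).encode(), dtype=np.uint8)
    bc = bc.reshape(len(lib), L)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    base_idx = np.full(256, 0, dtype=np.uint8)
    for i, ch in enumerate(b"ACGT"):
        base_idx[ch] = i

    paths: dict[str, Path] = {}
    for sample in counts.sample_ids:
        col = counts.counts[sample].to_numpy()
        n_reads = int(col.sum())
        path = outdir / f"{sample}.fastq"
        paths[sample] = path
        with open(path, "w", newline="\n") as fh:
            if n_reads == 0:
                continue
            clone_idx = np.repeat(np.arange(len(lib)), col)
            reads = np.tile(template, (n_reads, 1))
            reads[:, off : off + L] = bc[clone_idx]
            if params.error_rate > 0:
                err = rng.random((n_reads, read_len)) < params.error_rate
                if err.any():
                    shift = rng.integers(1, 4, size=int(err.sum()))
                    orig = base_idx[reads[err]]
                    reads[err] = bases[(orig + shift) % 4]
            qual = "I" * read_len
            out = []
            for i in range(n_reads):
                out.append(
                    f"@sim:{sample}:{i}\n{reads[i].tobytes().decode()}\n+\n{qual}\n"
                )
                if len(out) >= 100_000:
                    fh.write("".join(out))
                    out = []
            fh.write("".join(out))
    return paths


def simulate_gene_sets(
    lib: ShRNALibrary,
    truth: TruthLabels,
    n_sets: int = 20,
    set_size: tuple[int, int] = (10, 40),
    n_loaded_sets: int = 2,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Random gene sets over the simulated universe for enrichment demos.

    ``n_loaded_sets`` of them are deliberately packed with the designated
    synthetic-lethal genes so over-representation has a true signal to find.
    """
    rng = _rng(seed, _STAGE_GENESETS)
    universe = lib.genes
    sl = sorted(truth.sl_genes)
    sets: dict[str, set[str]] = {}
    lo, hi = set_size
    for i in range(1, n_sets + 1):
        size = int(rng.integers(lo, hi + 1))
        members = set(rng.choice(universe, size=min(size, len(universe)),
                                 replace=False))
        if sl and i <= n_loaded_sets:
            take = max(1, math.ceil(len(sl) / max(1, n_loaded_sets)))
            start = (i - 1) * take
            members |= set(sl[start : start + take])
            name = f"SET{i:03d}_LOADED"
        else:
            name = f"SET{i:03d}"
        if members:
            sets[name] = members
    return sets
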
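"""Synthetic-lethality hit calling from a two-genotype, two-replicate screen.

The procedure, stage by stage:

1. **Ratios.** With knockout replicates (#1, #2) and control replicates
   (#3, #4), four cross-replicate copy-number ratios are formed per clone —
   1/3, 1/4, 2/3, 2/4 — on optionally depth-normalized counts with a
   pseudocount:  ``r_ij = (n_i + pc) / (n_j + pc)``.  A ratio below 1 means
   the clone is less abundant in the knockout genotype, the signature of
   synthetic lethality in a dropout screen.
2. **Five-fold rule.** A clone is flagged as five-fold depleted (enriched)
   when all four ratios are <= 1/fold (>= fold).
3. **Gene call.** A gene is a synthetic-lethal candidate when at least
   ``min_depleted`` of its clones have all four ratios < 1 and at least
   ``min_fivefold`` of them pass the five-fold depletion rule.
4. **z-scores.** Each clone's mean log2 ratio is standardized across the
   library (sample sd); candidate-gene clones typically fall below -1.5.

Nontargeting controls are standardized with everything else but never enter
the gene universe.  Clones whose four raw counts are all below the abundance
floor are excluded from z standardization (ratio instability near zero) but
retained, flagged, in every table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .library import NONTARGETING, ShRNALibrary
from .quantify import CountMatrix

__all__ = [
    "ScreenDesign",
    "compute_ratios",
    "flag_fivefold",
    "call_genes",
    "compute_zscores",
    "report",
    "RATIO_COLUMNS",
]

logger = logging.getLogger(__name__)

RATIO_COLUMNS = ["r13", "r14", "r23", "r24"]


@dataclass(frozen=True)
class ScreenDesign:
    """Sample roles: knockout replicates (#1, #2) vs control replicates (#3, #4)."""

    ko_samples: tuple[str, str]
    control_samples: tuple[str, str]

    def __post_init__(self) -> None:
        ids = list(self.ko_samples) + list(self.control_samples)
        if len(ids) != 4 or len(set(ids)) != 4:
            raise ValueError("design needs four distinct sample ids")

    @property
    def samples(self) -> list[str]:
        return list(self.ko_samples) + list(self.control_samples)

    def validate_against(self, cm: CountMatrix) -> None:
        missing = [s for s in self.samples if s not in cm.sample_ids]
        if missing:
            raise ValueError(f"design samples missing from count matrix: {missing}")


def compute_ratios(
    cm: CountMatrix,
    lib: ShRNALibrary,
    design: ScreenDesign,
    pseudocount: float = 1.0,
    normalization: Literal["raw", "cpm"] = "cpm",
    min_count: int = 10,
) -> pd.DataFrame:
    """Per-clone cross-replicate ratios and mean log2 ratio.

    Parameters
    ----------
    pseudocount
        Added to numerator and denominator (after normalization if any).
        With ``pseudocount=0``, clones with any zero count among the four
        design samples are dropped with a logged tally, since their ratios
        or log ratios are undefined.
    normalization
        ``cpm`` rescales each sample to counts per million before ratios
        (replicate depth differences otherwise masquerade as depletion);
        ``raw`` uses counts as-is.
    min_count
        Abundance floor: clones with all four raw counts below it are
        flagged ``low_abundance`` and later excluded from z standardization.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    design.validate_against(cm)
    strays = sorted(set(cm.clone_ids) - set(lib.clone_ids))
    if strays:
        raise ValueError(f"count matrix clones not in library: {strays}")

    raw = cm.counts[design.samples].astype(float)
    zero_cols = [s for s in design.samples if raw[s].sum() == 0]
    if zero_cols:
        raise ValueError(
            f"sample column(s) {zero_cols} are all zero; suspect input"
        )

    if normalization == "cpm":
        # Normalize on full library depth (controls included).
        vals = raw / cm.counts.sum(axis=0)[design.samples] * 1e6
    elif normalization == "raw":
        vals = raw
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    low_abundance = (raw < min_count).all(axis=1)

    if pseudocount == 0:
        undefined = (raw == 0).any(axis=1)
        n_dropped = int(undefined.sum())
        if n_dropped:
            logger.info(
                "pseudocount=0: dropping %d clone(s) with a zero count among "
                "the four design samples", n_dropped,
            )
        vals = vals[~undefined]
        low_abundance = low_abundance[~undefined]

    gene_of = lib.gene_of()
    ko1, ko2 = design.ko_samples
    c1, c2 = design.control_samples
    pc = float(pseudocount)
    stats = pd.DataFrame(index=vals.index)
    stats["gene"] = [gene_of[c] for c in vals.index]
    stats["r13"] = (vals[ko1] + pc) / (vals[c1] + pc)
    stats["r14"] = (vals[ko1] + pc) / (vals[c2] + pc)
    stats["r23"] = (vals[ko2] + pc) / (vals[c1] + pc)
    stats["r24"] = (vals[ko2] + pc) / (vals[c2] + pc)
    with np.errstate(divide="ignore"):
        stats["mean_log2_ratio"] = np.log2(stats[RATIO_COLUMNS]).mean(axis=1)
    stats["low_abundance"] = low_abundance
    return stats


def flag_fivefold(stats: pd.DataFrame, fold_threshold: float = 5.0) -> pd.DataFrame:
    """Set ``fivefold_all4`` (depleted/enriched/none) and ``depleted_all4``.

    Depleted means all four ratios <= 1/fold_threshold; enriched means all
    four >= fold_threshold; ``depleted_all4`` is the weaker all-four-below-1
    condition used by the gene rule.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    r = stats[RATIO_COLUMNS]
    out = stats.copy()
    depleted = (r <= 1.0 / fold_threshold).all(axis=1)
    enriched = (r >= fold_threshold).all(axis=1)
    out["fivefold_all4"] = np.select([depleted, enriched], ["depleted", "enriched"],
                                     default="none")
    out["depleted_all4"] = (r < 1.0).all(axis=1)
    return out


def call_genes(
    stats: pd.DataFrame,
    lib: ShRNALibrary | None = None,
    min_depleted: int = 2,
    min_fivefold: int = 1,
) -> pd.DataFrame:
    """Aggregate clone flags to gene-level candidate calls.

    A gene is a candidate iff it has >= ``min_depleted`` clones with all four
    ratios < 1 and >= ``min_fivefold`` clones passing the five-fold depletion
    rule.  Controls are excluded; all genes are returned regardless of
    candidacy so negatives are auditable.
    """
    if "depleted_all4" not in stats or "fivefold_all4" not in stats:
        raise ValueError("run flag_fivefold before call_genes")
    targeting = stats[stats["gene"] != NONTARGETING]
    if lib is not None:
        unknown = sorted(set(targeting["gene"]) - set(lib.genes))
        if unknown:
            raise ValueError(f"stats contain gene(s) absent from library: {unknown}")

    grouped = targeting.groupby("gene", sort=True)
    out = pd.DataFrame(
        {
            "n_clones": grouped.size(),
            "n_depleted": grouped["depleted_all4"].sum().astype(int),
            "n_fivefold_depleted": grouped["fivefold_all4"]
            .apply(lambda s: int((s == "depleted").sum())),
            "n_fivefold_enriched": grouped["fivefold_all4"]
            .apply(lambda s: int((s == "enriched").sum())),
        }
    )
    out["candidate"] = (out["n_depleted"] >= min_depleted) & (
        out["n_fivefold_depleted"] >= min_fivefold
    )
    if "z" in targeting.columns:
        out["best_z"] = grouped["z"].min()
    else:
        out["best_z"] = np.nan
    out.index.name = "gene"
    return out.reset_index()


def compute_zscores(
    stats: pd.DataFrame, include_controls: bool = True
) -> pd.DataFrame:
    """Standardize mean log2 ratios to z-scores over the whole library.

    The standardization set is every clone passing the abundance filter with
    a finite mean log2 ratio (controls included by default); z uses the
    sample standard deviation, so over that set mean(z)=0 and sd(z)=1
    exactly.  Clones outside the set still receive a z on the same scale.
    """
    x = stats["mean_log2_ratio"]
    in_set = np.isfinite(x) & ~stats["low_abundance"]
    if include_controls is False:
        in_set &= stats["gene"] != NONTARGETING
    if int(in_set.sum()) < 2:
        raise ValueError("fewer than two clones in the z standardization set")
    mu = x[in_set].mean()
    sd = x[in_set].std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("degenerate screen: zero variance in mean log2 ratios")
    out = stats.copy()
    out["z"] = (x - mu) / sd
    out["in_z_set"] = in_set
    return out


def report(
    stats: pd.DataFrame,
    gene_calls: pd.DataFrame,
    outdir: str | Path,
    threshold_z: float = -1.5,
) -> dict:
    """Write ranked clone and gene tables plus a JSON summary.

    Gene tables are ordered by ascending best z, ties broken alphabetically,
    so outputs are byte-stable across runs.  Five-fold *enriched* genes go to
    a separate table rather than being mixed with depletion candidates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stats_out = stats.copy()
    stats_out = stats_out.sort_values(
        ["z", "gene"], kind="mergesort", na_position="last"
    ) if "z" in stats_out.columns else stats_out
    stats_out.to_csv(outdir / "shrna_stats.tsv", sep="\t",
                     float_format="%.6g", lineterminator="\n")

    calls = gene_calls.sort_values(
        ["best_z", "gene"], kind="mergesort", na_position="last"
    )
    calls.to_csv(outdir / "gene_calls.tsv", sep="\t", index=False,
                 float_format="%.6g", lineterminator="\n")

    enriched = calls[calls["n_fivefold_enriched"] >= 1]
    enriched.to_csv(outdir / "gene_enriched.tsv", sep="\t", index=False,
                    float_format="%.6g", lineterminator="\n")

    summary = {
        "n_clones": int(len(stats)),
        "n_genes": int(len(gene_calls)),
        "n_candidates": int(gene_calls["candidate"].sum()),
        "n_fivefold_depleted_clones": int(
            (stats["fivefold_all4"] == "depleted").sum()
        ),
        "n_fivefold_enriched_genes": int(len(enriched)),
        "n_low_abundance_clones": int(stats["low_abundance"].sum()),
        "threshold_z": threshold_z,
        "n_clones_below_threshold_z": (
            int((stats["z"] < threshold_z).sum()) if "z" in stats.columns else None
        ),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
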
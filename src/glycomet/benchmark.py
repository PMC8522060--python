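"""Threshold-grid evaluation of the identification scheme.

Truth-labelled benchmark reads are classified as glycan-related at each cell
of an identity x alignment-length grid (strict ``>`` at both thresholds) and
scored with precision, recall and false discovery rate per genome:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    FDR       = FP / (TP + FP)

Metrics with a zero denominator are undefined (NaN), never coerced to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .search import AlignmentHit


@dataclass(frozen=True)
class ThresholdGrid:
    """Identity fractions and alignment-length (aa) thresholds to scan."""

    identities: tuple = (0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90)
    lengths: tuple = (5, 10, 15, 20, 25)

    def __post_init__(self) -> None:
        for vals in (self.identities, self.lengths):
            if not vals or any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError("grid values must be non-empty and "
                                 "strictly increasing")

    @property
    def cells(self) -> list[tuple[float, int]]:
        return [(i, l) for i in self.identities for l in self.lengths]


@dataclass
class ConfusionCounts:
    genome_id: str
    id_thr: float
    len_thr: int
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def classify_read(hit: AlignmentHit | None, id_thr: float,
                  len_thr: int) -> bool:
    """Predict glycan-related iff a hit exists with identity > id_thr and
    alignment length > len_thr (both strictly)."""
    if not (0 <= id_thr <= 1):
        raise ValueError("identity threshold must lie in [0, 1]")
    if len_thr < 1:
        raise ValueError("length threshold must be >= 1")
    if hit is None:
        return False
    return hit.identity > id_thr and hit.alignment_length > len_thr


def confusion(predictions: dict[str, bool], truth: dict[str, bool],
              genome_id: str = "", id_thr: float = 0.0,
              len_thr: int = 1) -> ConfusionCounts:
    """Tally the 2x2 confusion counts over reads.

    Every predicted read must carry a truth label (missing label -> fatal);
    truth reads without a prediction are counted as predicted-negative.
    """
    counts = ConfusionCounts(genome_id, id_thr, len_thr)
    for rid in predictions:
        if rid not in truth:
            raise KeyError(f"read {rid} has no truth label")
    for rid, is_true in truth.items():
        pred = predictions.get(rid, False)
        if pred and is_true:
            counts.tp += 1
        elif pred and not is_true:
            counts.fp += 1
        elif not pred and is_true:
            counts.fn += 1
        else:
            counts.tn += 1
    return counts


def accuracy_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(precision, recall, FDR); NaN where the denominator is zero."""
    pp = c.tp + c.fp
    pos = c.tp + c.fn
    precision = c.tp / pp if pp else math.nan
    recall = c.tp / pos if pos else math.nan
    fdr = c.fp / pp if pp else math.nan
    return precision, recall, fdr


def evaluate_grid(best_hits: dict[str, AlignmentHit | None],
                  truth: dict[str, bool], grid: ThresholdGrid,
                  genome_of: dict[str, str] | None = None) -> pd.DataFrame:
    """Accuracy surface: one row per genome per grid cell (long format).

    ``best_hits`` maps read id to its best hit (reads with no hit may be
    absent). ``genome_of`` maps read id to genome; a single unnamed genome is
    assumed when omitted. Alignments are computed once upstream; the grid
    only re-thresholds them.
    """
    if not truth:
        raise ValueError("empty benchmark: no truth labels")
    genome_of = genome_of or {rid: "genome" for rid in truth}
    genomes = sorted(set(genome_of.values()))
    rows = []
    for id_thr, len_thr in grid.cells:
        preds = {rid: classify_read(best_hits.get(rid), id_thr, len_thr)
                 for rid in truth}
        for g in genomes:
            g_reads = [rid for rid in truth if genome_of[rid] == g]
            c = confusion({rid: preds[rid] for rid in g_reads},
                          {rid: truth[rid] for rid in g_reads},
                          genome_id=g, id_thr=id_thr, len_thr=len_thr)
            precision, recall, fdr = accuracy_metrics(c)
            rows.append((g, id_thr, len_thr, c.tp, c.fp, c.fn, c.tn,
                         precision, recall, fdr))
    return pd.DataFrame(rows, columns=[
        "genome_id", "id_thr", "len_thr", "TP", "FP", "FN", "TN",
        "precision", "recall", "FDR"])


def select_operating_point(surface: pd.DataFrame,
                           criterion: str = "precision"
                           ) -> tuple[float, int]:
    """Pick the grid cell maximising the mean metric across genomes.

    Ties are broken by lower mean FDR, then by larger identity threshold,
    then by larger length threshold. Cells where the metric is undefined for
    every genome are ignored; if that leaves nothing, this is fatal.
    """
    if surface.empty:
        raise ValueError("empty accuracy surface")
    agg = (surface.groupby(["id_thr", "len_thr"])
           .agg(metric=(criterion, "mean"), mean_fdr=("FDR", "mean"))
           .reset_index())
    agg = agg[agg["metric"].notna()]
    if agg.empty:
        raise ValueError("metric undefined over the whole grid")
    agg = agg.sort_values(
        by=["metric", "mean_fdr", "id_thr", "len_thr"],
        ascending=[False, True, False, False], kind="mergesort")
    top = agg.iloc[0]
    return float(top["id_thr"]), int(top["len_thr"])
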
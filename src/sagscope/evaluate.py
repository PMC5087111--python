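"""Retrieval validation against simulation ground truth.

Given pair assignments and the truth table from the simulator, computes
per-genome precision/recall/F1 and a confusion table (true origin × assigned
genome, plus the discarded classes), and sweeps assignment parameter grids
to find the best-performing configuration — the in-silico optimisation the
pipeline's mapping settings are justified by.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import (
    STATUS_UNIQUE,
    AssignParams,
    PairAssignment,
    assign_pairs,
    build_index,
)
from .reference import ReferenceSet


@dataclass
class RetrievalMetrics:
    """Per-genome and micro-averaged retrieval quality."""

    per_genome: pd.DataFrame  # index genome; columns tp, fp, fn, precision, recall, f1
    confusion: pd.DataFrame  # rows true genome, columns assigned genome/class
    micro_precision: float
    micro_recall: float
    micro_f1: float

    @property
    def n_pairs(self) -> int:
        return int(self.confusion.to_numpy().sum())


def _safe_div(num: float, den: float, empty: float = 1.0) -> float:
    """num/den with the 0/0 convention: no opportunities -> perfect score."""
    return num / den if den else empty


def evaluate_retrieval(
    assignments: Sequence[PairAssignment],
    truth: Mapping[str, str] | pd.DataFrame,
    target_genomes: Iterable[str] | None = None,
) -> RetrievalMetrics:
    """Score assignments against the recorded fragment origins.

    ``truth`` maps fragment_id -> true genome_id (a truth-table DataFrame is
    accepted).  TP: uniquely assigned to the true genome.  FP: uniquely
    assigned to a wrong genome.  FN: a fragment truly from the genome that
    was not uniquely assigned to it.  Precision/recall use the 0/0 := 1
    convention.  Raises on a fragment_id missing from the truth.
    """
    if isinstance(truth, pd.DataFrame):
        truth = dict(zip(truth["fragment_id"], truth["genome_id"]))
    genomes = sorted(set(truth.values()))
    if target_genomes is None:
        target_genomes = genomes
    target_genomes = list(target_genomes)

    rows = []
    for a in assignments:
        if a.fragment_id not in truth:
            raise ValueError(f"fragment {a.fragment_id!r} not in truth table")
        assigned = a.genome_id if a.status == STATUS_UNIQUE else f"__{a.status}"
        rows.append((truth[a.fragment_id], assigned))
    df = pd.DataFrame(rows, columns=["true_genome", "assigned"])
    confusion = pd.crosstab(df["true_genome"], df["assigned"], dropna=False)

    per = {}
    tp_sum = fp_sum = fn_sum = 0
    for g in target_genomes:
        tp = int(((df.true_genome == g) & (df.assigned == g)).sum())
        fp = int(((df.true_genome != g) & (df.assigned == g)).sum())
        fn = int(((df.true_genome == g) & (df.assigned != g)).sum())
        precision = _safe_div(tp, tp + fp)
        recall = _safe_div(tp, tp + fn)
        f1 = _safe_div(2 * precision * recall, precision + recall, empty=1.0)
        per[g] = dict(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, f1=f1)
        tp_sum, fp_sum, fn_sum = tp_sum + tp, fp_sum + fp, fn_sum + fn
    micro_p = _safe_div(tp_sum, tp_sum + fp_sum)
    micro_r = _safe_div(tp_sum, tp_sum + fn_sum)
    micro_f1 = _safe_div(2 * micro_p * micro_r, micro_p + micro_r, empty=1.0)
    return RetrievalMetrics(
        per_genome=pd.DataFrame.from_dict(per, orient="index"),
        confusion=confusion,
        micro_precision=micro_p,
        micro_recall=micro_r,
        micro_f1=micro_f1,
    )


def grid_search(
    pairs: Sequence[tuple[str, str, str]],
    truth: Mapping[str, str] | pd.DataFrame,
    refset: ReferenceSet,
    param_grid: Mapping[str, Sequence],
    target_genomes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Exhaustively evaluate assignment-parameter combinations.

    ``param_grid`` maps :class:`AssignParams` field names to value lists.
    Returns one row per combination (deterministic order: the Cartesian
    product over alphabetically sorted parameter names) with micro-averaged
    metrics; pick the winner with :func:`best_by_f1`.
    """
    if not param_grid:
        raise ValueError("param_grid must be non-empty")
    names = sorted(param_grid)
    rows = []
    index_cache: dict[int, object] = {}
    for combo in itertools.product(*(param_grid[n] for n in names)):
        params = AssignParams(**dict(zip(names, combo)))
        if params.seed_k not in index_cache:
            index_cache[params.seed_k] = build_index(refset, params.seed_k)
        assignments = assign_pairs(pairs, index_cache[params.seed_k], params)
        m = evaluate_retrieval(assignments, truth, target_genomes)
        n_unique = sum(1 for a in assignments if a.status == STATUS_UNIQUE)
        rows.append(
            dict(zip(names, combo))
            | dict(
                n_unique=n_unique,
                precision=m.micro_precision,
                recall=m.micro_recall,
                f1=m.micro_f1,
            )
        )
    return pd.DataFrame(rows)


def best_by_f1(grid_table: pd.DataFrame) -> pd.Series:
    """Best grid row by F1 (first row on ties — deterministic)."""
    return grid_table.loc[grid_table["f1"].idxmax()]


def assigned_share(totals: Mapping[str, int | float]) -> dict[str, float]:
    """Percent share of assigned fragments per genome.

    E.g. the share of all symbiont-assigned reads captured by the single
    best-represented reference genome.
    """
    total = float(sum(totals.values()))
    if total <= 0:
        raise ValueError("no assigned fragments")
    return {g: 100.0 * v / total for g, v in totals.items()}


def write_metrics_tsv(metrics: RetrievalMetrics, path) -> None:
    metrics.per_genome.to_csv(path, sep="\t", index_label="genome_id")
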
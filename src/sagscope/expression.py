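"""FPKM expression profiling relative to a housekeeping baseline.

FPKM_g = count_g / ((length_g / 10^3) * (N / 10^6)) with N the fragments
assigned to the target genome's CDS in that replicate, so the conservation
identity sum_g FPKM_g * len_kb_g = 10^6 holds whenever N > 0.  Genes are
expressed as fold over the mean FPKM of a housekeeping set (FPKM_HK); a
gene is *highly expressed* iff its replicate-mean FPKM strictly exceeds
that baseline.  Percentiles use the strictly-smaller-fraction definition
(ties share a percentile).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counting import CountTable
from .reference import CdsFeature


def compute_fpkm(
    counts: Mapping[str, int] | CountTable, lengths: Mapping[str, int]
) -> dict[str, float]:
    """Fragments per kilobase of CDS per million assigned fragments.

    ``counts`` is the per-CDS table for one replicate (class tallies, if a
    :class:`CountTable` is given, are not part of N).  All-zero when N = 0.
    Raises if a counted CDS has no length.
    """
    if isinstance(counts, CountTable):
        counts = counts.counts
    missing = [c for c in counts if c not in lengths]
    if missing:
        raise ValueError(f"no length for counted CDS: {missing[:3]}...")
    bad = [c for c in counts if lengths[c] <= 0]
    if bad:
        raise ValueError(f"non-positive CDS length: {bad[:3]}...")
    n_total = sum(counts.values())
    if n_total == 0:
        return {c: 0.0 for c in counts}
    return {
        c: counts[c] / ((lengths[c] / 1e3) * (n_total / 1e6)) for c in counts
    }


def fpkm_table(
    counts_by_replicate: Mapping[str, Mapping[str, int] | CountTable],
    lengths: Mapping[str, int],
) -> pd.DataFrame:
    """CDS × replicate FPKM matrix (replicates normalised independently)."""
    cols = {
        rep: compute_fpkm(counts, lengths)
        for rep, counts in counts_by_replicate.items()
    }
    return pd.DataFrame(cols)


def hk_baseline(
    mean_fpkm: Mapping[str, float] | pd.Series, housekeeping_ids: Iterable[str]
) -> float:
    """Arithmetic mean of replicate-averaged FPKM over the housekeeping set."""
    hk = list(housekeeping_ids)
    if not hk:
        raise ValueError("housekeeping set is empty")
    series = pd.Series(mean_fpkm)
    missing = [h for h in hk if h not in series.index]
    if missing:
        raise ValueError(f"housekeeping ids without FPKM: {missing[:3]}...")
    return float(series.loc[hk].mean())


def classify_high_expression(
    mean_fpkm: Mapping[str, float] | pd.Series, baseline: float
) -> set[str]:
    """CDS whose mean FPKM strictly exceeds the housekeeping baseline."""
    series = pd.Series(mean_fpkm)
    return set(series.index[series > baseline])


def fpkm_percentiles(values: Mapping[str, float] | pd.Series) -> pd.Series:
    """Percentile rank: fraction of CDS with strictly smaller value × 100."""
    series = pd.Series(values, dtype=float)
    if series.empty:
        raise ValueError("at least one CDS required")
    sorted_vals = np.sort(series.to_numpy())
    smaller = np.searchsorted(sorted_vals, series.to_numpy(), side="left")
    return pd.Series(100.0 * smaller / len(series), index=series.index)


def annotation_contrast(
    high_ids: Iterable[str], cds_features: Sequence[CdsFeature]
) -> tuple[float | None, float | None]:
    """Proportion annotated within the high-expression set vs the remainder.

    Returns ``(p_high, p_rest)``; a proportion is ``None`` when its
    denominator is empty (flagged rather than raised).
    """
    high = set(high_ids)
    flags_high = [f.annotated for f in cds_features if f.cds_id in high]
    flags_rest = [f.annotated for f in cds_features if f.cds_id not in high]
    p_high = sum(flags_high) / len(flags_high) if flags_high else None
    p_rest = sum(flags_rest) / len(flags_rest) if flags_rest else None
    return p_high, p_rest


def replicate_correlation(
    fpkm: pd.DataFrame,
) -> tuple[dict[tuple[str, str], float], float]:
    """Pairwise Pearson r between replicate FPKM vectors, plus the mean r.

    A zero-variance replicate makes its pairs NaN (flagged, not raised); the
    mean is taken over the defined pairs.
    """
    if fpkm.shape[1] < 2:
        raise ValueError("at least two replicates required")
    pairs: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(fpkm.columns, 2):
        x, y = fpkm[a].to_numpy(), fpkm[b].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            pairs[(a, b)] = float("nan")
        else:
            pairs[(a, b)] = float(stats.pearsonr(x, y).statistic)
    defined = [v for v in pairs.values() if not np.isnan(v)]
    mean_r = float(np.mean(defined)) if defined else float("nan")
    return pairs, mean_r


@dataclass
class ExpressionProfile:
    """Full per-CDS expression profile for one target genome.

    ``table`` is indexed by cds_id with columns ``fpkm_<rep>`` per replicate,
    ``mean_fpkm``, ``fold_hk``, ``percentile`` and ``highly_expressed``.
    """

    table: pd.DataFrame
    hk_baseline: float
    replicate_names: list[str]

    @classmethod
    def from_counts(
        cls,
        counts_by_replicate: Mapping[str, Mapping[str, int] | CountTable],
        lengths: Mapping[str, int],
        housekeeping_ids: Iterable[str],
    ) -> "ExpressionProfile":
        fpkm = fpkm_table(counts_by_replicate, lengths)
        mean_fpkm = fpkm.mean(axis=1)
        baseline = hk_baseline(mean_fpkm, housekeeping_ids)
        high = classify_high_expression(mean_fpkm, baseline)
        table = fpkm.rename(columns=lambda r: f"fpkm_{r}")
        table["mean_fpkm"] = mean_fpkm
        table["fold_hk"] = mean_fpkm / baseline if baseline > 0 else np.nan
        table["percentile"] = fpkm_percentiles(mean_fpkm)
        table["highly_expressed"] = table.index.isin(high)
        return cls(
            table=table,
            hk_baseline=baseline,
            replicate_names=list(counts_by_replicate),
        )

    @property
    def highly_expressed_ids(self) -> set[str]:
        return set(self.table.index[self.table["highly_expressed"]])

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="cds_id")
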
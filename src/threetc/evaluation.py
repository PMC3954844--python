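"""The 3TC evaluation sweep: sensitivity, %DEG across length restrictions,
DEG transcript-length contrasts and DEG-set overlaps.

Sensitivity here is detection capacity, not statistical power: the fraction
of genes still called expressed under restriction N relative to the
unrestricted (N = inf) annotation, both after isoform filtering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .annotation import (
    Annotation,
    filter_major_isoform,
    filter_threeprime_isoform,
    restrict_threeprime,
)
from .counting import CountMatrix, GeneIndex, build_matrix, count_sample
from .diffexpr import DEResultTable, run_de

__all__ = ["sensitivity", "sweep_lengths", "deg_length_summary", "deg_overlap",
           "LengthSummary"]

DEFAULT_LENGTHS: tuple[float, ...] = (math.inf, 1500, 1000, 500, 200)


def sensitivity(expressed_at_n: int, expressed_at_inf: int) -> float:
    """expressed(N) / expressed(inf); reported rounded to 2 decimals."""
    if expressed_at_inf <= 0:
        raise ValueError("baseline expressed-gene count must be positive")
    if expressed_at_n > expressed_at_inf:
        warnings.warn(
            "more genes expressed under restriction than without; "
            "check that the same isoform-filtered baseline is used"
        )
    return expressed_at_n / expressed_at_inf


def sweep_lengths(
    alignments: Mapping[str, object],
    ann: Annotation,
    sample_sheet: pd.DataFrame,
    abundance: Mapping[str, float] | None = None,
    lengths: Sequence[float] = DEFAULT_LENGTHS,
    isoform_mode: str = "expression",
    groups: tuple[str, str] | None = None,
    alpha_level: float = 0.05,
    expressed_threshold: float = 5.0,
    keep_results: bool = False,
):
    """Run the full 3TC grid: isoform filter → restrict(N) → count → DE.

    Parameters
    ----------
    alignments
        sample -> SAM/BAM path or FragmentSet, one per sample-sheet row.
    ann
        Unfiltered annotation.
    lengths
        Restriction grid; ``inf`` (no restriction) is the sensitivity
        baseline and is added automatically if missing.
    isoform_mode
        'expression' (major isoform by abundance; requires ``abundance``)
        or 'threeprime' (annotation-only).

    Returns a Table-2-style DataFrame with columns length_restriction,
    expressed, degs, pct_degs (1 dp), sensitivity (2 dp) — and, when
    ``keep_results`` is set, also the per-N :class:`DEResultTable` dict.
    """
    if isoform_mode == "expression":
        if abundance is None:
            raise ValueError("expression isoform mode needs an abundance table")
        filtered = filter_major_isoform(ann, abundance)
    elif isoform_mode == "threeprime":
        filtered = filter_threeprime_isoform(ann)
    else:
        raise ValueError(f"unknown isoform mode {isoform_mode!r}")

    lengths = list(lengths)
    if not any(math.isinf(n) for n in lengths):
        lengths = [math.inf] + lengths

    results: dict[float, DEResultTable] = {}
    rows = []
    expressed_inf: int | None = None
    for n in lengths:
        restricted = restrict_threeprime(filtered, n)
        index = GeneIndex(restricted)
        cols = [
            count_sample(alignments[s], restricted, sample=s, index=index)
            for s in sample_sheet["sample"]
        ]
        matrix = build_matrix(cols, sample_sheet)
        de = run_de(matrix, groups=groups, alpha_level=alpha_level,
                    expressed_threshold=expressed_threshold)
        results[n] = de
        if math.isinf(n):
            expressed_inf = de.n_expressed
        rows.append((n, de.n_expressed, len(de.degs)))

    if expressed_inf is None or expressed_inf == 0:
        raise ValueError("no expressed genes at N=inf; cannot form sensitivity")
    prev_expressed = None
    table_rows = []
    for n, expressed, degs in rows:
        if prev_expressed is not None and expressed > prev_expressed:
            warnings.warn(f"expressed-gene count increased at N={n}")
        prev_expressed = expressed
        table_rows.append(
            dict(
                length_restriction="inf" if math.isinf(n) else int(n),
                expressed=expressed,
                degs=degs,
                pct_degs=round(100.0 * degs / expressed, 1) if expressed else 0.0,
                sensitivity=round(sensitivity(expressed, expressed_inf), 2),
            )
        )
    report = pd.DataFrame(table_rows)
    if keep_results:
        return report, results
    return report


@dataclass
class LengthSummary:
    """Mean selected-isoform length of DEGs in one fold-change direction."""

    direction: str
    n_genes: int
    mean_length: float
    t_statistic: float
    p_value: float
    degenerate: bool = False


def deg_length_summary(
    de: DEResultTable | pd.DataFrame, ann: Annotation
) -> tuple[LengthSummary, LengthSummary]:
    """Split DEGs by fold-change sign and contrast their transcript lengths.

    ``ann`` must be the isoform-filtered annotation (lengths are those of
    the selected isoform).  Returns (higher-in-A, higher-in-B) summaries
    with a Welch two-sample t-test; with fewer than two genes in a
    direction the t statistic and p-value are undefined and the summary is
    flagged degenerate.
    """
    table = de.table if isinstance(de, DEResultTable) else de
    degs = table[table["is_deg"]]
    lengths = {g.gene_id: g.transcripts[0].transcript_length for g in ann}
    down = [lengths[g] for g in degs.index[degs["log2FoldChange"] < 0]]
    up = [lengths[g] for g in degs.index[degs["log2FoldChange"] > 0]]
    if len(down) >= 2 and len(up) >= 2:
        if np.var(down) == 0 and np.var(up) == 0 and np.mean(down) == np.mean(up):
            t, p = 0.0, 1.0  # identical constant lists: no evidence either way
        else:
            t, p = ttest_ind(down, up, equal_var=False)
            t, p = float(t), float(p)
        degenerate = False
    else:
        t, p, degenerate = float("nan"), float("nan"), True
    mk = lambda name, vals: LengthSummary(
        name, len(vals), float(np.mean(vals)) if vals else float("nan"),
        t, p, degenerate,
    )
    return mk("higher-in-A", down), mk("higher-in-B", up)


def deg_overlap(deg_sets: Sequence[set]) -> dict[tuple[int, ...], int]:
    """Pairwise and full intersections of DEG sets, keyed by set indices."""
    if len(deg_sets) < 2:
        raise ValueError("need at least two DEG sets")
    sets = [set(s) for s in deg_sets]
    out: dict[tuple[int, ...], int] = {}
    for i, j in combinations(range(len(sets)), 2):
        out[(i, j)] = len(sets[i] & sets[j])
    full = set.intersection(*sets)
    out[tuple(range(len(sets)))] = len(full)
    return out
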
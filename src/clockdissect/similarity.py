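"""Redundancy between clocks and genomic-feature enrichment of clock CpGs.

Clocks can agree either because they share CpGs outright or because
distinct CpGs are correlated ("proxies").  This module quantifies both,
and tests whether a clock's CpGs are enriched in CpG-island-centric
features, histone-mark peaks, and chromatin states relative to the
non-clock background of the array.

Coordinate conventions: CpG positions are 1-based points; all interval
tracks are BED-style 0-based half-open.  The conversion happens here, at
the boundary, and nowhere else.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .clocks import ClockModel


@dataclass
class OverlapMatrix:
    counts: pd.DataFrame     # symmetric shared-CpG counts; diagonal = clock sizes
    percent: pd.DataFrame    # % of the smaller set shared; diagonal 100


def cpg_overlap_matrix(clocks: Sequence[ClockModel]) -> OverlapMatrix:
    """Pairwise shared-CpG counts between clocks; percentages are taken
    against the smaller clock of each pair."""
    if len(clocks) < 2:
        raise ValueError("need at least 2 clocks")
    names = [c.name for c in clocks]
    sets = [set(c.coefficients) for c in clocks]
    n = len(clocks)
    counts = np.zeros((n, n), dtype=int)
    percent = np.zeros((n, n))
    for i in range(n):
        counts[i, i] = len(sets[i])
        percent[i, i] = 100.0
        for j in range(i + 1, n):
            shared = len(sets[i] & sets[j])
            counts[i, j] = counts[j, i] = shared
            smaller = min(len(sets[i]), len(sets[j]))
            pct = 100.0 * shared / smaller if smaller else np.nan
            percent[i, j] = percent[j, i] = pct
    return OverlapMatrix(
        counts=pd.DataFrame(counts, index=names, columns=names),
        percent=pd.DataFrame(percent, index=names, columns=names))


def proxy_fraction(clock: ClockModel, beta: pd.DataFrame,
                   reference_cpgs: Optional[Iterable[str]] = None,
                   thresholds: Sequence[float] = (0.5, 0.7, 0.9)) -> pd.Series:
    """Percentage of the clock's CpGs with at least one proxy at each
    absolute-correlation threshold.

    Between-clock mode (``reference_cpgs`` given): a clock CpG that is
    itself a member of the reference set counts as a proxy with r = 1.
    Within-clock mode (``reference_cpgs`` None): proxies are sought among
    the clock's other CpGs; the self-correlation is excluded.

    Percentages are over the clock CpGs available in the beta matrix;
    missing CpGs are dropped with a warning.
    """
    if beta.shape[0] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    clock_cpgs = [c for c in clock.coefficients if c in beta.columns]
    dropped = len(clock.coefficients) - len(clock_cpgs)
    if dropped:
        import warnings
        warnings.warn(f"clock {clock.name!r}: {dropped} CpGs absent from beta matrix, dropped",
                      stacklevel=2)
    if not clock_cpgs:
        raise ValueError("no clock CpGs present in the beta matrix")

    within = reference_cpgs is None
    if within:
        ref = clock_cpgs
    else:
        ref = [c for c in dict.fromkeys(reference_cpgs) if c in beta.columns]
        if not ref:
            raise ValueError("no reference CpGs present in the beta matrix")

    x = beta[clock_cpgs].values.astype(float)
    y = beta[ref].values.astype(float)
    xz = (x - x.mean(0)) / np.where(x.std(0) == 0, np.nan, x.std(0))
    yz = (y - y.mean(0)) / np.where(y.std(0) == 0, np.nan, y.std(0))
    corr = np.abs(xz.T @ yz) / x.shape[0]        # clock x reference

    ref_pos = {c: k for k, c in enumerate(ref)}
    shared = np.zeros(len(clock_cpgs), dtype=bool)
    for i, c in enumerate(clock_cpgs):
        if c in ref_pos:
            if within:
                corr[i, ref_pos[c]] = np.nan      # exclude self-correlation
            else:
                shared[i] = True                  # shared CpG counts as r = 1
    best = np.nanmax(np.where(np.isnan(corr), -np.inf, corr), axis=1)
    best[shared] = 1.0

    out = {}
    for t in sorted(thresholds):
        out[t] = 100.0 * float(np.mean(best >= t))
    return pd.Series(out, name=f"{clock.name}:{'within' if within else 'between'}")


def _build_trees(intervals: pd.DataFrame, pad: int = 0) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    bad = intervals[intervals["start"] >= intervals["end"]]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(f"malformed interval {row['chrom']}:{row['start']}-{row['end']}")
    for chrom, grp in intervals.groupby("chrom"):
        t = IntervalTree()
        for s, e in zip(grp["start"], grp["end"]):
            t[max(0, int(s) - pad):int(e) + pad] = True
        trees[chrom] = t
    return trees


def annotate_cpgs(cpg_coords: pd.DataFrame, cgi_intervals: pd.DataFrame,
                  peak_tracks: Optional[Mapping[str, pd.DataFrame]] = None,
                  state_track: Optional[pd.DataFrame] = None,
                  shore_width: int = 2000) -> pd.DataFrame:
    """Annotate CpG point positions with CGI class, peak membership, and
    chromatin state.

    CGI classes are mutually exclusive and exhaustive: inside a CGI
    interval -> ``CGI``; within ``shore_width`` bp of a CGI edge but
    outside -> ``shore``; otherwise ``non_CGI``.  Peak tracks are BED3+
    (boolean membership per track).  The optional state track is BED4
    with mutually exclusive labelled segments.
    """
    cgi_trees = _build_trees(cgi_intervals)
    shore_trees = _build_trees(cgi_intervals, pad=shore_width)
    peak_trees = {name: _build_trees(df) for name, df in (peak_tracks or {}).items()}
    state_trees: dict[str, IntervalTree] = {}
    if state_track is not None:
        if state_track["start"].ge(state_track["end"]).any():
            raise ValueError("malformed state intervals (start >= end)")
        for chrom, grp in state_track.groupby("chrom"):
            t = IntervalTree()
            for s, e, name in zip(grp["start"], grp["end"], grp["name"]):
                t[int(s):int(e)] = name
            state_trees[chrom] = t

    rows = {}
    for cpg, rec in cpg_coords.iterrows():
        chrom, p0 = rec["chrom"], int(rec["pos"]) - 1  # to 0-based point
        in_cgi = chrom in cgi_trees and bool(cgi_trees[chrom][p0])
        if in_cgi:
            cls = "CGI"
        elif chrom in shore_trees and bool(shore_trees[chrom][p0]):
            cls = "shore"
        else:
            cls = "non_CGI"
        row = {"cgi_class": cls}
        for name, trees in peak_trees.items():
            row[name] = chrom in trees and bool(trees[chrom][p0])
        if state_track is not None:
            hits = state_trees.get(chrom, IntervalTree())[p0]
            row["chrom_state"] = next(iter(hits)).data if hits else None
        rows[cpg] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "cpg"
    return out


def annotation_to_binary(annotation: pd.DataFrame) -> pd.DataFrame:
    """Expand an annotation table into one boolean column per feature:
    CGI classes and chromatin states one-vs-rest, peak tracks as-is."""
    out = {}
    if "cgi_class" in annotation:
        for cls in ("CGI", "shore", "non_CGI"):
            out[cls] = annotation["cgi_class"] == cls
    for col in annotation.columns:
        if col in ("cgi_class", "chrom_state"):
            continue
        out[col] = annotation[col].astype(bool)
    if "chrom_state" in annotation:
        for state in sorted(annotation["chrom_state"].dropna().unique()):
            out[f"state:{state}"] = annotation["chrom_state"] == state
    return pd.DataFrame(out, index=annotation.index)


def feature_enrichment(clock_cpg_ids: Iterable[str], background_cpg_ids: Iterable[str],
                       annotation: pd.DataFrame, m_bonferroni: int = 9) -> pd.DataFrame:
    """Per-feature enrichment of clock CpGs versus the non-clock background.

    Builds a 2x2 table per boolean feature column, computes the odds
    ratio (Haldane-Anscombe 0.5 correction when any cell is zero,
    flagged), a two-sided Fisher exact p, and a Bonferroni-adjusted p
    with family size ``m_bonferroni``.  Features annotating no CpG at all
    are flagged degenerate and excluded from the Bonferroni family.
    """
    clock = [c for c in dict.fromkeys(clock_cpg_ids)]
    bg = [c for c in dict.fromkeys(background_cpg_ids) if c not in set(clock)]
    if not clock or not bg:
        raise ValueError("clock and background CpG sets must be non-empty")
    binary = annotation if annotation.dtypes.map(
        lambda d: d == bool).all() else annotation_to_binary(annotation)
    rows = []
    for feat in binary.columns:
        fa = binary[feat]
        a = int(fa.reindex(clock).fillna(False).sum())
        b = len(clock) - a
        c = int(fa.reindex(bg).fillna(False).sum())
        d = len(bg) - c
        if a + c == 0 or b + d == 0:
            rows.append((feat, a, b, c, d, np.nan, np.nan, np.nan, "degenerate"))
            continue
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
            flag = "haldane"
        else:
            orr = (a * d) / (b * c)
            flag = ""
        rows.append((feat, a, b, c, d, orr, p, min(1.0, m_bonferroni * p), flag))
    return pd.DataFrame(
        rows, columns=["feature", "a", "b", "c", "d", "odds_ratio", "p", "p_bonf", "flag"]
    ).set_index("feature")
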
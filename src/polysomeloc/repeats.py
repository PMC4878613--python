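"""Transposable-element composition of transcripts and enrichment tests.

Coverage is computed against exonic (mature) coordinates and normalized by
mature transcript length; repeat strand is recorded but both orientations
count. Per-class summaries use one representative transcript per gene (the
one with the most exons). Enrichment of TE presence uses the upper-tail
hypergeometric test; differences in coverage/insertion frequency use the
Wilcoxon rank-sum test.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .models import RepeatFeature, TranscriptModel


def build_repeat_index(repeats: list[RepeatFeature]) -> dict[str, IntervalTree]:
    """Per-chromosome interval tree of repeats (payload: the feature)."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for rep in repeats:
        trees[rep.chrom].addi(rep.start, rep.end, rep)
    return dict(trees)


def te_coverage(
    tx: TranscriptModel, repeat_index: dict[str, IntervalTree]
) -> pd.DataFrame:
    """Fractional exonic coverage and insertion count per repeat class.

    Coverage = overlapped exonic nt / mature transcript length, with the
    per-class overlap unioned across a class's (possibly overlapping)
    repeat instances. A repeat spanning several exons counts as one
    insertion.

    Returns a DataFrame: transcript_id, repeat_class, coverage,
    insertions, insertions_per_nt.
    """
    tree = repeat_index.get(tx.chrom, IntervalTree())
    length = tx.length
    # Per class: set of distinct repeat instances and per-exon overlap spans.
    instances: dict[str, set[RepeatFeature]] = defaultdict(set)
    spans: dict[str, list[tuple[int, int, int]]] = defaultdict(list)  # exon_i, start, end
    for exon_i, (es, ee) in enumerate(tx.exons):
        for hit in tree.overlap(es, ee):
            rep: RepeatFeature = hit.data
            instances[rep.repeat_class].add(rep)
            spans[rep.repeat_class].append((exon_i, max(es, rep.start), min(ee, rep.end)))
    rows = []
    for repeat_class, cls_spans in spans.items():
        overlap_nt = 0
        by_exon: dict[int, list[tuple[int, int]]] = defaultdict(list)
        for exon_i, s, e in cls_spans:
            by_exon[exon_i].append((s, e))
        for exon_spans in by_exon.values():
            exon_spans.sort()
            cur_s, cur_e = exon_spans[0]
            for s, e in exon_spans[1:]:
                if s > cur_e:
                    overlap_nt += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            overlap_nt += cur_e - cur_s
        rows.append(
            {
                "transcript_id": tx.transcript_id,
                "repeat_class": repeat_class,
                "coverage": overlap_nt / length,
                "insertions": len(instances[repeat_class]),
                "insertions_per_nt": len(instances[repeat_class]) / length,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "repeat_class", "coverage", "insertions", "insertions_per_nt"],
    )


def te_profiles(
    transcripts: list[TranscriptModel], repeats: list[RepeatFeature]
) -> pd.DataFrame:
    """TE coverage table for many transcripts (zero rows are implicit)."""
    index = build_repeat_index(repeats)
    frames = [te_coverage(tx, index) for tx in transcripts]
    frames = [f for f in frames if not f.empty]
    if not frames:
        return pd.DataFrame(
            columns=["transcript_id", "repeat_class", "coverage", "insertions", "insertions_per_nt"]
        )
    return pd.concat(frames, ignore_index=True)


def representative_transcripts(transcripts: list[TranscriptModel]) -> list[TranscriptModel]:
    """One transcript per gene: highest exon count, ties broken by the
    lexicographically smallest transcript id."""
    best: dict[str, TranscriptModel] = {}
    for tx in transcripts:
        cur = best.get(tx.gene_id)
        if cur is None or (len(tx.exons), ) > (len(cur.exons), ) or (
            len(tx.exons) == len(cur.exons) and tx.transcript_id < cur.transcript_id
        ):
            best[tx.gene_id] = tx
    return [best[g] for g in sorted(best)]


def class_te_matrix(
    profiles: pd.DataFrame,
    classes: pd.DataFrame,
    transcripts: list[TranscriptModel],
    value: str = "coverage",
) -> pd.DataFrame:
    """Localization class x repeat class matrix of mean fractional coverage.

    ``classes`` maps transcript_id -> loc_class. Only one representative
    transcript per gene (max exon count) contributes; transcripts with no
    insertion of a class contribute 0 to that class's mean. Cells of empty
    localization classes are NaN.
    """
    reps = {t.transcript_id for t in representative_transcripts(transcripts)}
    cls_map = classes.set_index("transcript_id")["loc_class"]
    members = cls_map[cls_map.index.isin(reps)]
    repeat_classes = sorted(profiles["repeat_class"].unique())
    loc_classes = sorted(members.unique())
    wide = (
        profiles.pivot_table(
            index="transcript_id", columns="repeat_class", values=value, fill_value=0.0
        )
        .reindex(index=members.index, columns=repeat_classes)
        .fillna(0.0)
    )
    out = pd.DataFrame(index=loc_classes, columns=repeat_classes, dtype=float)
    for loc in loc_classes:
        ids = members.index[members == loc]
        if len(ids) == 0:
            continue
        out.loc[loc] = wide.loc[ids].mean(axis=0)
    return out


def presence_enrichment(
    foreground: set[str], background: set[str], carriers: set[str]
) -> float:
    """Upper-tail hypergeometric p for over-representation of TE carriers
    in the foreground, drawn from the background."""
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")
    N = len(background)
    K = len(background & carriers)
    n = len(foreground)
    k = len(foreground & carriers)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def coverage_rank_test(
    group_a: np.ndarray, group_b: np.ndarray
) -> dict[str, float]:
    """Two-sided Wilcoxon rank-sum comparison of TE coverage (or insertion
    frequency) between two transcript groups; reports both group means."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    result = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "p_value": float(result.pvalue),
        "statistic": float(result.statistic),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
    }
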
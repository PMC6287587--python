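"""Phenetic similarity between taxa based on bone-contact codings.

Two contacts of the same bone pair are compared segment-wise.  Any
difference in the spatial relation makes them dissimilar; the ordinal
suture depth only makes them dissimilar when it differs by at least two
categories (a faintly interfingering clasping suture is similar to a
moderately interfingering one, but not to a strongly interfingering one).
The pairwise similarity of two taxa is the percentage of comparable bone
pairs whose contacts are similar.

Several aspects of the statistic are not fixed by the coding scheme itself
(what enters the denominator, how unknown depths and multi-segment
contacts are treated); these are made explicit in
:class:`SimilarityPolicy` so they can be varied in sensitivity analyses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .contacts import ContactRecord, ContactSegment, ContactTable

__all__ = [
    "SimilarityPolicy",
    "SimilarityMatrix",
    "DegenerateComparisonError",
    "segments_similar",
    "contacts_similar",
    "pairwise_similarity",
    "similarity_matrix",
    "rank_report",
]


class DegenerateComparisonError(ValueError):
    """Two taxa share no comparable bone pair."""


@dataclass(frozen=True)
class SimilarityPolicy:
    """Tunable rules of the contact-similarity statistic.

    depth_threshold
        Depth-category difference at which depth alone makes two segments
        dissimilar (default 2, i.e. a one-step difference is tolerated).
    unknown_depth
        ``treat_as_similar``: an unknown depth never causes dissimilarity
        (spatial relations still must match); ``exclude_pair``: any unknown
        depth renders the bone pair non-comparable.
    both_absent
        ``exclude``: a pair absent in both taxa is uninformative and leaves
        the denominator; ``count_similar``: shared absence counts as a
        similar pair.
    multi_segment
        ``sequence_exact``: anterior-to-posterior segment sequences must
        match position by position (and in number); ``multiset``: order is
        ignored, segments are matched one-to-one in any order.
    excluded_bones
        Contacts involving these bones are dropped entirely (default: the
        nasal, which occurs in only one study taxon).
    """

    depth_threshold: int = 2
    unknown_depth: str = "treat_as_similar"
    both_absent: str = "exclude"
    multi_segment: str = "sequence_exact"
    excluded_bones: frozenset = frozenset({"nasal"})
    rounding: str = "nearest_integer_percent"

    def __post_init__(self) -> None:
        if self.depth_threshold < 1:
            raise ValueError("depth_threshold must be >= 1")
        if self.unknown_depth not in ("treat_as_similar", "exclude_pair"):
            raise ValueError(f"bad unknown_depth: {self.unknown_depth!r}")
        if self.both_absent not in ("exclude", "count_similar"):
            raise ValueError(f"bad both_absent: {self.both_absent!r}")
        if self.multi_segment not in ("sequence_exact", "multiset"):
            raise ValueError(f"bad multi_segment: {self.multi_segment!r}")
        if self.rounding != "nearest_integer_percent":
            raise ValueError(f"bad rounding: {self.rounding!r}")
        object.__setattr__(self, "excluded_bones", frozenset(self.excluded_bones))


def segments_similar(a: ContactSegment, b: ContactSegment,
                     policy: SimilarityPolicy = SimilarityPolicy()) -> bool:
    """Segment-level similarity rule.

    False when the spatial codes differ, or when both depths are known and
    differ by at least ``policy.depth_threshold`` categories.  A segment
    with an unknown depth is never dissimilar on depth grounds here; the
    ``exclude_pair`` policy acts at the contact level instead.
    """
    if a.spatial != b.spatial:
        return False
    if a.depth.known and b.depth.known:
        if abs(a.depth.level - b.depth.level) >= policy.depth_threshold:
            return False
    return True


def _has_unknown_depth(rec: ContactRecord) -> bool:
    return any(not seg.depth.known for seg in rec.segments)


def _multiset_match(segs_a, segs_b, policy) -> bool:
    # one-to-one matching under the segment rule; n <= 4 so brute force
    if len(segs_a) != len(segs_b):
        return False
    for perm in itertools.permutations(range(len(segs_b))):
        if all(segments_similar(sa, segs_b[j], policy)
               for sa, j in zip(segs_a, perm)):
            return True
    return False


def contacts_similar(a: ContactRecord, b: ContactRecord,
                     policy: SimilarityPolicy = SimilarityPolicy()) -> str:
    """Compare two records of the same canonical bone pair.

    Returns ``"similar"``, ``"dissimilar"`` or ``"not_comparable"``.
    """
    if a.pair != b.pair:
        raise ValueError(f"bone-pair mismatch: {a.pair} vs {b.pair}")
    if a.status == "unknown" or b.status == "unknown":
        return "not_comparable"
    if a.status == "absent" and b.status == "absent":
        return "similar" if policy.both_absent == "count_similar" else "not_comparable"
    if a.status != b.status:
        return "dissimilar"
    # both present
    if policy.unknown_depth == "exclude_pair" and (
        _has_unknown_depth(a) or _has_unknown_depth(b)
    ):
        return "not_comparable"
    if policy.multi_segment == "multiset":
        ok = _multiset_match(a.segments, b.segments, policy)
    else:
        ok = len(a.segments) == len(b.segments) and all(
            segments_similar(sa, sb, policy)
            for sa, sb in zip(a.segments, b.segments)
        )
    return "similar" if ok else "dissimilar"


def _round_half_up_percent(n_similar: int, n_compared: int) -> int:
    return int(np.floor(100.0 * n_similar / n_compared + 0.5))


def pairwise_similarity(table: ContactTable, taxon_a: str, taxon_b: str,
                        policy: SimilarityPolicy = SimilarityPolicy()):
    """Percentage of comparable bone pairs that are similar between two taxa.

    Only pairs scored in both taxa enter; pairs touching an excluded bone
    and non-comparable pairs are removed from the denominator.  Returns
    ``(percent, n_compared, n_similar)``.
    """
    for t in (taxon_a, taxon_b):
        if t not in table.taxa:
            raise KeyError(f"taxon not in table: {t!r}")
    recs_a = table.pairs_for(taxon_a)
    recs_b = table.pairs_for(taxon_b)
    n_compared = n_similar = 0
    for pair in sorted(set(recs_a) & set(recs_b)):
        if policy.excluded_bones & set(pair):
            continue
        verdict = contacts_similar(recs_a[pair], recs_b[pair], policy)
        if verdict == "not_comparable":
            continue
        n_compared += 1
        if verdict == "similar":
            n_similar += 1
    if n_compared == 0:
        raise DegenerateComparisonError(
            f"no comparable bone pairs between {taxon_a!r} and {taxon_b!r}"
        )
    return _round_half_up_percent(n_similar, n_compared), n_compared, n_similar


@dataclass
class SimilarityMatrix:
    """Symmetric taxon-by-taxon percentage matrix with audit counts.

    ``values`` is a square float array with NaN on the diagonal (printed as
    a dash) and in any cell flagged as degenerate; ``counts`` maps the
    unordered taxon pair to ``(n_compared, n_similar)``.
    """

    taxa: list
    values: np.ndarray
    counts: dict = field(default_factory=dict)
    degenerate: list = field(default_factory=list)

    def __getitem__(self, pair) -> float:
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return float(self.values[i, j])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)


def similarity_matrix(table: ContactTable,
                      policy: SimilarityPolicy = SimilarityPolicy()) -> SimilarityMatrix:
    """All pairwise similarities of a contact table as a symmetric matrix."""
    taxa = list(table.taxa)
    if len(taxa) < 2:
        raise ValueError("similarity matrix requires at least two taxa")
    n = len(taxa)
    values = np.full((n, n), np.nan)
    counts: dict = {}
    degenerate = []
    for i, j in itertools.combinations(range(n), 2):
        try:
            pct, nc, ns = pairwise_similarity(table, taxa[i], taxa[j], policy)
        except DegenerateComparisonError:
            degenerate.append((taxa[i], taxa[j]))
            continue
        values[i, j] = values[j, i] = pct
        counts[frozenset((taxa[i], taxa[j]))] = (nc, ns)
    return SimilarityMatrix(taxa, values, counts, degenerate)


def rank_report(matrix: SimilarityMatrix, focal: str) -> list:
    """Other taxa ranked by descending similarity to ``focal``.

    Ties are broken alphabetically.  Degenerate (NaN) cells are omitted.
    """
    if focal not in matrix.taxa:
        raise KeyError(f"unknown focal taxon: {focal!r}")
    rows = []
    for other in matrix.taxa:
        if other == focal:
            continue
        val = matrix[focal, other]
        if np.isnan(val):
            continue
        rows.append((other, val))
    rows.sort(key=lambda item: (-item[1], item[0]))
    return rows
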
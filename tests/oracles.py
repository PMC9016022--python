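"""Independent reference implementations used only to check the package.

These deliberately do not import the implementation modules they verify:
the score oracle is a line-by-line transcription of the published
spreadsheet expression, and the clustering oracle is a naive O(n^3)
agglomeration working directly on the definition of complete linkage.
"""

from __future__ import annotations

import itertools
import math


def excel_total(lines_1_14, line15, line16, line17, line18, line19, line20, line21):
    """Direct transcription of the spreadsheet expression for the total."""
    organ = sum(lines_1_14)
    hosp = line16 * 0.1 if line16 < 40 else 4
    icu = line17 * 0.8 if line17 < 10 else 8
    supportive = line18 + line19 + line20 + line21
    mult = 150 / line15 if line15 > 29 else 6
    return (organ + hosp + icu + supportive) * mult


def record_excel_total(record):
    """Evaluate the spreadsheet oracle on a VisitRecord (no missing items)."""
    igg_points = {"none": 0, "sporadic": 2, "iv": 3, "sc": 3}
    return excel_total(
        record.organ_grades,
        record.performance_scale,
        record.hospital_days_per_100,
        record.icu_days_per_100,
        igg_points[record.igg_substitution.value],
        record.chronic_infestation,
        record.other_organ_dysfunction,
        record.nutrition_status,
    )


def naive_complete_linkage(points):
    """Agglomerate by brute force; complete linkage, Euclidean distances.

    ``points`` is a sequence of coordinate sequences. Returns the merge
    list [(frozenset_a, frozenset_b, height), ...] of leaf-index sets in
    merge order; ties broken by the lexicographically smallest pair of
    cluster member sets.
    """

    def dist(a, b):
        return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))

    clusters = [frozenset([i]) for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for ci, cj in itertools.combinations(sorted(clusters, key=sorted), 2):
            h = max(dist(points[i], points[j]) for i in ci for j in cj)
            key = (h, sorted(ci), sorted(cj))
            if best is None or key < best[0]:
                best = (key, ci, cj)
        (h, _, _), ci, cj = best
        clusters.remove(ci)
        clusters.remove(cj)
        clusters.append(ci | cj)
        merges.append((ci, cj, h))
    return merges


def linkage_to_merges(Z):
    """Convert a SciPy linkage matrix to the oracle's merge-list form."""
    n = Z.shape[0] + 1
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for k, (a, b, h, _size) in enumerate(Z):
        ca, cb = members[int(a)], members[int(b)]
        merges.append((ca, cb, float(h)))
        members[n + k] = ca | cb
    return merges


def same_merges(merges_a, merges_b, tol=1e-9):
    """Compare merge sequences ignoring within-pair order."""
    if len(merges_a) != len(merges_b):
        return False
    for (a1, a2, ha), (b1, b2, hb) in zip(merges_a, merges_b):
        if {a1, a2} != {b1, b2} or abs(ha - hb) > tol * max(1.0, abs(ha)):
            return False
    return True
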
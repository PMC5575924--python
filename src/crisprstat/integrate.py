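"""Filtering, operon-array association, and strand segregation.

The association step implements the closest-array rule: for each cas operon,
base-pair distances to every array on the same replicon are computed and the
minimizer becomes the system's proximal array, under the assumption that
each set of cas genes is associated with exactly one CRISPR.

Distance conventions (documented against 1-based inclusive coordinates):
overlapping intervals have distance 0; otherwise the distance is the gap
between the nearest interval ends, e.g. an operon ending at 200 and an array
starting at 300 are 100 bp apart.  Distance is linear along the replicon —
no wrap across the origin.  Equidistant arrays tie-break on smaller start
coordinate, which makes the assignment deterministic.
"""
from __future__ import annotations

from collections import defaultdict
from typing import Dict, List, Sequence, Tuple

from .records import ArrayRecord, CasOperon, FilterCriteria, IntegratedSystem


def interval_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between two 1-based inclusive intervals; 0 if they overlap."""
    if a_start > a_end or b_start > b_end:
        raise ValueError("interval start must not exceed end")
    if a_end < b_start:
        return b_start - a_end
    if b_end < a_start:
        return a_start - b_end
    return 0


def filter_dataset(
    arrays: Sequence[ArrayRecord],
    operons: Sequence[CasOperon],
    criteria: FilterCriteria = FilterCriteria(),
) -> Tuple[List[ArrayRecord], List[CasOperon]]:
    """Apply the inclusion rules to both tables; order preserved.

    Arrays on disallowed replicon kinds (plasmids, by default) are dropped,
    as are questionable structures when requested.  Operons outside the
    allowed class/type sets, and operons without a cas1 anchor when
    ``require_cas1``, are dropped.  Empty outputs are legal.
    """
    kept_arrays = [
        a
        for a in arrays
        if a.replicon_kind in criteria.allow_replicon_kinds
        and not (criteria.exclude_questionable and a.questionable)
    ]
    kept_operons = [
        o
        for o in operons
        if o.system_class in criteria.allowed_classes
        and o.system_type in criteria.allowed_types
        and (o.has_cas1 or not criteria.require_cas1)
    ]
    return kept_arrays, kept_operons


def _distance_to_operon(op: CasOperon, arr: ArrayRecord) -> int:
    return interval_distance(
        op.operon_start_bp, op.operon_end_bp, arr.start_bp, arr.end_bp
    )


def associate_arrays(
    operons: Sequence[CasOperon],
    arrays: Sequence[ArrayRecord],
) -> Tuple[List[IntegratedSystem], List[CasOperon]]:
    """Join each operon to the closest array on its replicon.

    Returns ``(systems, unpaired)``: operons whose accession carries no
    array are not silently dropped but reported in the second list.
    Within each system, trans arrays are sorted by increasing distance,
    ties by smaller start coordinate.
    """
    by_accession: Dict[str, List[ArrayRecord]] = defaultdict(list)
    for arr in arrays:
        by_accession[arr.accession].append(arr)

    systems: List[IntegratedSystem] = []
    unpaired: List[CasOperon] = []
    for op in operons:
        candidates = by_accession.get(op.accession, [])
        if not candidates:
            unpaired.append(op)
            continue
        ranked = sorted(
            ((_distance_to_operon(op, a), a.start_bp, a) for a in candidates),
            key=lambda t: (t[0], t[1]),
        )
        dist, _, proximal = ranked[0]
        trans = tuple((a, d) for d, _, a in ranked[1:])
        systems.append(
            IntegratedSystem(
                operon=op,
                proximal_array=proximal,
                distance_bp=dist,
                trans_arrays=trans,
            )
        )
    return systems, unpaired


def segregate_by_strand(
    systems: Sequence[IntegratedSystem],
) -> Dict[str, List[IntegratedSystem]]:
    """Partition systems by the proximal array's strand.

    Returns a mapping with keys "+", "-" and "?"; unknown-strand systems
    land in the "?" bucket and are excluded from strand-specific tests.
    """
    buckets: Dict[str, List[IntegratedSystem]] = {"+": [], "-": [], "?": []}
    for s in systems:
        buckets[s.proximal_array.strand].append(s)
    return buckets


def cas_less_arrays(
    arrays: Sequence[ArrayRecord], operons: Sequence[CasOperon]
) -> List[ArrayRecord]:
    """Arrays on replicons with no classified cas operon at all.

    These are candidate inactive loci: a repeat-spacer array persists even
    when no cas machinery is annotated on the replicon.
    """
    with_cas = {o.accession for o in operons}
    return [a for a in arrays if a.accession not in with_cas]
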